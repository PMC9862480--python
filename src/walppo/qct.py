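"""Density-mask quantification of well-aerated lung (WAL) and low-attenuation
areas (LAA) from a CT volume plus a lobe label map.

The density mask is the classic HU-window threshold applied to a segmented
lung: well-aerated lung is the volume with attenuation in the closed window
[-950, -750] HU, and low-attenuation areas (the emphysema surrogate) are the
voxels strictly below -950 HU, so the -950 HU voxel is counted exactly once,
as WAL.  All aggregation is done on exact integer voxel counts; volumes in
liters are counts times the voxel volume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    SegmentationError,
    ShapeMismatchError,
    UnknownLabelError,
    ValidationError,
)

HU_MIN = -1024
HU_MAX = 3071

#: lobe label convention shared across the package (0 = background)
LOBE_LABELS = {1: "RUL", 2: "RML", 3: "RLL", 4: "LUL", 5: "LLL"}
LOBE_NAMES = tuple(LOBE_LABELS.values())

#: default density-mask settings: WAL window and LAA threshold in HU
DEFAULT_WAL_WINDOW = (-950, -750)
DEFAULT_LAA_THRESHOLD = -950


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3:
        raise ValidationError(f"spacing must have 3 components, got {spacing}")
    if any(not math.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield units with voxel spacing in millimeters.

    ``values`` is stored as a signed-integer array; the affine (RAS) is kept
    so volumes survive a NIfTI round trip bit-identically.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"CT volume must be 3D, got {self.values.ndim}D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValidationError("CT values must be integer HU")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        vmin, vmax = int(self.values.min()), int(self.values.max())
        if vmin < HU_MIN or vmax > HU_MAX:
            raise ValidationError(
                f"HU outside physical range [{HU_MIN}, {HU_MAX}]: [{vmin}, {vmax}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_l(self) -> float:
        return voxel_volume_liters(self.spacing_mm)


@dataclass
class LobeLabelMap:
    """Integer lobe assignment per voxel: 0 background, 1..5 = RUL, RML, RLL, LUL, LLL."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"label map must be 3D, got {self.values.ndim}D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValidationError("lobe labels must be integers")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        bad = set(np.unique(self.values)) - {0, 1, 2, 3, 4, 5}
        if bad:
            raise UnknownLabelError(f"unknown lobe labels {sorted(bad)}; allowed 0..5")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def lung_mask(self) -> np.ndarray:
        return self.values > 0


@dataclass(frozen=True)
class HUWindow:
    """Closed HU interval [lo, hi]; both boundary voxels are counted."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lo) & (values <= self.hi)


def voxel_volume_liters(spacing_mm) -> float:
    """Volume of one voxel in liters (product of edge lengths, mm^3 -> L)."""
    sx, sy, sz = _as_spacing(spacing_mm)
    return sx * sy * sz * 1e-6


def noise_reduce(ct: CTVolume, radius: int = 1) -> CTVolume:
    """3D median filter with cubic kernel of half-width ``radius``.

    ``radius=0`` is the identity.  Median filtering never leaves the input HU
    range, so density-mask boundary conventions are preserved.
    """
    radius = int(radius)
    if radius < 0:
        raise ValidationError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return ct
    filtered = ndimage.median_filter(ct.values, size=2 * radius + 1, mode="nearest")
    return CTVolume(filtered.astype(ct.values.dtype), ct.spacing_mm, ct.affine)


def segment_lungs(ct: CTVolume, air_threshold: int = -300) -> np.ndarray:
    """Threshold-based lung segmentation: HU below ``air_threshold`` inside the
    body, keeping the two largest 26-connected components.

    Components touching the volume boundary are treated as the background air
    shell and discarded.  If only one lung-like component remains (e.g. a
    pneumonectomy phantom) it is returned with a warning; zero components is a
    :class:`SegmentationError`.
    """
    import logging

    candidate = ct.values < air_threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(candidate, structure=structure)
    if n == 0:
        raise SegmentationError("no voxels below the air threshold")

    border = np.zeros(ct.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = set(np.unique(labeled[border])) - {0}

    counts = np.bincount(labeled.ravel())
    interior = [(counts[lab], lab) for lab in range(1, n + 1) if lab not in touching]
    if not interior:
        raise SegmentationError(
            "no interior air component found (volume may contain no lung)"
        )
    interior.sort(reverse=True)
    if len(interior) == 1:
        logging.getLogger(__name__).warning(
            "only one lung component found; returning a single-lung mask"
        )
    keep = [lab for _, lab in interior[:2]]
    return np.isin(labeled, keep)


def density_mask(
    ct: CTVolume, mask: np.ndarray, window: HUWindow
) -> tuple[int, float]:
    """Count voxels inside ``mask`` whose HU lies in the closed ``window``.

    Returns ``(count, volume_liters)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.shape:
        raise ShapeMismatchError(f"mask shape {mask.shape} != volume shape {ct.shape}")
    count = int(np.count_nonzero(window.contains(ct.values) & mask))
    return count, count * ct.voxel_volume_l


@dataclass
class LobeQuantification:
    """Voxel counts and derived volumes for one lobe (or the whole lung)."""

    total_voxels: int
    wal_voxels: int
    laa_voxels: int
    voxel_volume_l: float

    @property
    def total_l(self) -> float:
        return self.total_voxels * self.voxel_volume_l

    @property
    def wal_l(self) -> float:
        return self.wal_voxels * self.voxel_volume_l

    @property
    def laa_l(self) -> float:
        return self.laa_voxels * self.voxel_volume_l


@dataclass
class DensityMaskResult:
    """Per-lobe and whole-lung WAL/LAA quantification.

    Whole-lung numbers are exact sums of the per-lobe integer voxel counts.
    ``pct_laa`` is the LAA share of whole-lung volume in percent.
    """

    per_lobe: dict[str, LobeQuantification]
    wal_window: HUWindow
    laa_threshold: int
    voxel_volume_l: float
    noise_radius: int = 0

    @property
    def whole_lung(self) -> LobeQuantification:
        return LobeQuantification(
            total_voxels=sum(q.total_voxels for q in self.per_lobe.values()),
            wal_voxels=sum(q.wal_voxels for q in self.per_lobe.values()),
            laa_voxels=sum(q.laa_voxels for q in self.per_lobe.values()),
            voxel_volume_l=self.voxel_volume_l,
        )

    @property
    def pct_laa(self) -> float:
        whole = self.whole_lung
        return 100.0 * whole.laa_voxels / whole.total_voxels

    def wal_liters(self, lobe: str) -> float:
        return self.per_lobe[lobe].wal_l

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, q in [*self.per_lobe.items(), ("whole_lung", self.whole_lung)]:
            rows.append(
                {
                    "region": name,
                    "total_voxels": q.total_voxels,
                    "wal_voxels": q.wal_voxels,
                    "laa_voxels": q.laa_voxels,
                    "total_l": round(q.total_l, 4),
                    "wal_l": round(q.wal_l, 4),
                    "laa_l": round(q.laa_l, 4),
                }
            )
        frame = pd.DataFrame(rows)
        frame.loc[frame["region"] == "whole_lung", "pct_laa"] = round(self.pct_laa, 4)
        return frame

    def to_dict(self) -> dict:
        whole = self.whole_lung
        return {
            "wal_window_hu": [self.wal_window.lo, self.wal_window.hi],
            "laa_threshold_hu": self.laa_threshold,
            "noise_radius": self.noise_radius,
            "voxel_volume_l": self.voxel_volume_l,
            "per_lobe": {
                name: {
                    "total_voxels": q.total_voxels,
                    "wal_voxels": q.wal_voxels,
                    "laa_voxels": q.laa_voxels,
                    "total_l": round(q.total_l, 4),
                    "wal_l": round(q.wal_l, 4),
                    "laa_l": round(q.laa_l, 4),
                }
                for name, q in self.per_lobe.items()
            },
            "whole_lung": {
                "total_voxels": whole.total_voxels,
                "wal_voxels": whole.wal_voxels,
                "laa_voxels": whole.laa_voxels,
                "total_l": round(whole.total_l, 4),
                "wal_l": round(whole.wal_l, 4),
                "laa_l": round(whole.laa_l, 4),
                "pct_laa": round(self.pct_laa, 4),
            },
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def quantify_lobes(
    ct: CTVolume,
    lobes: LobeLabelMap,
    wal_window: HUWindow | tuple[int, int] = DEFAULT_WAL_WINDOW,
    laa_threshold: int = DEFAULT_LAA_THRESHOLD,
    noise_radius: int = 0,
) -> DensityMaskResult:
    """Quantify WAL and LAA per lobe and for the whole lung.

    WAL uses the closed window (default [-950, -750] HU) via :func:`density_mask`
    per lobe label; LAA counts voxels strictly below ``laa_threshold`` (default
    -950 HU).  ``noise_radius > 0`` applies :func:`noise_reduce` first.
    """
    if not isinstance(wal_window, HUWindow):
        wal_window = HUWindow(*wal_window)
    if lobes.shape != ct.shape:
        raise ShapeMismatchError(
            f"lobe map shape {lobes.shape} != volume shape {ct.shape}"
        )
    if not np.any(lobes.values > 0):
        raise ValidationError("lobe label map is all background")

    ct = noise_reduce(ct, noise_radius)
    values = ct.values
    vox_l = ct.voxel_volume_l
    per_lobe: dict[str, LobeQuantification] = {}
    for label, name in LOBE_LABELS.items():
        region = lobes.values == label
        total = int(np.count_nonzero(region))
        wal = int(np.count_nonzero(region & wal_window.contains(values)))
        laa = int(np.count_nonzero(region & (values < laa_threshold)))
        per_lobe[name] = LobeQuantification(total, wal, laa, vox_l)

    return DensityMaskResult(
        per_lobe=per_lobe,
        wal_window=wal_window,
        laa_threshold=int(laa_threshold),
        voxel_volume_l=vox_l,
        noise_radius=int(noise_radius),
    )
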