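"""Synthetic thoracic CT phantoms with known per-lobe density composition.

The phantom is two ellipsoidal "lungs" inside an ellipsoidal soft-tissue body,
surrounded by background air.  The right lung is split into three axial slabs
(RUL on top, then RML, RLL) and the left into two (LUL, LLL), which guarantees
five disjoint, nonempty lobe regions; anatomical fidelity is deliberately not
attempted, because only the density-mask arithmetic downstream is under test.

Each lobe's voxels are partitioned *exactly* (floor allocation, remainder to
the well-aerated compartment) into three HU compartments that mirror the
density-mask windows:

* ``emphysema``     — HU strictly below -950 (counted as LAA),
* ``wal``           — HU in the closed window [-950, -750],
* ``nonaerated``    — HU strictly above -750.

HU values are drawn from per-compartment normal distributions, rounded to
integers, then clipped into the compartment's interval, so every voxel is
guaranteed to land in its compartment even after int16 casting.  The realized
voxel counts are recorded in :class:`PhantomTruth`, which is therefore an
*exact* ground truth for :func:`walppo.qct.quantify_lobes`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .qct import CTVolume, LobeLabelMap, LOBE_LABELS, LOBE_NAMES, voxel_volume_liters

COMPARTMENTS = ("emphysema", "wal", "nonaerated")

#: integer HU interval per compartment (inclusive ends); chosen so that
#: emphysema < -950, wal in [-950, -750], non-aerated > -750 but still below
#: the -300 HU lung-segmentation threshold.
COMPARTMENT_HU_RANGE = {
    "emphysema": (-1024, -951),
    "wal": (-950, -750),
    "nonaerated": (-749, -400),
}

#: default normal (mean, sd) per compartment, in HU
DEFAULT_HU_PARAMS = {
    "emphysema": (-980.0, 15.0),
    "wal": (-860.0, 40.0),
    "nonaerated": (-600.0, 60.0),
}


def sample_lobe_hu(compartment: str, params, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` integer HU values for one compartment.

    Values are normal draws (``params = (mean, sd)``) rounded to integers and
    clipped into the compartment's interval, so the boundary contract holds
    for every returned value.  ``seed`` may be an int or a Generator.
    """
    if compartment not in COMPARTMENT_HU_RANGE:
        raise ValidationError(
            f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}"
        )
    n = int(n)
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    mean, sd = params
    if sd < 0:
        raise ValidationError(f"sd must be >= 0, got {sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = COMPARTMENT_HU_RANGE[compartment]
    draws = np.rint(rng.normal(mean, sd, size=n))
    return np.clip(draws, lo, hi).astype(np.int16)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom: grid, spacing, per-lobe composition, seed.

    ``fractions`` maps each lobe to ``(f_emphysema, f_wal, f_nonaerated)``
    summing to 1; ``hu_params`` maps each lobe to per-compartment
    ``(mean, sd)`` in HU.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fractions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {lobe: (0.0, 1.0, 0.0) for lobe in LOBE_NAMES}
    )
    hu_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {lobe: dict(DEFAULT_HU_PARAMS) for lobe in LOBE_NAMES}
    )
    body_hu: int = 40
    background_hu: int = -1000
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise GeometryError(
                f"grid_shape must be 3 axes of >= 16 voxels, got {self.grid_shape}"
            )
        object.__setattr__(self, "grid_shape", shape)
        if set(self.fractions) != set(LOBE_NAMES):
            raise ValidationError(
                f"fractions must cover exactly the lobes {LOBE_NAMES}"
            )
        for lobe, fracs in self.fractions.items():
            if len(fracs) != 3 or any(f < 0 for f in fracs):
                raise ValidationError(f"{lobe}: fractions must be 3 nonnegative values")
            if not math.isclose(sum(fracs), 1.0, abs_tol=1e-12):
                raise ValidationError(
                    f"{lobe}: fractions must sum to 1 (got {sum(fracs)!r})"
                )

    def with_uniform_fractions(self, f_emph: float, f_wal: float, f_nonaer: float):
        return replace(
            self, fractions={lobe: (f_emph, f_wal, f_nonaer) for lobe in LOBE_NAMES}
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Exact realized composition of a phantom.

    Every volume equals an integer voxel count times the voxel volume, and
    whole-lung values are exact sums over lobes.
    """

    counts: dict[str, dict[str, int]]  # lobe -> compartment -> voxels
    voxel_volume_l: float

    def lobe_voxels(self, lobe: str) -> int:
        return sum(self.counts[lobe].values())

    def wal_voxels(self, lobe: str) -> int:
        return self.counts[lobe]["wal"]

    def laa_voxels(self, lobe: str) -> int:
        return self.counts[lobe]["emphysema"]

    def wal_liters(self, lobe: str) -> float:
        return self.wal_voxels(lobe) * self.voxel_volume_l

    def laa_liters(self, lobe: str) -> float:
        return self.laa_voxels(lobe) * self.voxel_volume_l

    @property
    def total_voxels(self) -> int:
        return sum(self.lobe_voxels(lobe) for lobe in self.counts)

    @property
    def total_wal_voxels(self) -> int:
        return sum(self.wal_voxels(lobe) for lobe in self.counts)

    @property
    def total_laa_voxels(self) -> int:
        return sum(self.laa_voxels(lobe) for lobe in self.counts)

    @property
    def total_wal_l(self) -> float:
        return self.total_wal_voxels * self.voxel_volume_l

    @property
    def total_laa_l(self) -> float:
        return self.total_laa_voxels * self.voxel_volume_l

    @property
    def total_lung_l(self) -> float:
        return self.total_voxels * self.voxel_volume_l

    @property
    def pct_laa(self) -> float:
        return 100.0 * self.total_laa_voxels / self.total_voxels

    def to_dict(self) -> dict:
        return {
            "voxel_volume_l": self.voxel_volume_l,
            "counts": self.counts,
            "whole_lung": {
                "total_voxels": self.total_voxels,
                "wal_voxels": self.total_wal_voxels,
                "laa_voxels": self.total_laa_voxels,
                "wal_l": self.total_wal_l,
                "laa_l": self.total_laa_l,
                "pct_laa": self.pct_laa,
            },
        }


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_lobe_labels(grid_shape) -> np.ndarray:
    """Lobe label geometry: two ellipsoidal lungs, axially slabbed into lobes.

    Right lung (low x, labels 1-3: RUL/RML/RLL top to bottom), left lung
    (high x, labels 4-5: LUL/LLL).  Superior = high z (RAS convention).
    """
    sx, sy, sz = grid_shape
    center = ((sx - 1) / 2, (sy - 1) / 2, (sz - 1) / 2)
    lung_axes = (0.16 * sx, 0.30 * sy, 0.38 * sz)
    offset = 0.22 * sx
    right = _ellipsoid(grid_shape, (center[0] - offset, center[1], center[2]), lung_axes)
    left = _ellipsoid(grid_shape, (center[0] + offset, center[1], center[2]), lung_axes)
    if not right.any() or not left.any() or (right & left).any():
        raise GeometryError("cannot place two disjoint lungs on this grid")

    labels = np.zeros(grid_shape, dtype=np.int16)

    def slab_split(lung_mask: np.ndarray, lobe_labels: list[int]) -> None:
        zs = np.nonzero(lung_mask)[2]
        # contiguous z-slabs with roughly equal voxel counts; superior first
        edges = np.quantile(zs, np.linspace(1, 0, len(lobe_labels) + 1))
        z = np.arange(lung_mask.shape[2])
        assigned = np.zeros(lung_mask.shape[2], dtype=np.int16)
        for i, lab in enumerate(lobe_labels):
            lo, hi = edges[i + 1], edges[i]
            sel = (z <= hi) & (z > lo) if i < len(lobe_labels) - 1 else (z <= hi)
            assigned[sel & (assigned == 0).astype(bool)] = lab
        labels[lung_mask] = assigned[np.nonzero(lung_mask)[2]]

    slab_split(right, [1, 2, 3])  # RUL, RML, RLL
    slab_split(left, [4, 5])  # LUL, LLL

    for label, name in LOBE_LABELS.items():
        if not np.any(labels == label):
            raise GeometryError(f"grid too small: lobe {name} is empty")
    return labels


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, LobeLabelMap, PhantomTruth]:
    """Generate a phantom CT, its lobe label map and exact composition truth.

    Deterministic under ``spec.seed``.  Compartment assignment uses an exact
    partition of each lobe's (shuffled) voxel list: ``floor(f * n)`` voxels to
    emphysema and non-aerated tissue, the remainder to WAL.
    """
    rng = np.random.default_rng(spec.seed)
    labels = make_lobe_labels(spec.grid_shape)

    volume = np.full(spec.grid_shape, spec.background_hu, dtype=np.int16)
    body_axes = tuple(0.45 * s for s in spec.grid_shape)
    center = tuple((s - 1) / 2 for s in spec.grid_shape)
    body = _ellipsoid(spec.grid_shape, center, body_axes)
    # guarantee a closed soft-tissue shell around the lungs so that threshold
    # segmentation can never leak (26-)diagonally into the background air
    shell = ndimage.binary_dilation(labels > 0, structure=np.ones((3, 3, 3), bool))
    volume[body | shell] = spec.body_hu

    vox_l = voxel_volume_liters(spec.spacing_mm)
    counts: dict[str, dict[str, int]] = {}
    flat = volume.reshape(-1)
    flat_labels = labels.reshape(-1)
    for label, name in LOBE_LABELS.items():
        idx = np.flatnonzero(flat_labels == label)
        rng.shuffle(idx)
        n = idx.size
        f_emph, f_wal, f_nonaer = spec.fractions[name]
        n_emph = math.floor(f_emph * n)
        n_nonaer = math.floor(f_nonaer * n)
        if n_emph + n_nonaer > n:  # only via float pathologies
            n_nonaer = n - n_emph
        n_wal = n - n_emph - n_nonaer
        parts = {
            "emphysema": idx[:n_emph],
            "nonaerated": idx[n_emph : n_emph + n_nonaer],
            "wal": idx[n_emph + n_nonaer :],
        }
        for comp in COMPARTMENTS:
            part = parts[comp]
            flat[part] = sample_lobe_hu(comp, spec.hu_params[name][comp], part.size, rng)
        counts[name] = {"emphysema": n_emph, "wal": n_wal, "nonaerated": n_nonaer}

    ct = CTVolume(volume, spec.spacing_mm)
    lobe_map = LobeLabelMap(labels, spec.spacing_mm)
    truth = PhantomTruth(counts=counts, voxel_volume_l=vox_l)
    return ct, lobe_map, truth
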