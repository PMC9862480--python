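"""Simulated surgical cohorts for exercising the prediction/agreement pipeline.

The generator draws preoperative lung function and per-lobe well-aerated-lung
(WAL) volumes from log-normal distributions whose medians and spreads mimic a
typical early-stage lung-cancer resection cohort (n = 40; pre-FEV1 median
2.33 L, IQR 1.68-2.76 L; %DLCO median 71%; total WAL around 4.8 L with the
upper lobes near 1.2 L each), resection sites with upper-lobe predominance
(RUL 45%, LUL 27%, RLL 12%, LLL 16%, none in the middle lobe) and a 22%
segmentectomy rate.

Measured postoperative values are generated from the WAL-ratio prediction
with multiplicative log-normal noise::

    post = wal_ppo(pre, WAL_lobe, WAL_total) * exp(eps),  eps ~ N(0, sigma^2)

so the generative truth *is* the WAL formula: at ``sigma = 0`` the pipeline
closes exactly (measured equals predicted), and ``sigma`` is the single knob
controlling how well the two agree.  FEV1 in liters and in % predicted share
one noise draw (they are the same measurement on two scales); %DLCO gets an
independent draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ppo import segments_for_lobe, wal_ppo

LOBE_ORDER = ("RUL", "RML", "RLL", "LUL", "LLL")

#: fixed cohort CSV schema (order matters; round-trips byte-identically)
COHORT_COLUMNS = (
    "id",
    "pre_fev1_l",
    "pre_fev1_pct",
    "pre_dlco_pct",
    "wal_rul_l",
    "wal_rml_l",
    "wal_rll_l",
    "wal_lul_l",
    "wal_lll_l",
    "wal_total_l",
    "resected_lobe",
    "segments_resected",
    "post_fev1_l",
    "post_fev1_pct",
    "post_dlco_pct",
)


def _lognorm_sigma(q25: float, q75: float) -> float:
    # spread of ln X from the printed IQR: s = ln(q75/q25) / (2 * z_0.75)
    return math.log(q75 / q25) / (2 * 0.6744897501960817)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator parameters.

    Medians/spreads are log-normal parameters on the natural scale: a value X
    is drawn as ``median * exp(s * Z)``.  Defaults target the marginals
    described in the module docstring.
    """

    n_patients: int = 40
    fev1_median_l: float = 2.33
    fev1_log_sd: float = _lognorm_sigma(1.68, 2.76)
    fev1_pct_median: float = 85.0
    fev1_pct_log_sd: float = _lognorm_sigma(67.0, 101.0)
    dlco_median_pct: float = 71.0
    dlco_log_sd: float = _lognorm_sigma(58.0, 83.0)
    lobe_probs: dict[str, float] = field(
        default_factory=lambda: {
            "RUL": 0.45,
            "LUL": 0.27,
            "RLL": 0.12,
            "LLL": 0.16,
            "RML": 0.0,
        }
    )
    segmentectomy_prob: float = 0.225
    wal_median_l: dict[str, float] = field(
        default_factory=lambda: {
            "RUL": 1.20,
            "LUL": 1.20,
            "RML": 0.45,
            "RLL": 1.42,
            "LLL": 1.32,
        }
    )
    wal_log_sd: dict[str, float] = field(
        default_factory=lambda: {
            "RUL": _lognorm_sigma(1.08, 1.33),
            "LUL": _lognorm_sigma(1.06, 1.35),
            "RML": _lognorm_sigma(0.39, 0.57),
            "RLL": _lognorm_sigma(1.11, 1.58),
            "LLL": _lognorm_sigma(1.12, 1.51),
        }
    )
    sigma: float = 0.12  # log-scale sd of post-op noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError(f"n_patients must be >= 2, got {self.n_patients}")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        total = sum(self.lobe_probs.values())
        if set(self.lobe_probs) != set(LOBE_ORDER) or not math.isclose(
            total, 1.0, abs_tol=1e-9
        ):
            raise ValidationError(
                f"lobe_probs must cover {LOBE_ORDER} and sum to 1, got {self.lobe_probs}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: preoperative function, WAL volumes, resection, outcome."""

    id: str
    pre_fev1_l: float
    pre_fev1_pct: float
    pre_dlco_pct: float
    wal_per_lobe_l: dict[str, float]
    wal_total_l: float
    resected_lobe: str
    segments_resected: int
    post_fev1_l: float
    post_fev1_pct: float
    post_dlco_pct: float

    def __post_init__(self) -> None:
        if set(self.wal_per_lobe_l) != set(LOBE_ORDER):
            raise ValidationError(f"WAL volumes must cover lobes {LOBE_ORDER}")
        if not math.isclose(
            self.wal_total_l, sum(self.wal_per_lobe_l.values()), abs_tol=1e-9
        ):
            raise ValidationError("whole-lung WAL must equal the sum over lobes")
        n_seg = segments_for_lobe(self.resected_lobe)
        if not 1 <= self.segments_resected <= n_seg:
            raise ValidationError(
                f"segments_resected must be in [1, {n_seg}] for {self.resected_lobe}"
            )
        positives = (
            self.pre_fev1_l,
            self.pre_fev1_pct,
            self.pre_dlco_pct,
            self.post_fev1_l,
            self.post_fev1_pct,
            self.post_dlco_pct,
            *self.wal_per_lobe_l.values(),
        )
        if any(not v > 0 for v in positives):
            raise ValidationError(f"all volumes and PFT values must be > 0 ({self.id})")

    def wal_lobe_l(self, lobe: str) -> float:
        return self.wal_per_lobe_l[lobe]

    @property
    def is_segmentectomy(self) -> bool:
        return self.segments_resected < segments_for_lobe(self.resected_lobe)


def make_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lobes = list(LOBE_ORDER)
    probs = [spec.lobe_probs[lobe] for lobe in lobes]
    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        pre_fev1 = spec.fev1_median_l * math.exp(spec.fev1_log_sd * rng.standard_normal())
        pre_fev1_pct = spec.fev1_pct_median * math.exp(
            spec.fev1_pct_log_sd * rng.standard_normal()
        )
        pre_dlco = spec.dlco_median_pct * math.exp(
            spec.dlco_log_sd * rng.standard_normal()
        )
        wal = {
            lobe: spec.wal_median_l[lobe]
            * math.exp(spec.wal_log_sd[lobe] * rng.standard_normal())
            for lobe in lobes
        }
        wal_total = sum(wal.values())

        resected = rng.choice(lobes, p=probs)
        n_seg = segments_for_lobe(resected)
        if rng.random() < spec.segmentectomy_prob:
            # typical/atypical segmentectomies take one or two segments
            s = int(rng.integers(1, min(2, n_seg - 1) + 1))
        else:
            s = n_seg

        eff_lobe_wal = wal[resected] * (s / n_seg)
        eps_fev1 = spec.sigma * rng.standard_normal()
        eps_dlco = spec.sigma * rng.standard_normal()
        post_fev1 = wal_ppo(pre_fev1, eff_lobe_wal, wal_total) * math.exp(eps_fev1)
        post_fev1_pct = wal_ppo(pre_fev1_pct, eff_lobe_wal, wal_total) * math.exp(
            eps_fev1
        )
        post_dlco = wal_ppo(pre_dlco, eff_lobe_wal, wal_total) * math.exp(eps_dlco)

        records.append(
            PatientRecord(
                id=f"P{i + 1:04d}",
                pre_fev1_l=pre_fev1,
                pre_fev1_pct=pre_fev1_pct,
                pre_dlco_pct=pre_dlco,
                wal_per_lobe_l=wal,
                wal_total_l=wal_total,
                resected_lobe=str(resected),
                segments_resected=s,
                post_fev1_l=post_fev1,
                post_fev1_pct=post_fev1_pct,
                post_dlco_pct=post_dlco,
            )
        )
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "pre_fev1_l": r.pre_fev1_l,
                "pre_fev1_pct": r.pre_fev1_pct,
                "pre_dlco_pct": r.pre_dlco_pct,
                **{f"wal_{lobe.lower()}_l": r.wal_per_lobe_l[lobe] for lobe in LOBE_ORDER},
                "wal_total_l": r.wal_total_l,
                "resected_lobe": r.resected_lobe,
                "segments_resected": r.segments_resected,
                "post_fev1_l": r.post_fev1_l,
                "post_fev1_pct": r.post_fev1_pct,
                "post_dlco_pct": r.post_dlco_pct,
            }
        )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            PatientRecord(
                id=str(row["id"]),
                pre_fev1_l=float(row["pre_fev1_l"]),
                pre_fev1_pct=float(row["pre_fev1_pct"]),
                pre_dlco_pct=float(row["pre_dlco_pct"]),
                wal_per_lobe_l={
                    lobe: float(row[f"wal_{lobe.lower()}_l"]) for lobe in LOBE_ORDER
                },
                wal_total_l=float(row["wal_total_l"]),
                resected_lobe=str(row["resected_lobe"]),
                segments_resected=int(row["segments_resected"]),
                post_fev1_l=float(row["post_fev1_l"]),
                post_fev1_pct=float(row["post_fev1_pct"]),
                post_dlco_pct=float(row["post_dlco_pct"]),
            )
        )
    return records


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    # default float formatting round-trips exactly, keeping the
    # whole-lung-equals-sum-of-lobes invariant intact across write/read
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    # round_trip parsing keeps write->read bit-exact, which the sigma=0
    # closure property relies on
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))
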