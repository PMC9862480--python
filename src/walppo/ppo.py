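"""Predicted postoperative (ppo) lung function after lobectomy/segmentectomy.

Two estimators of residual function are provided, both scaling the
preoperative value (FEV1 in liters or % predicted, %DLCO):

* anatomical segment counting (ASC):
  ``ppo = pre * (1 - S * 0.0526)`` with ``S`` the number of resected
  bronchopulmonary segments out of the 19 total
  (RUL 3, RML 2, RLL 5, LUL 4, LLL 5);
* well-aerated-lung (WAL) ratio:
  ``ppo = pre * (1 - WAL_lobe / WAL_total)`` where the WAL volumes come from
  CT densitometry (:mod:`walppo.qct`).

The ASC coefficient 0.0526 (~ 1/19) is used literally, not recomputed.
For a segmentectomy the WAL formula has no canonical sub-lobar rule; here the
lobe's WAL volume is scaled by ``S / segments(lobe)`` and the row is flagged
so users can exclude scaled estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import PatientRecord

#: bronchopulmonary segments per lobe; they sum to 19
SEGMENTS_PER_LOBE = {"RUL": 3, "RML": 2, "RLL": 5, "LUL": 4, "LLL": 5}
TOTAL_SEGMENTS = 19
ASC_COEFFICIENT = 0.0526


def segments_for_lobe(lobe: str) -> int:
    """Number of bronchopulmonary segments in ``lobe`` (RUL/RML/RLL/LUL/LLL)."""
    try:
        return SEGMENTS_PER_LOBE[lobe]
    except KeyError:
        raise ValidationError(
            f"unknown lobe {lobe!r}; expected one of {sorted(SEGMENTS_PER_LOBE)}"
        ) from None


def asc_ppo(pre_value: float, segments_resected: int) -> float:
    """Anatomical-segment-counting prediction ``pre * (1 - S * 0.0526)``."""
    if not (pre_value > 0 and math.isfinite(pre_value)):
        raise ValidationError(f"preoperative value must be > 0, got {pre_value}")
    s = int(segments_resected)
    if s != segments_resected or not 0 <= s <= TOTAL_SEGMENTS:
        raise ValidationError(
            f"segments resected must be an integer in [0, {TOTAL_SEGMENTS}], got {segments_resected}"
        )
    factor = 1.0 - s * ASC_COEFFICIENT
    if factor <= 0:
        raise ValidationError(f"S * {ASC_COEFFICIENT} >= 1 for S={s}")
    return pre_value * factor


def wal_ppo(pre_value: float, wal_lobe_l: float, wal_total_l: float) -> float:
    """WAL-ratio prediction ``pre * (1 - WAL_lobe / WAL_total)``."""
    if not (pre_value > 0 and math.isfinite(pre_value)):
        raise ValidationError(f"preoperative value must be > 0, got {pre_value}")
    if not wal_total_l > 0:
        raise ValidationError(f"whole-lung WAL must be > 0, got {wal_total_l}")
    if not 0 <= wal_lobe_l <= wal_total_l:
        raise ValidationError(
            f"lobe WAL {wal_lobe_l} must lie in [0, whole-lung WAL {wal_total_l}]"
        )
    return pre_value * (1.0 - wal_lobe_l / wal_total_l)


@dataclass(frozen=True)
class ResectionSpec:
    """What is resected: a lobe and how many of its segments."""

    lobe: str
    segments_resected: int
    kind: str = "lobectomy"  # "lobectomy" | "segmentectomy"

    def __post_init__(self) -> None:
        n_seg = segments_for_lobe(self.lobe)
        if not 1 <= self.segments_resected <= n_seg:
            raise ValidationError(
                f"segments_resected must be in [1, {n_seg}] for {self.lobe}, "
                f"got {self.segments_resected}"
            )
        if self.kind not in ("lobectomy", "segmentectomy"):
            raise ValidationError(f"unknown resection kind {self.kind!r}")
        if self.kind == "lobectomy" and self.segments_resected != n_seg:
            raise ValidationError(
                f"lobectomy of {self.lobe} must resect all {n_seg} segments"
            )


@dataclass(frozen=True)
class PpoEstimates:
    """ASC and WAL predictions for one patient, with the inputs echoed."""

    patient_id: str
    asc_ppo_fev1_l: float
    wal_ppo_fev1_l: float
    asc_ppo_fev1_pct: float
    wal_ppo_fev1_pct: float
    asc_ppo_dlco_pct: float
    wal_ppo_dlco_pct: float
    pre_fev1_l: float
    pre_fev1_pct: float
    pre_dlco_pct: float
    wal_lobe_l: float
    wal_total_l: float
    resected_lobe: str
    segments_resected: int
    wal_lobe_scaled: bool


def predict_patient(record: "PatientRecord") -> PpoEstimates:
    """Apply both formulas to one cohort record.

    For segmentectomies the WAL lobe volume is scaled by
    ``S / segments(lobe)`` (flagged via ``wal_lobe_scaled``); ASC always uses
    ``S`` directly.
    """
    n_seg = segments_for_lobe(record.resected_lobe)
    s = record.segments_resected
    lobe_wal = record.wal_lobe_l(record.resected_lobe)
    scaled = s < n_seg
    eff_lobe_wal = lobe_wal * (s / n_seg) if scaled else lobe_wal
    return PpoEstimates(
        patient_id=record.id,
        asc_ppo_fev1_l=asc_ppo(record.pre_fev1_l, s),
        wal_ppo_fev1_l=wal_ppo(record.pre_fev1_l, eff_lobe_wal, record.wal_total_l),
        asc_ppo_fev1_pct=asc_ppo(record.pre_fev1_pct, s),
        wal_ppo_fev1_pct=wal_ppo(record.pre_fev1_pct, eff_lobe_wal, record.wal_total_l),
        asc_ppo_dlco_pct=asc_ppo(record.pre_dlco_pct, s),
        wal_ppo_dlco_pct=wal_ppo(record.pre_dlco_pct, eff_lobe_wal, record.wal_total_l),
        pre_fev1_l=record.pre_fev1_l,
        pre_fev1_pct=record.pre_fev1_pct,
        pre_dlco_pct=record.pre_dlco_pct,
        wal_lobe_l=eff_lobe_wal,
        wal_total_l=record.wal_total_l,
        resected_lobe=record.resected_lobe,
        segments_resected=s,
        wal_lobe_scaled=scaled,
    )


class CohortPredictionError(ValidationError):
    """One or more cohort rows failed validation; all failures are collected."""

    def __init__(self, failures: Sequence[tuple[int, Exception]]):
        self.failures = list(failures)
        lines = "; ".join(f"row {i}: {err}" for i, err in self.failures)
        super().__init__(f"{len(self.failures)} record(s) failed: {lines}")


def predict_cohort(records: Iterable["PatientRecord"]) -> list[PpoEstimates]:
    """Apply both formulas to every record; per-record validation failures are
    collected into a single :class:`CohortPredictionError`."""
    estimates: list[PpoEstimates] = []
    failures: list[tuple[int, Exception]] = []
    for i, record in enumerate(records):
        try:
            estimates.append(predict_patient(record))
        except ValidationError as err:
            failures.append((i, err))
    if failures:
        raise CohortPredictionError(failures)
    return estimates


def predictions_to_frame(estimates: Sequence[PpoEstimates]) -> pd.DataFrame:
    """Predictions as a tidy table, one row per patient."""
    return pd.DataFrame(
        {
            "id": [e.patient_id for e in estimates],
            "asc_ppo_fev1_l": [e.asc_ppo_fev1_l for e in estimates],
            "wal_ppo_fev1_l": [e.wal_ppo_fev1_l for e in estimates],
            "asc_ppo_fev1_pct": [e.asc_ppo_fev1_pct for e in estimates],
            "wal_ppo_fev1_pct": [e.wal_ppo_fev1_pct for e in estimates],
            "asc_ppo_dlco_pct": [e.asc_ppo_dlco_pct for e in estimates],
            "wal_ppo_dlco_pct": [e.wal_ppo_dlco_pct for e in estimates],
            "wal_lobe_scaled": [e.wal_lobe_scaled for e in estimates],
        }
    )
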