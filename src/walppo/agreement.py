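"""Agreement battery for paired measurement methods.

For each pair of series (two predictions, or a prediction and the measured
outcome) the report gives:

* Spearman rank correlation rho with a two-sided p (t approximation on
  ``n - 2`` degrees of freedom, tie-corrected via average ranks);
* the intraclass correlation coefficient ICC(2,1) — two-way random effects,
  absolute agreement, single measures — with a 95% F-based confidence
  interval and a banded interpretation
  (< 0.40 poor, 0.40-0.54 weak, 0.55-0.69 moderate, 0.70-0.84 good,
  0.85-1.00 excellent; band edges belong to the higher band);
* Bland-Altman bias and limits of agreement, ``bias +/- 1.96 * SD`` of the
  paired differences (1.96 literally, sample SD with n-1 denominator);
* a paired Wilcoxon signed-rank test (zero differences dropped, average ranks
  for ties, exact two-sided p by enumeration of sign assignments for
  effective n <= 25, normal approximation with tie correction otherwise).

Two-sided tests throughout; no multiple-testing correction.  The absolute-
agreement ICC is the deliberate variant choice: it asks whether the two
methods are interchangeable, penalising any systematic offset that a
consistency ICC would forgive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, UndefinedStatisticError, ValidationError

ALPHA = 0.05

ICC_BANDS = (
    (0.85, "excellent"),
    (0.70, "good"),
    (0.55, "moderate"),
    (0.40, "weak"),
    (-1.0, "poor"),
)


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length measurement vectors on the same subjects."""

    label_a: str
    label_b: str
    a: np.ndarray
    b: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
            raise ValidationError("paired series must be equal-length 1D vectors")
        keep = np.isfinite(a) & np.isfinite(b)  # explicit pairwise deletion
        object.__setattr__(self, "a", a[keep])
        object.__setattr__(self, "b", b[keep])

    @property
    def n(self) -> int:
        return self.a.size

    def swapped(self) -> "PairedSeries":
        return PairedSeries(self.label_b, self.label_a, self.b, self.a, self.units)


def _require_n(series: PairedSeries, n_min: int, what: str) -> None:
    if series.n < n_min:
        raise ValidationError(f"{what} requires n >= {n_min}, got n={series.n}")


def spearman(series: PairedSeries, exact: bool = False) -> tuple[float, float]:
    """Spearman rho with a two-sided p value.

    Default p is the t approximation with n-2 df (tie-corrected rho from
    Pearson on average ranks).  ``exact=True`` enumerates all permutations of
    one rank vector (only sensible for n <= 10) and is meant as an oracle for
    small samples.
    """
    _require_n(series, 3, "spearman")
    if np.ptp(series.a) == 0 or np.ptp(series.b) == 0:
        raise UndefinedStatisticError("spearman rho undefined for a constant vector")
    ra = stats.rankdata(series.a)
    rb = stats.rankdata(series.b)
    if np.array_equal(ra, rb):  # identical rankings: rho is exactly 1
        rho, p = 1.0, 0.0
    else:
        rho, p = stats.spearmanr(series.a, series.b)
        rho = float(rho)
    if not exact:
        return rho, float(p)
    if series.n > 10:
        raise ValidationError("exact permutation p only supported for n <= 10")
    obs = abs(_pearson(ra, rb))
    hits = total = 0
    for perm in permutations(rb):
        total += 1
        if abs(_pearson(ra, np.array(perm))) >= obs - 1e-12:
            hits += 1
    return rho, hits / total


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom


def _anova_two_way(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects x methods) decomposition."""
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_agreement(
    series: PairedSeries, alpha: float = ALPHA
) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Returns ``(icc, ci_low, ci_high)`` with the F-based confidence interval.
    Perfect agreement (zero residual and zero method effect) returns exactly
    ``(1.0, 1.0, 1.0)``; zero total variance is undefined.
    """
    _require_n(series, 3, "icc")
    if np.array_equal(series.a, series.b):  # perfect agreement is exactly 1
        if np.ptp(series.a) == 0:
            raise UndefinedStatisticError("ICC undefined: zero total variance")
        return 1.0, 1.0, 1.0
    msr, msc, mse, n, k = _anova_two_way(series.a, series.b)
    if msr == 0 and msc == 0 and mse == 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: degenerate variance structure")
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return 1.0, 1.0, 1.0

    # F-based CI (Satterthwaite df for the method/error mixture)
    if mse == 0:
        return float(icc), float(icc), float(icc)
    fj = msc / mse
    num = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    den = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = num / den
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    lower, upper = min(lower, icc), max(upper, icc)
    return float(icc), float(max(lower, -1.0)), float(min(upper, 1.0))


def interpret_icc(icc: float) -> str:
    """Band label for an ICC: poor / weak / moderate / good / excellent."""
    if not -1.0 <= icc <= 1.0 or not math.isfinite(icc):
        raise ValidationError(f"ICC must lie in [-1, 1], got {icc}")
    for edge, label in ICC_BANDS:
        if icc >= edge:
            return label
    return "poor"


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def bland_altman(series: PairedSeries) -> BlandAltman:
    """Bland-Altman bias and limits of agreement ``bias +/- 1.96 * SD``.

    Differences are ``a - b``; SD uses the n-1 denominator; 1.96 is applied
    literally (not a t quantile).  Per-pair means are returned for plotting.
    """
    _require_n(series, 2, "bland_altman")
    d = series.a - series.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(series.a + series.b) / 2.0,
        diffs=d,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min of positive/negative rank sums
    p_value: float
    method: str  # "exact" | "normal-approx"
    n_effective: int
    n_zero: int


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic by full enumeration of
    the 2^n equiprobable sign assignments, via a subset-sum distribution over
    doubled ranks (average ranks may be half-integers)."""
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(r2)
    w2 = int(round(2 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(series: PairedSeries, exact_max_n: int = 25) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive average
    ranks.  The two-sided p is exact (enumeration over sign assignments) for
    effective n <= ``exact_max_n``, else a normal approximation with tie
    correction.  The reported statistic is min(W+, W-).
    """
    d = series.a - series.b
    n_zero = int(np.count_nonzero(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        method = "normal-approx"
    return WilcoxonResult(w, float(min(p, 1.0)), method, n, n_zero)


@dataclass(frozen=True)
class ComparisonResult:
    """One row of the agreement report."""

    comparison: str
    units: str
    n: int
    rho: float
    rho_p: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_band: str
    wilcoxon_statistic: float
    wilcoxon_p: float
    wilcoxon_method: str
    note: str = ""


@dataclass(frozen=True)
class AgreementReport:
    """The six-comparison agreement table (FEV1 and %DLCO; WAL vs ASC vs
    measured postoperative), with p < ``alpha`` flagged significant."""

    rows: tuple[ComparisonResult, ...]
    alpha: float = ALPHA

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([vars(r) for r in self.rows])
        frame["rho_significant"] = frame["rho_p"] < self.alpha
        frame["wilcoxon_significant"] = frame["wilcoxon_p"] < self.alpha
        return frame

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "comparisons": [
                {
                    k: (None if isinstance(v, float) and math.isnan(v) else v)
                    for k, v in vars(r).items()
                }
                for r in self.rows
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def row(self, comparison: str) -> ComparisonResult:
        for r in self.rows:
            if r.comparison == comparison:
                return r
        raise KeyError(comparison)


def compare(series: PairedSeries) -> ComparisonResult:
    """Run the full battery on one pair; degenerate statistics are reported as
    NaN with a note rather than aborting the whole report."""
    note_parts = []
    try:
        rho, rho_p = spearman(series)
    except DegenerateDataError as err:
        rho, rho_p = math.nan, math.nan
        note_parts.append(f"spearman: {err}")
    ba = bland_altman(series)
    try:
        icc, ci_low, ci_high = icc_agreement(series)
        band = interpret_icc(icc)
    except DegenerateDataError as err:
        icc = ci_low = ci_high = math.nan
        band = "undefined"
        note_parts.append(f"icc: {err}")
    try:
        wres = wilcoxon_signed_rank(series)
        w_stat, w_p, w_method = wres.statistic, wres.p_value, wres.method
    except DegenerateDataError as err:
        w_stat, w_p, w_method = math.nan, math.nan, "degenerate"
        note_parts.append(f"wilcoxon: {err}")
    return ComparisonResult(
        comparison=f"{series.label_a} vs {series.label_b}",
        units=series.units,
        n=series.n,
        rho=rho,
        rho_p=rho_p,
        bias=ba.bias,
        sd_diff=ba.sd,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        icc=icc,
        icc_ci_low=ci_low,
        icc_ci_high=ci_high,
        icc_band=band,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
        wilcoxon_method=w_method,
        note="; ".join(note_parts),
    )


def build_report(predictions: pd.DataFrame, measured: pd.DataFrame) -> AgreementReport:
    """Assemble the six-comparison agreement report.

    ``predictions`` must carry ``wal_ppo_fev1_l``, ``asc_ppo_fev1_l``,
    ``wal_ppo_dlco_pct``, ``asc_ppo_dlco_pct`` and ``measured`` the columns
    ``post_fev1_l``, ``post_dlco_pct``; rows are aligned by position.
    """
    if len(predictions) != len(measured):
        raise ValidationError(
            f"predictions ({len(predictions)}) and measured ({len(measured)}) differ in length"
        )
    p = predictions.reset_index(drop=True)
    m = measured.reset_index(drop=True)
    pairs = [
        ("WAL ppo-FEV1", p["wal_ppo_fev1_l"], "ASC ppo-FEV1", p["asc_ppo_fev1_l"], "L"),
        ("WAL ppo-FEV1", p["wal_ppo_fev1_l"], "postoperative FEV1", m["post_fev1_l"], "L"),
        ("ASC ppo-FEV1", p["asc_ppo_fev1_l"], "postoperative FEV1", m["post_fev1_l"], "L"),
        ("WAL ppo-%DLCO", p["wal_ppo_dlco_pct"], "ASC ppo-%DLCO", p["asc_ppo_dlco_pct"], "%"),
        ("WAL ppo-%DLCO", p["wal_ppo_dlco_pct"], "postoperative %DLCO", m["post_dlco_pct"], "%"),
        ("ASC ppo-%DLCO", p["asc_ppo_dlco_pct"], "postoperative %DLCO", m["post_dlco_pct"], "%"),
    ]
    rows = tuple(
        compare(PairedSeries(la, lb, np.asarray(va), np.asarray(vb), units))
        for la, va, lb, vb, units in pairs
    )
    return AgreementReport(rows=rows)


def bland_altman_plot(series: PairedSeries, path) -> None:
    """Write a Bland-Altman scatter (mean vs difference) with bias/LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(series)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.8)
    for y, style, label in (
        (ba.bias, "-", f"bias {ba.bias:+.2f}"),
        (ba.loa_low, "--", f"-1.96 SD {ba.loa_low:+.2f}"),
        (ba.loa_high, "--", f"+1.96 SD {ba.loa_high:+.2f}"),
    ):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.annotate(label, (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel(f"mean of methods ({series.units})")
    ax.set_ylabel(f"{series.label_a} - {series.label_b} ({series.units})")
    ax.set_title(f"{series.label_a} vs {series.label_b}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
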