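"""Agreement statistics against brute-force oracles and on known cases."""

import math

import numpy as np
import pandas as pd
import pytest

from oracles import (
    bland_altman_oracle,
    icc_oracle,
    spearman_d2_formula,
    spearman_oracle,
    wilcoxon_oracle,
)
from walppo import (
    PairedSeries,
    bland_altman,
    build_report,
    icc_agreement,
    interpret_icc,
    spearman,
    wilcoxon_signed_rank,
)
from walppo.errors import DegenerateDataError, UndefinedStatisticError, ValidationError


def series(a, b, **kw):
    return PairedSeries("A", "B", np.asarray(a, float), np.asarray(b, float), **kw)


class TestSpearman:
    def test_linear_transform_gives_one(self):
        x = np.array([1.0, 3.0, 2.5, 7.0, 5.0])
        rho, p = spearman(series(x, 2 * x + 1))
        assert rho == 1.0 and p == 0.0

    def test_negation_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rho, _ = spearman(series(x, -x))
        assert rho == pytest.approx(-1.0)

    def test_small_integer_example_matches_rank_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        # sum d^2 = 4 -> rho = 1 - 6*4 / (5*24) = 0.8
        assert spearman_d2_formula(x, y) == pytest.approx(0.8)
        rho, _ = spearman(series(x, y))
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, p1 = spearman(series(x, y))
        rho2, p2 = spearman(series(np.exp(x), y**3))
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman(series([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_exact_permutation_p_on_perfect_ranking(self):
        # only the identity and the reversal reach |rho| = 1: p = 2/5!
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = spearman(series(x, x), exact=True)
        assert p == pytest.approx(2 / 120)

    def test_exact_permutation_close_to_t_approximation(self, rng):
        x = rng.normal(size=7)
        y = x + rng.normal(size=7)
        _, p_t = spearman(series(x, y))
        _, p_exact = spearman(series(x, y), exact=True)
        assert abs(p_t - p_exact) < 0.12


class TestICC:
    def test_perfect_agreement_is_exactly_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc_agreement(series(a, a)) == (1.0, 1.0, 1.0)

    def test_constant_shift_penalised_relative_to_identity(self, rng):
        a = rng.normal(10, 2, size=12)
        icc_shift, _, _ = icc_agreement(series(a, a + 5))
        assert icc_shift < 0.5  # absolute agreement punishes pure bias

    def test_six_pair_hand_anova(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [2.0, 1.0, 3.0, 5.0, 6.0, 4.0]
        icc, lo, hi = icc_agreement(series(a, b))
        assert icc == pytest.approx(icc_oracle(a, b), abs=1e-10)
        assert lo <= icc <= hi

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(10):
            n = int(rng.integers(5, 20))
            a = rng.normal(size=n)
            b = a + rng.normal(scale=0.5, size=n)
            icc, lo, hi = icc_agreement(series(a, b))
            frame = pd.DataFrame(
                {
                    "subject": np.r_[np.arange(n), np.arange(n)],
                    "rater": ["x"] * n + ["y"] * n,
                    "score": np.r_[a, b],
                }
            )
            ref = pingouin.intraclass_corr(
                frame, targets="subject", raters="rater", ratings="score"
            ).set_index("Type")
            assert icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
            # pingouin rounds the reported CI to 2 decimals
            ref_lo, ref_hi = ref.loc["ICC(A,1)", "CI95"]
            assert lo == pytest.approx(ref_lo, abs=6e-3)
            assert hi == pytest.approx(ref_hi, abs=6e-3)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_agreement(series([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))

    def test_swap_invariance(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(scale=0.3, size=10)
        s = series(a, b)
        assert icc_agreement(s)[0] == pytest.approx(icc_agreement(s.swapped())[0])


class TestInterpretICC:
    @pytest.mark.parametrize(
        "icc, band",
        [
            (0.904, "excellent"),
            (0.770, "good"),
            (0.39, "poor"),
            (-0.2, "poor"),
            (0.40, "weak"),
            (0.55, "moderate"),
            (0.70, "good"),
            (0.85, "excellent"),
            (1.0, "excellent"),
            (0.5499, "weak"),
        ],
    )
    def test_bands(self, icc, band):
        assert interpret_icc(icc) == band

    @pytest.mark.parametrize("bad", [1.5, -1.5, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            interpret_icc(bad)


class TestBlandAltman:
    def test_constant_difference_has_zero_sd(self):
        ba = bland_altman(series([1.1, 2.1, 3.1], [1.0, 2.0, 3.0]))
        assert ba.bias == pytest.approx(0.1)
        assert ba.sd == pytest.approx(0.0, abs=1e-15)
        assert ba.loa_low == pytest.approx(ba.loa_high)

    def test_symmetric_differences(self):
        ba = bland_altman(series([0.0, 1.0, 3.0], [1.0, 1.0, 2.0]))
        # d = [-1, 0, 1]: bias 0, sample sd 1
        assert ba.bias == 0.0
        assert ba.sd == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_identity_gives_zero_limits(self):
        a = np.array([1.0, 4.0, 2.0])
        ba = bland_altman(series(a, a))
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_swap_negates_bias(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        s = series(a, b)
        assert bland_altman(s).bias == pytest.approx(-bland_altman(s.swapped()).bias)


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))

    def test_all_positive_differences_exact_p(self):
        res = wilcoxon_signed_rank(series([2.0, 3.0, 4.0, 5.0, 6.0], [1.0] * 5))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 32)
        assert res.method == "exact"

    def test_one_sign_flip_weakens_evidence(self):
        zeros = np.zeros(5)
        p_all = wilcoxon_signed_rank(series([1.0, 2.0, 3.0, 4.0, 5.0], zeros)).p_value
        p_flip = wilcoxon_signed_rank(series([-1.0, 2.0, 3.0, 4.0, 5.0], zeros)).p_value
        assert p_flip > p_all

    def test_exact_p_with_ties_matches_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 11))
            a = rng.integers(0, 4, size=n).astype(float)
            b = rng.integers(0, 4, size=n).astype(float)
            if np.all(a == b):
                continue
            stat, p = wilcoxon_oracle(a, b)
            res = wilcoxon_signed_rank(series(a, b))
            assert res.statistic == pytest.approx(stat, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_large_n_uses_tie_corrected_normal_approximation(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(scale=0.5, size=40) + 0.2
        res = wilcoxon_signed_rank(series(a, b))
        assert res.method == "normal-approx"
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(a, b, correction=False, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestBuildReport:
    def test_report_contains_six_comparisons(self, rng):
        n = 20
        frame = pd.DataFrame(
            {
                "wal_ppo_fev1_l": rng.uniform(1, 3, n),
                "asc_ppo_fev1_l": rng.uniform(1, 3, n),
                "wal_ppo_dlco_pct": rng.uniform(40, 90, n),
                "asc_ppo_dlco_pct": rng.uniform(40, 90, n),
                "post_fev1_l": rng.uniform(1, 3, n),
                "post_dlco_pct": rng.uniform(40, 90, n),
            }
        )
        report = build_report(frame, frame)
        assert len(report.rows) == 6
        table = report.to_frame()
        assert set(table["units"]) == {"L", "%"}
        assert table["icc_band"].isin(
            ["poor", "weak", "moderate", "good", "excellent", "undefined"]
        ).all()

    def test_length_mismatch_rejected(self):
        a = pd.DataFrame({"wal_ppo_fev1_l": [1, 2]})
        b = pd.DataFrame({"post_fev1_l": [1]})
        with pytest.raises(ValidationError):
            build_report(a, b)


class TestOracleEquivalence:
    """Each statistic matches an independent textbook implementation."""

    def test_fifty_random_vectors(self, rng):
        for trial in range(50):
            n = int(rng.integers(5, 21))
            a = np.round(rng.normal(size=n), 2)
            b = np.round(a + rng.normal(scale=0.8, size=n), 2)
            if np.ptp(a) == 0 or np.ptp(b) == 0 or np.all(a == b):
                continue
            s = series(a, b)

            rho, p = spearman(s)
            rho_ref, p_ref = spearman_oracle(a, b)
            assert rho == pytest.approx(rho_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)

            icc, _, _ = icc_agreement(s)
            assert icc == pytest.approx(icc_oracle(a, b), abs=1e-9)

            ba = bland_altman(s)
            bias, sd, lo, hi = bland_altman_oracle(a, b)
            assert ba.bias == pytest.approx(bias, abs=1e-9)
            assert ba.sd == pytest.approx(sd, abs=1e-9)
            assert (ba.loa_low, ba.loa_high) == pytest.approx((lo, hi), abs=1e-9)

            if n <= 16:
                stat_ref, p_wref = wilcoxon_oracle(a, b)
                res = wilcoxon_signed_rank(s)
                assert res.statistic == pytest.approx(stat_ref, abs=1e-9)
                assert res.p_value == pytest.approx(p_wref, abs=1e-9)
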