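"""Harmonization and the Wald/IVW estimators."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import norm

from targetmr import (
    HarmonizedPair,
    apply_f_filter,
    bonferroni_threshold,
    harmonize,
    ivw,
    or_ci,
    select_top_instrument,
    simulate_mr_study,
    wald_ratio,
)
from targetmr.mr import MREstimate

from conftest import record


def pair(beta_x=0.5, se_x=0.05, beta_y=0.1, se_y=0.02, snp="rs1", action="kept"):
    return HarmonizedPair(snp, beta_x, se_x, beta_y, se_y, action)


class TestHarmonize:
    def test_identical_orientation_kept(self):
        ex = record("rs1", beta=0.5, ea="A", oa="G")
        out = record("rs1", beta=0.1, ea="A", oa="G")
        (h,) = harmonize([ex], [out])
        assert (h.action, h.beta_y) == ("kept", 0.1)

    def test_swapped_alleles_flip_outcome_beta(self):
        ex = record("rs1", beta=0.5, ea="A", oa="G")
        out = record("rs1", beta=0.1, ea="G", oa="A")
        (h,) = harmonize([ex], [out])
        assert (h.action, h.beta_y) == ("flipped", -0.1)

    def test_ambiguous_palindrome_dropped(self):
        ex = record("rs1", beta=0.5, ea="A", oa="T", eaf=0.50)
        out = record("rs1", beta=0.1, ea="A", oa="T", eaf=0.50)
        (h,) = harmonize([ex], [out])
        assert h.action == "dropped_palindromic"

    def test_palindrome_with_missing_eaf_dropped(self):
        ex = record("rs1", beta=0.5, ea="C", oa="G", eaf=None)
        out = record("rs1", beta=0.1, ea="C", oa="G", eaf=0.2)
        (h,) = harmonize([ex], [out])
        assert h.action == "dropped_palindromic"

    def test_informative_palindrome_oriented_by_frequency(self):
        ex = record("rs1", beta=0.5, ea="A", oa="T", eaf=0.2)
        same = record("rs1", beta=0.1, ea="A", oa="T", eaf=0.25)
        opposite = record("rs1", beta=0.1, ea="A", oa="T", eaf=0.75)
        (h1,) = harmonize([ex], [same])
        (h2,) = harmonize([ex], [opposite])
        assert (h1.action, h1.beta_y) == ("kept", 0.1)
        assert (h2.action, h2.beta_y) == ("flipped", -0.1)

    def test_incompatible_allele_sets_dropped(self):
        ex = record("rs1", ea="A", oa="G")
        out = record("rs1", ea="A", oa="C")
        (h,) = harmonize([ex], [out])
        assert h.action == "dropped_unmatched"

    def test_missing_outcome_snp_dropped(self):
        (h,) = harmonize([record("rs1")], [record("rs2")])
        assert h.action == "dropped_unmatched"

    def test_idempotent_on_aligned_records(self):
        ex = [record("rs1", beta=0.5, ea="A", oa="G"),
              record("rs2", beta=-0.2, ea="C", oa="T", pos=200)]
        out = [record("rs1", beta=0.1, ea="A", oa="G"),
               record("rs2", beta=0.05, ea="C", oa="T", pos=200)]
        once = harmonize(ex, out)
        assert all(h.action == "kept" for h in once)
        again = harmonize(ex, out)
        assert once == again

    def test_orientation_invariance_of_estimates(self):
        """Relabeling outcome alleles (swap + negate beta) changes nothing."""
        ex = [record(f"rs{i}", beta=b, se=0.05, ea="A", oa="G", pos=100 * i)
              for i, b in enumerate([0.5, 0.4, 0.3], start=1)]
        out = [record(f"rs{i}", beta=b, se=0.02, ea="A", oa="G", pos=100 * i)
               for i, b in enumerate([0.10, 0.12, 0.05], start=1)]
        flipped = [record(f"rs{i}", beta=-b, se=0.02, ea="G", oa="A", pos=100 * i)
                   for i, b in enumerate([0.10, 0.12, 0.05], start=1)]
        est1 = ivw(harmonize(ex, out))
        est2 = ivw(harmonize(ex, flipped))
        assert est1.beta == pytest.approx(est2.beta, rel=1e-12)
        assert est1.se == pytest.approx(est2.se, rel=1e-12)


class TestWaldRatio:
    def test_worked_example(self):
        est = wald_ratio(pair(0.5, 0.05, 0.1, 0.02))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)
        assert est.method == "wald" and est.n_snps == 1

    def test_null_outcome_gives_p_one(self):
        est = wald_ratio(pair(beta_y=0.0))
        assert est.beta == 0.0 and est.pval == 1.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wald_ratio(pair(beta_x=0.0))

    def test_delta_se_matches_monte_carlo_at_high_f(self):
        """At F > 100 the first-order SE tracks the true ratio sd within 5%."""
        rng = np.random.default_rng(0)
        bx, sx, by, sy = 0.5, 0.01, 0.15, 0.02  # F = 2500
        draws = rng.normal(by, sy, 50_000) / rng.normal(bx, sx, 50_000)
        est = wald_ratio(pair(bx, sx, by, sy))
        assert est.se == pytest.approx(np.std(draws), rel=0.05)


class TestIVW:
    def test_equal_weights_reduce_to_mean(self):
        p1 = pair(0.5, 0.05, 0.10, 0.02, "rs1")
        p2 = pair(0.5, 0.05, 0.06, 0.02, "rs2")
        est = ivw([p1, p2])
        assert est.beta == pytest.approx((p1.ratio + p2.ratio) / 2)
        assert est.method == "ivw" and est.n_snps == 2

    def test_single_valid_pair_degenerates_to_wald(self):
        good = pair(0.5, 0.05, 0.1, 0.02, "rs1")
        zero = pair(0.0, 0.05, 0.1, 0.02, "rs2")
        est = ivw([good, zero])
        ref = wald_ratio(good)
        assert est.method == "wald"
        assert (est.beta, est.se) == (ref.beta, ref.se)

    def test_all_pairs_invalid_rejected(self):
        with pytest.raises(ValueError, match="no usable"):
            ivw([pair(0.0), pair(action="dropped_unmatched")])

    def test_matches_weighted_least_squares_through_origin(self):
        """IVW equals WLS of beta_y on beta_x, no intercept, weights 1/se_y^2."""
        pairs = [
            pair(0.5, 0.05, 0.10, 0.02, "rs1"),
            pair(0.3, 0.04, 0.09, 0.05, "rs2"),
            pair(-0.4, 0.06, -0.07, 0.01, "rs3"),
        ]
        bx = np.array([p.beta_x for p in pairs])
        by = np.array([p.beta_y for p in pairs])
        w = np.array([1 / p.se_y**2 for p in pairs])
        fit = sm.WLS(by, bx, weights=w).fit()
        est = ivw(pairs)
        assert est.beta == pytest.approx(fit.params[0], rel=1e-12)

    def test_n_identical_pairs_shrink_se_by_sqrt_n(self):
        p = pair(0.5, 0.05, 0.1, 0.02)
        single = wald_ratio(p)
        est = ivw([pair(0.5, 0.05, 0.1, 0.02, f"rs{i}") for i in range(4)])
        assert est.se == pytest.approx(single.se / 2, rel=1e-12)

    def test_recovers_simulated_causal_effect(self):
        bundle = simulate_mr_study(m=50, rho=0.5, causal_betas={12: 0.3},
                                   theta=0.3, seed=5)
        top = select_top_instrument(bundle.exposure_panel)
        (inst,) = apply_f_filter([top])
        assert inst.f_stat > 100
        est = ivw(harmonize([inst.record], bundle.outcome_panel.records))
        assert abs(est.beta - 0.3) < 3 * est.se


class TestORCI:
    def test_null_effect_symmetric_about_one(self):
        est = MREstimate.from_beta_se(0.0, 0.1, "wald", 1)
        orv, lo, hi = or_ci(est)
        assert orv == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_or_is_geometric_mean_of_bounds(self):
        est = MREstimate.from_beta_se(-0.2433, 0.0468, "wald", 1)
        orv, lo, hi = or_ci(est)
        assert orv == pytest.approx(math.sqrt(lo * hi), rel=1e-12)
        assert lo < orv < hi

    def test_zero_se_collapses_to_point(self):
        est = MREstimate.from_beta_se(0.3, 0.0, "wald", 1)
        orv, lo, hi = or_ci(est)
        assert lo == orv == hi == pytest.approx(math.exp(0.3))

    def test_quantile_at_95(self):
        est = MREstimate.from_beta_se(0.0, 1.0, "wald", 1)
        _, lo, hi = or_ci(est, level=0.95)
        assert math.log(hi) == pytest.approx(norm.ppf(0.975), rel=1e-9)


class TestBonferroni:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([95, 13, 7], 5.78e-6),
            ([48, 7], 1.49e-4),
            ([1], 0.05),
        ],
    )
    def test_threshold_values(self, counts, expected):
        assert bonferroni_threshold(0.05, counts) == pytest.approx(expected, rel=5e-3)

    @pytest.mark.parametrize("counts", [[], [0, 5], [3, -1], [2.5]])
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, counts)
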