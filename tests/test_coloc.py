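"""Colocalization: ABFs, five-hypothesis posteriors, prior sensitivity."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm as norm_dist

from targetmr import (
    ColocPriors,
    SummaryPanel,
    coloc_posteriors,
    coloc_window,
    labf,
    p12_sensitivity,
    simulate_coloc_scenario,
)
from targetmr.coloc import HYPOTHESES

from conftest import record


def labf_quadrature(beta, se, prior_sd):
    """Oracle: log BF via numerical integration of the Gaussian marginal.

    BF = [integral of N(beta_hat; b, V) N(b; 0, W) db] / N(beta_hat; 0, V)
    """
    v = se**2

    def integrand(b):
        return norm_dist.pdf(beta, loc=b, scale=se) * norm_dist.pdf(
            b, loc=0.0, scale=prior_sd
        )

    # the integrand peaks near the posterior mean with width ~se; hint both
    # so adaptive quadrature cannot miss a narrow peak at large |z|
    peak = beta * prior_sd**2 / (prior_sd**2 + v)
    marginal, _ = quad(
        integrand, -10 * prior_sd, 10 * prior_sd,
        points=sorted({0.0, beta, peak}), limit=500, epsabs=0, epsrel=1e-10,
    )
    return math.log(marginal) - norm_dist.logpdf(beta, loc=0.0, scale=math.sqrt(v))


class TestPriors:
    def test_defaults(self):
        pr = ColocPriors()
        assert (pr.p1, pr.p2, pr.p12) == (1e-4, 1e-4, 1e-5)

    def test_p12_cannot_exceed_marginals(self):
        with pytest.raises(ValueError, match="p12"):
            ColocPriors(p12=5e-4)

    def test_prior_sd_by_trait_type(self):
        pr = ColocPriors()
        assert pr.prior_sd_for("quantitative") == 0.15
        assert pr.prior_sd_for("case_control") == 0.2


class TestLABF:
    def test_null_z_gives_negative_labf(self):
        val = labf(0.0, 0.1, 0.15)
        r = 0.15**2 / (0.15**2 + 0.1**2)
        assert val == pytest.approx(0.5 * math.log1p(-r))
        assert val < 0

    def test_uninformative_limit(self):
        assert labf(0.3, 1e6, 0.15) == pytest.approx(0.0, abs=1e-10)

    def test_matches_quadrature_oracle(self):
        val = labf(0.3, 0.05, 0.15)
        assert val == pytest.approx(labf_quadrature(0.3, 0.05, 0.15), rel=1e-6)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError, match="se"):
            labf(0.1, 0.0, 0.15)


def panel_from_z(zs, name, trait_type="quantitative", se=0.01, start_pos=1000):
    recs = [
        record(
            f"rs{i+1}",
            pos=start_pos + 1000 * i,
            beta=z * se,
            se=se,
            trait_type=trait_type,
        )
        for i, z in enumerate(zs)
    ]
    return SummaryPanel(name, recs)


class TestWindow:
    def test_all_within_window_intersected_only(self):
        p1 = panel_from_z([8, 1, 0.5], "t1")
        p2 = panel_from_z([8, 1, 0.5], "t2")
        w1, w2 = coloc_window(p1, p2, window_kb=100)
        assert w1.snp_ids == p1.snp_ids and w2.snp_ids == p2.snp_ids

    def test_window_boundary_inclusive(self):
        # top SNP at pos 1000; boundary SNP at exactly +100 kb; one 1 bp beyond
        recs1 = [
            record("top", pos=1000, beta=0.08, se=0.01),
            record("edge", pos=101_000, beta=0.001, se=0.01),
            record("out", pos=101_001, beta=0.001, se=0.01),
        ]
        recs2 = [
            record("top", pos=1000, beta=0.05, se=0.01),
            record("edge", pos=101_000, beta=0.001, se=0.01),
            record("out", pos=101_001, beta=0.001, se=0.01),
        ]
        w1, _ = coloc_window(SummaryPanel("t1", recs1), SummaryPanel("t2", recs2))
        assert set(w1.snp_ids) == {"top", "edge"}

    def test_trait2_only_snps_removed(self):
        p1 = panel_from_z([8, 1], "t1")
        p2 = panel_from_z([8, 1, 0.5], "t2")
        _, w2 = coloc_window(p1, p2)
        assert w2.snp_ids == ["rs1", "rs2"]

    def test_disjoint_panels_rejected(self):
        p1 = panel_from_z([8], "t1")
        p2 = SummaryPanel("t2", [record("other", pos=1000)])
        with pytest.raises(ValueError, match="share no SNPs"):
            coloc_window(p1, p2)


class TestPosteriors:
    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(3)
        p1 = panel_from_z(rng.normal(0, 2, 30), "t1")
        p2 = panel_from_z(rng.normal(0, 2, 30), "t2")
        res = coloc_posteriors(p1, p2)
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_null_panels_favour_h0(self):
        zs = np.full(100, 0.05)
        res = coloc_posteriors(panel_from_z(zs, "t1"), panel_from_z(zs, "t2"))
        assert res.pp["pp_h0"] > 0.99

    def test_single_shared_snp_forces_h3_zero(self):
        p1 = panel_from_z([8.0], "t1")
        p2 = panel_from_z([8.0], "t2")
        res = coloc_posteriors(p1, p2)
        assert res.pp["pp_h3"] == 0.0
        assert res.pp["pp_h4"] > max(res.pp["pp_h1"], res.pp["pp_h2"])

    def test_single_snp_matches_closed_form_enumeration(self):
        """With one SNP the posterior is softmax of the four log masses."""
        z1, z2, se = 8.0, 8.0, 0.01
        pr = ColocPriors()
        l1 = labf(z1 * se, se, pr.sd_quant)
        l2 = labf(z2 * se, se, pr.sd_quant)
        logm = np.array(
            [
                0.0,
                math.log(pr.p1) + l1,
                math.log(pr.p2) + l2,
                -math.inf,
                math.log(pr.p12) + l1 + l2,
            ]
        )
        expected = np.exp(logm - logm.max())
        expected /= expected.sum()
        res = coloc_posteriors(panel_from_z([z1], "t1"), panel_from_z([z2], "t2"), pr)
        np.testing.assert_allclose(
            [res.pp[h] for h in HYPOTHESES], expected, atol=1e-12
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        z1, z2 = rng.normal(0, 3, 20), rng.normal(0, 3, 20)
        p1, p2 = panel_from_z(z1, "t1"), panel_from_z(z2, "t2")
        res = coloc_posteriors(p1, p2)
        perm = rng.permutation(20)
        q1 = SummaryPanel("t1", [p1.records[i] for i in perm])
        q2 = SummaryPanel("t2", [p2.records[i] for i in perm])
        res_p = coloc_posteriors(q1, q2)
        for h in HYPOTHESES:
            assert res.pp[h] == pytest.approx(res_p.pp[h], abs=1e-12)

    @pytest.mark.parametrize(
        "scenario,hyp",
        [
            ("shared", "pp_h4"),
            ("distinct", "pp_h3"),
            ("trait1_only", "pp_h1"),
            ("trait2_only", "pp_h2"),
            ("null", "pp_h0"),
        ],
    )
    def test_scenario_fidelity(self, scenario, hyp):
        rho = 0.2 if scenario == "distinct" else 0.5
        p1, p2, _ = simulate_coloc_scenario(scenario, m=100, rho=rho, z_target=8,
                                            seed=3)
        w1, w2 = coloc_window(p1, p2)
        res = coloc_posteriors(w1, w2)
        assert res.pp[hyp] > 0.9


class TestP12Sensitivity:
    def shared_panels(self):
        p1, p2, _ = simulate_coloc_scenario("shared", m=100, rho=0.5, z_target=8,
                                            seed=3)
        return coloc_window(p1, p2)

    def test_h4_monotone_in_p12_and_vanishes_at_zero_limit(self):
        w1, w2 = self.shared_panels()
        grid = np.logspace(-40, -4, 25)
        tab = p12_sensitivity(w1, w2, p12_grid=grid)
        h4 = tab["pp_h4"].to_numpy()
        assert np.all(np.diff(h4) >= 0) and h4[0] < h4[-1]
        assert h4[0] < 0.01 and not tab["rule_pass"].iloc[0]

    def test_pass_zone_contiguous_and_contains_default(self):
        w1, w2 = self.shared_panels()
        tab = p12_sensitivity(w1, w2)
        passes = tab["rule_pass"].to_numpy()
        assert passes.any()
        first, last = np.flatnonzero(passes)[[0, -1]]
        assert passes[first : last + 1].all()
        default_row = tab.iloc[(tab["p12"] - 1e-5).abs().argmin()]
        assert default_row["rule_pass"]

    def test_grid_outside_marginal_priors_rejected(self):
        w1, w2 = self.shared_panels()
        with pytest.raises(ValueError, match="grid"):
            p12_sensitivity(w1, w2, p12_grid=np.array([5e-4]))
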