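"""Bayesian colocalization of two summary-statistic panels.

Given per-SNP (beta, se) for two traits over a shared locus, each SNP j
gets a Wakefield-style log approximate Bayes factor for association,

    lABF_j = 1/2 * [ log(1 - r) + r * z_j^2 ],   r = W / (W + se_j^2),

where W is the prior variance of the true effect (SD 0.15 for quantitative
traits, 0.2 on the log-OR scale for case-control traits). Under the
single-causal-variant assumption the five locus hypotheses —

    H0: no association with either trait
    H1/H2: association with trait 1 / trait 2 only
    H3: both traits, distinct causal variants
    H4: both traits, one shared causal variant

— have unnormalized masses built from the per-SNP ABFs and the priors
p1, p2, p12 (defaults 1e-4, 1e-4, 1e-5); the posterior PP.H0..PP.H4 is
their normalization. A PP.H4 above 0.5 is the conventional call for
colocalization. All mass arithmetic is in log space.

The analysis window is the +/-100 kb neighbourhood (inclusive) of trait 1's
top SNP; trait 1 is the disorder GWAS and trait 2 the QTL panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_model import SummaryPanel

__all__ = [
    "ColocPriors",
    "ColocResult",
    "coloc_window",
    "labf",
    "coloc_posteriors",
    "p12_sensitivity",
]

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass(slots=True, frozen=True)
class ColocPriors:
    """Per-SNP association priors and prior effect SDs."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    sd_quant: float = 0.15
    sd_cc: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError(
                f"p12 must satisfy 0 < p12 <= min(p1, p2); got "
                f"p1={self.p1}, p2={self.p2}, p12={self.p12}"
            )
        if not (self.sd_quant > 0 and self.sd_cc > 0):
            raise ValueError("prior effect SDs must be positive")

    def prior_sd_for(self, trait_type: str) -> float:
        return self.sd_cc if trait_type == "case_control" else self.sd_quant


@dataclass(slots=True)
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]
    n_snps: int
    top_snp: str
    window_kb: float
    priors: ColocPriors

    @property
    def pp_h4(self) -> float:
        return self.pp["pp_h4"]

    def likely_colocalized(self, threshold: float = 0.5) -> bool:
        return self.pp_h4 > threshold


def coloc_window(
    panel1: SummaryPanel,
    panel2: SummaryPanel,
    window_kb: float = 100.0,
) -> tuple[SummaryPanel, SummaryPanel]:
    """Restrict both panels to shared SNPs near trait 1's top SNP.

    SNPs at exactly ``window_kb`` from the top SNP are included (inclusive
    window on both ends).
    """
    shared = set(panel1.snp_ids) & set(panel2.snp_ids)
    if not shared:
        raise ValueError(
            f"panels {panel1.trait_name!r} and {panel2.trait_name!r} share no SNPs"
        )
    top = panel1.subset(shared).top_snp()
    window_bp = window_kb * 1000.0
    keep = {
        r.snp_id
        for r in panel1.records
        if r.snp_id in shared and abs(r.pos - top.pos) <= window_bp
    }
    return panel1.subset(keep), panel2.subset(keep)


def labf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one SNP's association."""
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    if not prior_sd > 0:
        raise ValueError(f"prior_sd must be > 0, got {prior_sd}")
    z = beta / se
    v = se * se
    w = prior_sd * prior_sd
    r = w / (w + v)
    return 0.5 * (math.log1p(-r) + r * z * z)


def _aligned_labfs(
    panel1: SummaryPanel, panel2: SummaryPanel, priors: ColocPriors
) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids2 = {r.snp_id: r for r in panel2.records}
    shared = [r.snp_id for r in panel1.records if r.snp_id in ids2]
    if not shared:
        raise ValueError("no shared SNPs between panels")
    sd1 = priors.prior_sd_for(panel1.trait_type)
    sd2 = priors.prior_sd_for(panel2.trait_type)
    l1 = np.array([labf(r.beta, r.se, sd1) for r in panel1.records if r.snp_id in ids2])
    l2 = np.array([labf(ids2[s].beta, ids2[s].se, sd2) for s in shared])
    return shared, l1, l2


def _log_masses(l1: np.ndarray, l2: np.ndarray, priors: ColocPriors) -> np.ndarray:
    big1 = float(logsumexp(l1))
    big2 = float(logsumexp(l2))
    big12 = float(logsumexp(l1 + l2))
    h0 = 0.0
    h1 = math.log(priors.p1) + big1
    h2 = math.log(priors.p2) + big2
    # sum over distinct pairs i != j equals exp(L1 + L2) - exp(L12);
    # clamp to zero mass when the log-difference is numerically non-positive
    diff = big12 - (big1 + big2)
    if diff >= 0.0 or len(l1) == 1:
        h3 = -math.inf
    else:
        h3 = math.log(priors.p1) + math.log(priors.p2) + big1 + big2 + math.log1p(-math.exp(diff))
    h4 = math.log(priors.p12) + big12
    return np.array([h0, h1, h2, h3, h4])


def _normalize(log_masses: np.ndarray) -> dict[str, float]:
    post = np.exp(log_masses - logsumexp(log_masses))
    post /= post.sum()
    return dict(zip(HYPOTHESES, post.tolist()))


def coloc_posteriors(
    panel1: SummaryPanel,
    panel2: SummaryPanel,
    priors: ColocPriors = ColocPriors(),
    window_kb: float = 100.0,
) -> ColocResult:
    """Five-hypothesis posterior for a windowed, intersected pair of panels.

    Callers normally pass panels through :func:`coloc_window` first; the
    intersection is recomputed here defensively so the two ABF vectors are
    always aligned. With a single shared SNP the distinct-variants
    hypothesis H3 has exactly zero posterior.
    """
    shared, l1, l2 = _aligned_labfs(panel1, panel2, priors)
    pp = _normalize(_log_masses(l1, l2, priors))
    top = panel1.subset(shared).top_snp().snp_id
    return ColocResult(pp=pp, n_snps=len(shared), top_snp=top, window_kb=window_kb,
                       priors=priors)


def p12_sensitivity(
    panel1: SummaryPanel,
    panel2: SummaryPanel,
    priors: ColocPriors = ColocPriors(),
    p12_grid: np.ndarray | None = None,
    rule_threshold: float = 0.5,
) -> pd.DataFrame:
    """Recompute the posterior over a grid of shared-variant priors p12.

    Per-SNP ABFs are computed once and reused; only the H4 mass scales with
    p12, so PP.H4 is monotone increasing along the grid. Returns a table
    with columns p12, pp_h0..pp_h4 and rule_pass (PP.H4 > ``rule_threshold``).
    """
    if p12_grid is None:
        p12_grid = np.logspace(-8, math.log10(min(priors.p1, priors.p2)), 50)
    p12_grid = np.asarray(p12_grid, dtype=float)
    if np.any(p12_grid <= 0) or np.any(p12_grid > min(priors.p1, priors.p2)):
        raise ValueError("p12 grid values must lie in (0, min(p1, p2)]")
    _, l1, l2 = _aligned_labfs(panel1, panel2, priors)
    rows = []
    for p12 in p12_grid:
        pr = ColocPriors(priors.p1, priors.p2, float(p12), priors.sd_quant, priors.sd_cc)
        pp = _normalize(_log_masses(l1, l2, pr))
        rows.append({"p12": float(p12), **pp, "rule_pass": pp["pp_h4"] > rule_threshold})
    return pd.DataFrame(rows)
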