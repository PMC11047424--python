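"""LD-aware simulation of QTL/GWAS/mediator summary statistics.

The generator works on the standardized-genotype scale: genotypes are taken
to have unit variance, so a marginal regression of a trait on one SNP in a
cohort of size n has standard error 1/sqrt(n), and the vector of true
marginal effects induced by sparse causal effects b is R @ b, where R is
the SNP correlation (LD) matrix. Observed effect estimates are a single
multivariate-normal draw with mean R @ b and covariance R / n — the standard
asymptotic distribution of marginal GWAS estimates under LD.

A study bundle wires three such panels into the causal chain

    exposure --a--> mediator --b--> outcome,   exposure --direct--> outcome

with the total exposure effect theta = direct + a*b, plus mediator-specific
causal variants so that the mediator has instruments of its own. Exposure,
outcome and mediator cohorts are sampled independently (two-sample design).

Case-control outcomes are simulated on the linear (liability) scale and only
*labeled* case_control — the label selects the colocalization prior effect
SD; no logistic sampling is performed. This keeps the generating truth in
closed form, which is what the recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io_model import LDMatrix, SummaryPanel, SummaryStatRecord

__all__ = [
    "Truth",
    "StudyBundle",
    "make_ld_ar1",
    "simulate_trait_sumstats",
    "simulate_mr_study",
    "simulate_coloc_scenario",
    "COLOC_SCENARIOS",
]

#: default cis-region length emulated by the uniform position grid
DEFAULT_REGION_KB = 200.0

P_FLOOR = 1e-300

# non-palindromic allele pairs cycled across SNP indices so that
# harmonization never has to drop simulated variants
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass(slots=True)
class Truth:
    """Generating parameters of a simulated study, for recovery tests."""

    theta: float
    a_effect: float
    b_effect: float
    direct_effect: float
    causal_idx_exposure: tuple[int, ...]
    causal_idx_outcome: tuple[int, ...]
    causal_betas: tuple[float, ...]
    n_exposure: int
    n_outcome: int
    n_mediator: int
    rho: float
    seed: int
    causal_idx_mediator: tuple[int, ...] = ()
    mediator_betas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        total = self.direct_effect + self.a_effect * self.b_effect
        if abs(total - self.theta) > 1e-12:
            raise ValueError(
                f"theta={self.theta} != direct + a*b = {total}; the total effect "
                "must decompose exactly"
            )


@dataclass(slots=True)
class StudyBundle:
    """Three aligned panels plus LD and the truth that generated them."""

    exposure_panel: SummaryPanel
    outcome_panel: SummaryPanel
    mediator_panel: SummaryPanel | None
    ld: LDMatrix
    truth: Truth

    def __post_init__(self) -> None:
        ids = self.ld.snp_ids
        panels = [self.exposure_panel, self.outcome_panel]
        if self.mediator_panel is not None:
            panels.append(self.mediator_panel)
        for p in panels:
            if p.snp_ids != ids:
                raise ValueError(f"panel {p.trait_name!r} not aligned with LD matrix")


def _grid_positions(m: int, region_kb: float) -> np.ndarray:
    """1-based positions on a uniform grid spanning ``region_kb`` kilobases."""
    if m == 1:
        return np.array([1], dtype=int)
    span = int(round(region_kb * 1000))
    return 1 + np.round(np.linspace(0, span, m)).astype(int)


def make_ld_ar1(m: int, rho: float) -> LDMatrix:
    """AR(1) LD: r[i, j] = rho ** |i - j|, SNP ids rs1..rsm."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix([f"rs{i + 1}" for i in range(m)], r)


def _as_effect_vector(causal_betas, m: int) -> np.ndarray:
    """Accept a dense vector or a sparse {index: beta} mapping."""
    if isinstance(causal_betas, dict):
        b = np.zeros(m)
        for i, v in causal_betas.items():
            b[int(i)] = float(v)
        return b
    b = np.asarray(causal_betas, dtype=float)
    if b.shape != (m,):
        raise ValueError(f"causal effect vector has shape {b.shape}, expected ({m},)")
    return b


def simulate_trait_sumstats(
    ld: LDMatrix,
    causal_betas,
    n: int,
    trait_type: str = "quantitative",
    seed: int | np.random.SeedSequence | None = 0,
    *,
    trait_name: str = "simulated",
    tissue: str = "NA",
    panel_kind: str = "gwas",
    region_kb: float = DEFAULT_REGION_KB,
    chrom: str = "1",
    eaf: np.ndarray | None = None,
    chol: np.ndarray | None = None,
) -> SummaryPanel:
    """Draw one cohort's marginal summary statistics for a trait.

    Parameters
    ----------
    ld
        SNP correlation matrix R; panel SNPs inherit its ids and order.
    causal_betas
        Sparse ({index: beta}) or dense true causal effects b on the
        standardized scale. True marginal effects are R @ b.
    n
        Cohort size; the per-SNP standard error is 1/sqrt(n).
    trait_type
        "quantitative" or "case_control" (label only; see module docstring).
    seed
        Integer or SeedSequence; the draw is deterministic given it.
    eaf
        Optional effect-allele frequencies; drawn U(0.05, 0.95) otherwise.
    chol
        Optional precomputed Cholesky factor of R (replicate loops).
    """
    m = len(ld)
    if n < 10:
        raise ValueError(f"n must be >= 10 for the asymptotics to apply, got {n}")
    b = _as_effect_vector(causal_betas, m)
    rng = np.random.default_rng(seed)
    beta_marg = ld.r @ b
    if chol is None:
        chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    se = 1.0 / np.sqrt(n)
    beta_obs = beta_marg + se * (chol @ rng.standard_normal(m))
    pval = np.maximum(2.0 * norm.sf(np.abs(beta_obs) / se), P_FLOOR)
    if eaf is None:
        eaf = rng.uniform(0.05, 0.95, size=m)
    pos = _grid_positions(m, region_kb)
    case_fraction = 0.5 if trait_type == "case_control" else None
    records = [
        SummaryStatRecord(
            snp_id=ld.snp_ids[j],
            chrom=chrom,
            pos=int(pos[j]),
            effect_allele=_ALLELE_CYCLE[j % 4][0],
            other_allele=_ALLELE_CYCLE[j % 4][1],
            eaf=float(eaf[j]),
            beta=float(beta_obs[j]),
            se=float(se),
            pval=float(pval[j]),
            n=int(n),
            trait_type=trait_type,
            case_fraction=case_fraction,
        )
        for j in range(m)
    ]
    return SummaryPanel(trait_name=trait_name, records=records, tissue=tissue, panel_kind=panel_kind)


def simulate_mr_study(
    m: int = 50,
    rho: float = 0.5,
    causal_betas=None,
    theta: float | None = None,
    a_effect: float = 0.0,
    b_effect: float = 0.0,
    direct_effect: float | None = None,
    n_exposure: int = 10_000,
    n_outcome: int = 10_000,
    n_mediator: int = 10_000,
    seed: int = 0,
    *,
    mediator_betas=None,
    region_kb: float = DEFAULT_REGION_KB,
) -> StudyBundle:
    """Simulate a two-sample MR study with an optional mediation chain.

    ``theta`` is the total exposure->outcome effect and must satisfy
    theta = direct_effect + a_effect * b_effect; supply either ``theta`` or
    ``direct_effect`` and the other is filled in (both default to a pure
    direct effect of 0 when neither is given).

    Mediator-specific causal variants (defaulting to one SNP at index
    3m//4 with effect 0.15 whenever a mediator chain is configured) give the
    mediator genome-wide-significant instruments of its own, as a real
    mediator GWAS would have.
    """
    if causal_betas is None:
        causal_betas = {m // 4: 0.3}
    b_x = _as_effect_vector(causal_betas, m)
    if not np.any(b_x != 0):
        raise ValueError("at least one nonzero exposure causal effect is required")
    if theta is None and direct_effect is None:
        theta, direct_effect = a_effect * b_effect, 0.0
    elif direct_effect is None:
        direct_effect = theta - a_effect * b_effect
    elif theta is None:
        theta = direct_effect + a_effect * b_effect

    chain = a_effect != 0.0 or b_effect != 0.0
    if mediator_betas is None:
        mediator_betas = {3 * m // 4: 0.15} if chain else {}
    g_m = _as_effect_vector(mediator_betas, m)

    ld = make_ld_ar1(m, rho)
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    ss = np.random.SeedSequence(seed)
    ss_exp, ss_out, ss_med, ss_eaf = ss.spawn(4)

    base_eaf = np.random.default_rng(ss_eaf).uniform(0.05, 0.95, size=m)
    common = dict(region_kb=region_kb, chol=chol, eaf=base_eaf)

    exposure = simulate_trait_sumstats(
        ld, b_x, n_exposure, "quantitative", ss_exp,
        trait_name="exposure", panel_kind="eqtl", **common,
    )
    # outcome sees the exposure's total effect plus the mediator-specific
    # variants acting through the mediator
    outcome = simulate_trait_sumstats(
        ld, theta * b_x + b_effect * g_m, n_outcome, "case_control", ss_out,
        trait_name="outcome", panel_kind="gwas", **common,
    )
    mediator = None
    if chain:
        mediator = simulate_trait_sumstats(
            ld, a_effect * b_x + g_m, n_mediator, "quantitative", ss_med,
            trait_name="mediator", panel_kind="mediator", **common,
        )
    truth = Truth(
        theta=float(theta),
        a_effect=float(a_effect),
        b_effect=float(b_effect),
        direct_effect=float(direct_effect),
        causal_idx_exposure=tuple(int(i) for i in np.flatnonzero(b_x)),
        causal_idx_outcome=tuple(int(i) for i in np.flatnonzero(theta * b_x + b_effect * g_m)),
        causal_betas=tuple(float(v) for v in b_x[b_x != 0]),
        n_exposure=n_exposure,
        n_outcome=n_outcome,
        n_mediator=n_mediator,
        rho=rho,
        seed=seed,
        causal_idx_mediator=tuple(int(i) for i in np.flatnonzero(g_m)),
        mediator_betas=tuple(float(v) for v in g_m[g_m != 0]),
    )
    return StudyBundle(exposure, outcome, mediator, ld, truth)


COLOC_SCENARIOS = ("shared", "distinct", "trait1_only", "trait2_only", "null")


def simulate_coloc_scenario(
    scenario: str,
    m: int = 100,
    rho: float = 0.5,
    z_target: float = 8.0,
    n: int = 10_000,
    seed: int = 0,
    *,
    region_kb: float = DEFAULT_REGION_KB,
) -> tuple[SummaryPanel, SummaryPanel, Truth]:
    """Simulate a pair of panels for one colocalization ground truth.

    ``shared``: one causal SNP common to both traits; ``distinct``: one
    causal SNP per trait, placed so their r-squared is < 0.01;
    ``trait1_only``/``trait2_only``: a single causal SNP in one trait, the
    other null; ``null``: both traits null. The causal effect size is
    z_target / sqrt(n), so z_target is the expected z-score at the causal
    SNP. Trait 1 is labeled case_control (the disorder GWAS), trait 2
    quantitative (the QTL panel).
    """
    if scenario not in COLOC_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {COLOC_SCENARIOS}")
    if scenario != "null" and not z_target > 0:
        raise ValueError("z_target must be > 0 for non-null scenarios")
    beta_c = z_target / np.sqrt(n)
    idx1, idx2 = m // 3, (2 * m) // 3
    if scenario == "distinct" and rho > 0:
        # enforce r^2 < 0.01 between the two causal SNPs
        min_gap = int(np.ceil(np.log(0.1) / np.log(rho))) if rho > 0.1 else 1
        if idx2 - idx1 < min_gap:
            raise ValueError(f"m={m} too small to separate causal SNPs at rho={rho}")
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    if scenario == "shared":
        b1[idx1] = b2[idx1] = beta_c
    elif scenario == "distinct":
        b1[idx1] = beta_c
        b2[idx2] = beta_c
    elif scenario == "trait1_only":
        b1[idx1] = beta_c
    elif scenario == "trait2_only":
        b2[idx1] = beta_c

    ld = make_ld_ar1(m, rho)
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    ss1, ss2, ss_eaf = np.random.SeedSequence(seed).spawn(3)
    eaf = np.random.default_rng(ss_eaf).uniform(0.05, 0.95, size=m)
    panel1 = simulate_trait_sumstats(
        ld, b1, n, "case_control", ss1,
        trait_name="trait1", panel_kind="gwas", region_kb=region_kb, chol=chol, eaf=eaf,
    )
    panel2 = simulate_trait_sumstats(
        ld, b2, n, "quantitative", ss2,
        trait_name="trait2", panel_kind="eqtl", region_kb=region_kb, chol=chol, eaf=eaf,
    )
    truth = Truth(
        theta=0.0,
        a_effect=0.0,
        b_effect=0.0,
        direct_effect=0.0,
        causal_idx_exposure=tuple(int(i) for i in np.flatnonzero(b2)),
        causal_idx_outcome=tuple(int(i) for i in np.flatnonzero(b1)),
        causal_betas=tuple(float(v) for v in b2[b2 != 0]),
        n_exposure=n,
        n_outcome=n,
        n_mediator=n,
        rho=rho,
        seed=seed,
    )
    return panel1, panel2, truth
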