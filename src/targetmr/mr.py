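"""Two-sample MR estimation: harmonization, Wald ratio, IVW, OR/CI.

The causal effect of an exposure X on an outcome Y is estimated from
marginal summary statistics of two non-overlapping cohorts. For a single
instrument j the Wald ratio is

    beta = beta_yj / beta_xj,    se = se_yj / |beta_xj|

(first-order delta method, which ignores the uncertainty in beta_x; the
F >= 10 instrument gate keeps that approximation adequate). With several
independent instruments the per-SNP ratios are combined by fixed-effect
inverse-variance weighting:

    w_j = 1 / se_j^2,  beta = sum(w_j * ratio_j) / sum(w_j),
    se = sum(w_j) ** -0.5

which is algebraically the weighted least-squares slope of beta_y on beta_x
through the origin with weights 1/se_y^2. Effects on case-control outcomes
are log odds ratios; OR and 95% CI are exp-transformed from the log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import norm

from .io_model import SummaryStatRecord

__all__ = [
    "HarmonizedPair",
    "MREstimate",
    "harmonize",
    "wald_ratio",
    "ivw",
    "or_ci",
    "bonferroni_threshold",
    "PALINDROME_EAF_WINDOW",
]

logger = logging.getLogger(__name__)

#: eaf range within which a palindromic SNP's strand cannot be inferred
PALINDROME_EAF_WINDOW = (0.42, 0.58)

P_FLOOR = 1e-300


def _two_sided_p(z: float) -> float:
    return float(max(2.0 * norm.sf(abs(z)), P_FLOOR))


@dataclass(slots=True)
class HarmonizedPair:
    """Exposure and outcome associations for one SNP on a common allele.

    ``action`` records what harmonization did: ``kept`` (orientations
    already agreed), ``flipped`` (outcome beta negated to match the exposure
    effect allele), ``dropped_palindromic`` or ``dropped_unmatched``.
    """

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    action: str

    @property
    def usable(self) -> bool:
        return self.action in ("kept", "flipped")

    @property
    def ratio(self) -> float:
        return self.beta_y / self.beta_x

    @property
    def ratio_se(self) -> float:
        return self.se_y / abs(self.beta_x)


@dataclass(slots=True)
class MREstimate:
    """A causal effect on the log scale with its OR/CI presentation."""

    beta: float
    se: float
    pval: float
    or_value: float
    ci_low: float
    ci_high: float
    method: str
    n_snps: int

    @classmethod
    def from_beta_se(cls, beta: float, se: float, method: str, n_snps: int) -> "MREstimate":
        orv, lo, hi = _or_bounds(beta, se, 0.95)
        p = _two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else P_FLOOR)
        return cls(beta=beta, se=se, pval=p, or_value=orv, ci_low=lo, ci_high=hi,
                   method=method, n_snps=n_snps)


def _palindromic_ambiguous(eaf: float | None) -> bool:
    lo, hi = PALINDROME_EAF_WINDOW
    return eaf is None or lo <= eaf <= hi


def harmonize(
    exposure: list[SummaryStatRecord],
    outcome: list[SummaryStatRecord],
) -> list[HarmonizedPair]:
    """Align outcome records to the exposure's effect alleles, SNP by SNP.

    Matching is on snp_id. Swapped effect/other alleles flip the outcome
    beta's sign (and conceptually eaf -> 1 - eaf). Palindromic SNPs (A/T,
    C/G) are oriented by allele frequency — dropped when either eaf is
    missing or inside the ambiguity window, kept/flipped according to
    whether the two eafs sit on the same side of 0.5. Incompatible allele
    sets and ids absent from the outcome are dropped with a warning.

    Dropped SNPs are returned too (with their ``action``) so callers can
    audit attrition; estimation uses only the usable pairs.
    """
    by_id = {r.snp_id: r for r in outcome}
    pairs: list[HarmonizedPair] = []
    for ex in exposure:
        out = by_id.get(ex.snp_id)
        if out is None:
            pairs.append(HarmonizedPair(ex.snp_id, ex.beta, ex.se, math.nan, math.nan,
                                        "dropped_unmatched"))
            continue
        if ex.is_palindromic() and {out.effect_allele, out.other_allele} == {
            ex.effect_allele, ex.other_allele
        }:
            if _palindromic_ambiguous(ex.eaf) or _palindromic_ambiguous(out.eaf):
                pairs.append(HarmonizedPair(ex.snp_id, ex.beta, ex.se, out.beta, out.se,
                                            "dropped_palindromic"))
                continue
            labels_swapped = out.effect_allele != ex.effect_allele
            # eaf of the exposure's effect allele as labeled in the outcome;
            # a side-of-0.5 disagreement then signals a strand mislabel
            aligned_eaf = 1.0 - out.eaf if labels_swapped else out.eaf
            freq_agree = (ex.eaf < 0.5) == (aligned_eaf < 0.5)
            flip = labels_swapped != (not freq_agree)
            action = "flipped" if flip else "kept"
            beta_y = -out.beta if flip else out.beta
            pairs.append(HarmonizedPair(ex.snp_id, ex.beta, ex.se, beta_y, out.se, action))
            continue
        if out.effect_allele == ex.effect_allele and out.other_allele == ex.other_allele:
            pairs.append(HarmonizedPair(ex.snp_id, ex.beta, ex.se, out.beta, out.se, "kept"))
        elif out.effect_allele == ex.other_allele and out.other_allele == ex.effect_allele:
            pairs.append(HarmonizedPair(ex.snp_id, ex.beta, ex.se, -out.beta, out.se, "flipped"))
        else:
            logger.warning(
                "%s: incompatible allele sets %s/%s vs %s/%s; dropping",
                ex.snp_id, ex.effect_allele, ex.other_allele,
                out.effect_allele, out.other_allele,
            )
            pairs.append(HarmonizedPair(ex.snp_id, ex.beta, ex.se, math.nan, math.nan,
                                        "dropped_unmatched"))
    return pairs


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate beta_y / beta_x."""
    if not pair.usable:
        raise ValueError(f"{pair.snp_id}: pair was dropped at harmonization ({pair.action})")
    if pair.beta_x == 0:
        raise ValueError(f"{pair.snp_id}: exposure beta is zero; Wald ratio undefined")
    return MREstimate.from_beta_se(pair.ratio, pair.ratio_se, "wald", 1)


def ivw(pairs: list[HarmonizedPair]) -> MREstimate:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    Pairs with a zero exposure beta are excluded with a warning; a single
    surviving pair degenerates to the Wald ratio.
    """
    usable = [p for p in pairs if p.usable]
    valid = []
    for p in usable:
        if p.beta_x == 0:
            logger.warning("%s: exposure beta is zero; excluded from IVW", p.snp_id)
        else:
            valid.append(p)
    if not valid:
        raise ValueError("no usable pairs with nonzero exposure beta for IVW")
    if len(valid) == 1:
        est = wald_ratio(valid[0])
        return MREstimate.from_beta_se(est.beta, est.se, "wald", 1)
    weights = [1.0 / p.ratio_se**2 for p in valid]
    wsum = sum(weights)
    beta = sum(w * p.ratio for w, p in zip(weights, valid)) / wsum
    se = wsum**-0.5
    return MREstimate.from_beta_se(beta, se, "ivw", len(valid))


def _or_bounds(beta: float, se: float, level: float) -> tuple[float, float, float]:
    z = norm.ppf(0.5 + level / 2.0)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def or_ci(estimate: MREstimate, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with its symmetric-on-log-scale CI."""
    if estimate.se < 0:
        raise ValueError("se must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    return _or_bounds(estimate.beta, estimate.se, level)


def bonferroni_threshold(alpha: float = 0.05, counts: list[int] | tuple[int, ...] = (1,)) -> float:
    """Family-wise threshold alpha / product(counts).

    ``counts`` are the multiplicity dimensions, e.g. (targets, tissues,
    outcomes): 0.05/(95*13*7) = 5.78e-6 for the eQTL family and
    0.05/(48*7) = 1.49e-4 for the pQTL family.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    prod = 1
    for c in counts:
        if int(c) != c or c < 1:
            raise ValueError(f"counts must be positive integers, got {c}")
        prod *= int(c)
    return alpha / prod
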