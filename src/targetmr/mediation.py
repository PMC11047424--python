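"""Two-step MR mediation analysis.

Decomposes a total exposure->outcome effect into an indirect path through a
mediator and a direct remainder:

    step 1 (a): exposure -> mediator, using the exposure's instruments;
    step 2 (b): mediator -> outcome, using genome-wide-significant,
                LD-clumped instruments from the mediator GWAS;
    indirect = a * b (product of coefficients),
    se(indirect) = sqrt(a^2 se_b^2 + b^2 se_a^2)  (delta method),
    proportion mediated = a * b / total.

A mediator is called ``mediating`` when the indirect and total effects share
a sign, ``suppressing`` when they oppose, and ``not_significant`` unless
both steps reach p < 0.05. Proportions are reported unclamped (they can be
negative or exceed 100%); the label carries the interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .instruments import Instrument, apply_f_filter, ld_clump
from .io_model import LDMatrix, SummaryPanel
from .mr import MREstimate, harmonize, ivw

__all__ = ["MediationResult", "step1_effect", "step2_effect", "mediation_summary"]

STEP_ALPHA = 0.05


@dataclass(slots=True)
class MediationResult:
    """Both mediation steps plus the indirect-effect decomposition."""

    a: float
    se_a: float
    p_a: float
    b: float
    se_b: float
    p_b: float
    total: float
    indirect: float
    se_indirect: float
    proportion: float
    label: str

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


def step1_effect(
    instruments: list[Instrument], mediator_panel: SummaryPanel
) -> MREstimate:
    """Exposure -> mediator effect using the exposure's instruments.

    Wald ratio for one instrument, IVW for several (delegated to the MR
    core, which handles the single-pair degenerate case).
    """
    if not instruments:
        raise ValueError("no exposure instruments supplied")
    pairs = harmonize([i.record for i in instruments], mediator_panel.records)
    if not any(p.usable for p in pairs):
        raise ValueError(
            "no exposure instrument overlaps the mediator panel after harmonization"
        )
    return ivw(pairs)


def step2_effect(
    mediator_panel: SummaryPanel,
    outcome_panel: SummaryPanel,
    ld: LDMatrix,
    gw_threshold: float = 5e-8,
    r2_cutoff: float = 0.001,
    *,
    exclude_snps: list[str] | None = None,
    f_min: float = 10.0,
) -> MREstimate:
    """Mediator -> outcome effect from the mediator's own instruments.

    The mediator panel is clumped at genome-wide significance
    (p < ``gw_threshold``, pairwise r^2 <= ``r2_cutoff``). SNPs in LD
    (r^2 > cutoff) with any id in ``exclude_snps`` — typically the exposure's
    instruments — are removed first, so that exposure-driven signal in the
    mediator GWAS cannot masquerade as a mediator instrument.
    """
    panel = mediator_panel
    if exclude_snps:
        drop = {
            r.snp_id
            for r in panel.records
            for ex in exclude_snps
            if ld.r2(r.snp_id, ex) > r2_cutoff
        }
        panel = panel.subset([s for s in panel.snp_ids if s not in drop])
    insts = apply_f_filter(
        ld_clump(panel, ld, p_threshold=gw_threshold, r2_cutoff=r2_cutoff), f_min
    )
    if not insts:
        near = sum(1 for r in panel.records if r.pval < gw_threshold * 100)
        raise ValueError(
            f"no mediator instruments reach p < {gw_threshold:g} after clumping "
            f"({near} SNPs within two orders of magnitude of the threshold)"
        )
    pairs = harmonize([i.record for i in insts], outcome_panel.records)
    return ivw(pairs)


def mediation_summary(
    a: MREstimate, b: MREstimate, total: MREstimate
) -> MediationResult:
    """Combine the two steps into an indirect effect and classification."""
    if total.beta == 0:
        raise ValueError("total effect is zero; proportion mediated undefined")
    indirect = a.beta * b.beta
    se_ind = math.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2)
    proportion = indirect / total.beta
    if a.pval >= STEP_ALPHA or b.pval >= STEP_ALPHA:
        label = "not_significant"
    elif math.copysign(1.0, indirect) == math.copysign(1.0, total.beta):
        label = "mediating"
    else:
        label = "suppressing"
    return MediationResult(
        a=a.beta, se_a=a.se, p_a=a.pval,
        b=b.beta, se_b=b.se, p_b=b.pval,
        total=total.beta, indirect=indirect, se_indirect=se_ind,
        proportion=proportion, label=label,
    )
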