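"""Genetic instrument selection and quality control.

Instruments are SNP-exposure associations that survive, in order:

1. a p-value threshold (eQTL panels: p < 1e-4 with a single top SNP per
   gene; pQTL panels: p < 0.05 followed by greedy LD clumping at
   r-squared <= 0.001),
2. the weak-instrument gate F = (beta/se)^2 >= 10, and
3. a confounder screen that drops SNPs with a known genome-wide-significant
   (p < 5e-8) association with any of the outcome disorders, emulating a
   PhenoScanner lookup.

All p-value thresholds are strict inequalities; F = 10 itself passes
(only F < 10 is excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_model import LDMatrix, SummaryPanel, SummaryStatRecord

__all__ = [
    "Instrument",
    "ConfounderLookup",
    "f_statistic",
    "select_top_instrument",
    "ld_clump",
    "apply_f_filter",
    "exclude_confounded",
]

logger = logging.getLogger(__name__)

F_MIN_DEFAULT = 10.0


@dataclass(slots=True)
class Instrument:
    """A selected SNP-exposure association with its strength statistic."""

    record: SummaryStatRecord
    f_stat: float
    selection_flags: set[str] = field(default_factory=set)

    @property
    def snp_id(self) -> str:
        return self.record.snp_id

    def passes_f(self, f_min: float = F_MIN_DEFAULT) -> bool:
        return self.f_stat >= f_min


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic: the squared z, (beta/se)^2."""
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def _make_instrument(record: SummaryStatRecord, *flags: str) -> Instrument:
    inst = Instrument(record, f_statistic(record.beta, record.se), set(flags))
    if inst.passes_f():
        inst.selection_flags.add("f_pass")
    return inst


def select_top_instrument(
    panel: SummaryPanel, p_threshold: float = 1e-4
) -> Instrument | None:
    """Single most significant SNP in an eQTL panel, or None.

    One gene yields one instrument: the SNP with the smallest p-value,
    provided it clears ``p_threshold`` (strict). Ties break by smaller
    position, then lexicographic snp_id.
    """
    if not panel.records:
        raise ValueError("cannot select an instrument from an empty panel")
    top = panel.top_snp()
    if top.pval >= p_threshold:
        return None
    return _make_instrument(top, "top_snp")


def ld_clump(
    panel: SummaryPanel,
    ld: LDMatrix,
    p_threshold: float = 0.05,
    r2_cutoff: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[Instrument]:
    """Greedy LD clumping of a panel, most significant SNPs first.

    Restrict to p < ``p_threshold``; repeatedly promote the remaining SNP
    with the smallest p-value (ties: position, then id) to index SNP and
    discard every remaining SNP within ``window_kb`` of it whose squared
    correlation with it exceeds ``r2_cutoff``. Index SNPs are returned in
    selection order; the output is pairwise r^2 <= cutoff by construction.
    """
    candidates = [r for r in panel.records if r.pval < p_threshold]
    for r in candidates:
        ld.index_of(r.snp_id)  # raises KeyError naming the SNP if absent
    candidates.sort(key=lambda r: (r.pval, r.pos, r.snp_id))
    window_bp = window_kb * 1000.0
    kept: list[SummaryStatRecord] = []
    order = 0
    instruments: list[Instrument] = []
    while candidates:
        index_snp = candidates.pop(0)
        kept.append(index_snp)
        instruments.append(_make_instrument(index_snp, "clumped_index", f"clump_order_{order}"))
        order += 1
        candidates = [
            r
            for r in candidates
            if abs(r.pos - index_snp.pos) > window_bp
            or ld.r2(r.snp_id, index_snp.snp_id) <= r2_cutoff
        ]
    # defensive post-condition: the clump is pairwise uncorrelated
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            if abs(a.pos - b.pos) <= window_bp and ld.r2(a.snp_id, b.snp_id) > r2_cutoff:
                raise AssertionError(
                    f"clump invariant violated: {a.snp_id} vs {b.snp_id}"
                )
    return instruments


def apply_f_filter(
    instruments: list[Instrument], f_min: float = F_MIN_DEFAULT
) -> list[Instrument]:
    """Drop weak instruments (F < f_min); F == f_min passes."""
    kept = []
    for inst in instruments:
        if inst.f_stat < f_min:
            logger.info("excluding %s: F = %.3f < %g", inst.snp_id, inst.f_stat, f_min)
        else:
            kept.append(inst)
    return kept


@dataclass(slots=True)
class ConfounderLookup:
    """Known SNP-phenotype associations, keyed by snp_id.

    Emulates a PhenoScanner-style query result: each entry maps a SNP to
    (phenotype name, p-value) pairs from prior GWAS.
    """

    entries: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for snp, hits in self.entries.items():
            for pheno, p in hits:
                if not 0 < p <= 1:
                    raise ValueError(f"{snp}/{pheno}: lookup p-value {p} outside (0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "ConfounderLookup":
        """Read a TSV with columns snp_id, phenotype, pval."""
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "phenotype": str})
        for col in ("snp_id", "phenotype", "pval"):
            if col not in df.columns:
                raise ValueError(f"{path}: confounder lookup lacks column {col!r}")
        entries: dict[str, list[tuple[str, float]]] = {}
        for row in df.itertuples(index=False):
            entries.setdefault(row.snp_id, []).append((row.phenotype, float(row.pval)))
        return cls(entries)

    def hits_below(self, snp_id: str, p_threshold: float) -> list[tuple[str, float]]:
        return [(ph, p) for ph, p in self.entries.get(snp_id, []) if p < p_threshold]


def exclude_confounded(
    instruments: list[Instrument],
    lookup: ConfounderLookup,
    p_threshold: float = 5e-8,
) -> list[Instrument]:
    """Remove instruments previously associated with an outcome disorder.

    An instrument is dropped when the lookup holds any association with
    p < ``p_threshold`` (strict) for its SNP; removals are logged with the
    offending phenotype.
    """
    kept = []
    for inst in instruments:
        hits = lookup.hits_below(inst.snp_id, p_threshold)
        if hits:
            inst.selection_flags.add("confounder_excluded")
            for pheno, p in hits:
                logger.warning(
                    "excluding %s: prior association with %s (p = %g)",
                    inst.snp_id, pheno, p,
                )
        else:
            kept.append(inst)
    return kept
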