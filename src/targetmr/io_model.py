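"""Data model and TSV I/O for GWAS/QTL summary statistics and LD matrices.

The package operates entirely on marginal summary statistics: per-SNP effect
estimates (beta), standard errors, p-values and sample sizes, as released by
GWAS and QTL studies. A :class:`SummaryPanel` holds one trait's statistics
for a genomic region; an :class:`LDMatrix` holds the pairwise correlation
(r, not r-squared) between the same SNPs, as estimated from a reference
panel. Files are plain UTF-8 tab-separated text with ``.`` for missing
values, so that scientific notation round-trips losslessly.

Positions are 1-based and windows are inclusive on both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SummaryStatRecord",
    "SummaryPanel",
    "LDMatrix",
    "SumstatsFormatError",
    "SumstatsParseError",
    "LDValidationError",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "validate_panel",
]

VALID_ALLELES = frozenset("ACGT")
TRAIT_TYPES = ("quantitative", "case_control")

#: canonical column order of the summary-statistics TSV dialect
SUMSTAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "trait_type",
    "case_fraction",
]

MISSING = "."


class SumstatsFormatError(ValueError):
    """A file does not conform to the summary-statistics or LD TSV dialect."""


class SumstatsParseError(ValueError):
    """A field could not be parsed; the message carries the 1-based line number."""


class LDValidationError(ValueError):
    """An LD matrix violates symmetry, unit diagonal, or the [-1, 1] range."""


@dataclass(slots=True)
class SummaryStatRecord:
    """One SNP's marginal association with a trait.

    ``beta`` is a per-allele effect of the ``effect_allele``: a log odds
    ratio for case-control traits, SD units for quantitative ones.
    ``eaf`` (effect-allele frequency) and ``case_fraction`` may be missing
    (``None``); a missing eaf makes palindromic SNPs unharmonizable.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int
    trait_type: str = "quantitative"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        # structural invariants only; numeric sanity (se > 0, p in (0,1],
        # p/z consistency) is enforced by the reader and reported by
        # validate_panel so that questionable records remain representable
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"{self.snp_id}: unknown trait_type {self.trait_type!r}")
        if self.eaf is not None and not 0 <= self.eaf <= 1:
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.case_fraction is not None and not 0 < self.case_fraction < 1:
            raise ValueError(f"{self.snp_id}: case_fraction must be in (0, 1)")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """A/T or C/G SNPs cannot be oriented by allele labels alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(slots=True)
class SummaryPanel:
    """An ordered collection of summary statistics for one trait and region."""

    trait_name: str
    records: list[SummaryStatRecord]
    tissue: str = "NA"
    panel_kind: str = "gwas"

    def __post_init__(self) -> None:
        if self.panel_kind not in ("eqtl", "pqtl", "gwas", "mediator"):
            raise ValueError(f"unknown panel_kind {self.panel_kind!r}")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_ids in panel {self.trait_name!r}: {dupes}")
        kinds = {r.trait_type for r in self.records}
        if len(kinds) > 1:
            raise ValueError(f"mixed trait_type within panel {self.trait_name!r}: {kinds}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    @property
    def trait_type(self) -> str:
        if not self.records:
            return "quantitative"
        return self.records[0].trait_type

    def get(self, snp_id: str) -> SummaryStatRecord | None:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    def subset(self, snp_ids: Iterable[str]) -> "SummaryPanel":
        """Restrict to the given SNP ids, preserving this panel's order."""
        keep = set(snp_ids)
        return replace(self, records=[r for r in self.records if r.snp_id in keep])

    def top_snp(self) -> SummaryStatRecord:
        """Record with the smallest p-value; ties broken by position then id."""
        if not self.records:
            raise ValueError("empty panel has no top SNP")
        return min(self.records, key=lambda r: (r.pval, r.pos, r.snp_id))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pval": r.pval,
                    "n": r.n,
                    "trait_type": r.trait_type,
                    "case_fraction": r.case_fraction,
                }
            )
        return pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)


@dataclass
class LDMatrix:
    """Symmetric SNP-by-SNP correlation matrix (r) with unit diagonal."""

    snp_ids: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise SumstatsFormatError(
                f"LD matrix shape {self.r.shape} does not match {m} snp ids"
            )
        if len(set(self.snp_ids)) != m:
            raise SumstatsFormatError("duplicate snp ids in LD matrix")
        asym = float(np.max(np.abs(self.r - self.r.T))) if m else 0.0
        if asym > 1e-8:
            raise LDValidationError(f"LD matrix asymmetric (max |r - r.T| = {asym:g})")
        self.r = (self.r + self.r.T) / 2.0
        if m and float(np.max(np.abs(np.diag(self.r) - 1.0))) > 1e-6:
            raise LDValidationError("LD matrix diagonal differs from 1 by more than 1e-6")
        if m and (self.r.min() < -1 - 1e-9 or self.r.max() > 1 + 1e-9):
            raise LDValidationError("LD correlations outside [-1, 1]")
        np.fill_diagonal(self.r, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} absent from LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two SNPs."""
        return float(self.r[self.index_of(a), self.index_of(b)] ** 2)

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(s) for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# readers / writers


def _parse_float(value: str, column: str, lineno: int, *, allow_missing: bool) -> float | None:
    if value == MISSING or value == "":
        if allow_missing:
            return None
        raise SumstatsParseError(f"line {lineno}: missing value in required column {column!r}")
    try:
        return float(value)
    except ValueError:
        raise SumstatsParseError(
            f"line {lineno}: cannot parse {column}={value!r} as a number"
        ) from None


def read_sumstats(
    path,
    trait_name: str | None = None,
    tissue: str = "NA",
    panel_kind: str = "gwas",
) -> SummaryPanel:
    """Read a summary-statistics TSV into a validated :class:`SummaryPanel`.

    The header must name every column in :data:`SUMSTAT_COLUMNS`. ``eaf`` and
    ``case_fraction`` may be ``.`` (missing); everything else is required.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[], comment="#"
    )
    missing_cols = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SumstatsFormatError(
            f"{path}: missing required column(s): {', '.join(missing_cols)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        eaf = _parse_float(getattr(row, "eaf"), "eaf", lineno, allow_missing=True)
        cf = _parse_float(
            getattr(row, "case_fraction"), "case_fraction", lineno, allow_missing=True
        )
        beta = _parse_float(getattr(row, "beta"), "beta", lineno, allow_missing=False)
        se = _parse_float(getattr(row, "se"), "se", lineno, allow_missing=False)
        pval = _parse_float(getattr(row, "pval"), "pval", lineno, allow_missing=False)
        pos_f = _parse_float(getattr(row, "pos"), "pos", lineno, allow_missing=False)
        n_f = _parse_float(getattr(row, "n"), "n", lineno, allow_missing=False)
        if not se > 0:
            raise SumstatsParseError(f"line {lineno}: se must be > 0 (got {se!r})")
        if not 0 < pval <= 1:
            raise SumstatsParseError(f"line {lineno}: pval must be in (0, 1] (got {pval!r})")
        if n_f < 1:
            raise SumstatsParseError(f"line {lineno}: n must be >= 1 (got {n_f!r})")
        try:
            records.append(
                SummaryStatRecord(
                    snp_id=getattr(row, "snp_id"),
                    chrom=getattr(row, "chrom"),
                    pos=int(pos_f),
                    effect_allele=getattr(row, "effect_allele"),
                    other_allele=getattr(row, "other_allele"),
                    eaf=eaf,
                    beta=beta,
                    se=se,
                    pval=pval,
                    n=int(n_f),
                    trait_type=getattr(row, "trait_type"),
                    case_fraction=cf,
                )
            )
        except ValueError as exc:
            raise SumstatsParseError(f"line {lineno}: {exc}") from exc
    return SummaryPanel(
        trait_name=trait_name if trait_name is not None else str(path),
        records=records,
        tissue=tissue,
        panel_kind=panel_kind,
    )


def _fmt(x: float | int | None) -> str:
    if x is None:
        return MISSING
    # repr of a builtin float is the shortest lossless decimal form
    return repr(float(x)) if isinstance(x, float) else str(x)


def write_sumstats(panel: SummaryPanel, path) -> None:
    """Write a panel in the canonical TSV dialect (lossless float repr)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMSTAT_COLUMNS) + "\n")
        for r in panel.records:
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        str(r.n),
                        r.trait_type,
                        _fmt(r.case_fraction),
                    ]
                )
                + "\n"
            )


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD TSV: header row of SNP ids, one labeled row per SNP."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    row_ids = [str(i) for i in df.index]
    if df.shape[0] != df.shape[1]:
        raise SumstatsFormatError(
            f"{path}: LD matrix is not square ({df.shape[0]} rows x {df.shape[1]} cols)"
        )
    if row_ids != ids:
        raise SumstatsFormatError(f"{path}: LD row labels do not match column labels")
    try:
        body = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise SumstatsParseError(f"{path}: non-numeric entry in LD matrix: {exc}") from exc
    return LDMatrix(ids, body)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\t" + "\t".join(ld.snp_ids) + "\n")
        for sid, row in zip(ld.snp_ids, ld.r):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# validation


#: relative tolerance for the p-value vs |beta/se| consistency check
PZ_RTOL = 0.10


def validate_panel(panel: SummaryPanel) -> list[str]:
    """Report internal inconsistencies in a panel; an empty list means clean.

    Checks: duplicate ids (unreachable through the constructor but guarded
    for panels built by hand), non-positive standard errors, and p-values
    more than 10% (relative) away from the two-sided normal p implied by
    beta/se. The p/z check is skipped when the implied p underflows, where
    relative comparison is meaningless.
    """
    report: list[str] = []
    seen: set[str] = set()
    for r in panel.records:
        if r.snp_id in seen:
            report.append(f"{r.snp_id}: duplicate snp_id")
        seen.add(r.snp_id)
        if not r.se > 0:
            report.append(f"{r.snp_id}: se must be positive (got {r.se})")
            continue
        implied = 2.0 * norm.sf(abs(r.beta / r.se))
        if implied > 1e-290 and not math.isclose(r.pval, implied, rel_tol=PZ_RTOL):
            report.append(
                f"{r.snp_id}: pval {r.pval:g} inconsistent with |beta/se|="
                f"{abs(r.beta / r.se):.3f} (implied two-sided p {implied:g})"
            )
    return report
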