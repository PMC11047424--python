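"""End-to-end orchestration over target x tissue x outcome combinations.

Each combination flows through instrument selection -> MR estimation ->
(for Bonferroni-significant hits) colocalization and two-step mediation.
Inputs come either from summary-statistics files or from the built-in
simulator; a structured YAML config carries thresholds, multiplicity
counts, priors and the seed. All randomness derives from the single config
seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coloc as coloc_mod
from . import instruments as inst_mod
from . import io_model, mediation as med_mod, mr as mr_mod
from .synth import simulate_mr_study

__all__ = ["PipelineConfig", "Combination", "MRReportRow", "run_pipeline", "forest_table"]

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class Thresholds:
    eqtl_p: float = 1e-4
    pqtl_p: float = 5e-2
    clump_r2: float = 1e-3
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    confounder_p: float = 5e-8
    coloc_window_kb: float = 100.0
    rule_h4: float = 0.5
    alpha: float = 0.05
    mediator_gw_p: float = 5e-8

    def __post_init__(self) -> None:
        for name in ("eqtl_p", "pqtl_p", "confounder_p", "alpha", "mediator_gw_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"threshold {name}={v} outside (0, 1]")
        if not 0 < self.clump_r2 <= 1:
            raise ValueError(f"clump_r2={self.clump_r2} outside (0, 1]")
        if self.f_min < 0 or self.coloc_window_kb <= 0 or not 0 < self.rule_h4 < 1:
            raise ValueError("invalid threshold configuration")


@dataclass(slots=True)
class Combination:
    """One target x tissue x outcome analysis unit."""

    target: str
    tissue: str = "NA"
    outcome: str = "outcome"
    role: str = ""
    panel_kind: str = "eqtl"  # how instruments are selected
    simulate: dict | None = None  # parameters for simulate_mr_study
    paths: dict | None = None  # exposure/outcome/mediator/ld/confounders files

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ValueError(
                f"combination {self.target}: exactly one of 'simulate' or 'paths' required"
            )
        if self.panel_kind not in ("eqtl", "pqtl"):
            raise ValueError(f"panel_kind must be eqtl or pqtl, got {self.panel_kind!r}")


@dataclass(slots=True)
class PipelineConfig:
    combinations: list[Combination]
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_targets: int = 1
    n_tissues: int = 1
    n_outcomes: int = 1
    priors: coloc_mod.ColocPriors = field(default_factory=coloc_mod.ColocPriors)
    seed: int = 0
    force_all: bool = False  # run coloc/mediation on every row, not just hits

    def __post_init__(self) -> None:
        for name in ("n_targets", "n_tissues", "n_outcomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def bonferroni(self) -> float:
        return mr_mod.bonferroni_threshold(
            self.thresholds.alpha, [self.n_targets, self.n_tissues, self.n_outcomes]
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        thresholds = Thresholds(**{k: float(v) for k, v in raw.get("thresholds", {}).items()})
        priors = coloc_mod.ColocPriors(**{k: float(v) for k, v in raw.get("priors", {}).items()})
        mult = raw.get("multiplicity", {})
        combos = [Combination(**c) for c in raw["combinations"]]
        return cls(
            combinations=combos,
            thresholds=thresholds,
            n_targets=int(mult.get("n_targets", 1)),
            n_tissues=int(mult.get("n_tissues", 1)),
            n_outcomes=int(mult.get("n_outcomes", 1)),
            priors=priors,
            seed=int(raw.get("seed", 0)),
            force_all=bool(raw.get("force_all", False)),
        )


@dataclass(slots=True)
class MRReportRow:
    target: str
    tissue: str
    outcome: str
    role: str
    method: str
    n_snps: int
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    pval: float
    pass_bonferroni: bool
    nominal: bool
    pp_h4: float | None = None
    mediation_label: str | None = None


def _load_combination(combo: Combination, seed: int):
    """Return (exposure, outcome, mediator|None, ld, lookup|None)."""
    if combo.simulate is not None:
        params = dict(combo.simulate)
        params.setdefault("seed", seed)
        bundle = simulate_mr_study(**params)
        return (bundle.exposure_panel, bundle.outcome_panel, bundle.mediator_panel,
                bundle.ld, None)
    paths = combo.paths
    for key in ("exposure", "outcome", "ld"):
        if key not in paths:
            raise ValueError(f"combination {combo.target}: missing path {key!r}")
    exposure = io_model.read_sumstats(paths["exposure"], trait_name=combo.target,
                                      tissue=combo.tissue, panel_kind=combo.panel_kind)
    outcome = io_model.read_sumstats(paths["outcome"], trait_name=combo.outcome,
                                     panel_kind="gwas")
    mediator = None
    if paths.get("mediator"):
        mediator = io_model.read_sumstats(paths["mediator"], trait_name="mediator",
                                          panel_kind="mediator")
    ld = io_model.read_ld_matrix(paths["ld"])
    lookup = None
    if paths.get("confounders"):
        lookup = inst_mod.ConfounderLookup.from_tsv(paths["confounders"])
    return exposure, outcome, mediator, ld, lookup


def _select_instruments(combo, exposure, ld, thr, lookup, counts):
    if combo.panel_kind == "eqtl":
        top = inst_mod.select_top_instrument(exposure, thr.eqtl_p)
        selected = [top] if top is not None else []
    else:
        selected = inst_mod.ld_clump(exposure, ld, thr.pqtl_p, thr.clump_r2,
                                     thr.clump_window_kb)
    counts["selected"] = len(selected)
    strong = inst_mod.apply_f_filter(selected, thr.f_min)
    counts["f_pass"] = len(strong)
    if lookup is not None:
        strong = inst_mod.exclude_confounded(strong, lookup, thr.confounder_p)
    counts["confounder_pass"] = len(strong)
    return strong


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every configured combination; write result TSVs and a run log.

    Emits ``mr_results.tsv`` (every combination that produced an estimate),
    ``coloc_results.tsv`` and ``mediation_results.tsv`` (Bonferroni hits
    only, unless ``force_all``), and ``run_log.txt`` with the seed, the
    thresholds and per-stage record counts. Estimation failures in one
    combination are logged and skipped, never fatal to the batch.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    bonf = config.bonferroni
    log_lines = [
        f"seed\t{config.seed}",
        f"bonferroni_threshold\t{bonf:.6g}",
        f"multiplicity\t{config.n_targets}x{config.n_tissues}x{config.n_outcomes}",
    ] + [f"threshold_{k}\t{getattr(thr, k)}" for k in (
        "eqtl_p", "pqtl_p", "clump_r2", "f_min", "confounder_p",
        "coloc_window_kb", "rule_h4", "alpha", "mediator_gw_p")]

    mr_rows: list[MRReportRow] = []
    coloc_rows: list[dict] = []
    med_rows: list[dict] = []
    seed_seq = np.random.SeedSequence(config.seed)
    combo_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   seed_seq.spawn(len(config.combinations))]

    for combo, combo_seed in zip(config.combinations, combo_seeds):
        tag = f"{combo.target}/{combo.tissue}/{combo.outcome}"
        counts: dict[str, int] = {}
        try:
            exposure, outcome, mediator, ld, lookup = _load_combination(combo, combo_seed)
        except (OSError, io_model.SumstatsFormatError, io_model.SumstatsParseError) as exc:
            raise RuntimeError(f"{tag}: cannot read inputs: {exc}") from exc
        counts["exposure_snps"] = len(exposure)
        try:
            strong = _select_instruments(combo, exposure, ld, thr, lookup, counts)
            if not strong:
                log_lines.append(f"{tag}\tno instruments survived QC\t{counts}")
                continue
            pairs = mr_mod.harmonize([i.record for i in strong], outcome.records)
            counts["harmonized"] = sum(p.usable for p in pairs)
            est = mr_mod.ivw(pairs)
        except (ValueError, KeyError) as exc:
            logger.error("%s: estimation failed: %s", tag, exc)
            log_lines.append(f"{tag}\tFAILED\t{exc}")
            continue
        row = MRReportRow(
            target=combo.target, tissue=combo.tissue, outcome=combo.outcome,
            role=combo.role, method=est.method, n_snps=est.n_snps,
            beta=est.beta, se=est.se, or_value=est.or_value,
            ci_low=est.ci_low, ci_high=est.ci_high, pval=est.pval,
            pass_bonferroni=est.pval < bonf, nominal=est.pval < thr.alpha,
        )
        if row.pass_bonferroni or config.force_all:
            try:
                w1, w2 = coloc_mod.coloc_window(outcome, exposure, thr.coloc_window_kb)
                cres = coloc_mod.coloc_posteriors(w1, w2, config.priors, thr.coloc_window_kb)
                row.pp_h4 = cres.pp_h4
                coloc_rows.append({
                    "target": combo.target, "tissue": combo.tissue,
                    "outcome": combo.outcome, "top_snp": cres.top_snp,
                    "n_snps": cres.n_snps, **cres.pp,
                    "likely_coloc": cres.likely_colocalized(thr.rule_h4),
                })
            except ValueError as exc:
                logger.error("%s: coloc failed: %s", tag, exc)
                log_lines.append(f"{tag}\tCOLOC FAILED\t{exc}")
            if mediator is not None:
                try:
                    a = med_mod.step1_effect(strong, mediator)
                    b = med_mod.step2_effect(
                        mediator, outcome, ld, thr.mediator_gw_p, thr.clump_r2,
                        exclude_snps=[i.snp_id for i in strong], f_min=thr.f_min,
                    )
                    med = med_mod.mediation_summary(a, b, est)
                    row.mediation_label = med.label
                    med_rows.append({
                        "target": combo.target, "tissue": combo.tissue,
                        "outcome": combo.outcome, "mediator": mediator.trait_name,
                        "a": med.a, "se_a": med.se_a, "p_a": med.p_a,
                        "b": med.b, "se_b": med.se_b, "p_b": med.p_b,
                        "total": med.total, "indirect": med.indirect,
                        "proportion_pct": med.proportion_pct, "label": med.label,
                    })
                except ValueError as exc:
                    logger.error("%s: mediation failed: %s", tag, exc)
                    log_lines.append(f"{tag}\tMEDIATION FAILED\t{exc}")
        mr_rows.append(row)
        log_lines.append(f"{tag}\tok\t{counts}")

    forest_table(mr_rows).to_csv(outdir / "mr_results.tsv", sep="\t", index=False)
    import pandas as pd

    coloc_cols = ["target", "tissue", "outcome", "top_snp", "n_snps",
                  *coloc_mod.HYPOTHESES, "likely_coloc"]
    med_cols = ["target", "tissue", "outcome", "mediator", "a", "se_a", "p_a",
                "b", "se_b", "p_b", "total", "indirect", "proportion_pct", "label"]
    pd.DataFrame(coloc_rows, columns=coloc_cols).to_csv(
        outdir / "coloc_results.tsv", sep="\t", index=False)
    pd.DataFrame(med_rows, columns=med_cols).to_csv(
        outdir / "mediation_results.tsv", sep="\t", index=False)
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return outdir


def format_or_ci(or_value: float, ci_low: float, ci_high: float) -> str:
    """Forest-plot style string, e.g. ``0.784 (0.715–0.859)``."""
    return f"{or_value:.3f} ({ci_low:.3f}–{ci_high:.3f})"


def forest_table(rows: list[MRReportRow]):
    """Tabular stand-in for a forest plot: sorted, OR/CI at 3 dp.

    Rows are sorted by outcome then p-value with a stable sort, so p-value
    ties preserve input order.
    """
    import pandas as pd

    cols = ["target", "tissue", "outcome", "role", "method", "n_snps", "beta",
            "se", "or_value", "ci_low", "ci_high", "or_ci", "pval",
            "pass_bonferroni", "nominal", "pp_h4", "mediation_label"]
    recs = [
        {
            "target": r.target, "tissue": r.tissue, "outcome": r.outcome,
            "role": r.role, "method": r.method, "n_snps": r.n_snps,
            "beta": r.beta, "se": r.se, "or_value": r.or_value,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "or_ci": format_or_ci(r.or_value, r.ci_low, r.ci_high),
            "pval": r.pval, "pass_bonferroni": r.pass_bonferroni,
            "nominal": r.nominal, "pp_h4": r.pp_h4,
            "mediation_label": r.mediation_label,
        }
        for r in rows
    ]
    df = pd.DataFrame(recs, columns=cols)
    if len(df):
        df = df.sort_values(["outcome", "pval"], kind="stable").reset_index(drop=True)
    return df
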