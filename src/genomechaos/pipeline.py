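"""End-to-end report generation tying the analysis stages together.

``run_pipeline`` consumes a :class:`PipelineConfig` (paths plus thresholds;
all defaults are the study parameters), runs whichever stages have inputs,
writes per-stage TSVs into the output directory and returns the JSON-ready
summary dict. Deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import chromothripsis as ct
from . import damage, fusion_rna, io_formats, microhomology, sv_core

log = logging.getLogger("genomechaos")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    # inputs (any may be None; dependent stages are skipped)
    reference: str | None = None
    sv_calls: str | None = None          # BEDPE or VCF
    coverage: str | None = None
    gene_models: str | None = None
    expression: str | None = None
    fusions: str | None = None
    normal_panel: str | None = None      # TSV of gene5<TAB>gene3 keys
    ct_table: str | None = None
    out_dir: str = "chaos_out"
    seed: int = 0
    # thresholds: defaults are the study parameters
    min_spanning: int = 8
    min_split: int = 3
    min_allele_fraction: float = 0.10
    af_window_bp: int = 500
    context_window_bp: int = 200
    background_n: int = 500
    fisher_replicates: int = 100_000
    coverage_window_bp: int = 50_000
    deletion_strata_kb: tuple[int, int] = (5, 10)
    max_scan_bp: int = 25
    clustering_alpha: float = 0.005
    fold_threshold: float = 6.0
    bootstrap: int = 2000
    expressed_threshold: float = 1.0
    induction_threshold: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "deletion_strata_kb" in raw:
            raw["deletion_strata_kb"] = tuple(raw["deletion_strata_kb"])
        return cls(**raw)

    def effective_thresholds(self) -> dict:
        skip = {"reference", "sv_calls", "coverage", "gene_models", "expression",
                "fusions", "normal_panel", "ct_table", "out_dir"}
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self) if f.name not in skip}


def _read_normal_panel(path) -> set[tuple[str, str]]:
    panel = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            g5, g3 = line.rstrip("\n").split("\t")[:2]
            panel.add((g5, g3))
    return panel


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("effective thresholds: %s", config.effective_thresholds())
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "seed": config.seed,
                     "thresholds": config.effective_thresholds()}

    reference = io_formats.read_fasta(config.reference) if config.reference else None
    genes = (io_formats.read_gene_models(config.gene_models)
             if config.gene_models else None)
    expression = None
    if config.expression:
        expr_df = io_formats.read_expression_table(config.expression)
        expression = expr_df.iloc[:, 0].to_dict() if expr_df.shape[1] else {}

    calls = None
    if config.sv_calls:
        path = str(config.sv_calls)
        calls = (io_formats.read_sv_vcf_bnd(path) if path.endswith(".vcf")
                 else io_formats.read_sv_bedpe(path))
        thresholds = sv_core.FilterThresholds(
            config.min_spanning, config.min_split,
            config.min_allele_fraction, config.af_window_bp)
        filtered = sv_core.af_filter(
            sv_core.filter_sv_calls(calls, thresholds),
            config.min_allele_fraction)
        io_formats.write_sv_bedpe(filtered, out / "sv_filtered.bedpe")
        summary["sv"] = {"input": len(calls), "pass_filters": len(filtered)}
        calls = filtered

    if calls and reference:
        microhomology.measure_calls(calls, reference, config.max_scan_bp)
        strata = microhomology.LengthStrata(
            config.deletion_strata_kb[0] * 1000, config.deletion_strata_kb[1] * 1000)
        profile = microhomology.build_profile(calls, reference, strata)
        background = microhomology.random_background(
            reference, config.background_n, config.seed, config.max_scan_bp)
        pvals = microhomology.profile_vs_background(
            profile, background, config.fisher_replicates, config.seed)
        frame = profile.to_frame()
        frame["p_vs_background"] = frame["group"].map(pvals)
        frame.to_csv(out / "microhomology_profile.tsv", sep="\t", index=False)
        summary["microhomology"] = {
            g: {"n": profile.n(g), "fractions": profile.fractions(g),
                "p_vs_background": pvals[g]}
            for g in profile.counts}
        dels = [r for r in calls if r.sv_type == "DEL"]
        if len(dels) >= 3:
            rho, p = microhomology.length_homology_association(dels)
            summary["microhomology"]["deletion_length_association"] = {
                "spearman_rho": rho, "p": p}

    if calls:
        coverage = io_formats.read_coverage(config.coverage) if config.coverage else None
        thresholds_ct = ct.ChromothripsisThresholds(
            config.clustering_alpha, config.fold_threshold, bootstrap=config.bootstrap)
        reports = ct.analyze_genome(calls, coverage, thresholds_ct, config.seed)
        rows = [dataclasses.asdict(r) for r in reports]
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "chromothripsis.tsv", sep="\t", index=False)
        summary["chromothripsis"] = rows

    if config.fusions and genes is not None:
        fusions = io_formats.read_fusion_table(config.fusions)
        panel = (_read_normal_panel(config.normal_panel)
                 if config.normal_panel else set())
        fcfg = fusion_rna.FusionFilterConfig(
            min_spanning=config.min_spanning, min_split=config.min_split,
            context_window=config.context_window_bp, normal_panel=panel)
        kept = fusion_rna.filter_cascade(fusions, fcfg)
        io_formats.write_fusion_table(kept, out / "fusions_filtered.tsv")
        summary["fusion_filter"] = {"input": len(fusions), "pass": len(kept)}
        if calls is not None:
            results, per_sample = fusion_rna.concordance_summary(
                kept, calls, genes, fcfg)
            import pandas as pd
            pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
                out / "concordance.tsv", sep="\t", index=False)
            summary["concordance"] = per_sample
        if expression:
            p, effect = fusion_rna.partner_expression_enrichment(kept, expression)
            summary["partner_expression"] = {"p": p, **effect}

    if calls and genes is not None:
        _, fractions = sv_core.classify_breakpoints(
            calls, genes, expression, config.expressed_threshold)
        summary["breakpoint_classes"] = fractions

    if config.ct_table:
        table = io_formats.read_ct_table(config.ct_table)
        calls_df = damage.call_cohort(table, induction_threshold=config.induction_threshold)
        calls_df.to_csv(out / "p53_calls.tsv", sep="\t", index=False)
        summary["damage_response"] = calls_df.set_index("sample")["p53_call"].to_dict()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
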