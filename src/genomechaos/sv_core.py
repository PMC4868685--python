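"""Read-support filtering, allele-fraction estimation and breakpoint-vs-gene
classification of genomic rearrangements.

The study thresholds are the defaults: a call needs >= 8 spanning read pairs
and >= 3 split (breakpoint-covering) reads, and the allele fraction is taken
from read counts in a 500-bp window around each breakend, with a 10 %
floor for reporting. AF = S / (S + C_bar), where S is the supporting read
count (spanning + split) and C_bar the mean concordant count over the two
breakends — symmetric in the breakends and reducing to the plain read
fraction at a single junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .io_formats import GeneModel, Rearrangement

log = logging.getLogger("genomechaos")


@dataclass
class FilterThresholds:
    min_spanning: int = 8
    min_split: int = 3
    min_allele_fraction: float = 0.10
    af_window_bp: int = 500

    def __post_init__(self):
        if self.min_spanning < 0 or self.min_split < 0 or self.af_window_bp < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_allele_fraction <= 1.0:
            raise ValueError("min_allele_fraction must lie in [0, 1]")


def filter_sv_calls(calls: list[Rearrangement],
                    thresholds: FilterThresholds | None = None) -> list[Rearrangement]:
    """Keep calls with spanning >= min_spanning AND split >= min_split."""
    t = thresholds or FilterThresholds()
    return [r for r in calls
            if r.spanning_reads >= t.min_spanning and r.split_reads >= t.min_split]


def allele_frequency(rearrangement: Rearrangement) -> float | None:
    """Supporting-read fraction S/(S + C_bar); None when no reads at all.

    Concordant counts are assumed to have been collected in the configured
    window around each breakend; C_bar averages the two sides.
    """
    s = rearrangement.spanning_reads + rearrangement.split_reads
    c_bar = 0.5 * (rearrangement.concordant_a + rearrangement.concordant_b)
    if s + c_bar == 0:
        log.warning("%s: no reads in AF window; allele fraction undefined",
                    rearrangement.id)
        return None
    return s / (s + c_bar)


def af_filter(calls: list[Rearrangement], min_af: float = 0.10) -> list[Rearrangement]:
    """Subset with allele fraction >= min_af (inclusive); undefined AF drops."""
    kept = []
    for r in calls:
        af = allele_frequency(r)
        if af is not None and af >= min_af:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Breakpoint vs gene / expression classification
# ---------------------------------------------------------------------------

@dataclass
class BreakpointGeneClass:
    rearrangement_id: str
    gene_a: str | None
    gene_b: str | None
    category: str              # intergenic-both / intragenic-one / intragenic-both
    expression_category: str | None  # none-/one-/both-expressed (if >=1 intragenic)
    yields_fusion_transcript: bool = False


def _gene_trees(gene_models: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree())[g.start:g.end] = g
    return trees


def _lookup(trees, chrom: str, pos: int) -> GeneModel | None:
    tree = trees.get(chrom)
    if tree is None:
        return None
    hits = sorted(tree[pos], key=lambda iv: (iv.begin, iv.data.gene_id))
    return hits[0].data if hits else None


def classify_breakpoints(calls: list[Rearrangement],
                         gene_models: list[GeneModel],
                         expression: dict[str, float] | None = None,
                         expressed_threshold: float = 1.0,
                         fusion_gene_pairs: set[tuple[str, str]] | None = None,
                         ) -> tuple[list[BreakpointGeneClass], dict[str, float]]:
    """Classify each call's breakends against gene bodies and expression.

    Gene overlap is half-open body containment (start <= pos < end). Genes
    missing from ``expression`` are treated as not expressed (logged once).
    Returns per-call classes plus fraction summaries over the gene-overlap
    partition and, within intragenic calls, the expression partition.
    """
    trees = _gene_trees(gene_models)
    expression = expression or {}
    fusion_gene_pairs = fusion_gene_pairs or set()
    missing: set[str] = set()

    def expressed(gene: GeneModel | None) -> bool:
        if gene is None:
            return False
        if gene.gene_id not in expression:
            missing.add(gene.gene_id)
            return False
        return expression[gene.gene_id] > expressed_threshold

    results = []
    for r in calls:
        ga = _lookup(trees, r.breakend_a.chrom, r.breakend_a.pos)
        gb = _lookup(trees, r.breakend_b.chrom, r.breakend_b.pos)
        n_in = (ga is not None) + (gb is not None)
        category = ("intergenic-both", "intragenic-one", "intragenic-both")[n_in]
        expr_cat = None
        if n_in:
            n_expr = expressed(ga) + expressed(gb)
            expr_cat = ("none-expressed", "one-expressed", "both-expressed")[n_expr]
        fusion = False
        if ga is not None and gb is not None:
            fusion = ((ga.gene_id, gb.gene_id) in fusion_gene_pairs
                      or (gb.gene_id, ga.gene_id) in fusion_gene_pairs)
        results.append(BreakpointGeneClass(
            r.id, ga.gene_id if ga else None, gb.gene_id if gb else None,
            category, expr_cat, fusion))
    if missing:
        log.info("%d genes absent from expression table; treated as not expressed",
                 len(missing))

    n = len(results)
    summary: dict[str, float] = {}
    for cat in ("intergenic-both", "intragenic-one", "intragenic-both"):
        summary[cat] = sum(c.category == cat for c in results) / n if n else float("nan")
    intragenic = [c for c in results if c.expression_category is not None]
    m = len(intragenic)
    for cat in ("none-expressed", "one-expressed", "both-expressed"):
        summary[cat] = (sum(c.expression_category == cat for c in intragenic) / m
                       if m else float("nan"))
    if n:
        summary["intragenic-any"] = (summary["intragenic-one"]
                                     + summary["intragenic-both"])
    return results, summary


def intragenic_genome_fraction(gene_models: list[GeneModel],
                               genome_lengths: dict[str, int]) -> float:
    """Union length of gene bodies divided by total genome length."""
    total = sum(genome_lengths.values())
    if total <= 0:
        raise ValueError("empty genome")
    covered = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append((g.start, min(g.end, genome_lengths[g.chrom])))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return covered / total
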