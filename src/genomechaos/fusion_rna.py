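"""Fusion-transcript filtering and RNA-DNA concordance.

The RNA side of the analysis: chimeric transcript calls from two discovery
tools are merged, passed through the filter cascade (normal-tissue panel,
junction sequence complexity, read support), and then each surviving fusion
is matched against the genomic rearrangement calls. A fusion is *genomic*
when a rearrangement can physically produce the observed 5'->3' chimera,
*read-through* when the rearrangement lands in a neighbouring gene and
transcription runs through into the reported partner, and *unsupported*
otherwise — the trans-splicing candidates that turn out to dominate.

All thresholds default to the study values: >= 8 spanning and >= 3 split
reads, a 200-bp junction context for the complexity screen, and an
order-sensitive (gene5, gene3) key for the normal panel, because chimeric
transcripts are directional.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import HEAD, TAIL, FusionTranscript, GeneModel, Rearrangement


@dataclass
class FusionFilterConfig:
    min_spanning: int = 8
    min_split: int = 3
    context_window: int = 200            # bp around the junction
    complexity_threshold: float = 1.5    # dinucleotide entropy, bits/symbol
    repeat_coverage_max: float = 0.5     # tandem-repeat fraction of the window
    merge_tolerance_bp: int = 10
    read_through_window_bp: int = 1_000_000
    normal_panel: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        if min(self.min_spanning, self.min_split, self.context_window) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.context_window % 2:
            raise ValueError("context window must be even")


@dataclass
class ConcordanceResult:
    fusion_id: str
    status: str                      # genomic-direct / genomic-read-through / unsupported
    matched_rearrangement: str | None
    rationale: str

    def __post_init__(self):
        if self.status.startswith("genomic") and self.matched_rearrangement is None:
            raise ValueError("genomic status requires a matched rearrangement id")


# ---------------------------------------------------------------------------
# Merge of two callers
# ---------------------------------------------------------------------------

def merge_caller_outputs(calls_a: list[FusionTranscript],
                         calls_b: list[FusionTranscript],
                         tolerance_bp: int = 10) -> list[FusionTranscript]:
    """Union of two callers' fusions, keyed by partner pair and junction
    coordinates within ``tolerance_bp``; provenance marks A, B or both."""
    merged: list[FusionTranscript] = []
    for f in calls_a:
        f.provenance = "A"
        merged.append(f)
    for g in calls_b:
        match = next(
            (f for f in merged
             if f.pair_key == g.pair_key
             and f.chrom5 == g.chrom5 and f.chrom3 == g.chrom3
             and abs(f.pos5 - g.pos5) <= tolerance_bp
             and abs(f.pos3 - g.pos3) <= tolerance_bp),
            None)
        if match is not None:
            match.provenance = "both"
            match.spanning_reads = max(match.spanning_reads, g.spanning_reads)
            match.split_reads = max(match.split_reads, g.split_reads)
        else:
            g.provenance = "B"
            merged.append(g)
    return merged


# ---------------------------------------------------------------------------
# Filter cascade (independent predicates; order-free)
# ---------------------------------------------------------------------------

def normal_panel_filter(fusions: list[FusionTranscript],
                        panel: set[tuple[str, str]]) -> list[FusionTranscript]:
    """Drop fusions whose directional (gene5, gene3) key is in the panel."""
    return [f for f in fusions if f.pair_key not in panel]


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits/symbol) over overlapping dinucleotides."""
    if len(seq) < 2:
        return 0.0
    counts = Counter(seq[i:i + 2] for i in range(len(seq) - 1))
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def longest_tandem_repeat_coverage(seq: str, max_unit: int = 6) -> float:
    """Fraction of the sequence covered by its longest exact tandem run
    (repeat units of 1..max_unit bp)."""
    if not seq:
        return 0.0
    best = 0
    for u in range(1, min(max_unit, len(seq) // 2) + 1):
        run = u
        longest = 0
        for i in range(u, len(seq)):
            if seq[i] == seq[i - u]:
                run += 1
            else:
                longest = max(longest, run)
                run = u
        longest = max(longest, run)
        if longest >= 2 * u:  # at least two full copies
            best = max(best, longest)
    return best / len(seq)


def junction_complexity_filter(fusions: list[FusionTranscript],
                               config: FusionFilterConfig | None = None,
                               ) -> list[FusionTranscript]:
    """Drop low-complexity / highly repetitive junction contexts.

    Removed iff dinucleotide entropy < threshold OR the longest tandem
    repetition covers more than half the window. Contexts shorter than the
    configured window are evaluated on the available bases (warned).
    """
    cfg = config or FusionFilterConfig()
    kept = []
    for f in fusions:
        ctx = f.junction_context
        if not ctx:
            kept.append(f)  # nothing to evaluate; read filters still apply
            continue
        if 0 < len(ctx) < cfg.context_window:
            warnings.warn(f"{f.id}: junction context {len(ctx)} bp "
                          f"< {cfg.context_window} bp window; evaluated as is")
        if dinucleotide_entropy(ctx) < cfg.complexity_threshold:
            continue
        if longest_tandem_repeat_coverage(ctx) > cfg.repeat_coverage_max:
            continue
        kept.append(f)
    return kept


def read_support_filter(fusions: list[FusionTranscript],
                        config: FusionFilterConfig | None = None,
                        ) -> list[FusionTranscript]:
    cfg = config or FusionFilterConfig()
    return [f for f in fusions
            if f.spanning_reads >= cfg.min_spanning
            and f.split_reads >= cfg.min_split]


def filter_cascade(fusions: list[FusionTranscript],
                   config: FusionFilterConfig | None = None,
                   ) -> list[FusionTranscript]:
    cfg = config or FusionFilterConfig()
    out = normal_panel_filter(fusions, cfg.normal_panel)
    out = junction_complexity_filter(out, cfg)
    out = read_support_filter(out, cfg)
    return out


# ---------------------------------------------------------------------------
# RNA-DNA concordance
# ---------------------------------------------------------------------------

def _required_orientation(gene: GeneModel, five_prime: bool) -> str:
    """Breakend orientation that retains the needed transcript part.

    The 5' partner keeps its upstream (promoter-side) portion; the 3'
    partner keeps its downstream portion. On the + strand upstream means
    retain-left (tail)."""
    if five_prime:
        return TAIL if gene.strand == "+" else HEAD
    return HEAD if gene.strand == "+" else TAIL


def _breakend_in_gene(be, gene: GeneModel) -> bool:
    return be.chrom == gene.chrom and gene.contains(be.pos)


def _exon_compatible(gene: GeneModel, pos: int, fusion_exon: int,
                     five_prime: bool) -> bool:
    """Breakend must fall after the last fused 5' exon / before the first
    fused 3' exon, in transcript orientation."""
    if fusion_exon <= 0 or not gene.exons:
        return True  # exon annotation absent: body containment suffices
    exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
    if five_prime:
        if fusion_exon > len(exons):
            return True
        s, e = exons[fusion_exon - 1]
        return pos >= e if gene.strand == "+" else pos < s
    if fusion_exon > len(exons):
        return True
    s, e = exons[fusion_exon - 1]
    return pos < s if gene.strand == "+" else pos >= e


def match_fusion_to_genome(fusion: FusionTranscript,
                           rearrangements: list[Rearrangement],
                           gene_models: list[GeneModel],
                           config: FusionFilterConfig | None = None,
                           ) -> ConcordanceResult:
    """Match one fusion transcript against the genomic rearrangement calls.

    genomic-direct: some rearrangement places one correctly oriented
    breakend in the 5' partner (downstream of the last fused exon) and the
    other in the 3' partner (upstream of the first fused exon).

    genomic-read-through: the 3'-side breakend lies not in the partner but
    in a gene within ``read_through_window_bp`` of it on the same strand —
    transcription runs through the neighbour into the reported partner.
    """
    cfg = config or FusionFilterConfig()
    genes = {g.gene_id: g for g in gene_models}
    g5, g3 = genes.get(fusion.gene5), genes.get(fusion.gene3)
    if g5 is None or g3 is None:
        warnings.warn(f"{fusion.id}: partner gene missing from models")
        return ConcordanceResult(fusion.id, "unsupported", None,
                                 "partner gene absent from gene models")
    neighbours3 = [g for g in gene_models
                   if g.chrom == g3.chrom and g.gene_id != g3.gene_id
                   and g.strand == g3.strand
                   and abs(g.start - g3.start) <= cfg.read_through_window_bp]

    def five_prime_side_ok(be):
        return (_breakend_in_gene(be, g5)
                and be.orientation == _required_orientation(g5, True)
                and _exon_compatible(g5, be.pos, fusion.exon5, True))

    # direct matches take precedence over read-through across all calls
    for r in rearrangements:
        for be5, be3 in ((r.breakend_a, r.breakend_b), (r.breakend_b, r.breakend_a)):
            if (five_prime_side_ok(be5)
                    and _breakend_in_gene(be3, g3)
                    and be3.orientation == _required_orientation(g3, False)
                    and _exon_compatible(g3, be3.pos, fusion.exon3, False)):
                return ConcordanceResult(
                    fusion.id, "genomic-direct", r.id,
                    f"breakends in {g5.gene_id} and {g3.gene_id}, "
                    "orientations collinear")
    for r in rearrangements:
        for be5, be3 in ((r.breakend_a, r.breakend_b), (r.breakend_b, r.breakend_a)):
            if not five_prime_side_ok(be5):
                continue
            for nb in neighbours3:
                if (_breakend_in_gene(be3, nb)
                        and be3.orientation == _required_orientation(nb, False)):
                    return ConcordanceResult(
                        fusion.id, "genomic-read-through", r.id,
                        f"3' breakend in neighbour {nb.gene_id} of {g3.gene_id}")
    return ConcordanceResult(fusion.id, "unsupported", None,
                             "no compatible rearrangement")


def concordance_summary(fusions: list[FusionTranscript],
                        rearrangements: list[Rearrangement],
                        gene_models: list[GeneModel],
                        config: FusionFilterConfig | None = None,
                        ) -> tuple[list[ConcordanceResult], dict[str, dict[str, int]]]:
    """Per-sample matched/total fusion counts plus per-fusion results."""
    results = [match_fusion_to_genome(f, rearrangements, gene_models, config)
               for f in fusions]
    per_sample: dict[str, dict[str, int]] = {}
    for f, res in zip(fusions, results):
        d = per_sample.setdefault(f.sample, {"matched": 0, "total": 0})
        d["total"] += 1
        if res.status.startswith("genomic"):
            d["matched"] += 1
    return results, per_sample


# ---------------------------------------------------------------------------
# Partner expression enrichment
# ---------------------------------------------------------------------------

def partner_expression_enrichment(fusions: list[FusionTranscript],
                                  expression: dict[str, float],
                                  ) -> tuple[float | None, dict[str, float]]:
    """Wilcoxon rank-sum test: abundance of distinct fusion-partner genes
    versus all other genes. Two-sided; returns (p, effect summary)."""
    partners = sorted({g for f in fusions for g in (f.gene5, f.gene3)}
                      & set(expression))
    others = sorted(set(expression) - set(partners))
    if len(partners) < 3 or len(others) < 3:
        warnings.warn("fewer than 3 fusion partners with expression; "
                      "enrichment p undefined")
        return None, {"n_partners": len(partners), "n_others": len(others)}
    x = np.array([expression[g] for g in partners])
    y = np.array([expression[g] for g in others])
    stat, p = stats.ranksums(x, y)
    return float(p), {
        "n_partners": len(partners), "n_others": len(others),
        "median_partner": float(np.median(x)), "median_other": float(np.median(y)),
        "statistic": float(stat)}
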