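"""Fusion filter cascade, caller merging, genome concordance matching and
partner-expression enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from genomechaos import fusion_rna as fr
from genomechaos import synthetic
from genomechaos.fusion_rna import FusionFilterConfig
from genomechaos.io_formats import FusionTranscript
from genomechaos.synthetic import SimulationConfig


def _fusion(i=0, g5="A", g3="B", pos5=1000, pos3=2000, spanning=20, split=10,
            ctx=None, sample="s", rt=False):
    if ctx is None:
        rng = np.random.default_rng(i)
        ctx = "".join("ACGT"[b] for b in rng.integers(0, 4, 200))
    return FusionTranscript(id=f"f{i}", gene5=g5, gene3=g3, chrom5="chr1",
                            pos5=pos5, chrom3="chr2", pos3=pos3, exon5=2,
                            exon3=2, spanning_reads=spanning, split_reads=split,
                            junction_context=ctx, sample=sample, read_through=rt)


class TestMerge:
    def test_identical_call_merges_with_both_provenance(self):
        merged = fr.merge_caller_outputs([_fusion(1)], [_fusion(1)])
        assert len(merged) == 1 and merged[0].provenance == "both"

    def test_disjoint_calls_union(self):
        merged = fr.merge_caller_outputs([_fusion(1)], [_fusion(2, g5="C")])
        assert len(merged) == 2
        assert {f.provenance for f in merged} == {"A", "B"}

    @pytest.mark.parametrize("offset,n_expected", [
        (0, 1), (5, 1), (10, 1), (11, 2), (50, 2)])
    def test_coordinate_tolerance_rule(self, offset, n_expected):
        a = _fusion(1)
        b = _fusion(2, pos5=1000 + offset, pos3=2000)
        assert len(fr.merge_caller_outputs([a], [b])) == n_expected


class TestNormalPanel:
    def test_panel_pair_removed(self):
        assert fr.normal_panel_filter([_fusion(1)], {("A", "B")}) == []

    def test_reciprocal_pair_kept_order_sensitive(self):
        kept = fr.normal_panel_filter([_fusion(1)], {("B", "A")})
        assert len(kept) == 1

    def test_empty_panel_is_identity(self):
        fus = [_fusion(i) for i in range(4)]
        assert fr.normal_panel_filter(fus, set()) == fus


class TestComplexity:
    def test_poly_a_removed_entropy_zero(self):
        f = _fusion(1, ctx="A" * 200)
        assert fr.dinucleotide_entropy("A" * 200) == 0.0
        assert fr.junction_complexity_filter([f]) == []

    def test_uniform_random_contexts_pass(self):
        """Uniform random 200-mers pass the complexity screen > 99.9 %."""
        rng = np.random.default_rng(3)
        fus = [_fusion(i, ctx="".join("ACGT"[b] for b in rng.integers(0, 4, 200)))
               for i in range(2000)]
        kept = fr.junction_complexity_filter(fus)
        assert len(kept) / len(fus) > 0.999
        # near the closed-form maximum of 4 bits over the 16 dinucleotides
        assert fr.dinucleotide_entropy(fus[0].junction_context) > 3.5

    def test_dinucleotide_repeat_removed(self):
        f = _fusion(1, ctx="AC" * 100)
        assert fr.dinucleotide_entropy("AC" * 100) == pytest.approx(1.0, abs=0.01)
        assert fr.junction_complexity_filter([f]) == []
        assert fr.longest_tandem_repeat_coverage("AC" * 100) == 1.0

    def test_short_context_evaluated_with_warning(self):
        f = _fusion(1, ctx="ACGTTGCAACGTTGCA" * 4)  # 64 bp, complex enough
        with pytest.warns(UserWarning, match="context"):
            assert fr.junction_complexity_filter([f]) == [f]


class TestReadSupport:
    @pytest.mark.parametrize("spanning,split,kept", [
        (8, 3, True), (8, 2, False), (7, 3, False), (50, 50, True)])
    def test_boundaries(self, spanning, split, kept):
        out = fr.read_support_filter([_fusion(1, spanning=spanning, split=split)])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert fr.read_support_filter([]) == []


class TestCascadeOrderIndependence:
    def test_all_filter_orders_agree(self):
        """The three predicates are independent: any application order gives
        the same surviving set."""
        rng = np.random.default_rng(5)
        fus = []
        for i in range(40):
            ctx = ("A" * 200 if i % 5 == 0 else
                   "".join("ACGT"[b] for b in rng.integers(0, 4, 200)))
            fus.append(_fusion(i, g5=f"G{i % 7}", g3=f"H{i % 3}",
                               spanning=int(rng.integers(0, 20)),
                               split=int(rng.integers(0, 8)), ctx=ctx))
        cfg = FusionFilterConfig(normal_panel={("G1", "H1"), ("G2", "H2")})
        filters = [lambda x: fr.normal_panel_filter(x, cfg.normal_panel),
                   lambda x: fr.junction_complexity_filter(x, cfg),
                   lambda x: fr.read_support_filter(x, cfg)]
        outcomes = set()
        for order in itertools.permutations(filters):
            out = list(fus)
            for f in order:
                out = f(out)
            outcomes.add(tuple(x.id for x in out))
        assert len(outcomes) == 1


def _fusion_truth_setup(seed, **cfg_kwargs):
    cfg = SimulationConfig(seed=seed, n_chromosomes=2, chrom_length_bp=200_000,
                           **cfg_kwargs)
    ref, genes = synthetic.simulate_genome(cfg)
    fus, rearrs, truths, panel = synthetic.simulate_fusion_calls(
        cfg, ref, genes, np.random.default_rng(seed + 100))
    return genes, fus, rearrs, {t.id: t.label for t in truths}


class TestConcordance:
    def test_planted_genomic_fusions_matched_directly(self):
        genes, fus, rearrs, labels = _fusion_truth_setup(
            7, n_fusions=30, trans_splice_fraction=0.0,
            normal_panel_fraction=0.0, read_through_fraction=0.0)
        results, per_sample = fr.concordance_summary(fus, rearrs, genes)
        genomic = [r for r in results if labels[r.fusion_id] == "genomic"]
        assert genomic and all(r.status == "genomic-direct" for r in genomic)
        assert per_sample["sim"]["matched"] >= len(genomic)

    def test_planted_read_through_matched_via_neighbour(self):
        genes, fus, rearrs, labels = _fusion_truth_setup(
            9, n_fusions=40, trans_splice_fraction=0.0,
            normal_panel_fraction=0.0, read_through_fraction=1.0)
        results, _ = fr.concordance_summary(fus, rearrs, genes)
        rt = [r for r in results if labels[r.fusion_id] == "read-through"]
        # every planted read-through is linked to the genome (with heavy gene
        # reuse a collision may legitimately upgrade some to direct)
        assert rt and all(r.status.startswith("genomic") for r in rt)
        assert any(r.status == "genomic-read-through" for r in rt)

    def test_hand_built_read_through_case(self):
        """One translocation into gene N, fusion reported to N's neighbour:
        the matcher links them as read-through."""
        from genomechaos.io_formats import (HEAD, TAIL, Breakend, GeneModel,
                                            Rearrangement)
        g5 = GeneModel("G5", "chr1", "+", 1000, 9000,
                       [(1000, 2000), (4000, 5000), (8000, 9000)])
        nb = GeneModel("NB", "chr2", "+", 1000, 9000,
                       [(1000, 2000), (4000, 5000), (8000, 9000)])
        g3 = GeneModel("G3", "chr2", "+", 20_000, 28_000,
                       [(20_000, 21_000), (24_000, 25_000), (27_000, 28_000)])
        sv = Rearrangement("svX", "TRA", Breakend("chr1", 2_500, TAIL),
                           Breakend("chr2", 2_500, HEAD))
        fusion = _fusion(1, g5="G5", g3="G3", pos5=2_500, pos3=22_000)
        fusion.exon5 = 1  # breakend in intron 1: only exon 1 retained
        res = fr.match_fusion_to_genome(fusion, [sv], [g5, nb, g3])
        assert res.status == "genomic-read-through"
        assert res.matched_rearrangement == "svX"
        assert "NB" in res.rationale

    def test_trans_splice_only_never_genomic(self):
        """Specificity: without any planted rearrangement no fusion can be
        called genomic."""
        genes, fus, rearrs, _ = _fusion_truth_setup(
            11, n_fusions=50, trans_splice_fraction=1.0,
            normal_panel_fraction=0.0, read_through_fraction=0.0)
        assert rearrs == []
        results, per_sample = fr.concordance_summary(fus, rearrs, genes)
        assert all(r.status == "unsupported" for r in results)
        assert per_sample["sim"]["matched"] == 0

    def test_missing_partner_gene_unsupported_with_warning(self):
        genes, fus, rearrs, _ = _fusion_truth_setup(7, n_fusions=5,
                                                    trans_splice_fraction=0.0,
                                                    normal_panel_fraction=0.0,
                                                    read_through_fraction=0.0)
        with pytest.warns(UserWarning, match="missing"):
            res = fr.match_fusion_to_genome(fus[0], rearrs, genes[2:3])
        assert res.status == "unsupported"

    def test_counts_equal_all_pairs_oracle(self):
        """Matched counts agree with a quadratic body-containment oracle on a
        mixed 50-fusion set."""
        genes, fus, rearrs, labels = _fusion_truth_setup(
            13, n_fusions=50, trans_splice_fraction=0.5,
            normal_panel_fraction=0.0, read_through_fraction=0.0)
        gene_by_id = {g.gene_id: g for g in genes}

        def side_ok(be, gene, five_prime, fused_exon):
            # plain re-derivation: body containment, retained-side orientation,
            # and position beyond/before the fused exon in transcript order
            if be.chrom != gene.chrom or not gene.start <= be.pos < gene.end:
                return False
            if five_prime:
                want = "tail" if gene.strand == "+" else "head"
            else:
                want = "head" if gene.strand == "+" else "tail"
            if be.orientation != want:
                return False
            exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
            if not 1 <= fused_exon <= len(exons):
                return True
            s, e = exons[fused_exon - 1]
            if five_prime:
                return be.pos >= e if gene.strand == "+" else be.pos < s
            return be.pos < s if gene.strand == "+" else be.pos >= e

        def oracle_supported(f):
            g5, g3 = gene_by_id[f.gene5], gene_by_id[f.gene3]
            return any(
                side_ok(b5, g5, True, f.exon5) and side_ok(b3, g3, False, f.exon3)
                for r in rearrs
                for b5, b3 in ((r.breakend_a, r.breakend_b),
                               (r.breakend_b, r.breakend_a)))

        results, _ = fr.concordance_summary(fus, rearrs, genes)
        for f, r in zip(fus, results):
            assert (r.status == "genomic-direct") == oracle_supported(f)

    def test_sensitivity_on_planted_genomic_fusions(self):
        """>= 99 % of planted genomic fusions recover their rearrangement."""
        matched = total = 0
        for seed in (21, 22, 23, 24, 25):
            genes, fus, rearrs, labels = _fusion_truth_setup(
                seed, n_fusions=100, trans_splice_fraction=0.0,
                normal_panel_fraction=0.0, read_through_fraction=0.0)
            results, _ = fr.concordance_summary(fus, rearrs, genes)
            genomic = [r for r in results if labels[r.fusion_id] == "genomic"]
            total += len(genomic)
            matched += sum(r.status == "genomic-direct" for r in genomic)
        assert total >= 400
        assert matched / total >= 0.99


class TestPartnerExpression:
    def _expression(self, rng, n=1000):
        return {f"g{i}": float(x)
                for i, x in enumerate(rng.lognormal(0, 1.5, n))}

    def test_top_decile_partners_enriched(self):
        rng = np.random.default_rng(17)
        expr = self._expression(rng)
        top = sorted(expr, key=expr.get, reverse=True)[:100]
        fus = [_fusion(i, g5=top[2 * i], g3=top[2 * i + 1]) for i in range(20)]
        p, effect = fr.partner_expression_enrichment(fus, expr)
        assert p < 1e-4
        assert effect["median_partner"] > effect["median_other"]

    def test_uniform_partners_give_uniform_p(self):
        """Calibration: partners drawn at random leave p ~ Uniform(0,1)."""
        rng = np.random.default_rng(19)
        ps = []
        for _ in range(200):
            expr = self._expression(rng, 400)
            names = list(expr)
            pick = rng.choice(len(names), size=40, replace=False)
            fus = [_fusion(i, g5=names[pick[2 * i]], g3=names[pick[2 * i + 1]])
                   for i in range(20)]
            p, _ = fr.partner_expression_enrichment(fus, expr)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_partners_flagged(self):
        expr = {"A": 1.0, "B": 2.0, "X": 0.5}
        with pytest.warns(UserWarning, match="fewer than 3"):
            p, _ = fr.partner_expression_enrichment([_fusion(1)], expr)
        assert p is None
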