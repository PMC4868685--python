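"""Synthetic genomes, rearrangement truth sets, read evidence, coverage,
fusion calls and qPCR plates with the statistical structure the downstream
analyses assume.

The generator is the test bed for the whole pipeline: every quantity the
analysis modules estimate (junction microhomology, allele fraction,
breakpoint clustering, coverage fold change, fusion/genome concordance, p53
functional status) is planted here with known truth, so estimators can be
checked for exact recovery or unbiasedness without any external data.

Default parameters emulate the osteosarcoma study regime: four rearrangement
classes with short-deletion junctions enriched for 6-25 bp microhomology
(MMEJ-like) versus mostly <=5 bp for translocations/inversions/duplications,
interchromosomal allele fractions between 1 and 50 %, read evidence as a
binomial split of a 500-bp window's depth, a roughly 40 % intragenic genome,
and a fusion-call population in which only a minority has a genomic
rearrangement behind it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import HEAD, TAIL, Breakend, FusionTranscript, GeneModel, Rearrangement
from .microhomology import MAX_SCAN, junction_microhomology

_BASES = np.frombuffer(b"ACGT", dtype="u1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# minimum clearance between planted breakends (and from contig ends) so
# microhomology writes can never interact across junctions
_MARGIN = 2 * (MAX_SCAN + 1)
_MIN_SEPARATION = 200


# ---------------------------------------------------------------------------
# Configuration & truth records
# ---------------------------------------------------------------------------

def _default_mixture() -> dict[str, tuple[float, float, float]]:
    # (none, 1-5 bp, 6-25 bp); short deletions carry the MMEJ-like excess
    return {
        "DEL_short": (0.15, 0.25, 0.60),
        "DEL_long": (0.35, 0.40, 0.25),
        "DEL_verylong": (0.42, 0.45, 0.13),
        "DUP": (0.40, 0.47, 0.13),
        "INV": (0.40, 0.47, 0.13),
        "TRA": (0.40, 0.47, 0.13),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 500_000
    gc: float = 0.41
    gene_fraction: float = 0.40
    gene_length_bp: int = 8_000
    exons_per_gene: int = 4
    sv_counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 60, "DUP": 25, "INV": 25, "TRA": 40})
    microhomology_mixture: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_mixture)
    clustered_fraction: float = 0.0
    cluster_width_bp: int = 50_000
    amplified_fold: float = 1.0
    depth: int = 200                      # mean read pairs per 500-bp window
    allele_fraction_range: tuple[float, float] = (0.01, 0.50)
    split_read_fraction: float = 0.30     # of supporting reads that are split
    n_fusions: int = 60
    trans_splice_fraction: float = 0.70
    normal_panel_fraction: float = 0.10
    read_through_fraction: float = 0.05
    coverage_window_bp: int = 50_000

    def validate(self) -> None:
        for name, vec in self.microhomology_mixture.items():
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"mixture {name} does not sum to 1")
            if any(p < 0 for p in vec):
                raise ValueError(f"mixture {name} has negative probability")
        if any(n < 0 for n in self.sv_counts.values()):
            raise ValueError("negative SV count")
        lo, hi = self.allele_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("allele_fraction_range must be within [0, 1]")
        if not 0.0 <= self.clustered_fraction <= 1.0:
            raise ValueError("clustered_fraction must be a probability")
        if self.trans_splice_fraction + self.normal_panel_fraction \
                + self.read_through_fraction > 1.0 + 1e-9:
            raise ValueError("fusion label fractions exceed 1")
        if self.amplified_fold < 1.0:
            raise ValueError("amplified_fold must be >= 1")
        if self.chrom_length_bp < 10_000:
            raise ValueError("chromosomes < 10 kb are too small to plant junctions")


@dataclass
class TruthRecord:
    id: str
    mh_len: int | None = None            # planted junction homology, bp
    allele_fraction: float | None = None
    cluster_id: str | None = None
    label: str | None = None             # fusion mechanism label

    def __post_init__(self):
        if self.mh_len is not None and not 0 <= self.mh_len <= MAX_SCAN:
            raise ValueError(f"planted microhomology {self.mh_len} outside [0, {MAX_SCAN}]")


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-operation substreams so reordering one stage cannot
    perturb another."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[dict[str, bytearray], list[GeneModel]]:
    """Uniform-random toy genome plus gene models tiling ``gene_fraction``.

    The reference is returned as mutable bytearrays so junction homology can
    be planted in place; :func:`as_strings` finalises it.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    reference: dict[str, bytearray] = {}
    genes: list[GeneModel] = []
    for i in range(1, config.n_chromosomes + 1):
        chrom = f"chr{i}"
        idx = rng.choice(4, size=config.chrom_length_bp, p=p)
        reference[chrom] = bytearray(_BASES[idx].tobytes())
        genes.extend(_tile_genes(config, chrom, rng))
    return reference, genes


def _tile_genes(config: SimulationConfig, chrom: str,
                rng: np.random.Generator) -> list[GeneModel]:
    glen = config.gene_length_bp
    if config.gene_fraction <= 0 or glen <= 0:
        return []
    n_genes = int(round(config.gene_fraction * config.chrom_length_bp / glen))
    if n_genes == 0:
        return []
    period = config.chrom_length_bp // n_genes
    if period < glen:
        raise ValueError("gene_fraction/gene_length combination over-tiles the genome")
    genes = []
    for j in range(n_genes):
        start = j * period
        end = start + glen
        n_ex = config.exons_per_gene
        exon_len = glen // (2 * n_ex)
        step = glen // n_ex
        exons = [(start + k * step, start + k * step + exon_len) for k in range(n_ex)]
        exons[-1] = (exons[-1][0], end)  # last exon runs to the gene end
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"{chrom}_g{j}", chrom, strand, start, end, exons))
    return genes


def as_strings(reference: dict[str, bytearray]) -> dict[str, str]:
    return {c: bytes(s).decode("ascii") for c, s in reference.items()}


# ---------------------------------------------------------------------------
# Junction planting
# ---------------------------------------------------------------------------

def _write_pre_junction(reference: dict[str, bytearray], be: Breakend,
                        offset: int, base: str) -> None:
    """Set the reference base ``offset`` positions before ``be``'s retained
    segment (junction-oriented), respecting strand."""
    s = reference[be.chrom]
    if be.orientation == HEAD:
        s[be.pos - offset] = ord(base)
    else:
        s[be.pos + offset - 1] = ord(_COMP[base])


def plant_rearrangement(reference: dict[str, bytearray], sv_type: str,
                        breakend_a: Breakend, breakend_b: Breakend,
                        mh_len: int, rng: np.random.Generator,
                        rid: str = "sv0", sample: str = ".") -> tuple[Rearrangement, TruthRecord]:
    """Plant exactly ``mh_len`` bases of junction slide homology.

    The bases immediately preceding ``breakend_b``'s retained segment are
    overwritten with a copy of ``breakend_a``'s retained flank; the base one
    position further out is forced to mismatch so measurement returns exactly
    ``mh_len``. Requires clearance of at least ``2*(max_scan+1)`` bp from
    contig ends.
    """
    if not 0 <= mh_len <= MAX_SCAN:
        raise ValueError(f"mh_len {mh_len} outside the [0, {MAX_SCAN}] category system")
    for be in (breakend_a, breakend_b):
        if not _MARGIN <= be.pos <= len(reference[be.chrom]) - _MARGIN:
            raise ValueError(f"breakend {be.chrom}:{be.pos} too close to a contig end")
    if breakend_a.chrom == breakend_b.chrom and \
            abs(breakend_a.pos - breakend_b.pos) < _MIN_SEPARATION:
        raise ValueError("breakends too close together to plant independently")

    view = as_strings({c: reference[c] for c in
                       {breakend_a.chrom, breakend_b.chrom}})
    from .microhomology import upstream_flank
    up = upstream_flank(view, breakend_a, mh_len + 1)
    for j in range(1, mh_len + 1):
        _write_pre_junction(reference, breakend_b, j, up[-j])
    # force a mismatch one base beyond the planted homology
    if len(up) > mh_len:
        blocked = up[-(mh_len + 1)]
        alt = [b for b in "ACGT" if b != blocked]
        _write_pre_junction(reference, breakend_b, mh_len + 1,
                            alt[int(rng.integers(len(alt)))])

    view = as_strings({c: reference[c] for c in
                       {breakend_a.chrom, breakend_b.chrom}})
    measured, _ = junction_microhomology(view, breakend_a, breakend_b)
    if measured != mh_len:
        raise AssertionError(f"planting failed: wanted {mh_len}, measured {measured}")
    rearr = Rearrangement(id=rid, sv_type=sv_type, breakend_a=breakend_a,
                          breakend_b=breakend_b, sample=sample,
                          microhomology_len=None)
    truth = TruthRecord(id=rid, mh_len=mh_len)
    return rearr, truth


_SV_ORIENTATIONS = {"DEL": (TAIL, HEAD), "DUP": (HEAD, TAIL)}


def breakends_for_type(sv_type: str, chrom_a: str, pos_a: int,
                       chrom_b: str, pos_b: int,
                       rng: np.random.Generator) -> tuple[Breakend, Breakend]:
    """Standard join orientations: DEL tail-head, DUP head-tail, INV
    tail-tail or head-head, TRA any of the four combinations."""
    if sv_type in _SV_ORIENTATIONS:
        oa, ob = _SV_ORIENTATIONS[sv_type]
    elif sv_type == "INV":
        oa = ob = TAIL if rng.random() < 0.5 else HEAD
    elif sv_type == "TRA":
        oa = TAIL if rng.random() < 0.5 else HEAD
        ob = TAIL if rng.random() < 0.5 else HEAD
    else:
        raise ValueError(f"unknown sv_type {sv_type}")
    return Breakend(chrom_a, pos_a, oa), Breakend(chrom_b, pos_b, ob)


# ---------------------------------------------------------------------------
# Read evidence
# ---------------------------------------------------------------------------

def simulate_read_evidence(depth: int, allele_fraction: float,
                           rng: np.random.Generator,
                           split_fraction: float = 0.30,
                           ) -> tuple[int, int, tuple[int, int]]:
    """Binomial split of a window's read pairs into supporting vs concordant.

    Returns (spanning, split, (concordant_a, concordant_b)). The implied
    estimator support/(support + mean concordant) is unbiased for
    ``allele_fraction`` up to O(1/depth) ratio bias.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError("allele_fraction outside [0, 1]")
    support = int(rng.binomial(depth, allele_fraction))
    split = int(rng.binomial(support, split_fraction))
    spanning = support - split
    conc_a = int(rng.binomial(depth, 1.0 - allele_fraction))
    conc_b = int(rng.binomial(depth, 1.0 - allele_fraction))
    return spanning, split, (conc_a, conc_b)


# ---------------------------------------------------------------------------
# Full SV truth set
# ---------------------------------------------------------------------------

def _sample_mh(mixture: tuple[float, float, float], rng: np.random.Generator) -> int:
    cat = rng.choice(3, p=np.asarray(mixture))
    if cat == 0:
        return 0
    if cat == 1:
        return int(rng.integers(1, 6))
    return int(rng.integers(6, MAX_SCAN + 1))


def _del_stratum(length: int) -> str:
    if length < 5_000:
        return "DEL_short"
    return "DEL_long" if length < 10_000 else "DEL_verylong"


def _free_position(used: dict[str, list[int]], chrom: str, lo: int, hi: int,
                   rng: np.random.Generator, tries: int = 200) -> int:
    for _ in range(tries):
        pos = int(rng.integers(lo, hi))
        if all(abs(pos - q) >= _MIN_SEPARATION for q in used[chrom]):
            used[chrom].append(pos)
            return pos
    raise RuntimeError("could not place a breakpoint with the required clearance")


def _free_pair(used: dict[str, list[int]], chrom: str, lo: int, hi: int,
               size: int, rng: np.random.Generator, tries: int = 200) -> tuple[int, int]:
    """Two same-chromosome breakends ``size`` apart, both with clearance."""
    for _ in range(tries):
        pa = int(rng.integers(lo, hi))
        pb = pa + size
        if all(abs(p - q) >= _MIN_SEPARATION
               for p in (pa, pb) for q in used[chrom]):
            used[chrom].extend([pa, pb])
            return pa, pb
    raise RuntimeError("could not place a breakpoint pair with the required clearance")


def simulate_sv_truth_set(config: SimulationConfig,
                          ) -> tuple[dict[str, str], list[GeneModel],
                                     list[Rearrangement], list[TruthRecord]]:
    """Genome + planted rearrangements + read evidence + truth table."""
    config.validate()
    rng_genome, rng_place, rng_mh, rng_reads = _rng_streams(config.seed, 4)
    reference, genes = simulate_genome(config, rng_genome)
    chroms = list(reference)
    L = config.chrom_length_bp
    used: dict[str, list[int]] = {c: [] for c in chroms}

    # one cluster window per chromosome for the clustered fraction
    cluster_windows = {}
    for c in chroms:
        start = int(rng_place.integers(_MARGIN, L - config.cluster_width_bp - _MARGIN))
        cluster_windows[c] = (start, start + config.cluster_width_bp)

    calls: list[Rearrangement] = []
    truths: list[TruthRecord] = []
    counter = 0
    for sv_type, n in config.sv_counts.items():
        for _ in range(n):
            counter += 1
            rid = f"sv{counter:04d}"
            clustered = rng_place.random() < config.clustered_fraction
            if sv_type == "TRA":
                ca, cb = rng_place.choice(len(chroms), size=2, replace=False)
                ca, cb = chroms[ca], chroms[cb]
                if clustered:
                    wa, wb = cluster_windows[ca], cluster_windows[cb]
                    pa = _free_position(used, ca, wa[0], wa[1], rng_place)
                    pb = _free_position(used, cb, wb[0], wb[1], rng_place)
                else:
                    pa = _free_position(used, ca, _MARGIN, L - _MARGIN, rng_place)
                    pb = _free_position(used, cb, _MARGIN, L - _MARGIN, rng_place)
                stratum = "TRA"
            else:
                ca = cb = chroms[int(rng_place.integers(len(chroms)))]
                if sv_type == "DEL":
                    # log-uniform event sizes, 300 bp .. 100 kb
                    size = int(10 ** rng_place.uniform(np.log10(300), np.log10(100_000)))
                else:
                    size = int(10 ** rng_place.uniform(np.log10(300), np.log10(50_000)))
                stratum = _del_stratum(size) if sv_type == "DEL" else sv_type
                lo, hi = _MARGIN, L - size - _MARGIN
                if clustered:
                    w = cluster_windows[ca]
                    if w[0] < hi:
                        lo, hi = w[0], min(w[1], hi)
                pa, pb = _free_pair(used, ca, lo, max(hi, lo + 1), size, rng_place)
            mh = _sample_mh(config.microhomology_mixture[stratum], rng_mh)
            be_a, be_b = breakends_for_type(sv_type, ca, pa, cb, pb, rng_place)
            rearr, truth = plant_rearrangement(reference, sv_type, be_a, be_b,
                                               mh, rng_mh, rid=rid, sample="sim")
            af = float(rng_reads.uniform(*config.allele_fraction_range))
            spanning, split, (c_a, c_b) = simulate_read_evidence(
                config.depth, af, rng_reads, config.split_read_fraction)
            rearr.spanning_reads, rearr.split_reads = spanning, split
            rearr.concordant_a, rearr.concordant_b = c_a, c_b
            truth.allele_fraction = af
            truth.cluster_id = f"{ca}_cluster" if clustered else None
            calls.append(rearr)
            truths.append(truth)
    return as_strings(reference), genes, calls, truths


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def simulate_coverage(reference: dict[str, str],
                      amplified_regions: list[tuple[str, int, int]],
                      fold: float, depth: float,
                      rng: np.random.Generator | int = 0,
                      window: int = 50_000) -> pd.DataFrame:
    """Windowed Poisson coverage track; amplified windows at fold x depth."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for chrom, seq in reference.items():
        for start in range(0, len(seq), window):
            end = min(start + window, len(seq))
            amplified = any(c == chrom and s < end and start < e
                            for c, s, e in amplified_regions)
            lam = depth * (fold if amplified else 1.0)
            rows.append((chrom, start, end, int(rng.poisson(lam))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])


# ---------------------------------------------------------------------------
# Fusion calls
# ---------------------------------------------------------------------------

def simulate_fusion_calls(config: SimulationConfig,
                          reference: dict[str, str] | dict[str, bytearray],
                          genes: list[GeneModel],
                          rng: np.random.Generator | None = None,
                          sample: str = "sim",
                          ) -> tuple[list[FusionTranscript], list[Rearrangement],
                                     list[TruthRecord], set[tuple[str, str]]]:
    """Emit fusion calls with known mechanism labels.

    Labels: ``genomic`` (a planted rearrangement links the partners),
    ``read-through`` (the rearrangement's 3' breakend lies in the gene
    *adjacent* to the reported partner), ``trans-splice`` and
    ``normal-panel`` (no genomic support; the latter's partner key is added
    to the returned blacklist).
    """
    config.validate()
    if not genes:
        raise ValueError("gene models required to simulate fusions")
    rng = rng or np.random.default_rng(config.seed + 1)
    if isinstance(next(iter(reference.values())), bytearray):
        mutable = reference
    else:
        mutable = {c: bytearray(s.encode()) for c, s in reference.items()}

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)

    p_genomic = max(0.0, 1.0 - (config.trans_splice_fraction
                                + config.normal_panel_fraction
                                + config.read_through_fraction))
    labels = rng.choice(
        ["genomic", "read-through", "trans-splice", "normal-panel"],
        size=config.n_fusions,
        p=[p_genomic, config.read_through_fraction,
           config.trans_splice_fraction, config.normal_panel_fraction])

    fusions, rearrs, truths = [], [], []
    panel: set[tuple[str, str]] = set()
    sv_counter = 0
    for i, label in enumerate(labels):
        fid = f"fus{i:04d}"
        g5, g3 = _pick_partner_genes(genes, rng)
        spanning = int(rng.integers(8, 60))
        split = int(rng.integers(3, 25))
        ctx = "".join("ACGT"[b] for b in rng.integers(0, 4, size=200))
        if label in ("genomic", "read-through"):
            # breakend gene on the 3' side: the partner itself, or (read-through)
            # its left neighbour so transcription must run through into g3
            target3 = g3
            if label == "read-through":
                sibs = by_chrom[g3.chrom]
                j = sibs.index(g3)
                neighbours = [g for g in (sibs[j - 1:j] + sibs[j + 1:j + 2])
                              if g.strand == g3.strand and g.gene_id != g5.gene_id]
                if not neighbours:
                    label = "genomic"
                else:
                    target3 = neighbours[0]
            pos5 = _intron_position(g5, five_prime=True, rng=rng)
            pos3 = _intron_position(target3, five_prime=False, rng=rng)
            be5 = Breakend(g5.chrom, pos5, TAIL if g5.strand == "+" else HEAD)
            be3 = Breakend(target3.chrom, pos3,
                           HEAD if target3.strand == "+" else TAIL)
            sv_counter += 1
            rid = f"fsv{sv_counter:04d}"
            mh = int(rng.integers(0, 6))
            if be5.chrom == be3.chrom:
                a, b = sorted([be5, be3], key=lambda x: x.pos)
                sv_type = ({"tail": {"head": "DEL", "tail": "INV"},
                            "head": {"tail": "DUP", "head": "INV"}}
                           [a.orientation][b.orientation])
            else:
                a, b, sv_type = be5, be3, "TRA"
            try:
                rearr, _ = plant_rearrangement(mutable, sv_type, a, b, mh, rng,
                                               rid=rid, sample=sample)
            except ValueError:
                # clearance failure near a previous junction: fall back
                label = "trans-splice"
                rearr = None
            if rearr is not None:
                rearr.spanning_reads, rearr.split_reads = spanning, split
                rearrs.append(rearr)
                fusions.append(FusionTranscript(
                    id=fid, gene5=g5.gene_id, gene3=g3.gene_id,
                    chrom5=g5.chrom, pos5=pos5, chrom3=g3.chrom,
                    pos3=pos3 if label == "genomic" else _mid_intron(g3, rng),
                    exon5=_exon_before(g5, pos5), exon3=2,
                    spanning_reads=spanning, split_reads=split,
                    junction_context=ctx, sample=sample))
                truths.append(TruthRecord(id=fid, label=label))
                continue
        # no genomic support
        pos5 = _intron_position(g5, five_prime=True, rng=rng)
        pos3 = _mid_intron(g3, rng)
        fusions.append(FusionTranscript(
            id=fid, gene5=g5.gene_id, gene3=g3.gene_id,
            chrom5=g5.chrom, pos5=pos5, chrom3=g3.chrom, pos3=pos3,
            exon5=_exon_before(g5, pos5), exon3=1,
            spanning_reads=spanning, split_reads=split,
            junction_context=ctx, sample=sample))
        truths.append(TruthRecord(id=fid, label=label))
        if label == "normal-panel":
            panel.add((g5.gene_id, g3.gene_id))
    return fusions, rearrs, truths, panel


def _pick_partner_genes(genes: list[GeneModel],
                        rng: np.random.Generator) -> tuple[GeneModel, GeneModel]:
    while True:
        i, j = rng.choice(len(genes), size=2, replace=False)
        g5, g3 = genes[i], genes[j]
        if g5.chrom != g3.chrom or abs(g5.start - g3.start) > 50_000:
            return g5, g3


def _intron_position(gene: GeneModel, five_prime: bool,
                     rng: np.random.Generator) -> int:
    """Position in the first intron (3' partner) or last intron (5' partner),
    in transcript orientation."""
    introns = gene.introns
    if gene.strand == "-":
        introns = introns[::-1]
    s, e = introns[-1] if five_prime else introns[0]
    return int(rng.integers(s + 10, e - 10))


def _mid_intron(gene: GeneModel, rng: np.random.Generator) -> int:
    s, e = gene.introns[0]
    return int(rng.integers(s + 10, e - 10))


def _exon_before(gene: GeneModel, pos: int) -> int:
    """1-based index (transcript order) of the last exon upstream of pos."""
    exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
    n = 0
    for i, (s, e) in enumerate(exons, start=1):
        if (gene.strand == "+" and e <= pos) or (gene.strand == "-" and s >= pos):
            n = i
    return max(n, 1)


# ---------------------------------------------------------------------------
# Radiation-damage qPCR plates
# ---------------------------------------------------------------------------

DAMAGE_TARGETS = ("CDKN1A", "BAX")
REFERENCE_GENE = "TBP"


def simulate_damage_assay(p53_status: str, seed: int | np.random.Generator = 0,
                          sample: str = "cell", induction_fold: float = 4.0,
                          noise_sd: float = 0.15,
                          replicates: int = 3) -> pd.DataFrame:
    """Ct plate for one sample: CDKN1A/BAX + TBP reference at 0 h and 8 h.

    p53-functional samples get a planted target induction of
    ``induction_fold`` at 8 h (Ct drop of log2(fold)); deficient samples get
    none. Gaussian Ct noise, sigma ``noise_sd`` cycles.
    """
    if p53_status not in ("functional", "deficient"):
        raise ValueError("p53_status must be 'functional' or 'deficient'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    drop = np.log2(induction_fold) if p53_status == "functional" else 0.0
    rows = []
    for target, base in ((REFERENCE_GENE, 25.0), (DAMAGE_TARGETS[0], 28.0),
                         (DAMAGE_TARGETS[1], 29.0)):
        for timepoint in ("0h", "8h"):
            ct0 = base
            if target != REFERENCE_GENE and timepoint == "8h":
                ct0 = base - drop
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append((sample, target, int(target == REFERENCE_GENE),
                             timepoint, rep, ct0 + noise))
    return pd.DataFrame(rows, columns=["sample", "target", "reference_flag",
                                       "timepoint", "replicate", "ct"])


def simulate_damage_cohort(statuses: dict[str, str],
                           seed: int = 0, **kwargs) -> tuple[pd.DataFrame, dict[str, str]]:
    """Ct table for a cohort of samples with planted p53 statuses."""
    streams = _rng_streams(seed, len(statuses))
    tables = [simulate_damage_assay(status, rng, sample=name, **kwargs)
              for (name, status), rng in zip(sorted(statuses.items()), streams)]
    return pd.concat(tables, ignore_index=True), dict(statuses)
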