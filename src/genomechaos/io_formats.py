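"""Readers/writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversions to and from
1-based formats (VCF) happen here and nowhere else.

Breakend orientation vocabulary:

* ``"tail"``  -- the retained segment lies to the *left* of ``pos`` (the
  junction continues from the 3' end of the reference strand segment).
* ``"head"`` -- the retained segment lies at/right of ``pos``.

In BEDPE strand columns, ``+`` encodes tail and ``-`` encodes head.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("genomechaos")

TAIL = "tail"
HEAD = "head"
SV_TYPES = ("DEL", "DUP", "INV", "TRA")

_STRAND_TO_ORIENT = {"+": TAIL, "-": HEAD}
_ORIENT_TO_STRAND = {TAIL: "+", HEAD: "-"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Breakend:
    """One side of a rearrangement junction."""

    chrom: str
    pos: int          # 0-based
    orientation: str  # TAIL or HEAD

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")
        if self.orientation not in (TAIL, HEAD):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class Rearrangement:
    """A typed junction with its read evidence.

    ``microhomology_len`` is ``None`` when not yet measured.
    """

    id: str
    sv_type: str
    breakend_a: Breakend
    breakend_b: Breakend
    spanning_reads: int = 0
    split_reads: int = 0
    concordant_a: int = 0
    concordant_b: int = 0
    sample: str = "."
    microhomology_len: int | None = None

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        a, b = self.breakend_a, self.breakend_b
        if self.sv_type == "TRA":
            if a.chrom == b.chrom:
                raise ValueError(f"{self.id}: TRA breakends on the same chromosome")
        else:
            if a.chrom != b.chrom:
                raise ValueError(f"{self.id}: intrachromosomal SV on two chromosomes")
            if not a.pos < b.pos:
                raise ValueError(f"{self.id}: requires breakend_a.pos < breakend_b.pos")
        for n in (self.spanning_reads, self.split_reads,
                  self.concordant_a, self.concordant_b):
            if n < 0:
                raise ValueError(f"{self.id}: negative read count")

    @property
    def span(self) -> int | None:
        """Event length for intrachromosomal SVs, else None."""
        if self.sv_type == "TRA":
            return None
        return self.breakend_b.pos - self.breakend_a.pos


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int                       # transcript start, 0-based
    end: int                         # transcript end, half-open
    exons: list[tuple[int, int]] = field(default_factory=list)
    protein_length: int | None = None                 # aa
    domains: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based aa

    def __post_init__(self):
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if self.protein_length is not None:
            for name, s, e in self.domains:
                if not (1 <= s <= e <= self.protein_length):
                    raise ValueError(f"{self.gene_id}: domain {name} outside protein")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    def contains(self, pos: int) -> bool:
        """Gene-body containment, half-open [start, end)."""
        return self.start <= pos < self.end

    def intron_index(self, pos: int) -> int | None:
        """1-based intron number containing ``pos`` (strand-aware), or None."""
        introns = self.introns
        if self.strand == "-":
            introns = introns[::-1]
        for i, (s, e) in enumerate(introns, start=1):
            if s <= pos < e:
                return i
        return None


@dataclass
class FusionTranscript:
    """A chimeric transcript call with its genomic junction coordinates."""

    id: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    chrom3: str
    pos3: int
    exon5: int = 0            # last included exon of the 5' partner
    exon3: int = 0            # first included exon of the 3' partner
    spanning_reads: int = 0
    split_reads: int = 0
    junction_context: str = ""
    sample: str = "."
    read_through: bool = False
    provenance: str = "."

    def __post_init__(self):
        if self.gene5 == self.gene3 and not self.read_through:
            raise ValueError(f"{self.id}: identical partners without read-through flag")
        if self.spanning_reads < 0 or self.split_reads < 0:
            raise ValueError(f"{self.id}: negative read count")

    @property
    def pair_key(self) -> tuple[str, str]:
        """Order-sensitive partner key (chimeras are directional)."""
        return (self.gene5, self.gene3)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

_BEDPE_HEADER = ("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
                 "strand1\tstrand2\tsv_type\tspanning\tsplit\t"
                 "concordant_a\tconcordant_b\tsample\tmh_len")


def write_sv_bedpe(calls: list[Rearrangement], path) -> None:
    with open(path, "w") as fh:
        fh.write(_BEDPE_HEADER + "\n")
        for r in calls:
            a, b = r.breakend_a, r.breakend_b
            mh = "." if r.microhomology_len is None else str(r.microhomology_len)
            fh.write("\t".join(map(str, [
                a.chrom, a.pos, a.pos + 1, b.chrom, b.pos, b.pos + 1,
                r.id, ".",
                _ORIENT_TO_STRAND[a.orientation], _ORIENT_TO_STRAND[b.orientation],
                r.sv_type, r.spanning_reads, r.split_reads,
                r.concordant_a, r.concordant_b, r.sample, mh,
            ])) + "\n")


def read_sv_bedpe(path) -> list[Rearrangement]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 17:
                raise FormatError(f"{path}:{lineno}: expected 17 BEDPE columns, got {len(f)}")
            try:
                sv_type = f[10]
                if sv_type not in SV_TYPES:
                    raise ValueError(f"unknown sv_type {sv_type!r}")
                calls.append(Rearrangement(
                    id=f[6], sv_type=sv_type,
                    breakend_a=Breakend(f[0], int(f[1]), _STRAND_TO_ORIENT[f[8]]),
                    breakend_b=Breakend(f[3], int(f[4]), _STRAND_TO_ORIENT[f[9]]),
                    spanning_reads=int(f[11]), split_reads=int(f[12]),
                    concordant_a=int(f[13]), concordant_b=int(f[14]),
                    sample=f[15],
                    microhomology_len=None if f[16] == "." else int(f[16]),
                ))
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return calls


# ---------------------------------------------------------------------------
# VCF (BND subset)
# ---------------------------------------------------------------------------

def _parse_bnd_alt(alt: str) -> tuple[str, int, str, str]:
    """Decode a VCF breakend ALT string.

    Returns (mate_chrom, mate_pos_1based, this_orientation, mate_orientation),
    covering the four bracket cases of the VCF spec:

    ``t[m[`` tail/head, ``t]m]`` tail/tail, ``]m]t`` head/tail, ``[m[t`` head/head.
    """
    for br in "[]":
        if br in alt:
            left, mate, right = alt.split(br)[0], alt.split(br)[1], alt.split(br)[2]
            chrom, pos = mate.rsplit(":", 1)
            this = TAIL if left else HEAD
            mate_orient = HEAD if br == "[" else TAIL
            return chrom, int(pos), this, mate_orient
    raise FormatError(f"not a breakend ALT: {alt!r}")


def _bnd_internal_pos(pos_1based: int, orientation: str) -> int:
    # tail: POS names the last retained base -> retained [0, POS) 0-based.
    # head: POS names the first retained base -> internal pos = POS - 1.
    return pos_1based if orientation == TAIL else pos_1based - 1


def read_sv_vcf_bnd(path) -> list[Rearrangement]:
    """Read DELLY-style VCF: symbolic DEL/DUP/INV records plus BND pairs."""
    calls: list[Rearrangement] = []
    pending: dict[str, tuple] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype in ("DEL", "DUP", "INV"):
                end = rec.stop  # pysam: 0-based exclusive end from INFO/END
                orient_a, orient_b = {
                    "DEL": (TAIL, HEAD), "DUP": (HEAD, TAIL), "INV": (TAIL, TAIL),
                }[svtype]
                calls.append(Rearrangement(
                    id=rec.id or f"sv{len(calls)}", sv_type=svtype,
                    breakend_a=Breakend(rec.chrom, rec.pos - 1, orient_a),
                    breakend_b=Breakend(rec.chrom, end, orient_b),
                    spanning_reads=int(rec.info.get("PE", 0)),
                    split_reads=int(rec.info.get("SR", 0)),
                ))
            elif svtype == "BND" or (rec.alts and any(b in rec.alts[0] for b in "[]")):
                mate_chrom, mate_pos, this_o, mate_o = _parse_bnd_alt(rec.alts[0])
                key = rec.info.get("MATEID")
                key = key[0] if isinstance(key, tuple) else key
                if key in pending:
                    o_chrom, o_pos, o_orient, o_id, o_rec = pending.pop(key)
                    a = Breakend(o_chrom, _bnd_internal_pos(o_pos, o_orient), o_orient)
                    b = Breakend(rec.chrom, _bnd_internal_pos(rec.pos, this_o), this_o)
                    sv_type = "TRA" if a.chrom != b.chrom else _intra_type(a, b)
                    if sv_type != "TRA" and a.pos > b.pos:
                        a, b = b, a
                    calls.append(Rearrangement(
                        id=o_id, sv_type=sv_type, breakend_a=a, breakend_b=b,
                        spanning_reads=int(o_rec.info.get("PE", 0)),
                        split_reads=int(o_rec.info.get("SR", 0)),
                    ))
                else:
                    pending[rec.id] = (rec.chrom, rec.pos, this_o, rec.id, rec)
            elif svtype is not None:
                warnings.warn(f"skipping SVTYPE={svtype} record {rec.id} "
                              "(outside the DEL/DUP/INV/TRA system)")
    for key, (chrom, pos, orient, rid, _) in pending.items():
        warnings.warn(f"unpaired BND record {rid} at {chrom}:{pos}; skipped")
    return calls


def _intra_type(a: Breakend, b: Breakend) -> str:
    pair = tuple(sorted([a, b], key=lambda x: x.pos))
    o = (pair[0].orientation, pair[1].orientation)
    return {"tail": {"head": "DEL", "tail": "INV"},
            "head": {"tail": "DUP", "head": "INV"}}[o[0]][o[1]]


# ---------------------------------------------------------------------------
# Gene models (GTF-lite / BED12)
# ---------------------------------------------------------------------------

def write_gene_models_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gtf-lite\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join(map(str, [
                g.chrom, "genomechaos", "gene", g.start + 1, g.end, ".",
                g.strand, ".", attrs])) + "\n")
            for s, e in g.exons:
                fh.write("\t".join(map(str, [
                    g.chrom, "genomechaos", "exon", s + 1, e, ".",
                    g.strand, ".", attrs])) + "\n")


def _read_gtf_lite(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = f
            gid = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gid = part.split(None, 1)[1].strip('"')
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start0, end0 = int(start) - 1, int(end)
            if feature == "gene":
                if gid in genes:
                    raise FormatError(f"{path}:{lineno}: duplicate gene id {gid}")
                genes[gid] = GeneModel(gid, chrom, strand, start0, end0)
            elif feature == "exon":
                genes[gid].exons.append((start0, end0))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


def _read_bed12(path) -> list[GeneModel]:
    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {name}")
            seen.add(name)
            exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def read_gene_models(path) -> list[GeneModel]:
    """Dispatch on content: GTF-lite (9 columns, attribute field) or BED12."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                ncol = len(line.rstrip("\n").split("\t"))
                return _read_gtf_lite(path) if ncol == 9 else _read_bed12(path)
    return []


# ---------------------------------------------------------------------------
# Tables (TSV)
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.DataFrame:
    """Gene x sample abundance table (unit-free, FPKM-like)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [df.columns[0].lstrip("#")] + list(df.columns[1:])
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in expression table: {dups}")
    return df.astype(float)


def write_expression_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "#gene"
    out.to_csv(path, sep="\t")


_FUSION_COLS = ["id", "sample", "gene5", "gene3", "chrom5", "pos5", "chrom3",
                "pos3", "exon5", "exon3", "spanning", "split", "read_through",
                "provenance", "junction_context"]


def write_fusion_table(fusions: list[FusionTranscript], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_FUSION_COLS) + "\n")
        for fu in fusions:
            fh.write("\t".join(map(str, [
                fu.id, fu.sample, fu.gene5, fu.gene3, fu.chrom5, fu.pos5,
                fu.chrom3, fu.pos3, fu.exon5, fu.exon3, fu.spanning_reads,
                fu.split_reads, int(fu.read_through), fu.provenance,
                fu.junction_context or "."])) + "\n")


def read_fusion_table(path) -> list[FusionTranscript]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    fusions = []
    for _, row in df.iterrows():
        ctx = row["junction_context"]
        fusions.append(FusionTranscript(
            id=str(row["id"]), gene5=row["gene5"], gene3=row["gene3"],
            chrom5=str(row["chrom5"]), pos5=int(row["pos5"]),
            chrom3=str(row["chrom3"]), pos3=int(row["pos3"]),
            exon5=int(row["exon5"]), exon3=int(row["exon3"]),
            spanning_reads=int(row["spanning"]), split_reads=int(row["split"]),
            junction_context="" if ctx == "." or pd.isna(ctx) else str(ctx),
            sample=str(row["sample"]), read_through=bool(int(row["read_through"])),
            provenance=str(row["provenance"])))
    return fusions


def read_coverage(path) -> pd.DataFrame:
    """bedGraph-like windowed coverage: chrom, start, end, depth."""
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "start", "end", "depth"], comment="#")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_coverage(track: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tdepth\n")
        track.to_csv(fh, sep="\t", header=False, index=False)


def read_ct_table(path) -> pd.DataFrame:
    """qPCR Ct table: sample, target, reference_flag, timepoint, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"sample", "target", "reference_flag", "timepoint", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.columns = ["#" + out.columns[0]] + list(out.columns[1:])
    out.to_csv(path, sep="\t", index=False)
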