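"""Gene-centric aberration classification and cohort-level statistics.

Covers the tumor/cell-line summaries of the p53 pathway: classifying raw
aberration descriptions into {rearrangement, snv, indel, amplification},
per-sample pathway status with the precedence TP53 structural > TP53
point mutation/indel > MDM2 amplification, hotspot counting at intron
resolution, wild-type allele-fraction statistics, protein-level consequence
arithmetic, and the simple validation-rate / recurrence percentages.

Bundled data files encode the published screening and cohort tables this
module is exercised on; they are loaded with :func:`load_table1` etc.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from statistics import median

import pandas as pd

_DATA = resources.files("genomechaos") / "data"

# size at or above which a deletion/insertion counts as a structural
# rearrangement rather than an indel (standard SV convention)
SV_SIZE_THRESHOLD_BP = 50


@dataclass
class AberrationRecord:
    sample: str
    gene: str
    aberration_class: str          # rearrangement / snv / indel / amplification / none
    sub_type: str = "."            # del / dup / inv / tra / high-level-ampl / ...
    location: str = "."
    consequence: str = "."
    aberrant_af: float | None = None   # fraction in [0, 1]
    wt_af: float | None = None
    copy_number: float | None = None

    def __post_init__(self):
        if self.aberration_class == "amplification" and self.copy_number is None:
            raise ValueError(f"{self.sample}/{self.gene}: amplification requires "
                             "a copy number")
        for f in (self.aberrant_af, self.wt_af):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.sample}/{self.gene}: allele fraction "
                                 f"{f} outside [0, 1]")


@dataclass
class ProteinAnnotation:
    protein_length: int
    domains: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based aa

    def __post_init__(self):
        for name, s, e in self.domains:
            if not 1 <= s <= e <= self.protein_length:
                raise ValueError(f"domain {name} outside [1, {self.protein_length}]")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

_SIZE_RE = re.compile(r"\(\s*([\d.]+)\s*(bp|kb|Mb)\s*\)", re.IGNORECASE)
_UNIT_BP = {"bp": 1, "kb": 1_000, "mb": 1_000_000}
_CN_RE = re.compile(r"CN of\s+([\d.]+)", re.IGNORECASE)


def _parse_size_bp(type_str: str) -> float | None:
    m = _SIZE_RE.search(type_str)
    if m is None:
        return None
    return float(m.group(1)) * _UNIT_BP[m.group(2).lower()]


def _parse_percent(text: str) -> float | None:
    text = str(text).strip()
    if text in (".", "", "-", "nan"):
        return None
    return float(text.rstrip("%")) / 100.0


def classify_aberration(sample: str, gene: str, type_str: str,
                        position: str = ".", consequence: str = ".",
                        aberrant_af: float | None = None,
                        wt_af: float | None = None) -> AberrationRecord:
    """Classify a raw aberration description.

    Interchromosomal events and intrachromosomal events of >= 50 bp are
    structural rearrangements; smaller deletions/insertions are indels;
    single-nucleotide changes are SNVs; high-level amplifications carry
    their copy number parsed from the consequence text.
    """
    t = type_str.strip()
    low = t.lower()
    size = _parse_size_bp(t)
    common = dict(sample=sample, gene=gene, location=position,
                  consequence=consequence, aberrant_af=aberrant_af, wt_af=wt_af)
    if low.startswith("trans"):
        return AberrationRecord(aberration_class="rearrangement", sub_type="tra", **common)
    if low.startswith("inv"):
        return AberrationRecord(aberration_class="rearrangement", sub_type="inv", **common)
    if low.startswith("dup"):
        return AberrationRecord(aberration_class="rearrangement", sub_type="dup", **common)
    if "del" in low:
        if size is not None and size < SV_SIZE_THRESHOLD_BP:
            return AberrationRecord(aberration_class="indel", sub_type="del", **common)
        return AberrationRecord(aberration_class="rearrangement", sub_type="del", **common)
    if low == "snv" or low.startswith("snv"):
        return AberrationRecord(aberration_class="snv", sub_type="snv", **common)
    if "ampl" in low:
        m = _CN_RE.search(consequence)
        cn = float(m.group(1)) if m else None
        return AberrationRecord(aberration_class="amplification",
                                sub_type="high-level-ampl", copy_number=cn, **common)
    raise ValueError(f"unparseable aberration type {type_str!r} "
                     f"for {sample}/{gene}")


# ---------------------------------------------------------------------------
# Pathway status and cohort frequencies
# ---------------------------------------------------------------------------

PATHWAY_CLASSES = ("TP53-rearranged", "TP53-mutated", "MDM2-amplified", "none")


def pathway_status(sample_records: list[AberrationRecord]) -> str:
    """p53-pathway status for one sample with the fixed precedence
    TP53 structural > TP53 snv/indel > MDM2 amplification > none."""
    tp53 = [r for r in sample_records if r.gene == "TP53"]
    if any(r.aberration_class == "rearrangement" for r in tp53):
        return "TP53-rearranged"
    if any(r.aberration_class in ("snv", "indel") for r in tp53):
        return "TP53-mutated"
    if any(r.gene == "MDM2" and r.aberration_class == "amplification"
           for r in sample_records):
        return "MDM2-amplified"
    return "none"


def cohort_pathway_frequencies(records: list[AberrationRecord],
                               n_samples: int) -> dict[str, int]:
    """Integer percentages of pathway-status classes over ``n_samples``.

    Samples absent from ``records`` count as 'none'.
    """
    by_sample: dict[str, list[AberrationRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample, []).append(r)
    statuses = [pathway_status(rs) for rs in by_sample.values()]
    out = {}
    for cls in PATHWAY_CLASSES[:3]:
        out[cls] = round(100 * sum(s == cls for s in statuses) / n_samples)
    out["none"] = 100 - sum(out.values())
    return out


def class_frequencies(classes: list[str], n_samples: int) -> dict[str, int]:
    """Integer percentage per class label over ``n_samples`` (one label per
    sample, e.g. the cell-line p53-inactivation cause list)."""
    out: dict[str, int] = {}
    for cls in sorted(set(classes)):
        out[cls] = round(100 * classes.count(cls) / n_samples)
    return out


def wt_allele_stats(records: list[AberrationRecord]) -> tuple[float, float, float]:
    """(min, median, max) of the known wild-type allele fractions.

    One value per record carrying a wt fraction; an even count takes the
    mean of the central pair. Raises when no record has a known fraction.
    """
    values = [r.wt_af for r in records if r.wt_af is not None]
    if not values:
        raise ValueError("no records with a known wild-type allele fraction")
    return min(values), float(median(values)), max(values)


# ---------------------------------------------------------------------------
# Hotspots and protein consequences
# ---------------------------------------------------------------------------

_INTRON_RE = re.compile(r"^intron\s+(\d+)$", re.IGNORECASE)


def hotspot_detection(records: list[AberrationRecord],
                      hotspot_min: int = 2) -> dict[int, dict]:
    """Distinct-sample counts per intron, flagging hotspots.

    Only records whose location is an intron index are counted; a sample
    with several events in the same intron counts once. Introns reaching
    ``hotspot_min`` samples are flagged, the maximum labelled "hotspot".
    """
    per_intron: dict[int, set[str]] = {}
    for r in records:
        m = _INTRON_RE.match(r.location.strip())
        if m:
            per_intron.setdefault(int(m.group(1)), set()).add(r.sample)
    if not per_intron:
        return {}
    max_count = max(len(s) for s in per_intron.values())
    return {intron: {"count": len(samples),
                     "hotspot": len(samples) >= hotspot_min,
                     "label": ("hotspot" if len(samples) == max_count
                               and len(samples) >= hotspot_min else "")}
            for intron, samples in sorted(per_intron.items())}


def protein_consequence(annotation: ProteinAnnotation,
                        retained: tuple[int, int]) -> dict:
    """Residues lost and domains lost/disrupted for a retained aa interval.

    ``retained`` is 1-based inclusive. A domain disjoint from the retained
    interval is lost; a partially overlapping one is disrupted.
    """
    start, end = retained
    if not 1 <= start <= end <= annotation.protein_length:
        raise ValueError(f"retained interval {retained} outside "
                         f"[1, {annotation.protein_length}]")
    lost_aa = annotation.protein_length - (end - start + 1)
    lost, disrupted = [], []
    for name, s, e in annotation.domains:
        if e < start or s > end:
            lost.append(name)
        elif s < start or e > end:
            disrupted.append(name)
    return {"lost_residues": lost_aa, "lost_domains": lost,
            "disrupted_domains": disrupted}


# ---------------------------------------------------------------------------
# Simple cohort percentages
# ---------------------------------------------------------------------------

def validation_rate(table: pd.DataFrame, confirmed_col: str = "sanger") -> int:
    """Percent of tested candidates confirmed (here: by Sanger sequencing)."""
    if table.empty:
        raise ValueError("no candidates tested")
    confirmed = int((table[confirmed_col] == "+").sum())
    return round(100 * confirmed / len(table))


def recurrence_frequency(positive_ids, cohort_sizes: dict[str, int]) -> int:
    """Percent positive across the stated cohorts, deduplicated by id."""
    total = sum(cohort_sizes.values())
    if total <= 0:
        raise ValueError("empty cohorts")
    return round(100 * len(set(positive_ids)) / total)


# ---------------------------------------------------------------------------
# Bundled table loaders
# ---------------------------------------------------------------------------

def _read_tsv(name: str, **kwargs) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, **kwargs)
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def load_table1() -> pd.DataFrame:
    """Fusion-transcript validation screen (17 candidates)."""
    return _read_tsv("table1_fusion_validation.tsv")


def load_table2() -> pd.DataFrame:
    """Genomically supported fusion transcripts in the WGS cell lines."""
    return _read_tsv("table2_genomic_fusions.tsv")


def load_table3() -> list[AberrationRecord]:
    """Tumor-cohort TP53/MDM2 aberrations as classified records."""
    df = _read_tsv("table3_tp53_aberrations.tsv")
    records = []
    for _, row in df.iterrows():
        records.append(classify_aberration(
            sample=row["sample"], gene=row["gene"], type_str=row["type"],
            position=row["position"], consequence=row["consequence"],
            aberrant_af=_parse_percent(row["aberrant_af"]),
            wt_af=_parse_percent(row["wt_af"])))
    return records


TABLE3_N_SAMPLES = 25  # tumors screened for the cohort table


def load_cellline_status() -> pd.DataFrame:
    """Cell-line p53 inactivation causes and TP53 breakpoint locations."""
    return _read_tsv("cellline_tp53_status.tsv")


def load_tp53_domains() -> ProteinAnnotation:
    with (_DATA / "tp53_domains.tsv").open() as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh
                if line.strip() and not line.startswith("#")]
    domains = [(name, int(s), int(e)) for name, s, e in rows]
    return ProteinAnnotation(protein_length=393, domains=domains)


def load_pmp22_screen() -> tuple[set[str], dict[str, int]]:
    """Recurrent-fusion screen: positive sample ids and cohort sizes."""
    positives: set[str] = set()
    sizes: dict[str, int] = {}
    with (_DATA / "pmp22_elovl5_screen.tsv").open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#cohort_sizes"):
                for part in line.split("\t")[1:]:
                    k, v = part.split("=")
                    sizes[k] = int(v)
            elif line.startswith("#") or not line.strip():
                continue
            else:
                positives.add(line.split("\t")[0])
    return positives, sizes
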