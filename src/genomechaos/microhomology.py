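"""Breakpoint microhomology measurement and category statistics.

Microhomology at a rearrangement junction is the stretch of identical
sequence shared by the two joined flanks, which makes the exact junction
placement ambiguous — the classic footprint of microhomology-mediated
end-joining (MMEJ) and of MMBIR. We measure it as the maximal slide
ambiguity of the junction: the longest k such that the k bases entering the
junction from the upstream partner are identical to the k reference bases
immediately preceding the retained segment of the downstream partner
(reverse-complemented where the join inverts the strand). Lengths are
grouped into the three categories used throughout the analysis:
no microhomology, 1-5 bp, and 6-25 bp.

On junctions of two independent uniform-random flanks the expected measured
length is the geometric-series sum over k of (1/4)^k, roughly 0.33 bp, so a
real-data excess of 1-5 bp and especially 6-25 bp homology is the signal of
interest; significance versus a random-junction background is assessed with
a Monte-Carlo Fisher test on the 2x3 category table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_formats import HEAD, TAIL, Breakend, Rearrangement

MAX_SCAN = 25  # no homology longer than this is considered; longer is "25+"

CATEGORIES = ("none", "1-5", "6-25")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Junction flank geometry
# ---------------------------------------------------------------------------

def upstream_flank(reference: dict[str, str], be: Breakend, length: int) -> str:
    """Last ``length`` bases entering the junction from breakend ``be``.

    Returned 5'->3' along the derived chromosome, ending at the junction.
    """
    s = reference[be.chrom]
    if be.orientation == TAIL:
        return s[max(0, be.pos - length):be.pos]
    return revcomp(s[be.pos:be.pos + length])


def downstream_flank(reference: dict[str, str], be: Breakend, length: int) -> str:
    """First ``length`` bases leaving the junction into breakend ``be``."""
    s = reference[be.chrom]
    if be.orientation == HEAD:
        return s[be.pos:be.pos + length]
    return revcomp(s[max(0, be.pos - length):be.pos])


def pre_junction_reference(reference: dict[str, str], be: Breakend, length: int) -> str:
    """Reference bases that precede ``be``'s retained segment, junction-oriented.

    These are the bases a slid junction would consume: if they match the
    upstream partner's flank, the junction placement is ambiguous.
    """
    s = reference[be.chrom]
    if be.orientation == HEAD:
        return s[max(0, be.pos - length):be.pos]
    return revcomp(s[be.pos:be.pos + length])


def junction_microhomology(reference: dict[str, str],
                           breakend_a: Breakend,
                           breakend_b: Breakend,
                           max_scan: int = MAX_SCAN) -> tuple[int, str]:
    """Measure junction slide-ambiguity microhomology.

    ``breakend_a`` contributes the upstream (5') side of the derived junction
    and ``breakend_b`` the downstream side. Returns ``(length, sequence)``;
    the scan is capped at ``max_scan`` and truncated (without error) when a
    flank runs into a contig end.
    """
    up = upstream_flank(reference, breakend_a, max_scan)
    pre = pre_junction_reference(reference, breakend_b, max_scan)
    k = 0
    limit = min(len(up), len(pre))
    while k < limit and up[-(k + 1)] == pre[-(k + 1)]:
        k += 1
    return k, up[len(up) - k:] if k else ""


def measure_calls(calls: list[Rearrangement], reference: dict[str, str],
                  max_scan: int = MAX_SCAN) -> list[Rearrangement]:
    """Annotate ``microhomology_len`` on every call (in place; returns calls)."""
    for r in calls:
        k, _ = junction_microhomology(reference, r.breakend_a, r.breakend_b, max_scan)
        r.microhomology_len = k
    return calls


def categorize(mh_len: int) -> str:
    """Map a homology length to the three-category system (0 / 1-5 / 6-25)."""
    if mh_len < 0:
        raise ValueError("negative microhomology length")
    if mh_len > MAX_SCAN:
        raise ValueError(f"length {mh_len} exceeds the {MAX_SCAN}-bp category ceiling")
    if mh_len == 0:
        return "none"
    return "1-5" if mh_len <= 5 else "6-25"


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class LengthStrata:
    """Deletion-length strata: short < ``short_bp``; also reported are the
    overlapping >= ``short_bp`` and >= ``long_bp`` groups."""

    short_bp: int = 5_000
    long_bp: int = 10_000


@dataclass
class MicrohomologyProfile:
    """Category counts per group (SV type, optionally split by length)."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, group: str, category: str) -> None:
        self.counts.setdefault(group, {c: 0 for c in CATEGORIES})
        self.counts[group][category] += 1

    def n(self, group: str) -> int:
        return sum(self.counts.get(group, {}).values())

    def fractions(self, group: str) -> dict[str, float]:
        n = self.n(group)
        if n == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: self.counts[group][c] / n for c in CATEGORIES}

    def vector(self, group: str) -> np.ndarray:
        return np.array([self.counts.get(group, {}).get(c, 0) for c in CATEGORIES])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.counts:
            fr = self.fractions(g)
            for c in CATEGORIES:
                rows.append({"group": g, "category": c,
                             "count": self.counts[g][c], "fraction": fr[c]})
        return pd.DataFrame(rows)


def build_profile(calls: list[Rearrangement], reference: dict[str, str] | None = None,
                  strata: LengthStrata | None = None) -> MicrohomologyProfile:
    """Profile category counts by SV type; deletions additionally stratified
    into <short, >=short and >=long length groups (the latter two overlap).

    Calls lacking ``microhomology_len`` are measured from ``reference`` first.
    """
    strata = strata or LengthStrata()
    profile = MicrohomologyProfile()
    for r in calls:
        mh = r.microhomology_len
        if mh is None:
            if reference is None:
                raise ValueError(f"{r.id}: unmeasured call and no reference given")
            mh, _ = junction_microhomology(reference, r.breakend_a, r.breakend_b)
        if mh > MAX_SCAN:
            continue  # outside the category system; flagged upstream
        cat = categorize(mh)
        profile.add(r.sv_type, cat)
        if r.sv_type == "DEL":
            if r.span < strata.short_bp:
                profile.add(f"DEL<{strata.short_bp // 1000}kb", cat)
            else:
                profile.add(f"DEL>={strata.short_bp // 1000}kb", cat)
                if r.span >= strata.long_bp:
                    profile.add(f"DEL>={strata.long_bp // 1000}kb", cat)
    return profile


def random_background(reference: dict[str, str], n: int = 500,
                      seed: int | np.random.Generator = 0,
                      max_scan: int = MAX_SCAN) -> MicrohomologyProfile:
    """Category profile of ``n`` uniform-random synthetic junctions.

    Random breakend pairs, uniform over the genome and over orientations,
    measured identically to real calls: the empirical null against which
    observed profiles are compared.
    """
    if n <= 0:
        raise ValueError("background requires n > 0 random junctions")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    profile = MicrohomologyProfile()
    for _ in range(n):
        bes = []
        for _side in range(2):
            ci = rng.choice(len(chroms), p=weights)
            pos = int(rng.integers(max_scan, lengths[ci] - max_scan))
            orient = TAIL if rng.random() < 0.5 else HEAD
            bes.append(Breakend(chroms[ci], pos, orient))
        k, _ = junction_microhomology(reference, bes[0], bes[1], max_scan)
        profile.add("background", categorize(min(k, max_scan)))
    return profile


# ---------------------------------------------------------------------------
# Fisher tests on the 2x3 category table
# ---------------------------------------------------------------------------

def _table_logprob(row1: np.ndarray, colsums: np.ndarray, r1: int, r2: int,
                   total: int) -> np.ndarray:
    """Log multivariate-hypergeometric probability of 2xK tables given margins."""
    row2 = colsums - row1
    lp = (gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(colsums + 1).sum()
          - gammaln(total + 1)
          - gammaln(row1 + 1).sum(axis=-1) - gammaln(row2 + 1).sum(axis=-1))
    return lp


def compare_to_background(observed: np.ndarray, background: np.ndarray,
                          replicates: int = 100_000,
                          seed: int | np.random.Generator = 0) -> float:
    """Monte-Carlo Fisher exact test on the 2x3 category table.

    Rows are (observed, background) counts over the three categories. Tables
    are resampled conditional on both margins (multivariate hypergeometric);
    the p-value is the margin-corrected fraction of resamples whose null
    probability does not exceed the observed table's, as in the standard
    simulated-p Fisher test. Degenerate margins give p = 1.
    """
    observed = np.asarray(observed, dtype=int)
    background = np.asarray(background, dtype=int)
    if observed.shape != (3,) or background.shape != (3,):
        raise ValueError("expected two length-3 category count vectors")
    r1, r2 = int(observed.sum()), int(background.sum())
    colsums = observed + background
    total = r1 + r2
    if r1 == 0 or r2 == 0 or (colsums > 0).sum() < 2:
        import warnings
        warnings.warn("degenerate contingency margins; p = 1")
        return 1.0
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lp_obs = _table_logprob(observed, colsums, r1, r2, total)
    draws = rng.multivariate_hypergeometric(colsums, r1, size=replicates)
    lp = _table_logprob(draws, colsums, r1, r2, total)
    # tolerance mirrors floating-point ties in the exact enumeration
    hits = int(np.sum(lp <= lp_obs + 1e-7))
    return (hits + 1) / (replicates + 1)


def fisher_exact_2x3(observed: np.ndarray, background: np.ndarray) -> float:
    """Exact Fisher p for the 2x3 table by full enumeration over the margins.

    Feasible for the table sizes seen here (hundreds per row); serves as the
    closed-form counterpart of :func:`compare_to_background`.
    """
    observed = np.asarray(observed, dtype=int)
    background = np.asarray(background, dtype=int)
    r1 = int(observed.sum())
    colsums = observed + background
    total = int(colsums.sum())
    r2 = total - r1
    lp_obs = _table_logprob(observed, colsums, r1, r2, total)
    p = 0.0
    for a in range(min(r1, colsums[0]) + 1):
        rem = r1 - a
        b_lo = max(0, rem - colsums[2])
        b_hi = min(colsums[1], rem)
        if b_lo > b_hi:
            continue
        bs = np.arange(b_lo, b_hi + 1)
        rows = np.stack([np.full_like(bs, a), bs, rem - bs], axis=1)
        lps = _table_logprob(rows, colsums, r1, r2, total)
        p += float(np.exp(lps[lps <= lp_obs + 1e-7]).sum())
    return min(p, 1.0)


def profile_vs_background(profile: MicrohomologyProfile,
                          background: MicrohomologyProfile,
                          replicates: int = 100_000,
                          seed: int = 0) -> dict[str, float]:
    """Per-group Monte-Carlo Fisher p-values against the random background."""
    bg = background.vector("background")
    rng = np.random.default_rng(seed)
    return {g: compare_to_background(profile.vector(g), bg, replicates, rng)
            for g in profile.counts}


# ---------------------------------------------------------------------------
# Deletion length vs homology
# ---------------------------------------------------------------------------

def length_homology_association(deletions: list[Rearrangement]) -> tuple[float, float]:
    """Spearman rank correlation between deletion length and homology length.

    Negative under the regime where short deletions carry long (MMEJ-type)
    microhomology. Returns (rho, p); (nan, nan) with a warning when either
    variable is constant.
    """
    lengths = [r.span for r in deletions if r.sv_type == "DEL"]
    mhs = [r.microhomology_len for r in deletions if r.sv_type == "DEL"]
    if any(m is None for m in mhs):
        raise ValueError("all deletions must carry measured microhomology lengths")
    if len(lengths) < 3 or len(set(lengths)) == 1 or len(set(mhs)) == 1:
        import warnings
        warnings.warn("degenerate deletion set; correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(lengths, mhs)
    return float(rho), float(p)


def expected_random_microhomology(max_scan: int = MAX_SCAN) -> float:
    """Closed-form expected slide length for independent random flanks:
    sum over k of (1/4)^k, about 0.333 bp."""
    return sum(0.25 ** k for k in range(1, max_scan + 1))
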