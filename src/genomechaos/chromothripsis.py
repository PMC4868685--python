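"""Per-chromosome cluster statistics for chromothripsis-like rearrangement
patterns.

Three signals are computed per chromosome, following the standard inference
criteria for catastrophic shattering events:

1. *Breakpoint clustering*: successive gaps between sorted breakpoint
   positions are tested against the null of uniform random breakage, i.e.
   exponential inter-breakpoint distances with the observed mean. Because
   the mean is estimated from the data, the Kolmogorov-Smirnov statistic is
   calibrated with a parametric bootstrap (the statistic is scale-free, so
   the bootstrap null does not depend on the true mean).
2. *Join-orientation randomness*: chromothripsis predicts the four join
   classes (head-head, head-tail, tail-head, tail-tail) in equal proportion;
   a chi-square goodness-of-fit against 1/4 each (3 df) quantifies this.
3. *Coverage fold change*: median windowed coverage of the cluster region
   over the genome-wide median. Classical chromothripsis is copy-number
   neutral or lost; clustered breakpoints *with* strong amplification
   (> 6-fold here) point instead to MMBIR-like replicative repair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HEAD, TAIL, Rearrangement

JOIN_CLASSES = ("head-head", "head-tail", "tail-head", "tail-tail")


@dataclass
class ChromothripsisThresholds:
    clustering_alpha: float = 0.005
    fold_threshold: float = 6.0
    orientation_alpha: float = 0.9  # reported, not gating
    bootstrap: int = 2000


@dataclass
class ChromothripsisReport:
    chrom: str
    n_breakpoints: int
    gof_p: float | None
    orientation_p: float | None
    coverage_fold: float | None
    call: str  # not-clustered / clustered-copy-neutral / clustered-amplified


# ---------------------------------------------------------------------------
# Distances and the exponential goodness-of-fit test
# ---------------------------------------------------------------------------

def interbreakpoint_distances(positions: list[int]) -> np.ndarray:
    """Successive gaps of the sorted, deduplicated breakpoint positions."""
    uniq = np.unique(np.asarray(positions, dtype=np.int64))
    if len(uniq) < len(positions):
        warnings.warn(f"{len(positions) - len(uniq)} duplicate breakpoint "
                      "positions removed")
    if len(uniq) < 3:
        raise ValueError("need at least 3 distinct breakpoints for distances")
    return np.diff(uniq).astype(float)


def _ks_stat_exponential(x: np.ndarray) -> np.ndarray:
    """KS distance of each row of ``x`` to Exponential(mean of that row)."""
    x = np.sort(np.atleast_2d(x), axis=1)
    n = x.shape[1]
    cdf = 1.0 - np.exp(-x / x.mean(axis=1, keepdims=True))
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def exponential_gof_test(distances: np.ndarray, bootstrap: int = 2000,
                         seed: int | np.random.Generator = 0) -> float | None:
    """Parametric-bootstrap KS test of exponentiality with estimated mean.

    Small p: the gaps are incompatible with uniform random breakage (either
    clustered or overly regular). Returns None with a warning for < 5 gaps.
    """
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 0):
        raise ValueError("negative inter-breakpoint distance")
    n = len(distances)
    if n < 5:
        warnings.warn("fewer than 5 distances; goodness-of-fit p undefined")
        return None
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d_obs = float(_ks_stat_exponential(distances)[0])
    d_null = null_ks_distribution(n, bootstrap, rng)
    return (1 + int(np.sum(d_null >= d_obs))) / (bootstrap + 1)


def null_ks_distribution(n: int, bootstrap: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Bootstrap null distribution of the estimated-mean exponential KS
    statistic for sample size ``n`` (scale-free, so unit mean suffices)."""
    sims = rng.exponential(1.0, size=(bootstrap, n))
    return _ks_stat_exponential(sims)


# ---------------------------------------------------------------------------
# Join orientations
# ---------------------------------------------------------------------------

_INTRA_JOIN = {"DEL": "tail-head", "DUP": "head-tail"}


def join_class(rearrangement: Rearrangement) -> str:
    """Join class from breakend orientations; intrachromosomal types map to
    DEL=tail-head, DUP=head-tail, INV=head-head/tail-tail."""
    if rearrangement.sv_type in _INTRA_JOIN:
        return _INTRA_JOIN[rearrangement.sv_type]
    a, b = rearrangement.breakend_a.orientation, rearrangement.breakend_b.orientation
    return f"{a}-{b}".replace(TAIL, "tail").replace(HEAD, "head")


def count_join_orientations(calls: list[Rearrangement]) -> dict[str, int]:
    counts = {c: 0 for c in JOIN_CLASSES}
    for r in calls:
        counts[join_class(r)] += 1
    return counts


def join_orientation_test(counts: dict[str, int] | list[int]) -> float:
    """Goodness-of-fit of the four join classes to equal probability 1/4.

    Chi-square with 3 df for total >= 8; exact multinomial for smaller
    totals, where the chi-square approximation is unreliable.
    """
    obs = np.array([counts[c] for c in JOIN_CLASSES]) \
        if isinstance(counts, dict) else np.asarray(counts)
    if obs.min() < 0:
        raise ValueError("negative join count")
    total = int(obs.sum())
    if total == 0:
        raise ValueError("no joins to test")
    if total >= 8:
        return float(stats.chisquare(obs).pvalue)
    # exact multinomial: sum probabilities of all outcomes as or less likely
    from itertools import product
    p_obs = stats.multinomial.pmf(obs, total, [0.25] * 4)
    p = 0.0
    for a in range(total + 1):
        for b in range(total - a + 1):
            for c in range(total - a - b + 1):
                vec = (a, b, c, total - a - b - c)
                pv = stats.multinomial.pmf(vec, total, [0.25] * 4)
                if pv <= p_obs + 1e-12:
                    p += pv
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Coverage fold change
# ---------------------------------------------------------------------------

def coverage_fold_change(region: tuple[str, int, int],
                         coverage_track: pd.DataFrame) -> float:
    """Median window depth inside region / genome-wide median depth."""
    chrom, start, end = region
    sel = coverage_track[(coverage_track["chrom"] == chrom)
                         & (coverage_track["start"] < end)
                         & (coverage_track["end"] > start)]
    if sel.empty:
        raise ValueError(f"no coverage windows overlap {chrom}:{start}-{end}")
    genome_median = float(coverage_track["depth"].median())
    if genome_median == 0:
        raise ValueError("genome-wide median coverage is zero")
    return float(sel["depth"].median()) / genome_median


def cluster_region(positions: list[int], gap_factor: float = 10.0,
                   ) -> tuple[int, int]:
    """Minimal interval covering the largest single-linkage breakpoint
    cluster, linking gaps below ``gap_factor`` x the median gap."""
    uniq = np.unique(np.asarray(positions, dtype=np.int64))
    if len(uniq) < 2:
        return int(uniq[0]), int(uniq[0]) + 1
    gaps = np.diff(uniq)
    cut = gap_factor * float(np.median(gaps))
    best = (int(uniq[0]), int(uniq[0]))
    start = 0
    for i, g in enumerate(gaps):
        if g > cut:
            if uniq[i] - uniq[start] > best[1] - best[0]:
                best = (int(uniq[start]), int(uniq[i]))
            start = i + 1
    if uniq[-1] - uniq[start] > best[1] - best[0]:
        best = (int(uniq[start]), int(uniq[-1]))
    return best[0], best[1] + 1


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_cluster(gof_p: float | None, orientation_p: float | None,
                     fold: float | None,
                     thresholds: ChromothripsisThresholds | None = None) -> str:
    """Call: clustered iff gof_p < alpha; amplified iff fold > threshold.

    The orientation p is reported alongside but does not gate the call.
    """
    t = thresholds or ChromothripsisThresholds()
    if gof_p is None or gof_p >= t.clustering_alpha:
        return "not-clustered"
    if fold is not None and fold > t.fold_threshold:
        return "clustered-amplified"
    return "clustered-copy-neutral"


def analyze_chromosome(chrom: str, calls: list[Rearrangement],
                       coverage_track: pd.DataFrame | None = None,
                       thresholds: ChromothripsisThresholds | None = None,
                       seed: int | np.random.Generator = 0) -> ChromothripsisReport:
    """Full per-chromosome report: clustering, orientation, coverage, call."""
    t = thresholds or ChromothripsisThresholds()
    positions = [be.pos for r in calls for be in (r.breakend_a, r.breakend_b)
                 if be.chrom == chrom]
    n = len(positions)
    gof_p = orientation_p = fold = None
    if n >= 4:
        dists = interbreakpoint_distances(positions)
        gof_p = exponential_gof_test(dists, t.bootstrap, seed)
    touching = [r for r in calls
                if chrom in (r.breakend_a.chrom, r.breakend_b.chrom)]
    if touching:
        orientation_p = join_orientation_test(count_join_orientations(touching))
    if coverage_track is not None and n >= 2:
        region = (chrom, *cluster_region(positions))
        try:
            fold = coverage_fold_change(region, coverage_track)
        except ValueError:
            fold = None
    return ChromothripsisReport(chrom, n, gof_p, orientation_p, fold,
                                classify_cluster(gof_p, orientation_p, fold, t))


def analyze_genome(calls: list[Rearrangement],
                   coverage_track: pd.DataFrame | None = None,
                   thresholds: ChromothripsisThresholds | None = None,
                   seed: int = 0) -> list[ChromothripsisReport]:
    chroms = sorted({be.chrom for r in calls for be in (r.breakend_a, r.breakend_b)})
    rng = np.random.default_rng(seed)
    return [analyze_chromosome(c, calls, coverage_track, thresholds, rng)
            for c in chroms]
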