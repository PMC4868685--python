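"""Junction microhomology measurement vs brute-force oracles, background
statistics, and the Monte-Carlo Fisher test vs exact enumeration."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from genomechaos import microhomology as mh
from genomechaos import synthetic
from genomechaos.io_formats import HEAD, TAIL, Breakend, Rearrangement
from genomechaos.microhomology import (categorize, compare_to_background,
                                       expected_random_microhomology,
                                       fisher_exact_2x3, junction_microhomology,
                                       random_background, revcomp)


def _random_reference(rng, n_chrom=2, length=50_000):
    return {f"chr{i + 1}": "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            for i in range(n_chrom)}


def _oracle_mh(reference, be_a, be_b, max_scan=25):
    """Direct substring comparison over every candidate k (independent of the
    incremental scan): largest k whose full k-suffixes agree."""
    up = mh.upstream_flank(reference, be_a, max_scan)
    pre = mh.pre_junction_reference(reference, be_b, max_scan)
    best = 0
    for k in range(1, min(len(up), len(pre)) + 1):
        if up[-k:] == pre[-k:]:
            best = k
    return best


class TestCategorize:
    @pytest.mark.parametrize("length,category", [
        (0, "none"), (1, "1-5"), (5, "1-5"), (6, "6-25"), (7, "6-25"), (25, "6-25")])
    def test_category_boundaries(self, length, category):
        assert categorize(length) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(26)
        with pytest.raises(ValueError):
            categorize(-1)


class TestJunctionMeasurement:
    def test_agrees_with_substring_oracle_on_random_junctions(self):
        """10^4 random junctions: measurement equals the brute-force oracle."""
        rng = np.random.default_rng(7)
        reference = _random_reference(rng)
        mismatches = 0
        for _ in range(10_000):
            bes = []
            for _side in range(2):
                chrom = f"chr{int(rng.integers(1, 3))}"
                pos = int(rng.integers(30, 50_000 - 30))
                orient = TAIL if rng.random() < 0.5 else HEAD
                bes.append(Breakend(chrom, pos, orient))
            got, _ = junction_microhomology(reference, bes[0], bes[1])
            if got != _oracle_mh(reference, bes[0], bes[1]):
                mismatches += 1
        assert mismatches == 0

    def test_planted_length_round_trip(self, rng):
        cfg = synthetic.SimulationConfig(seed=3, n_chromosomes=2,
                                         chrom_length_bp=40_000)
        ref, _ = synthetic.simulate_genome(cfg)
        a = Breakend("chr1", 5_000, TAIL)
        b = Breakend("chr2", 9_000, HEAD)
        rearr, _ = synthetic.plant_rearrangement(ref, "TRA", a, b, 4, rng)
        got, seq = junction_microhomology(synthetic.as_strings(ref), a, b)
        assert got == 4 and len(seq) == 4

    def test_inversion_homology_needs_reverse_complement(self):
        """Hand-built 60-bp contig: tail-tail join whose homology exists only
        on the reverse strand."""
        left = "ACGTACCGGTTAGCATCGAT"          # bases 0..19; junction after pos 20
        core = "GGGGG"
        # pre-junction bases for a tail breakend at pos 25 are revcomp(s[25:]):
        # plant revcomp of the last 4 upstream bases (TCGAT -> CGAT) there
        planted = revcomp("CGAT")
        right = planted + "CCCCAAAATTTTGGGGCCCCAAAATTTTGGG"
        seq = left + core + right
        assert len(seq) == 60
        reference = {"c": seq}
        a, b = Breakend("c", 20, TAIL), Breakend("c", 25, TAIL)
        got, homology = junction_microhomology(reference, a, b)
        assert got == 4 and homology == "CGAT"
        # without reverse-complement logic the forward flanks do not match
        assert seq[16:20] != seq[21:25]

    def test_truncated_scan_near_contig_start(self):
        reference = {"c": "ACGT" * 30}
        a, b = Breakend("c", 2, TAIL), Breakend("c", 60, HEAD)
        got, _ = junction_microhomology(reference, a, b)
        assert 0 <= got <= 2  # scan truncated to the available flank


class TestRandomBackground:
    def test_mean_matches_geometric_series(self):
        """Unplanted junctions: mean homology ~ sum (1/4)^k ~ 0.33."""
        rng = np.random.default_rng(11)
        reference = _random_reference(rng, n_chrom=2, length=100_000)
        lengths = []
        for _ in range(5_000):
            a = Breakend("chr1", int(rng.integers(30, 99_970)), TAIL)
            b = Breakend("chr2", int(rng.integers(30, 99_970)), HEAD)
            lengths.append(junction_microhomology(reference, a, b)[0])
        expected = expected_random_microhomology()
        assert np.mean(lengths) == pytest.approx(expected, abs=0.03)
        assert expected == pytest.approx(1 / 3, abs=1e-6)

    def test_long_homology_vanishingly_rare_in_background(self):
        rng = np.random.default_rng(13)
        reference = _random_reference(rng, length=100_000)
        profile = random_background(reference, n=5_000, seed=5)
        assert profile.fractions("background")["6-25"] < 0.01

    def test_two_seeds_distributionally_equal(self):
        rng = np.random.default_rng(17)
        reference = _random_reference(rng, length=100_000)
        p1 = random_background(reference, n=5_000, seed=1)
        p2 = random_background(reference, n=5_000, seed=2)
        table = np.vstack([p1.vector("background"), p2.vector("background")])
        table = table[:, table.sum(axis=0) > 0]
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_zero_junctions_rejected(self):
        with pytest.raises(ValueError, match="n > 0"):
            random_background({"c": "ACGT" * 100}, n=0)


def _exact_fisher_oracle(row1, row2):
    """Independent exact 2x3 Fisher by full itertools enumeration with
    hypergeometric table probabilities."""
    row1, row2 = np.asarray(row1), np.asarray(row2)
    cols = row1 + row2
    r1, n = int(row1.sum()), int(row1.sum() + row2.sum())

    def logp(t):
        top = math.lgamma(r1 + 1) + math.lgamma(n - r1 + 1) \
            + sum(math.lgamma(c + 1) for c in cols) - math.lgamma(n + 1)
        return top - sum(math.lgamma(x + 1) for x in t) \
            - sum(math.lgamma(int(c) - x + 1) for c, x in zip(cols, t))

    lp_obs = logp(row1)
    total = 0.0
    for a in range(min(r1, cols[0]) + 1):
        for b in range(min(r1 - a, cols[1]) + 1):
            c = r1 - a - b
            if c > cols[2]:
                continue
            lp = logp((a, b, c))
            if lp <= lp_obs + 1e-7:
                total += math.exp(lp)
    return min(total, 1.0)


class TestFisher:
    def test_identical_distributions_give_p_near_one(self):
        p = compare_to_background([30, 40, 30], [30, 40, 30], 20_000, seed=1)
        assert p > 0.5

    def test_strong_enrichment_significant(self):
        p = compare_to_background([20, 80, 200], [240, 55, 5], 100_000, seed=1)
        assert p < 1e-4

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert compare_to_background([0, 0, 0], [10, 10, 10]) == 1.0

    def test_monte_carlo_within_three_se_of_exact(self):
        """50 random tables: MC p within 3 Monte-Carlo standard errors of the
        independent exact enumeration."""
        rng = np.random.default_rng(29)
        reps = 100_000
        for _ in range(50):
            row1 = rng.multinomial(int(rng.integers(20, 120)),
                                   rng.dirichlet([1, 1, 1]))
            row2 = rng.multinomial(int(rng.integers(20, 120)),
                                   rng.dirichlet([1, 1, 1]))
            if row1.sum() == 0 or row2.sum() == 0 \
                    or ((row1 + row2) > 0).sum() < 2:
                continue
            p_exact = _exact_fisher_oracle(row1, row2)
            p_mc = compare_to_background(row1, row2, reps, seed=rng)
            se = math.sqrt(p_exact * (1 - p_exact) / reps)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / reps

    def test_package_exact_matches_independent_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            row1 = rng.multinomial(60, rng.dirichlet([1, 1, 1]))
            row2 = rng.multinomial(80, rng.dirichlet([1, 1, 1]))
            assert fisher_exact_2x3(row1, row2) == \
                pytest.approx(_exact_fisher_oracle(row1, row2), abs=1e-9)


class TestProfiles:
    def test_single_call_single_group(self):
        r = Rearrangement("r1", "TRA", Breakend("chr1", 100, TAIL),
                          Breakend("chr2", 100, HEAD), microhomology_len=7)
        profile = mh.build_profile([r])
        assert profile.n("TRA") == 1
        assert profile.fractions("TRA")["6-25"] == 1.0

    def test_fractions_sum_to_one(self, sim_bundle):
        ref, _, calls, _ = sim_bundle
        profile = mh.build_profile(calls, ref)
        for g in profile.counts:
            assert sum(profile.fractions(g).values()) == pytest.approx(1.0)

    def test_deletion_strata_partition(self, sim_bundle):
        ref, _, calls, _ = sim_bundle
        profile = mh.build_profile(calls, ref)
        n_del = profile.n("DEL")
        assert profile.n("DEL<5kb") + profile.n("DEL>=5kb") == n_del
        assert profile.n("DEL>=10kb") <= profile.n("DEL>=5kb")


class TestLengthAssociation:
    def test_perfectly_antimonotone_is_minus_one(self):
        dels = [Rearrangement(f"d{i}", "DEL", Breakend("c", 100, TAIL),
                              Breakend("c", 100 + (i + 1) * 1000, HEAD),
                              microhomology_len=25 - i) for i in range(10)]
        rho, p = mh.length_homology_association(dels)
        assert rho == pytest.approx(-1.0)
        assert p < 0.01

    def test_constant_homology_flagged_undefined(self):
        dels = [Rearrangement(f"d{i}", "DEL", Breakend("c", 100, TAIL),
                              Breakend("c", 100 + (i + 1) * 1000, HEAD),
                              microhomology_len=3) for i in range(10)]
        with pytest.warns(UserWarning, match="degenerate"):
            rho, p = mh.length_homology_association(dels)
        assert math.isnan(rho)

    def test_decaying_homology_detected_negative(self):
        """Homology probability decaying with deletion length: rho < 0 at
        n = 500 with p < 0.05."""
        rng = np.random.default_rng(37)
        dels = []
        for i in range(500):
            size = int(10 ** rng.uniform(2.5, 5))
            p_long = 0.7 if size < 5_000 else 0.15
            k = int(rng.integers(6, 26)) if rng.random() < p_long \
                else int(rng.integers(0, 6))
            dels.append(Rearrangement(f"d{i}", "DEL", Breakend("c", 100, TAIL),
                                      Breakend("c", 100 + size, HEAD),
                                      microhomology_len=k))
        rho, p = mh.length_homology_association(dels)
        assert rho < 0 and p < 0.05
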