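# Methods

This note documents the models, conventions and numerical choices behind
`genomechaos`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and breakend geometry

All internal coordinates are 0-based half-open; conversions to 1-based
formats happen only in `io_formats` (VCF POS of a tail breakend names the
last retained base, of a head breakend the first retained base; symbolic
DEL/DUP/INV records map POS−1/END to the half-open event interval). A
breakend is (chromosome, position, orientation) with orientation `tail`
(retained segment to the left) or `head` (retained segment at/right of the
position). Intrachromosomal join semantics are the standard ones:
deletion = tail–head, tandem duplication = head–tail, inversion =
tail–tail or head–head; translocations may take any of the four classes.
In BEDPE, `+`/`-` strands encode tail/head. Insertions present in VCF input
are parsed but excluded (with a warning) from the four-class analyses.

## Junction microhomology

Microhomology is defined as junction slide ambiguity: the measured length
is the maximal k ≤ 25 such that the k bases entering the junction from the
upstream breakend (read 5′→3′ along the derived chromosome, hence
reverse-complemented for head breakends) equal the k reference bases
immediately preceding the downstream breakend's retained segment. This is
the standard MMEJ-footprint definition; it deliberately scans a single
canonical direction, which gives an expected length of Σ_{k≥1}(1/4)^k ≈
0.333 bp on junctions of independent random flanks — the closed form used
to sanity-check the random background. The 25-bp cap reflects the category
system {0, 1–5, 6–25} bp; longer homology would be flagged `25+` and
excluded from categories. Deletions are additionally stratified at 5 kb and
10 kb, the strata in which the MMEJ-like long-homology excess concentrates.

The background model is n (default 500) synthetic junctions with breakend
pairs drawn uniformly over the genome and orientations uniform over the
four classes, measured identically to real calls. A GC-matched background
could be substituted by resampling flanks; with the uniform-composition toy
genomes the two coincide.

Observed-vs-background category tables (2×3) are tested with a Monte-Carlo
Fisher exact test: tables are resampled conditional on both margins
(multivariate hypergeometric draws of the first row), and
p = (1 + #{T : P(T) ≤ P(obs)})/(replicates + 1) with a 10⁻⁷ log-probability
tie tolerance, mirroring the common simulated-p implementation. The default
is 10⁵ replicates, so the smallest reportable p is ≈ 10⁻⁵. An exact
counterpart (`fisher_exact_2x3`, full enumeration over the margins) is
provided and is feasible for row sums in the hundreds; the test suite holds
the Monte-Carlo estimate to within three Monte-Carlo standard errors of an
independently coded enumeration. Per-group tests are reported without
multiple-testing correction, matching the per-group reporting convention of
this analysis style. Degenerate margins return p = 1 with a warning.

## Chromothripsis statistics

*Clustering.* For each chromosome with ≥4 breakpoint positions, successive
gaps of the sorted, deduplicated positions are tested against
Exponential(mean of the gaps) — the uniform-random-breakage null — with a
one-sample Kolmogorov–Smirnov statistic. Because the mean is estimated from
the same data, nominal KS quantiles would be badly conservative; the null
distribution is therefore obtained by parametric bootstrap (default 2000
resamples, each re-estimating its own mean). The statistic is scale-free
under this null, so unit-mean simulation suffices. The suite verifies a
type-I error within [0.03, 0.07] at α = 0.05 and ≥95 % power against a
two-cluster alternative at 100 breakpoints. Note the test rejects for any
non-exponential gap structure, including over-regular spacing; the call
threshold is p < 0.005.

*Join orientations.* The four join classes are tested against equal
probabilities (¼ each, 3 df χ²; exact multinomial below a total of 8, where
the asymptotic approximation fails). Equal class probabilities are used
rather than probabilities derived from genome composition, as the natural
null for mechanism-free end joining. The orientation p is reported but does
not gate the clustering call.

*Coverage.* Cluster regions are the minimal interval covering the largest
single-linkage cluster with gap threshold 10× the median gap (the region
definition is otherwise arbitrary; the factor is exposed). Fold change is
the median of overlapping 50-kb windows divided by the genome-wide median.
Calls: `not-clustered` (gof p ≥ 0.005), else `clustered-amplified` when
fold > 6 (MMBIR-like) and `clustered-copy-neutral` otherwise. No
derivative-chromosome reconstruction or copy-number segmentation is
attempted.

## Allele fraction

AF = S/(S + C̄) with S = spanning + split reads and C̄ the mean of the two
per-breakend concordant counts from 500-bp windows. The mean (rather than
the sum) keeps the estimator symmetric in the breakends and reduces to the
plain supporting-read fraction at a single junction; the alternative is a
one-line change and the choice is exposed by construction (the counts are
stored per breakend). Zero total reads gives an undefined (None) AF, never
0. The estimator is a ratio of binomials and carries O(1/depth) bias,
negligible at the ≥100-pair windows simulated; the suite checks recovery of
planted fractions to within two standard errors.

## Fusion filtering and concordance

Filters are independent predicates, so cascade order is irrelevant
(property-tested): normal-panel removal on directional (gene5, gene3) keys
— chimeric transcripts are directional, so the reciprocal pair is *not*
removed; a complexity screen dropping 200-bp junction contexts with
overlapping-dinucleotide Shannon entropy < 1.5 bits or a single tandem
repeat (unit ≤ 6 bp) covering > 50 % of the window — uniform random
200-mers sit near 4 bits and pass at > 99.9 %; and the ≥8 spanning / ≥3
split read-support rule. Caller merging unions calls keyed by partner pair
and junction coordinates within ±10 bp.

A fusion is `genomic-direct` when some rearrangement places one breakend in
the 5′ partner, oriented to retain the promoter-side portion and located
past the last fused exon, and the other breakend in the 3′ partner,
oriented to retain the downstream portion and located before the first
fused exon. `genomic-read-through` relaxes the 3′ side to a same-strand
gene within 1 Mb of the partner (transcription running through the
neighbour, as when one translocation explains two different chimeras).
Direct matches are searched across all rearrangements before read-through
is considered. Everything else is `unsupported` — the trans-splicing-like
class. Partner-expression enrichment compares distinct partner genes
against all other genes with a two-sided Wilcoxon rank-sum test; fewer than
three expressed partners yields an undefined p with a warning.

## Cohort conventions

Intrachromosomal events of ≥50 bp (and all interchromosomal events) are
structural rearrangements; smaller deletions/insertions are indels — the
standard SV size convention, applied because source tables distinguish
"small del (10 bp)" from kb/Mb-scale events without stating a cutoff.
Pathway status uses the precedence TP53-structural > TP53 SNV/indel >
MDM2-amplification; percentages are integer-rounded with `none` absorbing
the remainder so classes sum to 100. Hotspot counting is per sample (a
sample with two events in one intron counts once) on locations of the form
"Intron N". Wild-type allele statistics use one value per record that
carries one; the even-count median is the mean of the central pair. Protein
consequences treat a domain as lost when disjoint from the retained
interval and disrupted when partially overlapping; the bundled p53 domain
table (393 aa; TAD1 1–42, TAD2 43–63, DBD 101–292, NLS 303–322, OD 323–356,
BR 363–393) is this package's working annotation of the canonical layout
and is editable. Events flanking but outside a gene body are accepted as
gene-affecting when their consequence text says so (tables are trusted;
synthetic data computes consequences from coordinates).

## Damage response

2^−ΔΔCt with technical replicates averaged per condition before
differencing; ΔCt = Ct_target − Ct_reference at 0 h and 8 h post-
irradiation, fold = 2^−(ΔCt₈ − ΔCt₀). The p53-functional call requires
*both* CDKN1A and BAX at ≥2-fold induction; the threshold is exposed, and a
`partial` category (exactly one induced target, the MDM2-amplified
borderline phenotype) is available behind a flag. No amplification-
efficiency correction is applied.

## Synthetic data: what it emulates, and what it does not

The generator produces uniform-random A/C/G/T genomes (GC configurable,
default 0.41) with gene models tiled to a configurable intragenic fraction
(default 0.40, the human-annotation ratio). Junction homology is planted by
copying the upstream flank into the bases preceding the downstream
breakend's retained segment and forcing a mismatch one base further out, so
measurement returns exactly the planted k for every k ∈ [0, 25] — the
round-trip the suite exploits. Breakends keep ≥52 bp from contig ends and
≥200 bp from each other so plants cannot interact. Default microhomology
mixtures encode the study regime: short deletions (0.15, 0.25, 0.60) over
{0, 1–5, 6–25} bp, all other groups ≈ (0.40, 0.47, 0.13). Read evidence is
a binomial split of the window depth (spanning/split at 0.7/0.3 of
supporting reads); allele fractions default to Uniform(0.01, 0.50), the
observed heterogeneity range. Coverage is Poisson per 50-kb window with
amplified regions at fold × depth. Fusion calls carry mechanism labels
(genomic, read-through, trans-splice, normal-panel) with genomic ones
backed by physically planted rearrangements. Ct plates plant a 4-fold
(ΔΔCt = −2) induction for p53-functional samples with σ = 0.15-cycle
Gaussian noise. One seed drives everything through per-operation
substreams, so outputs are byte-identical across runs and robust to stage
reordering.

Not emulated: read-level data (no FASTQ/BAM — evidence is count-level),
overdispersion of real read counts (binomial/Poisson is an assumption,
exposed via config), repeat-rich or GC-biased genome composition, aneuploid
copy-number backgrounds, and caller-specific artifacts. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to alignment or calling noise.

## Problem sizes and runtime choices

The suite and the acceptance script run on deliberately compact instances
chosen to keep statistical resolution while staying fast: toy genomes of
2–4 × 200–600 kb, 10⁴ junctions for oracle agreement, 600 planted
junctions per regime group, 500 replicates for allele-fraction recovery,
1000 null simulations (n = 100 gaps, 2000 bootstrap resamples) for the
goodness-of-fit calibration, 200 simulations for power, and 10⁵ Fisher
resamples. At these sizes the whole test suite completes in well under a
minute and the acceptance script in a few seconds.

## Pipeline configuration

`chaos run-all` takes a YAML file whose keys mirror `PipelineConfig`:
input paths (`reference`, `sv_calls`, `coverage`, `gene_models`,
`expression`, `fusions`, `normal_panel`, `ct_table`), `out_dir`, `seed`,
and the thresholds, whose defaults are the study parameters (8/3 read
support, 10 % AF over 500-bp windows, 200-bp context, 500 background
junctions, 10⁵ Fisher replicates, 50-kb coverage windows, 5/10-kb deletion
strata, 25-bp scan cap, α = 0.005 clustering, 6-fold coverage threshold,
2-fold induction). Stages whose inputs are absent are skipped; the JSON
summary is schema-versioned and deterministic for a fixed seed.
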