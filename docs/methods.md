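# Methods

## The single-family consistency model

A family is founded by one monogamous male–female pair. Under strict maternal
inheritance of a non-recombining mtDNA marker, with de-novo mutation within a
family taken as zero over ~1 kb, every family member except the father carries
the founding mother's haplotype; the father carries his own mother's
haplotype, acquired outside the family. The sampled adults of a log are
therefore explainable by a single family **iff** removing at most one
non-female member leaves a haplotypically monomorphic set. `classify_log`
implements the closed-form version of this rule (SH for one haplotype; MF for
three or more haplotypes, or two haplotypes whose minority class has two or
more carriers or a female sole carrier; OMH otherwise) and is tested for exact
agreement with a brute-force role-assignment search over every assemblage of
up to five members, three haplotypes and all sex combinations. The rule on
three-member assemblages reduces exactly to the published 14-row pattern
table; the generalization to other sizes is the unique extension of the same
premises.

Assumptions worth keeping in view: one founding pair per family (serial
monogamy/replacement mates are not modelled); adults of unknown sex are
treated as male, which can only suppress MF calls — every reported MF
frequency is a lower bound. The same asymmetry produces a female-biased sex
ratio among *detected* MF logs, a detection artifact rather than a biological
signal; the simulator reproduces it.

## Haplotype handling

Haplotype identity is exact string equality after case-folding. Ambiguity
codes and gaps are compared literally, so an 'N' yields a distinct haplotype;
a warning flags inputs where this matters. Difference counts use
pairwise-complete unambiguous sites only (A/C/G/T on both sequences) with no
substitution-model correction, and percentages are uncorrected p-distances
reported to one decimal. Segregating sites are columns with at least two
distinct unambiguous bases; G+C% is computed over unambiguous bases only.

## Spatial clustering

The Cuzick–Edwards statistic T_k counts, over all case logs (MF), the case
logs among each case's k nearest neighbours. Design choices:

* **Distance**: haversine on WGS84 degrees (the emulated landscape spans
  several degrees); a planar metric is available by flag for small extents.
* **Ties**: after a stable sort on distance, ties resolve by ascending input
  index. Coincident coordinates are legal.
* **Null**: case/control labels are permuted over the fixed locations;
  p = (1 + #{T\* ≥ T_obs}) / (n_reps + 1) (add-one convention, upper tail),
  so p is never 0 and the test is valid at any finite rep count. Default
  9,999 permutations, evaluated vectorised in blocks.
* **Multiplicity**: Bonferroni over the k values tested (default k = 1..5,
  factor 5) per control scheme; a flag extends the factor over schemes.
* **Calibration**: on small point sets the Monte-Carlo p agrees with exact
  enumeration of all labelings within binomial error; on null landscapes of
  88 logs (19 cases, k = 2, 999 reps) the empirical type-I error at
  α = 0.05 sits slightly below nominal (≈ 0.04) because the integer-valued
  statistic makes the permutation test conservative.

Elevation comparisons use the pooled-variance two-tailed t-test
(df = n₁+n₂−2) with a two-tailed variance-ratio F-test (larger variance in
the numerator) reported alongside, as the equal-variance check.

## Divergence partitioning

Within each multi-haplotype log all C(h,2) unordered pairs of distinct
haplotypes contribute one record (redundant haplotypes omitted, so counts are
non-zero). An MF-log pair is *between-family* iff each haplotype is carried
by at least one female in that log — the weakest rule under which the two
matrilines are provably distinct; pairs involving male-only haplotypes remain
*ambiguous* (the male could be a father). OMH-log pairs form the comparison
class. The MF vs OMH distributions are compared by a paired t-test over
per-bin counts for integer bins 1..max (df = max−1); the pairing unit is the
difference bin. Both two-sided (default) and one-sided alternatives are
exposed, since a paired t can be read either way and the choice is
substantive only near the threshold.

## The synthetic-data generator

`populate_and_sample` emulates the study design: 88 logs over a
southern-Appalachian-sized extent (lat 33.5–38.5, lon −85.5 to −79.5,
elevations 300–1,700 m drawn uniformly, i.e. the elevation null is true by
construction); two or three adults sampled per log with P(3) = 0.78
(mean 2.78); a 1,125-bp marker with G+C = 0.338.

Matrilines come from a **serial-chain haplotype pool**: lineage i+1 derives
from lineage i by a geometric number (mean 1.2, support ≥ 1) of substitutions
at globally distinct sites, so chain distance equals nucleotide distance
exactly — every simulated divergence is known in closed form. Each log draws
a base chain position; co-occurring families sit 1–2 steps apart and a mate's
matriline is the same as the mother's with probability 0.5, otherwise 1–3
steps away (local mating). This produces the right-skewed within-log
divergence distribution (most pairs 1–2 mutations apart, occasional larger
divergences from the geometric tail); a `locality=False` flag makes all
draws uniform over the pool instead.

`p_multi_family` defaults to **0.40**. The observed multi-family frequency in
the emulated design is a lower bound on the true co-occurrence rate, because
a 2–3 adult sample proves co-occurrence only when it includes females of two
matrilines or three haplotypes; with 0.40 true co-occurrence the *classified*
SH/OMH/MF shares land near the 53/25/22% neighbourhood over replicates, and
roughly two thirds of within-log haplotype pairs differ by at most two
mutations. Families carry the father with probability 0.8 (he may have died),
the mother always, and two not-yet-dispersed adult offspring of balanced sex
ratio inheriting the mother's haplotype verbatim (an optional per-offspring
de-novo mutation rate, default 0, exists to study that simplification).
Sampling never pools across logs. `ensure_detectable=True` forces both
mothers of a two-family log into the sample, giving construction-guaranteed
sensitivity 1 for validation; `spatial_clustering_strength > 0` draws
multi-family logs around a common Gaussian centre for power studies of the
clustering test.

What the generator does **not** emulate: more than two families per log,
serial monogamy, age-structured sampling, real topography or
elevation–habitat correlations, recombination, and sequencing error. Passing
tests on synthetic data therefore demonstrate correctness of the inference
machinery under the model's assumptions, not robustness to their violation in
field data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the Monte-Carlo machinery at
moderate sizes chosen as good estimator practice: 9,999 permutations where a
single p-value is the object of interest, 999 permutations inside repeated
calibration loops (500 null landscapes), and 10 simulation replicates for
reported class-share averages. Monte-Carlo p-values use the add-one
estimator; percentages mirror field reporting conventions (whole percent for
class shares, one decimal for divergences, three decimals for χ²). All
randomness flows from explicit `numpy.random.default_rng` seeds; suite-level
child seeds are drawn deterministically from the master seed, making every
pipeline run bit-reproducible.

## Known limitations

* MF frequencies are lower bounds; sensitivity depends strongly on how many
  females the sample contains (quantified by the monotone sensitivity tests).
* The between-family attribution rule is the weakest sound rule; it cannot
  attribute male-only contrasts even when they are in fact between families.
* A study's specific clustering p-values depend on the distance metric and
  tie policy of the software used; with coordinates of real logs unavailable
  here, such values are context, not targets — the implementation pins its
  own metric and tie policy explicitly instead.
* Haplotype tallies on real data (e.g. counts of unique haplotypes and
  segregating sites from archived sequence accessions) require downloading
  those sequences; the package validates the same statistics on generated
  alignments with planted, exactly-known truth.
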