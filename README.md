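# matrilog

Inference of family-group co-occurrence in log-dwelling sub-social insects
from mitochondrial haplotypes and individual sex.

Sub-social woodroaches (and many other saproxylic invertebrates) live as
families — one monogamous founding pair plus their offspring — inside rotting
logs. Because direct observation inside a log is impossible, a basic question
of their population biology is hard to answer: how often does one log house
*two or more* families? `matrilog` implements a matriline-based inference
framework for exactly this setting: sample a few adults per log, sequence a
maternally inherited mtDNA marker, record each adult's sex, and classify every
log as

* **SH** — single haplotype: all sampled adults share one haplotype;
* **OMH** — other multi-haplotype: several haplotypes, but still consistent
  with a single family founded by one male–female pair;
* **MF** — multi-family: no single-family explanation exists.

## The inference rule

mtDNA is strictly maternally inherited and non-recombining, and de-novo
mutation over a ~1 kb marker within a family is negligible. In a single family
everyone — mother, daughters, sons — carries the mother's haplotype except the
father, who carries *his* mother's haplotype. An assemblage of sampled adults
is therefore consistent with one founding pair **iff all members share one
haplotype except at most one member, and that member is male**. Concretely, a
log is MF when it contains three or more haplotypes, or two haplotypes where
the minority haplotype has two or more carriers, or where its sole carrier is
female (two females with different haplotypes prove two matrilines). The
implementation is verified against an exhaustive brute-force search over all
role assignments (≤ 5 members, ≤ 3 haplotypes, every sex combination).

Around that core the package provides:

* `haplotypes` — haplotype collapse by exact sequence identity, segregating
  sites, G+C%, uncorrected pairwise difference counts and p-distances;
* `classify` — the SH/OMH/MF classifier plus χ² sex-ratio tests;
* `spatial` — the Cuzick–Edwards k-nearest-neighbour case–control test
  (statistic T_k = the number of case neighbours of cases) with a Monte-Carlo
  permutation null, Bonferroni correction over k = 1..5, and pooled-variance
  elevation t-tests with their companion F-tests;
* `divergence` — the within-log pairwise nucleotide-difference distribution,
  its partition into provably-between-family vs ambiguous vs OMH comparisons,
  and a paired t-test comparing the MF and OMH distributions over difference
  bins;
* `synthetic` — a forward simulator of colonisation and sampling with full
  ground truth (true family memberships, matrilines and haplotypes), used to
  validate specificity and sensitivity of the whole pipeline;
* a `matrilog` command-line interface orchestrating everything.

## Worked example

Simulate a ground-truthed landscape and analyse it:

```bash
matrilog simulate --seed 4 --out-dir demo/sim
# simulated 240 adults in 88 logs (34 truly multi-family); wrote demo/sim

matrilog report --fasta demo/sim/alignment.fasta \
                --metadata demo/sim/metadata.tsv \
                --out-dir demo/out --seed 1
# 88 logs: 58% SH, 22% OMH, 20% MF; 43 within-log haplotype pairs
# (fraction <=2 differences: 0.698)
```

`demo/out/` then contains `haplotypes.tsv`, `log_classes.tsv`,
`sex_ratio.tsv`, `clustering.tsv`, `elevation.tsv`, `diff_records.tsv`,
`diff_histogram.tsv` and `summary.json`. Reading the numbers: of 88 logs, 20%
were called multi-family although 34/88 ≈ 39% truly host two families — the
classifier is a lower bound by design, because a 2–3 adult sample only proves
co-occurrence when it catches females of two matrilines (or three
haplotypes). The same run shows the detection side-effect familiar from field
data, a female bias among MF logs (`sex_ratio.tsv`):

```
group   n_female  n_male  pct_female  chi2   df  p
MF          36      17        68      6.811   1  0.0091
```

and `clustering.tsv` reports T_k with raw and Bonferroni-corrected
Monte-Carlo p-values per control scheme (OMH logs, SH logs, or both combined)
for k = 1..5, e.g.

```
scheme  k  n_cases  n_controls  t_obs  n_reps  p_raw   p_bonferroni
omh     1    18        19        10     9999   0.3287  1.0
omh     4    18        19        39     9999   0.1548  0.774
```

Within-log divergence is strongly right-skewed: most co-occurring haplotypes
are 1–2 mutations apart (here 69.8% of pairs; maximum 6 differences = 0.5%
p-distance over 1,125 bp).

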