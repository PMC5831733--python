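# Methods

This note documents the models, parameter choices and numerical decisions
behind `echinodev`, and what the synthetic-data generators do and do not
emulate.

## Quantification and internal-standard normalization

Counts are held per expression cluster (EC) and sample; samples carry a
time point (hpf) and an `included` flag. Excluded samples (e.g. chemically
perturbed replicates collected alongside a stage) never contribute to
filtering totals, library sizes or standard-deviation computations — they
ride along in the tables for provenance only.

- **Low-count filter.** An EC is kept iff its total count over included
  samples is ≥ `min_reads` (default 10; the boundary is strict "less
  than": a 10-read EC survives). Totals are taken across samples, matching
  the behaviour of read-sharing cluster quantifiers whose output these
  tables mimic. The filter is idempotent.
- **RPKM.** Included samples sharing an hpf are summed; value =
  count · 10⁹ / (length_bp · library), library being the included total at
  that time point.
- **Peak normalization.** Each row is divided by its own maximum; all-zero
  rows are rejected with the offending ids listed, since a flat-zero
  trajectory has no peak and would otherwise silently produce NaNs.
- **Internal standard.** On the peak-normalized matrix, rows with sample
  standard deviation (n−1 denominator; conventional for 4 observations,
  and a one-line change if the population form is preferred) below 0.01
  form the standard set. Selection on an empty result is an error: without
  a standard the scaling is undefined, and the right response is to review
  the threshold, not to return an empty normalization.
- **Scaling.** The factor is computed per time point (the mean RPKM of the
  standard set there) rather than globally: only per-time-point division
  removes depth differences between samples. Every value is divided by its
  time point's factor and multiplied by 10⁶, which enforces the invariant
  that the standard-set mean is exactly 10⁶ at every stage (it holds to
  machine precision, ~1e-16 relative). Within a time point the scaling is
  a single multiplicative constant, so expression ratios between ECs are
  preserved exactly.

A practical caveat documented here because it shapes how the standard
should be selected: at finite sequencing depth, Poisson counting noise
alone gives a peak-normalized trajectory an SD of roughly 1/√(mean count),
which exceeds 0.01 for any EC with fewer than ~10⁴ reads per sample.
Standard selection on count-derived RPKM therefore requires very deep
libraries; on expression-scale values (as the generator returns, or as
averaged replicates approximate) the 0.01 threshold cleanly separates
near-constant genes (noise SD 0.002) from shaped ones, with recall ≥ 0.98.

- **Annotation propagation.** An EC inherits the most frequent annotation
  of its constituent contigs, with ortholog-tier (reciprocal-hit)
  annotations strictly prioritized over homolog-tier (one-directional)
  ones; frequency ties break to the lexicographically smallest annotation
  id and are flagged ambiguous, so the output is deterministic and the
  ambiguity is auditable. Contigs missing from the annotation table count
  as tier `none` and are logged, not fatal.

## Consensus fuzzy trajectory clustering

Input is the peak-normalized trajectory (z-scoring is available upstream
but not default: peak scale is what the normalization pipeline produces
and keeps flat trajectories flat). Fuzzy c-means uses the standard
alternating updates with Euclidean distance; a point coinciding exactly
with a centroid receives crisp membership 1 there (the limit of the update
rule). The objective Σ u^m d² is recorded every iteration and is
non-increasing; iteration stops when its relative change is ≤ `tol`
(1e-6) or at `max_iter` (300). Cluster count defaults to 3^(T−1) — the
number of possible sign paths of a T-point trajectory, 27 for T = 4 — and
is recomputed if T differs.

Parameter choices:

- **Fuzzifier m = 1.25.** Low fuzzifiers give near-crisp memberships,
  appropriate when k (27) already over-segments a 4-dimensional shape
  space; m is exposed on the API and CLI.
- **Runs and seeds.** The clustering is repeated (default 100 runs; the
  recovery analyses in the test-suite use 20, which at these problem sizes
  gives indistinguishable consensus labels) with run r seeded
  `base_seed + r`; all seeds are recorded in output provenance.
- **Consensus.** Labels of every run are aligned to run 0 by
  minimum-total-Euclidean-distance matching of centroids (Hungarian
  assignment, optimal). The consensus label is the modal aligned hard
  label; support is the modal fraction; ties break by highest mean
  membership for the tied cluster, then lowest cluster index —
  deterministic and permutation-invariant.
- **Mode classification.** For centroid c, step differences d_t are
  flattened when |d_t| ≤ flat_eps · max(c) (flat_eps default 0.05 —
  small enough to keep genuine monotone change, large enough to absorb
  noise wobble; exposed). Peaks of the resulting sign pattern, endpoints
  included, decide the mode: one peak at the start → EARLY, at the end →
  LATE, interior → INTERMEDIATE, two peaks → BI_MODAL, no non-flat step →
  UNCLASSIFIED. With T = 4 at most two peaks are possible, so the five
  labels are exhaustive.
- **Gene-level modes.** A gene inherits the mode of its consensus
  cluster's centroid, where the consensus cluster's centroid is the mean
  trajectory of its member genes: averaging run centroids across
  alignments blurs co-assigned shapes, whereas the member mean is the
  sharpest summary of what the consensus cluster contains (the aligned
  mean remains available as a fallback when the clustered matrix is not
  supplied). Genes whose maximum normalized expression falls below
  `min_expression` are UNCLASSIFIED regardless of cluster — too weakly
  expressed to call a temporal mode.

## Cross-species mode comparison

Gene pairs come from an ortholog/homolog table. One-to-many mappings
resolve deterministically: the unique ortholog-relation partner if there
is one, otherwise the lexicographically smallest partner, flagged and
logged. UNCLASSIFIED is a genuine fifth row/column of the contingency, not
dropped — unclassifiable genes are part of the comparison. Subset genes
without a partner carrying a mode in the other species count as unmapped,
so contingency total + unmapped equals the subset size.

## Gene-set conservation

The resampling null draws `n_draws` (default 1000) sets of the candidate's
size without replacement from the full universe and records each set's
all-species overlap. The empirical p uses (r+1)/(n+1), the standard
convention that avoids zero p-values at finite draw counts. The RNG stream
is salted with a module constant so that passing one global seed to both a
data generator and the null keeps their streams distinct.

The two-proportion chi-squared is the standard 2×2 statistic
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with 1 df and upper-tail p; Yates
continuity correction is available but off by default (immaterial at the
counts this test is used for). Because the published denominators of such
comparisons are often ambiguous (all genes in the set vs genes detected in
at least one non-reference species), the conservation report emits both
proportion pairs, clearly labelled, rather than guessing one.

A calibration note: when the comparison universe is itself one random
realization, the appropriate 3-SE band for mean(draws) against the
analytic expectation n·p^(S−1) combines the universe-level binomial
variance of the all-species count with the resampling variance of the
mean; the pure draw-mean SE alone is too tight by an order of magnitude.

## Transcript families

Identity is computed from a global alignment with fixed scoring (match +1,
mismatch −1, linear gap −2, end gaps penalized like internal ones) as
identical columns / alignment length *including gap columns* — the
strictest common convention, configurable only through the code because
changing it silently changes what "97%" means. When several alignments are
co-optimal the maximum identity over at most 64 of them is used, so ties
resolve deterministically and identically to the brute-force oracle in the
tests. Families are single-linkage connected components of the
≥ threshold graph ("partitioning" implies transitive grouping); family ids
are the smallest member id. A length-band prefilter skips pairs whose
shorter/longer length ratio is below the threshold — under the
gap-inclusive denominator identity cannot exceed that ratio — keeping the
all-vs-all pass tractable without affecting results. The polymorphism
helper reports 100·mismatches/aligned_length to one decimal (7 mismatches
over 588 bp → 1.2%).

## Synthetic-data generators

All generators take an explicit seed and are bitwise reproducible.

- **Time course.** Each regular gene draws a mode from the configured
  proportions (default uniform over the four modes), an amplitude
  log-uniform over two orders of magnitude (so normalization is exercised
  across the dynamic range), and a trajectory = template × amplitude ×
  exp(N(0, noise_sd)) per time point (multiplicative log-normal noise —
  the simplest model giving positive, right-skewed RNA-seq-like values;
  default noise_sd 0.1 on the log scale). Planted internal-standard genes
  are constant with log-scale wobble 0.002; planted low-count ECs have
  totals drawn uniformly below 10 reads. Counts are Poisson with
  expectation ∝ expression × gene length, scaled to the configured depth
  (default 5·10⁶ reads/sample); lengths are uniform on 500–3000 bp. The
  generator can emit extra samples flagged excluded at the third time
  point, mirroring perturbed replicates. Default sizes (2000 genes, 50
  standards) are the conditions under which the recovery properties in the
  test suite are stated. Template sign patterns are validated at
  construction to classify to their own mode, so the planted truth is
  well-defined. Not emulated: read-level errors, isoform structure,
  overdispersion beyond Poisson, batch effects, and correlated noise
  between genes — recovery results on this generator bound what the
  pipeline can do when its model assumptions hold, not its behaviour on
  arbitrary real libraries.
- **Presence/absence.** Every gene is present in the reference species;
  presence elsewhere is independent Bernoulli with background or enriched
  retention probability. Independence across species is an idealization —
  real homolog detection correlates with gene length, expression and
  divergence time — so the analytic p^(S−1) calibration checks the null
  machinery, not biological realism.
- **Protein families.** Family ancestors are random 20-letter sequences
  rejection-sampled until all cross-family identities fall below the
  configured cap (default 0.8), guaranteeing separable truth between
  families. Members substitute each position i.i.d. at the configured rate
  (default 0.01), with the per-member substitution count capped at
  ⌊(1−threshold)·L/2⌋ by redrawing, which bounds every within-family pair
  at ≥ the partition threshold via the triangle inequality: the planted
  partition is separable by construction on both sides, so partition
  recovery tests the clustering machinery rather than the luck of the
  draw. The truncation is mild (expected pairwise identity ≈ 98% at the
  defaults, as in the untruncated model).

## Problem sizes and determinism

The analyses in the test suite and acceptance script run at desk scale —
2000-gene time courses, 20 clustering runs, 10,000-gene presence
universes with 1000 resampling draws, 30-sequence family sets — sizes at
which every statistical property of interest is already stable and the
whole suite completes in well under a minute of compute per analysis.
Every stochastic component takes a seed, derived seeds stay below 2³¹,
and identical configuration + seed reproduces every table byte for byte.

## Known limitations

Fuzzy c-means consensus depends on the run-0 reference for alignment;
degenerate runs (empty clusters) keep their previous centroids rather than
re-seeding. Mode classification is a verbal rule made precise by peak
counting; centroids hovering at the flat_eps boundary can flip between
INTERMEDIATE and BI_MODAL readings. The family partitioner is quadratic in
the number of sequences and meant for desk-scale inputs, not
100k-sequence assemblies. The conservation test treats the presence
matrix as error-free; detection failures in any species count as genuine
absence.
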