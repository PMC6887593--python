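# Methods

## Study design emulated by the synthetic generator

The pipeline targets a two-cohort design: a discovery cohort (microarray
scale, n = 240 tumors by default) and a validation cohort (RNA-seq scale,
n = 500 tumors plus 45 normal lung samples).  Both cohorts are drawn from
one generative law; only sizes and subtype frequencies differ.  Defaults
describe an adenocarcinoma-like branch with three expression subtypes at
frequencies TRU/PI/PP = 0.614/0.212/0.174 (discovery) and 0.458/0.353/0.189
(validation); a four-subtype squamous-like branch is configured by supplying
four subtype names and frequency vectors.

On the log2 scale, for tumor sample *j* of subtype *s(j)*:

* **mRNA**: `x_gj = b_g + c_{g,s(j)}·1[g classifier] + δ_k·1[g shifted member
  of set k, s(j) shifted] + β·(m_tj − b_t)·1[g target of t] + ε`,
  with gene baselines `b_g ~ N(9, 1)`, centroid entries
  `c_gs ~ N(0, centroid_scale²)` (`centroid_scale = 2`), pathway shifts
  `|δ| = 1` applied to 70% of a shifted set's 30 genes, repression slope
  `β = −0.65`, and noise `ε ~ N(0, noise_sd²)`, `noise_sd = 1`.
* **miRNA**: `m_ij = b_i + Δ·(±1)·1[i marker of s(j)] + ε`, with
  `b_i ~ N(7, 1)` and marker shift `Δ = 1.5` log2 units.  Twelve markers are
  planted among 300 miRNAs, spread over the subtypes with mixed directions.
* **Normals** (validation only) sit at the feature baselines, so every
  default marker differs from normal tissue; a `normal_shift` field makes a
  marker "normal-like" to exercise the normal filter.
* **Detection**: per-cell Bernoulli flags with probability 0.98, except a
  6% tranche of non-marker miRNAs at 0.05 that the detection filter removes.
  Planted markers are always well-detected — markers that reached a real
  study's analysis stage passed its detection filter by construction.
* **Couplings and targets**: a set shifted downward in subtype *s* is
  genuinely anticorrelated with every up-marker of *s* (and vice versa);
  the default plan yields 8 such marker–set couplings.  Twenty planted
  targets are shifted members of coupled sets repressed by the coupled
  marker; with the coherent pathway shift the design Spearman correlation is
  about −0.65.  The predicted-target table holds the planted pairs as
  `very_high` plus 10× decoys: `very_high` pairs on *unshifted* members of
  selected sets (these enter the candidate universe and must fail the
  correlation gate), `high`-class pairs on genuinely anticorrelated genes
  (must fail the class gate), and random `medium`/`low` pairs.

What the generator does **not** model: probe-level microarray physics, batch
effects, RNA-seq count overdispersion, correlated gene–gene noise, tumor
purity, or cross-platform calibration differences (a configurable fraction
of features can be dropped from one cohort to mimic platform mismatch, off
by default).  Passing recovery tests therefore demonstrates that the
procedure is implemented correctly and has the designed power under clean
Gaussian conditions — not that it would achieve these rates on real arrays.

## Pipeline and parameter choices

**Normalization.** miRNA matrices are normalized by subtracting each
sample's 90th percentile (linear-interpolation percentile; the operation is
shift-equivalent to division on the raw scale, idempotent, and leaves every
downstream rank statistic invariant to the choice of target constant, so the
post-normalization percentile is 0).  mRNA matrices are quantile-normalized
to the mean of order statistics; tied values within a sample receive the
mean of the reference values at their tied ranks, removing input-order
dependence.  The detection filter removes features detected in strictly less
than the branch threshold (0.10 AD-like, 0.20 SCC-like) of all samples.

**Subtyping.** Pearson correlation of each tumor's profile with each
centroid over the intersected classifier genes; genes are median-centered
across the cohort's tumor samples first (`center_genes` flag, default on,
since published centroid classifiers are built on centered data).  A sample
is UNASSIGNED when its maximum correlation is ≤ 0 or its profile is
constant; calls are suppressed entirely when fewer than half the classifier
genes are present.  Degenerate case: when one subtype exceeds 50% of a
cohort and noise is very low, median centering can collapse exactly those
samples to an all-zero profile; classification then falls back to the
uncentered profile (logged).  This keeps the zero-noise limit exact without
affecting realistic noise levels, where the collapse has probability zero.

**Rank statistics.** Midranks everywhere.  Kruskal–Wallis uses the
tie-corrected H with a chi-square tail (df = k−1); all-identical data return
the degenerate convention H = 0, p = 1.  Dunn's z uses the pooled-rank
variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`; the BH family for Dunn is the
k(k−1)/2 pairs of one feature (the convention of the common fisheries-
statistics implementation), while BH across features is applied at the
omnibus stage.  Mann–Whitney is exact by enumeration for tie-free inputs
with `n_a·n_b ≤ 400`, otherwise normal with tie-corrected variance and
continuity correction.  Spearman p-values use the Student-t transform with
n−2 df.  Distribution tails come from scipy; everything else is implemented
here and cross-checked against scipy/statsmodels in the test suite.

**Enrichment scores.** Gene-level expression is smoothed into CDF space
with a Gaussian kernel of bandwidth `s_i/4` (sample standard deviation;
zero-variance genes score 1/2 everywhere and are retained so gene universes
match across cohorts).  Genes are ranked per sample by decreasing CDF value
with ties broken by stable input order (deterministic; tie counts logged),
weighted by `|p/2 − d|` with exponent τ = 1, and a weighted walk produces
the enrichment score.  The default convention is `max_diff` (largest
positive plus largest negative deviation); `max_abs` is available.  Scores
are computed on tumor samples per cohort.  Sets with fewer than 2 measured
genes are skipped; a set covering every measured gene is an error (the
decrement denominator vanishes).  Note the score is *not* exactly
antisymmetric under data negation: orderings reverse exactly, but the
positional weight is shifted by one index under reversal, so only the sign
flips exactly.

**Marker consensus.** The omnibus screen BH-corrects KW p-values across
miRNAs within each cohort and intersects the survivors.  A candidate
(miRNA, subtype) needs every pairwise Dunn comparison significant in both
cohorts with one consistent mean-rank sign; direction is "up" when the
subtype out-ranks all others.  The borderline relaxation (for small
subtypes, e.g. a primitive-like group) applies only to discovery-cohort
pairs involving the named subtype, requires the validation cohort to pass
at the ordinary alpha, and flags the call.  No default relaxed alpha is
shipped — it must be configured deliberately.  The normal filter runs
Mann–Whitney of the candidate subtype's tumors against each normal-bearing
cohort's normals, BH-corrected across candidates, and requires direction
concordance; with no normals anywhere it warns and passes candidates
through (configurable to hard-fail).

**Associations and targets.** Spearman correlations between marker miRNAs
and set scores use all subtype-assigned tumor samples of a cohort; the
Bonferroni family is (markers × sets) per cohort, and for target testing
the number of candidate pairs per cohort.  "Most anticorrelated in both
cohorts" is resolved minimax — the set whose *worse-cohort* rho is most
negative — with a mean-rho alternative behind `set_pick_rule`.  Extra
configured sets (the Spermatogenesis / E2F-targets style exception) are
appended to a marker's selection only when they are themselves
significantly negative in both cohorts, preserving the invariant that
everything entering target analysis is dual-cohort significant-negative.
Accepted targets must be `very_high`-class predictions inside a selected
set, measured in both cohorts, with negative rho and Bonferroni-adjusted
p < 0.05 in both; acceptance implying negative rho is asserted, not just
tested.  Correlation matrices for reporting are ordered by Ward-criterion
agglomerative clustering on Euclidean distances (the ward.D2 convention,
via scipy); the heatmap sign rule multiplies rho by −1 for down-regulated
markers so that reported pathway directions read as program activity.

## Problem sizes and determinism

The test suite runs the full pipeline at the design scale (240/500 tumors,
300 miRNAs) over 20 seeds for marker/coupling/target recovery, 10 null
seeds for false-call rates, 2,000-replicate null simulations for the
Kruskal–Wallis type-I error and the BH false discovery rate, and fuzzed
instances up to 50 genes × 10 samples × 5 sets for oracle equivalence of
the enrichment scorer (tolerance 1e-12 against a direct double-summation
implementation).  The acceptance script uses 5 full-scale recovery runs and
3 null runs per invocation.  All randomness flows from
`numpy.random.default_rng` seeded by the configuration, so identical
config + seed reproduce every result file byte for byte (the run manifest
records config, seed and library versions).

## Known limitations

* The Gaussian, independent-noise generator makes rank tests close to their
  nominal power; real array/RNA-seq noise is heavier-tailed and correlated.
* Enrichment scoring follows the kernel-CDF method's published formulas;
  numeric identity with any particular release of the original R
  implementation is not claimed (conventions such as the tie policy are
  documented above).
* The borderline relaxation has no principled default alpha; it is a
  deliberate, logged analysis choice.
* Cross-platform feature matching is by identifier only; no alias
  resolution is attempted.
* With fewer than two normal-bearing cohorts the normal filter cannot
  distinguish platform effects from biology; it simply tests each
  normal-bearing cohort independently.
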