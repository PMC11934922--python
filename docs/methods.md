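# Methods

`probefold` models RNA secondary structure from chemical-probing reactivity
profiles. This note records the statistical and algorithmic choices, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Reactivity preprocessing

Input profiles are per-nucleotide reactivities (1-based position, value). The
sentinel value **−10** marks an undetermined nucleotide and is excluded from
every statistic; it propagates unchanged through all stages.

Two normalization methods are available, and a project uses exactly one:

* **simple** (boxplot-style, default, recommended below ~300 nt): with `V`
  the valid values sorted descending, the top `ceil(0.02·|V|)` are outliers
  (intrinsic reverse-transcriptase stops) and are set to −10; the next
  `ceil(0.08·|V|)` are averaged into the normalization factor `A`; every
  remaining valid value is divided by `A`. After normalization the reference
  set has mean exactly 1. Ties at a cutoff are broken by position index so
  the operation is deterministic.
* **interquartile** (for longer molecules): values above `Q3 + 1.5·IQR` are
  outliers; `A` is the mean of the top `ceil(0.10·n)` remaining values.
  Quartiles use linear interpolation (the common "type 7" convention; the
  choice is documented because it slightly moves the cutoff on small
  profiles).

**Stage order.** The negative-value rules run *last*, on the normalized
scale: values in `[−0.3, 0)` become 0; values below −0.3 become −10. This
matters: a mildly negative raw value that normalization shrinks into the
`[−0.3, 0)` window is clamped to zero rather than dropped.

**Non-idempotence of the simple method.** Removing the top 2% is defined
relative to whatever profile the operation receives, so re-preprocessing an
already-preprocessed profile trims a further `ceil(0.02·|V′|)` positions and
rescales by a new (near-1) factor. This is an intrinsic property of
count-based trimming, not an implementation artifact; the interquartile
method *is* idempotent on profiles without IQR outliers because its cutoff is
scale-invariant and its second-pass factor is exactly 1. Both behaviours are
asserted in the unit suite. Do not run the preprocess stage twice on the same
files; the project orchestration prevents this by tracking input hashes.

The ≤300 nt guideline for the simple method is advisory: the tool warns and
never switches methods silently, since one method per project is enforced for
consistency.

## Replicate aggregation

Aggregation is position-wise. With fewer than `min_ndata` (default 2, clamped
to 1 when the condition has a single replicate) valid replicate values a
position is **undetermined**. Otherwise the mean `m` and sample standard
deviation `s` (n−1 denominator) are computed, and the position is
**accepted** when `s ≤ min_std` (default 0.15) or when all pairwise replicate
means fall in the same reactivity class as `m` (classes: low < 0.4 ≤ medium ≤
0.7 < high, boundaries closed into `medium`; the sentinel maps to
`undefined`).

Two consequences of this formalization are worth stating:

* With exactly two valid values the single pairwise mean *is* the total mean,
  so the class criterion would be vacuous; the implementation instead accepts
  two-replicate positions only when the two values themselves share a class
  (or `s ≤ min_std`), preserving the criterion's intent of range agreement.
  Rejected two-replicate positions are flagged `nonconsistent`.
* The total mean is a convex combination of the pairwise means. If every
  pairwise mean lies in one class interval, the mean lies in that interval
  too, so a "warning" flag (pairwise means agreeing on a class *different*
  from the mean's) is unreachable for interval-shaped classes. Rejected
  positions therefore surface as `nonconsistent` (pairwise means spanning
  several classes). The `warning` value is kept in the flag vocabulary for
  file compatibility and for severity ordering during primer merging.

Only accepted positions constrain structure modeling; warning, nonconsistent
and undetermined positions all behave as missing data downstream. Pairwise
Pearson/Spearman correlations between replicates are reported as QC (over
positions valid in both replicates; undefined below 3 common positions) and
deliberately have no automated consequences — excluding a failed experiment
is a user decision recorded as `discarded` in the samples table.

**Primer concatenation.** Long RNAs probed with several primers yield
segment profiles that are merged after aggregation. Uncovered positions are
undetermined. Where segments overlap: two accepted values average (std
combined conservatively as the max); one accepted value wins over any
rejected one; two rejected values keep the more severe flag
(warning < nonconsistent < undetermined).

## Folding engine

Reactivities enter the folding model as per-nucleotide pseudo-energies
`g(r) = m·ln(r + 1) + b` (defaults m = 2.6, b = −0.8 kcal/mol), added once
per *paired* nucleotide; undetermined positions contribute 0. The slope
penalizes pairing reactive nucleotides; the negative intercept mildly rewards
pairing unreactive ones.

The built-in energy model is deliberately minimal: per-pair energies
GC −3.0, AU −2.0, GU −1.0 kcal/mol, hairpin loops of at least 3 nt,
RT = 0.616 kcal/mol (37 °C), no stacking or loop terms. The partition
function over all nested structures is computed by exact dynamic programming
(inside recursion `O(n³)`; the empty structure contributes 1), base-pair
probabilities by an exact outside recursion (`O(n⁴)` as implemented —
intended for short RNAs and for validation; sampling does not need it), and
structures are drawn i.i.d. from the Boltzmann distribution by stochastic
traceback with per-interval cached decision weights. Everything is checked
against exhaustive enumeration for short sequences in the test suite, at
machine precision.

The engine is a contract, not a commitment: any engine exposing
`partition_function` and `sample_structures` with the same signatures can be
substituted (e.g. an adapter to a full nearest-neighbor implementation), and
every downstream stage depends only on the returned samples.

Because the model is stacking-free, helices are not cooperative: terminal
base pairs fray more than under a nearest-neighbor model, and isolated decoy
pairs cost nothing extra. This shapes the synthetic benchmark design (below)
and is the main known limitation for real sequences.

## Alignment (phylogenetic) pseudo-condition

A multiple sequence alignment contributes to prediction exactly like one more
probing condition. Each column pair is scored by

```
mean pair energy over rows whose residues form a WC/GU pair
+ covariation_bonus · max(0, #distinct pair types − 1)
+ inconsistency_penalty · #rows that cannot pair (gaps included)
```

with defaults `covariation_bonus = −1.0` and `inconsistency_penalty = +0.5`
kcal/mol. The scored alignment is folded and sampled with the same ensemble
machinery (sampling the consensus ensemble rather than taking a single
consensus structure, so alignment uncertainty is represented the same way as
probing uncertainty); sampled column pairs are mapped to reference
coordinates by deleting reference-gap columns, dropping pairs that touch
them. This is a deliberately simplified analogue of covariance-scored
consensus folding, not a reimplementation of any specific consensus folder.

## Multi-condition prediction

Per condition, accepted reactivities become pseudo-energies and `n_samples`
(default 1000) structures are drawn, each condition with its own RNG stream
spawned from the master seed. The pooled samples are clustered by base-pair
distance (symmetric difference of pair sets) with average-linkage
agglomerative clustering; the number of clusters maximizes the mean
silhouette over k = 2..max_k (default 10), with a single cluster when the
pool's mean pairwise distance is below 2 (near-degenerate ensembles).
Samples are clustered in a canonical order (sorted by dot-bracket string) so
the result is deterministic and invariant under pool permutation.

Clusters are ranked by the multiplicative cross-condition support score
`∏_c (occupancy_c + ε)` with ε = 0.01: a cluster absent from one condition is
strongly penalized but not zeroed, so broad support across experiments beats
dominance in a single one (e.g. 50%/50% across two conditions scores 0.2601
against 0.0101 for 100%/0%). Ties break by total occupancy, then lower mean
sample energy, then lexicographic centroid. Each cluster is represented by
its **centroid**: the pairs present in more than half of its members, which
is always a valid structure (two conflicting pairs cannot both exceed 50%
among nested structures). The top two centroids are the best and second-best
models; when at least two clusters exist they come from different clusters
and may represent alternative foldings.

The multiplicative score is this package's concrete instantiation of
"large, favorable clusters supported by multiple conditions"; additive or
Pareto-style combinations are plausible alternatives and no claim is made
that results are bit-identical to any other implementation.

## Footprinting

For two conditions with per-position replicate values, a position is called
significant when all three hold: `ΔR = |R1 − R2| > 0.2`, relative difference
`ΔR/(R1+R2) > 0.2` (defined as 0 when `R1+R2 = 0`), and a two-sided Welch
(unequal-variance) t-test on the replicate values gives `p < 0.05`. The dual
effect-size guard discards small changes between weakly reactive nucleotides
and large-but-meaningless changes between highly reactive ones. Undetermined
positions are excluded; with fewer than two replicates on a side no test is
possible and the position is reported unsignificant with a `no-test` flag.
No multiple-testing correction is applied by default, matching the stated
rule (the thresholds act as the effect-size guard); Benjamini–Hochberg
adjustment is available but off by default. Swapping the conditions flips
direction labels and the histogram sign but never the significance set.

## Synthetic data generator

The generator emulates *already-normalized* reactivity profiles for a known
structure: unpaired positions draw from Gamma(shape 3, scale 0.27; mean
≈ 0.81), paired positions from Gamma(shape 2, scale 0.05; mean 0.1) — both
nonnegative and right-skewed, sitting on the scale where the 0.4/0.7 class
thresholds are meaningful. Replicates share the per-position base reactivity
and multiply by log-normal noise (σ default 0.3); sparse ×10 spikes (rate
0.01) emulate intrinsic RT stops and random dropouts (rate 0.02) emulate
undetermined nucleotides. A DMS-like probe masks everything except A and C;
a SHAPE-like probe observes every position. With these defaults a 0.4
threshold separates paired from unpaired positions with ≈ 90% accuracy,
which is what makes recovery experiments informative.

Because the profiles are generated on the normalized scale, benchmark
pipelines feed them directly to aggregation; running them through
normalization again would divide the signal by the mean of the upper tail
(≈ 1.9×) — a double normalization that no real pipeline performs. The raw
project pipeline (read → preprocess → aggregate → predict) is exercised
separately with the same generator, where the spikes give the outlier
removal real work.

Alignments are simulated by mutating the reference at a per-position rate
(default 0.1 over 8 rows); mutations hitting a paired position co-mutate the
partner with probability 0.9 to a random WC/GU pair, so true pairs carry
covariation signal; sparse gaps (rate 0.01) are inserted. Not emulated
anywhere: sequence-dependent probe biases, signal decay along the read,
correlated replicate error, indel-rich alignments, pseudoknots. Passing
recovery tests on this generator therefore demonstrates correctness of the
integration machinery, not performance on real probing data.

Footprint simulations model differential sites as *exposure events*:
protected (paired-like, low) baselines that gain +0.6 in the second
condition, as when a ligand-bound junction opens; replicate noise is
additive Gaussian (σ 0.1) truncated at zero. Shifting an already highly
reactive baseline (> 1.2) would by construction fail the relative-difference
guard — that is the guard's documented purpose, so such sites are not used
as planted positives.

## The designed recovery benchmark

Multi-condition recovery is measured on a designed 63-nt two-hairpin RNA
(10-bp stems, GAAA loops, pure-adenosine tails and linker). The flanks are
pure A so that stem nucleotides find no decoy partners outside their helix,
and the stem sequences were optimized against the package's own energy model
(random search followed by single-base hill-climbing) to maximize the margin
between the least probable true pair and the most probable false pair under
idealized SHAPE and DMS reactivities (final margin: min true-pair probability
0.98, max false-pair probability 0.006). Under a stacking-free model an
unoptimized sequence leaves register-shifted and cross-linker decoy helices
that no probing data can resolve; the optimization makes the design
*well-determined*, which is the premise of a recovery benchmark. Each trial
simulates 3 replicates per condition at σ = 0.3, aggregates, samples 500
structures per condition, and scores the best centroid against the design by
base-pair F1 (exact pair matching, no ±1 slippage tolerance). Per-condition
sample sets are drawn once per seed and reused across the single-condition,
integrated and alignment-augmented settings so the comparison is paired.

## Determinism and traceability

Every stochastic step takes an explicit seed; per-condition streams are
spawned deterministically from the master seed. All numeric output is
formatted with 6 significant digits, so identical inputs, configuration and
seeds reproduce byte-identical TSV/dot-bracket outputs. Output files carry
the configuration hash (and, where relevant, the input-file hash) in a
header comment; the preprocess stage skips files whose recorded hashes match,
which is what makes incremental re-runs after adding an experiment cheap.
Staleness is tracked by content hashes rather than timestamps, so copying a
project does not trigger recomputation.

## Problem sizes used in the test and acceptance runs

Engine exactness: 50 random sequences of length ≤ 12 against exhaustive
enumeration. Sampler fidelity: 50 000 samples on six short sequences,
total-variation ≤ 0.02. Aggregation: the exhaustive 13³ grid of replicate
triples against an independently coded rule evaluator. Footprinting: 100
simulated 100-nt RNAs, 3+3 replicates, 10 planted +0.6 shifts. Recovery: 20
seeds × 500 samples/condition on the designed benchmark. These sizes were
chosen so the whole suite runs in well under a minute of engine time while
keeping Monte-Carlo error far from every threshold.

## Known limitations

* The built-in energy model has no stacking, loop, or dangling-end terms;
  predictions on real RNAs should use a nearest-neighbor engine through the
  adapter contract. All pipeline-level properties (clustering, scoring,
  centroids, footprinting) are engine-agnostic.
* Pseudoknots are out of scope throughout (nested structures only).
* The base-pair probability (outside) recursion is O(n⁴) as implemented and
  intended for short RNAs and validation; ensemble sampling, which the
  pipeline actually uses, is O(n³) + O(n log n) per sample.
* The covariation scorer measures raw pair-type diversity; it applies no
  significance assessment of covariation.
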