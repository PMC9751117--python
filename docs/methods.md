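# Methods

## The problem this package models

A genotype–phenotype screen of the kind `seq2exp` emulates measures reporter
fluorescence for a large library of short DNA variants. The library is not
random: it is built from a few dozen *seed* sequences chosen to be mutually
distant in Hamming space, each randomized into a *mutational series* of
thousands of local variants. This gives the dataset a two-level structure —
broad coverage across seeds, deep coverage within each series — that is
exactly what makes it useful for studying how training-set size and
*sequence diversity* affect regression accuracy. The pipeline's default
study conditions mirror such a screen: 56 series of ~4000 variants with
96-nt variable regions, fluorescence normalized to [0, 1].

## Synthetic library generator

### Seed design

`design_seeds` uses greedy maximin: the first seed is uniform random; each
subsequent seed is the candidate (among `candidate_pool` uniform draws, or
all 4^L strings when the pool covers them) maximizing the minimum Hamming
distance to the seeds already chosen, ties to the first candidate. Greedy
maximin is not guaranteed optimal, but it is deterministic, cheap, and
verifiable against brute force at tiny L. With default settings at L=96 the
realized minimum pairwise distance is ≈ 70–75 of 96 positions.

### Mutation model

Each variant mutates each seed position independently with probability
`mutation_rate` (substitutions uniform over the three other bases). The
default rate is **0.05 per position**, i.e. a mean seed↔variant distance of
≈ 4.8 and a mean within-series pairwise distance of ≈ 9 at L=96 — far below
the ≈ 72 between-series distance, so series form tight, well-separated
clusters. The depth of real mutational series is not derivable from the
emulated screen's description; 0.05 was fixed once as a realistic
"local-exploration" rate and is exposed as a configuration field, not
inferred. After mutation, in-frame stop codons are repaired (third base
rewritten to T: TAA/TAG→TAT, TGA→TGT) so the translated-peptide property is
defined for every record; this happens at library assembly, not inside
`generate_series`, whose i.i.d. contract stays exact.

### Ground-truth phenotype map

No published ground truth exists for sequence→expression; the generator
therefore defines one that (a) reuses the same eight biophysical properties
the encodings use, making parameter recovery testable, and (b) can produce
the qualitatively distinct per-series phenotype distributions seen in real
screens. For a sequence s with normalized property vector φ(s) ∈ [0,1]⁸:

    u = w·φ(s) + b − d·1[φ_j(s) < τ]
    y = clip( link(u) + ε, 0, 1 ),   ε ~ N(0, noise_sd²)

with `link` the logistic squashing by default (an `identity` link, clamped,
is available and makes the noise-free map exactly linear — used by the
parameter-recovery tests). Property normalization uses library-wide min–max
statistics.

Per series, a base weight vector is drawn at random and the linear score is
standardized by the series' empirical mean and standard deviation; a *shape
preset* then fixes the gain a, offset b and switch depth d:

| preset     | a   | b    | d   | resulting distribution            |
|------------|-----|------|-----|-----------------------------------|
| gaussian   | 0.9 | 0    | 0   | symmetric, \|skew\| < 0.5         |
| right_skew | 1.0 | −2.0 | 0   | mass near 0, right tail           |
| left_skew  | 1.0 | +2.0 | 0   | mass near 1, left tail            |
| bimodal    | 0.6 | +2.2 | 4.4 | two lobes separated by a trough   |
| uniform    | 1.7 | 0    | 0   | ≈ flat on [0,1] (logistic(1.7z) ≈ Φ(z)) |

Because some properties are discrete (bottleneck position, the integer fold
scores), a single random weight draw can give a strongly skewed score; the
generator draws up to 20 candidate weight vectors per series and keeps the
most symmetric one, so the presets transform the standardized score
predictably across seeds. The bimodal switch is placed on a *continuous*
property (%AT, CAI, Btl_S or MHI — preferring the largest absolute weight
with an acceptably balanced median split), with threshold τ at the series
median, giving two roughly equal lobes. Default measurement noise is
`noise_sd = 0.02` on the [0,1] fluorescence scale.

Shape contracts (skewness signs, bimodal trough) are asserted at ≥ 2000
variants per series and L=96; at much shorter L the discreteness of the
properties degrades them.

### Randomness

Everything flows from one master seed through `numpy` `SeedSequence` spawn
keys indexed by (stage, series, repeat, …), so a single series — or a single
Monte Carlo repeat — is reproducible in isolation. Libraries are
byte-identical across runs for a fixed configuration.

### What the generator does not emulate

Growth-rate covariates and experimental replicate structure; D-Tailor-style
property-grid randomization (variants are i.i.d. mutants, not
property-balanced); linkage between series and phenotype scale beyond the
preset shapes; sequencing noise models. Consequently, passing tests show the
*pipeline* is correct and the *directional* claims (diversity → coverage)
hold under a plausible ground truth — they do not certify accuracy numbers
on any real screen.

## Biophysical properties

%AT, CAI (geometric-mean relative adaptiveness; the default codon table is
an E. coli-like relative-adaptiveness table computed from standard
codon-usage frequencies, shipped as JSON package data), bottleneck
position/strength (sliding window, default 8 codons, minimum geometric-mean
weight, first window on ties), MHI (Kyte–Doolittle mean over the in-frame
translation). The three "MFE" scores are **not** thermodynamic minimum free
energies: they are Nussinov maximum-base-pairing scores (pairs AU/GC/GU,
hairpin loops ≥ 3, −1 per pair) over three half-overlapping windows
([0, L/2), [L/4, 3L/4), [L/2, L); for L=96: [0,48), [24,72), [48,96)). The
stand-in keeps the computation dependency-free and exactly verifiable
against exhaustive pair-set enumeration; it preserves the qualitative
"structure density" signal but not folding energetics. The 96-nt region is
treated as in-frame codons 1–32.

## Partitioning and evaluation

Per series: a stratified 10% test set is held out first and stays fixed;
from the remainder a validation slice (default 400/series, merged across
series for hyperparameter selection) and a training pool are drawn.
Stratification uses quantile bins on fluorescence (default 10) with
largest-remainder proportional allocation, ties to the lower bin index.
Training sets are stratified-sampled from the pool per Monte Carlo repeat
(default 5 repeats); accuracy is the mean R² over repeats on the fixed test
set. A `resample_test` switch exists for sensitivity checks because the two
natural protocols (fixed vs resampled test sets) differ; fixed-test is the
default. R² = 1 − Σ(y−f)²/Σ(y−ȳ)² is computed from stored measured and
predicted vectors and may be negative; it is undefined (raises) for a
constant test set.

## Models

Ridge, RBF-kernel SVR and random forest delegate to scikit-learn. The MLP
(default three hidden layers of 64, ReLU) and CNN (default three conv
stages 64/5, 128/5, 64/3 with pool 2, dense 128/64/32/1, dropout 0.2 on
binary one-hot input) run on a small in-package numpy engine: MSE loss,
Adam at step size 1e-3 with no schedule, batch 64, at most 100 epochs,
early stopping after 15 epochs without improvement on a 10% target-
stratified validation split of the training sample, best weights restored.
Two engine-specific choices matter in small-data regimes: the output layer
is initialized near zero and its bias set to the training-target mean (the
initial model is the mean baseline), which removes many epochs of drift;
and hidden layers use He-scaled Gaussian init. The default three-stage
architecture assumes L=96; at shorter lengths the pooling stack does not
fit and callers supply a length-matched `CnnArchitecture`.

Hyperparameter selection implements both protocols: per-encoding grid
search (10-fold CV MSE on 90% of the merged validation set, consensus =
most frequent winner across the six encodings, ties broken by MSE on the
held-out 10%), and a categorical Tree-of-Parzen-Estimators search for CNN
architectures (independent iterations of `n_trials` trials; good/bad split
at the 25% quantile with Laplace-smoothed per-dimension densities,
candidates ranked by the density ratio; the per-iteration winner with the
best held-out MSE is returned). Default budgets (50 trials × 5 iterations)
are scalable downwards for desk-scale runs.

## Diversity experiments

The constant-size/increasing-diversity protocol holds the training total
fixed (default 5800) while drawing evenly (floor + remainder to the first
groups, so e.g. 5800 over 54 series gives 22×108 + 32×107) from 2, 4, …
series of a seeded random order; a configurable number of series (default
2) is excluded from training throughout. Every model is evaluated on every
series' fixed test set. Training-set diversity is 1/Σcᵢ over the `top_m`
(default 100) most frequent overlapping 5-mers — doubling a training set
halves the score; flatter k-mer usage raises it. The grouped variant
aggregates many small variant clusters (default 199 clusters, 3929 records,
as in promoter-variant screens) into 12 groups and runs a 5-step schedule
at total 400 with ~30 held-out sequences per group.

## Attribution analysis

Attributions are computed against a blank (all-zeros one-hot) reference.
For the in-package networks the implementation propagates
difference-from-reference multipliers (the rescale rule: ReLU multipliers
are Δout/Δin, linear layers use their weights, max-pool routes through the
input's argmax); for dense ReLU networks the per-unit contributions sum
exactly to f(x) − f(reference), and the channel-summed per-position scores
have length L. The reveal-cancel refinement is intentionally not
implemented. Linear (ridge) models use the exact closed form w·x. Tree and
kernel models raise a capability error — they expose no gradient surface.
Pairwise cosine distances (1 − cos, in [0, 2]) between attribution vectors
are hierarchically ordered (average linkage) for display, and cluster
structure is summarized by k-means score curves: for each k (default
2..15), k-means with random init is restarted 20 times from seeded states
and the within-cluster sums of squares averaged (the per-k best is also
reported; it is the quantity with the clean monotone-nesting property).
Whether per-position (length-L) or per-unit (length-4L) vectors feed the
cosine distance was an open choice; per-position is implemented.

## Scaled study conditions in the tests

The full 56 × 4000, L=96 conditions remain the library defaults. The test
suite runs the same protocols at sizes chosen once for a desk machine: the
partition-arithmetic check builds 56 series × 500 variants at L=30; the
diversity-direction check runs the exact constant-total protocol (5800,
random forest, 2 excluded) on 14 series × 3700 at L=96 over the 6-step
schedule 2..12; network comparisons use L=30 with length-matched
architectures. The acceptance script regenerates a 3 × 600 library and
re-derives the R² boundary values on a real held-out test set.

## Known limitations

- The fold score is a pairing-count stand-in, not an energy model; its
  scale (integer pairs) makes the mfe columns coarsely discrete.
- The CNN-vs-MLP accuracy ordering observed on real screens depends on the
  architecture being matched to the sequence length and on the structure of
  real data; under this generator's global-property ground truth the
  default L=96 architecture does not beat an MLP, while length-matched
  convolutional stages do (the invariant tested).
- Backend determinism: scikit-learn models are deterministic given
  `random_state`; the numpy engine is fully deterministic; BLAS-level
  reduction order can introduce ~1e-12 float variation across machines.
- The TPE implementation is categorical-only (no continuous kernels) and is
  a faithful but minimal variant of the published estimator.
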