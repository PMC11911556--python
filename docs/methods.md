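# Methods

## Problem and representation

The package classifies 41-nt RNA windows centered on a candidate
cytosine (1-based position 21) as m5C sites or non-sites. Windows are
validated strictly: length exactly 41, alphabet {A, C, G, U} with no
IUPAC ambiguity codes (ambiguous windows are rejected rather than
imputed — none of the feature definitions has a meaningful value for
them), and a C at the center by default. The center check can be
disabled for exploratory inputs. DNA-alphabet submissions (T) are
transparently converted to U. All coordinates are 1-based.

Nucleotides are encoded A=1, C=2, G=3, U=4 — alphabetical order, the
simplest convention that makes the encoding a per-position bijection.
The encoding is a package constant; the moment features depend on it,
so it is pinned rather than configurable per run.

## Moment descriptors

The encoded window is placed row-major into a 7×7 matrix, the smallest
square that holds 41 values; the trailing 8 cells are zero. A square
shape is required because the Hahn basis uses the same support length
on both axes. Three families of moments, all orders (u, v) with
u+v ≤ 3 (10 per family, 30 total):

- raw: `R_uv = Σ_a Σ_b a^u b^v β_ab` with 1-based indices;
- central: the same sums about the centroid (R10/R00, R01/R00). A
  zero-mass matrix has no centroid; its central moments are defined as
  0 so degenerate inputs still yield total, finite features;
- Hahn: projections onto discrete Hahn polynomials
  `Q_n(x; u, v, N−1) = 3F2(−n, n+u+v+1, −x; u+1, −(N−1); 1)`,
  orthogonal on x = 0..N−1 under the weight
  `w(x) = C(u+x, x)·C(v+N−1−x, N−1−x)`. Each order is multiplied by
  √w and divided by its L2 norm, making the basis exactly orthonormal
  under the plain inner product; for the default u = v = 0 the weight
  is uniform and the family coincides with the discrete Chebyshev
  polynomials. Pochhammer products are evaluated in log space with
  sign tracking so the 64×64 case stays finite.

Numerical notes. The alternating hypergeometric sum loses accuracy at
high orders for large N (cancellation); the descriptor only needs
orders ≤ 3, so the basis is truncated to the orders requested. The
full-order basis is exposed for the transform/inverse-transform round
trip, which reconstructs random 7×7 and 16×16 matrices to better than
1e-6 — the end-to-end correctness check of the Hahn implementation.
Hahn parameters default to u = v = 0 and are configurable.

## Positional k-mer features

For k = 1, 2, 3, k-mers are counted with stride 1 (overlapping) and
ordered lexicographically with A < C < G < U.

PRIM, the position relative incidence matrix, quantifies where each
k-mer occurs relative to the first occurrence of every other k-mer:
entry (i, j) is `Σ (p − f_i)` over occurrences p of k-mer j with
p > f_i, where f_i is the first occurrence of k-mer i; rows of absent
k-mers are zero. This accumulation rule is the established relative-
position construction in this family of site predictors; it is
deterministic, integer-valued, and verified in the tests against an
independent all-pairs enumeration oracle. It lives behind a single
function so alternative rules can be swapped in. RPRIM is the PRIM of
the character-reversed window — plain reversal, no complementation,
since RNA windows are single-stranded.

The mono (4×4) PRIM and RPRIM enter the feature vector raw (16 values
each); the di (16×16) and tri (64×64) matrices are reduced to their 30
moment coefficients each. The frequency vector counts overlapping
occurrences (sums are 41/40/39 for k = 1/2/3); AAPIV accumulates the
1-based occurrence positions per k-mer (mono sums to 861 = Σ1..41);
RAAPIV is the AAPIV of the reversed window.

## Feature assembly and scaling

Pinned composition, 434 features in fixed order: window moments (30) ‖
PRIM mono/di/tri (16+30+30) ‖ RPRIM mono/di/tri (16+30+30) ‖ FV (84) ‖
AAPIV (84) ‖ RAAPIV (84). Feature names are stable and unique;
assembly is a pure function of the sequence, so identical inputs
produce byte-identical feature tables. Valid inputs cannot produce
missing values; a non-finite feature raises instead of being imputed.

Standardization is z-scoring with mean/SD learned from training rows
only and applied unchanged to held-out rows — fitting the scaler on
all rows before splitting would leak test-set statistics into
training. Zero-variance features keep scale 1 (centering only).

## Classifiers and evaluation

Eight tree ensembles: RF, ETC, DT and BC (bagging; BC bags decision
trees, the conventional base learner) and GB, HGB, AB, XGB (boosting).
No hyperparameter search is performed; ensemble sizes are pinned to
100 estimators where the library default differs, all other settings
are library defaults, and every fitted model records its resolved
hyperparameters and seed. Protocols: stratified 80:20 independent
split, and stratified 10-fold cross-validation with per-fold scaler
fitting (the no-leakage contract is asserted by instrumentation in the
tests). Metrics are Acc, Sp, Sn and MCC from the confusion counts
(positive = 1 = m5C), with MCC defined as 0 when a marginal of its
denominator vanishes, plus a threshold-sweep ROC with trapezoid AUC.
Hard calls use a 0.5 probability threshold (configurable constant).

## Synthetic data generator

The generator emulates the structure of the benchmark sets this kind
of predictor is trained on: balanced classes of fixed-length windows
with a centered C, where a two-sample logo of positives vs negatives
shows enrichment at a few positions flanking the center. The negative
class is uniform per position; the positive class mixes a fraction
`effect` of a point mass on G into positions 17–20 and 22–25
(positions and base configurable), giving a per-position G probability
of 0.25 + 0.75·effect there. Positions are sampled independently.

What this does not emulate: real base composition, dinucleotide or
longer-range dependence, and class imbalance. Passing tests therefore
demonstrate that the pipeline recovers per-position compositional
bias, not that it reaches any particular accuracy on real benchmark
data.

A consequence worth stating: with effect 0.4 the only informative
statistic in a generated window is the number of Gs at the eight
enriched positions, which caps the accuracy of *any* classifier at
about 0.81 (the Bayes limit of the generative model); the aggregate
features land the tree ensembles around 0.65 held-out accuracy at
n = 1000/class, and at effect 0 accuracy sits at chance. The test
suite asserts the chance bracket, the monotone improvement with
effect, and perfect training-set separation on separable features.

## Sizes and defaults

- Window length 41, center 21 — fixed by the problem formulation.
- effect default 0.4 (a clearly detectable but non-trivial signal),
  n = 1000 per class for the behavioral checks; smaller sets (50–150
  per class) exercise the protocols elsewhere in the suite.
- 10-fold CV, 80:20 split, 100 estimators, threshold 0.5, Hahn
  u = v = 0 — all stated above.
- All randomness flows from explicit integer seeds; a fixed seed
  reproduces datasets, splits, models and reports exactly.

## Known limitations

- The PRIM accumulation rule and the 7×7 embedding are pinned
  conventions among several defensible choices; both are isolated
  behind single functions.
- The feature composition (434) uses each described descriptor block
  exactly once; alternative compositions can be assembled from the
  public per-block functions.
- Hahn basis accuracy degrades for full-order transforms beyond
  N ≈ 16; the pipeline never needs them.
- The generator's per-position independence understates the
  sequence structure of real RNA; see above.
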