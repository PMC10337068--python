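# Methods

## Model

Given `n` samples with `p` features (typically `n ≪ p`), a positive
semi-definite kernel `k` defines the Gram matrix `K_ij = k(x_i, x_j)`.
Feature-space centering is performed on `K` directly:
`K̃ = K − (1/n)K11ᵀ − (1/n)11ᵀK + (1/n²)(1ᵀK1)11ᵀ`, equivalently
`HKH` with `H = I − (1/n)11ᵀ`. Kernel PCA is the symmetric
eigendecomposition `K̃ e_k = λ'_k e_k`; we store the eigenvalues of `K̃`
(`λ'`) and expose the covariance-scale eigenvalues `λ = λ'/n` on
demand. The dual coefficients are `a_k = e_k / √λ'_k`, which makes each
principal axis `v_k = Σ_i a_ik φ̃(x_i)` unit-norm in feature space and
satisfies `a_kᵀ K̃ a_l = δ_kl`. This normalization is load-bearing: the
gradient importance scores scale linearly with the axis norm, so fixing
`‖v_k‖ = 1` is what makes their absolute magnitudes well-defined.

A new point `x` with kernel vector `Z_i = k(x, x_i)` projects as
`ρ = (Zᵀ − (1/n)1ᵀK) H A`. For training points this reduces to rows of
`K̃A`. Note that a hypothetical point with identical kernel value to
every training sample does *not* project to the origin: the constant
part of `Zᵀ` is annihilated by `H`, but the `−(1/n)1ᵀK` term leaves the
fixed residual `−(1/n)1ᵀK H A`. The implementation follows the formula
exactly and the test suite pins this residual down.

## Gradient importance

The projected gradient field of feature `j` at the training points is
`Wʲ = Gʲ H A` with `Gʲ_ai = ∂k(x_a, x_i)/∂x_aʲ`. For the RBF kernel
`k = exp(−σ‖x−y‖²)` this is `Gʲ = −2σ K ⊙ (xʲ1ᵀ − 1xʲᵀ)`, computed for
all features from the cached `K` with no kernel re-evaluation; features
are processed in column blocks (default 256) to bound the `n × n ×
block` intermediate, with results identical to the one-shot path. For
the linear kernel the derivative `x_iʲ` is independent of the
evaluation point, so all rows of `Wʲ` coincide and the per-sample norm
spread is exactly zero.

The score is `rʲ = (1/n) Σ_a ‖Wʲ_a‖`; the reported spread is the
sample standard deviation (n−1 denominator) of the n norms — the
natural dispersion of the quantity being averaged. Ranking sorts `rʲ`
descending with ties broken by original column order (stable argsort),
so results are deterministic. The number of retained components `q` is
a required, user-chosen parameter: scores answer "importance *for these
q axes*", and no automatic variance cutoff is applied.

## Parameters

- `sigma` (RBF width, multiplies the squared distance): the single
  tunable that matters. Default selection maximizes the cumulative
  explained-variance fraction of the first `q` components over a grid
  of 13 log-spaced values `1e−8 … 1e−2` (ties to the smaller σ); the
  grid suits z-scored data where squared distances are of order `2p`.
  The full (σ, variance) table is logged and recorded in run manifests.
- `q` (components): set by the analyst per dataset, commonly 2–5.
- Preprocessing: features are z-scored by default before the kernel
  (`scale=False` keeps raw variances; per-feature means are always
  removed, which is invisible to the translation-invariant RBF kernel
  and absorbed by feature-space centering for the linear kernel).
  Features with zero variance — detected with a tolerance of
  `1e−12·max(1, |mean|)` to absorb round-off in the column mean — are
  set identically to 0 and warned about; they receive score exactly 0.
- `eig_tol` (relative eigenvalue cutoff, default `1e−12`): directions
  below `eig_tol·λ'_max` are treated as rank deficiency and dropped,
  reducing `q` with a warning. Rank deficiency is the norm when
  `n` exceeds the effective data rank.
- Eigenvector signs are fixed by making each dual-coefficient column's
  largest-magnitude entry positive; plots and scores inherit this
  convention, so reruns are bit-identical.

## Evaluation harness

Clustering accuracy matches predicted clusters to true classes by
optimal one-to-one assignment (Hungarian algorithm on the contingency
table) — the standard in the unsupervised feature-selection literature,
and provably ≥ any greedy matching. NMI uses the geometric-mean
normalization `I/√(H_t H_p)` by default (arithmetic available via
`average=`). `subset_kmeans_eval` runs k-means with `k` equal to the
true group count, fresh initialization per run, seeded per
(subset-size, run). Silhouette curves refit KPCA on each top-d subset,
re-selecting σ per subset by default (a fixed-σ mode exists for speed),
cluster the embedding by k-means and score the embedding's mean
silhouette; seeded random rankings provide the comparison curves.
Train/test variance curves rank features on the training split only and
compare cumulative explained variance of KPCA fit separately on train
and test restricted to the same top-d columns, reusing the
training-selected σ so the two spectra are comparable.

## Synthetic data

`make_clustered_data` draws equal-covariance spherical Gaussian
clusters (balanced by default; a weights parameter allows imbalance).
Informative feature `f` is assigned round-robin to cluster
`f mod n_clusters` and shifts that cluster's mean by `separation`, so
each informative feature separates one cluster from the rest by exactly
`separation` in expectation; all remaining features are i.i.d. noise.
One seed fans out through `SeedSequence` substreams so the label stream
and the noise stream do not perturb each other. Defaults (n=60, p=200,
10 informative, 3 clusters, separation 4, noise sd 1) give a clearly
clustered but high-dimensional regime in which the top-10 recovery and
dominance checks below are run. The generator emulates the *shape* of
expression data, not its marginal distributions: no probe effects,
heteroscedastic noise, batch structure or correlated gene modules.
Passing tests therefore demonstrate correctness of the computations and
sane behavior under clean cluster structure, not performance on real
microarray noise.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: gradient/finite-
difference agreement on 20×8 (relative tolerance 1e−5 against central
differences with step 1e−6), clustering evaluation on 60×200, and the
train/test variance comparison on 257 samples split 192/65. The split
sizes for the variance comparison are deliberate: the explained-
variance *fraction* of a fixed number of components is biased upward
for smaller sample counts (the total variance spreads over fewer
eigenvalues), so train/test agreement within a tight absolute band is a
property of this sample-size regime; at much smaller n the baseline
offset between a 45-sample and a 15-sample spectrum exceeds the band
regardless of the ranking's quality.

Gram matrices are materialized densely (`n` is the small dimension) and
symmetric by construction — RBF via condensed pairwise distances
evaluated once per unordered pair, linear by mirroring the upper
triangle — never by averaging `K` with its transpose after the fact.

## Known limitations

- Only RBF and linear kernels ship; the scoring contract (a kernel with
  a first partial derivative) admits more, but score magnitudes are not
  comparable across kernel families and no cross-family normalization
  is attempted.
- The ranking is conditional on `q` and σ; different choices yield
  different (both defensible) rankings.
- No statistical significance is attached to scores, and no selection
  threshold is automated.
- Model archives are versioned but not portable across incompatible
  format revisions.
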