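# kpcaig

Gradient-based variable importance for kernel PCA, aimed at
high-dimensional omics matrices (few samples, many features) where the
sample manifold is nonlinear and ordinary PCA loadings are unavailable
because the kernel map is implicit.

## The problem and the method

Kernel PCA embeds samples by eigendecomposing the double-centered Gram
matrix `K̃ = HKH`, `H = I − (1/n)11ᵀ`, with `K_ij = k(x_i, x_j)`. The
embedding is expressed only through pairwise similarities, so the
original variables disappear — the classic pre-image problem. Instead of
inverting the map, `kpcaig` measures how strongly each variable *moves*
the embedding.

For dual coefficients `A` (n × q, scaled so each principal axis has unit
norm in feature space), the projected gradient field of variable `j`
evaluated at every training point is

```
Wʲ = Gʲ H A,    Gʲ_ai = ∂k(x_a, x_i)/∂x_aʲ
```

For the RBF kernel `k(x, y) = exp(−σ‖x − y‖²)` the derivative has the
closed form `−2σ k(x_a, x_i)(x_aʲ − x_iʲ)`, so the whole ranking is a
handful of dense linear-algebra operations. The importance score of
variable `j` is the mean of the per-sample gradient norms,

```
rʲ = (1/n) Σ_a ‖Wʲ_a‖ ,
```

reported together with the standard deviation of those n norms.
Variables are ranked by descending `rʲ`: a large score means the
variable steers where samples land on the leading kernel principal
axes; a variable with zero variance scores exactly 0. The same field
`Wʲ`, restricted to two components, draws an arrow at each sample
showing the direction of increasing expression — the arrow-field plot.

Also included: out-of-sample projection, an RBF-width (σ) selection
heuristic maximizing cumulative explained variance, a synthetic
clustered-data generator with known informative features, and an
evaluation harness (k-means accuracy with optimal cluster matching,
NMI, silhouette curves against random rankings, train/test
explained-variance curves).

## Worked example

`examples/rank_features.py` plants 3 sample groups separated along 10 of
200 genes, selects σ, fits 3-component kernel PCA and ranks all genes:

```
data: 60 samples x 200 genes; informative: ['gene0', ..., 'gene9']
selected RBF width sigma = 1e-08 (maximizes 3-component explained variance)
explained variance of the 3 retained components: [0.0413 0.039  0.037 ]

top 12 genes by gradient importance (score = mean per-sample gradient norm):
 rank feature_id    score           sd
    1      gene7 0.040999 1.017024e-08
    2      gene0 0.040778 9.269503e-09
    ...
   10      gene4 0.033728 7.291904e-09
   11    gene123 0.030945 1.008949e-08

10 of the 10 planted informative genes appear in the top 10.
```

Scores here are printed ×1000 (`to_frame(scale=1000)`), a common display
convention for these magnitudes. All ten planted genes outrank the 190
pure-noise genes — the ranking recovers exactly the variables carrying
the group structure, with no labels used. `examples/arrow_field_plot.py`
and `examples/evaluate_ranking.py` demonstrate the arrow-field display
and the unsupervised evaluation harness.

The same workflow is available from a shell:

```sh
kpcaig simulate --n 60 --p 200 --informative 10 --clusters 3 --seed 1 \
    --output sim.tsv --labels-output labels.tsv
kpcaig fit --input sim.tsv -q 3 --model-output model.npz
kpcaig rank --model model.npz --scale 1000 --output ranking.tsv
kpcaig plot variable --model model.npz --feature gene0 --output arrows.svg
kpcaig evaluate kmeans --input sim.tsv --labels labels.tsv \
    --ranking ranking.tsv --d-grid 10,50,100 --output eval.tsv
```

Real expression matrices load with `kpcaig.io.read_matrix`; GEO-style
probes-as-rows files take `--orientation features-by-samples`.

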