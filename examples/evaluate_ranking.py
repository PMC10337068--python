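"""Judge a feature ranking without using the labels it was built without.

Compares the gradient-importance ranking against random feature orders
by (a) k-means clustering accuracy / NMI on nested top-d subsets and
(b) silhouette of the kernel PCA embedding refit on each subset. A good
unsupervised ranking concentrates the label structure in its first few
features, so its curves should sit above the random ones at small d.
"""

import kpcaig as kg

ds = kg.make_clustered_data(n=60, p=200, n_informative=10, n_clusters=3,
                            separation=4.0, noise_sd=1.0, seed=1)
sigma = kg.select_sigma(ds.X, q=3)
model = kg.fit(ds.X, kg.KernelSpec("rbf", sigma), q=3)
ranking = kg.rank_features(model)

report = kg.subset_kmeans_eval(ds.X, ds.labels, ranking,
                               d_grid=[10, 50, 100, 200], k=3, runs=20, seed=5)
print("k-means on top-d features (20 runs each):")
print(report.round(3).to_string(index=False))

curve = kg.silhouette_curve(ds.X, ranking, [5, 10, 20, 50], n_clusters=3,
                            q=3, random_rankings=3, seed=5)
piv = curve.pivot(index="d", columns="ranking", values="silhouette")
print("\nsilhouette of the KPCA embedding per subset size (vs random orders):")
print(piv.round(3).to_string())
print("\nACC/NMI of 1.0 at d=10 means the top-10 genes alone recover the")
print("true groups perfectly; the kpca-ig silhouette column staying above")
print("every random column shows the ranking concentrates that structure.")
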