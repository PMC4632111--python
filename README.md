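# camcr — cluster-aided MCR-ALS for NMR metabolomics

Multivariate curve resolution–alternating least squares (MCR-ALS) factorizes
a non-negative samples × variables matrix of binned ¹H-NMR spectra as

    D = C Sᵗ + E,    C ≥ 0,  S ≥ 0,

pairing each component's concentration profile (across samples) with a
spectral profile (a pure-compound-like spectrum).  Its practical weakness is
that the number of components k must be chosen in advance, and the standard
estimators (Kaiser, scree, parallel analysis, CNG, multiple regression,
cross-validation, cumulative contribution) routinely disagree.

`camcr` implements the *cluster-aided* strategy instead: run MCR-ALS for
every k = 1 … kmax, pool all concentration profiles, cluster them with
average linkage on correlation distance, attach multiscale-bootstrap
AU (approximately unbiased) p-values to every dendrogram node, and keep the
significant (AU > 0.95), maximal clusters that (a) are larger than any
cluster arising in shuffled data and (b) have minimum internal pairwise
correlation above 0.6 after recursive refinement.  A component is "reliable"
when it re-emerges reproducibly regardless of k — a criterion independent of
variance share, so reproducible low-information biology survives.  Each
reliable cluster is summarized by the element-wise mean/SD/CV of its
members' C×Sᵗ matrices, typical concentration and spectral profiles, and a
sum-of-squared-deviations information score.

The package is aimed at NMR-based metabolomics (urine, fecal extracts,
standard mixtures) but applies to any non-negative bilinear data.  It
includes a synthetic standard-mixture generator with known ground truth, the
eight conventional component-number estimators, a conventional single-fit
MCR-ALS baseline, and a CLI.

## Worked example

```python
from camcr import ClusterAidedMCR, standard_mixture_preset

ds = standard_mixture_preset(n_samples=20, seed=1)     # 20 x 250 matrix
model = ClusterAidedMCR(ds.data, kmax=20, nboot=200, n_shuffle=5)
res = model.fit(seed=1)
print(res.summary())
print(res.detection_score(ds.true_concentrations).to_string(index=False))
```

`summary()` starts:

```
Cluster-aided MCR-ALS results
==============================================
samples x bins        : 20 x 250
sweep kmax            : 20
pooled components     : 210 (raw 210)
AU threshold          : 0.95
size threshold        : >7 (replicate maxima [4, 7, 6, 7, 5])
min internal corr     : 0.6
reliable clusters     : 9

cluster_id  size      ssd         top_bins
 cluster_1     8 2.989005  1.94, 1.9, 1.98
 cluster_2    11 1.954247  1.94, 1.9, 1.98
 cluster_3    19 1.551975  3.26, 2.9, 2.86
 ...
```

All 210 concentration profiles from the twenty factorizations were pooled;
no shuffled replicate produced a chance cluster larger than 7, so a reliable
cluster needs more than 7 members; nine clusters qualify, ranked by their
sum-of-squared-deviations (SSD) information score, each labelled with the
three ppm bins dominating its typical spectrum (clusters 1 and 2 sit on the
acetate-like 1.92-ppm singlet, cluster 4 on the aromatic pair at
7.32/7.42 ppm).  The detection table then lists, for each known compound,
its best-matching cluster and the Pearson correlation between the true
concentration series and that cluster's typical concentration profile
(detected means r > 0.8):

```
compound best_cluster  best_correlation  detected
 amino_1    cluster_4          0.989052      True
  scfa_1    cluster_1          0.990774      True
 sugar_b    cluster_3          0.902563      True
 amine_2    cluster_3          0.901487      True
 ...
```

The deliberately concentration-confounded pair (`sugar_b`, `amine_2`)
resolves into one shared cluster matching both — expected for compounds with
indistinguishable concentration patterns.  With only 20 samples the
reliability filter has little margin (chance clusters under the shuffled
null are nearly as large as true ones), so some compounds fail the 0.8
criterion at this scale; see `docs/methods.md` for the scale analysis.

The command-line interface mirrors the library:

```sh
camcr simulate --n-samples 20 --seed 1 --out sim/
camcr run --input sim/data.csv --out results/ --kmax 20 --nboot 200 --seed 1
camcr ncomp sim/data.csv          # the eight conventional estimators
camcr baseline --input sim/data.csv --out base/   # conventional MCR-ALS
```

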