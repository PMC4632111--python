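# Methods

## The model

`camcr` analyses a non-negative samples × variables matrix `D` (binned
¹H-NMR spectra) under the bilinear mixture model

    D = C Sᵗ + E,    C ≥ 0 (samples × k),  S ≥ 0 (bins × k),

where each of the k components pairs a *concentration profile* (its loading
across samples) with a *spectral profile* (a pure-compound-like spectrum).
The factorization is fitted by MCR-ALS: alternating exact non-negative least
squares, solving S given C per bin and C given S per sample.  The
concentration matrix is initialized with PCA scores of the column-centered
data (covariance PCA, no scaling; column signs fixed so each score column's
largest-magnitude entry is positive) and the spectral matrix with ones, the
S half-step running first.  Because every half-step solves its subproblem
exactly, the residual sum of squares is non-increasing — a property the test
suite asserts directly.

Choosing k is the classical weak point: the eight conventional estimators in
`camcr.ncomp` routinely disagree on noisy data.  The cluster-aided strategy
sidesteps the choice: the factorization is repeated for every
k = 1 … kmax (kmax defaults to the number of samples, the largest k the
PCA-score initialization supports), all concentration profiles are pooled
(kmax(kmax+1)/2 of them before all-zero components are removed), and
components that *re-emerge reproducibly across k* are identified by
clustering the pooled profiles.  A component's reliability is its
reproducibility, not its variance share, so low-information but reproducible
biology is retained.

## Cluster selection

Pooled profiles are clustered with average linkage (UPGMA) on the
correlation distance 1 − r.  Cluster uncertainty is assessed with the
multiscale bootstrap: the sample axis is resampled with replacement at
relative sizes r ∈ {0.5, 0.6, …, 1.4}, each resample is reclustered, and
BP_r(node) is the fraction of bootstrap trees containing the node's exact
leaf set.  With z_r = Φ⁻¹(1 − BP_r), the weighted fit z_r ≈ v√r + c/√r
(weights from the delta-method binomial variance of z_r) yields the
approximately unbiased p-value AU = 1 − Φ(v − c).  BP values are capped
into [1/(B+1), B/(B+1)] before the transform, so censored scales (raw BP
exactly 0 or 1) enter the fit at the resolution limit of the bootstrap;
this anchors the curve and keeps nodes with near-zero support everywhere
from extrapolating to spuriously high AU through the curvature term.  A
node found in every bootstrap tree at every scale (or in none) gives the
fit no scale information and its AU degenerates directly to 1 (or 0).
Nodes with AU > 0.95 are selected; nested selections keep only the maximal
node (dendrogram leaf sets are laminar, so the survivors are disjoint), and
the root — trivially present in every bootstrap tree — is never a candidate.

Two further filters make a selected cluster "reliable":

1. **Size threshold.**  The CList is shuffled (each record's values
   independently permuted across sample positions, destroying inter-profile
   correlation while preserving each profile's value multiset), reclustered
   and re-selected; over `n_shuffle` replicates (default 10) the maximum
   selected-cluster size is recorded.  Reliability requires size strictly
   greater than that maximum.  This absorbs a real property of AU values:
   clusters with near-zero BP at every scale can still extrapolate to
   AU > 0.95 through the curvature term, so chance-significant clusters of
   nontrivial size do occur under the null.
2. **Internal correlation.**  If a cluster's minimum pairwise profile
   correlation is ≤ 0.6 it is re-clustered on its members alone (same
   average-linkage/correlation-distance engine) and divided at the top
   split of the resulting dendrogram; each part is re-checked recursively.
   Parts at or below the size threshold are discarded.  The division is
   deterministic — no bootstrap enters the refinement loop — and every
   division strictly shrinks the cluster, guaranteeing termination.  (An
   alternative refinement that re-runs the full AU selection on the members
   and keeps only significant sub-clusters was evaluated and rejected: on
   small member sets the bootstrap noise of the sub-selection frequently
   discards coherent compound families wholesale.)

Each reliable cluster is summarized through the stack of its members'
rank-one matrices C×Sᵗ: element-wise mean, sample SD (n−1) and CV
(defined 0 where the mean is 0); the row and column of the mean matrix
through its global maximum are the typical spectral and concentration
profiles; the sum of squared deviations (SSD) of the typical concentration
profile ranks clusters by information content.  In evaluation mode, a known
concentration table scores detection: a compound is detected when its best
Pearson correlation against the typical concentration profiles exceeds 0.8.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `kmax` | n_samples | largest component number in the sweep |
| `alpha` | 0.95 | AU significance threshold |
| `nboot` | 1000 | bootstrap replicates per scale |
| `scales` | 0.5 … 1.4 | relative bootstrap sample sizes (10 scales) |
| `n_shuffle` | 10 | shuffled replicates for the size threshold |
| `corr_min` | 0.6 | minimum internal pairwise correlation |
| `tol` / `max_iter` | 1e-8 / 200 | ALS stopping rule (relative SSE change) |

The desk-scale benchmark (`camcr.evaluation.run_standard_benchmark`, also
what `scripts/acceptance.py` runs) uses 20 samples, kmax = 20, nboot = 200
and 5 shuffle replicates so a full run completes in a few minutes on one
core; the defaults above are the full-scale settings.

## Numerical choices

- ALS subproblems use an exact multi-right-hand-side active-set NNLS
  (columns sharing a passive set share one normal-equation solve); columns
  that cycle (degenerate Gram matrices) fall back to Lawson–Hanson.
- Between half-steps, S columns are rescaled to unit maximum.  This is not a
  model constraint: each half-step re-solves the other factor completely, so
  the iterates' products are unchanged in exact arithmetic.  It prevents the
  scale indeterminacy from drifting paired columns to extreme magnitudes and
  destroying conditioning.
- A component is dropped as "all zero" when its concentration or spectral
  column's maximum is ≤ 1e-12 × max(D).
- Correlation distances are clipped to [0, 2]; inside bootstrap replicates a
  resampled profile can become constant, and its distances are set to the
  maximum 2 for that replicate.
- UPGMA ties are broken by scipy's deterministic cluster-index order; with
  continuous data ties have probability zero, and determinism is what the
  reproducibility contract needs.
- The bin grid is ascending with half-open bins [lo + iw, lo + (i+1)w); bin
  labels are centers; exclusion windows drop a bin when its center lies in
  the closed interval; bin values are sums, so binning conserves total
  intensity and row normalization to total intensity 1 commutes with the
  retained-bin restriction.

## The synthetic-mixture generator

`camcr.synth` emulates the validation design of a known standard mixture
measured across samples.  The library has two tiers, rendered as sums of
Lorentzian lines (HWHM 0.02 ppm — sub-bin at 0.04-ppm binning, as for real
small molecules) on a 250-bin 0–10 ppm grid:

- **Foreground** — eight compounds loosely patterned on urine/feces
  metabolites (phenylalanine-, leucine-, acetate-, butyrate-, glucose-,
  trehalose-, TMA- and taurine-like) with roughly equal total line
  intensity (the two singlets, acetate- and TMA-like, are tall, as their
  3H/9H methyl resonances are in real spectra).  These carry the
  recoverable signal.
- **Background** — sixteen minor metabolites (single lines at otherwise
  unused shifts, amplitude 0.35) whose concentrations co-vary in four
  pathway-style groups (within-group design correlation ≈ 0.85).  They
  emulate the minor-metabolite backdrop of real biofluid spectra and keep
  the data's effective rank at the sample count, so no sweep run is
  over-factored.  Over-factored runs of a low-rank matrix produce
  degenerate mixture components — a near-flat optimum manifold rather than
  re-emerging profiles — and a preset without this backdrop cannot
  reproduce the reproducibility signal the method relies on.

Design choices that matter:

- **Sparsity.**  Each foreground compound is absent from ~25 % of samples,
  otherwise uniform(0.1, 1).  A strictly positive dense design makes the
  non-negative factorization non-identifiable (rotated mixtures fit as
  well or better — observed directly during development), which no amount
  of clustering can undo; absence patterns are both realistic for
  varied-concentration standard mixtures and the standard identifiability
  condition.
- **Confounding.**  One pair (trehalose-like `sugar_b`, taurine-like
  `amine_2`) shares a concentration design up to a small jitter (r ≥ 0.9):
  concentration-based clustering cannot separate them, so they are
  expected to resolve into shared clusters, and they are excluded from the
  distinct-pattern recovery score — as are the background compounds, whose
  group-mates correlate above any distinctness cutoff ≤ 0.7.
- **Spectral overlap.**  The two sugars share the congested 3.76-ppm line
  (not either sugar's tallest line, so typical profiles are read off
  resolved bins); every compound keeps at least one resolved signature bin.
- **Noise.**  Additive i.i.d. Gaussian, truncated at zero, SD = 1 % of the
  mean clean signal by default.

What the generator does *not* emulate: free-induction decays, phasing or
baseline artifacts, chemical-shift drift across samples (peak positions are
fixed; real data would show bin-boundary migration, which the clustering
can in fact classify separately), multiplet fine structure, and broad
macromolecular baselines.  Passing tests therefore show that the pipeline
recovers reproducible components under a faithful bilinear model with
realistic binned line shapes — not that it is robust to uncorrected
instrumental artifacts.

## Known limitations

- With few samples (n ≈ 20) the bootstrap trees are noisy and shuffled-data
  chance clusters grow to sizes comparable with true compound clusters (a
  compound's component re-emerges only over a window of the sweep, not at
  every k), so the reliability filter loses its margin: some
  distinct-pattern compounds fail the r > 0.8 detection criterion at this
  scale, seed-dependently.  The effect is a property of the operating
  scale, not of noise level: doubling the sample count (same kmax, nboot
  and shuffle count) collapses the null threshold and recovers essentially
  every distinct compound.  The method rewards larger n and nboot.
- Over-factored runs (k well above the effective compound count) yield mixed
  profiles; the sweep tolerates this (mixed components simply fail to form
  large clusters) but they contribute nothing, so a sweep on data with very
  low effective rank wastes most of its runs.
- The refinement's discard rule means fragments of a heterogeneous selected
  cluster that end at or below the size threshold are lost rather than
  re-pooled with other discards.
- SSD ranks clusters by the typical concentration profile only; the
  element-wise CV matrices are the place to look when a cluster's support is
  doubted.
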