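# Methods

## The model

`specnet` represents each subject's spectrum (NMR, Raman, or any binned
intensity vector) as a weighted network whose nodes are spectral bins.
Given labeled training cohorts — an `m_c x n` control matrix `C` and an
`m_d x n` disease matrix `D` — two ordinary least-squares lines are fitted
for every ordered bin pair `(i, j)`:

    c[.,j] = alpha  * c[.,i] + beta  + eps        (control group)
    d[.,j] = alpha' * d[.,i] + beta' + eps'       (disease group)

The standard deviation of each residual vector defines a Gaussian error
model around its line.  For a new subject with values `(x_i, x_j)`, the
two lines predict `x_j` from `x_i`; the link weight is the normalized
probability that the observation comes from the disease model,

    w(i -> j) = N(x_j; yhat_d, sigma_d) / (N(x_j; yhat_c, sigma_c) + N(x_j; yhat_d, sigma_d))

a number in [0, 1].  All `n(n-1)` ordered weights are computed, the two
directions are combined (arithmetic mean by default; max and directed
modes available), and the symmetric weighted network is thresholded —
links with weight strictly above 0.65 by default — into a binary graph.
Four structural descriptors summarize it:

* **link density**: edges / (n(n-1)/2);
* **clustering coefficient** (transitivity): 3 N_triangles / N_triples;
* **global efficiency**: mean over node pairs of 1/d(i,j), with
  disconnected pairs contributing 0;
* **eigenvector centrality**: principal eigenvector of the adjacency
  matrix, normalized to unit maximum.

Subjects are classified from these descriptors (by default a linear SVM on
density and efficiency) with leave-one-out validation, and a single
subject measured repeatedly can be tracked through time by the link
density of its per-visit networks.

## Statistical and numerical choices

* **Residual spread.** The unbiased OLS estimate with denominator
  `m - 2` is used.  A perfect fit would collapse the Gaussian to a delta,
  so spreads are floored at `1e-9` times the response bin's intensity
  range per class; floored pairs behave continuously.
* **Degenerate pairs.** If either bin has zero variance in either class
  the pair cannot be fitted; it is flagged and its weight pinned at the
  neutral 0.5 rather than dropped, keeping the node set constant across
  subjects.
* **Weight computation.** The density ratio is evaluated in log space
  with a shifted-softmax normalizer: `w = e^(Ld - s) / (e^(Lc - s) +
  e^(Ld - s))` with `s = max(Lc, Ld)`.  Distant points never overflow,
  equal log-densities give exactly 0.5, and swapping the class labels maps
  `w` to `1 - w` to machine precision.
* **Vectorization.** All `n(n-1)` fits are computed at once from the
  class Gram matrices (`slope[i,j] = S[i,j]/S[i,i]`, residual sums from
  the same products), so a full refit on a 200-bin, 50-subject cohort
  takes milliseconds; a complete jackknifed leave-one-out run takes
  seconds.
* **Graph metrics.** Shortest paths use breadth-first search
  (`scipy.sparse.csgraph`); eigenvector centrality uses power iteration on
  `A + I` (the identity shift makes the leading eigenvalue strictly
  dominant so bipartite components converge), to relative tolerance 1e-10
  with a 1e5-iteration cap, computed on the largest connected component
  with zeros elsewhere; a graph with no edges returns the zero vector.
  The clustering coefficient is the global transitivity form named by the
  triangle/triple counts, not the per-node average, and density uses the
  undirected denominator n(n-1)/2 so a complete graph has density 1.
* **Binarization** uses strict `>` ("weight higher than 0.65"), so
  threshold 1.0 yields an empty graph.

## Leave-one-out protocol

The leakage-free mode is a jackknife: subject `k`'s network features are
computed under pair models fitted on all labeled subjects *except* `k`
(asserted at run time), and the classifier fold for `k` trains on the
other subjects' equally-out-of-sample features.  This matters: if
training-subject features were computed under models that include them,
they would be systematically "in-sample" (controls biased toward weight 0,
patients toward 1) while the held-out subject's features are not, and the
classifier would face a covariate shift between its training rows and the
point it predicts — measured to cost tens of accuracy points.  An
explicit `refit_models=False` mode fits the pair models once on everybody
(the in-sample protocol some studies use); it is provided for fidelity
comparisons only.

Classifiers are scikit-learn pipelines with training-fold
standardization: linear SVM with unit regularization (default), RBF SVM,
Gaussian naive Bayes, decision tree and a 10-unit MLP as baselines.
Feature-subset selection is an exhaustive search over subsets up to a
size cap, scored by leave-one-out accuracy, with ties broken toward
smaller subsets then lexicographic names — exact and cheap because the
feature space is a handful of metrics.

## The synthetic cohort generator

No spectral cohort ships with the package; `specnet.synthetic` generates
cohorts with exactly the statistical structure the dual model assumes, so
the whole pipeline is testable end to end.

Most bins are independent baseline intensity (1.0) plus Gaussian noise
(sd 0.1), identically in both classes.  Three *hub* bins, each with 30
*partner* bins (defaults), carry the disease:

* **Hub displacement.** Hubs reflect a marker metabolite: baseline in
  controls, displaced by `hub_shift = 1.5` in patients (within-class sd
  0.1, the same intrinsic variability as every other bin).  In a patient's
  network each hub therefore links to essentially every other bin — the
  star-like topology with hub bins topping the centrality ranking.
* **Coupling flip.** Partners follow `partner = slope*hub + intercept +
  N(0, 0.1)` with slope −0.5 (intercept 2.0) in controls and +0.5
  (intercept 0.25) in patients — a slope offset of 1.0.  The intercepts
  are chosen so the partner bins' *marginal* distribution is identical in
  the two classes: this part of the disease is purely relational.
* **Pathway factor.** In patients the partner residuals of one hub share
  a per-subject latent factor (loading 0.995), modelling a common pathway
  response; controls fluctuate independently.  The factor changes only the
  correlation structure — the residual spread stays 0.1 — and fills each
  patient's hub blocks with links.

`disease_strength` interpolates every disease-specific quantity between 0
(the class generators are identical — the null used for calibration
tests) and 1; trajectories for longitudinal tracking draw one subject per
timepoint at a given strength.  All randomness flows from one seed
through per-subject `SeedSequence` substreams, so cohorts are reproducible
and cohorts of different sizes share their leading subjects.

For cohorts emulating *raw* (unbinned) spectra, `feature_width` spreads
each hub/partner feature over that many consecutive columns, the way a
physical peak spans adjacent measurements; aggregating with a matching
bin size recovers the feature values.  The leukemia-style design (1000
raw measurements, 102 controls vs 31 patients, bin size 10) uses width 10.

### Why these defaults

The defaults were fixed after measuring an intrinsic property of the
method: with 25 subjects per class, about 7% of *null* ordered-pair
weights exceed 0.65 purely from OLS sampling error, so every
reconstructed network carries a floor of spurious links (the "promoted
links" that form a random structure in control networks).  A disease
signature confined to the 90 hub-partner links (0.45% of pairs) is
invisible against this floor; perfect classification requires the
signature to span an order of magnitude more pairs, which the hub
displacement (3 hubs x ~197 links each) and the pathway factor (~1300
block links) provide.  Couplings and hub variability are on the scale of
the background noise, which a spectroscopist would read as: the marker
peaks are displaced by 15 times the within-group variability, and the
coupled peaks respond to them with opposite sign in patients.

### What the generator does not emulate

Physically realistic lineshapes, baseline drift, chemical-shift jitter,
correlated (pink or multiplicative) noise, batch effects, and any overlap
of spectral features.  Passing tests therefore demonstrate the pipeline's
statistical correctness under its own model assumptions, not performance
on real spectra; in particular the perfect scores reflect a cohort whose
class difference is, by construction, exactly the kind of pattern the
dual-model weight detects.

## Experiments

* **Noise robustness**: an ensemble of cohort copies (default 100,
  reducible) polluted with additive zero-mean Gaussian noise per sigma;
  the network pipeline is compared against the baselines trained on raw
  bin intensities (the baselines' inputs are a documented choice — the
  comparison contrasts the network *representation* against classifiers
  on the data itself).  Sigma is in absolute intensity units, with a
  fractional (per-bin sd) mode available.  A structural caveat, measured
  and documented: the network's exclusive correlation signal dies once
  noise exceeds the 0.1 residual scale, and marginal signals are used
  more efficiently by Gaussian naive Bayes than by threshold-counting, so
  under moderate noise naive Bayes can edge out the network method by a
  couple of points on these synthetic cohorts.
* **Bin-size sweep**: re-bin, refit, re-score per size; a size that
  leaves fewer than two bins is reported as NaN with a flag.
* **Longitudinal tracking**: link density per timepoint under a fixed
  reference model, in input order.

All experiment results carry their seed and tidy per-replicate records;
reruns with the same configuration are asserted byte-equal in tests.

## Problem sizes used in the shipped analyses

The headline reproductions run the full study designs (200 bins with
25 + 25 subjects; 1000 raw measurements binned to 100 with 102 + 31
subjects).  Unit tests use scaled-down cohorts (40-60 bins, 8-12 subjects
per class) that keep the full hub/partner structure; the noise sweep in
the acceptance suite uses 10 replicates over sigmas {0, 0.05, 0.1} —
noise up to the generator's background/biological variability scale — and
the trajectory check averages 10 replicate series.

## Known limitations

* The link-weight floor at small cohort sizes (above) means absolute
  density values are not comparable across training-set sizes; only
  within-study contrasts are meaningful.
* Eigenvector centrality is reported for the largest component only;
  for very sparse networks (high thresholds) most nodes receive 0 and
  centrality summaries mostly describe the dominant cluster.
* The dual model is strictly linear by design; nonlinear bin
  relationships are projected onto the best line and may inflate residual
  spreads.
* Weighted-graph metric generalizations are provided only as a clearly
  flagged extension (`weighted_density`); the reference procedure
  binarizes first.
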