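# Methods

## Model

`spanmrf` assigns each spot (or cell) of a spatially resolved
transcriptomics sample to one of *K* known types using only the raw counts
of a curated marker-gene panel plus the spot positions. Two components are
combined.

**Marker-informed NB mixture.** Conditional on type `z_i = k`, counts are
negative binomial with mean

    log mu_igk = log s_i + delta_gk * rho_gk + beta_g0 + sum_p beta_gp x_ip

and inverse-dispersion `phi_igk` (variance `mu + mu^2/phi`). `rho` is the
binary gene-by-type marker indicator supplied by the user; `delta_gk > 0`
is the marker's log fold change, so a marker multiplies its type's mean by
`exp(delta_gk)`. `delta` carries a log-normal prior (mean 0, variance 1 on
the log scale) and the mixing weights `pi` a symmetric Dirichlet(0.01)
prior; both enter estimation as MAP penalty terms on the EM Q function.
`phi` is not free per gene: it is a sum of `B = 10` radial basis functions
of the mean, with centers fixed on an equal-spaced grid from 0 to the
maximum observed count and learnable amplitudes/widths. This borrows
strength across genes for the mean-dispersion trend, the way
single-cell NB models commonly regularize dispersion.

Size factors are `s_i = (total counts of spot i over the panel) / median
spot total`: the ratio-to-median convention is scale-free, robust to
outlying spots, and standard practice for count normalization.

**HMRF label prior.** Labels follow a Potts-like Markov random field on
the spot neighbor graph: `p(z) ∝ exp(sum_k eta_k n_k − sum_{k<l} zeta_kl
n_kl)` with `zeta_kl > 0` penalizing discordant neighbor pairs; the exact
per-spot conditional is `p(z_i = k | neighbors) ∝ exp(eta_k − sum_{l≠k}
zeta_kl u_i(l))` where `u_i(l)` counts neighbors of `i` with label `l`
(asserted against brute-force joint enumeration in the tests). Because the
partition function is intractable, `(eta, zeta)` are estimated by
maximizing the pseudolikelihood — the product of these conditionals.

**Neighbor graphs.** Classic ST arrays use rook (4-neighbor) adjacency;
Visium arrays use the hexagonal 6-neighbor rule in array coordinates,
offsets (0, ±2) and (±1, ±1); imaging platforms use a k-nearest-neighbor
graph (default `k = 15`) symmetrized by union, with distance ties broken
toward the lower spot index for determinism.

## Training

1. **Pretrain** the mixture alone by MAP EM: exact E-step in log space;
   partial M-step of 30 Adam ascent steps (rate 0.01) on Q per iteration;
   stop when the marginal log posterior changes by < 1e-4 (relative) or
   after 50 iterations. Initial labels are the argmax responsibilities.
2. **Alternate** until fewer than 0.1% of labels change in a sweep, or 20
   iterations: (i) 30 Adam steps on the hard-label conditional likelihood
   L2 (plus the delta prior), warm-started; (ii) 50 Adam steps of
   pseudolikelihood ascent for `(eta, zeta)`; (iii) one sequential ICM
   sweep in ascending spot order with in-sweep label propagation, each
   spot set to the argmax of NB log-likelihood + field logit (ties to the
   smallest type index). The mixing weights `pi` act only during
   pretraining; final posteriors are softmax scores of likelihood + field.

All positivity constraints are handled by reparameterization
(`delta = exp`, `a, b = softplus`, `pi = softmax`), so the ascent is
unconstrained. Every Adam call returns the best iterate seen (the
objective is evaluated at each step anyway), which makes the EM and ICM
loops monotone even when individual steps overshoot.

### Numerical choices

- `phi` is floored at 1e-6 so the pmf stays defined if the RBF sum
  underflows; the floor's flat region contributes zero gradient.
- A perfectly smooth labeling drives the pseudolikelihood optimum of
  `zeta` to infinity; a ridge penalty (1e-3 on the raw parameters) plus a
  hard cap `zeta ≤ 20` keeps ICM numerically stable while preserving
  effectively-infinite smoothing.
- `eta_1` is pinned at 0: the conditionals are invariant to shifting all
  `eta`, so only differences are identifiable.
- `delta` is initialized at the prior median (`delta = 1` for every
  gene/type): a symmetric start in which components differ only through
  which genes they boost. Random starts drawn from the prior were observed
  to collapse the mixture onto a single component when markers are weak
  (one component's small initial boosts make it the best "average"
  explanation for every spot, and EM cannot escape). With the symmetric
  start the whole fit is deterministic; the seed argument is kept for
  interface stability.
- `zeta` is initialized at 0.1, near spatially-neutral, so smoothing
  strength is learned from the label field rather than imposed; the
  warm-started pseudolikelihood updates let it grow over the ICM
  iterations as far as the data support.
- An ICM iteration that empties a cluster logs a warning and keeps the
  cluster (its parameters remain anchored by the marker prior); clusters
  are never re-seeded mid-run.
- The hot M-step closures run through a fused numba kernel that skips the
  gamma-function terms for zero counts and pools the identical
  contributions of all unmarked types per gene; a pure-numpy
  implementation of the same quantities is the fallback and the two are
  asserted equivalent (and both checked against central finite
  differences) in the test suite. `digamma` inside the kernel uses the
  recurrence + asymptotic series, accurate to ~1e-13.

## Synthetic data generator

The generator reproduces the group-structured core of the Splatter
single-cell simulator, laid out spatially: gene base means
`lambda_g ~ Gamma(shape 0.6, rate 0.3)`; per group, a `de_prob = 0.1`
fraction of genes receives a DE factor `exp(N(0, sigma^2))`; library sizes
`L_i ~ logNormal(ln 2000, 0.35)`; expected counts are library-normalized
group means; observed counts NB with inverse-dispersion 2. Markers are the
genes whose DE factor exceeds 1.5 (strict), mirroring how marker panels
are derived from simulated fold changes. Ground-truth labels form
contiguous horizontal bands on a square grid, a cortical-layer-like
geometry. `sigma` is the signal-strength dial: with ~1000 genes,
`sigma = 0.5` yields ~20 markers per type and an easy, well-separated
problem, while `sigma = 0.3` yields ~9 weak markers per type and a genuinely
hard one.

Scenario perturbations: *spatial noise* swaps the expression rows and
labels of a fraction of cross-group spot pairs (coordinates fixed), which
roughens the spatial arrangement without changing class sizes or totals;
*fake markers* replace part of the panel with non-DE genes assigned to
random types; *misassigned markers* move part of the panel to wrong types;
*batch effects* multiply per-batch per-gene factors `exp(N(0,
batch_sigma^2))` into the means before counts are redrawn, with batch IDs
exported as one-hot covariates.

What the generator does **not** emulate: dropout/zero inflation, the
mean-BCV trend, doublets or within-spot mixtures of types, irregular
tissue geometry, and real-platform artifacts. Passing tests on these
simulations therefore demonstrate correctness of the estimator under its
own generative assumptions and robustness to the listed perturbations —
not performance on real tissue, where within-spot mixing at region borders
and imperfect marker curation are the dominant error sources.

## Evaluation

Accuracy, macro F1 (one-vs-rest mean over classes present in the truth;
empty precision+recall scores 0) and the covariance (Gorodkin) form of the
multiclass Matthews correlation coefficient, with MCC = 0 on a zero
denominator. The model outputs named types, so no label matching is needed
to score it; for unsupervised baselines/ablations whose cluster identities
are arbitrary, `match_labels` applies Hungarian assignment on the
confusion matrix, and surplus predicted clusters score as errors.

## Problem sizes used in the shipped checks

Replicated end-to-end checks run on a 30×30 banded grid (900 spots, K = 4,
1000 genes, ten fixed seeds): a scale at which every regime of interest
(strong signal `sigma = 0.5`, weak signal with 10% spatial noise
`sigma = 0.3`, marker corruption 10–20%) is exercised while a full fit takes
seconds. The corruption sweep fixes `sigma = 0.5` so its clean arm
coincides with the recovery runs. `scripts/acceptance.py` re-runs the same
designs with five replicates per scenario and reports the resulting
summary numbers.

## Known limitations

- *K* and the marker panel are taken as given; unknown or surplus types
  are not discovered (a phantom type with spurious markers simply attracts
  few or no spots).
- Spots are assigned whole: no deconvolution of within-spot type mixtures.
- The field is first-order (immediate neighbors only) with a single
  pairwise penalty matrix; longer-range or anisotropic dependence is out
  of scope.
- Pseudolikelihood is a surrogate, not the true MRF likelihood; its known
  degeneracy on perfectly smooth labelings is handled by ridge + cap
  rather than resolved.
- ICM finds a local optimum that depends on the (fixed, ascending) sweep
  order.
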