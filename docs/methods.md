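# Methods

## Model and quantities

All information quantities are differential (continuous-variable) and
reported in nats. For series X (recording before attenuation), X′ (after)
and Y (skin-blood-flow interferer):

- conditional entropy H(X|Y) = H(X, Y) − H(Y);
- mutual information I(X;Y) = H(X) − H(X|Y);
- transfer entropy at lag L with target history m,

  T(Y→X; L) = I( y[t+1−L] ; x[t+1] | x[t], …, x[t−m+1] ),

  i.e. the conditional mutual information between the lagged interferer
  sample and the target's next state given the target's own past. Histories
  default to m = ℓ = 1; longer embeddings are supported but off by default
  because the evaluation design states none.

The five criteria (c1–c5 in the README) are evaluated per recording as raw
inequalities; statistical significance across a cohort is a separate layer
(`stats`), so measurement and inference stay decoupled.

## Estimators

Two families, selected by `EstimatorConfig.method`:

- `gaussian`: closed forms on the (ddof=1) sample covariance.
  H = ½ ln((2πe)^d det Σ); conditional MI as a log-ratio of conditional
  variances. Exact for Gaussian data given its covariance; used as the
  oracle in tests and as a fast scan estimator.
- `ksg` (default): Chebyshev-metric k-NN estimators — Kozachenko–Leonenko
  entropy, Kraskov algorithm 1 for MI, Frenzel–Pompe for conditional MI —
  with k = 4 neighbours. Ties are broken by seeded Gaussian jitter of
  1e-8 × the sample SD per variable (`jitter_sd` configurable). Slightly
  negative MI/TE estimates are reported as-is with a flag, never clamped,
  so before/after comparisons stay unbiased. A dimension guard warns above
  3 dimensions, where k-NN entropy estimates degrade.

Numerical details: neighbour counts use strictly-less-than radii
(`nextafter` shrink); the KSG ball counts exclude the query point; the
Gaussian family raises a typed error on singular covariance (e.g. X′ ≡ X)
and points the user at the jittered k-NN route.

### Standardisation inside the criteria engine

Differential entropies are scale-dependent, and attenuation shrinks signal
amplitude severalfold, so in raw units every conditional-entropy criterion
would be dominated by the amplitude change rather than by dependence
structure. The criteria engine therefore z-scores each series over the
task window before estimation (`standardize=True`, exposed). This matches
the default variance-normalisation convention of the JIDT estimators
commonly used in this field, makes c2/c3/c5 compare information content,
and turns the c5 margin H(X′) − H(X|X′) into I(X;X′) up to estimator bias.
The estimator primitives themselves (`entropy`, `mutual_information`, …)
stay raw-scale.

## Preprocessing

Baseline normalisation subtracts each channel's resting-prefix mean.
The band-pass is a first-order Butterworth, 0.01–0.6 Hz, applied
forward–backward (zero-phase) so transfer-entropy lag semantics are not
shifted; a causal single-pass mode is exposed since the original
description does not state the phase convention. Edge transients are
suppressed by reflect-padding with 3× the dominant time constant of the
low band edge (fs/(2π·0.01 Hz) ≈ 159 samples at 10 Hz, capped at the
series length). Linear detrending removes the full-series least-squares
line; no segmenting. Pipeline order relative to attenuation follows each
algorithm's lineage: preprocess-then-PCA, ICA-then-preprocess. The
recording's `meta["steps"]` records the applied order for audit.

## Attenuation algorithms

**PCA spatial filter.** Channel-space eigenvectors come from the
covariance (not correlation) matrix of the column-centred resting prefix —
baseline normalisation has already equalised offsets; a unit-variance
normalisation mode is exposed for sensitivity analysis. Task rows are
projected onto the complement of the first r ∈ {1, 2, 3} eigenvectors;
the resting prefix passes through unmodified. Eigenvector signs are fixed
(largest-magnitude element positive) for deterministic output. The
per-eigenvector variance fractions are reported for all components; the
component sets "PC12"/"PC123" mean the prefix sets {1,2}/{1,2,3}.

**ICA uniform-component removal.** Symmetric fixed-point ICA (log-cosh
contrast, whitening included, max 1,000 iterations, tol 1e-6,
seed-controlled initialisation) decomposes the full raw series into as
many components as channels. The coefficient of spatial uniformity of
component j with mixing weights a_j is CSU_j = |mean(a_j)| / sd(a_j)
(sd = 0 ⇒ +∞, perfectly uniform); the maximiser's contribution
a_j·s_j(t) is subtracted from every channel. The literal |coefficient of
variation| reading — which would select the *least* uniform component —
is selectable (`csu_mode="abs_cv"`) but not the default, since the
algorithm's stated intent is to remove the most spatially uniform
component. The selected component is attributed to the channel with the
largest absolute mixing weight (the attribution rule is not fixed by the
source literature; this is the natural choice). Non-convergence within
the iteration cap is recorded in diagnostics rather than raised:
exactly-Gaussian sources — the synthetic study's regime — never satisfy
the fixed-point tolerance, yet the returned decomposition is precisely
what this algorithm family produces on such data.

## The synthetic study

Each round draws four i.i.d. Gaussian channels (mean 5.76, SD 18.61 device
units; 600 resting + 2,500 task samples at 10 Hz) and one shared Gaussian
interferer added to every channel over the full length, resting prefix
included. The interferer moments default to the realised values
(mean 15.56, SD 43.25); a `threefold` mode derives them per round as 3×
the pooled channel moments — the two prescriptions in the source
description are mutually inconsistent (3 × 18.61 ≈ 55.8 ≠ 43.25), and the
realised moments are the default because they also reproduce the
leading-eigenvalue share of the spiked channel covariance,
(σ_s² + 4σ_n²) / (4(σ_s² + σ_n²)) ≈ 0.883. The stated 600 + 2,500 split is
honoured over the stated total of 3,000 (also mutually inconsistent); all
three numbers are configurable. Simulated data run through the same
preprocessing chain as real data before estimation.

Two features of this generator matter for interpreting results:

- *Transfer entropy exists only through the filter.* An i.i.d. interferer
  carries no lagged information, so T(Y→X) = 0 at every lag ≥ 1 in the raw
  data. The zero-phase band-pass makes the shared noise autocorrelated and
  non-Markovian, which creates genuine positive TE before attenuation
  (peaking at small lags, ≈ 0.12 nats at the grand-average argmax of 3)
  and near-zero TE after. Complete before/after separation across rounds
  is therefore a property of the preprocessed study, and the grand-average
  lag is a property of the filter, not of any physiological delay.
- *The interferer dominates the signal* (SD ratio 2.3), so
  corr(X, Y) ≈ 0.92 while corr(X, C) ≈ 0.40 for the clean channels C.
  Criterion c4 — "X′ explains X better than Y does" — is consequently
  false in population for every attenuation setting, including the
  ground-truth oracle X′ = C. Tests exercise c4 on constructions with the
  interferer weaker than the signal, where it discriminates as intended.
  Passing tests on this generator show estimator and pipeline correctness
  under a global additive Gaussian interferer; they say nothing about
  structured physiology (Mayer waves, cardiac harmonics, task-locked
  scalp responses), which the generator deliberately omits.

All randomness fans out deterministically from one study seed via
`SeedSequence` (sub-streams per simulation round, ICA initialisation, and
estimator jitter), so studies are bit-reproducible.

## Statistics layer

Wilcoxon rank-sum uses the tie-corrected normal approximation with the 0.5
continuity correction (matching the printed precision of the reference
statistics, e.g. 50-vs-50 complete separation gives z = 8.6138); the
signed-rank test uses the uncorrected approximation (zero differences
dropped). Both report effect size r = |z|/√N — N being the total
observation count, 2× pairs for the paired design. Kruskal–Wallis reports
the tie-corrected H with χ² p-values and r = √(H/N). Bonferroni
multiplies p by the number of comparisons in the family (the explicit
`bonferroni_factor`, or the contrast count of the post-hoc battery),
capped at 1. Exact small-sample Wilcoxon p-values are out of scope.

The study driver runs all four settings on the same rounds with shared
preprocessing (a paired design), applies Kruskal–Wallis across
{before, PC1, PC12, PC123, IC1} per criterion, rank-sum post-hoc
contrasts, and ranks settings by mean c5 margin with ties reported rather
than silently broken.

## Problem sizes and scan estimator

The default study is 50 rounds × 4 channels × 3,100 samples. The
grand-average lag scan uses the Gaussian plug-in estimator by default
(only the argmax of the mean TE curve is consumed downstream, and the
plug-in scan agrees with the k-NN scan on the argmax at a fraction of the
cost); criterion quantities use the configured estimator. The test suite
exercises the full 50-round study for the PCA/ICA/TE-separation checks and
scaled-down replicas (3–10 rounds, single analysis channel, short lag
grids) elsewhere; scaled sizes are stated in the tests themselves.

## Known limitations

- ICA on exactly Gaussian sources is unidentifiable; the recovered
  rotation is sample- and seed-dependent, which is why the uniform
  component tracks the true interferer at |r| ≈ 0.75–0.85 rather than
  ≈ 1, why channel attribution is close to uniform across rounds, and why an
  occasional round misses the interferer direction entirely.
- k-NN estimators are biased at strong dependence and small n; absolute
  nat values are estimator-dependent and only orderings/inequalities
  should be compared across studies.
- Differential-entropy identities from the discrete world (e.g.
  H(X|Y) = 0 when X = Y) do not hold; degenerate identical inputs raise in
  the Gaussian family and proceed on jittered copies with a warning in the
  k-NN family.
- No surrogate-based significance testing of TE; no motion-artifact or
  cardiac/respiratory regressors; no SNIRF/HDF5 container support.
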