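# Methods

## Spectra as probability distributions

The package's unit of data is a per-channel power spectral density on a
shared, equally spaced frequency grid (bin centers in Hz). After rescaling
to unit total mass, a spectrum is treated as a probability distribution
with point masses at the bin centers — point masses, not band integrals,
which matches the sampling view below. Preprocessing mirrors what
multi-site quantitative-EEG collections require: truncation of all sites
to the lowest common maximum cutoff frequency (with re-rescaling
afterwards, since truncated spectra must remain unit-mass distributions),
exclusion of subjects without a recorded age or outside a stated age
range (bounds inclusive), and exclusion of reference electrodes such as
Cz. Grid alignment between sites is checked to 1e-6 Hz, loose enough to
absorb decimal printing of 0.39-Hz grids. Missing age is an explicit
missing value, never a sentinel number.

## MMD between spectra

With an inner kernel k on frequencies, the squared maximum mean
discrepancy between distributions P and Q is estimated by the V-statistic

    MMD²(P,Q) = (1/n²) ΣΣ k(x_i, x_j) + (1/m²) ΣΣ k(z_i, z_j)
              − (2/nm) ΣΣ k(x_i, z_j),

with self-pair diagonal terms included; the unbiased U-statistic is
available behind a flag (default off) for users who want the de-biased
estimator. Two computation modes:

- **weighted** (default): bin weights enter directly as probabilities;
  this is exact, deterministic, and equals the sampled estimator whenever
  every n·w_i is an integer (a tested identity).
- **samples**: each spectrum is expanded into n deterministic samples
  (default n = 1000) by largest-remainder (Hamilton) apportionment of
  n·w_i, ties broken toward lower frequencies, so counts always sum to
  exactly n. This mode reproduces the sampling description of the method
  and converges to the weighted mode as n grows.

Both modes are computed from count/weight-weighted Gram sums over bin
centers; n·m sample pairs are never materialized. Inner kernel families:
RBF exp(−γ(x−z)²) (default, γ = 1), linear, polynomial. Frequencies enter
the inner kernel in raw Hz; no rescaling of the support axis is applied.
With γ = 1 and ~0.4-Hz bins the RBF inner kernel is fairly local: it
reacts to mass moving across roughly ±1–2 Hz, which suits alpha-peak
displacements. The inner bandwidth is exposed but not tuned by default.

Distances are D_ij = sqrt(max(0, MMD²)); tiny negative values from
floating-point cancellation are clamped before the square root. Distance
matrices are cached per (channel, kernel spec, mode, content hash of the
spectra), so repeated cross-validation folds reuse one computation.

## The predictors

All three methods share one scoring interface and one dual solver.

- **KMER**: outer kernel K_ij = exp(−γ_outer D_ij²) on MMD distances. The
  Gaussian kernel of a Hilbertian metric is positive semidefinite, which
  the tests verify empirically (minimum eigenvalue ≥ −1e-8 on random
  spectra).
- **KRR**: the same outer kernel on Euclidean distances between bin-power
  feature vectors. Configuring the KMER path with Euclidean feature
  distances reproduces KRR to machine precision — a tested equivalence
  that pins down the shared plumbing.
- **RR**: primal linear ridge on bin powers with an unpenalised intercept,
  solved by normal equations on centred features.

The dual solve is (K + αI)β = y − ȳ via Cholesky factorization (one shot
of 1e-10 jitter on marginal matrices, least-squares as a last resort;
α = 0 on a rank-deficient system raises an error advising α > 0).
Targets are mean-centred and the mean restored at prediction; without
this, dual ridge biases predictions toward zero. An optional per-bin
normalisation (each bin scaled to unit variance across training subjects)
affects only the feature view used by RR/KRR; the distribution view used
by KMER is untouched.

## Evaluation protocol

Acquisition sites are never split across folds: leave-site-out is the
default, grouped k-fold (whole sites packed greedily into k folds,
largest site first into the currently smallest fold) and within-site
k-fold are available. Hyperparameters are selected by nested CV: inner
folds are built from the outer-training sites under the same grouping
rule (leave-site-out inner folds by default; if fewer than two training
sites exist the selection falls back to subject-level k-fold with a
warning). The selection criterion is mean inner MAE — scale-honest in
years — with ties broken toward smaller α, then smaller γ. The winning
pair is refit on the full outer-training set and applied once to the
outer test set, so every subject receives exactly one out-of-site
prediction. Reported R² and MAE are pooled over all out-of-sample
predictions (per-fold breakdowns are also emitted).

Grids default to α ∈ 10⁻³…10³ (7 points/decades) and γ ∈ 10⁻³…10²
(6 points). Because unit-mass spectra yield squared distances far below 1,
absolute γ values in that range would linearise the outer kernel; by
default the γ grid therefore acts as multipliers of 1/median(d²) over the
outer-training distances (the median heuristic). Absolute bandwidths are
available via `gamma_scale="none"`.

Randomness policy: a single run-level seed feeds `numpy.random.default_rng`
generators; per-fold subsidiary seeds are derived by a fixed offset
scheme. All evaluation outputs are reproducible bit-for-bit given the
seed.

### Delta, log-space and bias correction

The brain-age delta is ŷ − y per subject, summarised per site/sex.
Log-space mode trains on log(age) and back-transforms before scoring
(scores reported in both domains); it amplifies differences among the
young, where spectral change is fastest. The post-hoc bias correction
fits residual = a + b·y on training pairs and corrects test predictions
as ŷ′ = ŷ + a + b·y_test. Two points deserve emphasis. First, the
correction uses the test subject's chronological age — it is a correction
of the delta (making residuals orthogonal to age), not a blind predictor.
Second, inside nested CV the line is fitted on *out-of-sample* training
predictions recomputed from the inner folds at the selected
hyperparameters; in-sample residuals at small α are near zero and would
make the fit degenerate.

### Permutation tests

Method and subgroup comparisons use a paired sign-flip permutation test
across channels: the statistic is the mean per-channel score difference,
the null flips each channel's difference independently, and the two-sided
p-value is (1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm), bounded below by
1/(n_perm + 1). With 18 channels the sign-flip space caps attainable
p-values near 2⁻¹⁸. Calibration is verified by simulation: under a
symmetric null the rejection rate at level 0.05 stays within [0.03, 0.07]
over 500 replicates.

## The synthetic generator

`synthdata` defines its own ground truth explicitly, using the
field-standard spectral decomposition: an aperiodic power-law background
b·f^(−χ) plus a Gaussian alpha-like peak, per subject and channel:

    s(f) = b f^(−χ) + A(age, sex) · exp(−(f − μ(age))² / 2σ²),

multiplied by a per-site gain tilt (gain · f^tilt), optionally a random
per-subject tilt, and per-bin multiplicative log-normal noise, then
rescaled to unit mass. Defaults (chosen once as a realistic desk-scale
cohort): 4 sites × 100 subjects with truncated-normal age distributions
centred at 28/45/58/70 years (prior shift is present by default, as in
real multi-site collections); grid 1.17–19.11 Hz at 0.39 Hz (47 bins);
χ = 1; peak σ = 1.4 Hz; peak center 10.8 Hz at the youngest age,
declining by 2.8 Hz over the age range (the alpha slowdown); ages
reported to 0.1-year resolution; 19-channel 10/20 montage with a coarse
parieto-occipital-dominant alpha gain map.

The nonlinearity flag controls two features jointly:

- the ageing coordinate u is tanh(r·a)/tanh(r) of normalised age
  (r = 2.2), so spectral change is fast in youth and nearly flat in old
  age — the regime in which all methods predict older ages poorly, and
- the peak amplitude follows the nonmonotone arc characteristic of alpha
  power (rising to a maximum around u ≈ 0.3, then declining,
  base 0.5 / bump 1.0 of A₀ = 1.2), so age is recoverable only from the
  joint configuration of peak height and position. No single linear
  readout of the bins decodes it, which is precisely where kernel methods
  gain over the linear ridge.

With the flag off, u is normalised age, the amplitude declines linearly
(slope −0.4 over the range) and the model is linear in age up to the mild
curvature introduced by unit-mass rescaling; in that regime the linear
ridge matches kernel ridge (tested to within 0.05 R²).

The sex multiplier (default 1.1 for males) scales the magnitude of the
ageing displacement — peak-center shift and amplitude deviation — so male
spectra change more per year and carry a stronger ageing signal,
reproducing directionally the higher male prediction accuracy; it also
creates a realistic male/female ambiguity (the same spectrum corresponds
to slightly different ages per sex) that acts as irreducible noise.

The per-bin noise level (σ = 0.45, log-normal) was calibrated once so
that default-scenario leave-site-out KMER R² lands near the top of the
0.6–0.8 band, comparable in difficulty to a within-site analysis of real
multi-site EEG; all other defaults were fixed independently of any test
outcome. The problem sizes used throughout the examples and acceptance
checks (400 subjects, one channel, 4 sites) keep a full three-method
nested-CV comparison under a few seconds while leaving the statistical
conclusions stable across seeds.

What the generator does **not** emulate: raw time series, cross-spectra,
channel covariance (channels differ only by a gain on the alpha peak),
artifacts, or site differences beyond a smooth gain tilt. Passing tests
on these cohorts validate the machinery — estimators, solvers, protocol —
and the claimed orderings under the stated generative assumptions; they
do not certify accuracy levels on real recordings.

## Numerical choices and degenerate inputs

- Grid invariants: strictly ascending, equally spaced (1e-9), positive.
- All-zero spectra cannot be rescaled (error); zero-weight bins receive
  zero deterministic samples.
- Distance matrices are symmetrised, clamped at 0, zero-diagonal by
  construction.
- Constant feature bins pass through per-bin normalisation unscaled, with
  a warning; a single subject is an error.
- Zero target variance makes R² undefined (NaN, with a warning); MAE is
  still reported.
- Subgroups with fewer than three subjects are skipped in subgroup
  scoring, with a warning.
- Bias correction requires ≥ 3 training subjects and non-constant
  training age.

## Design choices where the design was open

- The printed form of the distance-to-similarity kernel is implemented
  with the decaying sign, exp(−γD²): a similarity must decay with
  distance, and only this form yields K_ii = 1 and a PSD kernel.
- The dual weights are the standard regularised solution
  β = (K + αI)⁻¹(y − ȳ); the solve-free form would not reproduce training
  targets even at α → 0.
- Whether spectra should be re-normalised after truncation was open;
  re-normalising keeps the distribution interpretation and is what the
  unit-mass invariant requires.
- Fold construction ("sites never split") is ambiguous between
  leave-site-out and grouped k-fold; both are implemented, with
  leave-site-out as the default for cohorts with a manageable number of
  sites, since it matches the statement that no subject of a test site
  was part of training.
- The permutation scheme is a paired sign-flip across channels (channels
  are the natural paired units for method and sex comparisons).
- The interchange format is plain CSV + JSON rather than any
  instrument-native container; an adapter for native cross-spectral
  containers is deliberately out of scope.

## Known limitations

- Kernel predictors cannot extrapolate beyond the training age range;
  under strong prior shift their pooled cross-site R² can fall below a
  linear extrapolator's on the shifted extremes (the prior-shift example
  makes this visible).
- Single-channel only: no stacking or multichannel fusion.
- The bias correction requires chronological age at test time and must
  not be presented as improving blind prediction.
- MMD two-sample hypothesis testing and scalp-topography rendering are
  out of scope (channel-level tables and bar charts only).
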