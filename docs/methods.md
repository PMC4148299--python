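# Methods

`boldretest` asks a single question: how do first-level fMRI modeling choices
— the flexibility of the hemodynamic response model and the handling of
physiological noise — change (i) how well the fitted GLM satisfies its error
assumptions and (ii) the test-retest reliability of the contrast estimates it
produces? Because no suitable public two-session dataset accompanies the
question, every stage runs against a synthetic BOLD phantom whose ground
truth (activation amplitudes, reliability, noise structure) is known exactly.

## The phantom

**Geometry.** A 20×20×12 voxel grid (3 mm isotropic) holds an ellipsoidal
"brain" with a white-matter core, a central CSF block, a posterior "visual"
active region (~120 voxels), two small amygdala-analog blobs (~16 voxels),
and a randomly placed set of high-variance gray-matter voxels (2% of the
brain). The grid is deliberately desk-scale: 48 subjects × 2 sessions × 4
pipelines fit in minutes, and nothing in the pipeline depends on the grid
being MNI-sized. The geometry is parameterized; smaller grids are used where
only a handful of ROI voxels are needed.

**Paradigm.** One run is 378 volumes at TR = 2 s. Twelve emotion blocks
(four conditions × three blocks, each twelve contiguous 1 s stimuli) and six
shape-control blocks (six stimuli) are pseudorandomized so that no two
consecutive blocks share a condition, with uniform inter-block gaps filling
the run (the source design specifies block counts but not gap structure).
An optional identity-morph control condition can be added as a
modeled-but-uncontrasted condition.

**Signal model.** Per voxel,

    BOLD(t) = 100 + a_sj · x_c(t; HRF_sj)            (active regions)
            + physio loading · amplitude · c_sj(t)    (everywhere in brain)
            + AR(1) + white noise,

where `x_c` are the task regressors convolved with the subject-session HRF.
Amplitudes follow a two-way random-effects model,
`a_sj = amplitude_mean · (1 + b_s + w_sj)`, with `b ~ N(0, σ²_b)` and
`w ~ N(0, σ²_w)`; the true consistency ICC of every active region is the
analytic ratio σ²_b/(σ²_b + σ²_w). The multiplicative form means
`amplitude_mean = 0` switches off all task signal regardless of the variance
settings. The shapes response is a fixed fraction (0.2) of `amplitude_mean`
with no subject variance, so the emotions-minus-shapes contrast inherits the
amplitude model exactly. The amygdala scales the signal by 0.5, which (with
measurement noise fixed) attenuates its estimated reliability relative to
the visual region — the phantom's analog of the lower amygdala ICCs
typically observed.

**Defaults and why** (all in % of a baseline of 100):

| parameter | default | rationale |
|---|---|---|
| n_subjects / sessions / volumes / TR | 48 / 2 / 378 / 2 s | the emulated study design |
| amplitude_mean | 0.5 | ≈2.4% peak block response (visual cortex, strong stimuli) |
| σ²_b, σ²_w (relative) | 0.12, 0.12 | subject CV ≈ 0.5, true ICC 0.5 — mid-range reliability |
| sigma2_noise | 1.0 | thermal noise SD = 1% of baseline |
| ar1_rho | 0.3 | typical lag-1 autocorrelation at TR = 2 s |
| physio_amplitude | 2.5 | coherent global physiological signal: 2.5% SD in WM/CSF and high-variance voxels, ×0.4 (loading 0.5·2.5 = 1.25%) elsewhere; at 3 T physiological noise in gray matter is comparable to thermal noise, and a consequential confound is precisely the regime in which physiological-noise correction matters |
| physio spectrum | 0.025–0.035 Hz + 0.20–0.30 Hz bands | a slow (quasi-CO₂/vasomotion) and an aliased quasi-respiratory component; any stationary shared process serves the design's purpose |
| HRF jitter | subject latency SD 1.0 s, session 0.5 s; dispersion log-SD 0.10 / 0.05 | empirical HRF latency variability is of order ±1 s; a *session-varying* component is included because a purely subject-stable HRF offset cancels in test-retest consistency and could never interact with reliability |
| motion | 6 smoothed random-walk series, leak 0 | all pipelines carry motion covariates; actual leakage into voxels is off by default |

All randomness flows from one seed through named `SeedSequence` spawn keys
(paradigm / subject / session), so any single run is reproducible in
isolation and cohorts are bit-reproducible.

**What the phantom does not emulate.** Scanner artifacts (spikes, ghosting,
distortion, dropout), spatially varying HRFs, nonstationary noise, real
anatomy, and preprocessing (realignment, normalization; an optional Gaussian
smoothing exists for realism only). Passing tests therefore demonstrate the
*estimators and comparisons* behave correctly under a controlled generative
model — not that any particular real dataset has these properties.

## Design matrices

The canonical HRF is the double-gamma kernel (peak delay 6 s, undershoot
delay 16 s, dispersions 1, undershoot ratio 1/6) sampled at dt = TR/16 and
scaled so its dense-grid peak equals 1 (normalizing by the dense peak keeps
the kernel's scale independent of sampling resolution; the units cancel in
every contrast). Temporal and dispersion derivatives are finite differences
(δt = 1 s onset shift, δd = 0.01 dispersion perturbation — conventional
values) sharing the canonical normalization; they are *not* orthogonalized
against the canonical column by default, keeping the contrast-on-canonical
convention (a flag enables orthogonalization). Regressors are convolved in
microtime and sampled at the middle of each TR. Drift is an orthonormal
discrete-cosine basis with `floor(2·N·TR/cutoff) + 1` non-constant columns
(cutoff 128 s), included as regressors rather than applied as a filter, so
each voxel is one linear system. The "mixed block/event" model treats every
1 s stimulus as an event convolved with all bases and adds no separate
sustained regressor — the simplest reading that changes the temporal model;
with contiguous stimuli the canonical event train equals the block boxcar,
so the material difference is the derivative columns.

The emotions-minus-shapes contrast puts +1/4 on each canonical emotion
column and −1 on canonical shapes (average-of-emotions minus shapes);
derivative, nuisance, drift and intercept columns get 0.

## GLM and serial correlation

Fitting is two-pass, in the spirit of Cochrane–Orcutt: OLS per voxel, a
single *global* lag-1 autocorrelation pooled over all in-mask voxels, AR(1)
prewhitening of both sides, and one GLS refit. Full restricted-maximum-
likelihood estimation of an AR(1)+white-noise variance model is deliberately
replaced by this transparent estimator; the global-whitening intent is
preserved and every step is unit-testable.

One subtlety matters: the lag-1 autocorrelation of OLS *residuals* is a
biased estimate of the error autocorrelation, because drift and other smooth
regressors absorb low-frequency noise power (at ρ = 0.3, T = 378 and ~24
columns the raw pooled estimate is ≈0.22). The estimator therefore inverts
the analytic map ρ → E[pooled residual lag-1 | design], computed exactly
from the design's projection matrix with O(T²p) trace identities, via a few
secant steps. Degrees of freedom are T − rank(whitened design); no
Satterthwaite correction is applied.

## Residual diagnostics

Shapiro–Wilk (normality, via the standard Royston approximation),
Breusch–Pagan (homoscedasticity: n·R² of the auxiliary regression of squared
residuals on the design, χ² with one df per non-intercept column), and
Durbin–Watson (independence). The DW p-value uses a normal approximation
whose mean and variance are the **exact** null moments of d given the
design, obtained from the spectrum of the projected difference form
(E d = tr B/ν, E d² = (2 tr B² + (tr B)²)/(ν(ν+2)) with B = MAM): at
T = 378 this reproduces the simulated null to three decimals, while the full
Imhof/Pan distribution would add nothing at this sample size. Tests run on
the model's own (whitened) residuals, so successful whitening passes the
independence check and remaining structure indicates misspecification; a
violation is p < α = 0.05, reported as raw proportions with no across-voxel
multiplicity correction (the proportion itself is the outcome). The
calibration of all three tests under the correctly specified phantom
(rejection ≈ α, near-uniform p-values) is asserted by the acceptance suite.

## Reliability

ICC(3,1) — subjects random, sessions fixed, consistency rather than absolute
agreement — is computed voxelwise from the two-session contrast maps as
(BMS − EMS)/(BMS + (k−1)·EMS) with k = 2 throughout. Negative estimates are
retained (medians and rank comparisons need them); the Cicchetti labels map
them to Poor (<0.40; Fair to 0.60, Good to 0.75, Excellent above). Voxels
with an undefined ICC are excluded from medians with a logged count. The
regional summary is the median voxelwise ICC (mvICC); a subject-level
bootstrap SE is provided (and labeled as such — the original SE's method is
not specified). ICC(1,1)/ICC(2,1) variants exist behind a flag for
comparison only.

## Pipeline comparisons

Pipelines are repeated measures within voxels (t, ICC) or within subjects
(violation proportions, standing in for a generalized linear mixed model on
the binary violation indicators — the subject-blocked Friedman respects the
voxels-nested-in-subjects structure without importing a mixed-model fitter).
The Friedman χ² uses average ranks and the standard tie correction; it is
implemented in-package so the k = 2 case works, and cross-checked against
an independent implementation for k ≥ 3. Nemenyi all-pairs post-hoc tests
use the studentized-range form (mean-rank difference over √(k(k+1)/6n),
referred to the studentized range with infinite df); exact numeric parity
with any particular macro's χ²-scaled output is out of scope — decision and
direction parity is the contract.

The t statistics entering the voxel-blocked comparison are the *group-level*
one-sample t values of the session-1 contrast maps. At the first level the
comparison would be confounded: an under-whitened default pipeline (its
pooled ρ diluted by the confound's aliased high-frequency band)
underestimates residual variance and thereby inflates its own t values —
the invalid-inference mechanism the analysis is designed to expose.

## Activation maps and ROIs

Activation masks come from thresholding the session-1 group t-map at the
one-sided t quantile for voxel p = 0.001 and keeping face-connected (6-
neighbor; 18 available) clusters of at least `min_extent` voxels.
Random-field-theory FWE correction is not implemented; the extent threshold
is user-set or calibrated by a seeded sign-flip permutation null. The
cross-pipeline comparison ROI is the voxelwise intersection of the four
activation masks; the amygdala ROI is the fixed anatomical-analog region of
the phantom geometry.

## Standard experiments and problem sizes

`boldretest.experiments` packages the validation experiments so tests and
`scripts/acceptance.py` run identical code. Sizes are the package's own
choices balancing Monte-Carlo precision against desk-scale runtimes:

- **ICC parameter recovery** — true ICC ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, 48
  subjects per cohort, 16 cohorts per level averaged, 12×12×8 grid, thermal
  variance 0.25, confound and jitter off. A recovery experiment probes the
  estimator, so measurement noise is kept small; even so, the *realized*
  amplitude ICC of one 48-subject cohort scatters around the population
  value with SD ≈ 0.11–0.14, which is why levels are averaged over cohorts.
- **Diagnostic calibration** — 10 subjects × 2 sessions × 120 ROI voxels =
  2400 voxel-fits under the correctly specified model.
- **Prewhitening sensitivity** — ρ = 0.3 phantom, 12 runs, fitted with and
  without whitening.
- **Headline four-pipeline study** — 24 subjects under full study conditions
  for violation tables, the overlap ROI and group-t comparisons.
- **Multi-cohort mvICC comparison** — 24 independent 48-subject cohorts on
  an 8×8×6 grid, default vs mCompCor vs combined. The mvICC *difference*
  between pipelines has per-cohort SD ≈ 0.08 (chance correlations between
  subjects' amplitude draws and their confound projections), an order of
  magnitude above what the per-voxel counts suggest, so direction claims are
  made on the cohort average. The same realization noise afflicts any
  single-cohort study.

Expected directions in this phantom: flexhrf < default < combined <
mcompcor on mvICC. The flexible-HRF basis pays a genuine variance penalty
(its dispersion derivative correlates ≈0.54 with the canonical block
regressor, inflating contrast variance ≈75%) while, in a *block* design,
HRF latency jitter perturbs the convolved regressor only at block edges — so
derivative bases cannot recoup the penalty through better HRF fit, and the
reliability benefit of HRF flexibility reported for real data (where HRF
mismatch is larger and partly unmodeled) does not reproduce. The
physiological-noise mechanism does reproduce: removing the confound lowers
within-subject contrast noise (higher ICC), restores the pooled ρ, and
yields the fewest assumption violations for the combined pipeline.

## Numerical choices and degenerate inputs

- Ties in the mCompCor top-SD selection break by flat voxel order (stable
  sort); the regressor is demeaned but not variance-normalized (its scale is
  absorbed by the beta).
- "Whole brain" for the top-2% pool means the brain mask, not the field of
  view (air voxels would dominate meaninglessly). SD is computed on the raw
  series, before any high-pass handling, since the regressor enters the same
  model as the drift terms.
- Rank-deficient designs abort with the collinear column names (QR with
  pivoting); constant residual series abort autocorrelation and diagnostic
  tests explicitly.
- A noise-free run is fitted exactly: the data lie in the design's span, so
  the contrast reproduces the injected amplitude to ~1e-8 regardless of the
  (then meaningless) whitening parameter.
- Microtime convolution sampled at the TR agrees with a direct TR-grid
  convolution up to the coarse path's own left-rule quadrature error (~2%
  of the block plateau).
- `run_study` refuses to overwrite a non-empty output directory unless
  explicitly resumed; reruns with one seed are byte-identical in all summary
  tables.

## Known limitations

- The global-AR(1) noise model is intentionally simple; voxelwise or
  spatially regularized serial-correlation models are out of scope.
- The phantom's confound is a single shared time series per run; real
  physiological noise has spatial structure and local components, so the
  mCompCor regressor recovers it more cleanly here (r > 0.99) than it would
  in vivo.
- Violation proportions are compared by subject-blocked Friedman tests, not
  a generalized linear mixed model; decisions, not coefficients, are the
  output.
- With k = 2 sessions, ICC(3,1) estimates at n ≤ 48 are noisy (SD ≈ 0.1);
  every reliability claim in the package is therefore either averaged over
  cohorts or stated as a seeded direction.
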