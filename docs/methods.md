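# Methods

`restdcm` replays, on synthetic data, an inference chain for rapid
perceptual learning and overnight consolidation of its trace in
hippocampo–striatal effective connectivity during rest. This note
documents the models, the estimation machinery, the synthetic-data
generator, and the numerical and design choices behind them.

## Behavioral model and learning curve

Performance on the coherent-motion task is summarized per block by inverse
efficiency, `IE = mean RT / accuracy` (seconds; lower is better). Before
averaging, single-trial reaction times deviating from their block mean by
more than three sample standard deviations (n−1 denominator) are excluded
in a single pass; a block with zero RT variance can never flag a trial, so
no special case is needed. Omitted responses count as errors and
contribute no RT (a conservative choice; the source analysis does not
specify one).

The 25 motion-block IE values are fitted by nonlinear least squares with

    y = a · exp(−b · x),  x = 1, …, 25,

where `a` is the amplitude (s) and `b` the learning rate (1/block). The
block index starts at 1 (configurable; the convention is not dictated by
the statistic). The optimizer is Levenberg–Marquardt with multi-start over
b₀ ∈ {0.01, 0.05, 0.2} keeping the lowest residual sum of squares, and the
amplitude initialized so the curve passes through the first block's IE.
A negative fitted `b` (no learning) is permitted and surfaces in the
screening flags. The fitted values — not the raw IE — enter the task GLM
as parametric modulator, and IE is fitted on motion blocks only (control
blocks are at ceiling and carry no learning signal); a flag allows
including them for diagnostics.

## Task GLM

The first-level model is an ordinary-least-squares convolution GLM on
region-averaged series: condition boxcars convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, undershoot ratio 6, 32-s
support, unit-sum normalized), a motion regressor whose block amplitudes
are the fitted IE values mean-centered per run before convolution, a
discrete-cosine high-pass basis per run (128-s cutoff for task data,
256 s for rest), and per-run constants. Contrast t-values use
t = c′β̂ / √(σ̂² c′(X′X)⁻¹c) with residual degrees of freedom after all
design columns (including the filter). Group inference is a one-sample
t-test of per-subject contrasts.

Serial correlations are not modeled by default; the type-I error of the
IE-modulator t-statistic is verified by simulation in the test suite
(empirical 5%-level rejection rate within [3%, 7%] over 1000 pure-noise
datasets). The voxel-wise SPM with random-field correction of a full
imaging analysis is out of scope: the GLM operates on the two named ROI
series only.

The DCT high-pass basis retains the non-constant DCT-II columns
j = 1 … k−1 with k = ⌊2·N·TR/cutoff + 1⌋ (276 rest volumes at TR 2.176 s
and a 256-s cutoff give 4 drift columns). A truncated cosine basis removes
cosine-phase drifts at the retained periods essentially exactly, but the
quadrature (sine) component at the shortest retained period leaks
partially (~36% residual variance at period 300 s); this is inherent to
DCT high-pass filtering and is documented by a test rather than hidden.

## PPI screening

For each rest run, coupling between seed (hippocampus) and target
(striatum) is the OLS slope of the target on the seed after partialling
the constant and the 256-s DCT basis from both series; runs are filtered
independently because they are separate acquisitions. The four slopes
(day1-pre, day1-post, day2-pre, day2-post) form a 2×2 factorial:

    main_day    = (β1+β2) − (β3+β4)
    main_time   = (β1+β3) − (β2+β4)
    interaction = (β2−β1) − (β4−β3)

The interaction is the day-1 pre→post change minus the day-2 pre→post
change, so a pure within-day adaptation profile [0,1,0,1] cancels exactly
while the consolidation profile [0,2,1,1] yields 2 per unit slope change.
The signs are a reporting convention; all tests are two-sided. Group
inference is again a one-sample t-test over subjects.

## Dynamic causal model

Neuronal dynamics of the two regions follow the bilinear stochastic form

    dz/dt = (A + Σ_j m_j(r) B_j) z + u(t),

with A the average 2×2 coupling (Hz), self-connections fixed at −0.5 Hz
(not estimated and not modulated; only extrinsic connections change),
B_j per-connection bilinear parameters, and m_j(r) run-weight vectors over
the four rest runs:

| modulator     | weights     | meaning                                  |
|---------------|-------------|------------------------------------------|
| adaptation    | [0, 1, 0, 1] | non-specific within-day change          |
| learning      | [0, 1, 0, 0] | day-1-only change after learning        |
| consolidation | [0, 2, 1, 1] | learning change persisting at half level |

Learning and consolidation models carry the adaptation modulator plus
their own, i.e. two bilinear parameters per modulated connection
(four in the bidirectional variants). Crossing {adaptation, learning,
consolidation} × {forward, backward, both} and adding the single shared
null model gives exactly 10 models.

Each region's neuronal state drives a balloon hemodynamic cascade
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q):

    ds/dt = z − κs − γ(f−1),  df/dt = s,
    τ dv/dt = f − v^{1/α},
    τ dq/dt = f·(1−(1−E0)^{1/f})/E0 − v^{1/α} q/v,
    BOLD% = 100·V0·(k1(1−q) + k2(1−q/v) + k3(1−v)),

with the standard constants κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2 s,
α = 0.32, E0 = 0.32, V0 = 0.04, k1 = 7E0, k2 = 2, k3 = 2E0 − 0.2.

### Inversion: linear-Gaussian state space

Resting-state DCM is often inverted by generalized filtering; this package
deliberately uses a different, exactly marginalizable scheme. The balloon
cascade is linearized at its fixed point (s=0, f=v=q=1), giving a 4-state
linear hemodynamic operator per region and a 10-state linear-Gaussian
model per run (2 neuronal + 2×4 hemodynamic states). The endogenous drive
is modeled as continuous-time white noise with one shared spectral
amplitude. Discretization at the TR uses the matrix exponential with the
exact integrated innovation covariance (Van Loan), not an Euler step —
the TR of 2.176 s is far too coarse for Euler. The initial state of each
run is the stationary distribution of its discretized system; runs share
one parameter vector but state is not carried across runs (they are
separate acquisitions — "concatenation" is honored at the parameter
level).

The marginal likelihood of each run is computed exactly by the Kalman
filter prediction-error decomposition and summed over runs. A test
verifies this against a brute-force joint-Gaussian density on short
series to 1e-8 (observed agreement ~1e-13). Once the Riccati recursion
has converged (relative change ≤ 1e-11), gain and innovation covariance
are frozen and only the mean recursion is iterated; this is a pure
speed optimization with perturbations far below every tolerance used.

Parameters θ = (A off-diagonals, bilinear b's, log noise SDs) carry
zero-mean Gaussian shrinkage priors: SD 0.25 Hz on couplings and
bilinear parameters, SD 1 on the log noise SDs. MAP estimation uses
L-BFGS-B (bounded well away from degenerate noise regimes) with
multi-start: couplings start at the prior mean, log noise SDs at
data-variance-matched values, plus jittered restarts (3 starts by
default). Unstable parameter proposals (max real eigenvalue of any
run-effective matrix ≥ 0) receive a smooth quadratic penalty rather than
a hard failure. The log evidence is the Laplace approximation

    log p(y|m) ≈ log p(y|θ*) + log p(θ*) + (d/2)·log 2π − ½·log|H|,

with H the finite-difference Hessian of the negative log posterior at the
MAP; a non-positive-definite Hessian triggers an eigenvalue-clipped
nearest-PD fallback and is flagged on the fit object.

Before fitting, the first five volumes of every run are dropped
(T1 equilibration) and the per-run mean and 256-s DCT drift terms are
projected out; the state-space model is zero-mean, and estimated
observation noise absorbs the residual filtering mismatch.

### Model selection

Fixed-effects BMS sums log evidences over subjects (the design assumes
one model generated every subject's data). Reported "relative" evidences
subtract the worst model's sum, so the worst model sits at zero. The
selection criterion is a winner–runner-up difference of ≥ 3 nats
(Bayes factor ≈ 20:1); exact ties are reported and fail the criterion
rather than being silently broken. Per-subject winners are the row-wise
argmax (identical whether raw or relative evidences are used).

Coupling changes under the winning model are reconstructed as
change_c(r) = Σ_j m_j(r)·b_jc, reported relative to rest run 1 (whose
weight is zero under all shipped patterns). For positive parameters the
consolidation profile peaks at rest run 2 and persists at a lower level
through runs 3–4.

## Synthetic data generator

The generator is first-class, tested code that defines the study
conditions for every downstream claim.

**Behavior.** Per trial: correctness ~ Bernoulli with probability rising
logistically toward an asymptote, RT ~ truncated normal with mean decaying
exponentially toward an asymptote. Both smooth curves share the learning
rate `b`, so a zero rate yields genuinely flat performance, and block IE
follows an approximately exponential curve. Defaults: RT amplitude 0.8 s
over an 0.55-s asymptote, trial RT scatter 0.15 s, accuracy rising
0.55 → 0.95, control condition at 0.995 accuracy (sampled accuracies
97–100%, matching the near-ceiling control performance the task is
designed to produce), 0.5% omissions. Blocks strictly alternate between
conditions with the starting condition counterbalanced across subjects.

**Rest BOLD.** Euler–Heun integration of the full nonlinear balloon
cascade at dt = TR/32, driven by AR(1) endogenous fluctuations with a 2-s
correlation half-life and stationary SD 0.02 (a.u.); a 60-s burn-in
brings every run to stationarity before recording, and states are
re-initialized per run. On top of the clean signal the generator adds
(i) slow drift: the three lowest-frequency DCT components with random
amplitudes (SD 0.5% per component), removable by the 256-s high-pass,
and (ii) white observation noise (SD 0.2% BOLD). Run-wise coupling
follows A + Σ m_j(r)B_j under the configured change pattern.

Default effect sizes — average coupling 0.12 Hz each way, b_adapt =
0.06 Hz, b_consolidation = 0.13 Hz on both connections — were chosen
jointly with the noise levels so that (i) every run-effective matrix
stays well inside the stable, weakly nonlinear balloon regime (the run-2
off-diagonal reaches 0.44 Hz against the 0.5-Hz self-decay; clean BOLD
SD stays ≤ ~3.5%), and (ii) model recovery is achievable but not
trivial: across master seeds the bidirectional consolidation model wins
for 9–11 of 11 subjects, with the occasional subject going to the
neighboring bidirectional learning model. Effect sizes are configuration,
not hard-coded.

A neuronal drive much above SD ~0.05 pushes flow and volume into regions
where the fractional powers of the balloon equations blow up; the
integrator clamps f and v away from zero as a guard, but default
amplitudes keep the system far from that regime.

**Task BOLD.** The hippocampus-like region's evoked amplitude on motion
blocks is base + gain × fitted IE (gain 0.5 per second of IE), built with
the same HRF machinery the GLM uses, so the noiseless modulator beta is
recovered exactly; the striatal region responds to the task without
learning modulation. Drift and observation noise as for rest.

**What the generator does not emulate.** Spatial structure (it emits
region averages directly), physiological (cardiac/respiratory) noise —
the drift + white-noise components stand in for generic nuisance,
scanner artifacts, motion, and any mismatch between the two-region
closed system and a real brain's open network. Passing tests therefore
demonstrate the estimators' internal consistency and calibration under
the assumed generative family, not robustness to real fMRI artifacts.
Two deliberate model mismatches are present and shared across all
candidate models: the generator integrates the nonlinear balloon
equations and colored (AR(1)) neuronal noise, while the inversion uses
linearized hemodynamics and white neuronal noise — model comparison is
unaffected because every model inherits the same mismatch.

## Numerical choices

- Matrix exponentials inside the likelihood use scaling-and-squaring with
  a degree-18 Taylor core (truncation ≪ machine epsilon at the scaled
  norm); verified against `scipy.linalg.expm`.
- Stationary covariances solve the discrete Lyapunov equation by doubling;
  verified against `scipy.linalg.solve_discrete_lyapunov`.
- The Heun (predictor–corrector) step makes the deterministic flow
  second-order accurate: halving dt from 0.1 s changes sampled output by
  ≪ 1% RMS. Samples are recorded before the step update so volume k sits
  at time k·dt exactly.
- Numerical Hessians use central differences with relative step 1e-3.
- Optimizer failure of one start falls through to the next; all-start
  failure raises. Degenerate inputs (zero-variance seed series, zero
  accuracy blocks, zero between-subject variance) raise typed errors
  rather than returning NaN.

## Problem sizes

Full-scale experiments (11 subjects, 4 × 276 volumes, 10 models,
3 starts) run in a few minutes. The shipped calibration studies use
deliberately reduced sizes, stated here as the package's own choices:
null-calibration BMS uses 50 replicate cohorts of 8 subjects with 80
retained volumes per run and single-start inversion (conservative in
cohort size: each added subject strengthens the Occam penalty against
change models under the null); the PPI uniformity study uses 500
replicate 11-subject cohorts at full run length. The pipeline exposes
`rest_volumes` and `max_fit_volumes` to trade runtime against precision.

## Known limitations

- The Laplace evidence is a local approximation; with weak effects and
  short runs, neighboring models (e.g. bidirectional learning vs.
  consolidation) can swap ranks for individual subjects.
- The linearized observation model biases absolute noise estimates when
  fluctuations leave the small-signal regime; comparisons between models
  remain valid as the bias is shared.
- Fixed-effects BMS assumes a single generating model for all subjects;
  random-effects BMS is intentionally not implemented.
- The region-swap symmetry of the evidence holds to optimizer convergence
  tolerance (~1e-4 nats), not machine precision, because the two mirrored
  optimizations take different numerical paths.
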