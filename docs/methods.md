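# Methods

`latentsim` is a simulation toolkit for the *latent-input* approach to
model-based fMRI: fit a computational model to behavior, derive a
trial-wise latent variable (here, the reward prediction error), convolve
it with a hemodynamic response function, and regress the measured BOLD
signal on it. The regression weight φ — the "neural coding" parameter —
is a common target of individual-differences inference. The package
exists to show, by controlled simulation, when individual differences in
φ̂ are real, absent, or spurious.

## Behavioral model

Each simulated subject plays a two-armed bandit (or, in *pavlovian*
mode, passively observes one option's outcomes). Values update by the
delta rule with learning rate α ∈ [0, 1]:

    PE_t = γ·O_t − V_chosen,t
    V_chosen,t+1 = V_chosen,t + α_t · PE_t
    α_t = α₀ · exp(−λ·(t−1))

and choices follow a softmax on the value difference with inverse
temperature β ≥ 0. γ > 0 is an outcome-sensitivity weight (γ = 1 gives
the standard model), and λ ≥ 0 an exponential learning-rate decay
(λ = 0 gives the static model). The decay form was chosen because it is
one-parameter, monotone, and nests the static model; other dynamic
learning-rate families (Pearce-Hall, Bayesian learners) are out of
scope.

Task defaults: 2 options with reward probabilities (0.8, 0.2), outcomes
+1 (win) / −1 (loss) in a win-or-lose-a-dollar framing, initial value
v₀ = 0.5. In pavlovian mode the uniform draws for outcomes are
generated up front, so subjects sharing a seed experience identical
outcome sequences regardless of their learning parameters — the yoking
that lets learning-rate effects be isolated.

**γ and initial values.** Initial values are specified on the objective
outcome scale and enter the γ-model as γ·v₀. With this convention the
whole value trajectory scales with γ, and the choice probabilities under
(β, γ) are *identical* to those under (β·γ, 1): outcome sensitivity and
inverse temperature are exactly non-identifiable from choice data. The
fitter therefore refuses a model specification in which both β and γ are
free, rather than returning an arbitrary point on the likelihood ridge.

## Fitting

Maximum likelihood on the per-trial softmax choice probabilities, with
values rebuilt trial-by-trial from the candidate parameters (the first
trial uses v₀; no lapse or choice-kernel terms). Optimization is
bounded Nelder-Mead with multi-start (default 10 restarts: one default
start plus uniform draws within bounds α ∈ [0,1], β ∈ [0,50],
γ ∈ (0.01,10], λ ∈ [0,0.1]). The simplex method is used deliberately:
when β is small the likelihood is nearly flat in α, and
finite-difference quasi-Newton methods stall on the (α=0, β=0) corner.
Datasets in which every choice is the same option leave β unidentified;
the boundary estimate is returned with `non_identified=True` rather
than raising. `fit_shared` fits several subjects jointly with selected
parameters forced equal (a deliberately misspecifiable analysis used to
study shared-parameter assumptions).

## Neural model

The trial-wise PE series becomes a boxcar train (height = PE, width =
event duration, onsets on a regular grid at the trial duration) on a
10 ms oversampling grid, convolved with a double-gamma HRF in the SPM
convention (peak 6 s, undershoot 16 s, ratio 1/6, unit-peak normalized;
cross-checked against nilearn's reference implementation in the test
suite) and sampled at the TR. The simulated signal is
φ · regressor + white Gaussian noise added at scan resolution. Noise is
set either as an SD or as a contrast-to-noise ratio, defined as
CNR = SD(noiseless convolved signal) / noise SD; CNR = 0.1 — noise ten
times the signal — is the default for the noisy experiments. "Stick
function" analyses use a 0.01 s boxcar. No jitter, drift, or
autocorrelated noise is simulated.

Estimation is ordinary least squares of the signal on the convolved PE
regressor plus an intercept, with classical (white-noise) standard
errors — appropriate because the generative noise is white by
construction. Optional standardization divides the *trial-level* PE
amplitudes by their sample SD (n−1 denominator, as for all variances in
the package) before convolution, with no mean-centering, and records
the divided-out SD; by OLS algebra this multiplies φ̂ by that SD
exactly.

## Scenario experiments

Seven scripted experiments compose these pieces (driver scripts under
`analysis/`, library functions in `latentsim.scenarios`). Replicate
counts default to 50 for the PE-variance experiment and 400 for the
misspecification experiment, with a fast mode at 1/10 scale; the test
suite and acceptance script run the sweeps at 100 datasets of 1000
trials and the misspecification experiment at 40 datasets of 300
trials, sizes at which every directional claim is stable.

1. **Learning rate only.** Yoked pavlovian pair, α = 0.05 vs 0.5,
   equal φ = 1, noise SD 0.1. PE variance rises with α; φ̂ does not
   differ.
2. **Standardization.** Same data analyzed raw vs standardized; the
   standardized φ̂ equals the raw φ̂ times the subject's PE SD, exactly.
3. **Coding and learning differences together.** (α=0.05, φ=2) vs
   (α=0.5, φ=0.5); signal variability (SD of the noiseless convolved
   signal) now favors the slow learner.
4. **Duration bias.** True event durations 0.01–1 s analyzed as a
   0.01 s stick, noiseless; φ̂ grows nearly linearly with the true
   duration (doubling ratios ≈ 2 for durations ≤ 0.5 s).
5. **Inverse temperature.** Evenly spaced β sweep over [0.2, 10], one
   dataset per β, 1000 trials, α = 0.1, φ = 1, CNR = 0.1; the full
   pipeline (fit, then GLM on the fitted PEs) recovers β accurately and
   shows no systematic β → PE-variance or β → φ̂ relation.
6. **Outcome sensitivity.** γ swept over [0.5, 3] (log-spaced grid)
   with fits fixing γ = 1; the sensitivity loads onto β̂ (choices
   identify only β·γ) and onto φ̂ (true PEs scale with γ, fitted ones
   do not) — spurious coding differences undetectable by model
   comparison.
7. **Model misspecification.** (a) The yoked pair of scenario 1 at 300
   trials, 4 s trials, TR = 1, CNR = 0.1. Using each subject's own
   learning rate recovers equal φ̂; assuming the *high* learning rate
   for both attenuates the slow learner's φ̂ (the misassumed regressor
   carries excess variance) and flags a spurious difference.
   (b) Choices generated with a decaying learning rate (α₀ = 0.8,
   λ = 0.02 — plasticity halving every ≈ 35 trials) fitted with the
   static model underestimate φ relative to the matched decay fit on
   the same data and time series.

**Yoking and contrast flags.** Within a simulated dataset of scenario
7a the two subjects share both the outcome sequence and the
scanner-noise draws, so the between-subject contrast is evaluated with
the paired SE of the per-dataset φ̂ differences (`paired_contrast_flag`)
— the correct standard error for a yoked design, under which both the
positive and the null verdicts are stable at 40 datasets. For unpaired
cells the two-sample pooled-SE rule (`spuriousness_verdict`) applies.
Both use a conservative 3-SE threshold; the flag is an internal
screening device, not an inferential test. Summary tables still report
conventional across-dataset SDs and SEs per cell.

## What the generator does and does not emulate

The synthetic data reproduce the structural features the arguments rely
on: probabilistic choice-dependent (or yoked choice-free) outcomes,
delta-rule latent dynamics, HRF-convolved parametric modulation, and
calibrated white noise. They omit: hemodynamic variability across
subjects and regions, autocorrelated/physiological noise, motion and
drift, trial-timing jitter, multi-region structure, and any volumetric
(voxel-level) organization. Passing tests therefore establish the
*logic* of the interpretive claims — which analysis choices can or
cannot manufacture individual differences in φ̂ — not their effect
sizes in real fMRI data.

## Numerical choices and edge cases

- Softmax probabilities via the logistic sigmoid (`scipy.special.expit`),
  saturating rather than overflowing for extreme |β·ΔV|.
- Log-likelihood accumulated as −log(1+e^(−x)) with a linear tail for
  x < −30; inner loops JIT-compiled with numba (pure-Python fallback).
- Sample statistics use the n−1 denominator throughout.
- Convolution by FFT (`scipy.signal.fftconvolve`) on a 10 ms grid;
  regressors are exactly linear in the PE amplitudes, which is what
  makes the standardization identity hold to machine precision.
- All randomness flows through a `numpy` `SeedSequence` tree rooted at a
  master seed; every scenario is bit-reproducible from (config, seed).
- Degenerate inputs fail loudly: zero-variance regressors, constant PE
  series under standardization, pavlovian data passed to the choice
  likelihood, fewer than two trials for a variance.

## Known limitations

- The decaying-learning-rate model is the only dynamic variant; mixture
  or hierarchical treatments of model heterogeneity are out of scope.
- OLS assumes white noise; no prewhitening is implemented, matching the
  generative model but not real scanner noise.
- The bandit has exactly two options.
- φ̂ attenuation from noisily estimated PEs (errors-in-regressor) is
  visible at very low β, where α is weakly identified; this is a
  property of the estimation problem, not of the implementation.
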