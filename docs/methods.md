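# Methods

## Stimulus model

Each trial is 12 s. Masker tones live on a grid of frequencies equally
spaced on a log scale between 239 and 5000 Hz; at `fpo` frequencies per
octave the grid has `round(fpo·log2(5000/239)) + 1` points with both
endpoints included (the source description fixes the endpoints and the
density but not the count; this rule honors both). Each grid frequency is
an independent renewal process: the first onset is uniform on
[0, iti_max] — a stationary-like start — and successive onset-to-onset
gaps are i.i.d. uniform on [iti_min, iti_max] with iti_min = 100 ms.
"Inter-tone interval" is read as onset-to-onset: together with tone
durations ≤ 100 ms this guarantees no within-channel overlap and matches
the renewal-process entropy framing. Tones whose offset would pass the
trial end are dropped.

Targets are regular streams: tones of fixed duration at `rate` Hz
(onset-to-onset), starting 600 ms after masker onset, emitted while
onset + duration ≤ 12 s. Target frequency is drawn per trial from six
log-spaced values, 489–2924 Hz (489, 699, 1000, 1430, 2045, 2924 Hz). A
protected region of one ERB on each side of the target frequency
(ERB = 24.7(4.37·F + 1) Hz, F in kHz) is removed from the masker grid. On
catch trials a *virtual* target frequency is drawn and its protected
region applied anyway, so target and catch maskers are statistically
indistinguishable to the listener.

A schedule is 243 trials: each of the 27 factorial conditions once per
target frequency (162 target trials) plus three catch trials per condition
(81; the 27×3 balance is a package choice — only the 81 total is fixed by
the design). Trials are randomly ordered into 6 blocks sized
{41,41,41,40,40,40} (the only composition matching "41 or 40" and 243),
with the block-size order itself randomized. Per-trial seeds derived from
the master seed make event materialization reproducible after the fact.

Audio rendering sums equal-amplitude sinusoids with 10 ms raised-cosine
on/off ramps at 44.1 kHz. The common gain is 0.9 divided by the maximum
instantaneous polyphony of the trial — a deterministic no-clip rule; the
original hardware calibration to a sound-pressure level is out of scope,
so full-scale digital convention stands in. Output is mono (presentation
was diotic) 16-bit PCM WAV via `scipy.io.wavfile`.

## Stimulus statistics

- Entropy H = fpo · ln(Δ), Δ in ms, natural log (nats). Taking Δ in ms is
  the only convention that reproduces the published table; note that that
  table's last printed digits mix rounding and truncation
  (e.g. 4·ln 1400 = 28.9769 printed 28.97 but 32·ln 1400 = 231.8153
  printed 231.82), so checks accept one unit in the last place.
- Similarity S = masker − target tone duration (ms); negative means the
  target tone is longer.
- Spectro-temporal density STD = fpo / miti in s⁻¹·oct⁻¹.
- Segregation time constant τ: smallest t with F(t) ≥ 0.63 for a detection
  CDF F, linearly interpolated between evaluation points (no rule is
  stated; linear is the least structured choice), censored when F never
  reaches the level within 12 s.

## Synthetic behavior generator

The generator emulates exactly the structure the analysis assumes:

- latent detection time from target onset ~ Weibull(k, λ) baseline under
  proportional hazards, S(t|x,w) = exp(−w e^{xβ}(t/λ)^k), drawn by
  inverse CDF. A Weibull baseline is used because the semiparametric
  baseline of the analysis model is not identifiable for a generator; it
  inverts in closed form and spans increasing/decreasing hazards.
- shared frailty w per subject ~ Gamma(1/v, v) (mean 1, variance v),
  the hazard-scale equivalent of an additive log-scale random effect.
- administrative censoring at 11.4 s of exposure (12 s trial minus the
  600 ms onset); a response is a "hit" only if it lands inside the trial.
- catch trials: first event of a Poisson process (rate per second) on
  (0, 12] s, else a correct rejection.
- guesses: with probability p_guess the response is replaced by a uniform
  draw below the experiment's cut-off, exercising the dismissal rule
  downstream; the pipeline, not the generator, decides their handling.

Default scenario: 14 subjects, frailty variance 0.3, k = 1 (exponential
baseline), effects that rank conditions as the study found (hazard highest
at low uncertainty / strongly negative similarity / high rate). The
per-experiment false-alarm rates (0.024, 0.0116, 0.007 s⁻¹) and the
Experiment-I baseline scale (4.5 s; 6 s otherwise) put the synthetic hit
and false-alarm rates near the published per-experiment behavioral means.
Covariates are carried as factor labels (entropy rounded to 2 decimals,
similarity in ms, rate in Hz).

What the generator does **not** emulate: attention lapses, learning across
blocks, non-proportional hazards, response-time motor noise, or any
within-subject correlation beyond the shared frailty. Passing recovery
tests therefore shows the pipeline is correct *under its own model
assumptions* at the study's scale — not that the model is true of human
listeners.

## Survival pipeline

Categorization: hit = target trial with response in [cut-off, 12 s]
(cut-offs 1600/700/1100 ms for Experiments I/II/III — two repetitions of
the slowest target); faster responses on target trials are guesses,
excluded from both d′ counts and the survival data (dismissal read as
exclusion, not recoding as miss); miss = no valid response; any response
on a catch trial is a false alarm. Block 1 is dropped before analysis.
The survival dataset contains only target trials, time origin at target
onset, censored at 11.4 s; catch trials never enter it.

d′ uses the log-linear edge correction (count + 0.5)/(N + 1) — symmetric
and standard where the source is silent — and is defined only per
masker-uncertainty condition, since false alarms carry no target
properties. The mixed model of d′ is a REML random-intercept fit
(statsmodels MixedLM); the F statistic uses the between-within denominator
df, N − g − df1, i.e. (g−1)(k−1) for balanced data.

The frailty Cox fit maximizes the Breslow-ties partial log-likelihood in
(β, ξ) jointly, where ξ are per-subject log-frailties carrying the gamma
penalty (1/θ)Σ(ξᵢ − e^{ξᵢ}); Newton steps with step-halving converge to a
score sup-norm below 1e-6 (target 1e-9, 60-iteration cap). At fixed θ the
stationarity condition gives the classic posterior-mean frailties
e^{ξ̂ᵢ} = (1/θ + dᵢ)/(1/θ + Aᵢ). θ is chosen by maximizing the marginal
likelihood — the gamma frailty integrated out of the Breslow-baseline full
likelihood — via bounded scalar search on log θ over [1e-4, 5] (profile
solutions pinned to the lower bound with no likelihood gain collapse to
the plain Cox fit). With θ = 0 the machinery reduces exactly to plain Cox;
a fixed-θ fit reproduces R's `coxph + frailty.gamma(theta=...)`
coefficients to 4 decimals (development cross-check), while profiled θ can
differ from R's default, which uses an EM/approximate-REML criterion
rather than the marginal profile.

Standard errors come from the inverse penalized information (fixed-effect
block). Effective degrees of freedom are trace(H_pen⁻¹ H_unpen), summed
per term; sequential (type-I) likelihood-ratio tests compare nested fits —
each profiling its own θ when a frailty group is present — on the marginal
likelihood with Δedf as (possibly non-integer) df. The frailty term itself
is tested against the plain Cox fit with df = its effective df. This
effective-df convention matches the spirit, not provably the letter, of
the non-integer dfs in the source analyses.

Estimated marginal means are cell means of the linear predictor averaged
over a balanced grid of the remaining model factors, with delta-method
SEs; treatment contrasts against the lowest factor levels pin the
reference cell at 0 with SE 0, reproducing the published table
parameterization. Tukey adjustment uses the studentized-range distribution
for k estimates (the equicorrelation/large-sample approximation of the
exact multivariate-t method; it matches R's `ptukey` evaluations).
Letters come from insert-and-absorb, and every display is verified
against the pairwise significance graph before being returned.

Cox–Snell residuals are r = e^{ξ̂ + xβ̂} Ĥ₀(t) with censoring flags; the
through-origin slope of their Nelson–Aalen cumulative hazard against r is
the model-adequacy summary (≈1 when well specified). Predicted curves use
the Breslow baseline: population-averaged survival through the gamma
Laplace transform (1 + θ e^{xβ} H₀)^{−1/θ} by default (the published
figures show group curves and are silent on conditioning), conditional
ξ = 0 as an option; hazards smooth the baseline increments with a
Gaussian kernel (default bandwidth 0.5 s) and grids beyond the last event
time are clamped and flagged. Kaplan–Meier and Nelson–Aalen steps go
through lifelines.

Outlier screening — originally a by-eye inspection — is operationalized
as a reproducible rule: exclude subjects whose mean false-alarm rate
exceeds the across-subject mean by 2 SD. (The rule needs ~10+ subjects to
be able to fire at all; with n ≤ 5 the maximum attainable z is below 2.)

## Accumulator

X_{n+1} = X_n + r(T − X_n) + ε with ε ~ N(0, σ²); σ = 0 gives
X_n = T(1 − (1−r)^n) + X₀(1−r)^n exactly. Defaults follow the published
example (T = 0.9, X₀ = 0, r = 0.7, σ = 0.15). The threshold is never
printed in the source; it defaults to 1.0 and is a parameter. Crossing is
checked at integer steps without interpolation. The step-to-time mapping
defaults to one update per target tone (step_dt = 1/rate) — the natural
bridge to repetition-rate effects — with a plain fixed-dt mode. Binned
empirical hazards are events / (at-risk at bin start × width); note this
estimator carries O(h·width) discretization bias, so checks against
closed-form hazards use narrow bins. Kernel/moving-average smoothing is
provided in a separate, labeled column only.

## Numerical choices and problem sizes

- Newton tolerance 1e-9 on the score sup-norm, step-halving to 2⁻³⁰;
  θ-profile tolerance 1e-3 on log θ.
- Ties: Breslow everywhere (millisecond times make ties rare; consistent
  with the baseline estimator used for curves).
- Degenerate inputs: empty inter-tone-interval range, non-monotone CDFs,
  negative variances, unknown factor levels and event-free datasets raise
  `ValueError`/`KeyError` rather than propagating NaNs.
- Test problem sizes are the study's own: 14 subjects × 243 trials for
  recovery (100 replicates), 200 simulated datasets for test calibration,
  10⁵ draws for distributional checks, 10⁴ accumulator trials. The d′
  example check (HR 84/100, FAR 16/100 → d′ ≈ 1.98) is asserted at 0.05
  because the edge correction shifts the uncorrected 1.989 to 1.963.

## Known limitations

- Exact reproduction of the published coefficient tables is impossible
  without the human data; the pipeline reproduces the machinery and is
  validated by oracle equivalence and parameter recovery instead.
- The profiled frailty variance uses the marginal-likelihood criterion;
  values are not numerically identical to R's default EM criterion
  (coefficients agree closely; fixed-θ fits agree to 4 decimals).
- The mixed-model denominator df convention matches two of the three
  published F-test layouts; the third (F(2,27) from a 10×3 layout) is not
  derivable from any standard convention we know.
- Audio levels are digital full scale, not SPL-calibrated.
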