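# tonemask

Stimulus generation and time-to-event analysis for informational-masking
experiments: how long does it take a listener to become aware of a regular
tone stream hidden in a random multi-tone cloud, and how do the masker's
uncertainty, its temporal similarity to the target, and the target's
repetition rate shape that time course?

The package is organized as an analysis project. Every computation lives in
the `tonemask` library (`src/`); the numbered scripts under `analysis/` are
thin drivers that run the study end to end on synthetic behavior and write
tidy tables under `results/`.

## The problem and the model

A 12 s trial presents a multi-tone masker — log-spaced frequency channels
between 239 and 5000 Hz, each an independent renewal process with
inter-tone intervals uniform on [100 ms, iti_max] — and, on two thirds of
trials, a regular target tone stream starting at 600 ms. A protected region
of ±1 ERB (equivalent rectangular bandwidth, 24.7(4.37·F + 1) Hz with F in
kHz) around the target frequency is kept masker-free, so failures to hear
the target are informational, not energetic. Three stimulus statistics
summarize a condition:

- masker uncertainty (entropy): H = n·ln(Δ) nats, with n frequencies per
  octave and Δ the inter-tone-interval range in ms;
- masker–target similarity: masker minus target tone duration (ms);
- spectro-temporal density: n / miti tones·s⁻¹·oct⁻¹.

Detection latencies are time-to-event data, right-censored at the trial
end. The core analysis is a Cox proportional-hazards model with a shared
gamma frailty per subject,

    h(t | x, w) = w · h₀(t) · exp(x β),     w ~ Gamma(1/θ, θ),  E[w] = 1,

fitted by Newton maximization of the gamma-penalized partial likelihood
(Breslow ties), with the frailty variance θ profiled on the marginal
likelihood. On top of the fit sit sequential likelihood-ratio effect tests
(with effective, possibly non-integer, degrees of freedom), estimated
marginal means on the log-hazard scale, Tukey-adjusted all-pairwise
comparisons condensed into a compact letter display, Cox–Snell residual
diagnostics, and population-averaged hazard/CDF curves. Detection
performance itself is summarized by d′ = z(HR) − z(FAR) with a
random-intercept mixed model across subjects.

Because no behavioral data ship with the package, the `synth` module is a
first-class generator: Weibull-baseline proportional-hazards detection
times with gamma frailty, administrative censoring at 11.4 s after target
onset, sub-cut-off guesses, and Poisson false alarms on the 33% catch
trials — everything the pipeline assumes, with known ground truth so that
recovery is testable. A small evidence-accumulation model
(X_{n+1} = X_n + r(T − X_n) + ε, detection = first passage of a threshold
above the saturation level T) provides qualitative hazard curves for
comparison.

## Worked example

```sh
python analysis/01_build_stimuli.py  --seed 0 --out results
python analysis/02_simulate_behavior.py --seed 0 --out results
python analysis/03_detection_performance.py --seed 0 --out results
python analysis/04_survival_analysis.py --seed 0 --out results
python analysis/05_accumulator.py --seed 0 --out results
```

Driver 03 prints, per experiment, the behavioral summary and the
mixed-model test of masker uncertainty on d′:

```
Experiment I: mean d' = 0.35 (HR 0.40, FAR 0.27); uncertainty effect F(2,26) = 15.49, p = 3.71e-05
Experiment II: mean d' = 2.18 (HR 0.83, FAR 0.17); uncertainty effect F(2,26) = 23.48, p = 1.49e-06
```

Driver 04 prints the survival-model summary; for Experiment I:

```
Experiment I: 1737 trials, 681 detections; frailty variance 0.227 (chi2 = 110.9, df = 12.0, p = 3.74e-18); 15 cells in 8 CLD groups; Cox-Snell slope 1.05
  uncertainty: chi2 = 119.1, df = 2.1, p = 1.8e-26
  similarity: chi2 = 113.5, df = 4.1, p = 1.5e-23
  uncertainty:similarity: chi2 = 8.7, df = 8.0, p = 0.366
```

Read: after dropping block 1 and dismissing guesses, 1737 target trials
remain, 681 of which ended in detection before 12 s. The profiled frailty
variance 0.227 is close to the generator's true 0.3, and both stimulus
factors shift the detection hazard strongly (the interaction here does
not). The 15 condition cells (3 uncertainty × 5 similarity levels) fall
into 8 compact-letter groups of mutually indistinguishable marginal means,
and the Cox–Snell slope near 1 says the proportional-hazards fit is
consistent with how the data were generated. Full tables (`emmeans_cld_*`,
`anova_*`, `curves_*`, `segregation_tau_*`, …) land in `results/`.

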