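# Methods

## The measurement model

The EMAIL-style test asks how long a peripheral 4AFC stimulus (a Landolt C
at 8° eccentricity, gap in one of four diagonal orientations, 75% contrast)
must stay on screen for an observer to identify the gap with 71%
probability. That total, the integrated saccade latency (ISL), is treated as
the sum of three serial stages: the saccadic latency T1, the saccade
duration T2, and the post-saccadic processing time T3 = ISL − (T1 + T2).
All times are milliseconds; angles are degrees of visual angle.

`emovis` implements the complete measurement-and-analysis chain and a
generative counterpart of it, so every stage can be validated by parameter
recovery on simulated observers.

## The simulated observer

A trial is correct (up to lapses) when the presentation time exceeds
T1 + T2 + τ, with τ the processing time that trial *requires*; otherwise
the observer guesses at the 4AFC chance level of 0.25. Components:

- **Latency T1**: truncated normal (at 0), default mean 123.4 ms, SD
  12.64 ms — the cohort means the "typical" preset reproduces. Only mean
  and SD are known, so a normal is the least-informative choice; a shifted
  gamma (shift 60 ms, matched moments) is available via
  `latency_family="shifted_gamma"` for skew-sensitivity checks.
- **Duration T2**: deterministic main-sequence line
  `intercept + slope × amplitude`, default 21.0 + 2.425 ms/°, i.e. 40.4 ms
  at the 8° eccentricity. The split into intercept and slope is a modeling
  choice constrained only by the 8° value.
- **Required processing time τ**: log-normal with median `t3_median`
  (default 52 ms) and log-SD `t3_spread` (default 0.24, giving a realized
  SD near 12.5 ms). A strictly positive right-skewed law is the standard
  assumption for processing-time variability; only the realized mean/SD of
  T3 are externally constrained, so the generative law is flagged as a
  modeling decision.
- **Lapse rate** in [0, 0.06]: on a "seen" trial the response is correct
  with probability 1 − λ. **Guess rate** fixed at 0.25 — every task here is
  4AFC. **Blink rate** (default 0.05/trial) produces a 50–150 ms validity
  dropout with NaN positions, as a video tracker reports. **Anticipatory
  rate** (default 0.02) replaces the latency by U(20, 60) ms, producing the
  trials the < 60 ms rule must catch.

`ObserverModel.p_correct(t)` gives the closed-form trial-level accuracy by
quadrature over the latency mixture and the τ distribution;
`ObserverModel.true_isl()` inverts it. These are the recovery targets for
the staircase, detection and fitting stages.

The gaze trace embeds fixation noise (Gaussian, SD 0.05° per axis), a
minimum-jerk displacement to ±8° over T2 (any smooth monotone profile
preserves onset/offset detectability; minimum-jerk has a realistic velocity
peak of ~1.88·A/T2 ≈ 375°/s at 8°/40 ms), and the blink gap. Timestamps are
exactly uniform at 1000 Hz by construction.

What the generator does **not** emulate: saccadic under/overshoot and
corrective saccades, drift and microsaccades during fixation, pupil-size
artefacts around blinks, main-sequence variability of T2, and any
dependence of the response on where the eye actually lands. Passing
recovery tests therefore shows the pipeline is correct under clean
single-saccade kinematics, not that it is robust to every tracker artefact.

## Staircase

2-down/1-up with variable step sizes: two consecutive correct responses
make the task harder (level down), every error makes it easier (level up).
Levels are task units where larger = easier (arcmin gap, % contrast, ms
duration) — one sign convention across tasks avoids the classic direction
bug. The equilibrium satisfies p² = ½, so the long-run accuracy is
√0.5 ≈ 70.7%, the "71%" criterion.

Unreported protocol details are package defaults, config-exposed: initial
step 25% of the start level, halved after each of the first 4 reversals
then constant; termination at 10 reversals or 80 trials; threshold = mean
of the last 6 reversals. Degenerate runs (too few reversals) return flagged
estimates with a diagnostic rather than raising. Acuity staircases can run
on a log grid (`scale="log"`), the natural spacing for acuity steps.

The convergence checks use an explicit Markov chain on the (level, counter)
state space — stationary accuracy within 0.01 of √0.5 — and a free-running
Monte-Carlo staircase with a constant 2 ms step, which sustains the same
accuracy over 10⁵ trials.

## Saccade detection

Savitzky–Golay differentiation (quadratic, 11 ms window scaled to the
sample rate) gives 2-D speed; an event opens above 30°/s and its edges are
refined outward to 10°/s, a dual-threshold scheme that reports onsets near
the true movement start instead of the main-threshold crossing. Events
shorter than 8 ms, or overlapping a blink guard interval (invalid runs
± 50 ms, merged), are discarded. The derivative polynomial order of 2 keeps
the noise gain low enough that fixation noise of 0.05° produces no false
events at these thresholds.

T1/T2 come from the first saccade toward the target side with amplitude
≥ half the eccentricity (microsaccade veto). Exclusion precedence is fixed —
blink > anticipatory (< 60 ms) > no_saccade > incorrect_response — so
exclusion reasons are deterministic. At 1000 Hz the detector recovers
injected onsets with median |error| < 1 ms and durations within 4 ms;
halving the sample rate moves the median onset by ≤ 2 ms.

Whether the original custom detector used velocity or acceleration criteria
is unknowable; velocity was chosen as the field's default, and every
threshold is configurable.

## Psychometric fit

Binomial maximum likelihood of the chance-corrected Weibull with γ = 0.25
fixed and λ either fixed at 0.01 (default — stabilizes the slope at modest
n) or free in [0, 0.06]. Optimization is a fixed grid of starts (duration
quartiles × β ∈ {1, 2, 4, 8, 16}) polished by L-BFGS-B; best likelihood
wins, ties broken by smaller α, so fits are bit-reproducible. All-correct
or at-chance data are flagged degenerate instead of producing a spurious
threshold.

The ISL is the numerical inversion of the fitted function at the criterion.
The 0.71 criterion is applied on the **raw** probability scale by default
(the staircase converges at ~71% raw correct); applying it on the
chance-adjusted scale is a config switch, since the original description is
ambiguous between the two readings. For λ = 0 the closed form
α(−ln(1 − (c − γ)/(1 − γ)))^(1/β) is the test oracle; the inversion matches
it to 10⁻⁶ ms.

GOF — used as a response-variability index, not a model-selection statistic
— has no published formula, so the package defines it as the n-weighted R²
between observed and fitted chance-adjusted proportions, floored at 0; a
binomial-deviance alternative (1 − D/D₀) sits behind `method="deviance"` so
variability conclusions can be checked under both definitions. With only
trial counts changing (50 vs 10 per bin), mean GOF rises with n, which is
exactly the scatter-sensitivity the index is meant to capture.

Fitting uses only artifact-free trials (blinks, anticipatory saccades
removed); incorrect responses are data — correctness is the response
variable. The T1/T2 means that enter the decomposition use only correct,
artifact-free trials, per the measurement protocol. Fixed programmed
durations bin exactly; a 2 ms grid is available for photodiode-measured
durations.

## Cohort generation and statistics

Cohorts come from a Gaussian copula. Schizotypy subscale scores get
beta-binomial marginals matched by moments to the cohort descriptives
(positive 2.0/2.5 on 0–13, negative 2.4/2.1 on 0–13, disorganized 2.3/3.0
on 0–12 — binomial would be underdispersed); outcomes are normal with the
cohort means/SDs. Because discretization attenuates Pearson correlation,
the latent correlation for each targeted pair is inflated by the inverse of
the marginal's linear Hermite coefficient (computed by quadrature), so the
realized sample r converges to the planted target. The implied latent
matrix is validated for positive semi-definiteness before sampling.
Untargeted pairs are latently independent; real visual/oculomotor outcomes
are of course mutually correlated (ISL contains T1 + T2 + T3), so the
default cohort emulates the marginal and targeted-pair structure only.

The statistics stage: exact-count MSS-B scoring over a validated 13/13/12
item partition (the bundled item→dimension map is a placeholder keying;
only the partition is structural); winsorization of values strictly beyond
Tukey's outer fences (3 × IQR — a formula stand-in for visual
stem-and-leaf inspection), each replaced by the most extreme retained value
on its side; Pearson r with Fisher-z 95% CIs; Benjamini–Hochberg step-up
FDR applied within each outcome family (VA, CS, saccadic variables can be
separate families via config); an effect-size gate at |r| ≥ 0.30 (medium);
OLS with overall F-test and a Shapiro–Wilk residual-normality flag at
α = .05 standing in for a Q–Q precheck (exportable as a plot; the flag
never blocks the fit); and Huber M-estimation (tuning constant 1.345,
IRLS to 10⁻⁸) as the robustness confirmation. OLS and the robust fit
delegate to statsmodels; BH-FDR is implemented directly from the step-up
definition and cross-checked against statsmodels in the tests.

## Numerical choices and problem sizes

- Staircase convergence measurements use 10⁵ post-burn-in trials with a
  constant 2 ms step; a step much larger than the local slope of the
  psychometric function would bias the long-run accuracy upward.
- Detection recovery suites use 1000 synthetic trials; fit recovery uses
  8 durations × 10⁴ trials; cohort recovery uses n = 2000 and a Fisher-z
  95% acceptance band. Null-calibration suites use 200 replicates. These
  sizes put Monte-Carlo error comfortably inside each tolerance while the
  full suite stays fast.
- All stochastic operations consume an explicit `numpy.random.Generator`;
  nothing touches the global RNG state.

## Known limitations

- The age-normed VA table ships only as a synthetic uniform stub (cohort
  mean median/UNL per polarity applied to all ages); analyses against it
  are non-normative until a real table is supplied via CSV.
- The GOF definition, the staircase step schedule/termination, and the
  saccade-detection mechanics are package choices where the original
  protocol is unreported; all are config-exposed and labelled as such
  above.
- Published cohort-level correlations and regression tables from real
  participants are not reproducible from scratch (no raw data); the
  statistics stage is validated by planted-effect recovery and calibration
  instead.
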