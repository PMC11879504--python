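# emovis

Adaptive psychophysics, saccade analysis and cohort statistics for
integrated-saccade-latency (EMAIL-style) vision testing.

`emovis` is aimed at visual-psychophysics and oculomotor researchers who
measure how long an observer needs a peripheral stimulus on screen in order
to find it, foveate it, and identify a detail of it. The total time — the
**integrated saccade latency (ISL)** — decomposes into

    ISL = T1 + T2 + T3

where **T1** is the saccadic latency (target onset to saccade start), **T2**
the saccade duration, and **T3** the post-saccadic processing time still
available before the stimulus disappears. The package provides:

- **`emovis.synthetic`** — simulated observers (latency, duration and
  processing-time distributions, lapses, blinks, anticipatory saccades),
  per-trial gaze traces at 1000 Hz, and synthetic cohorts with planted
  correlations between schizotypy dimension scores and visual outcomes.
- **`emovis.staircase`** — the 4AFC 2-down/1-up staircase with variable step
  sizes. The rule equilibrates where `P(correct)^2 = 1/2`, i.e. at the
  `sqrt(0.5) ≈ 70.7%`-correct level ("71% threshold").
- **`emovis.saccades`** — velocity-based saccade and blink detection on gaze
  traces, with per-trial T1/T2 extraction and the protocol's exclusion rules
  (blinks, anticipatory latencies < 60 ms, absent target-directed saccades,
  incorrect responses).
- **`emovis.psychometrics`** — maximum-likelihood fitting of the
  chance-corrected Weibull

      P(t) = γ + (1 − γ − λ) (1 − exp(−(t/α)^β)),  γ = 0.25 (4AFC)

  inversion to the 71% ISL, a goodness-of-fit (GOF) response-variability
  index, and the T3 = ISL − (T1 + T2) decomposition.
- **`emovis.acuity`** — Weber contrast, visual-acuity / contrast-sensitivity
  threshold assembly per optotype polarity, and comparison against
  age-normed VA medians (a synthetic uniform stub ships; real norms load
  from CSV).
- **`emovis.stats`** — MSS-B questionnaire scoring (13/13/12 items),
  Tukey-fence winsorization, Pearson correlations with Fisher-z CIs,
  Benjamini–Hochberg FDR per outcome family, a medium-effect gate
  (|r| ≥ 0.30), multiple OLS regression and Huber robust regression.
- **`emovis` CLI** — `simulate`, `detect`, `fit`, `analyze`, `report`
  subcommands driven by one YAML configuration and one seed.

## Worked example

Simulate a typical observer through three fixed-duration runs of 50
presentations each, detect its saccades, fit the psychometric function and
decompose the ISL:

```bash
emovis analyze --seed 11 --out run/
```

prints (output of this exact command):

```
ISL = 225.2 ms = T1 122.2 + T2 40.8 + T3 62.3; exclusions {'anticipatory': 5, 'blink': 7, 'incorrect_response': 61, 'none': 77}
```

The observer's generative truth puts its 71%-correct duration near 222 ms
with mean latency 123.4 ms and saccade duration 40.4 ms at 8° eccentricity,
so the fitted ISL, the detected T1/T2 means, and the residual T3 all land
where the generative model says they should. `run/table1.csv` holds the
descriptive block (mean, SD) for T1, T2, T1+T2, ISL and T3;
`run/summary.json` the fit parameters, decomposition and exclusion counts.

For the cohort stage:

```python
from emovis import CohortSpec, simulate_cohort, correlation_table

cohort = simulate_cohort(CohortSpec(
    n_participants=2000,
    target_correlations={("disorganized", "va_neg_arcmin"): 0.41},
    seed=17,
))
print(correlation_table(cohort, ["disorganized"], ["va_neg_arcmin"])
      [["r", "ci_low", "ci_high", "p_fdr", "significant"]].round(3))
```

```
       r  ci_low  ci_high  p_fdr  significant
0  0.422   0.386    0.458    0.0         True
```

The planted disorganized-schizotypy/acuity correlation of 0.41 is recovered
within its Fisher-z sampling band, passes the medium-effect gate, and
survives FDR correction.

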