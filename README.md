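# naaglm

Point-process GLM analysis of **nocturnal arrhythmia avalanches (NAA)** —
transient runs of shortened heartbeats during sleep — from polysomnographic
R-R interval series.

NAA episodes are detected as R-R intervals dropping more than 30% below the
local baseline (the mean R-R in the enclosing 10-min window) and ending once
the interval recovers to 90% of that baseline. Their occurrence is then
modelled as a discrete-time point process whose conditional intensity
λ(t | H_t) depends on sleep stage, concurrent sleep-disordered-breathing
(SDB) and arousal events, and the time elapsed since the previous episode:

    log λ(t | H_t) = β_SDB · I_SDB(t) + β_Ar · I_Ar(t)
                     + Σ_{s ∈ SS} β_s · I_s(t)
                     + Σ_{k=1..K} h_k · g_k(H_t)

with SS = {wake, light NREM, deep NREM, REM} partitioning time (the stage
term plays the intercept role), indicator covariates for scored SDB and
arousal intervals, and a cardinal-spline basis g_k (tension 0.5, knots over
0–120 s of lag) smoothing the event-history filter. Time is binned at 1 s
and the likelihood is Bernoulli with a log link — numerically equivalent to
the Poisson reading at the per-mille per-bin probabilities involved —
maximised by Newton's method with step halving; the coefficient covariance
is the inverse observed information.

From a fitted model the package derives:

- **multipliers** exp(β_SDB), exp(β_Ar): rate ratios while an SDB/arousal
  event overlaps the bin;
- the **history-modulation curve** exp(Σ h_k g_k(lag)) with delta-method 95%
  bounds, summarised by the refractory period, increased-propensity (IP)
  period duration, and IP peak height/lag/width;
- **goodness of fit** by the time-rescaling theorem: rescaled inter-event
  intervals are tested against Uniform(0, 1) with the KS statistic and its
  sample-size-dependent critical value;
- **cohort statistics**: multiplier CDFs and classification fractions,
  Welch-t/ANOVA/ANCOVA on features, label-permutation tests on whole
  modulation curves, and exposure-weighted χ² stage-rate contrasts.

Access to clinical polysomnography is restricted, so the package ships a
first-class synthetic-night generator (`naaglm.simulate`): a semi-Markov
sleep-stage chain, stage-conditional Poisson SDB/arousal interval processes,
an avalanche train drawn forward from a known ground-truth GLM, an R-R
series with each avalanche embedded as a detectable ≥30% drop, and a
template ECG with known R-peak times for exercising the Pan-Tompkins QRS
detector and signal-quality screening (`naaglm.ecg`).

## Worked example

```python
import numpy as np, naaglm as na

model = na.TrueModel.from_rates_per_hour(
    {na.StageCode.WAKE: 4, na.StageCode.LIGHT: 10,
     na.StageCode.DEEP: 5, na.StageCode.REM: 8},
    beta_sdb=np.log(2.0), beta_ar=np.log(1.5),
    history_curve=na.gaussian_bump(peak=2.0, peak_lag_s=15.0, width_s=5.0),
)
night = na.simulate_night(na.SimConfig(), model, seed=42)

train = na.AvalancheDetector().detect(night.rr.rr)
rates = na.stage_rates(train, night.hypnogram)
print(f"detected {len(train)} avalanches; overall rate {rates['overall']:.1f}/h")

fit = na.PointProcessGLM().fit_night(train, night.hypnogram, night.events)
print(f"SDB multiplier {fit.sdb_multiplier_:.2f}  "
      f"arousal multiplier {fit.arousal_multiplier_:.2f}")

curve = na.modulation_curve(fit)
feats = na.extract_features(curve)
print(f"IP peak {feats.ip_peak_height:.2f} at lag {feats.ip_peak_lag_s:.1f} s")

intensity = fit.predict_intensity(fit.design_)
m = fit.design_.include
intensity.lam, intensity.bin_start = intensity.lam[m], intensity.bin_start[m]
ks = na.ks_test(intensity, train, seed=0)
print(f"KS stat {ks.ks_stat:.3f} vs threshold {ks.threshold:.3f} -> "
      f"{'pass' if ks.passed else 'fail'}")
```

Output:

```
detected 89 avalanches; overall rate 11.1/h
SDB multiplier 1.58  arousal multiplier 1.18
IP peak 3.43 at lag 23.4 s
KS stat 0.074 vs threshold 0.146 -> pass
```

The detector recovers every avalanche the generator embedded. The single
night holds ~90 events, so the per-night multiplier estimates (1.58, 1.18
against truths 2.0 and 1.5) and the history-curve features carry visible
sampling noise — pooling nights tightens them, which is exactly what the
reproduction script below quantifies. The KS statistic falling below its
critical value says the fitted intensity is consistent with the observed
event times.

A command-line interface mirrors the library (`naa simulate | ecg2rr |
detect | fit | features | gof | cohort | run`); per-recording results are
written as CSV/JSON validated against the schemas in `src/naaglm/schemas/`.

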