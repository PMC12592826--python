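# Methods

## The event process and its model

A nocturnal arrhythmia avalanche (NAA) is treated as an instantaneous
event at its onset beat. Onsets form a point process on the recording
timeline; we model its conditional intensity λ(t | H_t) — the expected
event rate at time t given the episode history H_t — as a log-linear
function of sleep stage, concurrent scored events, and time since the
last episode.

Time is discretised into 1-s bins. Within a bin the event indicator is
Bernoulli with log-link probability p_t = exp(x_tᵀθ). At the avalanche
rates this package targets (roughly 4–30 events/h) p_t is of order 10⁻³,
where the Bernoulli and Poisson likelihoods agree to O(p²); 1-s bins also
make two onsets in one bin practically impossible (it is an error if it
happens — halve the bin width). Bins are half-open [start, start+width);
an onset exactly on an edge belongs to the bin on its right.

The covariate vector per bin:

- **Sleep stages.** Four one-hot indicators (wake, light NREM = stages
  1–2, deep NREM = stage 3, REM) taken from the 30-s epoch containing the
  bin midpoint. They partition time, so the model carries no separate
  intercept and each β_s is directly the log event rate per bin in that
  stage; no aliasing arises (the design is full rank on generic data, as
  the tests verify).
- **SDB and arousal.** I_SDB(t) = 1 when the bin overlaps any scored
  obstructive apnea, central apnea or hypopnea interval (pooled into one
  indicator; per-subtype indicators would be a one-line change but the
  pooled model is the default). I_Ar(t) likewise for arousals. An
  optional symmetric pad (default 0 s) can extend scored intervals
  before the overlap test; we do not assume scored intervals should
  bleed into neighbouring bins. exp(β_SDB) and exp(β_Ar) are the
  reported multipliers — rate ratios while the indicator is active.
- **History.** The filter depends on the lag since the *most recent*
  prior onset only (the lag is what the per-participant summary plots
  show on their x-axis), not a convolution over all past events. Lags
  beyond 120 s contribute nothing: the basis is identically zero there,
  and bins with no prior event within 120 s get a zero history block.
  The history uses onsets strictly before the bin's start, so an event
  never modulates its own bin.

**Analysis window.** By default the window runs from the first to the
last scored sleep epoch, inclusive of interior wake. Its first 120 s are
kept in the design but excluded from the likelihood (burn-in), so the
history filter enters estimation in a well-defined state.

## The cardinal-spline history basis

The history filter Σ h_k g_k(lag) uses cardinal (Catmull-Rom family)
splines with tension 0.5: piecewise cubics that *interpolate* their knot
coefficients, so each h_k is readable as the log modulation at its knot.
On each knot interval the curve is the cubic Hermite interpolant with
tangents

    m_i = 2 · tension · (y_{i+1} − y_{i−1}) / (t_{i+1} − t_{i−1}),

the Catmull-Rom slope on non-uniform knots at tension 0.5. Phantom
boundary knots at −5 s and +130 s supply the endpoint derivatives; their
values are linearly extrapolated from the adjacent real knots, which
collapses the boundary tangent to the one-sided difference slope and
keeps the basis a pure function of the K real-knot coefficients. The
curve is C¹ on [0, 120] s.

Knots: {0, five inner knots, 100, 120} s. The inner knots are spread
(linearly by default; log spacing is a config option) between the 10th
percentile of the observed inter-event intervals and 80 s, adapting
resolution to where the data actually carry lag information. With fewer
than two events the percentile is undefined and a fixed grid
{0, 5, 15, 30, 50, 80, 100, 120} s is used; the same grid provides the
common basis whenever several nights are pooled into one likelihood. If
the 10th percentile reaches 80 s the inner knots are compressed to the
fixed spacing with a warning.

## Fitting

Newton's method maximises the Bernoulli log-link likelihood, with step
halving so the log-likelihood never decreases; for this model the Newton
step equals the IRLS step built from the zero-event rows (event rows
contribute linearly to the log-likelihood and nothing to the curvature).
Convergence: relative log-likelihood change below 1e-8, cap 100
iterations. Initialisation solves least squares for a flat predictor at
the observed mean rate, which is always feasible (p < 1). All-zero
covariate columns (e.g. a stage that never occurs) are dropped with a
warning. If the Hessian is singular or a step cannot increase the
likelihood — separation, in practice — the fit is retried with a ridge
of 1e-4 and flagged `regularized_`. Fits with fewer than 5 events are
flagged unreliable but still returned. The covariance is the inverse
*observed* information at the optimum (for this non-canonical link it
differs from the expected information; the tests check it against a
numerical Hessian).

## Modulation curve and features

The curve exp(g(lag)ᵀh) is evaluated on a 0.1-s lag grid (a resolution
chosen so grid error is negligible against statistical error;
configurable) with pointwise 95% delta-method bounds
exp(gᵀh ± 1.96·√(gᵀΣ_h g)), Σ_h the history block of the covariance. A
non-PSD block yields curves without bounds, and the two bound-dependent
features become NaN.

Features, resolving the ambiguities in their verbal definitions:

- **Refractory period**: length of the run of upper bound < 1 *starting
  at lag 0* (0 if the upper bound starts at or above 1); an interior dip
  does not count.
- **IP duration**: length of the *first* run with lower bound ≥ 1,
  ending at the first lag where it falls strictly below 1.
- **IP peak height / lag**: global maximum of the modulation over
  [0, 120] s and its (first) argmax.
- **IP peak width**: full width at half *prominence* above the neutral
  level 1 — the span around the peak where the modulation stays at or
  above 1 + (peak − 1)/2. Half of the raw peak height is offered as
  `width_mode="half_height"`; prominence is the default because 1 means
  "no modulation", so prominence measures the bump itself. Width is 0
  for a curve that never exceeds 1.

## Goodness of fit

By the time-rescaling theorem, if the intensity is correct the rescaled
waiting times z_j = Λ(t_j) − Λ(t_{j−1}) (Λ the running-sum cumulative
intensity, linearly interpolated within bins; the first interval is
measured from the analysis-window start) are unit-exponential, so
u_j = 1 − exp(−z_j) ~ Uniform(0, 1). Because events live in 1-s bins,
each event time is first de-discretised by a uniform jitter within its
bin (toggleable, seeded). The two-sided KS statistic of the u_j against
the uniform CDF is compared with the 5% critical value: the exact
finite-n two-sided KS distribution for n < 35, the asymptotic
1.358/√n beyond. Simulation shows the true-model pass rate sits at the
nominal ~95% across synthetic nights, and that refitting without the
history columns under a strongly clustered truth collapses it.

## Cohort statistics

- **Multiplier summary**: each participant's exp(β) classified into
  (1, ∞), (ε, 1], [0, ε] with ε = 1e-3 (the near-zero class needs a
  numeric cut-off; 1e-3 means "the covariate essentially switches the
  rate off"), plus the empirical CDF.
- **Feature comparisons**: Welch's t for two groups, one-way ANOVA for
  three or more (age bins <65 / 65–75 / ≥75; BMI bins <25 / 25–30 / ≥30,
  the conventional overweight/obesity cuts), ANCOVA via an OLS model
  `feature ~ group + covariates` (type-II F for the group effect,
  covariate-adjusted means at the covariate mean).
- **Curve permutation test**: observed statistic = mean over the lag
  grid of the pointwise group statistic — |t| (pooled variance) for two
  groups, F for more; the absolute value makes the two-group test
  two-sided under the one-tailed permutation p-value
  (1 + #{perm ≥ obs}) / (n_perm + 1), which is valid by construction.
  The max-over-lags variant and the 95th-percentile permutation envelope
  of the pointwise statistic are returned for global pointwise bounds.
- **Stage-rate contrasts** (light vs deep, light vs REM, sleep vs wake):
  pooled event counts tested with an exposure-weighted χ² — expected
  counts proportional to pooled stage exposure, since raw counts
  confound rate with time in stage — plus a paired t-test on
  per-participant rates as a heterogeneity-robust companion.
  Participants lacking exposure to a side of a contrast are excluded
  from that contrast.

## The synthetic-night generator

The generator emulates the *structure* of scored polysomnography, not
its physiology; it exists so every stage has exact ground truth.

- **Hypnogram**: first-order semi-Markov chain over 30-s epochs;
  geometric dwell times (means: wake 10, light 20, deep 10, REM 14
  epochs) and an embedded transition matrix with a typical
  wake→light→deep→REM cycling structure. Default duration 8 h, start in
  wake. Long-run occupancy follows from the embedded chain's stationary
  vector weighted by mean dwell (checked against eigen-analysis).
- **Scored events**: stage-conditional homogeneous Poisson onsets (SDB:
  25/18/8/2 per hour of light/REM-ish stages — see `SimConfig` for the
  exact map; arousals similarly), lognormal durations (SDB median 20 s,
  arousal median 10 s, log-SD 0.4 — typical scored-event durations),
  same-kind overlaps merged. SDB onsets are OSA/hypopnea/CSA in a
  70/25/5 mix, matching the predominance of obstructive events in
  clinical cohorts.
- **Avalanche train**: forward Bernoulli simulation of the GLM itself,
  bin by bin, with the history looked up at the whole-bin lag to the
  last drawn event; a warning fires if any per-bin probability exceeds
  0.5 (the discrete approximation degrades). Event times are recorded at
  bin midpoints.
- **R-R series**: baseline 1.0 s with 2% Gaussian jitter (estimable
  baselines, non-trivial detection). Each avalanche is embedded as three
  descending beats, a 4-beat plateau at (1 − depth) × baseline (default
  depth 0.35), and a two-beat recovery ending at 0.95 × baseline —
  the thresholds are what matter to the detector; the waveform is a
  convenience. The recorded "embedded onset" is the first full-depth
  beat, which is the beat the detector's 30%-drop rule fires on (one
  beat of tolerance covers deep avalanches whose descent already
  crosses the threshold). Onsets arriving before the previous avalanche
  has recovered are skipped with a warning.
- **ECG**: one Gaussian QRS bump (σ = 10 ms) per beat at 256 Hz plus
  optional white noise; true R-peak times are returned alongside. No
  P/T waves, ectopy morphology or baseline wander — the signal validates
  detector timing logic, not morphology handling.

What passing on this generator shows — and does not. Detection,
fitting, rescaling and feature extraction are exercised against exact
ground truth under the model's own assumptions. Real recordings add
baseline drift, ectopy, scorer disagreement and history structure
outside the spline span; results here bound implementation correctness,
not clinical performance.

## Validation experiment sizes

The reproduction script (`scripts/acceptance.py`) and the heavier tests
use: 100 four-hour nights per detector round-trip arm (≥ 0.35-depth
recall, 0.25-depth false alarms); 1000 random lags for the spline
oracle; three ≤ 2000-row designs for the optimiser oracle; 50 eight-hour
nights for parameter recovery — per-night fits give the multiplier
means and Wald-interval coverage (pooled over the two multipliers), and
one likelihood stacked over all 50 nights with the fixed knot grid gives
the history-bump peak lag, since a single night's ~60 events cannot
localise a 5-s-wide bump to seconds; 200 nights for KS calibration and
60 paired fits for its power comparison; 200 null cohorts (n_perm = 199)
for permutation validity and 100 shifted cohorts for power; 300 beats
for Pan-Tompkins accuracy. These sizes put Monte-Carlo error comfortably
inside the asserted bands while keeping a full run to a couple of
minutes.

## ECG processing choices

Pan-Tompkins with the canonical constants: 5–15 Hz band-pass (3rd-order
Butterworth, applied zero-phase so fiducials need no group-delay
correction), derivative, squaring, 150-ms moving-window integration,
adaptive dual thresholds with 0.125/0.875 running updates (0.25/0.75 on
search-back), search-back at 1.66 × the running R-R average, 200-ms
refractory. The R time is refined to the band-passed extremum within
±75 ms of each accepted integrator peak. Quality screening per 10-s
segment combines: agreement between Pan-Tompkins and an independent
amplitude-threshold detector (bSQI ≥ 0.8, 150-ms matching), the longest
constant run as a flatline fraction (< 0.2 — a run-based definition so
an isoelectric baseline between beats does not trip it), sustained
dwelling at the extreme deviation as a saturation fraction (< 0.2), and
kurtosis ≥ 2 (QRS-dominated segments are heavy-tailed; white noise is
not). A trailing partial segment inherits its neighbour's flag.
R-R assembly drops intervals with either endpoint in a BAD segment and
intervals outside [0.3, 3.0] s — wide enough to keep true 30% avalanche
drops, tight enough to remove missed/false beats.

## Known limitations

- Baseline windows include in-episode beats; a very high avalanche
  burden therefore depresses baselines slightly. Documented, not
  corrected.
- The history filter uses the last event only; genuinely cumulative
  excitation would need a convolutional filter.
- Wald intervals at ~60 events per night are near-calibrated but
  slightly conservative; per-night history curves are noisy at lags
  with little data (the long-lag knots), which is why pooled fits are
  preferred for curve-shape inference.
- The Bernoulli-in-bins construction caps the intensity at 1 event per
  bin; models implying per-bin probabilities near 1 are outside scope
  (a warning fires at 0.5).
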