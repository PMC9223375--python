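# Methods

## Scope and model

The package studies whether wearable physiological signals improve
thermal-sensation (TS) prediction over Fanger's PMV in a controlled chamber
setting. Because no public recording of such a cohort is available, the
first-class component is a simulator whose outputs carry the statistical
structure the downstream analysis assumes; every later stage (feature
extraction, quality screening, wrapper selection, evaluation) operates
identically on simulated or user-supplied data in the same CSV schema.

## Synthetic cohort

**Design.** Twenty subjects (9 male : 11 female) each experience all eight
settings of the 2×2×2 factorial — air temperature 23/27 °C, relative
humidity 60/80 %, fan level breeze/strong — in a per-subject randomized
order. Fan levels map to air speeds of 0.3 and 0.9 m/s, typical of ceiling
fans and inside the PMV validity envelope.

**Latent vote.** Each trial's latent TS is linear in the environment
factors plus a Gaussian subject intercept and trial noise:

    ts* = β_T (T−25) + β_v (v−0.6) + β_RH (RH−70) + b_subject + ε

with defaults β_T = 0.35 /°C, β_v = 0.7 /(m/s), β_RH = −0.01 /%,
sd(b) = 0.6, sd(ε) = 0.8. The reported vote rounds half-away-from-zero and
clips to ±3. The defaults were set so the pooled feature–vote correlations
land near the magnitudes a chamber study of this size reports (air
temperature ≈ 0.5, calf temperature ≈ 0.55–0.65, EEG beta ≈ 0.4,
EMG ≈ −0.2 to −0.3, SDNN ≈ −0.2, RH weak and non-significant).

**Signals.** All responses are phenomenological, with directions fixed by
the known physiology of the sedentary cool-to-warm range:

* *RR series*: RR(t) = 800 + A_LF sin(2π·0.10 t) + A_HF sin(2π·0.30 t) +
  jitter ms, emitted beat by beat. Amplitudes are solved so the LF/HF
  band-power ratio equals the "smile" curve c₀ + c₁·ts² (low at neutral,
  high at either extreme; c₀ = 1.2, c₁ = 0.3) and the interval SD matches
  an SDNN target of (50 − 2.5·ts) ms scaled by a subject gain. A fifth of
  the SDNN budget is white jitter.
* *EMG*: band-limited (20 Hz–Nyquist) Gaussian noise with amplitude
  σ₀·exp(−0.12·ts) — more muscle tone when cold.
* *EEG*: fixed-gain alpha (8–13 Hz), beta (13–30 Hz) whose gain rises with
  ts, and a 1–40 Hz broadband floor.
* *GSR*: tonic level 4 − 0.12·ts µS plus slow (<1 Hz) drift.
* *Skin temperatures*: baseline + slope·ts + AR(1) wander; the chest
  (core-like) slope 0.10 °C/TS is below the calf's 0.15 °C/TS.

**Trial-level variability.** Each trial draws lognormal gain jitter for the
EMG amplitude, each EEG band, and the GSR tonic level, and a Gaussian
reattachment offset per temperature site; subject temperature baselines are
drawn independently per site. Without these, band-power ratios and
between-site temperature contrasts become nearly noiseless functions of the
latent vote — a leakage channel absent from real recordings, which the
development history of this package showed a Gaussian-process selector will
exploit. The "null model" property test (all response slopes zero ⇒ no
feature correlates with TS) guards the same channel from the other side.

**Corruption and attrition.** With probability 0.4375 a trial has one
random modality damaged by clipping (saturation at the inner deciles),
flatline (second half constant), or added broadband noise (narrowband
modalities only — EMG's physiological band reaches nearly to Nyquist, so
out-of-band power carries no information there, and an interval series has
no meaningful broadband mode). One damaged modality voids the whole trial,
so of 160 trials about 90 survive, the attrition a study of this kind
reports. The screen's thresholds (flatline: ≥45 % of 1-s chunks with
variance below 10⁻¹²; clipping: ≥10 % of samples within 0.1 % of a rail;
low SNR: out-of-band/in-band power ratio > 0.15) separate the clean and
corrupted populations with no observed overlap at these settings; the 0.45
flatline fraction absorbs chunk quantization of an exactly-half flatline.

**Seeding.** One root seed feeds named child streams per (subject, setting,
modality), so regenerating one modality never shifts another, and equal
(config, seed) pairs give byte-identical serialized cohorts.

## Feature extraction

Features are computed on the trailing 5-minute window. Filters are 4th-order
Butterworth applied forward–backward (zero phase); 1 s at each end of a
filtered window is discarded against edge transients. Band conventions the
source material leaves open were fixed as: EEG alpha 8–13 Hz, beta
13–30 Hz, broadband 1–40 Hz (clinical convention); EMG high-pass 20 Hz
(band-pass 20–450 Hz when the sampling rate permits); HRV total band
0.003–0.4 Hz, so LF and HF relative powers share a denominator without
summing to one. The HRV spectrum is an averaged periodogram (Welch, 120-s
segments, 50 % overlap) of the tachogram cubic-spline-resampled to 4 Hz and
mean-detrended — linear resampling was rejected because its sinc² roll-off
attenuates the HF band by ~30 % at typical beat rates. "EEG average" is the
mean absolute amplitude of the broadband-filtered signal: a plain mean is
≈0 after any high-pass and could not carry a correlation with TS.

Degenerate spectral inputs (constant RR series, zero EEG power) yield NaN
with a warning rather than an exception, so one dead derived quantity does
not discard a trial's remaining features. Trials failing the quality screen
are refused unless explicitly overridden.

## PMV baseline

The Fanger equation set is implemented from the ISO 7730 formulation:
saturation vapour pressure exp(16.6536 − 4030.183/(t+235)) kPa; clothing
surface temperature solved by the standard's damped fixed-point iteration
(tolerance 10⁻⁴ °C, max 150 steps, non-convergence raised with the
residual). Chamber conventions: tᵣ = tₐ (uniform room), 1.0 met seated,
0.5 clo summer clothing. PMV values are **not** clipped to ±3 — clipping
would silently shrink the baseline's RMSE on strongly cool conditions. The
test suite checks parity within ±0.01 PMV against an independently coded
solver of the same equations (bracketing root-finder on the unscaled heat
balance, written separately from the package route) over a 405-point grid,
plus strict monotonicity in temperature.

## Selection engine

Stage 1 grows the combination from empty: every unselected feature is
appended to the running best set, candidates are scored, the best is kept
while it improves the overall best; the first non-improving round stops the
stage. Stage 2 tries removing each single feature; an improving removal is
committed and resets the worse-step counter, one non-improving round is
tolerated (the next round removes from the *worse* combination — the more
exploratory of the two readings the stage-2 rule admits), and the second
consecutive non-improving round since the last improvement terminates.

Scoring is repeated k-fold cross-validation — 5 folds × 3 repeats with a
fixed seed, mean per-fold RMSE as the criterion, pooled out-of-fold R²
reported alongside; the empty set scores as the mean predictor. The inner
protocol is the largest genuinely open choice in the procedure and is
isolated behind a `Protocol` value so alternatives plug in. "Better" is
strictly lower RMSE, ties broken toward fewer features then lexicographic
order, making runs bit-reproducible; on mocked performance lookups the
engine's decisions match hand-simulated traces exactly and equal exhaustive
search on additive landscapes.

Backends: ordinary least squares; Gaussian process with constant×RBF +
white-noise kernel, hyperparameters by marginal-likelihood optimization
(L-BFGS capped at 30 iterations — selection fits thousands of GPs);
RBF-kernel SVR (ε = 0.1); depth-5 decision tree. Kernel methods see z-scored
features (training-fold statistics); linear and tree fits use raw values.
Environment features compete on equal footing with physiological ones.

## Evaluation suite

Out-of-sample R² is 1 − SS_res/SS_tot on the evaluation rows and may be
negative. The PMV comparison resamples a 4:1 train/test split (72/18 on a
90-row table) three times, retrains the model on the selected features, and
scores PMV on the same test rows without training. The gender analysis
stratifies the split by sex (four fifths of each group to training),
compares signed errors with a pooled-variance t-test (Welch behind a flag)
and a tie-corrected normal-approximation Mann–Whitney U reported as Z
(scipy's exact method behind a flag for small tie-free samples); a
calibration utility confirms the t-test's type-I rate sits at the nominal
5 % under the null. Signal ranking starts from environment-only features
and greedily adds whole signal-wise groups (EMG, body temperature, ECG,
EEG — the groups a selected combination typically retains), ties broken by
declared group order.

## Problem sizes and reduced geometry

`GeneratorConfig.compact()` keeps the full 20×8 design and the 5-minute
analysis window but trims trials to 5.5 minutes and lowers sampling rates
(EMG 250 Hz, EEG 128 Hz, GSR 16 Hz). Every statistical property of the
cohort — correlations, recovery errors, attrition — is unchanged, and the
whole pipeline runs in minutes on one CPU; the full-rate default
(15-minute trials, EMG 1 kHz) remains available. Tests and the acceptance
script use the compact geometry.

## Known limitations

* All responses load on a single scalar latent vote; real signals carry
  rich structure (circadian drift, motion artifacts, inter-signal coupling)
  that no test here can certify. Passing tests show the *pipeline* recovers
  what the generator injects, not that the generator matches human data.
* The corruption taxonomy is generic (no blink/EMG-bleed EEG artifacts).
* The wrapper's selected set on simulated cohorts is typically smaller than
  on real data: with one latent factor, a strong temperature feature
  saturates the criterion quickly and weaker-family features add little
  beyond cross-validation noise.
* Greedy wrapper selection occasionally (order 10–15 % of seeds) retains a
  single pure-noise feature through a chance cross-validation improvement;
  more CV repeats shrink but do not eliminate this, which is worth
  remembering when reading any single selected combination.
* Whether the GSR feature should be conductance or resistance is left as
  conductance (µS); the EEG "average" amplitude-vs-power ambiguity is
  resolved as amplitude.
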