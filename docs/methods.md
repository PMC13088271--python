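# Methods

## Signal model and coupling procedure

The package treats cuffless BP estimation as a four-stage pipeline on
uniformly sampled, time-aligned ECG and PPG channels sharing one clock.

**Preprocessing.** Both channels pass a zero-phase band-pass filter
(4th-order Butterworth run forward–backward via `sosfiltfilt`, ~1 s of
reflected padding against edge transients). The band is 0.5–40 Hz:
the low cut removes baseline drift, the high cut retains the QRS complex.
The filter family and order are design choices — only the band and the
zero-phase property are essential, since any group delay would bias PTT.
The PPG is then rescaled so that its robust amplitude (median per-beat
peak-to-trough span) is `amp_ratio` (default 2.0) times the robust ECG R
amplitude (median of prominent-peak heights); at this ratio, α = 0.5 and
β = 1 leave both signals' features legible in the fused waveform.

**R detection and sparsification.** R waves are found by a
dynamic-threshold difference method: the rectified first difference is
compared against `c` (default 0.4) times a per-beat peak tracker that
decays by λ = 0.98 per beat (seeded from the first 2 s), each crossing is
refined to the local ECG maximum within ±50 ms, a 0.25 s refractory period
enforces a 240 bpm ceiling, ties break to the earliest sample, and
candidates whose refinement window touches the record edge are discarded
(filter transients are not provable local maxima). The ECG is then zeroed
outside ±30 ms of each R peak. Sparsification serves two purposes: the
Q/S deflections cannot perturb the phase of the coupled waveform, and the
preserved R samples are bit-exact temporal anchors.

**Coupling and fiducial detection.** The coupled signal is
α·PPG + β·ECG_sparse, sample for sample. For each RR interval the onset
search window spans 0.1–0.9 of the interval — the physiological range of
the R→foot lag — and windows are half-open in samples with 0-based
indices. The onset (pulse foot) is localized in three steps: (1) the
window argmin, which always lands in the foot region because the dicrotic
notch sits far above the foot; (2) the systolic upstroke, taken as the
derivative maximum within 0.35 s after that minimum — long enough to cover
any physiologic systolic rise, short enough to exclude the dicrotic limb;
(3) the foot itself, the last non-positive derivative sample before the
upstroke, snapped to the sampled minimum within the following two samples.
A plain argmin is biased early under broadband noise (the end-diastolic
approach to the foot is nearly flat, so noise moves the argmin along the
run-in), whereas the decay-to-rise handover sits in a high-curvature
region and stays put; on noise-free pulses the two definitions coincide
to within one sample. The systolic peak is the argmax between the onset
and the start of the next R wave's preserved support (a 30 ms guard —
inside the support the waveform is ECG-dominated by construction, and the
R spike's rising edge would otherwise masquerade as the systolic peak).
Beats whose window is degenerate (too few samples, flat) or whose
extremum lies on a window boundary are flagged missing rather than
guessed; every emitted onset is hard-asserted to obey the window bounds.

**Features and BP models.** Per complete beat: RR, PTT = onset − R,
T = peak − onset, and PIR, the ratio of PPG intensity at the systolic
peak to that at the onset. PIR is read from the PPG component
reconstructed as (coupled − β·ECG_sparse)/α so the ECG spike never
contaminates it. Band-passed signals have no absolute intensity
baseline, so the pipeline restores one before forming the ratio: the
component is shifted to its 1st percentile and a pseudo-DC of twice the
median pulse amplitude is added to numerator and denominator (the
`baseline_restored` mode; the `direct` mode divides amplitudes as given
and skips beats with non-positive onset amplitude). Features are averaged
over a 10 s trailing window emitted every 5 s (windows with fewer than
3 beats are skipped), augmented with 1/PTT and ln PTT, and joined with
sex, age and weight. Reference BP readings per subject are screened by
Tukey's fence (k = 1.5 on the quartiles). Subjects are split train/test
8:2 within mean-PTT tertiles (largest-remainder allocation of the test
quota; tiers of fewer than two subjects merge with a neighbour), so no
subject contributes rows to both sets. Separate XGBoost regressors for
SBP and DBP are tuned by a tree-structured Parzen estimator
(`ppgecg.tpe`, written for this package: Parzen mixtures with a
Scott-style bandwidth floor and a uniform exploration component, γ = 0.25
split, 10 random start-up trials, 24 candidates per dimension, fully
seeded) over nine hyperparameters — trees 50–600, learning rate
0.005–0.3 (log), depth 2–8, min child weight 1–10, L1/L2 1e-8–10 (log),
gamma 0–5, subsample and feature-sampling ratios 0.5–1 — with mean R²
under 5-fold subject-grouped CV as the objective; the best configuration
is refit on all training rows. Predictions are clipped to 30–250 mmHg
with a flag; mean BP is reported as DBP + (SBP − DBP)/3, the standard
clinical estimate.

## Comparator methods

Two PPG-only detectors represent conventional single-channel processing.
*Local extrema*: systolic peaks are local maxima (minimum spacing 0.3 s)
exceeding half the rolling 75th percentile of recent peak heights; onsets
are the minimum in a 0.5 s lookback. *Adaptive derivative*: upstrokes are
runs where the first derivative exceeds 0.4 of its rolling (2 s) maximum,
with a 0.3 s refractory; the onset is the preceding zero-crossing of the
derivative (a second-derivative-maximum variant is available behind
`onset_mode`), the peak the next downward crossing. Neither accepts an
ECG argument, so R anchoring is impossible by interface. PTT pairing is
greedy first-match: each R claims the first unclaimed onset within
0.9 RR, so a missed onset leaves its R unpaired or steals the next beat's
onset — the documented failure mode of unanchored detection. Every
constant is a config key; the comparison is parameter-transparent.

## What the simulator emulates — and what it does not

Each subject draws a heart rate (N(75, 8) bpm clipped to 55–100), a mean
R→foot lag (N(0.20, 0.03) s clipped to 0.15–0.30 — within the coupling
method's stated 0.1–0.9 RR operating envelope at these rates), and
demographics (age N(29.5, 9.4) years, weight N(70, 12) kg, sex by fair
coin). Inter-beat intervals are truncated-normal (mean 60/HR, SD from the
HR variability by the delta method, truncated to 0.3–2.0 s), R times are
snapped to the sample grid, and the default rate is 500 Hz (configurable;
no particular hardware rate is assumed). The ECG renders each cycle as
five Gaussian bumps (P, Q, R, S, T) with the R bump dominant. The PPG
pulse is a monotone PCHIP spline through physiologic control points —
foot (zero), 42 % at 40 % of the rise, systolic peak at `t_sys`
(default 0.15 s), dicrotic notch (45 % of pulse height), dicrotic wave
(notch + prominence), then a decay that is largely complete by 70 % of
the segment and approaches the next foot through a near-baseline
plateau. The spline places the unique interior minimum exactly at the
annotated foot and the maximum exactly at the annotated peak, which is
what makes the ±1-sample clean-signal oracle exact. The beat-level lag is
mean + slow sinusoidal drift (±0.02 s over 60 s, emulating within-session
BP variation) + i.i.d. jitter (SD 12 ms), truncated to (0.05 s, 0.9 RR).
Pulse amplitudes carry respiratory modulation (depth 0.25, period 4 s ≈
15 breaths/min by default); the default cohort additionally draws
per-subject morphology (rise time 0.10–0.22 s, notch depth 0.35–0.60,
dicrotic prominence 0.02–0.28, modulation depth 0.10–0.45), because a
cohort of identical waveforms would misrepresent the inter-individual
variety that fiducial detectors must cope with. Named presets pin single
morphologies (narrow/wide pulse, prominent/damped dicrotic, steady or
strongly modulated amplitude) for per-morphology evaluation.

Noise comprises sinusoidal baseline wander (0.2–0.4 Hz, default amplitude
0.10 of the normalized signal), white Gaussian noise (default SD 0.03),
and Poisson-placed half-sine motion transients (0.1–0.3 s, 2–4× signal
SD, default 1 event/min — a seated-rest rate; ambulatory stress levels
are one config key away). The generative BP model is
BP = c₀ + c₁/PTT + c₂·RR + c₃·PIR + c₄·age + ε with
SBP coefficients (71, 8, −10, 4, 0.3) and DBP (49, 4, −5, 2, 0.2),
centring SBP near 120 and DBP near 75 mmHg at the default operating point
with ~2 mmHg sensitivity per 10 ms of PTT; ε is redrawn if a sample would
invert SBP > DBP, and a coefficient set violating that ordering in the
noise-free mean is rejected. Ground-truth PIR uses the optical-intensity
convention (pulse riding on a DC perfusion baseline of twice the
normalized pulse amplitude).

The simulator does **not** model: hemodynamically realistic arterial-tree
propagation, skin-tone or optical-path effects, respiration-modulated
PTT, arrhythmia or ectopy, powerline interference, or sensor-contact
dropout. Passing tests therefore demonstrate correctness of the coupling,
detection, feature and modelling machinery under controlled, physiologic
signal structure — not clinical performance on human recordings.

## Numerical choices and degenerate inputs

Times are seconds from record start, indices 0-based, windows half-open.
All extremum ties break to the earliest sample. Zero-noise configurations
return the input bit-identically from the noise stage, and identical
configurations reproduce subjects bit-identically (per-stage independent
seed streams). The clean-signal oracle is exercised with the band-pass
bypassed: filtering exists to remove noise and drift, and itself reshapes
the waveform by a few samples near the 0.5 Hz edge; noisy-corpus
evaluations always run the full pipeline. Degenerate inputs fail loudly
and specifically: flat ECG (no measurable R amplitude), series shorter
than the filter or detector needs, mismatched lengths or rates, BP
coefficient sets with SBP ≤ DBP, unknown config keys, non-uniform
timestamps in signal files (first offending row named). Empty results
(no beats in a too-short record, no detections on a flat signal) are
empty values, not exceptions. Fiducial F1 uses maximum-cardinality
one-to-one matching within ±40 ms (both sides sorted, each truth event
takes the earliest unclaimed detection in its window — optimal for
interval-structured matching and verified against exhaustive assignment
in tests); per-landmark and pooled aggregations are both reported. PTT
detection rate counts ground-truth beats that form a complete cardiac
cycle, since R-to-onset pairing is defined per RR interval and a record's
final beat has none.

## Known limitations

- The exact dynamic-threshold R detector, the comparator algorithms, and
  the F1 matching tolerance are reconstructions of standard practice;
  every constant is exposed in `RunConfig` rather than asserted as the
  original instruments' values.
- Boosted trees extrapolate poorly across subjects on continuous
  per-subject covariates (age, weight, mean PTT): under the subject-wise
  split, held-out R² saturates below what the noise level alone would
  allow, because piecewise-constant models cannot interpolate between
  training subjects' covariate values. A linear probe on the generative
  features confirms the mapping itself is exactly learnable.
- PIR calibration on band-passed signals depends on the baseline-restore
  convention; estimated PIR is monotone in, but not numerically equal to,
  the generative PIR.
- Evaluation problem sizes (20 × 120 s detection corpus; 24 subjects for
  BP modelling; 50 TPE trials) are desk-scale choices that keep a full
  reproduction in the minutes range on one CPU.
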