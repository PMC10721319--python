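# Methods

This note documents the models, algorithms and numerical choices behind
`apneamap`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic experiments do and do not
demonstrate.

## Airflow model and apnea scoring

### Breathing model

Baseline breathing is a train of stereotyped breaths at period `T0`
(default 4 s, i.e. 15 breaths/min). Each breath is a pair of half-sine
lobes: an inspiratory lobe of duration `inspiratory_fraction·T0` (default
0.35) and amplitude `A0`, followed by a longer, shallower expiratory lobe
scaled so each breath moves zero net volume. Additive white noise
(`noise_sd`, default 0.05·A0) and slow sinusoidal baseline wander
(`drift_sd`, default 0.02·A0, 0.01–0.05 Hz) emulate sensor noise and
drift. Airflow units are arbitrary, as in nasal-pressure transduction; all
scoring thresholds are therefore relative, and the scoring is exactly
invariant to rescaling the signal and to shifting its time origin (tested).

Apnea injection removes the suppressed breaths from the schedule, restarts
breathing with a fresh breath exactly at each suppression-interval end
(resumption is not phase-locked to pre-apnea breathing), and multiplies
the signal inside the interval by 0.05 rather than zeroing it, so noise
statistics stay realistic while remaining far below the flatness
criterion. The phase reset matters: it makes injected durations exact
rather than quantized to the breath grid, which is what lets threshold
sweeps recover scoring boundaries at their nominal values.

### Breath detection

The trace is zero-phase low-pass filtered at 2 Hz (4th-order Butterworth)
and detrended by subtracting a 15 s moving average. Breaths are delimited
by positive-going zero crossings; each crossing is then snapped to the
nearest crossing of the *unfiltered* detrended signal within ±0.35 s,
because the zero-phase filter smears sharp inspiratory onsets backward by
a few tens of milliseconds — without this refinement the 20 s persistent
boundary cannot be recovered to 0.1 s. The inspiratory peak is the maximum
between crossings; candidates with amplitude below 0.2× the 75th-percentile
candidate amplitude are rejected as noise ripples. A breath's end is capped
at one typical period past its onset so that breaths bordering long gaps do
not swallow the gap.

### Apnea detection

Baseline statistics (median inter-onset interval `T0`, median amplitude
`A0`, window RMS `rms0`) come from a pre-stimulation window (default the
60 s before the epoch). Every onset-to-onset gap exceeding `k·T0`
(k = 1.75: tolerant of normal cycle variability, strict enough to catch a
single skipped cycle) whose interior RMS is below `0.25·rms0` becomes one
central-apnea interval with `missed_breaths = round(gap/T0) − 1`; edge
gaps are scored against the trace boundaries. The interval's start is the
previous onset plus one nominal period when that breath completed
normally, or the point where its airflow magnitude vanished when the
breath was clipped mid-cycle (detected when flow ends more than `0.1·T0`
early). Detection is cross-checked in the tests against an exhaustive
gap-scan oracle on 100 seeded traces.

### Trial metrics and normalization

Breathing counts as normalized at the first window of `normal_resume_s`
(20 s) that is apnea-free and contains regular baseline-like breaths —
onset intervals and amplitudes within ±35% of baseline (the tolerance is
configuration; the study definition of "regular baseline-like" is
qualitative). Total apnea time sums apnea durations from epoch onset to
normalization; disrupted-breathing time runs from epoch onset to the start
of that window. If the trace ends first, metrics are computed on the
available data and flagged right-censored.

Threshold comparisons (the 20 s persistent boundary, the 90% epoch
coverage) carry a small slack `time_tol_s = 0.05 s` that absorbs
sampling-grid quantization of detected onsets; it is an order of magnitude
below the sweep resolutions used anywhere.

## Trial classification

Labels, in decreasing precedence:

1. `persistent_apnea` — apnea beyond the epoch end, summed until
   normalization, totals ≥ 20 s (repeated post-event apneas accumulate as
   long as no 20 s normalization window intervenes);
2. `apnea` — apnea covers ≥ 90% of the epoch with no qualifying normal
   resumption inside it (literal 100% coverage is too strict: trials with
   intermittent sporadic breaths during stimulation still read as apnea);
3. `transient_apnea` — apnea occurred and normal breathing resumed before
   the epoch end;
4. `no_apnea`.

For stimulation-plus-seizure trials the epoch ends at electrographic
seizure termination as given in the events file; seizure boundaries are
never inferred from iEEG. One edge of the rule chain is worth noting: a
trial whose apnea neither covers the epoch nor resolves before its end,
with < 20 s beyond it, falls through to `no_apnea`; the synthetic
scenarios never produce this shape, and real uses can tighten
`apnea_coverage_frac` if it arises. Sites take the modal trial label with
ties broken toward the more prolonged effect
(persistent > apnea > transient > none); aggregation is
permutation-invariant.

## Outcome probability mapping

Site coordinates are midpoints of stimulated contact pairs in a common RAS
space (mm). Left-sided sites are reflected to the right hemisphere
(|x|), since no systematic laterality is assumed; fitting mirrors
internally, so pre-mirroring inputs is a no-op.

The classifier is a one-vs-one error-correcting output code over
RBF-kernel SVMs on standardized coordinates. Decoding uses a softplus
(smoothed hinge) codeword distance — a plain hinge zero-clips deep inside
each class region, producing exact probability ties that make the argmax
voxel arbitrary — and probabilities are a softmax over negative decoded
distances (pairwise Platt coupling is available as an option).
Hyperparameters are deliberately simple and logged: C = 1; kernel scale =
half the median pairwise distance of the standardized training sites (the
full median over-smooths a focal ~3 mm cluster inside an ~8 mm site
cloud and biases the recovered peak by several mm); pairwise SVMs use
balanced class weights because persistent apnea is a rare class. The
prediction grid is isotropic (default 1 mm) over the training bounding box
padded by 10 mm, clipped to the right hemisphere; per-voxel probabilities
sum to 1 by construction. Volumes export as one float32 NIfTI-1 file per
class with the grid affine.

The synthetic cohort scatters sites (SD 8 mm) around an amygdala-like
center, with distance-dependent class weights: a sharp persistent-apnea
cluster (SD 3 mm) nested inside a broader apnea cluster (SD 6 mm), a
diffuse transient ring, and a flat no-effect floor. The persistent weight
is strong enough that sites inside the focal cluster elicit persistent
apnea on nearly every trial, matching the deterministic per-site
phenomenology of mapped persistent-apnea sites. Under these conditions the
fitted map recovers the generating center to ~2 mm (median over 10 seeds,
200-site cohorts) and the half-maximum persistent region nests inside the
half-maximum any-apnea region. What this does *not* show: robustness to
electrode-localization error, non-Gaussian site placement along real
electrode trajectories, or inter-patient anatomical variability.

## Ventilation and CO2

VE [L/min] = RR [1/min] · TV [mL] / 1000 (validated to 1% on
construction). etCO2 follows a one-compartment store

    dC/dt = a − b · VE(t) · (C − Cmin)

with production `a` (mmHg/s, default 0.6), clearance coefficient `b`
(default 0.005 per L/min per s) and floor `Cmin` (20 mmHg): during apnea
(VE = 0) C rises linearly at `a`; at constant VE the fixed point is
`Cmin + a/(b·VE)` (40 mmHg at 6 L/min with defaults). The integrator is a
fixed-step explicit Euler scheme at the channel sampling rate (default
10 Hz); the dynamics are non-stiff at these rates and the integrator
matches the analytic fixed point to < 0.1 mmHg (tested). Instantaneous RR
is 60 over the inter-onset gap; gaps longer than twice the median gap
count as apnea (RR = 0).

Hypoventilation intervals are maximal runs (≥ 10 s by default) where TV
and VE are both below their pre-stimulation baseline means while etCO2 is
above its baseline mean; both conditions are required, and samples with
VE = 0 are excluded so apnea (scored from airflow) and hypoventilation
remain disjoint states. Baseline defaults to the 60 s before stimulation.

## iEEG spectral analysis

Canonical bands: delta 1–4, theta 4–8, alpha 8–12, beta 13–30, low gamma
30–80, high gamma 80–150 Hz. Band power is the integral of the Welch PSD
(1 s Hann segments, 50% overlap) over the band, averaged across channels,
compared on a log10 scale for variance stabilization. Band envelopes are
the magnitude of the analytic signal of the zero-phase band-passed trace;
envelope–respiration correlation is Pearson's r after linear resampling of
the respiratory signal onto the envelope's time base (≥ 10 s overlap
required). Baseline and apnea epochs should be duration-matched by the
caller to avoid estimator-variance bias.

Group inference uses Wilcoxon's signed-rank test per band against zero
median — the paired before/during design calls for the signed-rank form;
an independent-samples rank-sum option exists — with the exact null
distribution for n ≤ 25 (no ties) and the normal approximation otherwise,
then Benjamini–Hochberg FDR across the six bands at α = 0.01. All-zero
differences yield p = 1 by convention with a warning. The exact p-values
and the BH step-up are verified against full-enumeration oracles in the
tests. Note that with n = 5 patients the smallest attainable two-sided
exact p is 1/16, so no single band can reach α = 0.01 — the null
calibration experiment (1000 simulated cohorts) reproduces the expected
all-negative pattern by construction of the test, not merely by chance.

## Synthetic experiments: problem sizes

The test suite and acceptance script use: 0.1 s sweeps over 0–60 s of
post-epoch apnea and 0.5 s sweeps of the recovery gap (noiseless, 40 Hz
airflow, chosen so the sweep steps are integer numbers of samples);
100 seeded traces for the apnea-detection oracle and 500 seeded scenarios
for the classification oracle; 200-site cohorts over 10 seeds for spatial
recovery (2 mm evaluation grid); 1000 five-patient cohorts (40 s traces at
400 Hz) for the null-calibration experiment. These sizes were chosen to
make every stochastic check stable across re-runs at interactive run
times.

## Known limitations

* Central vs obstructive apnea is not discriminated; the scoring assumes
  flattened airflow reflects absent drive (verified clinically by other
  means, e.g. chest-wall video).
* The breath detector expects inspiration-positive airflow with a roughly
  stationary baseline period; highly irregular (e.g. Cheyne–Stokes)
  breathing would need retuned gap/regularity tolerances.
* The classifier-based map is a smoothed interpolation of sparse labelled
  sites; its voxel probabilities are calibrated only in the softmax sense
  and should be read as relative, not frequentist, probabilities.
* The CO2 store is a single compartment with linear clearance in VE: it
  reproduces trend and fixed-point behavior, not breath-by-breath etCO2
  waveforms or ventilation–perfusion effects.
* EDF ingestion is read-only and requires the optional `mne` dependency.
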