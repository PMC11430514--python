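# Methods

This note documents the models and numerical choices behind `qeegperm`:
what the synthetic cohort generator produces, how the preprocessing and
analysis stages are defined, and how the cluster-permutation statistic is
computed.  Defaults quoted here are the package defaults; everything is
config-exposed.

## 1. Synthetic cohort generator

The generator (`qeegperm.simulate`) emulates the design of a small
familial-disease EEG study: `n_patients = 9` versus `n_controls = 50`
age-matched healthy controls, 19 channels in the standard 10-20 montage at
250 Hz, three conditions (eyes open 180 s, eyes closed 180 s, and a cued
GO/NOGO task), and per-patient behavioral memory scores on the T-score
scale.

### Task structure

Each trial presents a cue followed by an imperative stimulus: pairs of
picture categories `aa`, `ap`, `pp`, `ph` (animal/plant/human) drawn with
equal probability, 400 trials per session.  Timing is exact by
construction: 1000 ms cue-to-second-stimulus, 3000 ms between pairs,
100 ms stimulus duration.  `aa` requires a button press (GO), `ap` is the
prepared-but-withheld NOGO, `pp`/`ph` are ignored.  Compliant simulated
subjects press only on `aa`, with Gaussian reaction times (mean 380 ms,
SD 40 ms, clipped to 150–900 ms) written to a separate button channel.
A trial-count override exists for fast tests (a 400-trial session is
~27 min of signal).

### Signal model

Each session is a sum of, per channel:

* **Background noise** — independent 1/f power-law noise (flat shelf below
  2 Hz so the 0–1 Hz band stays bounded) at 6 µV RMS plus white noise at
  1.5 µV RMS.  Amplitudes keep the background below the 100 µV rejection
  threshold except in deliberately inserted artifact segments.
* **Rhythms** — amplitude-modulated sinusoids (random phase per subject,
  positive slow envelope from low-passed noise), not filtered noise, so
  peak frequencies are exactly controllable.  All subjects carry posterior
  alpha at 9.0 Hz with a right occipito-temporal gain maximum (O2/T6);
  its amplitude scales ×1.0 eyes-open, ×2.0 eyes-closed, ×0.9 task.
  Patients additionally carry a 7.6 Hz low-alpha source with a left
  temporofrontal gain maximum (F7 > T3 > T5, bilateral with left
  dominance).  Per-subject source amplitudes are Gaussian (mean 8 and
  9 µV respectively, SD 1.2 µV).
* **ERP components** — Hann-shaped bumps time-locked to stimuli: an early
  occipital response (peak ~140 ms, 4 µV, all stimuli), a parietal GO P3
  (peak ~330 ms, 8 µV, identical in both groups), and a late central NOGO
  positivity (support ~260–500 ms, Cz-maximal with frontal spread) whose
  amplitude is the per-subject `true_nogo_amplitude`: Gaussian with mean
  5 µV (controls) versus 2 µV (patients, i.e. 40% of control), SD 0.6 µV.
  Single-trial amplitudes jitter by ×N(1, 0.15).
* **Ocular artifacts** — a fixed dipolar blink topography maximal at
  Fp1/Fp2 and zero posteriorly, with a biphasic ~400 ms waveform
  (~55 µV), at ~10 blinks/min.  The stereotyped map is what makes the ICA
  correction step recoverable and testable.
* **Gross artifact segments** — optional 1 s movement-like bursts
  (~200 µV) hitting a random subset of 4–8 channels (so they survive
  average re-referencing), at a configurable rate (default 0.3/min), with
  an override for exact placement in tests.

Topographies are direct per-channel gain maps; there is no
volume-conduction head model, no spatially correlated background noise,
and no latency jitter of ERP components.  Passing recovery tests on this
generator therefore demonstrates that the *analysis machinery* recovers
known effects at realistic amplitudes and sample sizes — not that it would
behave identically on real EEG, where topographies are smoother, noise is
spatially correlated and component latencies vary.

### Behavioral scores

Patient delayed-recall scores are built by the bivariate-normal
construction `score_z = ρ·z_amp + sqrt(1−ρ²)·ε` against the standardized
true NOGO amplitudes, rescaled to mean 29.6 / SD 11.5 (the patient-group
anchor), with default population correlation ρ = 0.78.  This makes
recovery analytic: the sample correlation converges to ρ, and equals ±1
exactly when |ρ| = 1.  Clipping to the observed T-score range 15–50 is
off by default (it slightly attenuates ρ).  Controls receive no score:
normative-database controls have none, and the correlation analysis is
patient-only.

All randomness derives from explicit integer seeds via per-subject,
per-stream child generators (CRC32 of subject id and stream name), so any
single session can be regenerated bit-for-bit in isolation.

## 2. Preprocessing

* **Filters** — forward-backward (zero-phase) order-4 Butterworth
  throughout: analysis band-pass 0.53–30 Hz, notch as 45–55 Hz band-stop,
  rule filters 0–1 Hz low-pass and 20–35 Hz band-pass.  Zero-phase
  filtering preserves ERP latencies; generous reflect padding (3 s) keeps
  edge transients of the low cutoff small.
* **Re-referencing** — recordings are produced in a linked-ears reference
  and re-referenced to a weighted channel average.  The exact weighting of
  the original hardware montage is not public, so the default weight
  vector is uniform (plain average reference) with a config hook; the
  reference state is tracked and double re-referencing is an error.
* **ICA ocular correction** — extended-Infomax ICA (via MNE, fixed seed,
  8× temporal decimation) fitted on a copy band-passed to 2–30 Hz to limit
  low-frequency overlearning.  Components whose sensor topography
  correlates with a frontal ocular template (unit map maximal at Fp1/Fp2,
  fading to zero posteriorly) at |ρ| ≥ 0.8 are zeroed and the original
  recording reconstructed.  This replaces manual component selection with
  a deterministic rule and a machine-readable report.  At least 60 s of
  data are required; less is an explicit error, never a silent pass-through.
* **Artifact rules** — consecutive non-overlapping 5 s epochs; an epoch is
  flagged `abs` if any channel of the broadband signal exceeds 100 µV,
  `slow` if the 0–1 Hz band exceeds 50 µV, `fast` if the 20–35 Hz band
  exceeds 35 µV.  Comparisons are strict (`>`), any channel triggers, and
  flags are unioned.  The quality gate requires ≥ 8 clean epochs (≈ 40 s)
  per subject and condition and raises otherwise, naming the subject.
  The 5 s epoch length is chosen so that 8 epochs ≈ 40 s of data.

## 3. Spectra

Welch-style averaging of per-epoch Hann periodograms over clean 5 s
epochs; 0.2 Hz resolution over the 0–30 Hz analysis band.  Power is
stored per bin (PSD × bin width, µV²) so a sinusoid's power summed across
its peak equals its variance; amplitude = √power (µV); relative amplitude
normalizes each channel's amplitude to 100% over the band.  **Relative
amplitude is the group statistic** fed to the cluster test (it is
scale-invariant, hence robust to per-subject gain differences); power and
amplitude are exposed alongside.  Task-condition spectra are computed on
clean 5 s segments of the continuous task recording, ignoring trial
structure.  Grand averages are plain means over subjects, with the
per-subject maps retained for statistics.

## 4. ERPs

Epochs span −200…+800 ms, baseline −200…0 ms, time-locked to the second
(imperative) stimulus for GO/NOGO and to the first stimulus for Ignore
pairs.  Trials overlapping artifact-flagged epochs are dropped; a
condition with zero surviving trials is a quality-gate error.  Component
amplitudes are window means of the per-subject average waveform:
late NOGO at Cz over 300–500 ms (the component's map peak sits inside
this window), GO P3 at Pz over 250–450 ms, early sensory response at O1
over 80–180 ms.  A window mean is preferred over a peak amplitude because
it is robust at small trial counts; peak extraction would be an easy
extension.

## 5. Cluster-based permutation statistics

Pointwise statistic: Wilcoxon signed-rank (paired designs; zero
differences dropped, ties mid-ranked) or rank-sum / Mann-Whitney
(independent groups), both as tie-corrected normal-approximation
z-scores, positive when the first group exceeds the second.  The reported
z is the plain standardized statistic; the two-sided p applies the
standard 0.5 continuity correction toward the mean, which keeps p within
a few hundredths of the exact discrete null even at n = 6–9 (a
`continuity` flag reverts to the uncorrected CDF).  Degenerate points
(all values identical) get z = 0, p = 1 and are flagged.

Cluster formation: points with p below the cluster-forming threshold
(default 0.05, config-exposed) are nodes; edges join neighboring bins on
the same channel and montage-neighbor channels at the same bin; connected
components are split by z sign and scored by **summed z** (the cluster
mass).  Spatial adjacency uses the azimuthal-equidistant projection of
the 10-20 coordinates scaled to outermost-electrode radius 0.5 with a
0.35 distance threshold, which gives every channel 2–9 neighbors; the
positions and threshold are data, not code, and can be overridden.

Permutation null: the distribution of the **maximum absolute cluster
mass** per relabeling (the standard max-statistic familywise correction)
— group labels permuted for the independent design, per-subject condition
sign-flips for the paired design.  Monte-Carlo p-values use the
(1 + exceedances)/(1 + n_perm) estimator, so p is never exactly 0; with
`exact=True` all distinct relabelings are enumerated instead (2ⁿ
sign-flips, or all label assignments up to a 200 000 cap) and the p-value
is the plain exceedance fraction including the identity.  Because pooled
ranks (independent) and |differences| (paired) are invariant under
relabeling, ranks are computed once and each permutation's z map is a
single matrix product — thousands of permutations cost seconds.

Patients-versus-controls comparisons use the **independent rank-sum
design by default**: the cohorts are unpaired, and whether the original
normative-database comparison paired each patient to a matched control is
unknown.  The paired signed-rank design is implemented and selected by
`design="paired"`; every result file records the design used.

## 6. Correlation stage

Pearson r between the patients' late-NOGO window means at Cz and their
behavioral scores, two-sided p from the t transform
`t = r·sqrt((n−2)/(1−r²))`, plus an optional seeded permutation p
(shuffling the scores) because n ≈ 9 strains the t approximation, and a
Fisher-z 95% CI.  Zero variance in either variable is an explicit error.

## 7. Problem sizes in the tests and the reproduction script

Spectra stabilize after a few dozen clean 5 s epochs (the quality gate
needs only eight), so the group-level test fixtures use 2-minute resting
runs and 100-trial task sessions for the full 9 + 50 cohort, and the ERP
fixtures 80-trial sessions; the reproduction script
(`scripts/acceptance.py`) uses the full default design (3-minute resting
runs, 400-trial task).  Null calibration of the cluster test uses 200
simulated experiments on a reduced 19 × 20 grid with ~200 permutations
each.  These sizes were chosen once, from the convergence properties
above.

## 8. Known limitations

* Gain-map topographies and spatially independent noise make spatial
  clustering easier than on real EEG, where volume conduction correlates
  neighboring channels under the null as well as under the effect.
* The ICA step is tested against the generator's stereotyped blink; real
  ocular activity (saccades, partial blinks) is more varied and the 0.8
  template threshold may need tuning on real data.
* The weighted-average reference defaults to uniform weights; results
  under a hardware-specific channel weighting may differ slightly.
* The exact enumeration modes are limited to ≤ 20 paired subjects /
  200 000 labelings; beyond that only Monte-Carlo p-values are available.
* Reaction-time analysis assumes a clean binary button channel; no
  debouncing beyond onset detection is implemented.
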