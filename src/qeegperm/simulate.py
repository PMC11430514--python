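"""Seeded synthetic EEG cohorts for a cued GO/NOGO study.

The generator emulates the group structure of a small familial
neurodegenerative cohort compared against age-matched healthy controls:

* all subjects carry a posterior alpha rhythm (default peak 9.0 Hz) with a
  right occipito-temporal maximum, stronger with eyes closed;
* patients additionally carry a low-alpha rhythm (default peak 7.6 Hz) with
  a left temporofrontal maximum (F7/T3/T5);
* in the task condition, stimuli evoke an early occipital sensory response,
  GO (animal-animal) second stimuli evoke a parietal P3, and NOGO
  (animal-plant) second stimuli evoke a late central positivity whose
  per-subject amplitude is suppressed in patients;
* stereotyped frontal blinks and optional gross-amplitude artifact segments
  are mixed in, on top of 1/f plus white background noise;
* patient behavioral memory scores (T-score scale) are generated with a
  controlled population correlation against the per-subject NOGO amplitude.

Topographies are direct per-channel gain maps; there is no volume-conduction
head model.  All randomness flows from explicit integer seeds, so any
session can be regenerated bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .containers import (
    CUE_TO_SECOND_MS,
    INTER_PAIR_MS,
    PAIR_TYPES,
    STIMULUS_DURATION_MS,
    EEGRecording,
    EventList,
    Trial,
)
from .montage import CHANNELS_1020, check_montage_labels

CONDITIONS = ("eyes_open", "eyes_closed", "task")

# Trial slot length: 1000 ms cue->second + 3000 ms to the next cue.
TRIAL_SLOT_MS = CUE_TO_SECOND_MS + INTER_PAIR_MS
#: lead-in before the first cue (also the tail after the last trial), ms
TASK_PAD_MS = 2000.0


def _gain_map(values: dict[str, float]) -> dict[str, float]:
    """Complete a per-channel gain map with zeros, in montage order."""
    out = {c: 0.0 for c in CHANNELS_1020}
    for k, v in values.items():
        if k not in out:
            raise ValueError(f"unknown channel {k!r} in gain map")
        if v < 0:
            raise ValueError("gain maps must be non-negative")
        out[k] = float(v)
    return out


#: Left temporofrontal map of the excess low-alpha rhythm: bilateral
#: temporofrontal, clearly maximal at F7/T3/T5.
LOW_ALPHA_TOPOGRAPHY = _gain_map({
    "F7": 1.0, "T3": 0.9, "T5": 0.75,
    "F3": 0.55, "Fp1": 0.4, "C3": 0.35,
    "F8": 0.45, "T4": 0.35, "T6": 0.15,
    "Fp2": 0.3, "F4": 0.3, "Fz": 0.3,
    "Cz": 0.2, "C4": 0.2,
    "P3": 0.15, "Pz": 0.1, "P4": 0.1,
    "O1": 0.1, "O2": 0.05,
})

#: Posterior alpha map with right occipito-temporal maximum (O2/T6).
CONTROL_ALPHA_TOPOGRAPHY = _gain_map({
    "O2": 1.0, "T6": 0.9, "O1": 0.8,
    "P4": 0.7, "Pz": 0.6, "P3": 0.55,
    "T5": 0.45, "T4": 0.3, "C4": 0.25,
    "Cz": 0.2, "C3": 0.15, "T3": 0.1,
    "F3": 0.05, "Fz": 0.05, "F4": 0.05, "F7": 0.05, "F8": 0.05,
    "Fp1": 0.02, "Fp2": 0.02,
})

#: Fixed dipolar blink map: maximal at Fp1/Fp2, zero posteriorly.
BLINK_TOPOGRAPHY = _gain_map({
    "Fp1": 1.0, "Fp2": 1.0,
    "F7": 0.45, "F3": 0.5, "Fz": 0.5, "F4": 0.5, "F8": 0.45,
    "T3": 0.1, "C3": 0.15, "Cz": 0.15, "C4": 0.15, "T4": 0.1,
})

#: ERP component topographies.
EARLY_SENSORY_TOPOGRAPHY = _gain_map({
    "O1": 1.0, "O2": 0.9, "T5": 0.5, "T6": 0.45, "Pz": 0.4, "P3": 0.4, "P4": 0.35,
})
GO_P3_TOPOGRAPHY = _gain_map({
    "Pz": 1.0, "P3": 0.8, "P4": 0.8, "Cz": 0.6, "C3": 0.4, "C4": 0.4, "O1": 0.3, "O2": 0.3,
})
NOGO_LATE_TOPOGRAPHY = _gain_map({
    "Cz": 1.0, "Fz": 0.8, "C3": 0.6, "C4": 0.6, "F3": 0.5, "F4": 0.5, "Pz": 0.5,
    "Fp1": 0.2, "Fp2": 0.2, "P3": 0.3, "P4": 0.3,
})

#: condition-dependent scaling of the posterior alpha source
ALPHA_CONDITION_SCALE = {"eyes_open": 1.0, "eyes_closed": 2.0, "task": 0.9}


@dataclass
class CohortSpec:
    """Study design: who is recorded, how, and for how long."""

    n_patients: int = 9
    n_controls: int = 50
    sampling_rate: float = 250.0
    channel_labels: tuple[str, ...] = CHANNELS_1020
    #: seconds per resting condition; the task length follows from n_trials
    session_durations: dict = field(
        default_factory=lambda: {"eyes_open": 180.0, "eyes_closed": 180.0}
    )
    n_trials: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        check_montage_labels(self.channel_labels)
        self.channel_labels = tuple(self.channel_labels)

    def duration(self, condition: str) -> float:
        """Session length in seconds for a condition."""
        if condition == "task":
            return (2 * TASK_PAD_MS + self.n_trials * TRIAL_SLOT_MS) / 1000.0
        try:
            return float(self.session_durations[condition])
        except KeyError:
            raise ValueError(f"unknown condition {condition!r}") from None


@dataclass
class EffectSpec:
    """Injected group effects and nuisance-signal levels (µV, Hz)."""

    patient_low_alpha_peak: float = 7.6
    control_alpha_peak: float = 9.0
    low_alpha_topography: dict = field(default_factory=lambda: dict(LOW_ALPHA_TOPOGRAPHY))
    control_alpha_topography: dict = field(default_factory=lambda: dict(CONTROL_ALPHA_TOPOGRAPHY))
    #: mean single-subject source amplitudes at the map maximum, µV
    alpha_amplitude_uv: float = 8.0
    low_alpha_amplitude_uv: float = 9.0
    subject_amplitude_sd_uv: float = 1.2
    #: late NOGO positivity, per-group mean of the per-subject true amplitude
    nogo_amplitude_patient: float = 2.0    # ~40% of control
    nogo_amplitude_control: float = 5.0
    nogo_amplitude_sd: float = 0.6
    go_p3_amplitude: float = 8.0
    early_sensory_amplitude: float = 4.0
    #: population correlation between NOGO amplitude and behavioral score
    behavioral_true_r: float = 0.78
    behavioral_mean: float = 29.6
    behavioral_sd: float = 11.5
    #: background noise
    pink_rms_uv: float = 6.0
    white_rms_uv: float = 1.5
    #: ocular artifacts
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 55.0
    #: gross-amplitude artifact segments
    artifact_rate_per_min: float = 0.3
    artifact_amplitude_uv: float = 200.0
    artifact_duration_s: float = 1.0
    #: mean simulated reaction time on GO trials, ms
    rt_mean_ms: float = 380.0
    rt_sd_ms: float = 40.0

    def __post_init__(self) -> None:
        for peak in (self.patient_low_alpha_peak, self.control_alpha_peak):
            if not (1.0 <= peak <= 30.0):
                raise ValueError("rhythm peaks must lie in 1-30 Hz")
        if abs(self.behavioral_true_r) > 1:
            raise ValueError("|behavioral_true_r| must be <= 1")
        self.low_alpha_topography = _gain_map(self.low_alpha_topography)
        self.control_alpha_topography = _gain_map(self.control_alpha_topography)


@dataclass
class SubjectRecord:
    """One simulated subject."""

    subject_id: str
    group: str                      # 'patient' | 'control'
    true_nogo_amplitude: float      # µV, drives the late NOGO positivity
    behavioral_score: Optional[float] = None   # T-score scale

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")


def _subject_seed(seed: int, subject_id: str, stream: str) -> np.random.Generator:
    """Deterministic per-subject, per-stream generator."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(subject_id.encode()),
                                zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# task events
# ---------------------------------------------------------------------------

def generate_task_events(
    n_trials: int,
    seed: int,
    rt_mean_ms: float = 380.0,
    rt_sd_ms: float = 40.0,
    first_cue_ms: float = TASK_PAD_MS,
) -> EventList:
    """Random cued GO/NOGO trial sequence with exact canonical timing.

    The four stimulus pairs (aa, ap, pp, ph) are sampled with equal
    probability.  Every trial has a 1000 ms cue-to-second-stimulus interval,
    3000 ms from its second stimulus to the next cue, and 100 ms stimulus
    duration.  Compliant responses (on aa trials only) get a Gaussian
    reaction time.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = np.random.default_rng(seed)
    pair_idx = rng.integers(0, 4, size=n_trials)
    rts = rng.normal(rt_mean_ms, rt_sd_ms, size=n_trials).clip(150.0, 900.0)
    trials = []
    for i in range(n_trials):
        pair = PAIR_TYPES[pair_idx[i]]
        cue = first_cue_ms + i * TRIAL_SLOT_MS
        trials.append(
            Trial(
                pair_type=pair,
                cue_onset_ms=float(cue),
                second_onset_ms=float(cue + CUE_TO_SECOND_MS),
                stimulus_duration_ms=STIMULUS_DURATION_MS,
                response_time_ms=float(round(rts[i])) if pair == "aa" else None,
            )
        )
    ev = EventList(trials=trials)
    ev.validate_timing()
    return ev


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float, shelf_hz: float = 2.0,
                n_channels: Optional[int] = None) -> np.ndarray:
    """Unit-RMS 1/f noise with a flat shelf below ``shelf_hz``.

    With ``n_channels`` set, returns (n_channels, n) independent traces.
    """
    shape = (n // 2 + 1,) if n_channels is None else (n_channels, n // 2 + 1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], shelf_hz))
    spec = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * shaping
    spec[..., 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _am_sinusoid(rng: np.random.Generator, n: int, fs: float, freq: float) -> np.ndarray:
    """Amplitude-modulated sinusoid with random phase; envelope mean ~1."""
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2 * np.pi)
    # slow (<1.5 Hz) positive envelope
    slow = _pink_noise(rng, n, fs, shelf_hz=0.5)
    sos = signal.butter(2, 1.5, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, slow)
    sd = env.std()
    if sd > 0:
        env = 1.0 + 0.4 * env / sd
    else:
        env = np.ones(n)
    env = np.clip(env, 0.1, None)
    return env * np.sin(2 * np.pi * freq * t + phase)


def _hann_bump(n_samples: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n_samples) / max(n_samples - 1, 1)))


def _add_at(data: np.ndarray, gains: np.ndarray, wave: np.ndarray, start: int) -> None:
    """Mix ``gains x wave`` into ``data`` starting at sample ``start``, clipped."""
    n = data.shape[1]
    if start >= n or start + len(wave) <= 0:
        return
    lo = max(start, 0)
    hi = min(start + len(wave), n)
    data[:, lo:hi] += gains[:, None] * wave[lo - start: hi - start][None, :]


def _erp_wave(fs: float, start_ms: float, width_ms: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Hann-shaped component; returns (wave, offset in samples from stimulus)."""
    width = int(round(width_ms / 1000.0 * fs))
    return amplitude * _hann_bump(width), int(round(start_ms / 1000.0 * fs))


def _blink_wave(fs: float, amplitude: float) -> np.ndarray:
    """Biphasic ~400 ms blink: positive lobe then smaller negative rebound."""
    up = amplitude * _hann_bump(int(round(0.25 * fs)))
    down = -0.3 * amplitude * _hann_bump(int(round(0.15 * fs)))
    return np.concatenate([up, down])


def synthesize_session(
    subject: SubjectRecord,
    condition: str,
    cohort: CohortSpec,
    effects: EffectSpec,
    seed: int,
    events: Optional[EventList] = None,
    artifact_times_s: Optional[Sequence[float]] = None,
) -> EEGRecording:
    """Generate one continuous 19-channel session for a subject/condition.

    ``artifact_times_s`` overrides the random placement of gross-amplitude
    artifact segments (useful for testing the rejection rules); ``events``
    overrides the internally generated task trial sequence.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    fs = cohort.sampling_rate
    labels = cohort.channel_labels

    if condition == "task" and events is None:
        ev_rng = _subject_seed(seed, subject.subject_id, "events")
        events = generate_task_events(
            cohort.n_trials, int(ev_rng.integers(0, 2**31)),
            rt_mean_ms=effects.rt_mean_ms, rt_sd_ms=effects.rt_sd_ms,
        )
    if condition == "task":
        duration = (2 * TASK_PAD_MS + len(events) * TRIAL_SLOT_MS) / 1000.0
    else:
        duration = cohort.duration(condition)
    n = int(round(duration * fs))
    data = np.zeros((len(labels), n))

    # --- background noise (independent per channel)
    rng_bg = _subject_seed(seed, subject.subject_id, f"background:{condition}")
    if effects.pink_rms_uv > 0:
        data += effects.pink_rms_uv * _pink_noise(rng_bg, n, fs, n_channels=len(labels))
    if effects.white_rms_uv > 0:
        data += effects.white_rms_uv * rng_bg.standard_normal((len(labels), n))

    # --- rhythms
    rng_subj = _subject_seed(seed, subject.subject_id, "amplitudes")
    alpha_amp = max(rng_subj.normal(effects.alpha_amplitude_uv, effects.subject_amplitude_sd_uv), 0.0)
    low_amp = max(rng_subj.normal(effects.low_alpha_amplitude_uv, effects.subject_amplitude_sd_uv), 0.0)
    if effects.alpha_amplitude_uv == 0:
        alpha_amp = 0.0
    if effects.low_alpha_amplitude_uv == 0:
        low_amp = 0.0

    rng_rhythm = _subject_seed(seed, subject.subject_id, f"rhythm:{condition}")
    alpha_gain = np.array([effects.control_alpha_topography[c] for c in labels])
    if alpha_amp > 0:
        src = _am_sinusoid(rng_rhythm, n, fs, effects.control_alpha_peak)
        data += (ALPHA_CONDITION_SCALE[condition] * alpha_amp) * alpha_gain[:, None] * src[None, :]
    if subject.group == "patient" and low_amp > 0:
        low_gain = np.array([effects.low_alpha_topography[c] for c in labels])
        src = _am_sinusoid(rng_rhythm, n, fs, effects.patient_low_alpha_peak)
        data += low_amp * low_gain[:, None] * src[None, :]

    # --- event-locked components + button channel
    button = None
    if condition == "task":
        button = np.zeros(n)
        rng_trial = _subject_seed(seed, subject.subject_id, "trials")
        early_gain = np.array([EARLY_SENSORY_TOPOGRAPHY[c] for c in labels])
        p3_gain = np.array([GO_P3_TOPOGRAPHY[c] for c in labels])
        nogo_gain = np.array([NOGO_LATE_TOPOGRAPHY[c] for c in labels])
        for tr in events:
            cue_smp = int(round(tr.cue_onset_ms / 1000.0 * fs))
            sec_smp = int(round(tr.second_onset_ms / 1000.0 * fs))
            jitter = lambda: max(rng_trial.normal(1.0, 0.15), 0.0)
            if effects.early_sensory_amplitude > 0:
                wave, off = _erp_wave(fs, 90.0, 100.0, effects.early_sensory_amplitude)
                _add_at(data, early_gain, jitter() * wave, cue_smp + off)
                _add_at(data, early_gain, jitter() * wave, sec_smp + off)
            if tr.pair_type == "aa" and effects.go_p3_amplitude > 0:
                wave, off = _erp_wave(fs, 230.0, 200.0, effects.go_p3_amplitude)
                _add_at(data, p3_gain, jitter() * wave, sec_smp + off)
            if tr.pair_type == "ap" and subject.true_nogo_amplitude > 0:
                wave, off = _erp_wave(fs, 260.0, 240.0, subject.true_nogo_amplitude)
                _add_at(data, nogo_gain, jitter() * wave, sec_smp + off)
            if tr.response_time_ms is not None:
                press = sec_smp + int(round(tr.response_time_ms / 1000.0 * fs))
                button[press: press + int(round(0.05 * fs))] = 1.0

    # --- blinks
    if effects.blink_amplitude_uv > 0 and effects.blink_rate_per_min > 0:
        rng_blink = _subject_seed(seed, subject.subject_id, f"blinks:{condition}")
        n_blinks = rng_blink.poisson(effects.blink_rate_per_min * duration / 60.0)
        blink_gain = np.array([BLINK_TOPOGRAPHY[c] for c in labels])
        for start in np.sort(rng_blink.uniform(0, duration, size=n_blinks)):
            amp = max(rng_blink.normal(effects.blink_amplitude_uv, 8.0), 20.0)
            _add_at(data, blink_gain, _blink_wave(fs, amp), int(start * fs))

    # --- gross-amplitude artifact segments
    if effects.artifact_amplitude_uv > 0:
        rng_art = _subject_seed(seed, subject.subject_id, f"artifacts:{condition}")
        if artifact_times_s is None:
            n_art = rng_art.poisson(effects.artifact_rate_per_min * duration / 60.0)
            artifact_times_s = rng_art.uniform(0, duration - effects.artifact_duration_s,
                                               size=n_art)
        t_art = np.arange(int(round(effects.artifact_duration_s * fs))) / fs
        burst = np.sin(2 * np.pi * 1.3 * t_art) * _hann_bump(len(t_art))
        for start in artifact_times_s:
            # movement-like: hits a channel subset, so it survives re-referencing
            ch_gain = np.zeros(len(labels))
            hit = rng_art.choice(len(labels), size=rng_art.integers(4, 9), replace=False)
            ch_gain[hit] = rng_art.uniform(0.8, 1.2, size=len(hit))
            _add_at(data, effects.artifact_amplitude_uv * ch_gain, burst, int(start * fs))

    return EEGRecording(
        data=data,
        channel_labels=labels,
        sampling_rate=fs,
        reference="linked_ears",
        events=events,
        subject_id=subject.subject_id,
        condition=condition,
        button=button,
    )


# ---------------------------------------------------------------------------
# behavioral scores and cohort assembly
# ---------------------------------------------------------------------------

def generate_behavioral_scores(
    subjects: list[SubjectRecord],
    true_r: float,
    seed: int,
    mean: float = 29.6,
    sd: float = 11.5,
    clip: bool = False,
    clip_range: tuple[float, float] = (15.0, 50.0),
) -> list[SubjectRecord]:
    """Draw patient memory scores correlated with the true NOGO amplitude.

    Bivariate-normal construction: the score is ``true_r`` times the
    standardized amplitude plus independent Gaussian noise, rescaled to the
    requested T-score mean/SD, so the population correlation equals
    ``true_r`` exactly (and the sample correlation is exactly ±1 when
    ``|true_r| = 1``).  Controls are left unscored.
    """
    if abs(true_r) > 1:
        raise ValueError("|true_r| must be <= 1")
    patients = [s for s in subjects if s.group == "patient"]
    if len(patients) < 2:
        raise ValueError("need at least 2 patient subjects")
    rng = np.random.default_rng(seed)
    amp = np.array([s.true_nogo_amplitude for s in patients])
    if amp.std() == 0:
        raise ValueError("degenerate amplitudes: zero variance")
    z_amp = (amp - amp.mean()) / amp.std()
    noise = rng.standard_normal(len(patients))
    z_score = true_r * z_amp + np.sqrt(1.0 - true_r**2) * noise
    scores = mean + sd * z_score
    if clip:
        scores = scores.clip(*clip_range)
    for s, sc in zip(patients, scores):
        s.behavioral_score = float(sc)
    return subjects


def generate_cohort(cohort: CohortSpec, effects: EffectSpec, seed: Optional[int] = None) -> list[SubjectRecord]:
    """Draw the subject table: ids, groups, NOGO amplitudes, patient scores."""
    if seed is None:
        seed = cohort.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x5EED]))
    subjects = []
    for i in range(cohort.n_patients):
        amp = max(rng.normal(effects.nogo_amplitude_patient, effects.nogo_amplitude_sd), 0.2)
        subjects.append(SubjectRecord(f"P{i + 1:02d}", "patient", true_nogo_amplitude=float(amp)))
    for i in range(cohort.n_controls):
        amp = max(rng.normal(effects.nogo_amplitude_control, effects.nogo_amplitude_sd), 0.2)
        subjects.append(SubjectRecord(f"C{i + 1:02d}", "control", true_nogo_amplitude=float(amp)))
    generate_behavioral_scores(
        subjects, effects.behavioral_true_r, seed=int(rng.integers(0, 2**31)),
        mean=effects.behavioral_mean, sd=effects.behavioral_sd,
    )
    return subjects
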