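"""Event-related potentials for the cued GO/NOGO task.

Trials are labeled GO (aa pairs: press), NOGO (ap pairs: prepared response
withheld) or Ignore (pp/ph pairs).  GO/NOGO epochs are time-locked to the
second (imperative) stimulus, Ignore epochs to the first stimulus of the
non-cue pairs.  Epochs overlapping artifact-flagged segments are dropped,
each trial is baseline-corrected over the pre-stimulus window, and per-
condition averages are summarized by window-mean component amplitudes
(late NOGO positivity at Cz, GO P3 at Pz, early sensory response at O1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import EEGRecording, EventList, QualityGateError
from .preprocess import ArtifactRules, artifact_sample_mask

#: pair type -> task condition
CONDITION_OF_PAIR = {"aa": "GO", "ap": "NOGO", "pp": "Ignore", "ph": "Ignore"}

DEFAULT_WINDOW_MS = (-200.0, 800.0)
DEFAULT_BASELINE_MS = (-200.0, 0.0)

#: component name -> (channel, window ms)
COMPONENT_WINDOWS = {
    "late_NOGO_Cz": ("Cz", (300.0, 500.0)),
    "GO_P3_Pz": ("Pz", (250.0, 450.0)),
    "early_sensory_O1": ("O1", (80.0, 180.0)),
}


@dataclass
class ERPSet:
    """Per-condition average waveform for one subject."""

    subject_id: str
    condition: str                 # GO | NOGO | Ignore
    times_ms: np.ndarray
    waveform: np.ndarray           # (n_channels, n_times), µV
    n_trials: int
    baseline_ms: tuple[float, float]
    channel_labels: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channel_labels):
            rows.append(pd.DataFrame({
                "subject": self.subject_id,
                "condition": self.condition,
                "channel": ch,
                "time_ms": self.times_ms,
                "amplitude_uv": self.waveform[ci],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class ComponentMeasure:
    subject_id: str
    component: str
    channel: str
    window_ms: tuple[float, float]
    amplitude: float               # window mean, µV


def assign_trial_conditions(events: EventList) -> list[str]:
    """GO for aa, NOGO for ap, Ignore for pp/ph."""
    labels = []
    for t in events:
        try:
            labels.append(CONDITION_OF_PAIR[t.pair_type])
        except KeyError:
            raise ValueError(f"unknown pair type {t.pair_type!r}") from None
    return labels


def epoch_and_average(
    rec: EEGRecording,
    events: Optional[EventList] = None,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
    rules: Optional[ArtifactRules] = None,
) -> dict[str, ERPSet]:
    """Average artifact-free, baseline-corrected trials per task condition."""
    if events is None:
        events = rec.events
    if events is None or len(events) == 0:
        raise ValueError("no events to epoch around")
    if not (window_ms[0] <= baseline_ms[0] < baseline_ms[1] <= window_ms[1]):
        raise ValueError("baseline must lie within the epoch window")
    labels = assign_trial_conditions(events)
    fs = rec.sampling_rate
    bad = artifact_sample_mask(rec, rules) if rules is not None else None

    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    times_ms = np.arange(lo, hi) / fs * 1000.0
    bsel = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for tr, lab in zip(events, labels):
        seen.add(lab)
        t0_ms = tr.second_onset_ms if lab in ("GO", "NOGO") else tr.cue_onset_ms
        t0 = int(round(t0_ms / 1000.0 * fs))
        a, b = t0 + lo, t0 + hi
        if a < 0 or b > rec.n_samples:
            continue
        if bad is not None and bad[a:b].any():
            continue
        ep = rec.data[:, a:b]
        ep = ep - ep[:, bsel].mean(axis=1, keepdims=True)
        if lab not in sums:
            sums[lab] = np.zeros((rec.n_channels, hi - lo))
            counts[lab] = 0
        sums[lab] += ep
        counts[lab] += 1

    out = {}
    for lab in seen:
        if counts.get(lab, 0) == 0:
            raise QualityGateError(
                f"subject {rec.subject_id!r}: no surviving trials for condition {lab!r}"
            )
        out[lab] = ERPSet(
            subject_id=rec.subject_id,
            condition=lab,
            times_ms=times_ms,
            waveform=sums[lab] / counts[lab],
            n_trials=counts[lab],
            baseline_ms=baseline_ms,
            channel_labels=rec.channel_labels,
        )
    return out


def extract_component(
    erp: ERPSet,
    channel: str,
    window_ms: tuple[float, float],
    name: str = "",
) -> ComponentMeasure:
    """Window-mean amplitude of the average waveform at one channel."""
    if channel not in erp.channel_labels:
        raise ValueError(f"channel {channel!r} not in montage")
    if window_ms[0] < erp.times_ms[0] or window_ms[1] > erp.times_ms[-1] + 1e-9:
        raise ValueError(f"window {window_ms} outside epoch "
                         f"[{erp.times_ms[0]}, {erp.times_ms[-1]}] ms")
    ci = erp.channel_labels.index(channel)
    sel = (erp.times_ms >= window_ms[0]) & (erp.times_ms <= window_ms[1])
    return ComponentMeasure(
        subject_id=erp.subject_id,
        component=name or f"{channel}_{window_ms[0]:.0f}-{window_ms[1]:.0f}ms",
        channel=channel,
        window_ms=tuple(window_ms),
        amplitude=float(erp.waveform[ci, sel].mean()),
    )


def measure_components(erps: dict[str, ERPSet]) -> pd.DataFrame:
    """Standard component table: late NOGO at Cz, GO P3 at Pz, early at O1."""
    rows = []
    wanted = {"late_NOGO_Cz": "NOGO", "GO_P3_Pz": "GO", "early_sensory_O1": "Ignore"}
    for comp, cond in wanted.items():
        if cond not in erps:
            continue
        ch, win = COMPONENT_WINDOWS[comp]
        m = extract_component(erps[cond], ch, win, name=comp)
        rows.append({
            "subject": m.subject_id, "component": comp, "channel": ch,
            "window_lo_ms": win[0], "window_hi_ms": win[1],
            "amplitude_uv": m.amplitude, "n_trials": erps[cond].n_trials,
        })
    return pd.DataFrame(rows)


@dataclass
class RTResult:
    rts_ms: list[float]
    misses: int
    false_alarms: int

    @property
    def mean_rt_ms(self) -> float:
        return float(np.mean(self.rts_ms)) if self.rts_ms else float("nan")


def reaction_times(
    rec: EEGRecording,
    events: Optional[EventList] = None,
    max_rt_ms: float = 2000.0,
) -> RTResult:
    """Offline reaction times from the button channel.

    RT = press onset minus GO second-stimulus onset; GO trials without a
    press count as misses, presses attributed to non-GO trials as false
    alarms.
    """
    if rec.button is None:
        raise ValueError("recording has no button channel")
    if events is None:
        events = rec.events
    if events is None:
        raise ValueError("no events supplied")
    fs = rec.sampling_rate
    b = rec.button > 0.5
    onsets = np.where(b & ~np.r_[False, b[:-1]])[0]
    onset_ms = onsets / fs * 1000.0
    labels = assign_trial_conditions(events)

    used = np.zeros(len(onset_ms), dtype=bool)
    rts: list[float] = []
    misses = 0
    for tr, lab in zip(events, labels):
        in_win = (onset_ms > tr.second_onset_ms) & (onset_ms <= tr.second_onset_ms + max_rt_ms) & ~used
        idx = np.where(in_win)[0]
        if lab == "GO":
            if len(idx) == 0:
                misses += 1
            else:
                rts.append(float(onset_ms[idx[0]] - tr.second_onset_ms))
                used[idx[0]] = True
        else:
            used[idx] = True  # consumed by a non-GO trial window
    # every detected press not attributed to a GO trial is a false alarm
    false_alarms = len(onset_ms) - len(rts)
    return RTResult(rts_ms=rts, misses=misses, false_alarms=false_alarms)
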