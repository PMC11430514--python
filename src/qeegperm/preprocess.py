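"""Signal conditioning: filtering, re-referencing, ICA ocular correction,
and threshold-based artifact epoch rejection.

All filters are zero-phase (forward-backward order-4 Butterworth), so ERP
latencies are preserved.  The artifact rules flag an epoch when any channel
exceeds (a) 100 µV on the unfiltered signal, (b) 50 µV in the 0-1 Hz band,
or (c) 35 µV in the 20-35 Hz band; comparisons are strict and the flags are
unioned.  A quality gate then requires a minimum number of clean epochs
(default 8, i.e. about 40 s at the default 5 s epoch length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .containers import (
    FLAG_ABS,
    FLAG_FAST,
    FLAG_SLOW,
    EEGRecording,
    EpochSet,
    QualityGateError,
)
from .montage import CHANNELS_1020


class ReferenceStateError(RuntimeError):
    """Raised when a recording is re-referenced twice."""


@dataclass
class ArtifactRules:
    """Epoch-rejection thresholds (µV) and the clean-data quality gate."""

    abs_threshold: float = 100.0       # on the unfiltered signal
    slow_threshold: float = 50.0       # in the 0-1 Hz band
    fast_threshold: float = 35.0       # in the 20-35 Hz band
    epoch_length_s: float = 5.0
    min_clean_epochs: int = 8

    def __post_init__(self) -> None:
        if min(self.abs_threshold, self.slow_threshold, self.fast_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        if self.min_clean_epochs < 1:
            raise ValueError("min_clean_epochs must be >= 1")


def _sos_filtfilt(data: np.ndarray, fs: float, btype: str, band) -> np.ndarray:
    sos = signal.butter(4, band, btype=btype, fs=fs, output="sos")
    # generous reflect-padding keeps edge transients of the low cutoffs small
    padlen = min(data.shape[-1] - 1, 3 * int(fs))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def bandpass(rec: EEGRecording, low: float, high: float) -> EEGRecording:
    """Zero-phase band-pass; events/metadata preserved."""
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) for fs={rec.sampling_rate}")
    return rec.copy_with(data=_sos_filtfilt(rec.data, rec.sampling_rate, "bandpass", (low, high)))


def notch(rec: EEGRecording, band: tuple[float, float] = (45.0, 55.0)) -> EEGRecording:
    """Zero-phase band-stop, by default 45-55 Hz against mains interference."""
    nyq = rec.sampling_rate / 2.0
    low, high = band
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid notch band {band} for fs={rec.sampling_rate}")
    return rec.copy_with(data=_sos_filtfilt(rec.data, rec.sampling_rate, "bandstop", band))


def reref_weighted_average(rec: EEGRecording, weights: Optional[np.ndarray] = None) -> EEGRecording:
    """Subtract a (weighted) channel mean from every sample.

    Default weights are uniform, i.e. the plain average reference; a custom
    weight vector can be supplied.  Re-referencing an already re-referenced
    recording is a state error.
    """
    if rec.reference == "weighted_average":
        raise ReferenceStateError("recording is already weighted-average referenced")
    n_ch = rec.n_channels
    if weights is None:
        w = np.full(n_ch, 1.0 / n_ch)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_ch,):
            raise ValueError("weights must have one entry per channel")
        if w.sum() == 0:
            raise ValueError("weights must not sum to zero")
        w = w / w.sum()
    ref = w @ rec.data
    return rec.copy_with(data=rec.data - ref[None, :], reference="weighted_average")


#: Frontal ocular template: unit map maximal at Fp1/Fp2, fading to zero
#: posteriorly; ICA component topographies are matched against it.
OCULAR_TEMPLATE = {
    "Fp1": 1.0, "Fp2": 1.0,
    "F7": 0.45, "F3": 0.5, "Fz": 0.5, "F4": 0.5, "F8": 0.45,
    "T3": 0.1, "C3": 0.15, "Cz": 0.15, "C4": 0.15, "T4": 0.1,
}


def ocular_template_vector(channel_labels) -> np.ndarray:
    return np.array([OCULAR_TEMPLATE.get(c, 0.0) for c in channel_labels])


@dataclass
class ICAReport:
    n_components: int
    removed: list[int]
    template_correlations: list[float]
    threshold: float


def remove_ocular_ica(
    rec: EEGRecording,
    prefilter_band: tuple[float, float] = (2.0, 30.0),
    seed: int = 0,
    template: Optional[np.ndarray] = None,
    threshold: float = 0.8,
    n_components: Optional[int] = None,
    min_duration_s: float = 60.0,
    decim: int = 8,
) -> tuple[EEGRecording, ICAReport]:
    """Remove eye-movement components by template-matched ICA.

    The unmixing is estimated by extended-Infomax ICA on a copy band-passed
    to ``prefilter_band`` (2-30 Hz, limiting low-frequency overlearning);
    components whose sensor topography correlates with the frontal ocular
    template at ``|rho| >= threshold`` are zeroed and the *original*
    recording is reconstructed without them.
    """
    import mne

    if rec.duration < min_duration_s:
        raise ValueError(
            f"need >= {min_duration_s:.0f} s of data for a stable unmixing, "
            f"got {rec.duration:.1f} s"
        )
    filt = bandpass(rec, *prefilter_band)
    info = mne.create_info(list(rec.channel_labels), rec.sampling_rate, ch_types="eeg")
    raw_fit = mne.io.RawArray(filt.data * 1e-6, info, verbose="error")
    ica = mne.preprocessing.ICA(
        n_components=n_components,
        method="infomax",
        fit_params={"extended": True},
        random_state=int(seed) % 2**31,
        max_iter=1000,
        verbose="error",
    )
    ica.fit(raw_fit, decim=max(int(decim), 1), verbose="error")

    topo = ica.get_components()            # (n_channels, n_components)
    if template is None:
        template = ocular_template_vector(rec.channel_labels)
    t = template - template.mean()
    corrs = []
    for k in range(topo.shape[1]):
        v = topo[:, k] - topo[:, k].mean()
        denom = np.linalg.norm(t) * np.linalg.norm(v)
        corrs.append(float(t @ v / denom) if denom > 0 else 0.0)
    removed = [k for k, c in enumerate(corrs) if abs(c) >= threshold]

    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    if removed:
        ica.apply(raw, exclude=removed, verbose="error")
    out = rec.copy_with(data=raw.get_data() * 1e6)
    report = ICAReport(
        n_components=topo.shape[1],
        removed=removed,
        template_correlations=corrs,
        threshold=threshold,
    )
    return out, report


def mark_artifact_epochs(
    rec: EEGRecording,
    rules: ArtifactRules,
    analysis_rec: Optional[EEGRecording] = None,
) -> EpochSet:
    """Cut consecutive non-overlapping epochs and flag artifact rules.

    Rule signals are derived from ``rec`` (the amplitude rule from the
    signal as given, the slow/fast rules from 0-1 Hz and 20-35 Hz filtered
    copies).  If ``analysis_rec`` is supplied (e.g. a band-passed version of
    the same recording) its samples populate the returned epochs while the
    flags still come from ``rec``.
    """
    if analysis_rec is not None and analysis_rec.n_samples != rec.n_samples:
        raise ValueError("analysis_rec must match rec in length")
    fs = rec.sampling_rate
    ep_len = int(round(rules.epoch_length_s * fs))
    n_ep = rec.n_samples // ep_len

    slow = _sos_filtfilt(rec.data, fs, "lowpass", 1.0)
    fast = _sos_filtfilt(rec.data, fs, "bandpass", (20.0, 35.0))
    src = analysis_rec.data if analysis_rec is not None else rec.data

    epochs = np.empty((n_ep, rec.n_channels, ep_len))
    flags: list[set] = []
    starts = np.arange(n_ep) * ep_len
    for e, s in enumerate(starts):
        sl = slice(s, s + ep_len)
        epochs[e] = src[:, sl]
        fl = set()
        if np.abs(rec.data[:, sl]).max() > rules.abs_threshold:
            fl.add(FLAG_ABS)
        if np.abs(slow[:, sl]).max() > rules.slow_threshold:
            fl.add(FLAG_SLOW)
        if np.abs(fast[:, sl]).max() > rules.fast_threshold:
            fl.add(FLAG_FAST)
        flags.append(fl)

    return EpochSet(
        epochs=epochs,
        channel_labels=rec.channel_labels,
        sampling_rate=fs,
        flags=flags,
        condition_labels=[rec.condition or "rest"] * n_ep,
        start_samples=starts,
        subject_id=rec.subject_id,
        condition=rec.condition,
    )


def artifact_sample_mask(rec: EEGRecording, rules: ArtifactRules) -> np.ndarray:
    """Boolean per-sample mask of artifact-flagged epoch spans."""
    epochs = mark_artifact_epochs(rec, rules)
    mask = np.zeros(rec.n_samples, dtype=bool)
    ep_len = int(round(rules.epoch_length_s * rec.sampling_rate))
    for s, fl in zip(epochs.start_samples, epochs.flags):
        if fl:
            mask[s: s + ep_len] = True
    return mask


def require_min_clean(epochs: EpochSet, rules: ArtifactRules) -> EpochSet:
    """Return the clean epochs, or raise if fewer than the quality gate."""
    clean = epochs.select(epochs.clean_mask)
    if clean.n_epochs < rules.min_clean_epochs:
        raise QualityGateError(
            f"subject {epochs.subject_id!r} condition {epochs.condition!r}: "
            f"{clean.n_epochs} artifact-free epochs < required {rules.min_clean_epochs}"
        )
    return clean
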