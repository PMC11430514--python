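"""Per-channel spectra, group grand averages, and difference spectra.

Spectra are Welch-style averages of per-epoch Hann-tapered FFT power over
artifact-free epochs; with the default 5 s epochs the frequency resolution
is 0.2 Hz over the 0-30 Hz analysis band.  Three quantities are carried per
(channel, bin): power (µV², the per-bin integrated PSD), amplitude (µV,
square root of power), and relative amplitude (% of the channel's summed
amplitude over the band) — the group statistic compared downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, QualityGateError

ANALYSIS_BAND = (0.0, 30.0)


@dataclass
class SpectrumSet:
    """One subject/condition: channel x frequency-bin spectra."""

    subject_id: str
    condition: str
    freqs: np.ndarray                 # Hz
    power: np.ndarray                 # (n_channels, n_bins), µV² per bin
    amplitude: np.ndarray             # µV
    relative_amplitude: np.ndarray    # % per channel over the band
    channel_labels: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channel_labels):
            rows.append(pd.DataFrame({
                "subject": self.subject_id,
                "condition": self.condition,
                "channel": ch,
                "freq_hz": self.freqs,
                "power_uv2": self.power[ci],
                "amplitude_uv": self.amplitude[ci],
                "rel_amp_pct": self.relative_amplitude[ci],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class GroupSpectra:
    """Grand average plus retained per-subject samples for statistics."""

    condition: str
    freqs: np.ndarray
    channel_labels: tuple[str, ...]
    subject_ids: list[str]
    power_samples: np.ndarray         # (n_subjects, n_channels, n_bins)
    amplitude_samples: np.ndarray
    relative_samples: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def grand_power(self) -> np.ndarray:
        return self.power_samples.mean(axis=0)

    @property
    def grand_amplitude(self) -> np.ndarray:
        return self.amplitude_samples.mean(axis=0)

    @property
    def grand_relative(self) -> np.ndarray:
        return self.relative_samples.mean(axis=0)

    def samples(self, metric: str = "relative_amplitude") -> np.ndarray:
        return {
            "power": self.power_samples,
            "amplitude": self.amplitude_samples,
            "relative_amplitude": self.relative_samples,
        }[metric]


def compute_spectrum(clean_epochs: EpochSet, band: tuple[float, float] = ANALYSIS_BAND) -> SpectrumSet:
    """Average per-epoch Hann periodograms; derive amplitude and relative %.

    Power is reported per bin (PSD integrated over the bin width) so that a
    pure sinusoid's power summed over its spectral peak equals its variance.
    """
    if clean_epochs.n_epochs < 1:
        raise QualityGateError("no clean epochs to compute a spectrum from")
    fs = clean_epochs.sampling_rate
    x = clean_epochs.epochs                       # (n_ep, n_ch, n_smp)
    freqs, psd = signal.periodogram(x, fs=fs, window="hann", axis=-1, scaling="density")
    df = freqs[1] - freqs[0]
    power = psd.mean(axis=0) * df                 # (n_ch, n_bins), µV² per bin
    keep = (freqs >= band[0]) & (freqs <= band[1])
    freqs = freqs[keep]
    power = power[:, keep]
    amplitude = np.sqrt(power)
    denom = amplitude.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    relative = 100.0 * amplitude / denom
    return SpectrumSet(
        subject_id=clean_epochs.subject_id,
        condition=clean_epochs.condition,
        freqs=freqs,
        power=power,
        amplitude=amplitude,
        relative_amplitude=relative,
        channel_labels=clean_epochs.channel_labels,
    )


def group_spectra(spectra: list[SpectrumSet]) -> GroupSpectra:
    """Stack per-subject spectra of one condition into a group container."""
    if not spectra:
        raise ValueError("empty group")
    ref = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.freqs, ref.freqs):
            raise ValueError("frequency axes differ across subjects")
        if s.channel_labels != ref.channel_labels:
            raise ValueError("channel sets differ across subjects")
    return GroupSpectra(
        condition=ref.condition,
        freqs=ref.freqs,
        channel_labels=ref.channel_labels,
        subject_ids=[s.subject_id for s in spectra],
        power_samples=np.stack([s.power for s in spectra]),
        amplitude_samples=np.stack([s.amplitude for s in spectra]),
        relative_samples=np.stack([s.relative_amplitude for s in spectra]),
    )


def group_difference_spectra(
    patients: GroupSpectra,
    controls: GroupSpectra,
    metric: str = "relative_amplitude",
) -> np.ndarray:
    """Patient-minus-control grand-average difference, (n_channels, n_bins)."""
    if patients.n_subjects == 0 or controls.n_subjects == 0:
        raise ValueError("both groups must be non-empty")
    if not np.array_equal(patients.freqs, controls.freqs):
        raise ValueError("frequency axes differ between groups")
    if patients.channel_labels != controls.channel_labels:
        raise ValueError("channel sets differ between groups")
    return patients.samples(metric).mean(axis=0) - controls.samples(metric).mean(axis=0)


def topographic_map(spectra: GroupSpectra, freq: float, metric: str = "power") -> np.ndarray:
    """Grand-average value per channel at the bin nearest ``freq``."""
    if not (spectra.freqs[0] <= freq <= spectra.freqs[-1]):
        raise ValueError(f"{freq} Hz outside the analysis band "
                         f"[{spectra.freqs[0]}, {spectra.freqs[-1]}]")
    b = int(np.argmin(np.abs(spectra.freqs - freq)))
    return spectra.samples(metric).mean(axis=0)[:, b]


def peak_frequency(
    spectra: GroupSpectra,
    channel: str,
    search_band: tuple[float, float] = (4.0, 13.0),
    metric: str = "power",
) -> float:
    """Frequency of the grand-average spectral maximum within a band."""
    ci = spectra.channel_labels.index(channel)
    grand = spectra.samples(metric).mean(axis=0)[ci]
    sel = (spectra.freqs >= search_band[0]) & (spectra.freqs <= search_band[1])
    if not sel.any():
        raise ValueError("empty search band")
    return float(spectra.freqs[sel][np.argmax(grand[sel])])
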