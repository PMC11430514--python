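"""File exchange: EDF recordings, event tables, subject tables, YAML config.

EDF is written by a small built-in writer (16-bit EDF, one-second data
records, per-signal symmetric physical range) and read back through MNE,
which also serves as the round-trip check in the tests.  Events travel as a
tab-separated table of (onset_ms, type, trial_index) rows; subjects as CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import EEGRecording, EventList, Trial
from .simulate import CohortSpec, EffectSpec, SubjectRecord

BUTTON_LABEL = "BUTTON"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> Path:
    """Write a recording (plus any button channel) as 16-bit EDF."""
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))               # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    signals = [rec.data[i] for i in range(rec.n_channels)]
    labels = [f"EEG {c}" for c in rec.channel_labels]
    if rec.button is not None:
        signals.append(rec.button)
        labels.append(BUTTON_LABEL)
    n_rec = int(np.ceil(rec.n_samples / spr))
    ns = len(signals)

    phys_max = [max(1.0, float(np.ceil(np.max(np.abs(s)) + 1e-6))) for s in signals]
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _pad("0", 8),
        _pad(f"subject {rec.subject_id}", 80),
        _pad(f"condition {rec.condition}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    header += b"".join(_pad(lab, 16) for lab in labels)
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad("uV" if lab != BUTTON_LABEL else "", 8) for lab in labels)
    header += b"".join(_pad(f"{-pm:g}", 8) for pm in phys_max)
    header += b"".join(_pad(f"{pm:g}", 8) for pm in phys_max)
    header += b"".join(_pad(str(dig_min), 8) for _ in range(ns))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad(str(spr), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for s, pm in zip(signals, phys_max):
                chunk = s[r * spr: (r + 1) * spr]
                if len(chunk) < spr:
                    chunk = np.pad(chunk, (0, spr - len(chunk)))
                scale = dig_max / pm
                dig = np.clip(np.round(chunk * scale), dig_min, dig_max).astype("<i2")
                fh.write(dig.tobytes())
    return path


def read_edf(path, subject_id: str = "", condition: str = "") -> EEGRecording:
    """Read an EDF file back into an EEGRecording (µV)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    labels = [c.removeprefix("EEG ") for c in raw.ch_names]
    button = None
    if BUTTON_LABEL in labels:
        bi = labels.index(BUTTON_LABEL)
        button = data[bi] / 1e6      # stored unitless
        data = np.delete(data, bi, axis=0)
        labels = [c for c in labels if c != BUTTON_LABEL]
    return EEGRecording(
        data=data,
        channel_labels=tuple(labels),
        sampling_rate=float(raw.info["sfreq"]),
        reference="linked_ears",
        subject_id=subject_id,
        condition=condition,
        button=button,
    )


# ---------------------------------------------------------------------------
# events / subjects
# ---------------------------------------------------------------------------

def write_events_tsv(events: EventList, path) -> Path:
    """Tab-separated (onset_ms, type, trial_index) event rows."""
    rows = []
    for i, t in enumerate(events):
        rows.append({"onset_ms": t.cue_onset_ms, "type": f"cue_{t.pair_type}",
                     "trial_index": i})
        rows.append({"onset_ms": t.second_onset_ms, "type": f"second_{t.pair_type}",
                     "trial_index": i})
        if t.response_time_ms is not None:
            rows.append({"onset_ms": t.second_onset_ms + t.response_time_ms,
                         "type": "response", "trial_index": i})
    pd.DataFrame(rows, columns=["onset_ms", "type", "trial_index"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_events_tsv(path) -> EventList:
    df = pd.read_csv(path, sep="\t")
    trials: dict[int, dict] = {}
    for row in df.itertuples():
        d = trials.setdefault(int(row.trial_index), {})
        if row.type.startswith("cue_"):
            d["pair_type"] = row.type.removeprefix("cue_")
            d["cue_onset_ms"] = float(row.onset_ms)
        elif row.type.startswith("second_"):
            d["second_onset_ms"] = float(row.onset_ms)
        elif row.type == "response":
            d["response_ms"] = float(row.onset_ms)
    out = []
    for i in sorted(trials):
        d = trials[i]
        rt = d.get("response_ms")
        out.append(Trial(
            pair_type=d["pair_type"],
            cue_onset_ms=d["cue_onset_ms"],
            second_onset_ms=d["second_onset_ms"],
            response_time_ms=None if rt is None else rt - d["second_onset_ms"],
        ))
    return EventList(trials=out)


def write_subjects_csv(subjects: list[SubjectRecord], path) -> Path:
    pd.DataFrame([dataclasses.asdict(s) for s in subjects]).to_csv(
        path, index=False, float_format="%.17g")
    return Path(path)


def read_subjects_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples():
        score = row.behavioral_score
        out.append(SubjectRecord(
            subject_id=str(row.subject_id),
            group=str(row.group),
            true_nogo_amplitude=float(row.true_nogo_amplitude),
            behavioral_score=None if pd.isna(score) else float(score),
        ))
    return out


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> tuple[CohortSpec, EffectSpec, dict]:
    """YAML config with 'cohort' and 'effects' sections mirroring the
    CohortSpec / EffectSpec dataclasses."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cohort_kwargs = dict(cfg.get("cohort", {}))
    if "channel_labels" in cohort_kwargs:
        cohort_kwargs["channel_labels"] = tuple(cohort_kwargs["channel_labels"])
    cohort = CohortSpec(**cohort_kwargs)
    effects = EffectSpec(**cfg.get("effects", {}))
    extras = {k: v for k, v in cfg.items() if k not in ("cohort", "effects")}
    return cohort, effects, extras


def save_config(cohort: CohortSpec, effects: EffectSpec, path, **extras) -> Path:
    cfg = {
        "cohort": {**dataclasses.asdict(cohort),
                   "channel_labels": list(cohort.channel_labels)},
        "effects": dataclasses.asdict(effects),
        **extras,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return Path(path)
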