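"""Shared fixtures.

The two session-scoped "bundle" fixtures simulate a full 9-patient /
50-control cohort once, at a reduced per-subject session length (spectra
need only a few dozen clean 5 s epochs, ERPs a few dozen trials per type),
and are shared by all group-level recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import qeegperm as q
from qeegperm.pipeline import (
    cohort_erp_analysis,
    cohort_group_spectra,
    erp_cluster_test,
    spectral_cluster_tests,
)


@pytest.fixture(scope="session")
def montage() -> q.MontageGraph:
    return q.MontageGraph.standard_1020()


@pytest.fixture()
def rules() -> q.ArtifactRules:
    return q.ArtifactRules()


@pytest.fixture()
def quiet_effects() -> q.EffectSpec:
    """No noise, no blinks, no artifacts: deterministic forward model only."""
    return q.EffectSpec(
        pink_rms_uv=0.0, white_rms_uv=0.0,
        blink_amplitude_uv=0.0, blink_rate_per_min=0.0,
        artifact_amplitude_uv=0.0, artifact_rate_per_min=0.0,
    )


def make_recording(data: np.ndarray, fs: float = 250.0, **kwargs) -> q.EEGRecording:
    """Recording over the standard montage from a (19, n) array."""
    return q.EEGRecording(data=data, channel_labels=q.CHANNELS_1020,
                          sampling_rate=fs, **kwargs)


@pytest.fixture(scope="session")
def spectral_bundle(montage):
    """Default 9/50 cohort, all three conditions, at reduced session length:
    2-minute resting runs and a 100-trial task run per subject."""
    cohort = q.CohortSpec(
        seed=7, n_trials=100,
        session_durations={"eyes_open": 120.0, "eyes_closed": 120.0},
    )
    effects = q.EffectSpec()
    subjects = q.generate_cohort(cohort, effects, cohort.seed)
    spectra = cohort_group_spectra(subjects, cohort, effects, seed=cohort.seed)
    results = spectral_cluster_tests(spectra, montage, n_perm=1000, seed=cohort.seed)
    return {"cohort": cohort, "effects": effects, "subjects": subjects,
            "spectra": spectra, "cluster_results": results}


@pytest.fixture(scope="session")
def erp_bundle(montage):
    """Default 9/50 cohort, 80-trial task sessions, NOGO group comparison."""
    cohort = q.CohortSpec(seed=7, n_trials=80)
    effects = q.EffectSpec()
    subjects = q.generate_cohort(cohort, effects, cohort.seed)
    components, nogo_maps, times, labels = cohort_erp_analysis(
        subjects, cohort, effects, seed=cohort.seed)
    result = erp_cluster_test(nogo_maps, times, labels, montage,
                              n_perm=1000, seed=cohort.seed)
    return {"cohort": cohort, "effects": effects, "subjects": subjects,
            "components": components, "nogo_maps": nogo_maps,
            "times_ms": times, "channel_labels": labels, "cluster_result": result}
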