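"""Filters, re-referencing, ICA ocular correction, artifact rules."""

import numpy as np
import pytest

import qeegperm as q
from qeegperm.containers import QualityGateError
from qeegperm.preprocess import ReferenceStateError, ocular_template_vector
from qeegperm.simulate import (
    BLINK_TOPOGRAPHY,
    CONTROL_ALPHA_TOPOGRAPHY,
    _subject_seed,
)

from conftest import make_recording

FS = 250.0


def sinusoid_rec(freq: float, amp: float = 10.0, seconds: float = 20.0) -> q.EEGRecording:
    t = np.arange(int(seconds * FS)) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    return make_recording(np.tile(x, (19, 1)))


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


class TestFilters:
    def test_bandpass_stops_out_of_band(self):
        rec = sinusoid_rec(60.0)
        out = q.bandpass(rec, 0.5, 30.0)
        core = slice(int(2 * FS), -int(2 * FS))   # steady-state response
        assert rms(out.data[0][core]) < 0.05 * rms(rec.data[0][core])

    def test_bandpass_preserves_passband(self):
        rec = sinusoid_rec(10.0)
        out = q.bandpass(rec, 0.5, 30.0)
        core = slice(int(2 * FS), -int(2 * FS))   # avoid edge transients
        assert rms(out.data[0][core]) == pytest.approx(rms(rec.data[0][core]), rel=0.02)

    def test_bandpass_zero_in_zero_out(self):
        rec = make_recording(np.zeros((19, 2500)))
        assert np.allclose(q.bandpass(rec, 0.5, 30.0).data, 0.0)

    def test_bandpass_invalid_band(self):
        rec = sinusoid_rec(10.0)
        with pytest.raises(ValueError):
            q.bandpass(rec, 30.0, 0.5)
        with pytest.raises(ValueError):
            q.bandpass(rec, 1.0, 200.0)

    def test_notch_attenuates_50hz(self):
        rec = sinusoid_rec(50.0)
        out = q.notch(rec)
        assert rms(out.data[0]) <= 0.10 * rms(rec.data[0])

    def test_notch_preserves_10hz(self):
        rec = sinusoid_rec(10.0)
        out = q.notch(rec)
        core = slice(int(2 * FS), -int(2 * FS))
        assert rms(out.data[0][core]) == pytest.approx(rms(rec.data[0][core]), rel=0.02)

    def test_filters_are_linear(self):
        rng = np.random.default_rng(0)
        x = make_recording(rng.standard_normal((19, 2500)))
        y = make_recording(rng.standard_normal((19, 2500)))
        combo = make_recording(2.0 * x.data - 3.0 * y.data)
        lhs = q.bandpass(combo, 0.5, 30.0).data
        rhs = 2.0 * q.bandpass(x, 0.5, 30.0).data - 3.0 * q.bandpass(y, 0.5, 30.0).data
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestReref:
    def test_uniform_weights_zero_sum(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.standard_normal((19, 500)))
        out = q.reref_weighted_average(rec)
        assert np.allclose(out.data.sum(axis=0), 0.0, atol=1e-10)
        assert out.reference == "weighted_average"

    def test_single_channel_retains_18_19(self):
        data = np.zeros((19, 100))
        data[4] = 19.0
        out = q.reref_weighted_average(make_recording(data))
        assert np.allclose(out.data[4], 18.0)          # 19 * 18/19
        assert np.allclose(out.data[0], -1.0)

    def test_common_offset_removed(self):
        out = q.reref_weighted_average(make_recording(np.full((19, 100), 42.0)))
        assert np.allclose(out.data, 0.0)

    def test_double_reref_rejected(self):
        rec = q.reref_weighted_average(make_recording(np.zeros((19, 100))))
        with pytest.raises(ReferenceStateError):
            q.reref_weighted_average(rec)

    def test_bipolar_derivations_reference_invariant(self):
        rng = np.random.default_rng(2)
        rec = make_recording(rng.standard_normal((19, 500)))
        out = q.reref_weighted_average(rec)
        assert np.allclose(rec.data[3] - rec.data[9], out.data[3] - out.data[9])

    def test_custom_weights(self):
        w = np.zeros(19)
        w[0] = 1.0                      # reference to channel 0
        rng = np.random.default_rng(3)
        rec = make_recording(rng.standard_normal((19, 100)))
        out = q.reref_weighted_average(rec, weights=w)
        assert np.allclose(out.data[0], 0.0)
        assert np.allclose(out.data[5], rec.data[5] - rec.data[0])


class TestArtifactRules:
    def test_abs_rule_boundary(self, rules):
        data = np.zeros((19, 2500))       # two 5 s epochs
        data[7, 100] = 101.0
        epochs = q.mark_artifact_epochs(make_recording(data), rules)
        assert epochs.flags[0] == {"abs"}
        assert epochs.flags[1] == set()
        # exactly at threshold: strict comparison, not flagged
        data2 = np.zeros((19, 2500))
        data2[7, 100] = 100.0
        epochs2 = q.mark_artifact_epochs(make_recording(data2), rules)
        assert epochs2.flags[0] == set()

    def test_all_zero_clean(self, rules):
        epochs = q.mark_artifact_epochs(make_recording(np.zeros((19, 2500))), rules)
        assert all(f == set() for f in epochs.flags)

    def test_slow_rule_only(self, rules):
        t = np.arange(5000) / FS
        data = np.tile(60.0 * np.sin(2 * np.pi * 0.5 * t), (19, 1))
        epochs = q.mark_artifact_epochs(make_recording(data), rules)
        assert all(f == {"slow"} for f in epochs.flags)

    def test_fast_rule_only(self, rules):
        t = np.arange(5000) / FS
        data = np.tile(40.0 * np.sin(2 * np.pi * 25.0 * t), (19, 1))
        epochs = q.mark_artifact_epochs(make_recording(data), rules)
        assert all(f == {"fast"} for f in epochs.flags)

    def test_flagging_is_idempotent(self, rules):
        rng = np.random.default_rng(5)
        rec = make_recording(30.0 * rng.standard_normal((19, 12500)))
        a = q.mark_artifact_epochs(rec, rules)
        b = q.mark_artifact_epochs(rec, rules)
        assert a.flags == b.flags

    def test_inserted_artifacts_flagged_exactly(self, rules, quiet_effects):
        eff = quiet_effects
        eff.artifact_amplitude_uv = 200.0
        eff.pink_rms_uv = 6.0
        eff.white_rms_uv = 1.5
        cohort = q.CohortSpec(seed=4, session_durations={"eyes_open": 100.0,
                                                         "eyes_closed": 100.0})
        s = q.SubjectRecord("P01", "patient", true_nogo_amplitude=2.0)
        rec = q.synthesize_session(s, "eyes_open", cohort, eff, seed=4,
                                   artifact_times_s=[12.5, 61.0])
        epochs = q.mark_artifact_epochs(rec, rules)
        flagged = {i for i, f in enumerate(epochs.flags) if f}
        assert flagged == {2, 12}      # 12.5 s -> epoch 2; 61 s -> epoch 12

    def test_quality_gate_boundary(self, rules):
        # ten 5 s epochs (1250 samples each at 250 Hz); spikes dirty them one by one
        data = np.zeros((19, 10 * 1250))
        data[0, 0] = 500.0
        data[0, 1251] = 500.0            # two dirty -> 8 clean: passes
        ep = q.mark_artifact_epochs(make_recording(data), rules)
        clean = q.require_min_clean(ep, rules)
        assert clean.n_epochs == 8
        data[0, 2502] = 500.0            # three dirty -> 7 clean: gate trips
        ep7 = q.mark_artifact_epochs(make_recording(data), rules)
        with pytest.raises(QualityGateError):
            q.require_min_clean(ep7, rules)

    def test_empty_recording_trips_gate(self, rules):
        ep = q.mark_artifact_epochs(make_recording(np.zeros((19, 100))), rules)
        assert ep.n_epochs == 0
        with pytest.raises(QualityGateError):
            q.require_min_clean(ep, rules)


@pytest.fixture(scope="module")
def blinky_session():
    cohort = q.CohortSpec(seed=2, session_durations={"eyes_open": 120.0,
                                                     "eyes_closed": 120.0})
    eff = q.EffectSpec(artifact_amplitude_uv=0.0)
    s = q.SubjectRecord("S01", "control", true_nogo_amplitude=5.0)
    rec = q.synthesize_session(s, "eyes_open", cohort, eff, seed=3)
    # reconstruct ground-truth blink onsets from the seeded stream
    rng_blink = _subject_seed(3, "S01", "blinks:eyes_open")
    n_blinks = rng_blink.poisson(eff.blink_rate_per_min * rec.duration / 60.0)
    starts = np.sort(rng_blink.uniform(0, rec.duration, size=n_blinks))
    return rec, starts


class TestOcularICA:

    def test_blink_component_removed(self, blinky_session):
        rec, starts = blinky_session
        out, report = q.remove_ocular_ica(rec, seed=0)
        assert len(report.removed) == 1
        assert abs(report.template_correlations[report.removed[0]]) >= 0.8
        fs = rec.sampling_rate
        mask = np.zeros(rec.n_samples, bool)
        for st in starts:
            a = int(st * fs)
            mask[a: a + int(0.4 * fs)] = True
        fp1 = rec.channel_index("Fp1")
        v_before = rec.data[fp1][mask].var()
        v_after = out.data[fp1][mask].var()
        assert v_after <= 0.3 * v_before     # >= 70% variance removed

    def test_no_blinks_nothing_removed(self):
        cohort = q.CohortSpec(seed=2, session_durations={"eyes_open": 120.0,
                                                         "eyes_closed": 120.0})
        eff = q.EffectSpec(artifact_amplitude_uv=0.0, blink_amplitude_uv=0.0)
        s = q.SubjectRecord("S02", "control", true_nogo_amplitude=5.0)
        rec = q.synthesize_session(s, "eyes_open", cohort, eff, seed=5)
        _, report = q.remove_ocular_ica(rec, seed=0)
        assert report.removed == []

    def test_posterior_alpha_map_never_matches_template(self):
        t = ocular_template_vector(q.CHANNELS_1020)
        alpha = np.array([CONTROL_ALPHA_TOPOGRAPHY[c] for c in q.CHANNELS_1020])
        blink = np.array([BLINK_TOPOGRAPHY[c] for c in q.CHANNELS_1020])
        assert abs(np.corrcoef(t, alpha)[0, 1]) < 0.8
        assert np.corrcoef(t, blink)[0, 1] > 0.95

    def test_short_recording_rejected(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((19, 1000)))
        with pytest.raises(ValueError, match="60"):
            q.remove_ocular_ica(rec, seed=0)
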