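"""End-to-end orchestration: simulate -> preprocess -> spectra/ERP ->
cluster statistics -> correlation -> report.

The in-memory helpers stream one subject at a time (a full task session is
~20 minutes of 19-channel EEG, so whole-cohort arrays are never held at
once) and are what the command-line interface, the tests and the
reproduction script all build on.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import erp as erp_mod
from .cluster_stats import ClusterTestResult, permutation_test
from .containers import EEGRecording, EpochSet, QualityGateError
from .montage import MontageGraph
from .preprocess import (
    ArtifactRules,
    bandpass,
    mark_artifact_epochs,
    notch,
    remove_ocular_ica,
    reref_weighted_average,
    require_min_clean,
)
from .report import CorrelationResult, build_report, correlate
from .simulate import (
    CONDITIONS,
    CohortSpec,
    EffectSpec,
    SubjectRecord,
    generate_cohort,
    synthesize_session,
)
from .spectral import GroupSpectra, compute_spectrum, group_difference_spectra, group_spectra

log = logging.getLogger("qeegperm")

#: analysis band of the digital band-pass applied before spectra/ERPs
ANALYSIS_BANDPASS = (0.53, 30.0)


def preprocess_session(
    rec: EEGRecording,
    rules: Optional[ArtifactRules] = None,
    reref: bool = True,
    do_ica: bool = False,
    ica_seed: int = 0,
) -> tuple[EpochSet, dict]:
    """Condition one recording and cut it into flagged epochs.

    Chain: weighted-average re-reference, optional ICA ocular correction,
    artifact flagging on the broadband signal, then notch + band-pass for
    the analysis copy that populates the epochs.  Returns all epochs (clean
    and flagged) plus a JSON-able preprocessing report.
    """
    rules = rules or ArtifactRules()
    report: dict = {"subject": rec.subject_id, "condition": rec.condition}
    if reref:
        rec = reref_weighted_average(rec)
    if do_ica:
        rec, ica_report = remove_ocular_ica(rec, seed=ica_seed)
        report["ica"] = {
            "removed": ica_report.removed,
            "correlations": [round(c, 3) for c in ica_report.template_correlations],
        }
    analysis = bandpass(notch(rec), *ANALYSIS_BANDPASS)
    epochs = mark_artifact_epochs(rec, rules, analysis_rec=analysis)
    report["n_epochs"] = epochs.n_epochs
    report["n_clean"] = epochs.n_clean
    report["flags"] = {
        rule: int(sum(rule in f for f in epochs.flags))
        for rule in ("abs", "slow", "fast")
    }
    return epochs, report


def cohort_group_spectra(
    subjects: Sequence[SubjectRecord],
    cohort: CohortSpec,
    effects: EffectSpec,
    seed: int,
    conditions: Sequence[str] = CONDITIONS,
    rules: Optional[ArtifactRules] = None,
    do_ica: bool = False,
) -> dict[str, tuple[GroupSpectra, GroupSpectra]]:
    """Per-condition (patients, controls) group spectra, streaming subjects."""
    rules = rules or ArtifactRules()
    out: dict[str, tuple[GroupSpectra, GroupSpectra]] = {}
    for cond in conditions:
        by_group = {"patient": [], "control": []}
        for subj in subjects:
            rec = synthesize_session(subj, cond, cohort, effects, seed)
            epochs, _ = preprocess_session(rec, rules, do_ica=do_ica, ica_seed=seed)
            clean = require_min_clean(epochs, rules)
            by_group[subj.group].append(compute_spectrum(clean))
        out[cond] = (group_spectra(by_group["patient"]), group_spectra(by_group["control"]))
    return out


def cohort_erp_analysis(
    subjects: Sequence[SubjectRecord],
    cohort: CohortSpec,
    effects: EffectSpec,
    seed: int,
    rules: Optional[ArtifactRules] = None,
    do_ica: bool = False,
) -> tuple[pd.DataFrame, dict[str, dict[str, np.ndarray]], np.ndarray, tuple]:
    """Per-subject ERP components and NOGO waveform maps for group stats.

    Returns (component table, {group: {subject: NOGO waveform map}},
    times_ms, channel_labels).  The task recording is re-referenced and
    band-passed like the resting data; trials overlapping flagged epochs
    are excluded inside ``epoch_and_average``.
    """
    rules = rules or ArtifactRules()
    comp_rows = []
    nogo_maps: dict[str, dict[str, np.ndarray]] = {"patient": {}, "control": {}}
    times = None
    labels = None
    for subj in subjects:
        rec = synthesize_session(subj, "task", cohort, effects, seed)
        rec = reref_weighted_average(rec)
        if do_ica:
            rec, _ = remove_ocular_ica(rec, seed=seed)
        filtered = bandpass(notch(rec), *ANALYSIS_BANDPASS)
        erps = erp_mod.epoch_and_average(filtered, rules=rules)
        table = erp_mod.measure_components(erps)
        table["group"] = subj.group
        comp_rows.append(table)
        if "NOGO" in erps:
            nogo_maps[subj.group][subj.subject_id] = erps["NOGO"].waveform
            times = erps["NOGO"].times_ms
            labels = erps["NOGO"].channel_labels
    return pd.concat(comp_rows, ignore_index=True), nogo_maps, times, labels


def spectral_cluster_tests(
    spectra: dict[str, tuple[GroupSpectra, GroupSpectra]],
    montage: Optional[MontageGraph] = None,
    n_perm: int = 1000,
    p_threshold: float = 0.05,
    seed: int = 0,
    metric: str = "relative_amplitude",
) -> dict[str, ClusterTestResult]:
    """Patients-vs-controls rank-sum cluster test per condition."""
    montage = montage or MontageGraph.standard_1020()
    out = {}
    for cond, (pat, ctl) in spectra.items():
        out[cond] = permutation_test(
            pat.samples(metric), ctl.samples(metric), montage,
            design="independent", n_perm=n_perm, p_threshold=p_threshold,
            seed=seed, channel_labels=pat.channel_labels, bin_values=pat.freqs,
        )
    return out


def erp_cluster_test(
    nogo_maps: dict[str, dict[str, np.ndarray]],
    times_ms: np.ndarray,
    channel_labels: tuple,
    montage: Optional[MontageGraph] = None,
    n_perm: int = 1000,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Patients-vs-controls cluster test on the NOGO average waveforms."""
    montage = montage or MontageGraph.standard_1020()
    a = np.stack(list(nogo_maps["patient"].values()))
    b = np.stack(list(nogo_maps["control"].values()))
    return permutation_test(
        a, b, montage, design="independent", n_perm=n_perm,
        p_threshold=p_threshold, seed=seed,
        channel_labels=tuple(channel_labels), bin_values=times_ms,
    )


def patient_correlation(components: pd.DataFrame, subjects: Sequence[SubjectRecord],
                        n_perm: Optional[int] = 5000, seed: int = 0) -> CorrelationResult:
    """Late NOGO amplitude at Cz vs behavioral score, patients only."""
    comp = components[(components.component == "late_NOGO_Cz")
                      & (components.group == "patient")]
    scores = {s.subject_id: s.behavioral_score for s in subjects if s.group == "patient"}
    merged = [(row.amplitude_uv, scores[row.subject])
              for row in comp.itertuples() if scores.get(row.subject) is not None]
    x, y = zip(*merged)
    return correlate(np.array(x), np.array(y), n_perm=n_perm, seed=seed)


def run_all(
    cohort: CohortSpec,
    effects: EffectSpec,
    outdir,
    seed: Optional[int] = None,
    conditions: Sequence[str] = CONDITIONS,
    rules: Optional[ArtifactRules] = None,
    do_ica: bool = True,
    n_perm: int = 1000,
    with_correlation: bool = True,
) -> dict:
    """Full pipeline on a simulated cohort; writes tables, JSON and report."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cohort.seed if seed is None else seed
    rules = rules or ArtifactRules()
    montage = MontageGraph.standard_1020()

    subjects = generate_cohort(cohort, effects, seed)
    from .io import save_config, write_subjects_csv
    write_subjects_csv(subjects, outdir / "subjects.csv")
    save_config(cohort, effects, outdir / "config.yaml", seed=seed)

    log.info("spectra: %d subjects x %d conditions", len(subjects), len(conditions))
    spectra = cohort_group_spectra(subjects, cohort, effects, seed,
                                   conditions=conditions, rules=rules, do_ica=do_ica)
    spec_rows = []
    for cond, (pat, ctl) in spectra.items():
        for grp_name, grp in (("patient", pat), ("control", ctl)):
            grand = grp.grand_relative
            for ci, ch in enumerate(grp.channel_labels):
                spec_rows.append(pd.DataFrame({
                    "condition": cond, "group": grp_name, "channel": ch,
                    "freq_hz": grp.freqs, "rel_amp_pct": grand[ci],
                }))
    pd.concat(spec_rows, ignore_index=True).to_csv(outdir / "group_spectra.csv", index=False)

    log.info("spectral cluster tests (%d permutations)", n_perm)
    cluster_results = spectral_cluster_tests(spectra, montage, n_perm=n_perm, seed=seed)
    for cond, res in cluster_results.items():
        res.save_json(outdir / f"clusters_spectra_{cond}.json")

    log.info("ERP analysis")
    components, nogo_maps, times, labels = cohort_erp_analysis(
        subjects, cohort, effects, seed, rules=rules, do_ica=do_ica)
    components.to_csv(outdir / "components.csv", index=False)
    erp_result = erp_cluster_test(nogo_maps, times, labels, montage,
                                  n_perm=n_perm, seed=seed)
    erp_result.save_json(outdir / "clusters_erp_nogo.json")

    correlation = None
    if with_correlation:
        correlation = patient_correlation(components, subjects, seed=seed)
        (outdir / "correlation.json").write_text(json.dumps(correlation.to_dict(), indent=2))

    diff = {cond: (pat, ctl, group_difference_spectra(pat, ctl))
            for cond, (pat, ctl) in spectra.items()}
    erp_tables = {"NOGO": components[components.component == "late_NOGO_Cz"]}
    all_clusters = {**{f"spectra_{c}": r for c, r in cluster_results.items()},
                    "erp_NOGO": erp_result}
    build_report(
        outdir,
        spectra={c: diff[c] for c in diff},
        erp=erp_tables,
        clusters={c: cluster_results[c] for c in cluster_results} | {"erp_NOGO": erp_result},
        correlation=correlation,
        settings={"seed": seed, "n_perm": n_perm,
                  "n_patients": cohort.n_patients, "n_controls": cohort.n_controls,
                  "n_trials": cohort.n_trials, "elapsed_s": round(time.time() - t0, 1)},
        disabled=() if with_correlation else ("correlation",),
    )
    return {
        "subjects": subjects,
        "spectra": spectra,
        "cluster_results": cluster_results,
        "components": components,
        "erp_cluster": erp_result,
        "correlation": correlation,
    }
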