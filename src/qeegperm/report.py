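"""Correlation of ERP component amplitude with behavioral scores, and the
pipeline summary report.

The headline analysis relates the late NOGO positivity at Cz to the delayed
recall T-score across patients: Pearson r with the usual t-transform
p-value, plus an optional permutation p (the t approximation is strained at
n around 9) and a Fisher-z confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    x_name: str
    y_name: str
    pairs: list[tuple[float, float]]
    perm_p: Optional[float] = None

    def fisher_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        return fisher_ci(self.r, self.n, alpha)

    def to_dict(self) -> dict:
        lo, hi = self.fisher_ci()
        return {
            "r": self.r, "p": self.p, "n": self.n,
            "perm_p": self.perm_p,
            "ci95": [lo, hi],
            "x": self.x_name, "y": self.y_name,
            "pairs": [[float(x), float(y)] for x, y in self.pairs],
        }


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        return (-1.0, 1.0)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.isf(alpha / 2.0)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def correlate(
    x,
    y,
    x_name: str = "late_NOGO_Cz_uv",
    y_name: str = "delayed_recall_tscore",
    n_perm: Optional[int] = None,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t transform.

    With ``n_perm`` set, a permutation p-value (shuffling y, seeded,
    +1-corrected) is also computed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: zero variance")
    res = stats.pearsonr(x, y)
    out = CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=len(x),
        x_name=x_name, y_name=y_name, pairs=list(zip(x, y)),
    )
    if n_perm:
        rng = np.random.default_rng(seed)
        robs = abs(out.r)
        count = 0
        for _ in range(n_perm):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            count += abs(rp) >= robs
        out.perm_p = (1 + count) / (1 + n_perm)
    return out


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

REPORT_SECTIONS = ("spectra", "erp", "clusters", "correlation")


def build_report(
    outdir,
    spectra=None,
    erp=None,
    clusters=None,
    correlation: Optional[CorrelationResult] = None,
    settings: Optional[dict] = None,
    disabled: tuple[str, ...] = (),
) -> Path:
    """Assemble the pipeline's Markdown summary report.

    Each of the four sections (group spectra, ERP overlays, cluster tables,
    correlation scatter) must be supplied unless listed in ``disabled``, in
    which case the report records the omission.  Figures are written next
    to the report; numeric content comes from the supplied stage outputs
    only, so regeneration from saved intermediates is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_values = {"spectra": spectra, "erp": erp, "clusters": clusters,
                    "correlation": correlation}
    for name in REPORT_SECTIONS:
        if name not in disabled and stage_values[name] is None:
            raise ValueError(f"missing stage output: {name}")

    lines = ["# QEEG / ERP group analysis report", ""]
    if settings:
        lines += ["## Provenance", "", "```json",
                  json.dumps(settings, indent=2, default=str), "```", ""]

    if "spectra" in disabled:
        lines += ["## Group spectra", "", "_Stage disabled; section omitted._", ""]
    else:
        lines += ["## Group spectra", ""]
        for cond, (pat, ctl, diff) in spectra.items():
            lines += [f"### Condition: {cond}", "",
                      f"- patients: n={pat.n_subjects}; controls: n={ctl.n_subjects}",
                      f"- max |patient - control| relative amplitude: "
                      f"{np.max(np.abs(diff)):.2f} % "
                      f"at {_argmax_loc(diff, pat)}", ""]
            _plot_difference(diff, pat, clusters.get(cond) if clusters else None,
                             outdir / f"difference_{cond}.png")
            lines += [f"![difference {cond}](difference_{cond}.png)", ""]

    if "erp" in disabled:
        lines += ["## ERPs", "", "_Stage disabled; section omitted._", ""]
    else:
        lines += ["## ERPs", ""]
        for cond, table in erp.items():
            lines += [f"- {cond}: {len(table)} subject averages", ""]

    if "clusters" in disabled:
        lines += ["## Cluster statistics", "", "_Stage disabled; section omitted._", ""]
    else:
        lines += ["## Cluster statistics", ""]
        for cond, res in clusters.items():
            sig = res.significant(0.05)
            lines += [f"### {cond}",
                      f"- {len(res.clusters)} clusters, {len(sig)} with perm_p < 0.05", ""]
            for c in sorted(res.clusters, key=lambda c: abs(c.mass), reverse=True)[:5]:
                chs = sorted(res.channel_labels[i] for i in c.channels) \
                    if res.channel_labels else sorted(c.channels)
                lines += [f"  - mass={c.mass:+.1f}, perm_p={c.perm_p:.4g}, "
                          f"{len(c.points)} points, channels {', '.join(map(str, chs))}"]
            lines += [""]

    if "correlation" in disabled:
        lines += ["## Correlation", "", "_Stage disabled; section omitted._", ""]
    else:
        lo, hi = correlation.fisher_ci()
        lines += ["## Correlation", "",
                  f"- {correlation.x_name} vs {correlation.y_name}: "
                  f"r = {correlation.r:.3f}, p = {correlation.p:.4g}, "
                  f"n = {correlation.n}, 95% CI [{lo:.2f}, {hi:.2f}]"]
        if correlation.perm_p is not None:
            lines += [f"- permutation p = {correlation.perm_p:.4g}"]
        _plot_scatter(correlation, outdir / "correlation.png")
        lines += ["", "![correlation](correlation.png)", ""]

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path


def _argmax_loc(diff: np.ndarray, group) -> str:
    ci, bi = np.unravel_index(np.argmax(np.abs(diff)), diff.shape)
    return f"{group.channel_labels[ci]} / {group.freqs[bi]:.1f} Hz"


def _plot_difference(diff, group, cluster_result, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .cluster_stats import significance_bars

    show = ["F7", "T3", "T5", "Cz", "O2"]
    fig, axes = plt.subplots(len(show), 1, figsize=(6, 9), sharex=True)
    for ax, ch in zip(axes, show):
        ci = group.channel_labels.index(ch)
        ax.plot(group.freqs, diff[ci], lw=1.2)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel(ch)
        if cluster_result is not None:
            bars = significance_bars(cluster_result, ch)
            y0 = diff[ci].min()
            for level, height in ((0.05, 0.05), (0.01, 0.12)):
                for b0, b1 in bars.get(level, []):
                    ax.plot(group.freqs[[b0, b1]], [y0 - height * abs(y0) - 0.02] * 2,
                            lw=2 if level == 0.05 else 4, color="r")
    axes[-1].set_xlabel("frequency (Hz)")
    fig.suptitle("patient - control relative amplitude (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_scatter(corr: CorrelationResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = zip(*corr.pairs)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, color="k")
    ax.set_xlabel(corr.x_name)
    ax.set_ylabel(corr.y_name)
    ax.set_title(f"r = {corr.r:.2f}, p = {corr.p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
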