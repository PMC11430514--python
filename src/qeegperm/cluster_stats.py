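"""Nonparametric cluster-based permutation comparison of channel x bin maps.

The procedure follows the cluster-permutation scheme familiar from M/EEG
group analysis, with two deliberate substitutions: the pointwise statistic
is a Wilcoxon test expressed as a normal-approximation z-score (signed-rank
for paired designs, rank-sum for independent groups, both tie-corrected),
and the cluster-level statistic is the *sum of z-scores* over the cluster
rather than a sum of t-values.  Supra-threshold points are clustered by
spatial adjacency (montage neighbors at the same bin) and temporal/spectral
adjacency (neighboring bins on the same channel), split by sign.  The null
distribution of the maximum absolute cluster mass is built by relabeling
(group-label permutation, or per-subject sign flips for paired designs),
which controls the familywise error over all (channel, bin) points.

Because ranks depend only on the pooled data (independent design) or on
|differences| (paired design), they are computed once and every permutation
reduces to a matrix product, so thousands of permutations are cheap.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm, rankdata

from .montage import MontageGraph


@dataclass
class PointStatMap:
    """Pointwise z and two-sided p over a channel x bin grid."""

    z: np.ndarray                 # (n_channels, n_bins)
    p: np.ndarray
    test_type: str                # 'signed_rank_paired' | 'rank_sum_independent'
    degenerate: np.ndarray        # points where all values were identical

    def __post_init__(self) -> None:
        if self.z.shape != self.p.shape:
            raise ValueError("z and p must share a shape")


@dataclass
class Cluster:
    points: list[tuple[int, int]]     # (channel index, bin index)
    mass: float                       # sum of z over the cluster
    sign: int
    perm_p: Optional[float] = None

    @property
    def channels(self) -> set[int]:
        return {c for c, _ in self.points}

    @property
    def bins(self) -> set[int]:
        return {b for _, b in self.points}


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    stat_map: PointStatMap
    null_max_mass: np.ndarray
    n_permutations: int
    p_threshold: float
    design: str
    seed: Optional[int]
    exact: bool
    channel_labels: tuple[str, ...] = ()
    bin_values: Optional[np.ndarray] = None    # Hz or ms axis, if known

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.perm_p is not None and c.perm_p < alpha]

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "test_type": self.stat_map.test_type,
            "n_permutations": self.n_permutations,
            "exact": self.exact,
            "p_threshold": self.p_threshold,
            "seed": self.seed,
            "clusters": [
                {
                    "mass": c.mass,
                    "sign": c.sign,
                    "perm_p": c.perm_p,
                    "n_points": len(c.points),
                    "channels": sorted(
                        self.channel_labels[i] if self.channel_labels else i
                        for i in c.channels
                    ),
                    "points": [[int(a), int(b)] for a, b in c.points],
                }
                for c in self.clusters
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# pointwise Wilcoxon z-scores
# ---------------------------------------------------------------------------

def _tie_term(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per column, counting only ``valid`` rows."""
    n, P = values.shape
    out = np.zeros(P)
    masked = np.where(valid, values, np.nan)
    srt = np.sort(masked, axis=0)
    has_tie = np.any(srt[:-1] == srt[1:], axis=0) if n > 1 else np.zeros(P, bool)
    for j in np.where(has_tie)[0]:
        col = srt[:, j]
        col = col[~np.isnan(col)]
        _, counts = np.unique(col, return_counts=True)
        t = counts[counts > 1].astype(float)
        out[j] = np.sum(t**3 - t)
    return out


def _signed_rank_setup(d: np.ndarray):
    """Precompute rank machinery for signed-rank z under sign flips.

    d: (n, P) per-subject differences.  Returns a dict with everything the
    z computation needs; |d| (hence the ranks, n_eff, mu, sigma) is
    invariant under per-subject sign flips.
    """
    n, P = d.shape
    absd = np.abs(d)
    zero = absd == 0
    # zeros sink to the bottom of the ranking and are discarded ("wilcox" rule)
    key = np.where(zero, -np.inf, absd)
    ranks = rankdata(key, axis=0)
    n_zero = zero.sum(axis=0)
    r_adj = ranks - n_zero[None, :]
    signs = np.sign(d)
    u = np.where(zero, 0.0, r_adj)            # rank contribution per subject
    n_eff = n - n_zero
    mu = n_eff * (n_eff + 1) / 4.0
    ties = _tie_term(absd, ~zero)
    var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - ties / 48.0
    sigma = np.sqrt(np.maximum(var, 0.0))
    return {
        "us": u * signs,                      # (n, P)
        "total": u.sum(axis=0),               # (P,)
        "mu": mu,
        "sigma": sigma,
        "n": n,
    }


def _signed_rank_w(setup: dict, flips: np.ndarray) -> np.ndarray:
    """W+ statistic maps for sign-flip matrix ``flips`` (n_perm, n) of +/-1."""
    return (setup["total"][None, :] + flips @ setup["us"]) / 2.0


def _standardize(stat: np.ndarray, mu, sigma: np.ndarray, continuity: bool):
    """(z, z_p): plain standardized statistic and the variant used for p.

    ``z`` is the uncorrected normal approximation (the quantity summed into
    cluster masses); ``z_p`` applies the 0.5 continuity correction toward
    the mean before standardizing, which makes the two-sided p track the
    exact discrete null closely even at very small n.
    """
    sigma = np.broadcast_to(sigma, stat.shape)
    dev = stat - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = dev / sigma
        if continuity:
            zp = np.sign(dev) * np.maximum(np.abs(dev) - 0.5, 0.0) / sigma
        else:
            zp = z
    bad = sigma == 0
    z = np.where(bad, 0.0, z)
    zp = np.where(bad, 0.0, zp)
    return z, zp


def _rank_sum_setup(pooled: np.ndarray, n_a: int):
    """Precompute pooled ranks for rank-sum z under label permutation."""
    n, P = pooled.shape
    n_b = n - n_a
    ranks = rankdata(pooled, axis=0)
    mu = n_a * (n + 1) / 2.0
    ties = _tie_term(pooled, np.ones_like(pooled, dtype=bool))
    with np.errstate(invalid="ignore", divide="ignore"):
        var = n_a * n_b / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(var, 0.0))
    return {"ranks": ranks, "mu": mu, "sigma": sigma, "n": n, "n_a": n_a}


def _rank_sum_r(setup: dict, selectors: np.ndarray) -> np.ndarray:
    """Group-A rank-sum maps for 0/1 selector matrix (n_perm, n)."""
    return selectors @ setup["ranks"]


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * norm.sf(np.abs(z)), 0.0, 1.0)


def pointwise_wilcoxon(a: np.ndarray, b: np.ndarray, paired: bool = False,
                       continuity: bool = True) -> PointStatMap:
    """Wilcoxon z at every (channel, bin) point; positive z means a > b.

    Paired: signed-rank on the per-subject differences, zero differences
    dropped, ties mid-ranked, tie-corrected normal approximation.
    Independent: rank-sum (Mann-Whitney) z with tie correction.  The
    reported z is the plain standardized statistic; the two-sided p applies
    a 0.5 continuity correction by default (``continuity=False`` reverts to
    the uncorrected normal CDF).  Degenerate points (no information) get
    z = 0, p = 1 and are flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("expected (n_subjects, ...) arrays")
    shape = a.shape[1:]
    if b.shape[1:] != shape:
        raise ValueError("a and b must share the per-subject map shape")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired design requires equal sample counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 observations per group")
    A = a.reshape(a.shape[0], -1)
    B = b.reshape(b.shape[0], -1)
    if paired:
        setup = _signed_rank_setup(A - B)
        stat = _signed_rank_w(setup, np.ones((1, setup["n"])))[0]
    else:
        setup = _rank_sum_setup(np.vstack([A, B]), n_a=A.shape[0])
        sel = np.zeros((1, setup["n"]))
        sel[0, : A.shape[0]] = 1.0
        stat = _rank_sum_r(setup, sel)[0]
    degenerate = setup["sigma"] == 0
    z, zp = _standardize(stat, setup["mu"], setup["sigma"], continuity)
    p = _two_sided_p(zp)
    p[degenerate] = 1.0
    return PointStatMap(
        z=z.reshape(shape),
        p=p.reshape(shape),
        test_type="signed_rank_paired" if paired else "rank_sum_independent",
        degenerate=degenerate.reshape(shape),
    )


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def _spatial_pairs(adjacency: np.ndarray) -> np.ndarray:
    i, j = np.where(np.triu(adjacency, k=1))
    return np.stack([i, j], axis=1)


def _cluster_labels(z: np.ndarray, supra: np.ndarray, pairs: np.ndarray):
    """Connected components of same-sign supra-threshold points.

    Returns (labels flat array over the grid, masses per component id,
    component ids that contain supra points).
    """
    n_ch, n_bins = z.shape
    pos = z > 0
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    # temporal/spectral edges along each channel
    m = supra[:, :-1] & supra[:, 1:] & (pos[:, :-1] == pos[:, 1:])
    ci, bi = np.where(m)
    rows.append(ci * n_bins + bi)
    cols.append(ci * n_bins + bi + 1)
    # spatial edges at each bin
    for c1, c2 in pairs:
        m = supra[c1] & supra[c2] & (pos[c1] == pos[c2])
        bb = np.where(m)[0]
        if len(bb):
            rows.append(c1 * n_bins + bb)
            cols.append(c2 * n_bins + bb)
    r = np.concatenate(rows) if rows else np.array([], dtype=int)
    c = np.concatenate(cols) if cols else np.array([], dtype=int)
    n_nodes = n_ch * n_bins
    graph = sparse.coo_matrix((np.ones(len(r)), (r, c)), shape=(n_nodes, n_nodes))
    _, labels = connected_components(graph, directed=False)
    flat_supra = supra.ravel()
    masses = np.bincount(labels[flat_supra], weights=z.ravel()[flat_supra],
                         minlength=labels.max() + 1 if n_nodes else 0)
    comp_ids = np.unique(labels[flat_supra])
    return labels, masses, comp_ids


def form_clusters(
    stat_map: PointStatMap,
    montage: MontageGraph,
    p_threshold: float = 0.05,
) -> list[Cluster]:
    """Group supra-threshold points into same-sign spatio-temporal clusters.

    Points with p < ``p_threshold`` are nodes; edges join neighboring bins
    on a channel and montage-neighbor channels at a bin; components are
    sign-pure.  Clusters are ordered by their first point (channel index,
    then bin).
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    z = stat_map.z
    supra = stat_map.p < p_threshold
    pairs = _spatial_pairs(montage.adjacency)
    labels, masses, comp_ids = _cluster_labels(z, supra, pairs)
    n_bins = z.shape[1]
    clusters = []
    for cid in comp_ids:
        nodes = np.where((labels == cid) & supra.ravel())[0]
        points = sorted((int(n // n_bins), int(n % n_bins)) for n in nodes)
        mass = float(masses[cid])
        clusters.append(Cluster(points=points, mass=mass, sign=1 if mass > 0 else -1))
    clusters.sort(key=lambda c: c.points[0])
    return clusters


def _max_cluster_mass(z: np.ndarray, supra: np.ndarray, pairs: np.ndarray) -> float:
    if not supra.any():
        return 0.0
    _, masses, comp_ids = _cluster_labels(z, supra, pairs)
    return float(np.max(np.abs(masses[comp_ids])))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    montage: MontageGraph,
    design: str = "independent",
    n_perm: int = 1000,
    p_threshold: float = 0.05,
    seed: int = 0,
    exact: bool = False,
    continuity: bool = True,
    channel_labels: tuple[str, ...] = (),
    bin_values: Optional[np.ndarray] = None,
) -> ClusterTestResult:
    """Cluster-based permutation comparison of two sets of subject maps.

    ``a``/``b`` are (n_subjects, n_channels, n_bins); for the paired design
    they are the two condition maps of the same subjects in the same order.
    The null distribution is the maximum absolute summed-z cluster mass per
    relabeling: group labels are permuted for the independent design,
    per-subject signs flipped for the paired one.  Monte-Carlo p-values use
    the (1 + exceedances) / (1 + n_perm) estimator; with ``exact=True``
    every distinct relabeling is enumerated instead and the p-value is the
    plain exceedance fraction (the identity relabeling is included, so p
    is never 0).
    """
    if design not in ("independent", "paired"):
        raise ValueError(f"unknown design {design!r}")
    if not exact and n_perm < 100:
        raise ValueError("n_perm must be >= 100 (or use exact=True)")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 3 or b.ndim != 3:
        raise ValueError("maps must be (n_subjects, n_channels, n_bins)")
    n_ch, n_bins = a.shape[1:]
    pairs = _spatial_pairs(montage.adjacency)
    z_crit = float(norm.isf(p_threshold / 2.0))
    rng = np.random.default_rng(seed)

    observed = pointwise_wilcoxon(a, b, paired=(design == "paired"),
                                  continuity=continuity)
    clusters = form_clusters(observed, montage, p_threshold)

    if design == "paired":
        setup = _signed_rank_setup(a.reshape(a.shape[0], -1) - b.reshape(b.shape[0], -1))
        n = setup["n"]
        if exact:
            if n > 20:
                raise ValueError("exact paired enumeration limited to n <= 20 subjects")
            flips = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        else:
            flips = rng.choice([1.0, -1.0], size=(n_perm, n))
        stat_all = _signed_rank_w(setup, flips)
    else:
        n_a, n_b = a.shape[0], b.shape[0]
        n = n_a + n_b
        setup = _rank_sum_setup(np.vstack([a.reshape(n_a, -1), b.reshape(n_b, -1)]), n_a)
        if exact:
            combos = math.comb(n, n_a)
            if combos > 200_000:
                raise ValueError(f"exact enumeration of {combos} labelings is too large")
            sel = np.zeros((combos, n))
            for i, combo in enumerate(itertools.combinations(range(n), n_a)):
                sel[i, list(combo)] = 1.0
        else:
            order = np.argsort(rng.random((n_perm, n)), axis=1)
            sel = np.zeros((n_perm, n))
            np.put_along_axis(sel, order[:, :n_a], 1.0, axis=1)
        stat_all = _rank_sum_r(setup, sel)

    z_all, zp_all = _standardize(stat_all, setup["mu"], setup["sigma"], continuity)
    supra_all = np.abs(zp_all) > z_crit
    null_max = np.array([
        _max_cluster_mass(z_all[k].reshape(n_ch, n_bins),
                          supra_all[k].reshape(n_ch, n_bins), pairs)
        for k in range(z_all.shape[0])
    ])

    n_eff_perm = len(null_max)
    for cl in clusters:
        exceed = int(np.sum(null_max >= abs(cl.mass)))
        if exact:
            cl.perm_p = exceed / n_eff_perm
        else:
            cl.perm_p = (1 + exceed) / (1 + n_eff_perm)

    return ClusterTestResult(
        clusters=clusters,
        stat_map=observed,
        null_max_mass=null_max,
        n_permutations=n_eff_perm,
        p_threshold=p_threshold,
        design=design,
        seed=None if exact else seed,
        exact=exact,
        channel_labels=tuple(channel_labels),
        bin_values=bin_values,
    )


def significance_bars(
    result: ClusterTestResult,
    channel: int | str,
    levels: tuple[float, ...] = (0.05, 0.01),
) -> dict[float, list[tuple[int, int]]]:
    """Per-channel bin intervals covered by clusters below each p level.

    Mirrors the familiar difference-spectrum annotation: small bars at
    p < 0.05, larger bars at p < 0.01.  Intervals are inclusive bin-index
    ranges.
    """
    if isinstance(channel, str):
        if channel not in result.channel_labels:
            raise ValueError(f"unknown channel {channel!r}")
        channel = result.channel_labels.index(channel)
    out: dict[float, list[tuple[int, int]]] = {}
    for level in levels:
        bins = sorted({
            b for c in result.clusters
            if c.perm_p is not None and c.perm_p < level
            for ch, b in c.points if ch == channel
        })
        intervals: list[tuple[int, int]] = []
        for b in bins:
            if intervals and b == intervals[-1][1] + 1:
                intervals[-1] = (intervals[-1][0], b)
            else:
                intervals.append((b, b))
        out[level] = intervals
    return out
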