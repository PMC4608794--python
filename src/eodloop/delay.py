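"""Headline analysis: delay clustering and per-cluster Tukey profiles.

Across a batch of experiments each contributes one point (delay, qq-area).
K-means with k = 2 on the standardized points splits the strongly affected
short-delay experiments (small areas) from the weakly affected long-delay
ones; the silhouette coefficient scores the split and the gap between the
two delay groups locates the critical delay.  Each cluster's pooled Tukey
mean-difference pairs, averaged in 3 ms bins of the pair mean, give the
cluster's IPI-change profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import SessionPair, compute_ipis
from . import stats as ist

__all__ = [
    "ExperimentSummary", "ClusterResult", "TukeyProfile",
    "summarize_experiment", "kmeans_2d", "silhouette_mean",
    "cluster_tukey_profile", "critical_delay_report",
]


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-experiment statistics: the clustering input."""

    fish_id: str
    delay_ms: float
    n_control: int
    n_stim: int
    qq_area_ms2: float
    qq_area_norm: float
    ks_D: float
    ks_p: float
    pearson_r: float
    excluded: bool = False


@dataclass(frozen=True)
class ClusterResult:
    """Two-cluster partition of (delay, area) points.

    Cluster A is canonically the lower-mean-delay cluster;
    ``boundary_delay_ms`` is the midpoint between A's largest and B's
    smallest delay.  Centroids live in the standardized feature space.
    """

    labels: np.ndarray  # 0 = A, 1 = B, per included experiment
    centroids: np.ndarray
    silhouette_mean: float
    boundary_delay_ms: float
    included_ids: tuple = ()
    excluded_ids: tuple = ()
    points: np.ndarray | None = None  # raw (delay, area) rows, included only


@dataclass(frozen=True)
class TukeyProfile:
    """Binned average of pooled Tukey mean-difference pairs (3 ms grid)."""

    bin_center_ms: np.ndarray
    mean_diff_ms: np.ndarray
    mean_sd_ms: np.ndarray
    n_pairs: np.ndarray
    overall_mean_diff_ms: float


def summarize_experiment(pair: SessionPair, bin_ms: float = 20.0,
                         max_ms: float = 500.0,
                         ks_method: str = "auto") -> ExperimentSummary:
    """Chain the distribution statistics for one experiment.

    Uses the fish-only pulse trains directly (no detection stage): IPIs per
    session, qq curve/area, KS on raw samples, Pearson correlation on the
    binned histograms.  Deterministic.
    """
    ctrl = ist.IPISample(compute_ipis(pair.control), label="control")
    stim = ist.IPISample(compute_ipis(pair.stim_fish), label="stimulus")
    qq = ist.qq_curve(ctrl, stim)
    D, p = ist.ks_two_sample(ctrl, stim, method=ks_method)
    r = ist.hist_pearson(ist.ipi_histogram(ctrl, bin_ms, max_ms),
                         ist.ipi_histogram(stim, bin_ms, max_ms))
    return ExperimentSummary(
        fish_id=pair.fish_id, delay_ms=pair.delay_ms,
        n_control=pair.control.n, n_stim=pair.stim_fish.n,
        qq_area_ms2=ist.qq_area(qq), qq_area_norm=ist.qq_area_norm(qq),
        ks_D=D, ks_p=p, pearson_r=r, excluded=pair.excluded,
    )


def _standardize(points: np.ndarray) -> np.ndarray:
    mu = points.mean(axis=0)
    sd = points.std(axis=0)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    return (points - mu) / sd


def kmeans_2d(points: np.ndarray, seed: int = 0, n_restarts: int = 32,
              ids: tuple = (), excluded_ids: tuple = ()) -> ClusterResult:
    """2-cluster K-means on standardized (delay, area) points.

    Features are z-scored per axis before Lloyd's algorithm (delay in ms
    and area in ms^2 are incommensurate); the best of ``n_restarts`` runs
    by within-cluster sum of squares is kept.  Labels are canonicalized so
    cluster A has the lower mean delay.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 included experiments to cluster")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate input: all points identical")
    z = _standardize(pts)
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(z)
    labels = km.labels_.astype(int)
    # canonical order: A = lower mean delay
    if pts[labels == 0, 0].mean() > pts[labels == 1, 0].mean():
        labels = 1 - labels
        centroids = km.cluster_centers_[::-1].copy()
    else:
        centroids = km.cluster_centers_.copy()
    a_max = pts[labels == 0, 0].max()
    b_min = pts[labels == 1, 0].min()
    return ClusterResult(
        labels=labels, centroids=centroids,
        silhouette_mean=silhouette_mean(z, labels),
        boundary_delay_ms=float((a_max + b_min) / 2.0),
        included_ids=tuple(ids) if ids else tuple(range(pts.shape[0])),
        excluded_ids=tuple(excluded_ids), points=pts,
    )


def silhouette_mean(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient over all points (Euclidean distances).

    s_i = (b - a)/max(a, b) with a = mean distance to own-cluster
    co-members and b = mean distance to the other cluster; points in
    singleton clusters, and degenerate points with a = b = 0, score 0.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("silhouette_mean requires exactly 2 clusters")
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    s = np.zeros(pts.shape[0])
    for i in range(pts.shape[0]):
        own = labels == labels[i]
        other = ~own
        n_own = own.sum() - 1
        if n_own == 0:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / n_own  # excludes self (zero distance)
        b = d[i, other].mean()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def cluster_tukey_profile(experiments, bin_ms: float = 3.0,
                          weighting: str = "pair") -> TukeyProfile:
    """Average Tukey mean-difference profile of one cluster.

    Per experiment, Tukey pairs come from its qq curve; each pair falls in
    the ``bin_ms`` bin of its mean.  Per bin, ``mean_diff`` averages the
    pooled pairs (``weighting="pair"``; ``"experiment"`` averages the
    per-experiment bin means instead) and ``mean_sd`` is the across-
    experiment mean of per-experiment within-bin standard deviations
    (experiments with < 2 pairs in a bin contribute no SD).  Empty bins are
    flagged with n_pairs = 0 and NaN values.
    """
    if weighting not in ("pair", "experiment"):
        raise ValueError("weighting must be 'pair' or 'experiment'")
    tukeys: list[ist.TukeyPairs] = []
    for exp in experiments:
        if isinstance(exp, SessionPair):
            qq = ist.qq_curve(ist.IPISample(compute_ipis(exp.control)),
                              ist.IPISample(compute_ipis(exp.stim_fish)))
            tukeys.append(ist.tukey_pairs(qq))
        elif isinstance(exp, ist.TukeyPairs):
            tukeys.append(exp)
        else:
            raise TypeError("experiments must be SessionPair or TukeyPairs")
    if not tukeys:
        raise ValueError("need at least one experiment")
    all_means = np.concatenate([t.mean_ms for t in tukeys])
    all_diffs = np.concatenate([t.diff_ms for t in tukeys])
    lo = int(np.floor(all_means.min() / bin_ms))
    hi = int(np.floor(all_means.max() / bin_ms))
    n_bins = hi - lo + 1
    centers = (np.arange(lo, hi + 1) + 0.5) * bin_ms
    n_pairs = np.zeros(n_bins, dtype=int)
    mean_diff = np.full(n_bins, np.nan)
    mean_sd = np.full(n_bins, np.nan)

    pooled_sum = np.zeros(n_bins)
    per_exp_means: list[list[float]] = [[] for _ in range(n_bins)]
    per_exp_sds: list[list[float]] = [[] for _ in range(n_bins)]
    for t in tukeys:
        idx = np.floor(t.mean_ms / bin_ms).astype(int) - lo
        for b in range(n_bins):
            sel = idx == b
            if not sel.any():
                continue
            d = t.diff_ms[sel]
            n_pairs[b] += d.size
            pooled_sum[b] += d.sum()
            per_exp_means[b].append(float(d.mean()))
            if d.size >= 2:
                per_exp_sds[b].append(float(d.std(ddof=1)))
    for b in range(n_bins):
        if n_pairs[b] == 0:
            continue
        if weighting == "pair":
            mean_diff[b] = pooled_sum[b] / n_pairs[b]
        else:
            mean_diff[b] = float(np.mean(per_exp_means[b]))
        if per_exp_sds[b]:
            mean_sd[b] = float(np.mean(per_exp_sds[b]))
    overall = float(all_diffs.mean()) if weighting == "pair" else \
        float(np.mean([t.diff_ms.mean() for t in tukeys]))
    return TukeyProfile(bin_center_ms=centers, mean_diff_ms=mean_diff,
                        mean_sd_ms=mean_sd, n_pairs=n_pairs,
                        overall_mean_diff_ms=overall)


def critical_delay_report(cluster: ClusterResult, summaries=None) -> dict:
    """Human-readable summary of the critical-delay result.

    Reports the cluster-gap midpoint boundary plus the headline
    max-of-lower-cluster convention, cluster sizes, silhouette and, when
    summaries are given, the per-cluster mean qq-areas.
    """
    pts = cluster.points
    if pts is None:
        raise ValueError("ClusterResult carries no points")
    a = cluster.labels == 0
    b = cluster.labels == 1
    rep = {
        "boundary_delay_ms": cluster.boundary_delay_ms,
        "cluster_a_max_delay_ms": float(pts[a, 0].max()),
        "cluster_b_min_delay_ms": float(pts[b, 0].min()),
        "cluster_a_size": int(a.sum()),
        "cluster_b_size": int(b.sum()),
        "silhouette_mean": cluster.silhouette_mean,
        "cluster_a_mean_area_ms2": float(pts[a, 1].mean()),
        "cluster_b_mean_area_ms2": float(pts[b, 1].mean()),
        "excluded_ids": list(cluster.excluded_ids),
    }
    if summaries is not None:
        by_id = {i: s for i, s in zip(cluster.included_ids, np.asarray(summaries, object))} \
            if len(summaries) == len(cluster.included_ids) else None
        if by_id is not None:
            norms = np.array([s.qq_area_norm for s in summaries])
            rep["cluster_a_mean_area_norm"] = float(norms[a].mean())
            rep["cluster_b_mean_area_norm"] = float(norms[b].mean())
    return rep
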