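"""Optional figures mirroring the standard views of a closed-loop study:
IPI histogram overlays, qq plots with the y = x reference, area vs delay
scatter with cluster colors, and binned Tukey mean-difference profiles."""

from __future__ import annotations

import numpy as np

from .delay import ClusterResult, TukeyProfile
from .stats import Histogram, QQCurve


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_ipi_histograms(ctrl: Histogram, stim: Histogram, ax=None, title=""):
    plt = _plt()
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    centers = (ctrl.edges_ms[:-1] + ctrl.edges_ms[1:]) / 2
    ax.plot(centers, ctrl.probs, "--", color="gray", label="control")
    ax.plot(centers, stim.probs, "-", color="C0", label="stimulation")
    ax.set_xlabel("IPI (ms)")
    ax.set_ylabel("probability")
    ax.set_title(title)
    ax.legend(frameon=False)
    return ax


def plot_qq(qq: QQCurve, ax=None, title=""):
    plt = _plt()
    ax = ax or plt.figure(figsize=(4, 4)).add_subplot()
    lim = [min(qq.x_ms[0], qq.y_ms[0]), max(qq.x_ms[-1], qq.y_ms[-1])]
    ax.plot(lim, lim, "k-", lw=1, label="y = x")
    ax.plot(qq.x_ms, qq.y_ms, ".", color="C0", ms=4)
    ax.set_xlabel("control IPI quantiles (ms)")
    ax.set_ylabel("stimulation IPI quantiles (ms)")
    ax.set_title(title)
    return ax


def plot_area_vs_delay(cluster: ClusterResult, ax=None):
    plt = _plt()
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    pts = cluster.points
    a = cluster.labels == 0
    ax.plot(pts[a, 0], pts[a, 1], "x", color="C0", label=f"cluster A (n={a.sum()})")
    ax.plot(pts[~a, 0], pts[~a, 1], "o", mfc="none", color="C3",
            label=f"cluster B (n={(~a).sum()})")
    ax.axvline(cluster.boundary_delay_ms, color="k", ls=":",
               label=f"boundary {cluster.boundary_delay_ms:g} ms")
    ax.set_xlabel("stimulus delay d (ms)")
    ax.set_ylabel("qq area (ms$^2$)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_tukey_profiles(profiles: dict[str, TukeyProfile], ax=None):
    plt = _plt()
    ax = ax or plt.figure(figsize=(5.5, 3.5)).add_subplot()
    colors = {"A": "C0", "B": "C3"}
    for name, prof in profiles.items():
        ok = prof.n_pairs > 0
        ax.errorbar(prof.bin_center_ms[ok], prof.mean_diff_ms[ok],
                    yerr=np.nan_to_num(prof.mean_sd_ms[ok]),
                    fmt="o", ms=3, color=colors.get(name, None),
                    label=f"cluster {name} (mean {prof.overall_mean_diff_ms:.1f} ms)")
        ax.axhline(prof.overall_mean_diff_ms, color=colors.get(name, None),
                   lw=1, alpha=0.6)
    ax.axhline(0, color="k", lw=1)
    ax.set_xlabel("pair mean IPI (ms)")
    ax.set_ylabel("stimulation - control (ms)")
    ax.legend(frameon=False, fontsize=8)
    return ax
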