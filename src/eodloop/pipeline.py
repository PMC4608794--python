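"""Batch orchestration: simulate, analyze and persist whole studies.

The canonical delay schedule is the per-fish assignment of stimulation
delays used in the study (five fish, delays 5-282 ms, the 102 ms delay
repeated across four fish).  ``simulate_batch`` runs one closed-loop
experiment per schedule entry with independent child seeds of a single
root seed; ``analyze_batch`` chains the per-experiment statistics, the
2-cluster delay analysis and the per-cluster Tukey profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SessionPair
from .simulator import FishParams, ProtocolConfig, simulate_closed_loop
from .delay import (ClusterResult, TukeyProfile, cluster_tukey_profile,
                    critical_delay_report, kmeans_2d, summarize_experiment)
from . import io as eio

__all__ = ["STUDY_SCHEDULE", "simulate_batch", "analyze_batch", "BatchResult",
           "write_bundle", "read_bundle", "write_analysis"]

log = logging.getLogger("eodloop")

#: (fish_id, delay_ms) assignment of the study's enumerated experiments.
STUDY_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("A", 22), ("A", 45), ("A", 102), ("A", 202),
    ("B", 32), ("B", 102), ("B", 172),
    ("C", 12), ("C", 102), ("C", 162), ("C", 282),
    ("D", 5), ("D", 10), ("D", 40), ("D", 60), ("D", 70), ("D", 100),
    ("E", 52), ("E", 102),
)


def simulate_batch(params: FishParams | None = None,
                   schedule=STUDY_SCHEDULE,
                   minutes: float = 5.0,
                   seed: int = 0,
                   detect_latency_ms: float = 0.5) -> list[SessionPair]:
    """One closed-loop experiment per (fish, delay) schedule entry.

    Each experiment gets an independent child seed spawned from ``seed``,
    so the batch is reproducible as a whole and per experiment.
    """
    params = params or FishParams()
    children = np.random.SeedSequence(seed).spawn(len(tuple(schedule)))
    pairs = []
    for (fish_id, delay), child in zip(schedule, children):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        proto = ProtocolConfig(delay_ms=float(delay), control_min=minutes,
                               stim_min=minutes, detect_latency_ms=detect_latency_ms,
                               seed=child_seed)
        pairs.append(simulate_closed_loop(params, proto, fish_id=fish_id))
    return pairs


@dataclass
class BatchResult:
    summaries: pd.DataFrame
    cluster: ClusterResult | None
    profiles: dict[str, TukeyProfile]
    report: dict


def analyze_batch(pairs: list[SessionPair], cluster_seed: int = 0,
                  n_restarts: int = 32, bin_ms: float = 20.0,
                  tukey_bin_ms: float = 3.0) -> BatchResult:
    """Summaries -> clustering -> per-cluster Tukey profiles.

    Experiments flagged ``excluded`` (or unusable: fewer than two pulses in
    a session) are reported in the summary table but kept out of the
    clustering, mirroring the study's explicit outlier disclosure.
    Clustering is skipped, with a logged notice, below three usable
    experiments.
    """
    rows, summaries, usable = [], [], []
    for i, pair in enumerate(pairs):
        try:
            s = summarize_experiment(pair, bin_ms=bin_ms)
        except ValueError as exc:
            log.info("experiment %d (%s, d=%g ms) unusable: %s",
                     i, pair.fish_id, pair.delay_ms, exc)
            rows.append({"fish_id": pair.fish_id, "delay_ms": pair.delay_ms,
                         "n_control": pair.control.n, "n_stim": pair.stim_fish.n,
                         "qq_area_ms2": np.nan, "qq_area_norm": np.nan,
                         "ks_D": np.nan, "ks_p": np.nan, "pearson_r": np.nan,
                         "excluded": True})
            continue
        rows.append(vars(s).copy())
        if s.excluded:
            log.info("experiment %d (%s, d=%g ms) excluded by flag",
                     i, pair.fish_id, pair.delay_ms)
        else:
            summaries.append(s)
            usable.append(i)
    df = pd.DataFrame(rows, columns=["fish_id", "delay_ms", "n_control", "n_stim",
                                     "qq_area_ms2", "qq_area_norm", "ks_D", "ks_p",
                                     "pearson_r", "excluded"])
    if len(summaries) < 3:
        log.info("clustering skipped: only %d usable experiments", len(summaries))
        return BatchResult(summaries=df, cluster=None, profiles={}, report={})

    points = np.array([[s.delay_ms, s.qq_area_ms2] for s in summaries])
    excluded_ids = tuple(i for i in range(len(pairs)) if i not in usable)
    cluster = kmeans_2d(points, seed=cluster_seed, n_restarts=n_restarts,
                        ids=tuple(usable), excluded_ids=excluded_ids)
    profiles = {}
    for name, lab in (("A", 0), ("B", 1)):
        members = [pairs[i] for i, l in zip(usable, cluster.labels) if l == lab]
        if members:
            profiles[name] = cluster_tukey_profile(members, bin_ms=tukey_bin_ms)
    report = critical_delay_report(cluster, summaries)
    return BatchResult(summaries=df, cluster=cluster, profiles=profiles, report=report)


# ---------------------------------------------------------------------------
# on-disk bundles

def write_bundle(pairs: list[SessionPair], outdir, seed: int | None = None) -> None:
    """Folder-per-experiment bundle with a manifest recording the root seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pair in enumerate(pairs):
        name = f"exp{i:03d}_{pair.fish_id}_d{pair.delay_ms:g}"
        eio.write_session_pair(pair, outdir / name)
        entries.append({"folder": name, "fish_id": pair.fish_id,
                        "delay_ms": pair.delay_ms, "excluded": pair.excluded})
    manifest = {"seed": seed, "n_experiments": len(pairs), "experiments": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_bundle(indir) -> list[SessionPair]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    return [eio.read_session_pair(indir / e["folder"])
            for e in manifest["experiments"]]


def write_analysis(result: BatchResult, outdir) -> None:
    """summaries.csv, clusters.json and tukey_profile_{A,B}.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.summaries.to_csv(outdir / "summaries.csv", index=False)
    if result.cluster is not None:
        c = result.cluster
        (outdir / "clusters.json").write_text(json.dumps({
            "labels": ["A" if l == 0 else "B" for l in c.labels.tolist()],
            "included_ids": list(c.included_ids),
            "excluded_ids": list(c.excluded_ids),
            "centroids": c.centroids.tolist(),
            "silhouette_mean": c.silhouette_mean,
            "boundary_delay_ms": c.boundary_delay_ms,
            "report": result.report,
        }, indent=1))
    for name, prof in result.profiles.items():
        pd.DataFrame({"bin_center_ms": prof.bin_center_ms,
                      "mean_diff_ms": prof.mean_diff_ms,
                      "mean_sd_ms": prof.mean_sd_ms,
                      "n_pairs": prof.n_pairs,
                      }).to_csv(outdir / f"tukey_profile_{name}.csv", index=False)
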