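"""Plain-text and HDF5 persistence.

Pulse trains travel as CSV with a single ``t_ms`` column (6-decimal fixed
point) plus a JSON sidecar holding fish id, delay, source, duration and
seed; raw squared-sum recordings as HDF5 (``/signal`` float32 with
``fs_hz`` / ``duration_ms`` attributes); simulation configs as YAML
mirroring the parameter dataclasses field for field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import PulseTrain, SessionPair
from .simulator import FishParams, ProtocolConfig, RawRecording

__all__ = [
    "write_train_csv", "read_train_csv", "write_session_pair",
    "read_session_pair", "write_recording_h5", "read_recording_h5",
    "load_config", "dump_config",
]


def write_train_csv(train: PulseTrain, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("t_ms\n")
        for t in train.times_ms:
            fh.write(f"{t:.6f}\n")
    meta = {"source": train.source, "duration_ms": train.duration_ms}
    meta.update(sidecar or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_train_csv(path) -> PulseTrain:
    path = Path(path)
    times = np.loadtxt(path, skiprows=1, ndmin=1, dtype=float) if \
        path.read_text().strip() != "t_ms" else np.empty(0)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    duration = meta.get("duration_ms", float(times[-1]) if times.size else 1.0)
    return PulseTrain(times, duration_ms=duration, source=meta.get("source", "fish"))


def write_session_pair(pair: SessionPair, folder) -> None:
    """One experiment folder: control/stimulation/stimulus-log CSVs + metadata."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    common = {"fish_id": pair.fish_id, "delay_ms": pair.delay_ms, "seed": pair.seed}
    write_train_csv(pair.control, folder / "control.csv", common)
    write_train_csv(pair.stim_fish, folder / "stim_fish.csv", common)
    write_train_csv(pair.stimulus_log, folder / "stimulus_log.csv", common)
    meta = {"fish_id": pair.fish_id, "delay_ms": pair.delay_ms,
            "excluded": pair.excluded, "seed": pair.seed, **pair.meta}
    (folder / "metadata.json").write_text(json.dumps(meta, indent=1))


def read_session_pair(folder) -> SessionPair:
    folder = Path(folder)
    meta = json.loads((folder / "metadata.json").read_text())
    return SessionPair(
        fish_id=str(meta["fish_id"]), delay_ms=float(meta["delay_ms"]),
        control=read_train_csv(folder / "control.csv"),
        stim_fish=read_train_csv(folder / "stim_fish.csv"),
        stimulus_log=read_train_csv(folder / "stimulus_log.csv"),
        excluded=bool(meta.get("excluded", False)), seed=meta.get("seed"),
        meta={k: v for k, v in meta.items()
              if k not in ("fish_id", "delay_ms", "excluded", "seed")},
    )


def write_recording_h5(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=rec.samples.astype(np.float32))
        d.attrs["fs_hz"] = rec.fs_hz
        d.attrs["duration_ms"] = rec.duration_ms


def read_recording_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        d = f["signal"]
        return RawRecording(samples=d[:].astype(float), fs_hz=float(d.attrs["fs_hz"]),
                            duration_ms=float(d.attrs["duration_ms"]))


def dump_config(params: FishParams, protocol: ProtocolConfig | None, path) -> None:
    cfg = {"fish": dataclasses.asdict(params)}
    if protocol is not None:
        cfg["protocol"] = dataclasses.asdict(protocol)
    Path(path).write_text(yaml.safe_dump(_listify(cfg), sort_keys=False))


def load_config(path) -> tuple[FishParams, ProtocolConfig | None]:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    fish = cfg.get("fish", {})
    for k in ("mix_weights", "mix_medians_ms", "mix_shapes"):
        if k in fish:
            fish[k] = tuple(fish[k])
    params = FishParams(**fish)
    protocol = ProtocolConfig(**cfg["protocol"]) if "protocol" in cfg else None
    return params, protocol


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj
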