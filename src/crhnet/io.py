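"""Plain-text readers and writers for the package's data currencies:
spike trains (TSV), step-protocol sweeps (TSV), parameter documents
(JSON/YAML) and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adex import AdExParams, StepProtocol
from .metrics import SpikeTrain
from .synth import StepProtocolRecording, SweepRecording

__all__ = [
    "write_spike_trains",
    "read_spike_trains",
    "write_labels",
    "read_labels",
    "write_recording",
    "read_recording",
    "adex_params_to_dict",
    "adex_params_from_dict",
    "load_config_yaml",
    "dump_config_yaml",
    "write_manifest",
]


def write_spike_trains(trains, path, populations=None) -> None:
    """Tabular text: columns unit_id, [population,] spike_time_s."""
    rows = []
    for k, tr in enumerate(trains):
        pop = populations[k] if populations is not None else None
        for t in tr.times:
            row = {"unit_id": tr.unit_id, "spike_time_s": t}
            if pop is not None:
                row["population"] = pop
            rows.append(row)
    cols = ["unit_id"] + (["population"] if populations is not None else []) \
        + ["spike_time_s"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_spike_trains(path, t_start: float = 0.0,
                      t_stop: float | None = None) -> list[SpikeTrain]:
    df = pd.read_csv(path, sep="\t")
    out = []
    stop = t_stop if t_stop is not None else \
        (float(df["spike_time_s"].max()) if len(df) else t_start)
    for uid, grp in df.groupby("unit_id", sort=False):
        out.append(SpikeTrain(times=np.sort(grp["spike_time_s"].to_numpy()),
                              t_start=t_start, t_stop=stop, unit_id=str(uid)))
    return out


def write_labels(labeled, path) -> None:
    """Ground-truth label sidecar for a synthetic RB/SS train (JSON)."""
    doc = {
        "unit_id": labeled.train.unit_id,
        "is_burst_spike": [bool(x) for x in labeled.is_burst_spike],
        "true_bursts": [[float(t), int(n)] for t, n in labeled.true_bursts],
        "state_intervals": [[float(a), float(b), s]
                            for a, b, s in labeled.state_intervals],
    }
    Path(path).write_text(json.dumps(doc))


def read_labels(path) -> dict:
    return json.loads(Path(path).read_text())


def write_recording(recording: StepProtocolRecording, directory) -> None:
    """One TSV per sweep (time_s, voltage_mV, current_pA) plus a protocol
    sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, sw in enumerate(recording.sweeps):
        pd.DataFrame({
            "time_s": sw.t * 1e-3,
            "voltage_mV": sw.voltage,
            "current_pA": sw.current,
        }).to_csv(directory / f"sweep_{k:02d}.tsv", sep="\t", index=False)
    proto = {"dt_ms": recording.protocol.dt,
             "sweeps": [list(map(list, s)) for s in recording.protocol.sweeps]}
    (directory / "protocol.json").write_text(json.dumps(proto))


def read_recording(directory) -> StepProtocolRecording:
    directory = Path(directory)
    proto = json.loads((directory / "protocol.json").read_text())
    protocol = StepProtocol(sweeps=tuple(tuple(tuple(seg) for seg in s)
                                         for s in proto["sweeps"]),
                            dt=proto["dt_ms"])
    sweeps = []
    for f in sorted(directory.glob("sweep_*.tsv")):
        df = pd.read_csv(f, sep="\t")
        sweeps.append(SweepRecording(dt=protocol.dt,
                                     voltage=df["voltage_mV"].to_numpy(),
                                     current=df["current_pA"].to_numpy()))
    return StepProtocolRecording(protocol=protocol, sweeps=sweeps)


def adex_params_to_dict(p: AdExParams) -> dict:
    return dataclasses.asdict(p)


def adex_params_from_dict(d: dict) -> AdExParams:
    return AdExParams(**d)


def load_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_config_yaml(doc: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_manifest(path, config_doc: dict, seed: int, extra: dict | None = None):
    """Run manifest: config hash, seed, package versions."""
    import crhnet
    blob = json.dumps(config_doc, sort_keys=True).encode()
    doc = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "crhnet_version": crhnet.__version__,
        "numpy_version": np.__version__,
    }
    doc.update(extra or {})
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
    return doc
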