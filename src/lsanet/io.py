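"""Run artifacts: rasters, trial tables, metrics, weight matrices, snapshots.

All artifacts are plain text (TSV / CSV / JSON) except state snapshots,
which use numpy ``.npz`` so a run can be resumed bit-exactly.  The raster
format is one event per line, ``time_ms<TAB>neuron_id``, no header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .protocols import ProtocolRunner, RunResult, compute_metrics

__all__ = [
    "write_raster", "read_raster", "write_raster_binary", "read_raster_binary",
    "write_weights", "read_weights",
    "write_results", "read_trials", "read_metrics", "read_config",
    "save_snapshot", "load_snapshot",
]


def write_raster(raster: np.ndarray, path) -> None:
    """One spike event per line: time_ms<TAB>neuron_id."""
    np.savetxt(path, np.asarray(raster, np.int64), fmt="%d", delimiter="\t")


def read_raster(path) -> np.ndarray:
    if not Path(path).read_text().strip():
        return np.empty((0, 2), np.int64)
    return np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)


def write_raster_binary(raster: np.ndarray, path) -> None:
    """Columnar binary raster (.npz) for long runs."""
    raster = np.asarray(raster, np.int64)
    np.savez_compressed(path, time_ms=raster[:, 0], neuron_id=raster[:, 1])


def read_raster_binary(path) -> np.ndarray:
    with np.load(path) as z:
        return np.column_stack([z["time_ms"], z["neuron_id"]])


def write_weights(w: np.ndarray, path, time_ms: int = 0) -> None:
    """Dense weight matrix with a header carrying time and size."""
    with open(path, "w") as fh:
        fh.write(f"# time_ms={time_ms} n_neurons={w.shape[0]}\n")
        np.savetxt(fh, w, delimiter=",")


def read_weights(path) -> tuple[np.ndarray, int]:
    with open(path) as fh:
        header = fh.readline().strip()
        w = np.loadtxt(fh, delimiter=",", ndmin=2)
    time_ms = int(header.split("time_ms=")[1].split()[0])
    return w, time_ms


def write_results(result: RunResult, outdir) -> Path:
    """Write trials.csv, metrics.json, counts_1s.csv, weights, config echo."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(result.config.to_json())
    result.trials.to_csv(out / "trials.csv", index=False)
    m = compute_metrics(result.trials)
    (out / "metrics.json").write_text(json.dumps({
        "success": bool(m.success),
        "learning_time_s": m.learning_time_s,
        "attained_reaction_time_ms": m.attained_reaction_time_ms,
        "n_trials": int(m.n_trials),
    }, indent=2))
    np.savetxt(out / "counts_1s.csv", result.counts_1s, fmt="%d", delimiter=",")
    if result.raster is not None:
        write_raster(result.raster, out / "raster.tsv")
    if result.final_w is not None:
        write_weights(result.final_w, out / "weights_final.csv",
                      time_ms=result.config.duration_ms)
    zones = {f"zone_{k}": [int(i) for i in z]
             for k, z in enumerate(result.layout.zones)}
    (out / "zones.json").write_text(json.dumps(zones, indent=2))
    return out


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_metrics(path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path) -> RunConfig:
    return RunConfig.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# snapshot / resume (at chunk boundaries)
# ---------------------------------------------------------------------------

def save_snapshot(runner: ProtocolRunner, path) -> None:
    """Persist the full resumable state of a protocol run."""
    stp_on = runner.stp is not None
    np.savez(
        path,
        config=np.frombuffer(runner.config.to_json().encode(), np.uint8),
        t=np.int64(runner.t),
        v=runner.pop.v, u=runner.pop.u_recovery,
        w=runner.syn.w, exists=runner.syn.exists_mask,
        plastic=runner.syn.plastic_mask,
        last_spike=runner.syn.last_spike_time,
        pstate=runner.pstate, fired_prev=runner.fired_prev,
        delays=runner.delays,
        zones=np.array([len(z) for z in runner.layout.zones], np.int64),
        zone_flat=np.concatenate(runner.layout.zones).astype(np.int64),
        stp_on=np.bool_(stp_on),
        stp_x=runner.stp.x_depress if stp_on else np.zeros(0),
        stp_u=runner.stp.u_facil if stp_on else np.zeros(0),
    )


def load_snapshot(path) -> ProtocolRunner:
    """Rebuild a :class:`ProtocolRunner` that continues a saved run.

    Resuming reproduces an unbroken run bit-exactly as long as the snapshot
    was taken at a chunk boundary (the default, since runs advance in whole
    chunks).
    """
    with np.load(path) as z:
        cfg = RunConfig.from_dict(json.loads(bytes(z["config"]).decode()))
        runner = ProtocolRunner(cfg)
        t = int(z["t"])
        if t % cfg.chunk_ms != 0:
            raise ValueError("snapshot time is not at a chunk boundary")
        runner.t = t
        runner.pop.v[:] = z["v"]
        runner.pop.u_recovery[:] = z["u"]
        runner.syn.w[:] = z["w"]
        runner.syn.exists_mask[:] = z["exists"]
        runner.syn.plastic_mask[:] = z["plastic"]
        runner.syn.last_spike_time[:] = z["last_spike"]
        runner.pstate[:] = z["pstate"]
        runner.fired_prev[:] = z["fired_prev"]
        runner.delays = z["delays"].copy()
        if bool(z["stp_on"]):
            runner.stp.x_depress[:] = z["stp_x"]
            runner.stp.u_facil[:] = z["stp_u"]
    return runner
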