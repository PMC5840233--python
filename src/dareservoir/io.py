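"""HDF5 / CSV serialization for models, scan sets, rasters and targets."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .autonomous import AutoNetwork
from .codec import ScanSet
from .config import ExperimentConfig
from .core import LIFParams, SynapseParams, Topology
from .driven import DelayApportionment, DrivenNetwork, TargetPattern
from .ensemble import EnsembleModel

__all__ = [
    "save_driven", "load_driven", "save_ensemble", "load_ensemble",
    "save_scan_set", "load_scan_set", "raster_to_events", "events_to_raster",
    "write_raster_csv", "read_raster_csv", "write_target_csv",
    "read_target_csv",
]


def _write_params(group: h5py.Group, lif: LIFParams, syn: SynapseParams) -> None:
    group.attrs["lif"] = json.dumps(lif.__dict__)
    group.attrs["syn"] = json.dumps(syn.__dict__)


def _read_params(group: h5py.Group) -> tuple[LIFParams, SynapseParams]:
    return (LIFParams(**json.loads(group.attrs["lif"])),
            SynapseParams(**json.loads(group.attrs["syn"])))


def _write_driven(g: h5py.Group, driven: DrivenNetwork) -> None:
    topo = driven.topology
    g.create_dataset("j_fast", data=topo.j_fast, compression="gzip")
    g.create_dataset("u_d", data=driven.u_d, compression="gzip")
    g.create_dataset("w", data=driven.w, compression="gzip")
    g.create_dataset("tau_parts", data=driven.apportionment.tau_parts)
    g.attrs["apportionment_total"] = driven.apportionment.total
    g.attrs.update(n_res=topo.n_res, n_in=topo.n_in, n_out=topo.n_out,
                   p_conn=topo.p_conn, topo_seed=topo.seed,
                   alpha=driven.alpha, seed=driven.seed)
    _write_params(g, driven.lif, driven.syn)


def _read_driven(g: h5py.Group) -> DrivenNetwork:
    lif, syn = _read_params(g)
    topo = Topology(n_res=int(g.attrs["n_res"]), n_in=int(g.attrs["n_in"]),
                    n_out=int(g.attrs["n_out"]), p_conn=float(g.attrs["p_conn"]),
                    j_fast=g["j_fast"][()], seed=int(g.attrs["topo_seed"]))
    app = DelayApportionment(g["tau_parts"][()],
                             total=float(g.attrs["apportionment_total"]))
    return DrivenNetwork(
        topology=topo, u_d=g["u_d"][()], w=g["w"][()],
        p_inv=np.eye(topo.n_res) / float(g.attrs["alpha"]),
        alpha=float(g.attrs["alpha"]), lif=lif, syn=syn,
        apportionment=app, seed=int(g.attrs["seed"]),
    )


def save_driven(path: str | Path, driven: DrivenNetwork) -> None:
    with h5py.File(path, "w") as f:
        _write_driven(f.create_group("driven"), driven)


def load_driven(path: str | Path) -> DrivenNetwork:
    with h5py.File(path, "r") as f:
        return _read_driven(f["driven"])


def _write_auto(g: h5py.Group, auto: AutoNetwork) -> None:
    g.create_dataset("b", data=auto.b, compression="gzip")
    g.create_dataset("w_prime", data=auto.w_prime, compression="gzip")
    g.attrs.update(u_r=auto.u_r, seed=auto.seed)


def _read_auto(g: h5py.Group, driven: DrivenNetwork) -> AutoNetwork:
    b = g["b"][()]
    left = driven.u_d @ b
    auto = AutoNetwork(
        topology=driven.topology, j_slow=left @ driven.w,
        j_slow_factors=(left, driven.w), u=driven.u_d.copy(),
        u_r=float(g.attrs["u_r"]), b=b, w_prime=g["w_prime"][()],
        lif=driven.lif, syn=driven.syn, seed=int(g.attrs["seed"]),
    )
    return auto


def save_ensemble(path: str | Path, model: EnsembleModel) -> None:
    with h5py.File(path, "w") as f:
        _write_driven(f.create_group("driven"), model.driven)
        ag = f.create_group("autos")
        for key, auto in model.autos.items():
            _write_auto(ag.create_group(key), auto)
        f.attrs["classes"] = json.dumps(model.classes)
        f.attrs["config"] = model.config.to_json()


def load_ensemble(path: str | Path) -> EnsembleModel:
    from .driven import make_one_hot_target

    with h5py.File(path, "r") as f:
        driven = _read_driven(f["driven"])
        autos = {k: _read_auto(g, driven) for k, g in f["autos"].items()}
        classes = json.loads(f.attrs["classes"])
        config = ExperimentConfig.from_json(f.attrs["config"])
    targets = {
        i: make_one_hot_target(i, len(classes), config.bump(),
                               n_steps=config.trial_steps, dt=config.dt)
        for i in range(len(classes))
    }
    return EnsembleModel(driven=driven, autos=autos, classes=classes,
                         config=config, targets=targets)


# ---------------------------------------------------------------------------
# scan sets
# ---------------------------------------------------------------------------

def save_scan_set(path: str | Path, scan_set: ScanSet,
                  label: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        for k in scan_set.scans:
            g = f.create_group(k)
            g.create_dataset("scan", data=scan_set.scans[k], compression="gzip")
            g.create_dataset("frame_indices", data=scan_set.frame_indices[k])
            g.create_dataset("deleted",
                             data=np.asarray(scan_set.deleted_frames[k], dtype=int))
        f.create_dataset("cog_track", data=scan_set.cog_track)
        f.attrs["bb_size"] = scan_set.bb_size
        if label is not None:
            f.attrs["label"] = label


def load_scan_set(path: str | Path) -> tuple[ScanSet, str | None]:
    with h5py.File(path, "r") as f:
        scans, idx, deleted = {}, {}, {}
        for k in f:
            if k == "cog_track":
                continue
            scans[k] = f[k]["scan"][()]
            idx[k] = f[k]["frame_indices"][()]
            deleted[k] = f[k]["deleted"][()].tolist()
        ss = ScanSet(scans=scans, frame_indices=idx, deleted_frames=deleted,
                     cog_track=f["cog_track"][()],
                     bb_size=int(f.attrs["bb_size"]))
        label = f.attrs.get("label")
    return ss, (str(label) if label is not None else None)


# ---------------------------------------------------------------------------
# rasters and targets as CSV
# ---------------------------------------------------------------------------

def raster_to_events(raster: np.ndarray, dt: float = 1.0) -> pd.DataFrame:
    """(N, T) binary raster -> event list with columns neuron_id, t_ms."""
    nid, t = np.nonzero(np.asarray(raster))
    return pd.DataFrame({"neuron_id": nid, "t_ms": t * dt})


def events_to_raster(events: pd.DataFrame, n_neurons: int, n_steps: int,
                     dt: float = 1.0) -> np.ndarray:
    raster = np.zeros((n_neurons, n_steps), dtype=np.uint8)
    idx = (events["t_ms"].to_numpy() / dt).round().astype(int)
    raster[events["neuron_id"].to_numpy().astype(int), idx] = 1
    return raster


def write_raster_csv(path: str | Path, raster: np.ndarray, dt: float = 1.0) -> None:
    raster_to_events(raster, dt).to_csv(path, index=False)


def read_raster_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_target_csv(path: str | Path, target: TargetPattern) -> None:
    df = pd.DataFrame(target.f_out)
    df.insert(0, "row", range(target.f_out.shape[0]))
    df.to_csv(path, index=False)


def read_target_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["row"]).to_numpy()
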