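"""HDF5 / JSON persistence for graphs, spikes and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import CellPlacement, ConnectivityGraph, GranuleCell, LayoutSpec, MitralCell
from .spiking import SpikeRecord

__all__ = [
    "save_network",
    "load_network",
    "save_spikes",
    "load_spikes",
    "write_manifest",
]


def save_network(
    path: str | Path,
    placement: CellPlacement,
    graph: ConnectivityGraph,
    layout: LayoutSpec,
    seed: int | None = None,
) -> None:
    """Persist placement + graph to HDF5 with a JSON sidecar of the layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        mc = f.create_group("cells/mc")
        mc.create_dataset(
            "xyz", data=np.array([[m.x, m.y, m.z] for m in placement.mcs])
        )
        mc.create_dataset(
            "glomerulus", data=np.array([m.glomerulus for m in placement.mcs], dtype=np.int32)
        )
        mc.create_dataset(
            "mc_type", data=np.array([m.mc_type for m in placement.mcs], dtype=np.int8)
        )
        mc.create_dataset(
            "disc_radius", data=np.array([m.disc_radius for m in placement.mcs])
        )
        gc = f.create_group("cells/gc")
        gc.create_dataset(
            "xyz", data=np.array([[g.x, g.y, g.z_vertex] for g in placement.gcs])
        )
        gc.create_dataset(
            "half_angle_deg",
            data=np.array([g.half_angle_deg for g in placement.gcs]),
        )
        f.create_dataset("cells/glomeruli_xy", data=placement.glomeruli_xy)
        e = f.create_group("edges")
        e.create_dataset("mc", data=graph.mc_index)
        e.create_dataset("gc", data=graph.gc_index)
        e.create_dataset("L", data=graph.distance)
        f.create_dataset("pair/lambda", data=graph.lam)
        f.create_dataset("pair/p_connect", data=graph.p_connect)
        if seed is not None or graph.seed is not None:
            f.attrs["seed"] = seed if seed is not None else graph.seed
    sidecar = {"layout": dataclasses.asdict(layout), "seed": seed or graph.seed}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=_jsonable)
    )


def load_network(path: str | Path) -> tuple[CellPlacement, ConnectivityGraph, LayoutSpec]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        mc_xyz = f["cells/mc/xyz"][:]
        glom = f["cells/mc/glomerulus"][:]
        mc_type = f["cells/mc/mc_type"][:]
        radius = f["cells/mc/disc_radius"][:]
        gc_xyz = f["cells/gc/xyz"][:]
        half = f["cells/gc/half_angle_deg"][:]
        glom_xy = f["cells/glomeruli_xy"][:]
        graph = ConnectivityGraph(
            mc_index=f["edges/mc"][:],
            gc_index=f["edges/gc"][:],
            distance=f["edges/L"][:],
            lam=f["pair/lambda"][:],
            p_connect=f["pair/p_connect"][:],
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = dict(sidecar["layout"])
    for key, val in raw.items():
        if isinstance(val, list):
            raw[key] = tuple(val)
    layout = LayoutSpec(**raw)
    placement = CellPlacement(
        glomeruli_xy=glom_xy,
        mcs=[
            MitralCell(int(g), float(x), float(y), float(z), float(r), int(t))
            for (x, y, z), g, t, r in zip(mc_xyz, glom, mc_type, radius)
        ],
        gcs=[
            GranuleCell(float(x), float(y), float(z), float(h))
            for (x, y, z), h in zip(gc_xyz, half)
        ],
    )
    return placement, graph, layout


def save_spikes(path: str | Path, record: SpikeRecord, meta: dict | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["duration_ms"] = record.duration_ms
        f.attrs["dt_ms"] = record.dt_ms
        for i, s in enumerate(record.mc_spikes):
            f.create_dataset(f"spikes/mc{i}", data=np.asarray(s))
        for j, s in enumerate(record.gc_spikes):
            f.create_dataset(f"spikes/gc{j}", data=np.asarray(s))
        for name, trace in record.v_traces.items():
            f.create_dataset(f"v/{name}", data=trace)
    if meta is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, default=_jsonable)
        )


def load_spikes(path: str | Path) -> SpikeRecord:
    with h5py.File(path, "r") as f:
        mc, gc = [], []
        for name in sorted(f["spikes"], key=_spike_key):
            arr = f["spikes"][name][:]
            (mc if name.startswith("mc") else gc).append(arr)
        traces = {}
        if "v" in f:
            traces = {name: f["v"][name][:] for name in f["v"]}
        return SpikeRecord(
            mc_spikes=mc,
            gc_spikes=gc,
            duration_ms=float(f.attrs["duration_ms"]),
            dt_ms=float(f.attrs["dt_ms"]),
            v_traces=traces,
        )


def _spike_key(name: str) -> tuple[str, int]:
    return name[:2], int(name[2:])


def write_manifest(out_dir: str | Path, config_dict: dict, seed: int,
                   version: str) -> Path:
    """Drop a manifest (config hash, seed, package version) in an output dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config_dict, sort_keys=True, default=_jsonable)
    manifest = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package_version": version,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _jsonable(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
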