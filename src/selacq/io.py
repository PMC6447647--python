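"""Persistence: HDF5 recordings and YAML simulation configs."""

from __future__ import annotations

import json
from typing import Optional

import h5py
import yaml

from selacq.network import Recording, SimParams, Topology


def save_recording(
    path,
    rec: Recording,
    params: Optional[SimParams] = None,
    topology: Optional[Topology] = None,
) -> None:
    """Write a recording (and optionally params/topology) to an HDF5 file.

    Layout: ``/v/times``, ``/v/v_ex``, ``/w/times``, ``/w/values``,
    ``/w/edges``, ``/events`` (JSON string), ``/params`` (JSON attr),
    ``/topology/{ee,ei,ie}_mask``.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("v")
        g.create_dataset("times", data=rec.v_times)
        g.create_dataset("v_ex", data=rec.v_ex, compression="gzip")
        g = f.create_group("w")
        g.create_dataset("times", data=rec.w_times)
        g.create_dataset("values", data=rec.w, compression="gzip")
        g.create_dataset("edges", data=rec.w_edges)
        f.attrs["events"] = json.dumps([[t, name] for t, name in rec.events])
        if params is not None:
            f.attrs["params"] = json.dumps(params.to_dict())
        if topology is not None:
            g = f.create_group("topology")
            g.create_dataset("ee_mask", data=topology.ee_mask, compression="gzip")
            g.create_dataset("ei_mask", data=topology.ei_mask, compression="gzip")
            g.create_dataset("ie_mask", data=topology.ie_mask, compression="gzip")


def load_recording(path) -> tuple[Recording, Optional[SimParams], Optional[Topology]]:
    """Inverse of :func:`save_recording`."""
    with h5py.File(path, "r") as f:
        rec = Recording(
            v_times=f["v/times"][()],
            v_ex=f["v/v_ex"][()],
            w_times=f["w/times"][()],
            w=f["w/values"][()],
            w_edges=f["w/edges"][()],
            events=[(float(t), str(name)) for t, name in json.loads(f.attrs["events"])],
        )
        params = (
            SimParams.from_dict(json.loads(f.attrs["params"]))
            if "params" in f.attrs
            else None
        )
        topo = None
        if "topology" in f:
            topo = Topology(
                ee_mask=f["topology/ee_mask"][()],
                ei_mask=f["topology/ei_mask"][()],
                ie_mask=f["topology/ie_mask"][()],
            )
    return rec, params, topo


def load_sim_params(path) -> SimParams:
    """Read a YAML file whose keys mirror :class:`SimParams` field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of SimParams fields")
    return SimParams(**data)


def save_sim_params(path, params: SimParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
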