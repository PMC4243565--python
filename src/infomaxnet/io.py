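"""Reading and writing rasters, parameters, configs and metrics.

Formats: rasters as dense HDF5 datasets or sparse event TSV
(``time<TAB>neuron``, 0-based); parameters as a CSV matrix + CSV vector or an
HDF5 container bundling weights, thresholds, config and seed; configs as
YAML; metrics as JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import yaml

from .config import LearningConfig, NetworkConfig, configs_from_dict, configs_to_dict
from .network import SpikeRaster, SynapticParameters

__all__ = [
    "save_raster_h5",
    "load_raster_h5",
    "save_raster_events",
    "load_raster_events",
    "save_parameters_csv",
    "load_parameters_csv",
    "save_parameters_h5",
    "load_parameters_h5",
    "load_config",
    "save_config",
    "append_metrics",
    "read_metrics",
]


def save_raster_h5(path, raster: SpikeRaster) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=raster.spikes, compression="gzip")
        if raster.inputs is not None:
            f.create_dataset("inputs", data=raster.inputs, compression="gzip")
        f.attrs["t0"] = raster.t0


def load_raster_h5(path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        spikes = f["spikes"][...]
        inputs = f["inputs"][...] if "inputs" in f else None
        t0 = int(f.attrs.get("t0", 0))
    return SpikeRaster(spikes=spikes, inputs=inputs, t0=t0)


def save_raster_events(path, raster: SpikeRaster) -> None:
    """Sparse event list: one ``time<TAB>neuron`` line per spike (0-based)."""
    t, n = np.nonzero(raster.spikes)
    with open(path, "w") as f:
        f.write("time\tneuron\n")
        for ti, ni in zip(t, n):
            f.write(f"{ti + raster.t0}\t{ni}\n")


def load_raster_events(path, n_steps: Optional[int] = None, n_neurons: Optional[int] = None) -> SpikeRaster:
    data = np.loadtxt(path, dtype=np.int64, skiprows=1, ndmin=2)
    if data.size == 0:
        if n_steps is None or n_neurons is None:
            raise ValueError("empty event file needs explicit n_steps and n_neurons")
        return SpikeRaster(spikes=np.zeros((n_steps, n_neurons), dtype=np.uint8))
    t, n = data[:, 0], data[:, 1]
    n_steps = n_steps or int(t.max()) + 1
    n_neurons = n_neurons or int(n.max()) + 1
    spikes = np.zeros((n_steps, n_neurons), dtype=np.uint8)
    spikes[t, n] = 1
    return SpikeRaster(spikes=spikes)


def save_parameters_csv(weights_path, thresholds_path, params: SynapticParameters) -> None:
    np.savetxt(weights_path, params.weights, delimiter=",")
    np.savetxt(thresholds_path, params.thresholds, delimiter=",")


def load_parameters_csv(weights_path, thresholds_path) -> SynapticParameters:
    w = np.loadtxt(weights_path, delimiter=",", ndmin=2)
    h = np.loadtxt(thresholds_path, delimiter=",", ndmin=1)
    return SynapticParameters(w, h)


def save_parameters_h5(
    path,
    params: SynapticParameters,
    net: Optional[NetworkConfig] = None,
    learn: Optional[LearningConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Bundle weights, thresholds, configs and the root seed in one file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=params.weights)
        f.create_dataset("thresholds", data=params.thresholds)
        if net is not None and learn is not None:
            f.attrs["config_json"] = json.dumps(configs_to_dict(net, learn, seed))
        elif seed is not None:
            f.attrs["config_json"] = json.dumps({"seed": int(seed)})


def load_parameters_h5(path):
    """Returns (params, net_config or None, learn_config or None, seed or None)."""
    with h5py.File(path, "r") as f:
        params = SynapticParameters(f["weights"][...], f["thresholds"][...])
        raw = f.attrs.get("config_json")
    net = learn = seed = None
    if raw:
        d = json.loads(raw)
        if "network" in d:
            net, learn, seed = configs_from_dict(d)
        else:
            seed = d.get("seed")
    return params, net, learn, seed


def save_config(path, net: NetworkConfig, learn: LearningConfig, seed: Optional[int] = None) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(configs_to_dict(net, learn, seed), f, sort_keys=False)


def load_config(path):
    """Parse and validate a YAML/JSON config file into typed configs."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return configs_from_dict(raw)


def append_metrics(path, records: list[dict]) -> None:
    with open(path, "a") as f:
        for rec in records:
            f.write(json.dumps(rec) + "\n")


def read_metrics(path) -> list[dict]:
    out = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
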