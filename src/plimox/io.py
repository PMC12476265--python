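"""File formats: HDF5 cubes, TIFF images, CSV tables, JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .oximetry import CalibrationConstants, PO2Map, VesselStats
from .simul_correction import KcorrFit, KPair
from .trace_sim import AcquisitionConfig, TraceStack

__all__ = [
    "save_scene", "load_scene",
    "save_stack", "load_stack",
    "save_label_tiff", "save_float_tiff",
    "save_po2_map", "save_vessel_stats",
    "save_kcorr", "load_kcorr",
    "save_pairs_csv", "load_pairs_csv",
    "write_json",
]

_CONFIG_ATTRS = ("pixel_dwell", "pulse_duration", "sampling_rate",
                 "excitation_gain", "pmt_baseline", "noise_a", "noise_b",
                 "k_oct", "steady_state_scale", "guard_interval")


def save_scene(path, label, weight, po2_truth, *, pixel_pitch,
               temperature, seed=None) -> None:
    """Rendered phantom scene to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=np.asarray(label, dtype=np.int32))
        f.create_dataset("weights", data=np.asarray(weight, dtype=np.float32))
        f.create_dataset("po2_truth", data=np.asarray(po2_truth,
                                                      dtype=np.float32))
        f.attrs["pixel_pitch"] = float(pixel_pitch)
        f.attrs["temperature"] = float(temperature)
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_scene(path):
    with h5py.File(path, "r") as f:
        return (f["labels"][()], f["weights"][()], f["po2_truth"][()],
                dict(f.attrs))


def save_stack(path, stack: TraceStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=stack.data)
        f.attrs["temperature"] = float(stack.temperature)
        f.attrs["grid_shape"] = list(stack.config.grid_shape)
        f.attrs["noise_model"] = stack.config.noise_model
        for name in _CONFIG_ATTRS:
            f.attrs[name] = float(getattr(stack.config, name))
        if stack.seed is not None:
            f.attrs["seed"] = int(stack.seed)


def load_stack(path) -> TraceStack:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        attrs = dict(f.attrs)
    config = AcquisitionConfig(
        grid_shape=tuple(int(v) for v in attrs["grid_shape"]),
        noise_model=str(attrs["noise_model"]),
        **{name: float(attrs[name]) for name in _CONFIG_ATTRS})
    return TraceStack(data=data, config=config,
                      temperature=float(attrs["temperature"]),
                      seed=int(attrs["seed"]) if "seed" in attrs else None)


def save_label_tiff(path, label) -> None:
    tifffile.imwrite(path, np.asarray(label, dtype=np.uint16))


def save_float_tiff(path, image) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def save_po2_map(path_tiff, m: PO2Map, clip: bool = False,
                 sidecar: bool = True) -> None:
    """pO2 map as 32-bit TIFF with a JSON provenance sidecar."""
    img = m.clipped() if clip else m.po2_image
    save_float_tiff(path_tiff, img)
    if sidecar:
        meta = {"temperature": m.temperature,
                "clipped": clip,
                "calibration": dataclasses.asdict(m.calibration),
                "n_no_data": int(m.no_data.sum())}
        write_json(Path(path_tiff).with_suffix(".json"), meta)


def save_vessel_stats(path, stats: VesselStats) -> None:
    stats.to_frame().to_csv(path, index=False)


def save_kcorr(path, fit: KcorrFit) -> None:
    write_json(path, dataclasses.asdict(fit))


def load_kcorr(path) -> KcorrFit:
    with open(path) as f:
        return KcorrFit(**json.load(f))


def save_pairs_csv(path, pairs) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(path,
                                                                index=False)


def load_pairs_csv(path) -> list:
    df = pd.read_csv(path)
    required = {"vessel_id", "k_simul", "k_native"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pairs CSV missing columns: {sorted(missing)}")
    return [KPair(int(r.vessel_id), float(r.k_simul), float(r.k_native))
            for r in df.itertuples()]


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=default)
        f.write("\n")
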