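"""Delimited-text readers/writers and the model archive.

Recordings travel as comma-separated tables (a time column plus data
columns) with a sidecar metadata file of ``key: value`` lines recording the
generator config and seed.  Trained models are stored as a directory of
one ``.npy`` file per parameter tensor plus a JSON manifest; reload is
bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .bpnn import BpnnParams, BpnnTrainConfig
from .dbn import DbnModel, DbnTrainConfig, RbmParams
from .pipeline import PipelineConfig, PipelineModel
from .preprocess import FeatureDataset, FilterSpec, NormParams, WindowSpec
from .pso import FitnessConfig, SwarmConfig
from .simulate import CHANNEL_NAMES, SyntheticRecording

__all__ = [
    "write_emg",
    "read_emg",
    "write_angle",
    "read_angle",
    "write_markers",
    "read_markers",
    "write_metadata",
    "read_metadata",
    "write_recording",
    "read_recording",
    "write_features",
    "read_features",
    "write_predictions",
    "save_model",
    "load_model",
]


def _time_column(n: int, fs: float) -> np.ndarray:
    return np.arange(n) / fs


def _infer_fs(time: np.ndarray) -> float:
    if time.size < 2:
        raise ValueError("cannot infer sampling rate from fewer than two samples")
    # total span is robust to the per-sample rounding of the text format
    return float((time.size - 1) / (time[-1] - time[0]))


def write_emg(path, emg: np.ndarray, fs: float) -> None:
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    df = pd.DataFrame({"time_s": _time_column(emg.shape[1], fs)})
    for name, ch in zip(CHANNEL_NAMES, emg):
        df[name] = ch
    df.to_csv(path, index=False, float_format="%.9g")


def read_emg(path) -> Tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    emg = df[list(CHANNEL_NAMES)].to_numpy().T
    return emg, _infer_fs(df["time_s"].to_numpy())


def write_angle(path, angle: np.ndarray, fs: float) -> None:
    angle = np.asarray(angle, dtype=float)
    pd.DataFrame({"time_s": _time_column(angle.size, fs), "angle_deg": angle}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_angle(path) -> Tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    return df["angle_deg"].to_numpy(), _infer_fs(df["time_s"].to_numpy())


_MARKER_COLS = [f"{m}_{ax}_mm" for m in "ABC" for ax in "xyz"]


def write_markers(path, markers: np.ndarray, fs: float) -> None:
    markers = np.asarray(markers, dtype=float)
    if markers.ndim != 3 or markers.shape[1:] != (3, 3):
        raise ValueError("markers must have shape (n, 3, 3)")
    flat = markers.reshape(len(markers), 9)
    df = pd.DataFrame({"time_s": _time_column(len(markers), fs)})
    for i, col in enumerate(_MARKER_COLS):
        df[col] = flat[:, i]
    df.to_csv(path, index=False, float_format="%.9g")


def read_markers(path) -> Tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    flat = df[_MARKER_COLS].to_numpy()
    return flat.reshape(len(flat), 3, 3), _infer_fs(df["time_s"].to_numpy())


def write_metadata(path, meta: Dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"{key}: {value}\n")


def read_metadata(path) -> Dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if ":" in line:
                key, _, value = line.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_recording(directory, recording: SyntheticRecording) -> None:
    """Write emg/angle/markers tables plus the config sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = recording.config
    write_emg(directory / "emg.csv", recording.emg, cfg.fs_emg)
    write_angle(directory / "angle.csv", recording.angle, cfg.fs_angle)
    if recording.markers is not None:
        write_markers(directory / "markers.csv", recording.markers, cfg.fs_angle)
    write_metadata(directory / "meta.txt", dataclasses.asdict(cfg))


def read_recording(directory) -> Tuple[np.ndarray, float, np.ndarray, float, Optional[np.ndarray]]:
    """Read back (emg, fs_emg, angle, fs_angle, markers-or-None)."""
    directory = Path(directory)
    emg, fs_emg = read_emg(directory / "emg.csv")
    angle, fs_angle = read_angle(directory / "angle.csv")
    markers = None
    if (directory / "markers.csv").exists():
        markers, _ = read_markers(directory / "markers.csv")
    return emg, fs_emg, angle, fs_angle, markers


def write_features(path, dataset: FeatureDataset) -> None:
    """Features + labels table; normalization bounds go in a sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": dataset.window_times, "angle_deg": dataset.labels})
    for i, name in enumerate(CHANNEL_NAMES):
        df[f"rms_{name}"] = dataset.features[:, i]
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        f"norm_lo_{name}": repr(float(v))
        for name, v in zip(CHANNEL_NAMES, dataset.norm_params.lo)
    }
    meta.update(
        {
            f"norm_hi_{name}": repr(float(v))
            for name, v in zip(CHANNEL_NAMES, dataset.norm_params.hi)
        }
    )
    write_metadata(path.with_suffix(".meta.txt"), meta)


def read_features(path) -> FeatureDataset:
    path = Path(path)
    df = pd.read_csv(path)
    features = df[[f"rms_{n}" for n in CHANNEL_NAMES]].to_numpy()
    meta = read_metadata(path.with_suffix(".meta.txt"))
    lo = np.array([float(meta[f"norm_lo_{n}"]) for n in CHANNEL_NAMES])
    hi = np.array([float(meta[f"norm_hi_{n}"]) for n in CHANNEL_NAMES])
    return FeatureDataset(
        features=features,
        labels=df["angle_deg"].to_numpy(),
        norm_params=NormParams(lo=lo, hi=hi),
        window_times=df["time_s"].to_numpy(),
    )


def write_predictions(path, times: np.ndarray, estimated: np.ndarray, actual=None) -> None:
    df = pd.DataFrame({"time_s": times, "estimated_deg": estimated})
    if actual is not None:
        df["actual_deg"] = actual
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# model archive


def _config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def _config_from_dict(d: dict) -> PipelineConfig:
    return PipelineConfig(
        dbn=DbnTrainConfig(**d["dbn"]),
        bpnn=BpnnTrainConfig(**d["bpnn"]),
        swarm=SwarmConfig(**d["swarm"]),
        fitness=FitnessConfig(**d["fitness"]),
        filter_spec=FilterSpec(**d["filter_spec"]),
        window_spec=WindowSpec(**d["window_spec"]),
        fs_emg=d["fs_emg"],
        fs_angle=d["fs_angle"],
        seed=d["seed"],
    )


def save_model(directory, model: PipelineModel) -> None:
    """One ``.npy`` per tensor plus ``manifest.json``; reload is bit-exact."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tensors = {
        "norm_lo": model.norm_params.lo,
        "norm_hi": model.norm_params.hi,
        "bpnn_W_in": model.bpnn.W_in,
        "bpnn_b_in": model.bpnn.b_in,
        "bpnn_W_out": model.bpnn.W_out,
    }
    manifest = {
        "variant": model.variant,
        "bpnn_b_out": model.bpnn.b_out,
        "config": _config_to_dict(model.config),
        "provenance": model.provenance,
        "dbn": None,
    }
    if model.dbn is not None:
        manifest["dbn"] = {
            "layer_sizes": list(model.dbn.layer_sizes),
            "n_rbms": len(model.dbn.rbms),
            "fine_tuned": model.dbn.fine_tuned,
        }
        for i, rbm in enumerate(model.dbn.rbms):
            tensors[f"rbm{i}_W"] = rbm.W
            tensors[f"rbm{i}_b"] = rbm.b
            tensors[f"rbm{i}_c"] = rbm.c
        if model.dbn.encoder is not None:
            for i, (W, bias) in enumerate(model.dbn.encoder):
                tensors[f"enc{i}_W"] = W
                tensors[f"enc{i}_b"] = bias
            for i, (W, bias) in enumerate(model.dbn.decoder):
                tensors[f"dec{i}_W"] = W
                tensors[f"dec{i}_b"] = bias
    for name, arr in tensors.items():
        np.save(directory / f"{name}.npy", np.asarray(arr))
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_model(directory) -> PipelineModel:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)

    def arr(name):
        return np.load(directory / f"{name}.npy")

    dbn = None
    if manifest["dbn"] is not None:
        info = manifest["dbn"]
        rbms = [
            RbmParams(W=arr(f"rbm{i}_W"), b=arr(f"rbm{i}_b"), c=arr(f"rbm{i}_c"))
            for i in range(info["n_rbms"])
        ]
        encoder = decoder = None
        if info["fine_tuned"]:
            encoder = [(arr(f"enc{i}_W"), arr(f"enc{i}_b")) for i in range(info["n_rbms"])]
            decoder = [(arr(f"dec{i}_W"), arr(f"dec{i}_b")) for i in range(info["n_rbms"])]
        dbn = DbnModel(
            layer_sizes=info["layer_sizes"],
            rbms=rbms,
            encoder=encoder,
            decoder=decoder,
            trained=True,
        )

    return PipelineModel(
        variant=manifest["variant"],
        norm_params=NormParams(lo=arr("norm_lo"), hi=arr("norm_hi")),
        bpnn=BpnnParams(
            W_in=arr("bpnn_W_in"),
            b_in=arr("bpnn_b_in"),
            W_out=arr("bpnn_W_out"),
            b_out=manifest["bpnn_b_out"],
        ),
        dbn=dbn,
        config=_config_from_dict(manifest["config"]),
        provenance=manifest["provenance"],
    )
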