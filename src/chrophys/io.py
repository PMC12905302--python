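"""Readers/writers and run configuration shared by all stages.

Recordings travel as HDF5 (``/data`` channels x samples, ``/fs`` kHz,
``/events`` table, ``/electrode_depths``), images as OME-TIFF (CZYX with
physical pixel size in metadata), results as CSV with fixed column
order, parameters and run configs as YAML, and every run emits a
provenance JSON (config hash, seed, package versions).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from chrophys.datatypes import ImageStack, MEARecording


class FormatError(RuntimeError):
    """Raised when an input file is not in the expected layout."""


def write_recording(rec: MEARecording, path: str | Path) -> None:
    """Write a multi-electrode recording to HDF5 (+ JSON truth sidecar)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
        f.create_dataset("fs", data=rec.fs)
        f.create_dataset("electrode_depths", data=rec.electrode_depths)
        ev = f.create_group("events")
        for col in rec.events.columns:
            vals = rec.events[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            ev.create_dataset(col, data=vals)
    if rec.truth:
        sidecar = {}
        for k, v in rec.truth.items():
            if isinstance(v, (int, float, np.integer, np.floating, str)):
                sidecar[k] = float(v) if isinstance(v, (np.integer, np.floating)) else v
            elif isinstance(v, (list, tuple)) and all(
                isinstance(x, (int, float, np.integer, np.floating)) for x in v
            ):
                sidecar[k] = [float(x) for x in v]
        path.with_suffix(".truth.json").write_text(json.dumps(sidecar))


def read_recording(path: str | Path) -> MEARecording:
    """Read an HDF5 recording written by :func:`write_recording`."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            for key in ("data", "fs", "electrode_depths", "events"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset '{key}'")
            data = f["data"][...]
            fs = float(f["fs"][()])
            depths = f["electrode_depths"][...]
            cols = {}
            for col in f["events"]:
                vals = f["events"][col][...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            events = pd.DataFrame(cols)
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 recording ({exc})") from exc
    return MEARecording(data=data, fs=fs, electrode_depths=depths, events=events)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a two-channel stack as OME-TIFF (CZYX, µm pixel size)."""
    tifffile.imwrite(
        str(path),
        stack.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def read_image_stack(path: str | Path) -> ImageStack:
    """Read a CZYX OME-TIFF with physical pixel size metadata."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            px = z_step = None
            if tf.ome_metadata:
                import re

                m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    px = float(m.group(1))
                m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    z_step = float(m.group(1))
    except (tifffile.TiffFileError, OSError) as exc:
        raise FormatError(f"{path}: not a readable OME-TIFF ({exc})") from exc
    if data.ndim != 4:
        raise FormatError(f"{path}: expected CZYX axes, got shape {data.shape}")
    return ImageStack(data=data, pixel_size=px or 1.0, z_step=z_step or 1.0)


# fixed column orders for result CSVs
CELL_COLUMNS = [
    "cell_id",
    "area_um2",
    "circularity",
    "median_gfp",
    "positive",
    "membrane_ratio",
    "excluded",
    "reason",
]
EVENT_COLUMNS = ["pulse_idx", "success", "delay_ms", "peak_pA", "charge_pC"]
NEURO_COLUMNS = ["channel", "intensity", "auc", "dprime", "cum_dprime", "threshold_flag"]
VS_COLUMNS = ["channel", "rate_hz", "vs", "n", "L", "significant"]


def write_table(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    """CSV with a fixed column order and '.' decimal separator."""
    if columns is not None:
        df = df[[c for c in columns if c in df.columns]]
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a flat YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(out_dir: str | Path, cfg: dict[str, Any], seed: int) -> Path:
    """Emit the provenance JSON for one run."""
    import chrophys

    prov = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "versions": {
            "chrophys": chrophys.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": {k: v for k, v in cfg.items()},
    }
    out = Path(out_dir) / "provenance.json"
    out.write_text(json.dumps(prov, indent=2, default=str))
    return out
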