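"""File-format plumbing: clips, traces, grid images, configs, manifests.

Clips are read as sequences of 8-bit grayscale frames from any of:

* a directory of image frames (sorted by filename),
* a multi-page TIFF stack,
* a ``.npy`` array of shape (N, H, W) or a ``.npz`` with a ``frames``
  array (and optional scalar ``frame_rate``),
* any other single file imageio can decode into a frame stack.

Traces and grids have delimited-text twins so every artifact can be
inspected and diffed; grid images are additionally written as bit-exact
3x10 single-channel PNGs (plus an upscaled block rendering for viewing).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .grid import AXES, TEST_ORDER, GridImage
from .pupil import EyeTrace, Frame
from .torsion import TorsionTrace

__all__ = [
    "read_clip",
    "write_clip",
    "write_trace",
    "read_trace",
    "write_torsion_trace",
    "read_torsion_trace",
    "save_grid_png",
    "load_grid_png",
    "save_grid_text",
    "load_grid_text",
    "save_grid_preview",
    "load_config",
    "resolve_config",
    "write_manifest",
]

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg", ".pgm"}


def _to_gray8(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim == 3 and a.shape[-1] in (3, 4):
        a = a[..., :3].mean(axis=-1)
    if a.dtype != np.uint8:
        a = np.clip(a, 0, 255).astype(np.uint8)
    return a


def read_clip(path: str | Path, frame_rate: float = 30.0) -> list[Frame]:
    """Read a clip as a list of :class:`~nystagrid.pupil.Frame`."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise ValueError(f"no image frames found in {path}")
        stack = [_to_gray8(iio.imread(f)) for f in files]
    elif path.suffix == ".npy":
        stack = [_to_gray8(f) for f in np.load(path)]
    elif path.suffix == ".npz":
        with np.load(path) as z:
            stack = [_to_gray8(f) for f in z["frames"]]
            if "frame_rate" in z.files:
                frame_rate = float(z["frame_rate"])
    else:
        arr = iio.imread(path)
        if arr.ndim == 2:
            raise ValueError(f"{path} holds a single frame, not a clip")
        stack = [_to_gray8(f) for f in arr]
    return [
        Frame(f, index=i, timestamp=i / frame_rate) for i, f in enumerate(stack)
    ]


def write_clip(path: str | Path, frames: list[Frame], frame_rate: float = 30.0) -> Path:
    """Write a clip (.npz stack, or directory of PNGs if path has no suffix)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            frames=np.stack([f.pixels for f in frames]),
            frame_rate=frame_rate,
        )
    else:
        path.mkdir(parents=True, exist_ok=True)
        for f in frames:
            Image.fromarray(f.pixels).save(path / f"frame_{f.index:05d}.png")
    return path


# -- traces ----------------------------------------------------------------

def write_trace(path: str | Path, trace: EyeTrace) -> Path:
    path = Path(path)
    n = len(trace)
    df = pd.DataFrame(
        {
            "index": np.arange(n),
            "time_s": np.arange(n) / trace.frame_rate,
            "x_px": trace.x,
            "y_px": trace.y,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


def read_trace(path: str | Path, frame_rate: float | None = None) -> EyeTrace:
    df = pd.read_csv(path, sep="\t")
    valid = df["valid"].to_numpy().astype(bool)
    if frame_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        frame_rate = 1.0 / float(np.median(dt)) if len(dt) else 30.0
    first = int(np.flatnonzero(valid)[0]) if valid.any() else 0
    return EyeTrace(
        frame_rate=frame_rate,
        x=df["x_px"].to_numpy(),
        y=df["y_px"].to_numpy(),
        valid=valid,
        reference_x=float(df["x_px"].to_numpy()[first]),
        reference_y=float(df["y_px"].to_numpy()[first]),
    )


def write_torsion_trace(path: str | Path, trace: TorsionTrace) -> Path:
    path = Path(path)
    n = len(trace)
    pd.DataFrame(
        {
            "index": np.arange(n),
            "time_s": np.arange(n) / trace.frame_rate,
            "torsion_deg": trace.angles,
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


def read_torsion_trace(path: str | Path, frame_rate: float | None = None) -> TorsionTrace:
    df = pd.read_csv(path, sep="\t")
    if frame_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        frame_rate = 1.0 / float(np.median(dt)) if len(dt) else 30.0
    return TorsionTrace(
        df["torsion_deg"].to_numpy(), df["valid"].to_numpy().astype(bool), frame_rate
    )


# -- grid images -----------------------------------------------------------

def save_grid_png(path: str | Path, grid: GridImage) -> Path:
    """Bit-exact 10x3 single-channel PNG (one pixel per cell)."""
    path = Path(path)
    Image.fromarray(grid.values, mode="L").save(path)
    return path


def load_grid_png(path: str | Path) -> GridImage:
    arr = np.asarray(Image.open(path).convert("L"))
    return GridImage(arr)


def save_grid_text(path: str | Path, grid: GridImage) -> Path:
    df = pd.DataFrame(grid.values, index=list(AXES), columns=list(TEST_ORDER))
    df.to_csv(Path(path), sep="\t")
    return Path(path)


def load_grid_text(path: str | Path) -> GridImage:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GridImage(df.to_numpy())


def save_grid_preview(path: str | Path, grid: GridImage, cell: int = 16) -> Path:
    """Upscaled block rendering (each cell -> ``cell`` x ``cell`` px); for
    human viewing only, never fed to the classifier."""
    big = np.kron(grid.values, np.ones((cell, cell), dtype=np.uint8))
    Image.fromarray(big, mode="L").save(Path(path))
    return Path(path)


# -- config / manifest -----------------------------------------------------

def load_config(path: str | Path | None) -> dict:
    """Load a YAML-style ``key: value`` config file (empty dict if None)."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must hold a mapping")
    return data


def resolve_config(defaults: dict, file_config: dict, flags: dict) -> dict:
    """Merge with precedence: command-line flag > config file > default.

    Flags with value None are treated as unset.  Unknown keys in the
    config file raise, naming the offending field.
    """
    unknown = set(file_config) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    out = dict(defaults)
    out.update(file_config)
    out.update({k: v for k, v in flags.items() if v is not None})
    return out


def write_manifest(path: str | Path, config: dict) -> Path:
    """Write the fully resolved run configuration (JSON)."""
    path = Path(path)
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    return path
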