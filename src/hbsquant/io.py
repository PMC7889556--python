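"""File I/O: NIfTI frame stacks and volumes, JSON sidecars, CSV tables.

A dynamic study on disk is one NIfTI per view (frames stacked on the
last axis) plus a JSON sidecar holding frame mid-times and metadata;
masks are NIfTI label maps; time-activity curves and cohorts are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from hbsquant.planar import FrameStack, TimeActivityCurve

__all__ = [
    "save_frame_stack",
    "load_frame_stack",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_tac",
    "load_tac",
]


def save_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack as NIfTI (ny, nx, n_frames) + JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(stack.frames, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine=np.eye(4)), str(path))
    sidecar = {
        "view": stack.view,
        "frame_mid_times_s": stack.frame_mid_times.tolist(),
        **{k: v for k, v in stack.meta.items() if _jsonable(v)},
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame stack not found: {path}")
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"timing sidecar not found: {sidecar_path}")
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    sidecar = json.loads(sidecar_path.read_text())
    meta = {k: v for k, v in sidecar.items() if k not in {"view", "frame_mid_times_s"}}
    return FrameStack(
        view=sidecar["view"],
        frames=data,
        frame_mid_times=np.asarray(sidecar["frame_mid_times_s"], dtype=float),
        meta=meta,
    )


def save_volume(volume: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine=np.eye(4)), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    if not Path(path).exists():
        raise FileNotFoundError(f"volume not found: {path}")
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4)), str(path)
    )


def load_mask(path: str | Path) -> np.ndarray:
    if not Path(path).exists():
        raise FileNotFoundError(f"mask not found: {path}")
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_tac(tac: TimeActivityCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": tac.times, "counts": tac.counts}).to_csv(path, index=False)


def load_tac(path: str | Path, region: str = "roi") -> TimeActivityCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "counts"):
        if col not in df.columns:
            raise ValueError(f"TAC file {path} is missing column {col!r}")
    return TimeActivityCurve(
        region=region,
        times=df["time_s"].to_numpy(float),
        counts=df["counts"].to_numpy(float),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
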