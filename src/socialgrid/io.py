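"""Readers and writers: NIfTI BOLD/masks/stat maps, BIDS-style events
tables, JSON sidecars.

BOLD matrices are stored as 4D NIfTI with voxels reshaped into a small 3D
grid; a JSON sidecar carries the repetition time, the true number of
voxels and any simulation ground truth. Events follow the BIDS
convention (onset and duration as the first columns, tab-separated);
angles are serialised in degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import BoldRun

__all__ = [
    "write_bold",
    "read_bold",
    "write_events",
    "read_events",
    "read_mask",
    "write_statmap",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "run", "theta_deg", "distance", "on_avatar"]


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    side = max(int(np.ceil(n_voxels ** (1.0 / 3.0))), 1)
    depth = int(np.ceil(n_voxels / (side * side)))
    return (side, side, depth)


def write_bold(run: BoldRun, path: str | Path, truth: dict | None = None) -> Path:
    """Write a BoldRun as 4D NIfTI plus a JSON sidecar."""
    path = Path(path)
    shape = _grid_shape(run.n_voxels)
    vol = np.zeros((int(np.prod(shape)), run.n_scans))
    vol[: run.n_voxels] = run.data
    img = nib.Nifti1Image(vol.reshape(*shape, run.n_scans), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.repetition_time))
    nib.save(img, str(path))
    sidecar = {
        "RepetitionTime": run.repetition_time,
        "NVoxels": int(run.n_voxels),
        "Run": int(run.run),
    }
    if truth is not None:
        sidecar["GroundTruth"] = _jsonable(truth)
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def read_bold(path: str | Path) -> BoldRun:
    """Read a BoldRun written by :func:`write_bold` (sidecar required)."""
    path = Path(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    flat = data.reshape(-1, data.shape[-1])[: meta["NVoxels"]]
    return BoldRun(flat, meta["RepetitionTime"], run=meta.get("Run", 0))


def write_events(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a trial table as a BIDS-style tab-separated events file.

    Morph and choice stages become separate rows (trial_type column);
    trajectory metadata rides along on the morph rows.
    """
    path = Path(path)
    morph = pd.DataFrame(
        {
            "onset": trials["onset"],
            "duration": trials["duration"],
            "trial_type": "morph",
            "run": trials.get("run", 0),
            "theta_deg": trials["theta_deg"],
            "distance": trials["distance"],
            "on_avatar": trials["on_avatar"].astype(int),
        }
    )
    choice = pd.DataFrame(
        {
            "onset": trials["choice_onset"],
            "duration": trials["choice_duration"],
            "trial_type": "choice",
            "run": trials.get("run", 0),
            "theta_deg": np.nan,
            "distance": np.nan,
            "on_avatar": np.nan,
        }
    )
    table = pd.concat([morph, choice]).sort_values("onset")
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events file back into the wide per-trial table."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"events file {path} missing required columns: {missing}")
    morph = table[table["trial_type"] == "morph"].sort_values("onset").reset_index(drop=True)
    choice = table[table["trial_type"] == "choice"].sort_values("onset").reset_index(drop=True)
    if len(morph) != len(choice):
        raise ValueError("unbalanced morph/choice events")
    return pd.DataFrame(
        {
            "run": morph["run"].astype(int),
            "onset": morph["onset"],
            "duration": morph["duration"],
            "choice_onset": choice["onset"],
            "choice_duration": choice["duration"],
            "theta_deg": morph["theta_deg"],
            "distance": morph["distance"],
            "on_avatar": morph["on_avatar"].astype(bool),
        }
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Flat voxel indices of the nonzero entries of a NIfTI mask."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return np.where(data.reshape(-1) > 0)[0]


def write_statmap(values: np.ndarray, reference: str | Path | BoldRun, path: str | Path) -> Path:
    """Write per-voxel statistics as a 3D NIfTI matching a reference geometry."""
    values = np.asarray(values, dtype=float)
    if isinstance(reference, (str, Path)):
        shape = nib.load(str(reference)).shape[:3]
    else:
        shape = _grid_shape(reference.n_voxels)
    vol = np.full(int(np.prod(shape)), np.nan)
    vol[: values.size] = values
    img = nib.Nifti1Image(vol.reshape(shape), affine=np.eye(4))
    nib.save(img, str(path))
    return Path(path)
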