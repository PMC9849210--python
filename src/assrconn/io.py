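"""File formats: epochs as flat binary + JSON sidecar, volumes and masks
as NIfTI-1 (TR carried in the header), motion traces and subject tables as
TSV, seeds and ground truth as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .assr import EEGEpochs
from .rsfc import MotionTrace, SeedSpec, TissueMasks, Volume4D

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_volume",
    "load_volume",
    "save_masks",
    "load_masks",
    "save_motion",
    "load_motion",
    "save_table",
    "load_table",
    "save_seeds",
    "load_seeds",
    "save_json",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def save_epochs(epochs: EEGEpochs, path) -> None:
    """Write float64 little-endian binary plus a ``.json`` sidecar holding
    shape, sampling rate, channel names, and any ground truth."""
    path = Path(path)
    epochs.data.astype("<f8").tofile(path)
    sidecar = {
        "shape": list(epochs.data.shape),
        "dtype": "<f8",
        "fs": epochs.fs,
        "channel_names": epochs.channel_names,
        "ground_truth": _jsonable(epochs.ground_truth),
    }
    save_json(sidecar, path.with_suffix(path.suffix + ".json"))


def load_epochs(path) -> EEGEpochs:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    gt = meta.get("ground_truth")
    if gt is not None:
        gt = {
            k: np.asarray(v) if isinstance(v, list) else v for k, v in gt.items()
        }
    return EEGEpochs(data, meta["fs"], meta["channel_names"], ground_truth=gt)


def save_volume(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    zooms = tuple(vol.voxel_mm) + (vol.tr_s,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_volume(path) -> Volume4D:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return Volume4D(np.asanyarray(img.dataobj, dtype=float), img.affine, tr)


def save_masks(masks: TissueMasks, affine: np.ndarray, prefix) -> None:
    prefix = Path(prefix)
    for name, arr in (("wm", masks.wm), ("csf", masks.csf)):
        nib.save(
            nib.Nifti1Image(arr.astype(np.uint8), affine),
            str(prefix.parent / f"{prefix.name}_{name}.nii"),
        )


def load_masks(prefix) -> TissueMasks:
    prefix = Path(prefix)
    arrs = {}
    for name in ("wm", "csf"):
        img = nib.load(str(prefix.parent / f"{prefix.name}_{name}.nii"))
        arrs[name] = np.asanyarray(img.dataobj).astype(bool)
    return TissueMasks(wm=arrs["wm"], csf=arrs["csf"])


MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def save_motion(motion: MotionTrace, path) -> None:
    pd.DataFrame(motion.params, columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def load_motion(path) -> MotionTrace:
    return MotionTrace(pd.read_csv(path, sep="\t")[MOTION_COLUMNS].to_numpy())


def save_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_seeds(seeds: list[SeedSpec], path) -> None:
    save_json(
        [
            {"name": s.name, "x": s.center[0], "y": s.center[1], "z": s.center[2],
             "radius": s.radius}
            for s in seeds
        ],
        path,
    )


def load_seeds(path) -> list[SeedSpec]:
    raw = json.loads(Path(path).read_text())
    return [
        SeedSpec(d["name"], (d["x"], d["y"], d["z"]), d.get("radius", 10.0))
        for d in raw
    ]
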