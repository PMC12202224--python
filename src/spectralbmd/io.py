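"""NIfTI and CSV input/output.

Volumes are written one NIfTI-1 file per channel plus an integer label
volume (loadable as an ITK-SNAP segmentation) and a JSON sidecar holding
the ground truth, seed and subject metadata. CSV tables carry run
metadata as ``# key=value`` comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .decomposition import BMDMap, DecompositionModel
from .synthetic import SpectralVolume

__all__ = [
    "save_spectral_volume",
    "load_spectral_volume",
    "save_bmd_map",
    "load_bmd_map",
    "write_table",
    "read_table",
]

_CHANNELS = ("conventional", "mono_low", "mono_high")


def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_spectral_volume(vol: SpectralVolume, outdir, prefix: str) -> dict:
    """Write channels, labels and truth sidecar; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(vol.spacing_mm, vol.origin_mm)
    paths = {}
    for name in _CHANNELS:
        p = outdir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.channel(name).astype(np.float32), aff), p)
        paths[name] = str(p)
    p = outdir / f"{prefix}_labels.nii.gz"
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), aff), p)
    paths["labels"] = str(p)
    sidecar = {
        "subject_id": vol.subject_id,
        "weight_kg": vol.weight_kg,
        "seed": vol.seed,
        "spacing_mm": list(vol.spacing_mm),
        "origin_mm": list(vol.origin_mm),
        "truth": {str(k): list(v) for k, v in vol.truth.items()},
    }
    p = outdir / f"{prefix}_truth.json"
    p.write_text(json.dumps(sidecar, indent=2))
    paths["truth"] = str(p)
    return paths


def load_spectral_volume(outdir, prefix: str) -> SpectralVolume:
    outdir = Path(outdir)
    channels = {}
    for name in _CHANNELS:
        img = nib.load(outdir / f"{prefix}_{name}.nii.gz")
        channels[name] = np.asarray(img.dataobj, dtype=np.float64)
    limg = nib.load(outdir / f"{prefix}_labels.nii.gz")
    labels = np.asarray(limg.dataobj, dtype=np.int16)
    meta = json.loads((outdir / f"{prefix}_truth.json").read_text())
    return SpectralVolume(
        channels=channels,
        labels=labels,
        spacing_mm=tuple(meta["spacing_mm"]),
        origin_mm=tuple(meta["origin_mm"]),
        seed=int(meta["seed"]),
        truth={int(k): tuple(v) for k, v in meta["truth"].items()},
        subject_id=meta["subject_id"],
        weight_kg=meta["weight_kg"],
    )


def save_bmd_map(bmd: BMDMap, path) -> None:
    nib.save(
        nib.Nifti1Image(
            bmd.values.astype(np.float32), _affine(bmd.spacing_mm, bmd.origin_mm)
        ),
        path,
    )


def load_bmd_map(path, model: DecompositionModel | None = None) -> BMDMap:
    img = nib.load(path)
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return BMDMap(
        values=np.asarray(img.dataobj, dtype=np.float64),
        spacing_mm=spacing,
        origin_mm=origin,
        model=model,
    )


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """CSV with ``# key=value`` metadata comment lines at the top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
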