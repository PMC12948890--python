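"""NIfTI and CSV input/output helpers (nibabel-backed)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .matching import ImageSeries, QuantMaps

__all__ = [
    "load_series",
    "save_series",
    "load_labels",
    "save_labels",
    "save_maps",
    "load_maps",
]


def load_series(path: str | Path, echo_times) -> ImageSeries:
    """Load a 4-D MESE NIfTI volume (echo axis last) with its echo times."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D NIfTI series, got shape {data.shape}")
    vox = img.header.get_zooms()[:3]
    return ImageSeries(
        voxels=data, echo_times=np.asarray(echo_times, float),
        voxel_size_mm=tuple(float(v) for v in vox), affine=img.affine,
    )


def save_series(series: ImageSeries, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(series.voxels.astype(np.float32), series.affine),
             str(path))


def load_labels(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).round().astype(np.int16)


def save_labels(labels: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16),
                             np.eye(4) if affine is None else affine), str(path))


def save_maps(maps: QuantMaps, out_prefix: str | Path,
              affine: np.ndarray | None = None,
              provenance: dict | None = None) -> None:
    """Write T2/B1/score NIfTI maps plus a JSON provenance sidecar."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4) if affine is None else affine
    for name, arr in (("t2", maps.t2_map), ("b1", maps.b1_map),
                      ("score", maps.score_map)):
        nib.save(nib.Nifti1Image(arr.astype(np.float32), aff),
                 str(out_prefix) + f"_{name}.nii.gz")
    nib.save(nib.Nifti1Image(maps.validity_mask.astype(np.uint8), aff),
             str(out_prefix) + "_valid.nii.gz")
    if provenance is not None:
        Path(str(out_prefix) + "_provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True))


def load_maps(out_prefix: str | Path) -> QuantMaps:
    p = str(Path(out_prefix))
    def _ld(suffix):
        return np.asarray(nib.load(p + suffix).get_fdata(), dtype=float)
    return QuantMaps(
        t2_map=_ld("_t2.nii.gz"),
        b1_map=_ld("_b1.nii.gz"),
        score_map=_ld("_score.nii.gz"),
        validity_mask=_ld("_valid.nii.gz") > 0.5,
    )
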