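"""NIfTI/JSON serialization helpers for parameter maps and reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import ParameterMap

_STATE_TAG = {"raw": "raw", "normalized": "norm", "smoothed": "norm_smooth"}
_TAG_STATE = {v: k for k, v in _STATE_TAG.items()}


def map_filename(subject_id: str, pmap: ParameterMap) -> str:
    return f"{subject_id}_{pmap.kind}_{_STATE_TAG[pmap.state]}.nii.gz"


def save_parameter_map(
    pmap: ParameterMap, subject_id: str, out_dir: str | Path, voxel_size_mm: float
) -> Path:
    """Write a map as 3D NIfTI-1 plus a JSON provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / map_filename(subject_id, pmap)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(pmap.values.astype(np.float32), affine), path)
    sidecar = {
        "kind": pmap.kind,
        "state": pmap.state,
        "provenance": _jsonable(pmap.provenance),
    }
    path.with_name(path.name.replace(".nii.gz", ".json")).write_text(
        json.dumps(sidecar, indent=2)
    )
    mask_path = out / f"analysis_mask_{pmap.kind}.nii.gz"
    if not mask_path.exists():
        nib.save(nib.Nifti1Image(pmap.mask.astype(np.uint8), affine), mask_path)
    return path


def load_parameter_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    sidecar = json.loads(
        path.with_name(path.name.replace(".nii.gz", ".json")).read_text()
    )
    values = np.asarray(nib.load(path).dataobj, dtype=float)
    mask_path = path.parent / f"analysis_mask_{sidecar['kind']}.nii.gz"
    if mask_path.exists():
        mask = np.asarray(nib.load(mask_path).dataobj, dtype=bool)
    else:
        mask = values != 0
    return ParameterMap(
        values=values,
        kind=sidecar["kind"],
        state=sidecar["state"],
        mask=mask,
        provenance=sidecar.get("provenance", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
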