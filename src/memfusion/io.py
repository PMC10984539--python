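"""File formats: NIfTI volumes, the RDM container, and delimited tables.

Volumes (t-maps, masks, fusion maps) are carried as NIfTI via nibabel, with
condition labels in a JSON sidecar.  RDMs and RDM series use a binary array
container (``.npz`` holding the condensed lower-triangle vectors) plus the
label manifest, metric tag, and optional time axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .rdm import RDM, RDMSeries, condensed_length, vector_to_square
from .searchlight import StatMapSet

__all__ = [
    "write_statmaps",
    "read_statmaps",
    "write_mask",
    "read_mask",
    "write_rdm",
    "read_rdm",
    "write_fusion_table",
    "write_onset_table",
]


def write_statmaps(maps: StatMapSet, path) -> Path:
    """Write a StatMapSet as a 4-D NIfTI (x, y, z, condition) + JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(maps.t_values, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float32), maps.affine), path)
    mask_path = path.with_name(path.name.split(".")[0] + "_mask.nii.gz")
    nib.save(nib.Nifti1Image(maps.brain_mask.astype(np.uint8), maps.affine), mask_path)
    sidecar = path.with_name(path.name.split(".")[0] + "_conditions.json")
    sidecar.write_text(json.dumps({"condition_ids": list(maps.condition_ids)}))
    return path


def read_statmaps(path, condition_ids=None) -> StatMapSet:
    """Read a StatMapSet from a 4-D NIfTI, or a list of 3-D per-condition files.

    All volumes must share grid shape and affine; a mismatch raises a
    ValueError naming the offending file.
    """
    if isinstance(path, (list, tuple)):
        vols, affine, shape = [], None, None
        for p in path:
            img = nib.load(str(p))
            arr = np.asarray(img.get_fdata())
            if arr.ndim != 3:
                raise ValueError(f"{p}: expected a 3-D condition volume, got shape {arr.shape}")
            if affine is None:
                affine, shape = img.affine, arr.shape
            elif arr.shape != shape or not np.allclose(img.affine, affine):
                raise ValueError(f"{p}: grid or affine mismatch with the first volume")
            vols.append(arr)
        t_values = np.stack(vols)
        base = Path(path[0])
    else:
        base = Path(path)
        img = nib.load(str(base))
        arr = np.asarray(img.get_fdata())
        if arr.ndim != 4:
            raise ValueError(f"{base}: expected 4-D (x, y, z, condition) NIfTI, got {arr.shape}")
        t_values = np.moveaxis(arr, -1, 0)
        affine = img.affine

    mask_path = base.with_name(base.name.split(".")[0] + "_mask.nii.gz")
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    else:
        mask = np.ones(t_values.shape[1:], dtype=bool)
    if condition_ids is None:
        sidecar = base.with_name(base.name.split(".")[0] + "_conditions.json")
        if sidecar.exists():
            condition_ids = json.loads(sidecar.read_text())["condition_ids"]
        else:
            condition_ids = [f"cond{i:04d}" for i in range(t_values.shape[0])]
    return StatMapSet(t_values, mask, affine, list(condition_ids))


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)
    return path


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0


def write_rdm(obj, path) -> Path:
    """Write an RDM or RDMSeries to the npz container (condensed vectors)."""
    path = Path(path)
    meta = {"condition_ids": list(obj.condition_ids), "metric_tag": obj.metric_tag}
    if isinstance(obj, RDMSeries):
        np.savez_compressed(path, vectors=obj.vectors(), time_axis=obj.time_axis)
        meta["kind"] = "series"
    elif isinstance(obj, RDM):
        np.savez_compressed(path, vectors=obj.vector())
        meta["kind"] = "rdm"
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as an RDM container")
    manifest = path.with_suffix(".json")
    manifest.write_text(json.dumps(meta))
    return path


def read_rdm(path):
    """Read back an RDM or RDMSeries written by :func:`write_rdm`."""
    path = Path(path)
    manifest = path.with_suffix(".json")
    if not manifest.exists():
        raise FileNotFoundError(f"missing label manifest {manifest}")
    meta = json.loads(manifest.read_text())
    ids = meta["condition_ids"]
    with np.load(path) as npz:
        vectors = npz["vectors"]
        n_expected = condensed_length(len(ids))
        if vectors.shape[-1] != n_expected:
            raise ValueError(
                f"{path}: vector length {vectors.shape[-1]} does not match {len(ids)} conditions"
            )
        if meta["kind"] == "series":
            return RDMSeries(vector_to_square(vectors), npz["time_axis"], ids, meta["metric_tag"])
        return RDM(vector_to_square(vectors), ids, meta["metric_tag"])


def write_fusion_table(series_by_label: dict, time_axis: np.ndarray, path) -> Path:
    """Subject × time fusion series as a long-format TSV."""
    rows = []
    for label, fs in series_by_label.items():
        for s in range(fs.values.shape[0]):
            for t, v in zip(time_axis, fs.values[s]):
                rows.append({"label": label, "subject": s, "time_ms": t, "correlation": v})
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_onset_table(results: dict, path) -> Path:
    """Onset results (per condition/ROI) as a TSV mirroring the onset tables."""
    rows = []
    for (roi, condition), res in results.items():
        rows.append(
            {
                "roi": roi,
                "condition": condition,
                "mean_onset_ms": res.mean_onset,
                "ci95_low_ms": res.ci95[0],
                "ci95_high_ms": res.ci95[1],
                "p_value": res.p_value,
                "n_subsamples": res.n,
                "not_significant": res.ns_flag,
            }
        )
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
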