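"""NIfTI-1 persistence for volumes, phantoms, compensation maps and NDBs.

Volumes are written through nibabel with a diagonal affine carrying the
voxel size; provenance travels in YAML sidecars next to the image files.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .harmonization import CompensationMap
from .phantoms import DigitalPhantom, SubjectVolume
from .zscore import NDB

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_phantom",
    "load_phantom",
    "save_subject",
    "load_subject",
    "save_compensation_map",
    "load_compensation_map",
    "save_ndb",
    "load_ndb",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = (float(v) for v in voxel_size_mm)
    return aff


def save_volume(data: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size_mm)), path)
    return path


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), voxel


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(voxel_size_mm)), path
    )
    return path


def load_mask(path) -> np.ndarray:
    data, _ = load_volume(path)
    return data > 0.5


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name.split(".")[0] + ".yaml")


def save_phantom(phantom: DigitalPhantom, prefix) -> dict[str, Path]:
    """Write activity/attenuation/labels as three NIfTI files plus a sidecar."""
    prefix = Path(prefix)
    paths = {
        "activity": save_volume(
            phantom.activity, phantom.voxel_size_mm, prefix.with_name(prefix.name + "_activity.nii")
        ),
        "attenuation": save_volume(
            phantom.attenuation,
            phantom.voxel_size_mm,
            prefix.with_name(prefix.name + "_attenuation.nii"),
        ),
        "labels": save_volume(
            phantom.labels.astype(np.float64),
            phantom.voxel_size_mm,
            prefix.with_name(prefix.name + "_labels.nii"),
        ),
    }
    sidecar = prefix.with_name(prefix.name + ".yaml")
    sidecar.write_text(yaml.safe_dump({"name": phantom.name, "kind": "phantom"}))
    paths["sidecar"] = sidecar
    return paths


def load_phantom(prefix) -> DigitalPhantom:
    prefix = Path(prefix)
    activity, voxel = load_volume(prefix.with_name(prefix.name + "_activity.nii"))
    attenuation, _ = load_volume(prefix.with_name(prefix.name + "_attenuation.nii"))
    labels, _ = load_volume(prefix.with_name(prefix.name + "_labels.nii"))
    sidecar = prefix.with_name(prefix.name + ".yaml")
    name = "phantom"
    if sidecar.exists():
        name = yaml.safe_load(sidecar.read_text()).get("name", name)
    return DigitalPhantom(activity, attenuation, np.rint(labels).astype(np.int16), voxel, name)


def save_subject(subject: SubjectVolume, path) -> Path:
    path = save_volume(subject.counts, subject.voxel_size_mm, path)
    meta = {
        "subject_id": subject.subject_id,
        "camera_id": subject.camera_id,
        "attenuation_corrected": bool(subject.attenuation_corrected),
        "meta": {k: _yamlable(v) for k, v in subject.meta.items()},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))
    return path


def load_subject(path) -> SubjectVolume:
    path = Path(path)
    counts, voxel = load_volume(path)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    return SubjectVolume(
        counts,
        voxel,
        subject_id=meta.get("subject_id", path.stem),
        camera_id=meta.get("camera_id", ""),
        attenuation_corrected=bool(meta.get("attenuation_corrected", True)),
        meta=meta.get("meta", {}),
    )


def save_compensation_map(comp: CompensationMap, prefix) -> dict[str, Path]:
    prefix = Path(prefix)
    paths = {
        "ratio": save_volume(
            comp.ratio, comp.voxel_size_mm, prefix.with_name(prefix.name + "_ratio.nii")
        ),
        "mask": save_mask(
            comp.valid_mask, comp.voxel_size_mm, prefix.with_name(prefix.name + "_mask.nii")
        ),
    }
    sidecar = prefix.with_name(prefix.name + ".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "source": comp.source,
                "n_acquisitions": int(comp.n_acquisitions),
                "smoothing_fwhm_mm": float(comp.smoothing_fwhm_mm),
            }
        )
    )
    paths["sidecar"] = sidecar
    return paths


def load_compensation_map(prefix) -> CompensationMap:
    prefix = Path(prefix)
    ratio, voxel = load_volume(prefix.with_name(prefix.name + "_ratio.nii"))
    mask = load_mask(prefix.with_name(prefix.name + "_mask.nii"))
    meta = yaml.safe_load(prefix.with_name(prefix.name + ".yaml").read_text())
    return CompensationMap(
        ratio,
        mask,
        source=meta["source"],
        n_acquisitions=int(meta["n_acquisitions"]),
        smoothing_fwhm_mm=float(meta["smoothing_fwhm_mm"]),
        voxel_size_mm=voxel,
    )


def save_ndb(ndb: NDB, prefix) -> dict[str, Path]:
    prefix = Path(prefix)
    paths = {
        "mean": save_volume(ndb.mean, ndb.voxel_size_mm, prefix.with_name(prefix.name + "_mean.nii")),
        "sd": save_volume(ndb.sd, ndb.voxel_size_mm, prefix.with_name(prefix.name + "_sd.nii")),
        "mask": save_mask(
            ndb.brain_mask, ndb.voxel_size_mm, prefix.with_name(prefix.name + "_mask.nii")
        ),
    }
    sidecar = prefix.with_name(prefix.name + ".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "n": int(ndb.n),
                "normalization_target": float(ndb.normalization_target),
                "smoothing_fwhm_mm": float(ndb.smoothing_fwhm_mm),
                "camera_id": ndb.camera_id,
            }
        )
    )
    paths["sidecar"] = sidecar
    return paths


def load_ndb(prefix) -> NDB:
    prefix = Path(prefix)
    mean, voxel = load_volume(prefix.with_name(prefix.name + "_mean.nii"))
    sd, _ = load_volume(prefix.with_name(prefix.name + "_sd.nii"))
    mask = load_mask(prefix.with_name(prefix.name + "_mask.nii"))
    meta = yaml.safe_load(prefix.with_name(prefix.name + ".yaml").read_text())
    return NDB(
        mean,
        sd,
        n=int(meta["n"]),
        brain_mask=mask,
        normalization_target=float(meta["normalization_target"]),
        smoothing_fwhm_mm=float(meta["smoothing_fwhm_mm"]),
        camera_id=meta.get("camera_id", ""),
        voxel_size_mm=voxel,
    )


def _yamlable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
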