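"""File I/O: NIfTI images and masks, measurement-table fixtures, run configs."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantoms import ActivityImage, ReferenceMask

__all__ = [
    "write_activity_image",
    "read_activity_image",
    "write_mask",
    "read_mask",
    "load_fixture_tables",
    "load_run_config",
    "write_json",
    "FIXTURE_SHA256",
]

#: SHA-256 digests of the packaged measurement tables (transcribed from the
#: published operator result tables, decimal commas normalized to dots).
FIXTURE_SHA256 = {
    "operator1_measurements.csv":
        "0daf2ab3079b9d5fe8c197aaf27a1e918c06c0448395b3cabf5f4651f601c682",
    "operator2_measurements.csv":
        "f849bea12ce0ebafac61c63c3fff2a5ff7185be0935c5e341859249cecc2138c",
}

TABLE_COLUMNS = ["operator", "config", "object", "sb_ratio", "method",
                 "isocontour_pct", "true_mL", "true_mL_alt", "measured_mL", "error_pct"]


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_activity_image(image: ActivityImage, path: str | Path) -> None:
    img = nib.Nifti1Image(image.values.astype(np.float32), _affine(image.voxel_size))
    img.header.set_zooms(tuple(image.voxel_size))
    if image.metadata:
        img.header["descrip"] = json.dumps(
            {k: v for k, v in image.metadata.items() if isinstance(v, (int, float, str, bool))}
        )[:79].encode()
    nib.save(img, str(path))


def read_activity_image(path: str | Path) -> ActivityImage:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ActivityImage(np.asarray(img.dataobj, dtype=float), voxel_size,
                         metadata={"source": str(path)})


def write_mask(mask: ReferenceMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.voxel_size))
    img.header.set_zooms(tuple(mask.voxel_size))
    nib.save(img, str(path))


def read_mask(path: str | Path, object_label: str = "") -> ReferenceMask:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ReferenceMask(np.asarray(img.dataobj) > 0, object_label or str(path), voxel_size)


def _fixture_bytes(name: str) -> bytes:
    ref = resources.files("maaspect") / "fixtures" / name
    return ref.read_bytes()


def load_fixture_tables(verify: bool = True) -> pd.DataFrame:
    """Load the two packaged operator measurement tables as one DataFrame.

    Each operator contributes 23 test objects x 2 methods; missing
    measurements (one object for operator 1) are preserved as NA.  With
    ``verify`` the packaged bytes are checked against recorded SHA-256
    digests and any mismatch is a hard failure.
    """
    frames = []
    for name, digest in FIXTURE_SHA256.items():
        raw = _fixture_bytes(name)
        if verify:
            actual = hashlib.sha256(raw).hexdigest()
            if actual != digest:
                raise RuntimeError(f"fixture {name} checksum mismatch: {actual}")
        from io import BytesIO
        frames.append(pd.read_csv(BytesIO(raw)))
    df = pd.concat(frames, ignore_index=True)
    if list(df.columns) != TABLE_COLUMNS:
        raise RuntimeError("fixture tables have unexpected columns")
    return df


def load_run_config(path: str | Path) -> dict:
    """Read a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
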