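"""Reading and writing FOV images, ground truth and manifests.

On disk an experiment is a directory of paired single-channel 16-bit TIFFs
(``<fov_id>_dapi.tif`` nuclei, ``<fov_id>_tritc.tif`` particles), optional
``<fov_id>_gt.json`` ground-truth sidecars, and a ``manifest.csv`` that is
the single source of condition metadata — file names carry no semantics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .synthetic import ConditionLabel, FieldOfView, GroundTruth

MANIFEST_NAME = "manifest.csv"

_MANIFEST_COLUMNS = [
    "fov_id",
    "nuclei_path",
    "particle_path",
    "gt_path",
    "pixel_size",
    "bit_depth",
    "seed",
    "phenotype",
    "wash",
    "particle_size_nm",
    "temperature_c",
    "replicate_id",
]


def write_fov(
    fov: FieldOfView,
    out_dir: Path,
    gt: GroundTruth | None = None,
    seed: int | None = None,
) -> dict:
    """Write one FOV (two TIFFs, optional ground-truth JSON); return its
    manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not fov.fov_id:
        raise ValidationError("FOV must have a fov_id before writing")
    nuclei_path = out_dir / f"{fov.fov_id}_dapi.tif"
    particle_path = out_dir / f"{fov.fov_id}_tritc.tif"
    tifffile.imwrite(nuclei_path, fov.nuclei_channel)
    tifffile.imwrite(particle_path, fov.particle_channel)
    gt_path = ""
    if gt is not None:
        gt_file = out_dir / f"{fov.fov_id}_gt.json"
        gt_file.write_text(json.dumps(gt.to_dict()))
        gt_path = gt_file.name
    row = {
        "fov_id": fov.fov_id,
        "nuclei_path": nuclei_path.name,
        "particle_path": particle_path.name,
        "gt_path": gt_path,
        "pixel_size": fov.pixel_size,
        "bit_depth": fov.bit_depth,
        "seed": seed if seed is not None else "",
    }
    row.update(fov.condition.to_dict())
    return row


def write_manifest(rows: list[dict], out_dir: Path) -> Path:
    path = Path(out_dir) / MANIFEST_NAME
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_manifest(image_dir: Path) -> pd.DataFrame:
    path = Path(image_dir) / MANIFEST_NAME
    if not path.exists():
        raise ValidationError(f"no {MANIFEST_NAME} found in {image_dir}")
    return pd.read_csv(path, keep_default_na=False)


def read_fov_pair(
    nuclei_path: Path,
    particle_path: Path,
    pixel_size: float,
    condition: ConditionLabel,
    fov_id: str = "",
) -> FieldOfView:
    """Load a registered channel pair from disk into a FieldOfView.

    The two TIFFs must exist, have identical shapes, and contain integer
    data; the bit depth is recorded from the dtype (8 or 16).
    """
    for p in (nuclei_path, particle_path):
        if not Path(p).exists():
            raise ValidationError(
                f"image file not found for FOV {fov_id or '<unknown>'}: {p}"
            )
    nuclei = tifffile.imread(nuclei_path)
    particles = tifffile.imread(particle_path)
    if nuclei.shape != particles.shape:
        raise ValidationError(
            f"channel shape mismatch for {fov_id or nuclei_path}: "
            f"{nuclei.shape} vs {particles.shape}"
        )
    for name, arr in (("nuclei", nuclei), ("particle", particles)):
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(
                f"{name} channel of {fov_id or nuclei_path} is not integer "
                f"(dtype {arr.dtype})"
            )
    bit_depth = 8 * nuclei.dtype.itemsize
    return FieldOfView(
        nuclei_channel=nuclei,
        particle_channel=particles,
        pixel_size=pixel_size,
        condition=condition,
        fov_id=fov_id,
        bit_depth=bit_depth,
    )


def read_experiment(image_dir: Path) -> list[FieldOfView]:
    """Read every FOV listed in the manifest of ``image_dir``."""
    image_dir = Path(image_dir)
    manifest = read_manifest(image_dir)
    fovs: list[FieldOfView] = []
    for _, row in manifest.iterrows():
        cond = ConditionLabel.from_dict(row)
        fov = read_fov_pair(
            image_dir / row["nuclei_path"],
            image_dir / row["particle_path"],
            float(row["pixel_size"]),
            cond,
            fov_id=str(row["fov_id"]),
        )
        fovs.append(fov)
    return fovs
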