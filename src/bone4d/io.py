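"""Reading/writing volumes, masks, label maps and transforms.

Volumes travel as multi-page TIFF (pages along the axial axis) or NIfTI;
each TIFF carries a YAML sidecar (``<name>.meta.yaml``) with spacing and
calibration, NIfTI stores spacing in its affine and calibration in a sidecar
as well.  Transforms and pipeline specs serialize as YAML (angles in degrees,
translations/centres in µm).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .core import BoneMask, CalibratedVolume, Calibration, RigidTransform


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_volume(volume: CalibratedVolume, path: Union[str, Path]) -> Path:
    path = Path(path)
    meta = {"spacing_um": float(volume.spacing),
            "calibration": {"slope": volume.calibration.slope,
                            "intercept": volume.calibration.intercept}}
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.transpose(volume.grid, (2, 1, 0)).astype(np.float32))
        _sidecar(path).write_text(yaml.safe_dump(meta))
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        affine = np.diag([volume.spacing, volume.spacing, volume.spacing, 1.0])
        nib.save(nib.Nifti1Image(volume.grid.astype(np.float32), affine), str(path))
        _sidecar(path).write_text(yaml.safe_dump(meta))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def read_volume(path: Union[str, Path]) -> CalibratedVolume:
    path = Path(path)
    side = _sidecar(path)
    meta = yaml.safe_load(side.read_text()) if side.exists() else {}
    cal = meta.get("calibration", {})
    calibration = Calibration(slope=cal.get("slope", Calibration().slope),
                              intercept=cal.get("intercept", 0.0))
    if path.suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        grid = np.transpose(arr, (2, 1, 0))
        spacing = float(meta.get("spacing_um", 10.5))
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj, dtype=np.float32)
        spacing = float(meta.get("spacing_um", abs(img.affine[0, 0])))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return CalibratedVolume(grid=grid, spacing=spacing, calibration=calibration)


def write_mask(mask: BoneMask, path: Union[str, Path]) -> Path:
    vol = CalibratedVolume(grid=mask.grid.astype(np.float32), spacing=mask.spacing)
    return write_volume(vol, path)


def read_mask(path: Union[str, Path]) -> BoneMask:
    vol = read_volume(path)
    return BoneMask(grid=vol.grid > 0.5, spacing=vol.spacing,
                    provenance=str(path))


def write_label_map(grid: np.ndarray, spacing: float, path: Union[str, Path]) -> Path:
    """Label maps use the fixed palette {0 bg, 1 quiescent, 2 formed, 3 resorbed}."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.transpose(grid, (2, 1, 0)).astype(np.uint8))
    else:
        affine = np.diag([spacing, spacing, spacing, 1.0])
        nib.save(nib.Nifti1Image(grid.astype(np.uint8), affine), str(path))
    _sidecar(path).write_text(yaml.safe_dump({"spacing_um": float(spacing),
                                              "palette": {0: "background", 1: "quiescent",
                                                          2: "formed", 3: "resorbed"}}))
    return path


def write_transform(transform: RigidTransform, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(transform.as_dict()))
    return path


def read_transform(path: Union[str, Path]) -> RigidTransform:
    return RigidTransform.from_dict(yaml.safe_load(Path(path).read_text()))
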