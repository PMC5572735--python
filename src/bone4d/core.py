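"""Core containers shared across the pipeline.

Conventions fixed here and relied on everywhere else:

* volumes are ``numpy`` arrays indexed ``grid[i, j, k]`` with the **third index
  axial** (the bone's long axis);
* voxel indices are 0-based, crop intervals half-open;
* the physical position of voxel ``(i, j, k)`` is ``((i + 0.5) s, (j + 0.5) s,
  (k + 0.5) s)`` µm for isotropic spacing ``s``;
* grey values are Hounsfield units (HU); mineral densities mg HA/cm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
import SimpleITK as sitk

#: HU value / density pair printed on the scanner calibration used throughout:
#: 4626 HU corresponds to 809.6 mg HA/cm³.
DEFAULT_THRESHOLD_HU = 4626.0
DEFAULT_THRESHOLD_DENSITY = 809.6
#: Proportional default calibration (slope mg HA/cm³ per HU, intercept mg HA/cm³).
DEFAULT_CALIBRATION = (DEFAULT_THRESHOLD_DENSITY / DEFAULT_THRESHOLD_HU, 0.0)
DEFAULT_VOXEL_SIZE_UM = 10.5


@dataclass(frozen=True)
class Calibration:
    """Affine HU ↔ mineral-density map: density = slope·HU + intercept."""

    slope: float = DEFAULT_CALIBRATION[0]
    intercept: float = DEFAULT_CALIBRATION[1]

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")

    def to_density(self, hu):
        return self.slope * np.asarray(hu, dtype=float) + self.intercept

    def to_hu(self, density):
        return (np.asarray(density, dtype=float) - self.intercept) / self.slope


@dataclass
class CalibratedVolume:
    """3D grey-value volume (HU) with isotropic spacing and a density calibration."""

    grid: np.ndarray
    spacing: float
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.grid.shape

    def density(self) -> np.ndarray:
        """Calibrated mineral-density volume (mg HA/cm³)."""
        return self.calibration.to_density(self.grid)

    def copy(self) -> "CalibratedVolume":
        return replace(self, grid=self.grid.copy())


@dataclass
class BoneMask:
    """Binary bone mask on the same grid conventions as :class:`CalibratedVolume`."""

    grid: np.ndarray
    spacing: float
    provenance: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.grid.shape

    def voxel_count(self) -> int:
        return int(self.grid.sum())

    def copy(self) -> "BoneMask":
        return replace(self, grid=self.grid.copy())


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform: intrinsic ZYX Euler rotation (deg) about ``centre`` (µm)
    followed by a translation (µm).

    ``apply``/resampling semantics: output(x) = input(T(x)) — the transform maps
    points of the output grid into the input volume (SimpleITK convention).
    """

    rotation_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    centre_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vals = (*self.rotation_deg, *self.translation_um, *self.centre_um)
        if not np.all(np.isfinite(vals)):
            raise ValueError("transform parameters must be finite")

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in self.centre_um])
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        t.SetRotation(float(rx), float(ry), float(rz))
        t.SetTranslation([float(v) for v in self.translation_um])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        rx, ry, rz = np.rad2deg(t.GetAngleX()), np.rad2deg(t.GetAngleY()), np.rad2deg(t.GetAngleZ())
        return cls(
            rotation_deg=(float(rx), float(ry), float(rz)),
            translation_um=tuple(float(v) for v in t.GetTranslation()),
            centre_um=tuple(float(v) for v in t.GetCenter()),
        )

    def inverse(self) -> "RigidTransform":
        inv = sitk.Euler3DTransform(self.to_sitk().GetInverse())
        return RigidTransform.from_sitk(inv)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation_deg, 0, atol=atol)
            and np.allclose(self.translation_um, 0, atol=atol)
        )

    def as_dict(self) -> dict:
        return {
            "rotation_deg": [float(v) for v in self.rotation_deg],
            "translation_um": [float(v) for v in self.translation_um],
            "centre_um": [float(v) for v in self.centre_um],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=tuple(d.get("rotation_deg", (0, 0, 0))),
            translation_um=tuple(d.get("translation_um", (0, 0, 0))),
            centre_um=tuple(d.get("centre_um", (0, 0, 0))),
        )


def volume_to_sitk(volume: CalibratedVolume) -> sitk.Image:
    """Convert to a SimpleITK image; our axis 0/1/2 become sitk x/y/z."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.grid, (2, 1, 0))))
    img.SetSpacing((volume.spacing,) * 3)
    # voxel (0,0,0) centre sits at (0.5 s, 0.5 s, 0.5 s)
    img.SetOrigin((0.5 * volume.spacing,) * 3)
    return img


def sitk_to_grid(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (reporting convention for printed values)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out
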