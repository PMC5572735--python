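"""Preprocessing for the longitudinal morphometry: thresholding, cortical
segmentation, VOI selection, and grey-value rigid registration.

These are steps 1–3 of the dynamic (re)modeling algorithm: register the
follow-up scan onto the baseline, threshold at the global cortical-bone
cutoff (4626 HU ↔ 809.6 mg HA/cm³), and exclude mineralized debris inside the
medullary cavity, keeping a single 26-connected cortex.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import (
    BoneMask,
    CalibratedVolume,
    Calibration,
    DEFAULT_THRESHOLD_HU,
    RigidTransform,
    sitk_to_grid,
    volume_to_sitk,
)

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VOISpec:
    """Axial volume of interest: a fraction of the bone length about a centre.

    Defaults follow the mid-diaphyseal convention: 5 % of the tibial length
    centred at the mid-shaft (2.5 % proximal + 2.5 % distal).
    """

    reference_length: float          # tibial length, µm
    fraction: float = 0.05
    centre_fraction: float = 0.50

    def __post_init__(self):
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if not (0 <= self.centre_fraction <= 1):
            raise ValueError("centre_fraction must be in [0, 1]")
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")

    def slice_count(self, spacing: float) -> int:
        return int(np.floor(self.fraction * self.reference_length / spacing + 0.5))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    converged: bool
    iterations: int
    stop_description: str = ""


def calibrate_density(hu, calibration: Calibration):
    """Affine HU → mineral density (mg HA/cm³); invertible via calibration.to_hu."""
    return calibration.to_density(hu)


def binarize(volume: CalibratedVolume, threshold_hu: float = DEFAULT_THRESHOLD_HU) -> BoneMask:
    """Global threshold: foreground iff grey value ≥ threshold (inclusive).

    Inclusivity is a declared convention so that thresholding in HU at 4626 and
    thresholding the calibrated volume at 809.6 mg HA/cm³ select identical
    voxels.  An empty foreground is legitimate (soft-tissue-only field) and
    only warns.
    """
    mask = volume.grid >= threshold_hu
    if not mask.any():
        warnings.warn("binarize produced an empty foreground", stacklevel=2)
    return BoneMask(grid=mask, spacing=volume.spacing,
                    provenance=f"binarize(threshold_hu={threshold_hu})")


def extract_cortex(mask: BoneMask) -> BoneMask:
    """Keep the largest 26-connected component (the cortex).

    Mineralized fragments floating in the medullary cavity (not connected to
    the cortex) are removed; the cavity itself stays background.  Idempotent.
    Ties between equal-size components break deterministically toward the
    component containing the lowest flat voxel index (logged).
    """
    if not mask.grid.any():
        raise ValueError("extract_cortex: mask is empty, no component found")
    labels, n = ndimage.label(mask.grid, structure=_STRUCT_26)
    if n == 1:
        out = mask.grid
    else:
        counts = np.bincount(labels.ravel())[1:]
        best = counts.max()
        tied = np.flatnonzero(counts == best) + 1
        if len(tied) > 1:
            flat = labels.ravel()
            first_idx = {lab: np.argmax(flat == lab) for lab in tied}
            keep = min(tied, key=lambda lab: first_idx[lab])
            logger.info("extract_cortex: %d equal-size components, keeping the one "
                        "with lowest voxel index (label %d)", len(tied), keep)
        else:
            keep = tied[0]
        out = labels == keep
    return BoneMask(grid=out, spacing=mask.spacing,
                    provenance=mask.provenance + "|cortex")


def select_voi(obj: Union[CalibratedVolume, BoneMask], voi: VOISpec):
    """Axial crop covering [centre − fraction/2, centre + fraction/2] of the
    reference length; slice count = round(fraction · length / spacing)."""
    nz = obj.grid.shape[2]
    n = voi.slice_count(obj.spacing)
    centre = voi.centre_fraction * nz
    start = int(np.floor(centre - n / 2.0 + 0.5))
    stop = start + n
    if start < 0 or stop > nz or n < 1:
        raise ValueError(
            f"VOI [{start}, {stop}) outside the scanned extent (0, {nz})")
    cropped = obj.grid[:, :, start:stop]
    if isinstance(obj, CalibratedVolume):
        return CalibratedVolume(grid=cropped.copy(), spacing=obj.spacing,
                                calibration=obj.calibration)
    return BoneMask(grid=cropped.copy(), spacing=obj.spacing,
                    provenance=obj.provenance + f"|voi[{start}:{stop}]")


def _interior_mask(shape, axial_margin: int) -> np.ndarray:
    interior = np.ones(shape, dtype=bool)
    nz = shape[2]
    if axial_margin > 0 and nz > 2 * axial_margin + 4:
        interior[:, :, :axial_margin] = False
        interior[:, :, nz - axial_margin:] = False
    return interior


def _run_registration(f, m, fixed_mask: np.ndarray, initial,
                      learning_rate, iterations, shrink_factors,
                      smoothing_sigmas, spacing) -> RegistrationResult:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    # step cap (in µm) keeps the line search from overshooting on noisy scans
    reg.SetOptimizerAsGradientDescentLineSearch(
        learningRate=learning_rate, numberOfIterations=iterations,
        convergenceMinimumValue=1e-9, convergenceWindowSize=10,
        maximumStepSizeInPhysicalUnits=2.0 * spacing)
    reg.SetOptimizerScalesFromPhysicalShift()
    if not fixed_mask.all():
        mask_img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.transpose(fixed_mask.astype(np.uint8), (2, 1, 0))))
        mask_img.CopyInformation(f)
        reg.SetMetricFixedMask(mask_img)
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=True)

    final = reg.Execute(f, m)
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "Maximum number of iterations" not in stop
    if not converged:
        logger.warning("register_rigid did not converge: %s", stop)
    return RegistrationResult(
        transform=RigidTransform.from_sitk(sitk.Euler3DTransform(final)),
        final_metric=float(reg.GetMetricValue()),
        converged=converged,
        iterations=int(reg.GetOptimizerIteration()),
        stop_description=stop,
    )


def register_rigid(
    moving: CalibratedVolume,
    fixed: CalibratedVolume,
    *,
    learning_rate: float = 1.0,
    iterations: int = 100,
    shrink_factors: Tuple[int, ...] = (2, 1),
    smoothing_sigmas: Tuple[float, ...] = (1.0, 0.0),
    axial_margin: int = 4,
    exclude_changed: bool = False,
    change_threshold: float = 0.4,
) -> RegistrationResult:
    """Grey-value rigid registration of ``moving`` onto ``fixed``.

    Mean-squares metric (both scans share one calibration), two-level
    multi-resolution gradient descent with line search, initialized from the
    moments (centre of mass) of the two volumes.  The pyramid is deliberately
    shallow: diaphyseal VOIs have few axial slices, and a deeper pyramid can
    leave too little axial structure at the coarsest level to keep the
    optimizer in the correct basin.  The returned transform maps fixed-grid
    points into the moving volume, i.e. ``resample_to(moving, transform)``
    yields the moving volume aligned onto the fixed grid.  Non-convergence is
    flagged in the diagnostics but a transform is still returned.

    ``axial_margin`` excludes that many slices at each axial end of the fixed
    image from the metric: a repositioned scan has no valid data beyond its
    field of view, and the fill value there otherwise biases the axial
    alignment.

    ``exclude_changed`` runs a second pass whose metric ignores voxels that
    disagree by more than ``change_threshold`` of the grey range after the
    first pass (dilated by one voxel).  Between longitudinal time points the
    remodeled bone is exactly such a change, and leaving it in the metric
    drags the pose toward "explaining" growth with a rigid motion.
    """
    sitk.ProcessObject_SetGlobalWarningDisplay(False)
    f = sitk.Cast(volume_to_sitk(fixed), sitk.sitkFloat32)
    m = sitk.Cast(volume_to_sitk(moving), sitk.sitkFloat32)
    interior = _interior_mask(fixed.grid.shape, axial_margin)

    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS)
    result = _run_registration(f, m, interior, initial, learning_rate,
                               iterations, shrink_factors, smoothing_sigmas,
                               fixed.spacing)
    if not exclude_changed:
        return result

    aligned = resample_to(moving, result.transform, "linear")
    grey_range = float(fixed.grid.max() - fixed.grid.min())
    changed = np.abs(aligned.grid - fixed.grid) > change_threshold * grey_range
    changed = ndimage.binary_dilation(changed, np.ones((3, 3, 3), bool))
    second_mask = interior & ~changed
    if second_mask.sum() < 0.05 * interior.sum():
        logger.warning("register_rigid: change mask removed nearly all voxels; "
                       "keeping first-pass transform")
        return result
    initial2 = sitk.Euler3DTransform(result.transform.to_sitk())
    return _run_registration(f, m, second_mask, initial2, learning_rate,
                             iterations, shrink_factors, smoothing_sigmas,
                             fixed.spacing)


def resample_to(
    moving: Union[CalibratedVolume, BoneMask],
    transform: RigidTransform,
    interpolation: str | None = None,
) -> Union[CalibratedVolume, BoneMask]:
    """Express ``moving`` on the fixed grid through ``transform``.

    Grey volumes default to linear interpolation, masks to nearest neighbour.
    The identity transform with nearest interpolation is a bit-identical copy.
    """
    is_mask = isinstance(moving, BoneMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    if transform.is_identity() and interpolation == "nearest":
        return moving.copy()

    if is_mask:
        vol = CalibratedVolume(grid=moving.grid.astype(np.float32),
                               spacing=moving.spacing)
    else:
        vol = moving
    img = volume_to_sitk(vol)
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    background = 0.0 if is_mask else float(vol.grid.min())
    out = sitk.Resample(img, img, transform.to_sitk(), interp, background)
    grid = sitk_to_grid(out)
    if is_mask:
        return BoneMask(grid=grid > 0.5, spacing=moving.spacing,
                        provenance=moving.provenance + "|resampled")
    return CalibratedVolume(grid=grid, spacing=moving.spacing,
                            calibration=moving.calibration)
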