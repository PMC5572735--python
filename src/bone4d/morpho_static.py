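"""Static cortical morphometry on a VOI: areas, thickness, moments, density.

Outputs one record per limb/time point with the conventional cortical
parameters: Ct.Ar, T.Ar (total area inside the periosteal envelope),
Ct.Ar/T.Ar, Ct.Th, Imax, Imin and Ct.vTMD.  Areas are per-slice values
averaged arithmetically over the VOI slices; Ct.Th uses the 3D
largest-inscribed-sphere (distance transform) method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
from scipy import ndimage

from .core import BoneMask, CalibratedVolume


@dataclass(frozen=True)
class StaticMorphometry:
    Ct_Ar: float           # mm²
    T_Ar: float            # mm²
    Ct_Ar_over_T_Ar: float
    Ct_Th: float           # µm
    Imax: float            # mm⁴
    Imin: float            # mm⁴
    Ct_vTMD: float         # mg HA/cm³

    def as_dict(self) -> dict:
        return asdict(self)


def cross_section_areas(mask: BoneMask) -> Tuple[float, float, float]:
    """(Ct.Ar, T.Ar, Ct.Ar/T.Ar) in mm², averaged over VOI slices.

    T.Ar fills the periosteal envelope per slice (2D hole fill); slices with
    no bone are excluded with a warning.  The ratio is the ratio of means.
    """
    s_mm = mask.spacing / 1000.0
    pixel_area = s_mm * s_mm
    ct, tt = [], []
    skipped = 0
    for k in range(mask.grid.shape[2]):
        sl = mask.grid[:, :, k]
        n_bone = int(sl.sum())
        if n_bone == 0:
            skipped += 1
            continue
        filled = ndimage.binary_fill_holes(sl)
        ct.append(n_bone * pixel_area)
        tt.append(int(filled.sum()) * pixel_area)
    if skipped:
        warnings.warn(f"cross_section_areas: {skipped} empty slice(s) excluded",
                      stacklevel=2)
    if not ct:
        raise ValueError("no slice contains bone")
    ct_ar, t_ar = float(np.mean(ct)), float(np.mean(tt))
    return ct_ar, t_ar, ct_ar / t_ar


def local_thickness(mask_grid: np.ndarray, spacing: float,
                    upsample: int = 2, radius_step_voxels: float = 0.25,
                    fill_frac: float = 0.02) -> np.ndarray:
    """Local thickness map (µm): diameter of the largest inscribed sphere
    containing each foreground voxel (Hildebrand–Rüegsegger definition).

    Computed by morphological opening with balls of decreasing radius taken
    from the distance transform, on a grid supersampled ``upsample``-fold so
    that sphere centres may sit between original voxel centres (this removes
    the one-voxel parity bias of centre-restricted sphere fitting).  The mask
    is edge-padded so structures cut by the VOI faces are treated as
    continuing, matching how a diaphyseal VOI is cropped from a longer bone.

    The opening passes run from the largest sphere radius downward and stop
    once at most ``fill_frac`` of the foreground remains uncovered; the
    residual staircase-boundary voxels inherit the value of their nearest
    covered neighbour (a slight overestimate confined to that fraction, so
    its effect on the volume-weighted mean is well below the voxel size).
    Returns the thickness map on the original grid.
    """
    m = np.asarray(mask_grid, bool)
    if not m.any():
        raise ValueError("local_thickness: empty mask")
    if upsample > 1:
        m_up = np.repeat(np.repeat(np.repeat(m, upsample, 0), upsample, 1), upsample, 2)
        s = spacing / upsample
    else:
        m_up, s = m, spacing

    dt0 = ndimage.distance_transform_edt(m_up, sampling=s)
    pad = int(np.ceil(dt0.max() / s)) + 2
    mp = np.pad(m_up, pad, mode="edge")
    dt = ndimage.distance_transform_edt(mp, sampling=s)

    # quantize sphere radii to a fraction of the (upsampled) voxel size so the
    # discretization error scales down with resolution
    step = max(radius_step_voxels * s, 1e-9)
    radii = np.unique(np.floor(dt[mp] / step)) * step
    radii = radii[radii > 0]

    # descending radii, first assignment wins (= max over covering spheres)
    lt = np.zeros_like(dt)
    unassigned = mp.copy()
    total = unassigned.sum()
    for r in radii[::-1]:
        centres = dt >= r
        if not centres.any():
            continue
        dilated = ndimage.distance_transform_edt(~centres, sampling=s) <= r + 1e-9
        newly = dilated & unassigned
        lt[newly] = 2.0 * r
        unassigned &= ~newly
        if unassigned.sum() <= fill_frac * total:
            break
    if unassigned.any():  # nearest-covered-neighbour fill for the residue
        assigned = mp & ~unassigned
        _, idx = ndimage.distance_transform_edt(~assigned, sampling=s,
                                                return_indices=True)
        lt[unassigned] = lt[tuple(i[unassigned] for i in idx)]

    lt = lt[pad:-pad, pad:-pad, pad:-pad]
    if upsample > 1:
        # average the upsample³ sub-voxels back onto the original grid
        nx, ny, nz = m.shape
        lt = lt.reshape(nx, upsample, ny, upsample, nz, upsample).mean(axis=(1, 3, 5))
        lt[~m] = 0.0
    return lt


def cortical_thickness(mask: BoneMask, upsample: int = 2, **kwargs) -> float:
    """Volume-weighted mean local thickness Ct.Th (µm)."""
    lt = local_thickness(mask.grid, mask.spacing, upsample=upsample, **kwargs)
    return float(lt[mask.grid].mean())


def moments_of_inertia(mask: BoneMask) -> Tuple[float, float]:
    """Principal second moments of area (Imax, Imin) in mm⁴.

    Per slice: second-moment tensor of the bone pixels about the slice bone
    centroid, eigen-decomposed; the larger/smaller eigenvalues are averaged
    over slices.  Slices with fewer than 2 pixels are excluded with a warning.
    """
    s_mm = mask.spacing / 1000.0
    a = s_mm * s_mm
    imax, imin = [], []
    skipped = 0
    for k in range(mask.grid.shape[2]):
        ii, jj = np.nonzero(mask.grid[:, :, k])
        if len(ii) < 2:
            skipped += 1
            continue
        x = (ii + 0.5) * s_mm
        y = (jj + 0.5) * s_mm
        dx, dy = x - x.mean(), y - y.mean()
        ixx = float(np.sum(dy * dy)) * a
        iyy = float(np.sum(dx * dx)) * a
        ixy = -float(np.sum(dx * dy)) * a
        eig = np.linalg.eigvalsh(np.array([[ixx, ixy], [ixy, iyy]]))
        imin.append(eig[0])
        imax.append(eig[1])
    if skipped:
        warnings.warn(f"moments_of_inertia: {skipped} degenerate slice(s) excluded",
                      stacklevel=2)
    if not imax:
        raise ValueError("no usable slices")
    return float(np.mean(imax)), float(np.mean(imin))


def vtmd(volume: CalibratedVolume, mask: BoneMask) -> float:
    """Mean calibrated mineral density over bone voxels (mg HA/cm³)."""
    if volume.grid.shape != mask.grid.shape:
        raise ValueError("mask and volume shapes differ")
    if not mask.grid.any():
        raise ValueError("vtmd: empty mask")
    return float(volume.density()[mask.grid].mean())


def static_morphometry(volume: CalibratedVolume, mask: BoneMask,
                       upsample: int = 2) -> StaticMorphometry:
    """All static cortical parameters for one limb/time point."""
    ct_ar, t_ar, ratio = cross_section_areas(mask)
    imax, imin = moments_of_inertia(mask)
    return StaticMorphometry(
        Ct_Ar=ct_ar, T_Ar=t_ar, Ct_Ar_over_T_Ar=ratio,
        Ct_Th=cortical_thickness(mask, upsample=upsample),
        Imax=imax, Imin=imin,
        Ct_vTMD=vtmd(volume, mask),
    )
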