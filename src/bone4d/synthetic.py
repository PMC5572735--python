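"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline is exercised on data generated here:
hollow elliptical-tube phantoms standing in for the tibial mid-diaphysis,
surface formation/resorption with exactly known voxel counts, rigid
misalignment between "scan" time points, and the tabular inputs (fluorochrome
section measurements, strain-gauge series, qPCR Ct values).

Geometry convention (see :mod:`bone4d.core`): tube axis along the third array
index, voxel centres at ``(i + 0.5) s``; a voxel belongs to the phantom iff its
**centre** lies inside the analytic annulus (centre-sampling rule), which makes
brute-force per-voxel oracles unambiguous.  Angular sectors are measured
counter-clockwise from the +x axis about the tube axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import (
    BoneMask,
    CalibratedVolume,
    Calibration,
    DEFAULT_VOXEL_SIZE_UM,
    RigidTransform,
    sitk_to_grid,
    volume_to_sitk,
)

MAX_ROTATION_DEG = 15.0
MAX_TRANSLATION_VOXELS = 20.0


# --------------------------------------------------------------------------- #
# specs and ground truth
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PhantomSpec:
    """Elliptical cortical-tube phantom.

    Semi-axes in µm; densities in mg HA/cm³ (bone above, background below the
    segmentation threshold); grey noise additive Gaussian in HU.
    """

    outer_radii: Tuple[float, float] = (500.0, 400.0)
    inner_radii: Tuple[float, float] = (330.0, 230.0)
    length: float = 800.0
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM
    bone_density: float = 1200.0
    background_density: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0
    margin_voxels: int = 6
    #: fractional linear change of both radii from the proximal to the distal
    #: end (a tibial diaphysis is not a perfect cylinder; a nonzero taper also
    #: makes the axial position observable for registration)
    taper: float = 0.0
    #: periosteal crest ridges (angle deg, amplitude µm) — Gaussian bumps on
    #: the outer boundary emulating the tibial crest; they give longitudinal
    #: registration the rigid landmarks a real cortex has
    crests: Tuple[Tuple[float, float], ...] = ()
    crest_width_deg: float = 18.0
    #: sinusoidal axial radius modulation (fractional amplitude, periods):
    #: non-monotone axial structure pins the axial registration coordinate,
    #: which a monotone taper alone leaves free to drift along growth
    axial_ripple: Tuple[float, float] = (0.0, 0.0)
    #: shift of the anatomy relative to the acquisition grid (µm) — a second
    #: scan of the same bone lands on a different grid; a sub-voxel offset
    #: here emulates residual misregistration without interpolation artifacts
    grid_offset_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: scanner point-spread blur (Gaussian sigma, µm) applied to the grey
    #: volume; both scans of a pair share it, so the off-midpoint threshold
    #: displaces both surfaces equally and the displacement cancels in the
    #: day-0/day-15 difference
    psf_sigma_um: float = 0.0

    def validate(self, calibration: Calibration) -> None:
        if not (self.inner_radii[0] < self.outer_radii[0]
                and self.inner_radii[1] < self.outer_radii[1]):
            raise ValueError(
                "invalid geometry: inner semi-axes must be strictly less than outer "
                f"(inner={self.inner_radii}, outer={self.outer_radii})")
        if min(self.inner_radii) <= 0 or self.length <= 0 or self.voxel_size <= 0:
            raise ValueError("radii, length and voxel_size must be positive")
        thr = 809.6  # segmentation threshold on the density scale
        if not (self.bone_density > thr > self.background_density):
            raise ValueError(
                "bone_density must lie above and background_density below the "
                f"809.6 mg HA/cm³ segmentation threshold, got {self.bone_density}"
                f"/{self.background_density}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ResorptionPit:
    surface: str                  # "periosteal" | "endocortical"
    angle_deg: float              # angular position, CCW from +x
    axial_um: float               # axial position of the pit centre
    radius_um: float              # ball radius limiting the pit extent
    depth_um: float               # radial penetration from the surface


@dataclass(frozen=True)
class RemodelingSpec:
    """Ground-truth surface remodeling between two time points.

    ``formation_thickness_map`` maps surface name to a sequence of per-angular-
    sector apposition depths (µm); sectors partition [0°, 360°) uniformly.
    """

    formation_thickness_map: Dict[str, Sequence[float]] = field(default_factory=dict)
    resorption_pits: Tuple[ResorptionPit, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for surf, depths in self.formation_thickness_map.items():
            if surf not in ("periosteal", "endocortical"):
                raise ValueError(f"unknown surface {surf!r}")
            if np.any(np.asarray(depths, dtype=float) < 0):
                raise ValueError("formation depths must be non-negative")
        for pit in self.resorption_pits:
            if pit.surface not in ("periosteal", "endocortical"):
                raise ValueError(f"unknown surface {pit.surface!r}")
            if pit.depth_um < 0 or pit.radius_um <= 0:
                raise ValueError("pit radius must be positive and depth non-negative")


@dataclass
class GroundTruth:
    formed_voxel_count: int = 0
    resorbed_voxel_count: int = 0
    baseline_bone_voxel_count: int = 0
    formed_surface_faces: int = 0
    eroded_surface_faces: int = 0
    baseline_surface_faces: int = 0
    applied_transform: RigidTransform = field(default_factory=RigidTransform)


# --------------------------------------------------------------------------- #
# geometry helpers
# --------------------------------------------------------------------------- #

def _ellipse_boundary_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    """Polar radius of the ellipse x²/a² + y²/b² = 1 along direction theta."""
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _phantom_frame(spec: PhantomSpec):
    """Grid shape, tube-axis centre (µm) and voxel-centre coordinate arrays."""
    s = spec.voxel_size
    crest = max((a for _, a in spec.crests), default=0.0)
    nx = int(math.ceil(2 * (spec.outer_radii[0] + crest) / s)) + 2 * spec.margin_voxels
    ny = int(math.ceil(2 * (spec.outer_radii[1] + crest) / s)) + 2 * spec.margin_voxels
    nz = max(1, int(round(spec.length / s)))
    cx, cy = nx * s / 2.0, ny * s / 2.0
    x = (np.arange(nx) + 0.5) * s - cx - spec.grid_offset_um[0]
    y = (np.arange(ny) + 0.5) * s - cy - spec.grid_offset_um[1]
    return (nx, ny, nz), (cx, cy), x, y


def _axial_scale(spec: PhantomSpec, nz: int) -> np.ndarray:
    """Per-slice radius scale: 1 + taper · (z/L − ½) plus optional ripple."""
    zfrac = ((np.arange(nz) + 0.5) * spec.voxel_size
             - spec.grid_offset_um[2]) / (nz * spec.voxel_size)
    scale = 1.0 + spec.taper * (zfrac - 0.5)
    amp, periods = spec.axial_ripple
    if amp:
        scale = scale + amp * np.sin(2 * np.pi * periods * zfrac)
    return scale


def _outer_boundary_radius(theta: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Outer boundary polar radius: ellipse plus any crest bumps (µm)."""
    rb = _ellipse_boundary_radius(theta, *spec.outer_radii)
    sigma = np.deg2rad(spec.crest_width_deg)
    for angle_deg, amplitude in spec.crests:
        d = np.angle(np.exp(1j * (theta - np.deg2rad(angle_deg))))
        rb = rb + amplitude * np.exp(-0.5 * (d / sigma) ** 2)
    return rb


def _annulus_mask(spec: PhantomSpec):
    (nx, ny, nz), (cx, cy), x, y = _phantom_frame(spec)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    if spec.taper == 0.0 and not spec.crests:
        in_outer = (xx / spec.outer_radii[0]) ** 2 + (yy / spec.outer_radii[1]) ** 2 <= 1.0
        in_inner = (xx / spec.inner_radii[0]) ** 2 + (yy / spec.inner_radii[1]) ** 2 < 1.0
        section = in_outer & ~in_inner
        mask = np.repeat(section[:, :, None], nz, axis=2)
    else:
        theta = np.mod(np.arctan2(yy, xx), 2 * np.pi)
        r3 = np.hypot(xx, yy)[:, :, None]
        sc = _axial_scale(spec, nz)[None, None, :]
        rb_out = _outer_boundary_radius(theta, spec)[:, :, None] * sc
        rb_in = _ellipse_boundary_radius(theta, *spec.inner_radii)[:, :, None] * sc
        mask = (r3 <= rb_out) & ~(r3 < rb_in)
    return mask, (cx, cy), (xx, yy)


def count_surface_faces(mask: np.ndarray, exclude_axial_ends: bool = True) -> int:
    """Exposed 6-connectivity faces of ``mask`` against non-foreground.

    Axial end faces at the first/last slice are crop artifacts of a VOI and are
    excluded by default (consistent with :mod:`bone4d.morpho_dynamic`).
    """
    m = np.asarray(mask, bool)
    faces = 0
    for axis in range(3):
        hi = np.take(m, range(1, m.shape[axis]), axis=axis)
        lo = np.take(m, range(0, m.shape[axis] - 1), axis=axis)
        faces += int(np.sum(lo & ~hi)) + int(np.sum(hi & ~lo))
        first = np.take(m, [0], axis=axis)
        last = np.take(m, [m.shape[axis] - 1], axis=axis)
        if not (axis == 2 and exclude_axial_ends):
            faces += int(first.sum()) + int(last.sum())
    return faces


# --------------------------------------------------------------------------- #
# generators
# --------------------------------------------------------------------------- #

def rasterize_greys(mask_grid: np.ndarray, spec: PhantomSpec,
                    calibration: Calibration, seed: int | None = None) -> np.ndarray:
    """Grey-value scan of a bone mask: densities → HU, scanner PSF, noise.

    Used for both time points of a pair so that blur and noise treatment are
    identical; ``seed`` overrides ``spec.seed`` for the second acquisition.
    """
    from scipy import ndimage as _ndi
    hu_bone = calibration.to_hu(spec.bone_density)
    hu_bg = calibration.to_hu(spec.background_density)
    grid = np.where(mask_grid, hu_bone, hu_bg).astype(np.float64)
    if spec.psf_sigma_um > 0:
        grid = _ndi.gaussian_filter(grid, spec.psf_sigma_um / spec.voxel_size)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        grid = grid + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    return grid


def make_cortex_phantom(
    spec: PhantomSpec, calibration: Calibration | None = None
) -> Tuple[CalibratedVolume, BoneMask, GroundTruth]:
    """Rasterize the elliptical-tube phantom and its calibrated grey volume."""
    calibration = calibration or Calibration()
    spec.validate(calibration)

    mask_grid, _, _ = _annulus_mask(spec)
    grid = rasterize_greys(mask_grid, spec, calibration)

    volume = CalibratedVolume(grid=grid, spacing=spec.voxel_size, calibration=calibration)
    mask = BoneMask(grid=mask_grid, spacing=spec.voxel_size,
                    provenance=f"phantom(seed={spec.seed})")
    truth = GroundTruth(
        baseline_bone_voxel_count=int(mask_grid.sum()),
        baseline_surface_faces=count_surface_faces(mask_grid),
    )
    return volume, mask, truth


def apply_remodeling(
    baseline_mask: BoneMask, spec: RemodelingSpec, phantom: PhantomSpec
) -> Tuple[BoneMask, GroundTruth]:
    """Apply analytic surface formation/resorption to a phantom baseline.

    The follow-up mask is ``baseline ∪ formed ∖ resorbed``; reported counts are
    measured on the voxel sets actually applied, so they are exact by
    construction.  The phantom spec supplies the analytic surfaces.
    """
    spec.validate()
    s = phantom.voxel_size
    (nx, ny, nz), (cx, cy), x, y = _phantom_frame(phantom)
    base = baseline_mask.grid
    if base.shape != (nx, ny, nz):
        raise ValueError("baseline mask does not match the phantom spec grid")

    xx, yy = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(xx, yy)
    theta = np.mod(np.arctan2(yy, xx), 2 * np.pi)
    sc = _axial_scale(phantom, nz)  # per-slice radius scale (taper)
    rb_out = _outer_boundary_radius(theta, phantom)[:, :, None] * sc
    rb_in = _ellipse_boundary_radius(theta, *phantom.inner_radii)[:, :, None] * sc
    r3 = r[:, :, None]

    def sector_depth(depths: Sequence[float]) -> np.ndarray:
        depths = np.asarray(depths, dtype=float)
        idx = np.floor(theta / (2 * np.pi) * len(depths)).astype(int) % len(depths)
        return depths[idx][:, :, None]

    formed = np.zeros((nx, ny, nz), dtype=bool)
    ps_depth = ec_depth = None
    if "periosteal" in spec.formation_thickness_map:
        ps_depth = sector_depth(spec.formation_thickness_map["periosteal"])
        formed |= (r3 > rb_out) & (r3 <= rb_out + ps_depth)
    if "endocortical" in spec.formation_thickness_map:
        ec_depth = sector_depth(spec.formation_thickness_map["endocortical"])
        formed |= (r3 < rb_in) & (r3 >= rb_in - ec_depth)
    formed &= ~base  # formation grows from the existing surfaces only

    resorbed = np.zeros_like(base)
    zc = (np.arange(nz) + 0.5) * s - phantom.grid_offset_um[2]
    for pit in spec.resorption_pits:
        th0 = np.deg2rad(pit.angle_deg % 360.0)
        k0 = min(nz - 1, max(0, int(pit.axial_um / s)))
        radii_pair = phantom.outer_radii if pit.surface == "periosteal" else phantom.inner_radii
        r0 = _ellipse_boundary_radius(np.array([th0]), *radii_pair)[0] * sc[k0]
        # perforation guard over the angular span the pit can reach
        dth = pit.radius_um / max(r0, 1e-9)
        span = np.linspace(th0 - dth, th0 + dth, 61)
        wall = (_ellipse_boundary_radius(span, *phantom.outer_radii)
                - _ellipse_boundary_radius(span, *phantom.inner_radii)) * sc.min()
        if pit.depth_um >= wall.min():
            raise ValueError(
                f"pit at {pit.angle_deg}° depth {pit.depth_um} µm would perforate the "
                f"cortex (local wall {wall.min():.1f} µm)")
        # formation and resorption may not share a surface sector
        depth_here = {"periosteal": ps_depth, "endocortical": ec_depth}[pit.surface]
        if depth_here is not None:
            jj = np.argmin(np.abs(theta - th0) + np.abs(r - r0))
            if depth_here[:, :, 0].flat[jj] > 0:
                raise ValueError("formation and resorption overlap on the same "
                                 f"{pit.surface} sector at {pit.angle_deg}°")
        px = r0 * np.cos(th0)
        py = r0 * np.sin(th0)
        d2 = ((xx - px) ** 2 + (yy - py) ** 2)[:, :, None] + ((zc - pit.axial_um) ** 2)[None, None, :]
        within_ball = d2 <= pit.radius_um ** 2
        if pit.surface == "periosteal":
            within_depth = r3 >= rb_out - pit.depth_um
        else:
            within_depth = r3 <= rb_in + pit.depth_um
        resorbed |= within_ball & within_depth & base

    follow = (base | formed) & ~resorbed
    truth = GroundTruth(
        formed_voxel_count=int(formed.sum()),
        resorbed_voxel_count=int(resorbed.sum()),
        baseline_bone_voxel_count=int(base.sum()),
        formed_surface_faces=count_surface_faces(formed),
        eroded_surface_faces=count_surface_faces(resorbed),
        baseline_surface_faces=count_surface_faces(base),
    )
    out = BoneMask(grid=follow, spacing=baseline_mask.spacing,
                   provenance=baseline_mask.provenance + "+remodeled")
    return out, truth


def apply_rigid(
    volume: CalibratedVolume,
    transform: RigidTransform,
    interpolation: str = "linear",
) -> CalibratedVolume:
    """Resample ``volume`` through a rigid transform on its own grid.

    Out-of-field voxels take the volume's minimum grey value (background).
    Used to create the day-15 scan misalignment the registration must undo.
    """
    rot = np.max(np.abs(transform.rotation_deg))
    tra = np.max(np.abs(transform.translation_um)) / volume.spacing
    if rot > MAX_ROTATION_DEG or tra > MAX_TRANSLATION_VOXELS:
        raise ValueError(
            f"transform outside configured bounds (|rot| ≤ {MAX_ROTATION_DEG}°, "
            f"|t| ≤ {MAX_TRANSLATION_VOXELS} voxels)")
    if transform.is_identity() and interpolation == "nearest":
        return volume.copy()
    img = volume_to_sitk(volume)
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    background = float(volume.grid.min())
    out = sitk.Resample(img, img, transform.to_sitk(), interp, background)
    return CalibratedVolume(grid=sitk_to_grid(out), spacing=volume.spacing,
                            calibration=volume.calibration)


# --------------------------------------------------------------------------- #
# tabular generators
# --------------------------------------------------------------------------- #

def make_histo_dataset(
    group_params: pd.DataFrame,
    n_per_group: int,
    seed: int = 0,
    total_surface_um: float = 5000.0,
    n_distances: int = 8,
    label_interval_days: float = 9.0,
) -> pd.DataFrame:
    """Generate per-section fluorochrome measurements for histomorphometry.

    ``group_params`` needs one row per (genotype, age, limb, envelope) with
    columns ``sLS_BS_mean, sLS_BS_sd, dLS_BS_mean, dLS_BS_sd, MAR_mean, MAR_sd``
    (fractions in %, MAR in µm/day).  Label fractions are clamped to [0, 100] %
    and double-label distances are ``MAR × interval`` with matching noise.
    With all SDs zero every generated row reproduces the group means exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (no variance estimable otherwise)")
    req = {"sLS_BS_mean", "sLS_BS_sd", "dLS_BS_mean", "dLS_BS_sd", "MAR_mean", "MAR_sd"}
    missing = req - set(group_params.columns)
    if missing:
        raise ValueError(f"group_params missing columns: {sorted(missing)}")
    if (group_params[[c for c in req if c.endswith("_sd")]] < 0).any().any():
        raise ValueError("SDs must be >= 0")

    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    for _, g in group_params.iterrows():
        for i in range(n_per_group):
            sls = float(np.clip(rng.normal(g.sLS_BS_mean, g.sLS_BS_sd)
                                if g.sLS_BS_sd > 0 else g.sLS_BS_mean, 0, 100))
            dls = float(np.clip(rng.normal(g.dLS_BS_mean, g.dLS_BS_sd)
                                if g.dLS_BS_sd > 0 else g.dLS_BS_mean, 0, 100))
            if sls + dls > 100:          # single + double cannot exceed the surface
                scale = 100.0 / (sls + dls)
                sls, dls = sls * scale, dls * scale
            if dls > 0:
                mar = max(0.0, float(rng.normal(g.MAR_mean, g.MAR_sd))
                          if g.MAR_sd > 0 else float(g.MAR_mean))
                distances = [mar * label_interval_days] * n_distances
            else:
                distances = []
            rows.append({
                "animal": f"{g.genotype}-{g.age}-{i + 1}",
                "genotype": g.genotype, "age": g.age, "limb": g.limb,
                "envelope": g.envelope,
                "single_label_length_um": sls / 100.0 * total_surface_um,
                "double_label_length_um": dls / 100.0 * total_surface_um,
                "total_surface_length_um": total_surface_um,
                "interlabel_distances_um": ";".join(f"{d:.6g}" for d in distances),
                "label_interval_days": label_interval_days,
            })
    return pd.DataFrame(rows)


def make_strain_dataset(
    true_slope: float,
    intercept: float = 0.0,
    load_levels: Sequence[float] = (-2, -4, -6, -8, -10, -12, -14),
    noise_sd_strain: float = 0.0,
    n_animals: int = 7,
    seed: int = 0,
    group: str = "",
) -> pd.DataFrame:
    """Per-animal (load, strain) series with strain = (load − intercept)/slope + ε."""
    levels = np.asarray(sorted(set(float(l) for l in load_levels)))
    if len(levels) < 3:
        raise ValueError("need at least 3 distinct load levels")
    if true_slope == 0:
        raise ValueError("true_slope must be nonzero")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        strain = (levels - intercept) / true_slope
        if noise_sd_strain > 0:
            strain = strain + rng.normal(0, noise_sd_strain, size=len(levels))
        for load, eps in zip(levels, strain):
            rows.append({"animal": f"{group or 'grp'}-{a + 1}", "group": group,
                         "load_N": load, "strain_ue": eps})
    return pd.DataFrame(rows)


def make_qpcr_dataset(
    effects: Dict[str, Dict[str, float]],
    ct_ref_mean: float = 20.0,
    noise_sd_ct: float = 0.0,
    n: int = 6,
    seed: int = 0,
    reference_gene: str = "B2m",
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ct table per (animal, group, gene, limb): Ct = ref level − log2 expression + ε.

    ``effects`` maps group label → {gene: true log2 expression offset}; the
    reference gene's offset is fixed at 0 and must be present in every group.
    Each group carries both a loaded and a control limb; offsets apply to the
    loaded limb only, so loaded-vs-control fold changes equal 2**offset.
    """
    for grp, eff in effects.items():
        if reference_gene not in eff:
            raise ValueError(f"group {grp!r} is missing the reference gene {reference_gene!r}")
        if eff[reference_gene] != 0:
            raise ValueError("reference-gene offset must be 0")
    rng = np.random.default_rng(seed)
    rows = []
    for grp, eff in effects.items():
        gene_list = list(genes) if genes is not None else list(eff)
        for a in range(n):
            for limb in ("control", "loaded"):
                base = ct_ref_mean + (rng.normal(0, 1.0) if noise_sd_ct > 0 else 0.0)
                for gene in gene_list:
                    offset = eff.get(gene, 0.0) if limb == "loaded" else 0.0
                    ct = base - offset
                    if noise_sd_ct > 0 and gene != reference_gene:
                        ct = ct + rng.normal(0, noise_sd_ct)
                    rows.append({"animal": f"{grp}-{a + 1}", "group": grp,
                                 "limb": limb, "gene": gene, "ct": float(ct)})
    return pd.DataFrame(rows)
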