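"""Generators are pure functions of (spec, seed) and their ground truth is
measured on the emitted data, never assumed."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bone4d.core import Calibration, RigidTransform
from bone4d.synthetic import (
    PhantomSpec,
    RemodelingSpec,
    ResorptionPit,
    apply_remodeling,
    apply_rigid,
    make_cortex_phantom,
    make_histo_dataset,
    make_qpcr_dataset,
    make_strain_dataset,
)


def brute_force_annulus(spec: PhantomSpec) -> np.ndarray:
    """Independent per-voxel-centre containment oracle (no shared code path)."""
    s = spec.voxel_size
    import math
    nx = int(math.ceil(2 * spec.outer_radii[0] / s)) + 2 * spec.margin_voxels
    ny = int(math.ceil(2 * spec.outer_radii[1] / s)) + 2 * spec.margin_voxels
    nz = max(1, round(spec.length / s))
    out = np.zeros((nx, ny, nz), dtype=bool)
    cx, cy = nx * s / 2.0, ny * s / 2.0
    for i in range(nx):
        x = (i + 0.5) * s - cx
        for j in range(ny):
            y = (j + 0.5) * s - cy
            q_out = (x / spec.outer_radii[0]) ** 2 + (y / spec.outer_radii[1]) ** 2
            q_in = (x / spec.inner_radii[0]) ** 2 + (y / spec.inner_radii[1]) ** 2
            out[i, j, :] = (q_out <= 1.0) and not (q_in < 1.0)
    return out


class TestCortexPhantom:
    def test_matches_per_voxel_containment_oracle(self, circular_spec, circular_phantom):
        _, mask, truth = circular_phantom
        oracle = brute_force_annulus(circular_spec)
        assert np.array_equal(mask.grid, oracle)
        assert truth.baseline_bone_voxel_count == int(oracle.sum())

    def test_degenerate_geometry_rejected(self):
        spec = PhantomSpec(outer_radii=(300, 300), inner_radii=(300, 300))
        with pytest.raises(ValueError, match="geometry"):
            make_cortex_phantom(spec)

    def test_density_outside_threshold_band_rejected(self):
        with pytest.raises(ValueError):
            make_cortex_phantom(PhantomSpec(bone_density=700.0))

    def test_seeded_determinism(self):
        spec = PhantomSpec(outer_radii=(200, 160), inner_radii=(120, 80),
                           length=100, noise_sd=80.0, seed=11)
        v1, m1, _ = make_cortex_phantom(spec)
        v2, m2, _ = make_cortex_phantom(spec)
        assert np.array_equal(v1.grid, v2.grid)
        assert np.array_equal(m1.grid, m2.grid)

    def test_grey_values_follow_calibration(self, circular_phantom, default_calibration):
        vol, mask, _ = circular_phantom
        assert vol.grid[mask.grid][0] == pytest.approx(
            default_calibration.to_hu(1200.0), rel=1e-6)
        assert vol.grid[~mask.grid][0] == pytest.approx(
            default_calibration.to_hu(50.0), rel=1e-6)

    def test_voxel_count_converges_with_refinement(self):
        """Relative count error vs the analytic annulus area halves (or better)
        when the voxel size halves."""
        import math
        area = math.pi * (400e-3 ** 2 - 250e-3 ** 2)  # mm²
        errs = []
        for vs in (21.0, 10.5):
            spec = PhantomSpec(outer_radii=(400, 400), inner_radii=(250, 250),
                               length=4 * vs, voxel_size=vs, noise_sd=0)
            _, mask, truth = make_cortex_phantom(spec)
            nz = mask.grid.shape[2]
            meas = truth.baseline_bone_voxel_count / nz * (vs / 1000.0) ** 2
            errs.append(abs(meas - area) / area)
        assert errs[1] <= errs[0] / 2


class TestApplyRemodeling:
    def test_empty_spec_is_identity(self, circular_spec, circular_phantom):
        _, mask, _ = circular_phantom
        follow, truth = apply_remodeling(mask, RemodelingSpec(), circular_spec)
        assert np.array_equal(follow.grid, mask.grid)
        assert truth.formed_voxel_count == 0
        assert truth.resorbed_voxel_count == 0

    def test_uniform_apposition_matches_annulus_difference_oracle(
            self, circular_spec, circular_phantom):
        """21 µm periosteal apposition = difference of two rasterized annuli."""
        _, mask, _ = circular_phantom
        spec = RemodelingSpec(formation_thickness_map={"periosteal": [21.0]})
        follow, truth = apply_remodeling(mask, spec, circular_spec)
        grown = dataclasses.replace(
            circular_spec, outer_radii=(521.0, 521.0),
            margin_voxels=circular_spec.margin_voxels)  # same grid: margins absorb growth
        oracle_outer = brute_force_annulus(
            dataclasses.replace(grown, inner_radii=circular_spec.inner_radii))
        base_oracle = brute_force_annulus(circular_spec)
        expected_formed = int(oracle_outer.sum() - base_oracle.sum())
        assert truth.formed_voxel_count == expected_formed
        assert int(follow.grid.sum() - mask.grid.sum()) == expected_formed

    def test_ground_truth_counts_measured_on_masks(self, circular_spec, circular_phantom):
        _, mask, _ = circular_phantom
        spec = RemodelingSpec(
            formation_thickness_map={"endocortical": [0, 31.5, 0, 0]},
            resorption_pits=(ResorptionPit("periosteal", 180.0, 80.0, 50.0, 40.0),))
        follow, truth = apply_remodeling(mask, spec, circular_spec)
        formed = follow.grid & ~mask.grid
        resorbed = mask.grid & ~follow.grid
        assert truth.formed_voxel_count == int(formed.sum())
        assert truth.resorbed_voxel_count == int(resorbed.sum())

    def test_single_pit_is_connected_and_touches_surface(self, circular_spec, circular_phantom):
        from scipy import ndimage
        _, mask, _ = circular_phantom
        spec = RemodelingSpec(resorption_pits=(
            ResorptionPit("endocortical", 45.0, 80.0, 40.0, 30.0),))
        follow, truth = apply_remodeling(mask, spec, circular_spec)
        resorbed = mask.grid & ~follow.grid
        _, n = ndimage.label(resorbed, structure=np.ones((3, 3, 3), bool))
        assert n == 1
        assert truth.resorbed_voxel_count > 0

    def test_perforating_pit_rejected(self, circular_spec, circular_phantom):
        _, mask, _ = circular_phantom
        spec = RemodelingSpec(resorption_pits=(
            ResorptionPit("periosteal", 0.0, 80.0, 80.0, 250.0),))  # wall is 200 µm
        with pytest.raises(ValueError, match="perforate"):
            apply_remodeling(mask, spec, circular_spec)

    def test_formation_resorption_same_sector_rejected(self, circular_spec, circular_phantom):
        _, mask, _ = circular_phantom
        spec = RemodelingSpec(
            formation_thickness_map={"periosteal": [21.0]},
            resorption_pits=(ResorptionPit("periosteal", 90.0, 80.0, 40.0, 30.0),))
        with pytest.raises(ValueError, match="overlap"):
            apply_remodeling(mask, spec, circular_spec)


class TestApplyRigid:
    def test_identity_nearest_bit_identical(self, circular_phantom):
        vol, _, _ = circular_phantom
        out = apply_rigid(vol, RigidTransform(), interpolation="nearest")
        assert np.array_equal(out.grid, vol.grid)

    def test_integer_shift_nearest_is_lossless(self, circular_phantom):
        vol, _, _ = circular_phantom
        t = RigidTransform(translation_um=(2 * 10.5, -10.5, 3 * 10.5))
        out = apply_rigid(vol, t, interpolation="nearest")
        # output(x) = input(x + t): voxel (i,j,k) ← (i+2, j-1, k+3)
        assert np.array_equal(out.grid[:-2, 1:, :-3], vol.grid[2:, :-1, 3:])

    def test_rotation_conserves_grey_mass(self, circular_phantom):
        vol, _, _ = circular_phantom
        c = tuple(d * 10.5 / 2 for d in vol.shape)
        t = RigidTransform(rotation_deg=(0, 0, 7), centre_um=c)
        out = apply_rigid(vol, t, interpolation="linear")
        bg = vol.grid.min()
        mass0 = float((vol.grid - bg).sum())
        mass1 = float((out.grid - bg).sum())
        assert abs(mass1 - mass0) / mass0 < 0.01

    def test_out_of_bounds_transform_rejected(self, circular_phantom):
        vol, _, _ = circular_phantom
        with pytest.raises(ValueError, match="bounds"):
            apply_rigid(vol, RigidTransform(rotation_deg=(20, 0, 0)))


class TestHistoDataset:
    def test_zero_sd_reproduces_group_means(self):
        """Young-LC control endocortical row: sLS/BS 20.6 %, dLS/BS 53.1 %."""
        params = pd.DataFrame([{
            "genotype": "LC", "age": 10, "limb": "control", "envelope": "Ec",
            "sLS_BS_mean": 20.6, "sLS_BS_sd": 0.0,
            "dLS_BS_mean": 53.1, "dLS_BS_sd": 0.0,
            "MAR_mean": 1.21, "MAR_sd": 0.0}])
        df = make_histo_dataset(params, n_per_group=7, seed=1)
        assert len(df) == 7
        sls = 100 * df["single_label_length_um"] / df["total_surface_length_um"]
        dls = 100 * df["double_label_length_um"] / df["total_surface_length_um"]
        assert np.allclose(sls, 20.6)
        assert np.allclose(dls, 53.1)

    def test_zero_double_label_yields_no_distances(self):
        params = pd.DataFrame([{
            "genotype": "LC", "age": 26, "limb": "control", "envelope": "Ps",
            "sLS_BS_mean": 10.0, "sLS_BS_sd": 0.0,
            "dLS_BS_mean": 0.0, "dLS_BS_sd": 0.0,
            "MAR_mean": 1.0, "MAR_sd": 0.0}])
        df = make_histo_dataset(params, n_per_group=3, seed=0)
        assert (df["interlabel_distances_um"] == "").all()

    def test_seeded_determinism(self):
        params = pd.DataFrame([{
            "genotype": "KO", "age": 10, "limb": "loaded", "envelope": "Ec",
            "sLS_BS_mean": 7.3, "sLS_BS_sd": 7.6,
            "dLS_BS_mean": 84.6, "dLS_BS_sd": 9.2,
            "MAR_mean": 1.61, "MAR_sd": 0.15}])
        a = make_histo_dataset(params, n_per_group=7, seed=42)
        b = make_histo_dataset(params, n_per_group=7, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_small_group_rejected(self):
        params = pd.DataFrame([{
            "genotype": "LC", "age": 10, "limb": "control", "envelope": "Ec",
            "sLS_BS_mean": 20, "sLS_BS_sd": 0, "dLS_BS_mean": 50, "dLS_BS_sd": 0,
            "MAR_mean": 1.2, "MAR_sd": 0}])
        with pytest.raises(ValueError, match="n_per_group"):
            make_histo_dataset(params, n_per_group=1)


class TestStrainDataset:
    def test_noise_free_series_is_exactly_linear(self):
        df = make_strain_dataset(true_slope=-0.0143, load_levels=(-2, -6, -10, -14),
                                 n_animals=1, noise_sd_strain=0.0)
        fit = np.polyfit(df["strain_ue"], df["load_N"], 1)
        assert fit[0] == pytest.approx(-0.0143, abs=1e-12)
        resid = df["load_N"] - np.polyval(fit, df["strain_ue"])
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            make_strain_dataset(true_slope=-0.01, load_levels=(-2, -4))

    def test_seeded_determinism(self):
        a = make_strain_dataset(-0.0143, noise_sd_strain=25.0, n_animals=7, seed=5)
        b = make_strain_dataset(-0.0143, noise_sd_strain=25.0, n_animals=7, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestQpcrDataset:
    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            make_qpcr_dataset({"KO_10": {"Dkk1": 1.0}})

    def test_table_shape_matches_design(self):
        """n = 6 per group, one row per (animal, limb, gene)."""
        effects = {"KO_10": {"B2m": 0.0, "Dkk1": 0.5, "Lef1": -0.3}}
        df = make_qpcr_dataset(effects, n=6, seed=0)
        assert len(df) == 6 * 2 * 3
        assert set(df["limb"]) == {"loaded", "control"}

    def test_zero_offsets_zero_noise_gives_flat_ct(self):
        effects = {"LC_10": {"B2m": 0.0, "Axin2": 0.0}}
        df = make_qpcr_dataset(effects, ct_ref_mean=20.0, noise_sd_ct=0.0, n=3)
        assert np.allclose(df["ct"], 20.0)
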