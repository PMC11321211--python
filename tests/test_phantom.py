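"""Breathing-thorax phantom, projection/FBP surrogate and CBCT degradations."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from cyclesct import phantom as P
from cyclesct.core import PhaseVolume
from cyclesct.evaluation import mae, me, ssim


class TestMotion:
    def test_raised_cosine_endpoints(self, default_spec):
        spec = dataclasses.replace(default_spec, motion_amplitude=10.0)
        assert P.motion_displacement(spec, 0) == 0.0
        assert P.motion_displacement(spec, 5) == pytest.approx(10.0)

    def test_zero_amplitude(self, default_spec):
        spec = dataclasses.replace(default_spec, motion_amplitude=0.0)
        assert all(P.motion_displacement(spec, p) == 0.0 for p in range(10))

    def test_phase_out_of_range(self, default_spec):
        with pytest.raises(ValueError):
            P.motion_displacement(default_spec, 10)
        with pytest.raises(ValueError):
            P.motion_displacement(default_spec, -1)


class TestRender:
    def test_zero_motion_is_phase_invariant(self):
        spec = P.PhantomSpec(motion_amplitude=0.0)
        ref = P.render_phase(spec, 0).voxels
        for p in range(1, 10):
            np.testing.assert_array_equal(P.render_phase(spec, p).voxels, ref)

    def test_tumor_center_has_tumor_hu(self, default_spec, default_ct):
        tx, ty = default_spec.tumor_center
        half = (default_spec.grid_size - 1) / 2.0
        r = int(round(ty / default_spec.pixel_spacing + half))
        c = int(round(tx / default_spec.pixel_spacing + half))
        assert default_ct.voxels[r, c] == default_spec.tissue_hu["tumor"]

    def test_tumor_centroid_moves_by_motion_amplitude(self, default_spec):
        def centroid_mm(img, spec):
            mask = img == spec.tissue_hu["tumor"]
            r, c = ndimage.center_of_mass(mask)
            half = (spec.grid_size - 1) / 2.0
            return (r - half) * spec.pixel_spacing
        y0 = centroid_mm(P.render_phase(default_spec, 0).voxels, default_spec)
        y5 = centroid_mm(P.render_phase(default_spec, 5).voxels, default_spec)
        assert abs((y5 - y0) - default_spec.motion_amplitude) <= default_spec.pixel_spacing

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            P.Ellipse((0.0, 0.0), (0.0, 10.0))
        with pytest.raises(ValueError):
            P.PhantomSpec(tumor_center=(0.0, 0.0))  # tumor outside both lungs

    def test_tissue_hu_range_validated(self):
        with pytest.raises(ValueError):
            P.PhantomSpec(tissue_hu={**P.DEFAULT_TISSUE_HU, "bone": 5000.0})


class TestProjection:
    def test_empty_angle_list_rejected(self, default_ct):
        with pytest.raises(ValueError):
            P.forward_project(default_ct, [])

    def test_zero_attenuation_gives_zero_sinogram(self):
        vol = PhaseVolume(voxels=np.full((64, 64), -1000.0), phase=0, spacing=(2.0, 2.0))
        proj = P.forward_project(vol, P.uniform_angles(12))
        assert np.allclose(proj.sinogram, 0.0)

    def test_mass_conserved_across_angles(self, default_ct):
        proj = P.forward_project(default_ct, P.uniform_angles(60))
        sums = proj.sinogram.sum(axis=1)
        assert (sums.max() - sums.min()) / sums.mean() < 0.01

    def test_centered_disk_rows_rotation_invariant(self, default_spec):
        x, y = P._grid_mm(default_spec)
        img = np.where(x ** 2 + y ** 2 <= 80.0 ** 2, 0.0, -1000.0)
        vol = PhaseVolume(voxels=img, phase=0, spacing=(2.0, 2.0))
        rows = P.forward_project(vol, P.uniform_angles(24)).sinogram
        mean_row = rows.mean(axis=0)
        rel = np.linalg.norm(rows - mean_row, axis=1) / np.linalg.norm(mean_row)
        assert rel.max() < 0.05

    def test_angle_validation(self):
        with pytest.raises(ValueError):
            P.ProjectionSet(np.zeros((2, 8)), [10.0, 5.0], 1.0)
        with pytest.raises(ValueError):
            P.ProjectionSet(np.zeros((3, 8)), [0.0, 90.0], 1.0)


class TestFBP:
    def test_dense_roundtrip_mae_small(self, default_ct, default_spec):
        # bound recorded from the 720-angle round trip on the default phantom
        rec = P.fbp_reconstruct(P.forward_project(default_ct, P.uniform_angles(720)),
                                default_spec.grid_size)
        assert mae(rec.voxels, default_ct.voxels) < 25.0

    def test_zero_sinogram_gives_air(self):
        proj = P.ProjectionSet(np.zeros((12, 64)), P.uniform_angles(12), 2.0)
        rec = P.fbp_reconstruct(proj, 64)
        # zero attenuation maps back to -1000 HU (air) everywhere
        assert np.allclose(rec.voxels, -1000.0)

    def test_sparse_view_is_worse_than_dense(self, default_ct, default_spec):
        rec60 = P.fbp_reconstruct(P.forward_project(default_ct, P.uniform_angles(60)),
                                  default_spec.grid_size)
        rec720 = P.fbp_reconstruct(P.forward_project(default_ct, P.uniform_angles(720)),
                                   default_spec.grid_size)
        assert mae(rec60.voxels, default_ct.voxels) > mae(rec720.voxels, default_ct.voxels)

    def test_grid_mismatch_rejected(self, default_ct):
        proj = P.forward_project(default_ct, P.uniform_angles(12))
        with pytest.raises(ValueError):
            P.fbp_reconstruct(proj, 64)


class TestHUBias:
    def test_pure_offset_shifts_me_exactly(self):
        img = np.full((32, 32), 500.0)
        vol = PhaseVolume(voxels=img, phase=0, spacing=(2.0, 2.0))
        out = P.add_hu_bias(vol, offset=-100.0, cupping_coeff=0.0)
        assert abs(me(out.voxels, img) - (-100.0)) < 1e-9

    def test_zero_bias_is_identity(self):
        img = np.linspace(-500, 500, 1024).reshape(32, 32)
        vol = PhaseVolume(voxels=img, phase=0, spacing=(2.0, 2.0))
        out = P.add_hu_bias(vol, 0.0, 0.0)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-6)

    def test_cupping_center_vs_corner(self):
        img = np.full((33, 33), 500.0)
        vol = PhaseVolume(voxels=img, phase=0, spacing=(2.0, 2.0))
        out = P.add_hu_bias(vol, offset=-100.0, cupping_coeff=40.0)
        assert out.voxels[16, 16] == pytest.approx(400.0, abs=1e-4)
        assert out.voxels[0, 0] == pytest.approx(400.0 + 40.0, abs=1e-4)


class TestSimulateCBCT:
    def test_seeded_determinism(self, default_spec):
        a = P.simulate_cbct_phase(default_spec, 3, seed=9)
        b = P.simulate_cbct_phase(default_spec, 3, seed=9)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert a.modality == "CBCT"

    def test_clean_dense_simulation_close_to_truth(self, default_spec, default_ct):
        params = P.DegradationParams(n_angles=720, hu_offset=0.0,
                                     cupping_coeff=0.0, noise_sd=0.0)
        cb = P.simulate_cbct_phase(default_spec, 0, params, seed=0)
        assert ssim(cb.voxels, default_ct.voxels) > 0.999

    def test_undersampling_reduces_similarity(self, default_spec, default_ct):
        clean = P.DegradationParams(720, 0.0, 0.0, 0.0)
        sparse = P.DegradationParams(60, 0.0, 0.0, 0.0)
        s720 = ssim(P.simulate_cbct_phase(default_spec, 0, clean, 0).voxels,
                    default_ct.voxels)
        s60 = ssim(P.simulate_cbct_phase(default_spec, 0, sparse, 0).voxels,
                   default_ct.voxels)
        assert s60 < s720


class TestPairedDataset:
    def test_manifest_counts_and_geometry(self, micro_manifest):
        assert len(micro_manifest) == 2 * 10 * 1
        for rec in micro_manifest.records:
            pair = micro_manifest.load_pair(rec)
            assert pair.ct.shape == pair.cbct.shape == (32, 32)

    def test_regeneration_is_deterministic(self):
        specs = P.make_subject_specs(1, seed=3, grid_size=32, pixel_spacing=8.0)
        m1 = P.generate_paired_dataset(specs, P.DegradationParams(n_angles=16), None)
        m2 = P.generate_paired_dataset(specs, P.DegradationParams(n_angles=16), None)
        for r1, r2 in zip(m1.records, m2.records):
            assert r1 == r2
            np.testing.assert_array_equal(m1.load_pair(r1).cbct, m2.load_pair(r2).cbct)

    def test_empty_spec_list_rejected(self):
        with pytest.raises(ValueError):
            P.generate_paired_dataset([], None, None)

    def test_written_dataset_roundtrips(self, tmp_path):
        from cyclesct.data import DatasetManifest
        specs = P.make_subject_specs(1, seed=5, grid_size=32, pixel_spacing=8.0)
        manifest = P.generate_paired_dataset(
            specs, P.DegradationParams(n_angles=16), output_dir=tmp_path)
        loaded = DatasetManifest.load(tmp_path / "manifest.json")
        assert len(loaded) == len(manifest) == 10
        a = manifest.load_pair(manifest.records[4])
        b = loaded.load_pair(loaded.records[4])
        np.testing.assert_allclose(a.ct, b.ct, atol=1e-5)
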