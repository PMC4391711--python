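"""Virtual MRI: signal model, rasterization, k-space, noise, reconstruction."""

import dataclasses
import math

import numpy as np
import pytest

from plaquesim import mri as M

from conftest import annulus_section, circle, uniform_model


@pytest.fixture(scope="module")
def proto_coarse():
    return M.default_protocol_grid()[0]      # 0.62 x 0.62 x 2 mm


@pytest.fixture(scope="module")
def proto_fine():
    return M.default_protocol_grid()[5]      # 0.31 x 0.31 x 0.5 mm


@pytest.fixture(scope="module")
def phantom():
    """Axially uniform ring with one off-centre core."""
    sec = annulus_section(2.0, 5.0, lrncs=[circle(0.8, center=(3.2, 0.0))])
    return uniform_model(sec)


def fibrous_disc_map(protocol, params, radius=5.0, oversampling=4):
    s = M.spin_echo_signal("fibrous", params, protocol)
    n = oversampling * protocol.acquired_matrix
    ax = -protocol.fov / 2 + np.arange(n) * protocol.fov / n
    xx, yy = np.meshgrid(ax, ax)
    return M.SignalMap(np.where(xx ** 2 + yy ** 2 <= radius ** 2, s, 0.0),
                       protocol.fov, oversampling)


class TestSpinEchoSignal:
    def test_full_recovery_no_decay_returns_pd(self, tissue_params):
        p = M.SequenceProtocol(tr=1e9, te=1e-9)
        assert M.spin_echo_signal("fibrous", tissue_params, p) == pytest.approx(
            1.0, abs=1e-6)

    def test_closed_form_values(self, tissue_params, proto_coarse):
        for tissue, t1 in (("fibrous", 680.0), ("lrnc", 1220.0),
                           ("background", 1412.0)):
            expected = (1.0 - math.exp(-800.0 / t1)) * math.exp(-10.0 / 50.0)
            assert M.spin_echo_signal(tissue, tissue_params, proto_coarse) \
                == pytest.approx(expected, abs=1e-12)

    def test_contrast_ordering(self, tissue_params, proto_coarse):
        f = M.spin_echo_signal("fibrous", tissue_params, proto_coarse)
        l = M.spin_echo_signal("lrnc", tissue_params, proto_coarse)
        b = M.spin_echo_signal("background", tissue_params, proto_coarse)
        assert f > l > b > 0.0

    def test_blood_is_exactly_zero(self, tissue_params, proto_coarse):
        assert M.spin_echo_signal("blood", tissue_params, proto_coarse) == 0.0

    def test_nonpositive_relaxation_raises(self, proto_coarse):
        bad = M.TissueParams(t1={"fibrous": -1.0}, t2={"fibrous": 50.0},
                             proton_density={"fibrous": 1.0})
        with pytest.raises(ValueError):
            M.spin_echo_signal("fibrous", bad, proto_coarse)


class TestProtocolGrid:
    def test_six_protocols_with_16x_voxel_volume_span(self):
        grid = M.default_protocol_grid()
        assert len(grid) == 6
        vols = sorted(p.voxel_volume for p in grid)
        assert vols[0] == pytest.approx(0.05, abs=0.005)
        assert vols[-1] == pytest.approx(0.77, abs=0.01)
        assert vols[-1] / vols[0] == pytest.approx(16.0, rel=1e-9)

    def test_recon_voxel_is_half_acquired(self):
        for p in M.default_protocol_grid():
            assert p.recon_voxel == pytest.approx(p.acquired_voxel / 2)


class TestRasterize:
    def test_uniform_model_thickness_invariant(self, phantom, tissue_params,
                                               proto_coarse):
        a = M.rasterize_slab_signal(phantom, proto_coarse, tissue_params,
                                    n_z_levels=1)
        b = M.rasterize_slab_signal(phantom, proto_coarse, tissue_params,
                                    n_z_levels=9)
        assert np.allclose(a.values, b.values)

    def test_background_region_uniform(self, phantom, tissue_params,
                                       proto_coarse):
        smap = M.rasterize_slab_signal(phantom, proto_coarse, tissue_params)
        s_bg = M.spin_echo_signal("background", tissue_params, proto_coarse)
        n = smap.n
        # a patch inside the tissue disc but far from the vessel
        patch = smap.values[n // 2 - 4: n // 2 + 4, int(0.82 * n): int(0.86 * n)]
        assert np.allclose(patch, s_bg)

    def test_slab_outside_domain_raises(self, phantom, tissue_params):
        p = dataclasses.replace(M.default_protocol_grid()[0], slab_center_z=2.5)
        with pytest.raises(ValueError):
            M.rasterize_slab_signal(phantom, p, tissue_params)

    def test_oversampling_floor(self, phantom, tissue_params, proto_coarse):
        with pytest.raises(ValueError):
            M.rasterize_slab_signal(phantom, proto_coarse, tissue_params,
                                    oversampling=2)


class TestKSpace:
    def test_uniform_map_has_only_dc(self, proto_coarse):
        n = 4 * proto_coarse.acquired_matrix
        smap = M.SignalMap(np.full((n, n), 0.7), proto_coarse.fov, 4)
        ks = M.acquire_kspace(smap, proto_coarse)
        n_a = proto_coarse.acquired_matrix
        dc = ks.data[n_a // 2, n_a // 2]
        assert abs(dc) == pytest.approx(0.7 * n * n, rel=1e-12)
        off_dc = ks.data.copy()
        off_dc[n_a // 2, n_a // 2] = 0
        assert np.abs(off_dc).max() < 1e-6 * abs(dc)

    def test_truncation_is_identity_when_matrix_matches(self, tissue_params):
        p = dataclasses.replace(M.default_protocol_grid()[0])
        smap = fibrous_disc_map(p, tissue_params, oversampling=4)
        # acquiring at the map's own grid keeps the full spectrum
        p_full = dataclasses.replace(p, acquired_matrix=smap.n,
                                     recon_matrix=smap.n)
        ks = M.acquire_kspace(smap, p_full)
        img = M.reconstruct(ks, p_full, magnitude=False)
        assert np.allclose(img.data.real, smap.values, atol=1e-9)

    def test_truncated_energy_not_larger(self, tissue_params, proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        full = np.fft.fftshift(np.fft.fft2(smap.values))
        ks = M.acquire_kspace(smap, proto_coarse)
        assert np.sum(np.abs(ks.data) ** 2) <= np.sum(np.abs(full) ** 2)


class TestReconstruct:
    def test_zero_padding_preserves_acquired_lattice(self, tissue_params,
                                                     proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        ks = M.acquire_kspace(smap, proto_coarse)
        p_eq = dataclasses.replace(proto_coarse,
                                   recon_matrix=proto_coarse.acquired_matrix)
        padded = M.reconstruct(ks, proto_coarse, magnitude=False)
        plain = M.reconstruct(ks, p_eq, magnitude=False)
        stride = proto_coarse.recon_matrix // proto_coarse.acquired_matrix
        assert np.abs(padded.data[::stride, ::stride] - plain.data).max() < 1e-9

    def test_dc_preservation(self, tissue_params, proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        p_eq = dataclasses.replace(proto_coarse,
                                   recon_matrix=proto_coarse.acquired_matrix)
        img = M.reconstruct(M.acquire_kspace(smap, p_eq), p_eq, magnitude=False)
        assert img.data.real.mean() == pytest.approx(smap.values.mean(),
                                                     rel=1e-3)

    def test_uniform_phantom_central_ripple_below_1pct(self, proto_coarse):
        n = 4 * proto_coarse.acquired_matrix
        smap = M.SignalMap(np.full((n, n), 0.5), proto_coarse.fov, 4)
        img = M.reconstruct(M.acquire_kspace(smap, proto_coarse), proto_coarse)
        nr = img.data.shape[0]
        centre = img.data[nr // 4: 3 * nr // 4, nr // 4: 3 * nr // 4]
        assert np.abs(centre / 0.5 - 1.0).max() < 0.01

    def test_linearity_of_noiseless_pipeline(self, tissue_params, proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        ks1 = M.acquire_kspace(smap, proto_coarse)
        smap3 = M.SignalMap(3.0 * smap.values, smap.fov, smap.oversampling)
        ks3 = M.acquire_kspace(smap3, proto_coarse)
        img1 = M.reconstruct(ks1, proto_coarse, magnitude=False)
        img3 = M.reconstruct(ks3, proto_coarse, magnitude=False)
        assert np.abs(img3.data - 3.0 * img1.data).max() < 1e-9

    def test_recon_smaller_than_acquired_raises(self, tissue_params,
                                                proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        ks = M.acquire_kspace(smap, proto_coarse)
        p_bad = dataclasses.replace(proto_coarse, recon_matrix=64,
                                    acquired_matrix=64)
        ks_small = M.KSpace(ks.data, ks.map_n, ks.fov)
        p_tiny = dataclasses.replace(proto_coarse)
        with pytest.raises(ValueError):
            object.__setattr__(p_tiny, "recon_matrix", 32)
            M.reconstruct(ks_small, p_tiny)


class TestNoise:
    def test_same_seed_reproducible(self, tissue_params, proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        ks = M.acquire_kspace(smap, proto_coarse)
        a, _ = M.add_complex_noise(ks, proto_coarse, tissue_params, seed=4)
        b, _ = M.add_complex_noise(ks, proto_coarse, tissue_params, seed=4)
        assert np.array_equal(a.data, b.data)

    def test_infinite_snr_leaves_kspace_unchanged(self, tissue_params,
                                                  proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        ks = M.acquire_kspace(smap, proto_coarse)
        p_inf = dataclasses.replace(proto_coarse, target_snr=math.inf)
        out, sigma = M.add_complex_noise(ks, p_inf, tissue_params, seed=1)
        assert sigma == 0.0
        assert np.array_equal(out.data, ks.data)

    def test_magnitude_noise_flag(self, phantom, tissue_params, proto_coarse):
        img = M.simulate_protocol(phantom, proto_coarse, tissue_params,
                                  seed=3, noise="magnitude")
        assert img.realized_sigma > 0
        assert (img.data >= 0).all()


class TestMeasureSnr:
    def test_noiseless_image_infinite(self, tissue_params, proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        img = M.reconstruct(M.acquire_kspace(smap, proto_coarse), proto_coarse)
        assert math.isinf(M.measure_snr(img, M.center_disc_mask(img, 3.0),
                                        M.corner_noise_mask(img)))

    def test_known_sigma_recovered(self, tissue_params, proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        ks = M.acquire_kspace(smap, proto_coarse)
        snrs = []
        for seed in range(10):
            noisy, sigma = M.add_complex_noise(ks, proto_coarse, tissue_params,
                                               seed)
            img = M.reconstruct(noisy, proto_coarse, seed, sigma)
            snrs.append(M.measure_snr(img, M.center_disc_mask(img, 3.0),
                                      M.corner_noise_mask(img)))
        s_fib = M.spin_echo_signal("fibrous", tissue_params, proto_coarse)
        analytic = proto_coarse.target_snr
        assert np.mean(snrs) == pytest.approx(analytic, rel=0.10)
        del s_fib

    def test_empty_roi_raises(self, tissue_params, proto_coarse):
        smap = fibrous_disc_map(proto_coarse, tissue_params)
        img = M.reconstruct(M.acquire_kspace(smap, proto_coarse), proto_coarse)
        with pytest.raises(ValueError):
            M.measure_snr(img, np.zeros_like(img.data, dtype=bool),
                          M.corner_noise_mask(img))


class TestSimulateProtocol:
    def test_thickness_irrelevant_for_uniform_model(self, phantom,
                                                    tissue_params):
        grid = M.default_protocol_grid()
        img2 = M.simulate_protocol(phantom, grid[0], tissue_params, noise=None)
        img05 = M.simulate_protocol(phantom, grid[2], tissue_params, noise=None)
        assert np.abs(img2.data - img05.data).max() < 1e-6

    def test_recon_shape_and_voxel(self, phantom, tissue_params):
        p = M.default_protocol_grid()[0]    # 0.62 mm acquired
        img = M.simulate_protocol(phantom, p, tissue_params, seed=1)
        assert img.data.shape == (p.recon_matrix, p.recon_matrix)
        assert img.voxel_size == pytest.approx(0.31)

    def test_finer_inplane_tracks_map_better(self, phantom, tissue_params):
        grid = M.default_protocol_grid()
        smap = M.rasterize_slab_signal(phantom, grid[0], tissue_params,
                                       oversampling=8)
        errs = {}
        for p in (grid[0], grid[3]):        # 0.62 vs 0.31, 2 mm slab
            img = M.simulate_protocol(phantom, p, tissue_params, noise=None,
                                      oversampling=8)
            k = smap.n // img.data.shape[0]
            coarse_map = smap.values.reshape(
                img.data.shape[0], k, img.data.shape[0], k).mean(axis=(1, 3))
            errs[p.name] = np.abs(img.data - coarse_map).mean()
        assert errs[grid[3].name] < errs[grid[0].name]

    def test_nifti_sidecar_roundtrip(self, phantom, tissue_params, tmp_path):
        p = M.default_protocol_grid()[0]
        img = M.simulate_protocol(phantom, p, tissue_params, seed=2)
        img.to_nifti(tmp_path / "img.nii.gz")
        import json
        import nibabel as nib
        loaded = nib.load(tmp_path / "img.nii.gz")
        assert loaded.shape == img.data.shape
        sidecar = json.loads((tmp_path / "img.nii.gz.json").read_text())
        assert sidecar["noise_seed"] == 2
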