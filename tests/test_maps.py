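"""Density maps: MRC round trips, segmentation against a brute-force voxel
oracle, GMM parameter recovery, rendering equivariance, correlation and FSC
properties."""

import numpy as np
import pytest

from fuzzycoat.maps import (DensityMap, GaussianMixture, MapFormatError,
                            fit_gmm, fourier_shell_correlation, load_density_map,
                            load_gmm, real_space_correlation,
                            render_map_from_gmm, save_gmm, save_mrc, segment_map)


def blob_map(means, weights, sigma=0.2, voxel=0.1, pad=1.0):
    means = np.atleast_2d(means)
    gmm = GaussianMixture.isotropic(weights, means, sigma)
    lo = means.min(axis=0) - pad
    hi = means.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    grid = DensityMap(np.zeros(shape), lo, np.repeat(voxel, 3))
    return render_map_from_gmm(gmm, like=grid), gmm


class TestIO:
    def test_mrc_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(0)
        values = rng.random((8, 10, 12)).astype(np.float32).astype(float)
        dmap = DensityMap(values, origin=[0.5, -0.2, 1.0], voxel_size=0.12)
        path = tmp_path / "m.mrc"
        save_mrc(path, dmap)
        back = load_density_map(path)
        assert np.array_equal(back.values, dmap.values)
        np.testing.assert_allclose(back.voxel_size, dmap.voxel_size, rtol=1e-6)
        np.testing.assert_allclose(back.origin, dmap.origin, atol=1e-7)

    def test_argmax_voxel_transforms_to_nm(self, tmp_path):
        values = np.zeros((6, 6, 6))
        values[2, 3, 4] = 1.0
        dmap = DensityMap(values, origin=[1.0, 2.0, 3.0], voxel_size=[0.2, 0.3, 0.4])
        save_mrc(tmp_path / "m.mrc", dmap)
        back = load_density_map(tmp_path / "m.mrc")
        peak = np.unravel_index(np.argmax(back.values), back.shape)
        pos = back.origin + np.array(peak) * back.voxel_size
        np.testing.assert_allclose(pos, [1.4, 2.9, 4.6], atol=1e-6)

    def test_truncated_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.mrc"
        p.write_bytes(b"\x00" * 100)
        with pytest.raises(MapFormatError):
            load_density_map(p)

    def test_gmm_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 3)) * 0.1
        gmm = GaussianMixture([1.0, 2.0], rng.normal(size=(2, 3)),
                              np.stack([A @ A.T + 0.05 * np.eye(3)] * 2))
        save_gmm(tmp_path / "g.txt", gmm, metadata={"note": "test"})
        back = load_gmm(tmp_path / "g.txt")
        np.testing.assert_allclose(back.weights, gmm.weights, rtol=1e-9)
        np.testing.assert_allclose(back.covariances, gmm.covariances, rtol=1e-8)


class TestSegmentation:
    def test_huge_cutoff_is_identity(self):
        from conftest import point_model
        dmap, _ = blob_map([[0, 0, 0]], [1.0])
        out = segment_map(dmap, point_model([[0, 0, 0]]), cutoff=100.0)
        assert np.array_equal(out.values, dmap.values)

    def test_far_model_zeroes_map(self):
        from conftest import point_model
        dmap, _ = blob_map([[0, 0, 0]], [1.0])
        out = segment_map(dmap, point_model([[50.0, 0, 0]]), cutoff=0.5)
        assert np.all(out.values == 0)

    def test_single_atom_against_exhaustive_scan(self):
        """Kept voxels are exactly those whose center is within the cutoff."""
        from conftest import point_model
        dmap, _ = blob_map([[0, 0, 0]], [1.0], pad=0.8)
        atom = np.array([0.05, -0.1, 0.12])
        cutoff = 0.37
        out = segment_map(dmap, point_model([atom]), cutoff=cutoff)
        centers = dmap.voxel_centers().reshape(dmap.shape + (3,))
        keep = np.linalg.norm(centers - atom, axis=-1) <= cutoff
        assert np.array_equal(out.values != 0, keep & (dmap.values != 0))

    def test_output_bounded_by_input(self):
        from conftest import point_model
        dmap, _ = blob_map([[0, 0, 0]], [1.0])
        out = segment_map(dmap, point_model([[0.2, 0, 0]]), cutoff=0.3)
        assert np.all(out.values <= dmap.values + 1e-15)

    def test_empty_model_rejected(self):
        from conftest import point_model
        dmap, _ = blob_map([[0, 0, 0]], [1.0])
        empty = point_model([[0, 0, 0]]).select(np.array([False]))
        with pytest.raises(ValueError):
            segment_map(dmap, empty, cutoff=0.5)


class TestGMMFitting:
    def test_five_component_mean_recovery(self):
        rng = np.random.default_rng(5)
        means = rng.uniform(-0.8, 0.8, (5, 3))
        dmap, _ = blob_map(means, np.full(5, 1.0), sigma=0.12, voxel=0.08)
        fit = fit_gmm(dmap, 5, seed=2)
        got = fit.mixture.means
        for mu in means:
            nearest = got[np.argmin(np.linalg.norm(got - mu, axis=1))]
            assert np.linalg.norm(nearest - mu) < 0.08  # within one voxel

    def test_single_blob_moments(self):
        dmap, _ = blob_map([[0, 0, 0]], [1.0], sigma=0.2, voxel=0.06, pad=1.2)
        fit = fit_gmm(dmap, 1, seed=0)
        mu = fit.mixture.means[0]
        cov = fit.mixture.covariances[0]
        assert np.linalg.norm(mu) < 0.06
        evs = np.linalg.eigvalsh(cov)
        np.testing.assert_allclose(evs, 0.04, rtol=0.05)

    def test_correlation_non_decreasing_in_components(self):
        rng = np.random.default_rng(7)
        means = rng.uniform(-0.6, 0.6, (6, 3))
        dmap, _ = blob_map(means, rng.uniform(0.5, 2.0, 6), sigma=0.15, voxel=0.1)
        ccs = [fit_gmm(dmap, k, seed=1).correlation for k in (1, 2, 4, 8)]
        for lo, hi in zip(ccs, ccs[1:]):
            assert hi >= lo - 1e-3   # EM local-optimum slack

    def test_too_few_voxels_rejected(self):
        dmap = DensityMap(np.zeros((4, 4, 4)), np.zeros(3), 0.1)
        dmap.values[1, 1, 1] = 1.0
        with pytest.raises(ValueError):
            fit_gmm(dmap, 4, seed=0)


class TestRendering:
    def test_unit_component_normalization(self):
        dmap, _ = blob_map([[0, 0, 0]], [1.0], sigma=0.15, voxel=0.05, pad=1.2)
        total = dmap.values.sum() * dmap.voxel_volume
        assert abs(total - 1.0) < 0.01

    def test_translation_equivariance_by_one_voxel(self):
        voxel = 0.1
        dmap, gmm = blob_map([[0, 0, 0]], [1.0], voxel=voxel)
        shifted = GaussianMixture(gmm.weights, gmm.means + [voxel, 0, 0],
                                  gmm.covariances)
        out = render_map_from_gmm(shifted, like=dmap)
        np.testing.assert_allclose(out.values[1:], dmap.values[:-1], atol=1e-9)

    def test_fit_render_fit_stability(self):
        rng = np.random.default_rng(3)
        dmap, _ = blob_map(rng.uniform(-0.5, 0.5, (4, 3)), np.full(4, 1.0),
                           sigma=0.15, voxel=0.1)
        fit1 = fit_gmm(dmap, 4, seed=0)
        r1 = render_map_from_gmm(fit1.mixture, like=dmap)
        fit2 = fit_gmm(r1, 4, seed=0)
        r2 = render_map_from_gmm(fit2.mixture, like=dmap)
        assert real_space_correlation(r1, r2) > 0.99


class TestCorrelation:
    def test_self_and_negation(self):
        dmap, _ = blob_map([[0, 0, 0]], [1.0])
        assert real_space_correlation(dmap, dmap) == pytest.approx(1.0)
        neg = dmap.copy()
        neg.values = -neg.values
        assert real_space_correlation(dmap, neg, mask=dmap.values != 0) == \
            pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(11)
        a = DensityMap(rng.random((6, 6, 6)), np.zeros(3), 0.1)
        b = DensityMap(rng.random((6, 6, 6)), np.zeros(3), 0.1)
        mask = np.ones((6, 6, 6), dtype=bool)
        c1 = real_space_correlation(a, b, mask)
        c2 = real_space_correlation(b, a, mask)
        assert c1 == pytest.approx(c2)
        a2 = a.copy()
        a2.values = 3.0 * a2.values + 0.7
        assert real_space_correlation(a2, b, mask) == pytest.approx(c1)

    def test_zero_variance_raises(self):
        flat = DensityMap(np.ones((4, 4, 4)), np.zeros(3), 0.1)
        with pytest.raises(ValueError):
            real_space_correlation(flat, flat, mask=np.ones((4, 4, 4), bool))


class TestFSC:
    def test_self_correlation_unity(self):
        dmap, _ = blob_map([[0, 0, 0], [0.4, 0.1, -0.2]], [1.0, 0.7])
        fsc = fourier_shell_correlation(dmap, dmap)
        occupied = fsc.counts > 0
        np.testing.assert_allclose(fsc.correlation[occupied], 1.0, atol=1e-10)

    def test_scaling_invariance(self):
        dmap, _ = blob_map([[0, 0, 0]], [1.0])
        scaled = dmap.copy()
        scaled.values = 2.5 * scaled.values
        fsc = fourier_shell_correlation(dmap, scaled)
        np.testing.assert_allclose(fsc.correlation[fsc.counts > 0], 1.0, atol=1e-10)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        n = 32
        a = DensityMap(rng.normal(size=(n, n, n)), np.zeros(3), 0.1)
        b = DensityMap(rng.normal(size=(n, n, n)), np.zeros(3), 0.1)
        fsc = fourier_shell_correlation(a, b)
        sel = fsc.counts > 0
        bound = 3.0 / np.sqrt(np.maximum(fsc.counts[sel], 1))
        frac_outside = np.mean(np.abs(fsc.correlation[sel]) > bound)
        assert frac_outside <= 0.05

    def test_low_pass_filtered_self(self):
        rng = np.random.default_rng(1)
        n = 32
        vox = 0.1
        vals = rng.normal(size=(n, n, n))
        f = np.fft.fftn(vals)
        freq = np.fft.fftfreq(n, d=vox)
        kx, ky, kz = np.meshgrid(freq, freq, freq, indexing="ij")
        kr = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
        cutoff = 2.0  # nm^-1
        low = np.real(np.fft.ifftn(np.where(kr <= cutoff, f, 0)))
        a = DensityMap(vals, np.zeros(3), vox)
        b = DensityMap(low, np.zeros(3), vox)
        fsc = fourier_shell_correlation(a, b)
        below = fsc.frequencies < cutoff - 0.25
        above = fsc.frequencies > cutoff + 0.25
        assert np.all(fsc.correlation[below] > 0.99)
        assert np.all(np.abs(fsc.correlation[above & (fsc.counts > 0)]) < 0.3)

    def test_grid_mismatch_rejected(self):
        a = DensityMap(np.zeros((4, 4, 4)), np.zeros(3), 0.1)
        b = DensityMap(np.zeros((5, 5, 5)), np.zeros(3), 0.1)
        with pytest.raises(ValueError):
            fourier_shell_correlation(a, b)
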