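"""Metainference: the GMM forward model, overlap integrals against a
quadrature oracle, the hybrid-energy algebra, error-parameter Monte Carlo
against analytic conditionals, and the toy posterior sampler."""

import numpy as np
import pytest

from fuzzycoat import metainference as mi, synth
from fuzzycoat.maps import GaussianMixture, _gauss3, grid_for_support, \
    real_space_correlation, render_map_from_gmm
from fuzzycoat.model import Ensemble
from fuzzycoat.synth import render_synthetic_map, tail_coords_from_torsions


def random_component(rng, scale=0.3):
    A = rng.normal(size=(3, 3)) * 0.1
    cov = A @ A.T + 0.02 * np.eye(3)
    return (rng.uniform(0.5, 2.0), rng.normal(size=3) * scale, cov)


def quadrature_overlap(a, b, n=110):
    """Gauss–Legendre tensor quadrature of ∫ φ_a φ_b over a covering box."""
    wa, ma, ca = a
    wb, mb, cb = b
    smax = np.sqrt(max(np.linalg.eigvalsh(ca).max(), np.linalg.eigvalsh(cb).max()))
    lo = np.minimum(ma, mb) - 7 * smax
    hi = np.maximum(ma, mb) + 7 * smax
    xs, ws = [], []
    for d in range(3):
        x, w = np.polynomial.legendre.leggauss(n)
        xs.append(0.5 * (hi[d] - lo[d]) * x + 0.5 * (hi[d] + lo[d]))
        ws.append(0.5 * (hi[d] - lo[d]) * w)
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    f = wa * _gauss3(pts, ma, ca) * wb * _gauss3(pts, mb, cb)
    W = np.einsum("i,j,k->ijk", *ws).ravel()
    return float(np.sum(f * W))


class TestModelGMM:
    def test_one_component_per_heavy_atom(self, small_filament):
        gmm = mi.model_to_gmm(small_filament)
        n_heavy = int(np.sum(small_filament.elements != "H"))
        assert gmm.n_components == n_heavy
        assert gmm.weights.sum() == pytest.approx(
            small_filament.atomic_numbers().sum())

    def test_no_heavy_atoms_rejected(self):
        from conftest import point_model
        m = point_model([[0, 0, 0]], elements=["H"])
        with pytest.raises(ValueError):
            mi.model_to_gmm(m)

    def test_render_paths_agree(self, small_filament):
        """Rendering a model GMM equals the direct synthetic-map renderer."""
        sigma = 0.15
        direct = render_synthetic_map(small_filament, voxel_size=0.12,
                                      resolution_sigma=sigma)
        gmm = mi.model_to_gmm(small_filament, atom_sigma=sigma)
        via_gmm = render_map_from_gmm(gmm, like=direct)
        scale = np.abs(direct.values).max()
        np.testing.assert_allclose(via_gmm.values, direct.values,
                                   atol=1e-10 * scale)


class TestGaussianOverlap:
    def test_equal_isotropic_identity(self):
        s = 0.2
        comp = (1.0, np.zeros(3), s ** 2 * np.eye(3))
        assert mi.gaussian_overlap(comp, comp) == \
            pytest.approx((4 * np.pi * s ** 2) ** -1.5, rel=1e-12)

    def test_monotone_decay_with_distance(self):
        s = 0.2
        cov = s ** 2 * np.eye(3)
        values = [mi.gaussian_overlap((1, np.zeros(3), cov),
                                      (1, np.array([d, 0, 0]), cov))
                  for d in np.linspace(0, 3, 10)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-6 * values[0]

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = random_component(rng), random_component(rng)
        assert mi.gaussian_overlap(a, b) == pytest.approx(
            mi.gaussian_overlap(b, a), rel=1e-12)

    def test_quadrature_oracle_20_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_component(rng), random_component(rng)
            closed = mi.gaussian_overlap(a, b)
            quad = quadrature_overlap(a, b)
            assert abs(closed - quad) / abs(quad) < 1e-6

    def test_singular_covariance_rejected(self):
        bad = (1.0, np.zeros(3), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            mi.gaussian_overlap(bad, bad)


def toy_state(small_filament, n_replicas=4, seed=0, jitter=0.0):
    rng = np.random.default_rng(seed)
    coords = np.repeat(small_filament.coords[None], n_replicas, axis=0)
    if jitter:
        coords = coords + rng.normal(0, jitter, coords.shape)
    replicas = Ensemble(small_filament, coords)
    data = mi.model_to_gmm(small_filament)
    return mi.MetainferenceState.create(replicas, data, sigma_b_frac=0.3)


class TestReplicaAveraging:
    def test_identical_replicas_zero_sem(self, small_filament):
        state = toy_state(small_filament)
        ov_bar, sem = mi.replica_averaged_overlap(state)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)
        single = state.replica_overlaps()[0]
        np.testing.assert_allclose(ov_bar, single)

    def test_two_replicas_arithmetic_mean(self, small_filament):
        state = toy_state(small_filament, n_replicas=2, jitter=0.02, seed=1)
        rows = state.replica_overlaps()
        ov_bar, _ = mi.replica_averaged_overlap(state, rows)
        np.testing.assert_allclose(ov_bar, rows.mean(axis=0))

    def test_sem_matches_direct_recomputation(self, small_filament):
        state = toy_state(small_filament, n_replicas=8, jitter=0.03, seed=2)
        rows = state.replica_overlaps()
        _, sem = mi.replica_averaged_overlap(state, rows)
        np.testing.assert_allclose(sem, rows.std(axis=0, ddof=1) / np.sqrt(8))


class TestEnergyAlgebra:
    def test_perfect_model_zero_restraint(self, small_filament):
        state = toy_state(small_filament)   # data GMM == every replica's GMM
        report = mi.metainference_energy(state)
        assert report.restraint == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(report.residuals, 0.0, atol=1e-9)

    def test_doubling_sigma_quarters_restraint(self, small_filament):
        state = toy_state(small_filament, jitter=0.05, seed=3)
        state.sigma_sem = np.zeros_like(state.ov_dd)
        rows = state.replica_overlaps()
        res = state.ov_dd - rows.mean(axis=0)
        e1 = mi.restraint_energy(res, state.sigma_b, state.sigma_sem, 1.0)
        e2 = mi.restraint_energy(res, 2 * state.sigma_b, state.sigma_sem, 1.0)
        assert e2 == pytest.approx(e1 / 4.0, rel=1e-12)

    def test_restraint_monotone_in_residual(self, small_filament):
        state = toy_state(small_filament)
        sem = np.zeros_like(state.ov_dd)
        base = np.abs(np.random.default_rng(0).normal(size=len(state.ov_dd)))
        energies = [mi.restraint_energy(s * base, state.sigma_b, sem, 1.0)
                    for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(energies, energies[1:]))

    def test_report_total_is_sum_of_parts(self, small_filament):
        state = toy_state(small_filament, jitter=0.02, seed=5)
        report = mi.metainference_energy(state, bias=1.3, prior=0.7)
        assert report.total == pytest.approx(
            report.prior + report.restraint + report.error + report.bias)

    def test_nonpositive_sigma_rejected(self, small_filament):
        state = toy_state(small_filament)
        with pytest.raises(ValueError):
            mi.restraint_energy(np.ones_like(state.ov_dd),
                                0.0 * state.sigma_b,
                                np.zeros_like(state.ov_dd), 1.0)


class TestErrorParameterMC:
    def test_zero_residual_concentrates_at_lower_bound(self, small_filament):
        """With no residual the conditional density is ∝ 1/σ² on the bounds;
        the sampled median must match the analytic truncated median."""
        state = toy_state(small_filament)
        state.sigma_sem = np.zeros_like(state.ov_dd)
        res = np.zeros_like(state.ov_dd)
        samples, _ = mi.sample_error_parameters(
            state, 4000, proposal_width=1.0, seed=0, residuals=res)
        lo = mi.SIGMA_BOUNDS[0] * state.ov_dd
        hi = mi.SIGMA_BOUNDS[1] * state.ov_dd
        med_analytic = 2 * lo * hi / (lo + hi)   # median of c/σ² on [lo, hi]
        med = np.median(samples[2000:], axis=0).mean(axis=0)
        ratio = med / med_analytic
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_posterior_mean_grows_with_residual(self, small_filament):
        state = toy_state(small_filament)
        state.sigma_sem = np.zeros_like(state.ov_dd)
        means = []
        for scale in (0.01, 0.3):
            st = toy_state(small_filament)
            st.sigma_sem = np.zeros_like(st.ov_dd)
            samples, _ = mi.sample_error_parameters(
                st, 2000, proposal_width=0.8, seed=1,
                residuals=scale * st.ov_dd)
            means.append((samples[1000:] / st.ov_dd[None, None, :]).mean())
        assert means[1] > 2 * means[0]

    def test_tiny_proposal_accepts_everything(self, small_filament):
        state = toy_state(small_filament, jitter=0.02, seed=7)
        _, rate = mi.sample_error_parameters(state, 50, proposal_width=1e-9,
                                             seed=2)
        assert rate > 0.999


class TestRelativeError:
    def test_sigma_at_lower_bound_definition(self, small_filament):
        state = toy_state(small_filament)
        state.sigma_sem = np.zeros_like(state.ov_dd)
        lo = mi.SIGMA_BOUNDS[0]
        state.sigma_b = np.broadcast_to(lo * state.ov_dd,
                                        state.sigma_b.shape).copy()
        rel = mi.relative_error_per_gaussian(state)
        np.testing.assert_allclose(rel, lo, rtol=1e-9)

    def test_planted_discrepancy_shows_in_tail_components(self, small_spec,
                                                          small_filament):
        """Fitting a tail-less model against tail-bearing data raises the
        relative error of the data components near the missing tail."""
        chain = small_filament.chains[1]
        tail_mask = synth.tail_atom_mask(small_filament, small_spec, chain)
        heavy = small_filament.elements != "H"
        data = mi.model_to_gmm(small_filament)          # with tail
        tail_comp = tail_mask[heavy]                     # data components
        ablated = small_filament.select(~tail_mask)
        replicas = Ensemble(ablated, np.repeat(ablated.coords[None], 4, axis=0))
        state = mi.MetainferenceState(replicas, data, sigma_b=np.array(1.0))
        state.sigma_b = np.broadcast_to(0.3 * state.ov_dd,
                                        (4, len(state.ov_dd))).copy()
        mi.sample_error_parameters(state, 600, proposal_width=0.8, seed=3)
        rel = mi.relative_error_per_gaussian(state)
        # compare tail-adjacent data components with core components of the
        # same chain far from the tail
        assert np.median(rel[tail_comp]) > 2 * np.median(rel[~tail_comp])


class TestToySampler:
    def _two_conformer_setup(self, small_spec, small_filament):
        model = small_filament
        chain = model.chains[1]
        n_tail = len(small_spec.tail_residues)
        A = np.tile([-60.0, -40.0], (n_tail, 1))[None]
        B = np.tile([-150.0, 150.0], (n_tail, 1))[None]
        mask = synth.tail_atom_mask(model, small_spec, chain) & \
            (model.elements != "H")

        def coords_for(t):
            c = model.coords.copy()
            mm = synth.tail_atom_mask(model, small_spec, chain)
            c[mm] = tail_coords_from_torsions(model, chain, t[0])
            return c

        ca, cb = coords_for(A), coords_for(B)
        ga = mi.model_to_gmm(model.with_coords(ca).select(mask))
        gb = mi.model_to_gmm(model.with_coords(cb).select(mask))
        data = GaussianMixture.concatenate([ga.scaled(0.7), gb.scaled(0.3)])
        return model, chain, A, B, mask, ca, cb, data

    def test_prior_recovery_without_restraint(self, small_spec, small_filament):
        """With the restraint off, the sampled torsion marginal matches the
        (harmonic) prior distribution."""
        from scipy import stats

        model = small_filament
        chain = model.chains[1]
        n_tail = len(small_spec.tail_residues)
        base = np.array([synth.COIL_PHI, synth.COIL_PSI])
        sd = 25.0

        def prior(tors):
            return float(np.sum((tors - base) ** 2) / (2 * sd ** 2))

        res = mi.run_toy_metainference(
            prior, mi.model_to_gmm(model), 2, 3000, model, seed=0,
            chains=[chain], move_deg=25.0, restraint=False,
            burn_in=0.3, thin=10)
        # decorrelate: one torsion coordinate, widely spaced frames
        phis = res.torsion_samples[::4, 0, 0, 0]
        z = (phis - base[0]) / sd
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_posterior_map_beats_prior_map(self, small_spec, small_filament):
        model, chain, A, B, mask, ca, cb, data = \
            self._two_conformer_setup(small_spec, small_filament)
        grid = grid_for_support(data, 0.1)
        data_map = render_map_from_gmm(data, like=grid)

        def ens_map(result):
            gs = [mi.model_to_gmm(result.ensemble.frame(i).select(mask)).scaled(
                1.0 / result.ensemble.n_frames)
                for i in range(result.ensemble.n_frames)]
            return render_map_from_gmm(GaussianMixture.concatenate(gs), like=grid)

        kw = dict(chains=[chain], move_deg=12.0,
                  reference_conformers=np.concatenate([A[None], B[None]]),
                  reflect_prob=0.25, burn_in=0.3, thin=4)
        post = mi.run_toy_metainference(None, data, 4, 200, small_filament,
                                        seed=5, sigma_b_frac=0.2, **kw)
        prior = mi.run_toy_metainference(None, data, 4, 200, small_filament,
                                         seed=5, restraint=False, **kw)
        cc_post = real_space_correlation(ens_map(post), data_map)
        cc_prior = real_space_correlation(ens_map(prior), data_map)
        assert cc_post > cc_prior

    def test_stronger_restraint_not_worse(self, small_spec, small_filament):
        """Tighter σ bounds give map correlation ≥ looser bounds (allow one
        violation over three seeds)."""
        model, chain, A, B, mask, ca, cb, data = \
            self._two_conformer_setup(small_spec, small_filament)
        grid = grid_for_support(data, 0.12)
        data_map = render_map_from_gmm(data, like=grid)

        def cc_for(seed, bounds):
            res = mi.run_toy_metainference(
                None, data, 4, 150, small_filament, seed=seed, chains=[chain],
                move_deg=12.0, reference_conformers=np.concatenate([A[None], B[None]]),
                reflect_prob=0.25, sigma_b_frac=0.2, sigma_bounds=bounds,
                burn_in=0.3, thin=4)
            gs = [mi.model_to_gmm(res.ensemble.frame(i).select(mask)).scaled(
                1.0 / res.ensemble.n_frames)
                for i in range(res.ensemble.n_frames)]
            return real_space_correlation(
                render_map_from_gmm(GaussianMixture.concatenate(gs), like=grid),
                data_map)

        violations = 0
        for seed in (1, 2, 3):
            strong = cc_for(seed, (1e-4, 0.3))
            weak = cc_for(seed, (3.0, 1e2))
            if strong < weak:
                violations += 1
        assert violations <= 1
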