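"""Structural analyses: contact criteria, interaction typing, SASA against
point-sampling oracles, secondary structure on constructed geometries, and
solubility aggregation with planted shielding."""

import numpy as np
import pytest

from fuzzycoat import analysis as an
from fuzzycoat.model import AtomicModel, Ensemble
from fuzzycoat.synth import sample_tail_ensemble

from conftest import (as_ensemble, ideal_helix_model, point_model,
                      two_strand_model)


def residue_pair_model(d, res_names=("GLY", "GLY"), atom_names=("CA", "CA"),
                       elements=("C", "C")):
    return point_model([[0, 0, 0], [d, 0, 0]], chains=["A", "A"],
                       res_indices=[1, 2], res_names=list(res_names),
                       atom_names=list(atom_names), elements=list(elements))


class TestContactMap:
    def test_close_pair_probability_one(self):
        ens = as_ensemble(residue_pair_model(0.5))
        cm = an.contact_map(ens, chains=["A"])
        assert cm.probability(("A", 1), ("A", 2)) == 1.0

    def test_far_pair_probability_zero(self):
        ens = as_ensemble(residue_pair_model(1.5))
        cm = an.contact_map(ens, chains=["A"])
        assert cm.probability(("A", 1), ("A", 2)) == 0.0

    def test_symmetry_and_bounds(self, small_filament):
        ens = sample_tail_ensemble(small_filament, 6, seed=4)
        cm = an.contact_map(ens)
        np.testing.assert_allclose(cm.probabilities, cm.probabilities.T)
        assert np.all((cm.probabilities >= 0) & (cm.probabilities <= 1))

    def test_frame_weights_respected(self):
        close = residue_pair_model(0.5)
        far = close.with_coords(np.array([[0, 0, 0], [1.5, 0, 0.0]]))
        ens = Ensemble(close, np.stack([close.coords, far.coords]),
                       frame_weights=[0.25, 0.75])
        cm = an.contact_map(ens, chains=["A"])
        assert cm.probability(("A", 1), ("A", 2)) == pytest.approx(0.25)

    def test_single_residue_selection_rejected(self):
        m = point_model([[0, 0, 0]])
        with pytest.raises(ValueError):
            an.contact_map(as_ensemble(m), chains=["A"])


class TestClassifyContact:
    def _lys_glu(self, d):
        return point_model([[0, 0, 0], [d, 0, 0]], chains=["A", "A"],
                           res_indices=[1, 2], res_names=["LYS", "GLU"],
                           atom_names=["NZ", "OE1"], elements=["N", "O"])

    def test_salt_bridge_detected(self):
        types = an.classify_contact(self._lys_glu(0.30), ("A", 1), ("A", 2))
        assert "salt bridge" in types

    def test_salt_bridge_distance_limit(self):
        types = an.classify_contact(self._lys_glu(0.45), ("A", 1), ("A", 2))
        assert "salt bridge" not in types

    def test_hydrophobic_pair(self):
        m = point_model([[0, 0, 0], [0.40, 0, 0]], chains=["A", "A"],
                        res_indices=[1, 2], res_names=["LEU", "ILE"],
                        atom_names=["CD1", "CD1"], elements=["C", "C"])
        assert an.classify_contact(m, ("A", 1), ("A", 2)) == {"hydrophobic"}

    def test_hbond_rejected_beyond_cutoff(self):
        m = point_model([[0, 0, 0], [0.45, 0, 0]], chains=["A", "A"],
                        res_indices=[1, 2], res_names=["SER", "SER"],
                        atom_names=["OG", "OG"], elements=["O", "O"])
        assert "hydrogen bond" not in an.classify_contact(m, ("A", 1), ("A", 2))

    def test_hbond_within_cutoff(self):
        m = point_model([[0, 0, 0], [0.30, 0, 0]], chains=["A", "A"],
                        res_indices=[1, 2], res_names=["SER", "SER"],
                        atom_names=["OG", "OG"], elements=["O", "O"])
        assert "hydrogen bond" in an.classify_contact(m, ("A", 1), ("A", 2))

    def test_symmetric_under_relabeling(self):
        m = self._lys_glu(0.30)
        a = an.classify_contact(m, ("A", 1), ("A", 2))
        b = an.classify_contact(m, ("A", 2), ("A", 1))
        assert a == b

    def test_unknown_residue_named_in_error(self):
        m = point_model([[0, 0, 0], [0.3, 0, 0]], chains=["A", "A"],
                        res_indices=[1, 2], res_names=["XXX", "GLY"])
        with pytest.raises(ValueError, match="XXX"):
            an.classify_contact(m, ("A", 1), ("A", 2))


def brute_force_sasa(model, probe, n_points=100000, seed=0):
    """Independent dense-point oracle: uniformly random sphere points."""
    rng = np.random.default_rng(seed)
    radii = an._atom_radii(model) + probe
    areas = {}
    for i in range(model.n_atoms):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = model.coords[i] + radii[i] * v
        free = np.ones(n_points, dtype=bool)
        for j in range(model.n_atoms):
            if j == i:
                continue
            free &= np.linalg.norm(pts - model.coords[j], axis=1) >= radii[j]
        areas[i] = 4 * np.pi * radii[i] ** 2 * free.mean()
    return areas


class TestSASA:
    def test_isolated_atom_analytic_sphere(self):
        m = point_model([[0, 0, 0]], elements=["N"], atom_names=["N"])
        sasa = an.shrake_rupley_sasa(m, probe=0.34, n_points=960)
        r = an.VDW_RADII["N"] + 0.34
        assert abs(sasa[("A", 1)] - 4 * np.pi * r ** 2) / (4 * np.pi * r ** 2) < 0.01

    def test_caged_atom_zero(self):
        """An atom enclosed by a tight shell of neighbors is inaccessible."""
        from fuzzycoat.geometry import fibonacci_sphere
        shell = 0.25 * fibonacci_sphere(60)
        coords = np.vstack([[0, 0, 0], shell])
        m = point_model(coords, res_indices=[1] + [2] * 60)
        sasa = an.shrake_rupley_sasa(m, probe=0.14, n_points=240)
        per_atom_center = sasa[("A", 1)]
        assert per_atom_center == 0.0

    def test_random_cluster_matches_dense_oracle(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 0.6, (10, 3))
        m = point_model(coords, res_indices=np.arange(1, 11))
        sasa = an.shrake_rupley_sasa(m, probe=0.34, n_points=960)
        oracle = brute_force_sasa(m, probe=0.34, n_points=30000)
        total = sum(sasa.values())
        total_oracle = sum(oracle.values())
        assert abs(total - total_oracle) / total_oracle < 0.02

    def test_adding_atom_never_increases_sasa(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 0.5, (6, 3))
        m6 = point_model(coords, res_indices=np.arange(1, 7))
        m7 = point_model(np.vstack([coords, [[0.25, 0.25, 0.25]]]),
                         res_indices=np.arange(1, 8))
        s6 = an.shrake_rupley_sasa(m6, n_points=480)
        s7 = an.shrake_rupley_sasa(m7, n_points=480)
        for r in s6:
            assert s7[r] <= s6[r] + 1e-12


class TestShielding:
    def test_distant_removal_no_effect(self):
        coords = np.vstack([np.arange(5)[:, None] * [0.4, 0, 0],
                            [[50.0, 0, 0]]])
        m = point_model(coords, res_indices=[1, 2, 3, 4, 5, 6])
        ens = as_ensemble(m)
        delta = an.sasa_shielding(ens, [("A", 6)], n_points=240, chains=["A"])
        for r, v in delta.items():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_delta_nonnegative(self, small_filament, small_spec):
        ens = sample_tail_ensemble(small_filament, 3, seed=9)
        delta = an.sasa_shielding(ens, small_spec.tail_residues, n_points=96)
        assert all(v >= -1e-10 for v in delta.values())

    def test_planted_cover_has_largest_delta(self):
        """A cap of atoms directly over one residue shields it the most."""
        row = np.arange(7)[:, None] * [0.5, 0, 0]
        cap_center = row[3] + [0, 0, 0.45]
        cap = cap_center + 0.15 * np.array([[0, 0, 0], [1, 0, 0], [-1, 0, 0],
                                            [0, 1, 0], [0, -1, 0]])
        coords = np.vstack([row, cap])
        m = point_model(coords, res_indices=[1, 2, 3, 4, 5, 6, 7] + [8] * 5)
        delta = an.sasa_shielding(as_ensemble(m), [("A", 8)], n_points=480,
                                  chains=["A"])
        best = max(delta, key=delta.get)
        assert best == ("A", 4)
        assert delta[("A", 4)] > 0


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helix(self):
        ens = as_ensemble(ideal_helix_model(12))
        ss = an.assign_secondary_structure(ens, chains=["A"])
        for i in range(4, 9):
            assert ss[("A", i)]["helix"] == 1.0

    def test_parallel_strands_in_register_are_strand(self):
        ens = as_ensemble(two_strand_model())
        ss = an.assign_secondary_structure(ens, chains=["A", "B"])
        for ch in "AB":
            for i in range(4, 8):
                assert ss[(ch, i)]["strand"] == 1.0

    def test_isolated_extended_chain_is_coil(self):
        ens = as_ensemble(two_strand_model(offset=(0, 0, 50.0)))
        ss = an.assign_secondary_structure(ens, chains=["A"])
        assert all(v["coil"] == 1.0 for v in ss.values())

    def test_populations_sum_to_one(self, small_filament):
        ens = sample_tail_ensemble(small_filament, 4, seed=5)
        ss = an.assign_secondary_structure(ens)
        for v in ss.values():
            assert v["helix"] + v["strand"] + v["coil"] == pytest.approx(1.0)


class TestSolubility:
    def test_constant_scorer(self, small_filament):
        ens = sample_tail_ensemble(small_filament, 6, seed=2)

        def scorer(model):
            return {r: 2.5 for r in model.residues()}

        out = an.aggregate_solubility(ens, per_residue_scorer=scorer,
                                      n_conformations=4, seed=0)
        assert out.core_mean_with == pytest.approx(2.5)
        assert out.core_mean_without == pytest.approx(2.5)
        assert out.core_sd_with == pytest.approx(0.0)

    def test_too_many_conformations_rejected(self, small_filament):
        ens = sample_tail_ensemble(small_filament, 3, seed=2)
        with pytest.raises(ValueError):
            an.aggregate_solubility(ens, n_conformations=10, seed=0)

    def test_coat_shielding_raises_core_score(self, small_filament):
        """Burial by the fuzzy coat pulls hydrophobic penalties toward zero,
        so the with-coat core average exceeds the without-coat one."""
        ens = sample_tail_ensemble(small_filament, 8, seed=3)
        out = an.aggregate_solubility(ens, n_conformations=6, seed=1)
        assert out.core_mean_with > out.core_mean_without
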