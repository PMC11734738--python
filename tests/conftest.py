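import numpy as np
import pytest

from fuzzycoat import geometry as geo
from fuzzycoat.model import AtomicModel, Ensemble
from fuzzycoat.synth import ToyFilamentSpec, build_toy_filament

SMALL_SEQUENCE = "DAEFLVFFAEDVGS"   # 4-residue tail + 10-residue core


@pytest.fixture(scope="session")
def small_spec():
    return ToyFilamentSpec(n_chains_per_protofilament=3, n_protofilaments=1,
                           core_range=(5, 14), tail_range=(1, 4),
                           sequence=SMALL_SEQUENCE, seed=3, tail_flexibility=0.5)


@pytest.fixture(scope="session")
def small_filament(small_spec):
    return build_toy_filament(small_spec)


def backbone_model(phi_psi_list, chain="A", resname="ALA", shift=(0, 0, 0)):
    """Backbone-only model from a list of (phi, psi) pairs (degrees)."""
    bb = geo.build_backbone(np.asarray(phi_psi_list, dtype=float))
    return _from_backbones([(chain, bb, np.asarray(shift, dtype=float))],
                           resname=resname)


def _from_backbones(entries, resname="ALA"):
    recs = {k: [] for k in ("c", "ri", "rn", "an", "el", "xyz")}
    for chain, bb, shift in entries:
        n = len(bb["N"])
        for i in range(n):
            for a, e in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                recs["c"].append(chain)
                recs["ri"].append(i + 1)
                recs["rn"].append(resname)
                recs["an"].append(a)
                recs["el"].append(e)
                recs["xyz"].append(bb[a][i] + shift)
    return AtomicModel(np.array(recs["c"]), np.array(recs["ri"], dtype=int),
                       np.array(recs["rn"]), np.array(recs["an"]),
                       np.array(recs["el"]), np.array(recs["xyz"]))


def two_strand_model(offset=(0.0, 0.0, 0.48), n_res=8):
    """Two in-register parallel β strands separated by the cross-β rise."""
    pp = np.tile([-119.0, 113.0], (n_res, 1))
    bb = geo.build_backbone(pp)
    return _from_backbones([("A", bb, np.zeros(3)),
                            ("B", bb, np.asarray(offset, dtype=float))])


def ideal_helix_model(n_res=12):
    return backbone_model(np.tile([-57.0, -47.0], (n_res, 1)))


def point_model(coords, chains=None, res_indices=None, res_names=None,
                atom_names=None, elements=None):
    """Free-form small model for contact/SASA fixtures."""
    coords = np.atleast_2d(coords)
    n = len(coords)
    chains = np.array(chains if chains is not None else ["A"] * n)
    res_indices = np.array(res_indices if res_indices is not None
                           else np.arange(1, n + 1), dtype=int)
    res_names = np.array(res_names if res_names is not None else ["GLY"] * n)
    atom_names = np.array(atom_names if atom_names is not None else ["CA"] * n)
    elements = np.array(elements if elements is not None else ["C"] * n)
    return AtomicModel(chains, res_indices, res_names, atom_names, elements,
                       coords)


def as_ensemble(model):
    return Ensemble(model, model.coords[None])
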