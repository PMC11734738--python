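"""Atomic models and conformational ensembles.

An :class:`AtomicModel` is a flat, array-backed record of atoms (chain id,
residue index/name, atom name, element, nm coordinates, occupancy-like
weight). An :class:`Ensemble` is an ordered set of conformations sharing one
topology, stored as a single (n_frames, n_atoms, 3) coordinate array with
per-frame weights. Multi-model PDB is the on-disk interchange format
(coordinates converted nm ↔ Å at the boundary); reading goes through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# monoisotopic-ish masses (Da) and atomic numbers for the elements the toy
# models use; SC is the coarse side-chain pseudo-atom (carbon-like)
ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                "S": 32.06, "P": 30.974, "NA": 22.990}
ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "NA": 11}


@dataclass
class AtomicModel:
    """Array-backed atomic structure; one entry per atom."""

    chain_ids: np.ndarray          # (n,) str
    res_indices: np.ndarray        # (n,) int, 1-based within chain
    res_names: np.ndarray          # (n,) str, 3-letter codes
    atom_names: np.ndarray         # (n,) str
    elements: np.ndarray           # (n,) str
    coords: np.ndarray             # (n, 3) float, nm
    weights: np.ndarray = None     # (n,) float, occupancy-like

    def __post_init__(self):
        n = len(self.coords)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        for name in ("chain_ids", "res_indices", "res_names", "atom_names", "elements"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen, out = set(), []
        for c in self.chain_ids:
            if c not in seen:
                seen.add(c)
                out.append(str(c))
        return out

    def masses(self) -> np.ndarray:
        return np.array([ELEMENT_MASS.get(str(e).upper(), 12.011) for e in self.elements])

    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER.get(str(e).upper(), 6) for e in self.elements], dtype=float)

    def select(self, mask: np.ndarray) -> "AtomicModel":
        mask = np.asarray(mask)
        return AtomicModel(self.chain_ids[mask], self.res_indices[mask],
                           self.res_names[mask], self.atom_names[mask],
                           self.elements[mask], self.coords[mask], self.weights[mask])

    def atom_mask(self, chain: str | None = None, res_index: int | None = None,
                  atom_name: str | None = None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= self.chain_ids == chain
        if res_index is not None:
            m &= self.res_indices == res_index
        if atom_name is not None:
            m &= self.atom_names == atom_name
        return m

    def residues(self, chain: str | None = None) -> list[tuple[str, int]]:
        """(chain, res_index) pairs in atom order."""
        out, seen = [], set()
        for c, r in zip(self.chain_ids, self.res_indices):
            if chain is not None and c != chain:
                continue
            key = (str(c), int(r))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def residue_com(self, chain: str, res_index: int,
                    heavy_only: bool = True) -> np.ndarray:
        """Mass-weighted center of a residue's (heavy) atoms."""
        m = self.atom_mask(chain=chain, res_index=res_index)
        if heavy_only:
            m &= self.elements != "H"
        if not m.any():
            raise ValueError(f"no atoms for residue {chain}:{res_index}")
        w = self.masses()[m]
        return np.average(self.coords[m], axis=0, weights=w)

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        return AtomicModel(self.chain_ids, self.res_indices, self.res_names,
                           self.atom_names, self.elements, np.array(coords),
                           self.weights)

    def copy(self) -> "AtomicModel":
        return self.with_coords(self.coords.copy())


@dataclass
class Ensemble:
    """Conformations sharing one topology, with normalizable frame weights."""

    topology: AtomicModel
    coords: np.ndarray                 # (n_frames, n_atoms, 3) nm
    frame_weights: np.ndarray = None   # (n_frames,)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame/topology atom-count mismatch")
        if self.frame_weights is None:
            self.frame_weights = np.ones(self.coords.shape[0])
        self.frame_weights = np.asarray(self.frame_weights, dtype=float)
        if np.any(self.frame_weights < 0):
            raise ValueError("negative frame weights")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def normalized_weights(self) -> np.ndarray:
        w = self.frame_weights
        return w / w.sum()

    def frame(self, i: int) -> AtomicModel:
        return self.topology.with_coords(self.coords[i])

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_models(cls, models: list[AtomicModel], weights=None) -> "Ensemble":
        coords = np.stack([m.coords for m in models])
        return cls(models[0], coords, weights)


# ---------------------------------------------------------------------------
# PDB I/O

_PDB_ATOM = ("ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
             "{resi:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {elem:>2s}\n")


def _pdb_atom_name(name: str) -> str:
    # PDB column convention: 1-letter element names start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(path, model_or_ensemble, *, b_factors=None) -> None:
    """Write a model or ensemble as (multi-model) PDB, nm → Å."""
    if isinstance(model_or_ensemble, AtomicModel):
        ens = Ensemble(model_or_ensemble, model_or_ensemble.coords[None])
    else:
        ens = model_or_ensemble
    top = ens.topology
    with open(path, "w") as fh:
        for fi in range(ens.n_frames):
            if ens.n_frames > 1:
                fh.write(f"MODEL     {fi + 1:>4d}\n")
            xyz = ens.coords[fi] * 10.0  # nm -> Å
            serial = 0
            prev_chain = None
            for a in range(top.n_atoms):
                serial += 1
                ch = str(top.chain_ids[a])
                if prev_chain is not None and ch != prev_chain:
                    fh.write("TER\n")
                prev_chain = ch
                b = 0.0 if b_factors is None else float(b_factors[a])
                fh.write(_PDB_ATOM.format(
                    serial=min(serial, 99999), name=_pdb_atom_name(str(top.atom_names[a])),
                    alt=" ", res=str(top.res_names[a])[:3], chain=ch[:1],
                    resi=int(top.res_indices[a]), icode=" ",
                    x=xyz[a, 0], y=xyz[a, 1], z=xyz[a, 2],
                    occ=float(top.weights[a]), b=b, elem=str(top.elements[a])[:2]))
            fh.write("TER\n")
            if ens.n_frames > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path) -> Ensemble:
    """Read a (multi-model) PDB into an Ensemble, Å → nm (via gemmi)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    frames = []
    topo = None
    for mdl in st:
        chain_ids, res_idx, res_names, atom_names, elements, coords, occ = \
            [], [], [], [], [], [], []
        for chain in mdl:
            for res in chain:
                for atom in res:
                    chain_ids.append(chain.name)
                    res_idx.append(res.seqid.num)
                    res_names.append(res.name)
                    atom_names.append(atom.name)
                    elements.append(atom.element.name.upper())
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    occ.append(atom.occ)
        m = AtomicModel(np.array(chain_ids), np.array(res_idx, dtype=int),
                        np.array(res_names), np.array(atom_names),
                        np.array(elements), np.array(coords) / 10.0,
                        np.array(occ))
        if topo is None:
            topo = m
        frames.append(m.coords)
    if topo is None:
        raise ValueError(f"no models in {path}")
    return Ensemble(topo, np.stack(frames))
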