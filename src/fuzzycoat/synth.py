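"""Synthetic filaments, ensembles, density maps and solvent trajectories.

The toy filament emulates the architecture of an amyloid fibril with a
disordered fuzzy coat: each protofilament is a stack of identical chains
whose ordered cross-β core is an idealized extended backbone replicated
along the fibril axis with a fixed axial rise (default 0.48 nm, the
canonical cross-β stacking distance), while the terminal tail residues are
grown as self-avoiding random coils, independently per chain. Side chains
are coarse-grained to one pseudo-atom ("SC") per residue along the Cα–Cβ
direction, with residue-specific offset and radius — enough geometry for
contact, SASA and density-map work without rotamer libraries.

Every generator is a pure function of its arguments and seed; all lengths
are nm, times ps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .maps import DensityMap
from .model import ATOMIC_NUMBER, AtomicModel, Ensemble
from .solvent import CylinderRegion, SolventTrajectory

AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

# coarse side chain: (offset of pseudo-atom from CA along the Cβ direction,
# pseudo-atom radius, nominal element for contact chemistry), nm
SIDE_CHAIN = {
    "ALA": (0.153, 0.19, "C"), "ARG": (0.410, 0.29, "N"),
    "ASN": (0.250, 0.24, "C"), "ASP": (0.250, 0.24, "O"),
    "CYS": (0.210, 0.22, "S"), "GLN": (0.310, 0.26, "C"),
    "GLU": (0.310, 0.26, "O"), "HIS": (0.310, 0.27, "C"),
    "ILE": (0.230, 0.25, "C"), "LEU": (0.260, 0.25, "C"),
    "LYS": (0.350, 0.27, "N"), "MET": (0.290, 0.26, "S"),
    "PHE": (0.340, 0.28, "C"), "PRO": (0.190, 0.23, "C"),
    "SER": (0.190, 0.21, "O"), "THR": (0.190, 0.23, "C"),
    "TRP": (0.390, 0.30, "C"), "TYR": (0.380, 0.29, "C"),
    "VAL": (0.200, 0.23, "C"),
}

# formal side-chain charges near neutral pH
RESIDUE_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": 0}

KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}

# idealized torsions, degrees
CORE_PHI, CORE_PSI = -119.0, 113.0       # parallel-β backbone template
COIL_PHI, COIL_PSI = -100.0, 120.0       # coil base for tails
CLASH_DISTANCE = 0.20                    # nm, backbone self-avoidance
TAIL_ATTEMPTS = 30                       # retry budget per tail residue


class InvalidSpecError(ValueError):
    pass


@dataclass
class ToyFilamentSpec:
    """Geometry and composition of a toy two-region filament."""

    n_chains_per_protofilament: int = 6
    n_protofilaments: int = 2
    core_range: tuple[int, int] = (9, 42)    # 1-based inclusive
    tail_range: tuple[int, int] = (1, 8)
    axial_rise: float = 0.48                 # nm between stacked chains
    sequence: str = AB42_SEQUENCE
    tail_flexibility: float = 0.5            # rad, torsion jitter SD
    seed: int = 0

    def __post_init__(self):
        if self.n_chains_per_protofilament < 1:
            raise InvalidSpecError("need at least one chain per protofilament")
        if self.n_protofilaments not in (1, 2):
            raise InvalidSpecError("n_protofilaments must be 1 or 2")
        if self.axial_rise <= 0:
            raise InvalidSpecError("axial_rise must be positive")
        c = set(range(self.core_range[0], self.core_range[1] + 1))
        t = set(range(self.tail_range[0], self.tail_range[1] + 1))
        if c & t:
            raise InvalidSpecError("core_range and tail_range overlap")
        if c | t != set(range(1, len(self.sequence) + 1)):
            raise InvalidSpecError(
                "core_range and tail_range must cover the sequence exactly")
        for aa in self.sequence:
            if aa not in AA_1TO3:
                raise InvalidSpecError(f"unknown residue code {aa!r}")

    @property
    def n_chains(self) -> int:
        return self.n_chains_per_protofilament * self.n_protofilaments

    @property
    def core_residues(self) -> list[int]:
        return list(range(self.core_range[0], self.core_range[1] + 1))

    @property
    def tail_residues(self) -> list[int]:
        return list(range(self.tail_range[0], self.tail_range[1] + 1))

    def resname(self, idx: int) -> str:
        return AA_1TO3[self.sequence[idx - 1]]


# ---------------------------------------------------------------------------
# charge bookkeeping

def formal_charge(sequence: str, ph: float = 7.0) -> int:
    """Integer formal charge of one chain: side chains (Asp/Glu −1,
    Lys/Arg +1, His neutral above pH 6) plus the zwitterionic termini,
    which cancel."""
    q = 0
    for aa in sequence:
        res = AA_1TO3[aa]
        dq = RESIDUE_CHARGE.get(res, 0)
        if res == "HIS" and ph < 6.0:
            dq = +1
        if res in ("ASP", "GLU") and ph < 3.0:
            dq = 0
        if res in ("LYS", "ARG") and ph > 11.0:
            dq = 0
        q += dq
    return q  # N-terminal +1 and C-terminal -1 cancel


def counterions_to_neutralize(sequence: str, n_chains: int,
                              ph: float = 7.0) -> tuple[int, int]:
    """(number of monovalent counterions, their charge sign) that
    neutralize n_chains copies of the sequence."""
    total = formal_charge(sequence, ph) * n_chains
    if total == 0:
        return 0, 0
    return abs(total), (1 if total < 0 else -1)


# ---------------------------------------------------------------------------
# filament construction

def _chain_rng_seed(seed: int, chain_index: int, frame: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, chain_index, frame])
    return np.random.default_rng(ss)


def _assemble_residue(resname: str, backbone: dict, i: int):
    """Atom records for one residue from backbone arrays at row i."""
    names, elements, coords = ["N", "CA", "C", "O"], ["N", "C", "C", "O"], \
        [backbone["N"][i], backbone["CA"][i], backbone["C"][i], backbone["O"][i]]
    if resname in SIDE_CHAIN:
        offset, _, elem = SIDE_CHAIN[resname]
        cb = geo.place_cb(backbone["N"][i], backbone["CA"][i], backbone["C"][i])
        direction = (cb - backbone["CA"][i])
        direction /= np.linalg.norm(direction)
        names.append("SC")
        elements.append(elem)
        coords.append(backbone["CA"][i] + offset * direction)
    return names, elements, coords


def side_chain_radius(resname: str) -> float:
    return SIDE_CHAIN.get(resname, (0.0, 0.19, "C"))[1]


def _core_template(spec: ToyFilamentSpec) -> dict:
    n_core = len(spec.core_residues)
    phi_psi = np.tile([CORE_PHI, CORE_PSI], (n_core, 1))
    return geo.build_backbone(phi_psi)


def _sample_tail_torsions(rng, n, flexibility_rad):
    jitter_deg = np.degrees(flexibility_rad)
    phis = COIL_PHI + rng.normal(0.0, jitter_deg, n)
    psis = COIL_PSI + rng.normal(0.0, jitter_deg, n)
    return np.column_stack([phis, psis])


def _build_tail(spec: ToyFilamentSpec, anchor: dict, rng,
                fixed_coords: np.ndarray | None,
                flexibility: float | None = None) -> dict:
    """Self-avoiding coil for the tail of one chain, grown residue by
    residue off the core anchor; clashing residues are re-drawn up to a
    fixed attempt budget, then accepted."""
    flex = spec.tail_flexibility if flexibility is None else flexibility
    n_tail = len(spec.tail_residues)
    n_term = spec.tail_range[1] < spec.core_range[0]
    from scipy.spatial import cKDTree
    tree = cKDTree(fixed_coords) if fixed_coords is not None and len(fixed_coords) else None
    rows = {k: [] for k in ("N", "CA", "C", "O")}
    placed = []

    def clashes(coords):
        pts = np.asarray(coords)
        if tree is not None:
            d, _ = tree.query(pts, k=1, distance_upper_bound=CLASH_DISTANCE)
            if np.any(np.isfinite(d)):
                return True
        if placed:
            prev = np.concatenate(placed[:-1]) if len(placed) > 1 else None
            if prev is not None:
                dmin = np.min(np.linalg.norm(
                    pts[:, None, :] - prev[None, :, :], axis=2))
                if dmin < CLASH_DISTANCE:
                    return True
        return False

    if n_term:
        nxt = (anchor["N"], anchor["CA"], anchor["C"])
        phi_next = CORE_PHI
        for k in range(n_tail):           # grown outward from the core
            for attempt in range(TAIL_ATTEMPTS):
                tors = _sample_tail_torsions(rng, 1, flex)
                bb = geo.extend_backbone_reverse(tors, phi_next, *nxt)
                coords = np.concatenate([bb[a] for a in ("N", "CA", "C", "O")])
                if flex == 0.0 or not clashes(coords):
                    break
            placed.append(coords)
            for a in rows:
                rows[a].append(bb[a][0])
            nxt = (bb["N"][0], bb["CA"][0], bb["C"][0])
            phi_next = tors[0, 0]
        for a in rows:                    # chain order: most N-terminal first
            rows[a] = np.array(rows[a][::-1])
    else:
        prev = (anchor["N"], anchor["CA"], anchor["C"])
        psi_prev = CORE_PSI
        for k in range(n_tail):
            for attempt in range(TAIL_ATTEMPTS):
                tors = _sample_tail_torsions(rng, 1, flex)
                bb = geo.extend_backbone_forward(tors, psi_prev, *prev)
                coords = np.concatenate([bb[a] for a in ("N", "CA", "C", "O")])
                if flex == 0.0 or not clashes(coords):
                    break
            placed.append(coords)
            for a in rows:
                rows[a].append(bb[a][0])
            prev = (bb["N"][0], bb["CA"][0], bb["C"][0])
            psi_prev = tors[0, 1]
        for a in rows:
            rows[a] = np.array(rows[a])
    return rows


def _chain_ids(n: int) -> list[str]:
    import string
    letters = string.ascii_uppercase + string.ascii_lowercase + string.digits
    return [letters[i % len(letters)] for i in range(n)]


def build_toy_filament(spec: ToyFilamentSpec) -> AtomicModel:
    """Assemble the filament: exact axial stacking of the core template,
    independently sampled tails. The returned model carries the spec as
    ``model.filament_spec``."""
    core_bb = _core_template(spec)
    core_extent = core_bb["CA"][:, 1].max() - core_bb["CA"][:, 1].min() + 1.2
    transforms = [(np.eye(3), np.zeros(3))]
    if spec.n_protofilaments == 2:
        transforms.append((geo.rotation_about_axis([0, 0, 1.0], np.pi),
                           np.array([0.0, core_extent, 0.0])))

    # fixed (core) atom coordinates of every chain, for tail clash checks
    all_core_coords = []
    chain_cores = []
    for p, (R, t) in enumerate(transforms):
        for k in range(spec.n_chains_per_protofilament):
            shift = t + np.array([0.0, 0.0, k * spec.axial_rise])
            bb = {a: core_bb[a] @ R.T + shift for a in core_bb}
            chain_cores.append(bb)
            all_core_coords.append(np.concatenate([bb[a] for a in bb]))
    fixed = np.concatenate(all_core_coords)

    ids = _chain_ids(spec.n_chains)
    recs = {k: [] for k in ("chain", "ridx", "rname", "aname", "elem", "xyz")}
    for ci in range(spec.n_chains):
        rng = _chain_rng_seed(spec.seed, ci)
        bb_core = chain_cores[ci]
        anchor_row = 0 if spec.tail_range[1] < spec.core_range[0] else -1
        anchor = {a: bb_core[a][anchor_row] for a in ("N", "CA", "C")}
        bb_tail = _build_tail(spec, anchor, rng, fixed)
        _append_chain(spec, ids[ci], bb_core, bb_tail, recs)
    model = AtomicModel(np.array(recs["chain"]), np.array(recs["ridx"], dtype=int),
                        np.array(recs["rname"]), np.array(recs["aname"]),
                        np.array(recs["elem"]), np.array(recs["xyz"]))
    model.filament_spec = spec
    return model


def _append_chain(spec, chain_id, bb_core, bb_tail, recs):
    tail_first = spec.tail_range[1] < spec.core_range[0]
    segments = ([(spec.tail_residues, bb_tail), (spec.core_residues, bb_core)]
                if tail_first else
                [(spec.core_residues, bb_core), (spec.tail_residues, bb_tail)])
    for residues, bb in segments:
        for i, ridx in enumerate(residues):
            rname = spec.resname(ridx)
            names, elems, coords = _assemble_residue(rname, bb, i)
            for nm, el, xyz in zip(names, elems, coords):
                recs["chain"].append(chain_id)
                recs["ridx"].append(ridx)
                recs["rname"].append(rname)
                recs["aname"].append(nm)
                recs["elem"].append(el)
                recs["xyz"].append(xyz)


# ---------------------------------------------------------------------------
# tail ensembles with planted contacts

class PlantingError(RuntimeError):
    pass


def tail_atom_mask(model: AtomicModel, spec: ToyFilamentSpec | None = None,
                   chain: str | None = None) -> np.ndarray:
    """Boolean mask over the model's atoms selecting the fuzzy-coat (tail)
    residues, optionally restricted to one chain."""
    if spec is None:
        spec = model.filament_spec
    in_tail = np.isin(model.res_indices,
                      np.array(spec.tail_residues, dtype=model.res_indices.dtype))
    if chain is not None:
        in_tail &= model.chain_ids == chain
    return in_tail


_tail_atom_mask = tail_atom_mask


def _residue_com_from(coords, masses, idx):
    return np.average(coords[idx], axis=0, weights=masses[idx])


def sample_tail_ensemble(model: AtomicModel, n_frames: int,
                         tail_flexibility: float | None = None,
                         planted_contacts: list | None = None,
                         seed: int = 0, chains: list[str] | None = None,
                         contact_cutoff: float = 1.0,
                         max_attempts: int = 2000) -> Ensemble:
    """Ensemble with fixed core and per-frame resampled tails.

    ``planted_contacts`` entries are (tail_res, core_res, probability) —
    optionally (chain, tail_res, core_res, probability): for each frame the
    desired contact indicator is drawn Bernoulli(probability) and the tail is
    rejection-sampled until the residue-COM distance criterion (< 1 nm by
    default) matches, giving exact Bernoulli marginals. Contacts pair a
    chain's own tail with its own core; by default they are planted on the
    central chain.
    """
    spec: ToyFilamentSpec = model.filament_spec
    if chains is None:
        chains = model.chains
    flex = spec.tail_flexibility if tail_flexibility is None else tail_flexibility
    all_chains = model.chains
    central = all_chains[(len(all_chains) + 1) // 2 - 1]

    plants: dict[str, list[tuple[int, int, float]]] = {}
    core_set = set(spec.core_residues)
    tail_set = set(spec.tail_residues)
    for entry in planted_contacts or []:
        if len(entry) == 4:
            ch, tr, cr, p = entry
        else:
            tr, cr, p = entry
            ch = central
        if tr in core_set and cr in core_set:
            raise ValueError(f"planted contact ({tr},{cr}) joins two core residues")
        if tr not in tail_set:
            raise ValueError(f"planted residue {tr} is not in the tail range")
        if not 0.0 <= p <= 1.0:
            raise ValueError("planted probability outside [0, 1]")
        plants.setdefault(ch, []).append((tr, cr, float(p)))
        if ch not in chains:
            chains = list(chains) + [ch]

    masses = model.masses()
    coords0 = model.coords
    # per-chain bookkeeping
    per_chain = {}
    for ch in chains:
        mask = _tail_atom_mask(model, spec, ch)
        anchor_row = 0 if spec.tail_range[1] < spec.core_range[0] else -1
        core_mask = (model.chain_ids == ch) & ~mask
        anchor = {
            a: coords0[model.atom_mask(chain=ch,
                                       res_index=(spec.core_residues[anchor_row]),
                                       atom_name=a)][0]
            for a in ("N", "CA", "C")}
        core_coms = {r: model.residue_com(ch, r) for r in spec.core_residues}
        per_chain[ch] = (mask, anchor, core_coms, np.nonzero(core_mask)[0])

    frames = np.repeat(coords0[None], n_frames, axis=0)
    for fi in range(n_frames):
        for ci, ch in enumerate(chains):
            mask, anchor, core_coms, core_idx = per_chain[ch]
            rng = _chain_rng_seed(seed, all_chains.index(ch), fi + 1)
            targets = plants.get(ch, [])
            want = [rng.random() < p for (_, _, p) in targets]
            for attempt in range(max_attempts if targets else 1):
                tail_coords = _tail_coords_once(model, spec, ch, anchor, rng,
                                                fixed=coords0[core_idx], flex=flex)
                if not targets or flex == 0.0:
                    break
                ok = True
                for (tr, cr, _), w in zip(targets, want):
                    com = _tail_residue_com(model, spec, ch, tr, tail_coords, masses)
                    hit = np.linalg.norm(com - core_coms[cr]) < contact_cutoff
                    if hit != w:
                        ok = False
                        break
                if ok:
                    break
            else:
                raise PlantingError(
                    f"could not realize planted contacts on chain {ch} "
                    f"within {max_attempts} attempts (frame {fi})")
            frames[fi][mask] = tail_coords
    return Ensemble(model, frames)


def _tail_coords_once(model, spec, chain, anchor, rng, fixed, flex):
    bb = _build_tail(spec, anchor, rng, fixed, flexibility=flex)
    coords = []
    for i, ridx in enumerate(spec.tail_residues):
        rname = spec.resname(ridx)
        _, _, xyz = _assemble_residue(rname, bb, i)
        coords.extend(xyz)
    return np.array(coords)


def _tail_residue_com(model, spec, chain, res, tail_coords, masses):
    mask = _tail_atom_mask(model, spec, chain)
    sub_res = model.res_indices[mask]
    sub_mass = masses[mask]
    sel = sub_res == res
    return np.average(tail_coords[sel], axis=0, weights=sub_mass[sel])


def tail_coords_from_torsions(model: AtomicModel, chain: str,
                              torsions: np.ndarray) -> np.ndarray:
    """Deterministic tail coordinates for one chain from (n_tail, 2) phi/psi
    torsions in degrees, grown off the chain's core anchor residue. Atom
    order matches the model's tail atoms for that chain."""
    spec: ToyFilamentSpec = model.filament_spec
    torsions = np.asarray(torsions, dtype=float).reshape(-1, 2)
    n_term = spec.tail_range[1] < spec.core_range[0]
    anchor_res = spec.core_residues[0] if n_term else spec.core_residues[-1]
    anchor = {a: model.coords[model.atom_mask(chain=chain, res_index=anchor_res,
                                              atom_name=a)][0]
              for a in ("N", "CA", "C")}
    if n_term:
        bb = geo.extend_backbone_reverse(torsions, CORE_PHI,
                                         anchor["N"], anchor["CA"], anchor["C"])
    else:
        bb = geo.extend_backbone_forward(torsions, CORE_PSI,
                                         anchor["N"], anchor["CA"], anchor["C"])
    coords = []
    for i, ridx in enumerate(spec.tail_residues):
        _, _, xyz = _assemble_residue(spec.resname(ridx), bb, i)
        coords.extend(xyz)
    return np.array(coords)


# ---------------------------------------------------------------------------
# synthetic density maps

def render_synthetic_map(model_or_ensemble, voxel_size: float,
                         resolution_sigma: float, noise_sd: float = 0.0,
                         seed: int = 0, like: DensityMap | None = None,
                         truncation_sigma: float = 6.0) -> DensityMap:
    """Render a (frame-weight-averaged) density map: one isotropic Gaussian
    of width ``resolution_sigma`` per atom, weighted by atomic number ×
    occupancy, plus optional white noise. The grid is padded to cover all
    atoms plus 3·resolution_sigma."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if isinstance(model_or_ensemble, AtomicModel):
        ens = Ensemble(model_or_ensemble, model_or_ensemble.coords[None])
    else:
        ens = model_or_ensemble
    top = ens.topology
    aw = top.atomic_numbers() * top.weights
    if like is None:
        lo = ens.coords.reshape(-1, 3).min(axis=0) - 3.0 * resolution_sigma - voxel_size
        hi = ens.coords.reshape(-1, 3).max(axis=0) + 3.0 * resolution_sigma + voxel_size
        shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
        out = DensityMap(np.zeros(shape), lo, np.repeat(float(voxel_size), 3))
    else:
        out = like.copy()
        out.values = np.zeros_like(like.values)
    ax = [out.axis_coords(i) for i in range(3)]
    shape = out.shape
    fw = ens.normalized_weights()
    s2 = resolution_sigma ** 2
    norm = (2.0 * np.pi * s2) ** -1.5
    r = truncation_sigma * resolution_sigma
    for fi in range(ens.n_frames):
        coords = ens.coords[fi]
        for w, mu in zip(aw * fw[fi], coords):
            sl, gs = [], []
            for d in range(3):
                i0 = int(np.searchsorted(ax[d], mu[d] - r, side="left"))
                i1 = int(np.searchsorted(ax[d], mu[d] + r, side="right"))
                if i0 >= shape[d] or i1 <= 0:
                    sl = None
                    break
                s = slice(max(i0, 0), min(i1, shape[d]))
                sl.append(s)
                gs.append(np.exp(-0.5 * (ax[d][s] - mu[d]) ** 2 / s2))
            if sl is None:
                continue
            out.values[tuple(sl)] += (w * norm) * np.einsum(
                "i,j,k->ijk", gs[0], gs[1], gs[2])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out.values += rng.normal(0.0, noise_sd, out.shape)
    return out


# ---------------------------------------------------------------------------
# Brownian solvent

def simulate_brownian(n_particles: int, d_true: float, dt: float,
                      n_steps: int, confinement: CylinderRegion | None = None,
                      seed: int = 0, box=(5.0, 5.0, 5.0),
                      kind: str = "water") -> SolventTrajectory:
    """Ideal Brownian particles: per-axis step variance 2·D·dt; steps that
    cross a confining cylinder wall are reflected."""
    if d_true < 0 or dt <= 0:
        raise ValueError("need d_true >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    if confinement is None:
        start = rng.uniform(0.0, 1.0, (n_particles, 3)) * box
        steps = rng.normal(0.0, np.sqrt(2.0 * d_true * dt),
                           (n_steps, n_particles, 3))
        pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    else:
        c = confinement.center_at(0)
        start = np.empty((n_particles, 3))
        filled = 0
        while filled < n_particles:  # rejection from the bounding box
            cand = c + rng.uniform(-1.0, 1.0, (n_particles, 3)) * \
                [confinement.radius, confinement.radius, confinement.height / 2]
            ok = confinement.contains(cand)
            take = cand[ok][:n_particles - filled]
            start[filled:filled + len(take)] = take
            filled += len(take)
        pos = np.empty((n_steps + 1, n_particles, 3))
        pos[0] = start
        sd = np.sqrt(2.0 * d_true * dt)
        R, H = confinement.radius, confinement.height
        for t in range(n_steps):
            p = pos[t] + rng.normal(0.0, sd, (n_particles, 3))
            d = p - c
            # axial reflection
            z = d[:, 2]
            z = np.where(z > H / 2, H - z, z)
            z = np.where(z < -H / 2, -H - z, z)
            # radial reflection
            r = np.linalg.norm(d[:, :2], axis=1)
            scale = np.where(r > R, np.clip((2 * R - r), 0.0, None) /
                             np.maximum(r, 1e-12), 1.0)
            d[:, :2] *= scale[:, None]
            d[:, 2] = z
            pos[t + 1] = c + d
    return SolventTrajectory(pos, dt, np.full(n_particles, kind),
                             box=None if confinement else box,
                             d_true={kind: d_true})
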