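"""Structural analyses of filament ensembles.

Contact maps (residue center-of-mass criterion, < 1 nm), geometric typing of
non-covalent interactions, Shrake–Rupley solvent-accessible surface area
with fuzzy-coat ablation, a Kabsch–Sander three-state secondary-structure
assignment, and solubility-score aggregation over conformations.

Following the convention for filament stacks, analyses default to the two
central chains of each stack, which avoids finite-size effects at the
outermost chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import amide_hydrogen, fibonacci_sphere
from .model import AtomicModel, Ensemble
from .synth import (APOLAR_RESIDUES, AA_3TO1, RESIDUE_CHARGE, KYTE_DOOLITTLE,
                    side_chain_radius)

# van der Waals radii, nm
VDW_RADII = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
             "S": 0.180, "P": 0.180}
DEFAULT_PROBE = 0.34      # nm (water-probe scale; see docs for the Å flag)
BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "OXT"}

KABSCH_SANDER_CUTOFF = -0.5   # kcal/mol
KS_FACTOR = 0.084 * 332.0     # kcal·Å/mol


def central_chains(model: AtomicModel) -> list[str]:
    """The two central chains of each protofilament stack (chains ⌈n/2⌉ and
    ⌈n/2⌉+1, 1-based); falls back to the middle two of all chains when the
    model does not carry a filament spec."""
    chains = model.chains
    spec = getattr(model, "filament_spec", None)
    if spec is not None:
        k = spec.n_chains_per_protofilament
        out = []
        for p in range(spec.n_protofilaments):
            stack = chains[p * k:(p + 1) * k]
            mid = (k + 1) // 2 - 1
            out.extend(stack[mid:mid + 2] if k > 1 else stack[:1])
        return out
    if len(chains) <= 2:
        return chains
    mid = (len(chains) + 1) // 2 - 1
    return chains[mid:mid + 2]


# ---------------------------------------------------------------------------
# contact maps

@dataclass
class ContactMap:
    residues: list                # [(chain, res_index), ...]
    probabilities: np.ndarray     # (n, n) symmetric in [0, 1]
    n_frames: int
    chain_selection: list

    def probability(self, res_a, res_b) -> float:
        i = self.residues.index(tuple(res_a))
        j = self.residues.index(tuple(res_b))
        return float(self.probabilities[i, j])

    def to_frame(self):
        import pandas as pd
        rows = []
        n = len(self.residues)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"chain_i": self.residues[i][0], "res_i": self.residues[i][1],
                             "chain_j": self.residues[j][0], "res_j": self.residues[j][1],
                             "probability": self.probabilities[i, j]})
        return pd.DataFrame(rows)


def contact_map(ensemble: Ensemble, cutoff: float = 1.0,
                chains: list[str] | None = None) -> ContactMap:
    """Contact probability between residue pairs: weighted fraction of
    frames in which the residue center-of-mass distance is below `cutoff`
    (1 nm by default). Restricted to the two central chains unless an
    explicit chain selection is given."""
    top = ensemble.topology
    if chains is None:
        chains = central_chains(top)
    residues = [r for r in top.residues() if r[0] in chains]
    if len(residues) < 2:
        raise ValueError("selection resolves to fewer than two residues")
    masses = top.masses()
    heavy = top.elements != "H"
    idx = []
    for ch, ri in residues:
        m = top.atom_mask(chain=ch, res_index=ri) & heavy
        idx.append(np.nonzero(m)[0])
    w = ensemble.normalized_weights()
    n = len(residues)
    coms = np.empty((ensemble.n_frames, n, 3))
    for j, ii in enumerate(idx):
        coms[:, j] = np.average(ensemble.coords[:, ii], axis=1,
                                weights=masses[ii])
    prob = np.zeros((n, n))
    for f in range(ensemble.n_frames):
        d = np.linalg.norm(coms[f][:, None] - coms[f][None, :], axis=2)
        prob += w[f] * (d < cutoff)
    np.fill_diagonal(prob, 1.0)
    return ContactMap(residues, prob, ensemble.n_frames, list(chains))


# ---------------------------------------------------------------------------
# interaction typing

_POSITIVE_ATOMS = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}}
_NEGATIVE_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_SC_DONOR_ACCEPTOR = {  # side-chain heavy atoms that can donate/accept
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1", "ND2"},
    "GLN": {"OE1", "NE2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}

SALT_BRIDGE_CUTOFF = 0.40   # nm, charged N–O pair
HBOND_CUTOFF = 0.35         # nm, donor–acceptor heavy atoms
HBOND_ANGLE = 120.0         # degrees, donor-H-acceptor
HYDROPHOBIC_CUTOFF = 0.45   # nm, apolar carbon pair


def _residue_atoms(model: AtomicModel, chain: str, res_index: int):
    m = model.atom_mask(chain=chain, res_index=res_index)
    if not m.any():
        raise ValueError(f"no atoms for residue {chain}:{res_index}")
    name = str(model.res_names[m][0])
    if name not in AA_3TO1:
        raise ValueError(f"unknown residue name {name!r}")
    return m, name


def _charged_coords(model, mask, resname, sign):
    table = _POSITIVE_ATOMS if sign > 0 else _NEGATIVE_ATOMS
    charge = RESIDUE_CHARGE.get(resname, 0)
    names = model.atom_names[mask]
    elements = model.elements[mask]
    coords = model.coords[mask]
    want_elem = "N" if sign > 0 else "O"
    out = []
    if resname in table:
        sel = np.isin(names, list(table[resname]))
        out.append(coords[sel])
    # coarse pseudo-atom stands in for the charged group
    if charge == sign:
        sel = (names == "SC") & (elements == want_elem)
        out.append(coords[sel])
    return np.concatenate(out) if out else np.empty((0, 3))


def _min_pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    return float(np.min(np.linalg.norm(a[:, None] - b[None, :], axis=2)))


def classify_contact(frame: AtomicModel, res_a, res_b) -> set[str]:
    """Geometric interaction typing for a residue pair in one conformation.

    salt bridge — any charged-group N–O pair < 0.40 nm between oppositely
    charged side chains; hydrogen bond — donor/acceptor heavy atoms < 0.35
    nm with donor-H-acceptor angle > 120° (amide H built geometrically;
    distance-only for side-chain donors whose H position is undefined at
    this resolution); hydrophobic — any apolar side-chain carbon pair
    < 0.45 nm between apolar residues.
    """
    out = set()
    (ma, name_a) = _residue_atoms(frame, *res_a)
    (mb, name_b) = _residue_atoms(frame, *res_b)

    # salt bridges
    for sa, sb in ((+1, -1), (-1, +1)):
        d = _min_pair_distance(_charged_coords(frame, ma, name_a, sa),
                               _charged_coords(frame, mb, name_b, sb))
        if d < SALT_BRIDGE_CUTOFF:
            out.add("salt bridge")

    # hydrogen bonds (both directions)
    if _has_hbond(frame, ma, name_a, mb, name_b) or \
       _has_hbond(frame, mb, name_b, ma, name_a):
        out.add("hydrogen bond")

    # hydrophobic
    if name_a in APOLAR_RESIDUES and name_b in APOLAR_RESIDUES:
        d = _min_pair_distance(_apolar_carbons(frame, ma),
                               _apolar_carbons(frame, mb))
        if d < HYDROPHOBIC_CUTOFF:
            out.add("hydrophobic")
    return out


def _apolar_carbons(model, mask):
    names = model.atom_names[mask]
    elements = model.elements[mask]
    sel = (elements == "C") & ~np.isin(names, list(BACKBONE_ATOMS))
    return model.coords[mask][sel]


def _donor_positions(model, mask, resname):
    """(donor heavy-atom coordinate, H coordinate or None) pairs."""
    names = model.atom_names[mask]
    coords = model.coords[mask]
    out = []
    if resname != "PRO" and "N" in names:
        n_xyz = coords[names == "N"][0]
        h = None
        if "H" in names:
            h = coords[names == "H"][0]
        elif "CA" in names:
            # geometric H needs the preceding carbonyl C; approximate with
            # the CA-opposed direction when it is not in this residue
            ca = coords[names == "CA"][0]
            h = n_xyz + 0.1 * (n_xyz - ca) / np.linalg.norm(n_xyz - ca)
        out.append((n_xyz, h))
    sc = _SC_DONOR_ACCEPTOR.get(resname, set())
    for nm in sc:
        if nm in names and nm[0] in "NO":
            out.append((coords[names == nm][0], None))
    names_sc = (names == "SC")
    if names_sc.any() and model.elements[mask][names_sc][0] in "NO":
        out.append((coords[names_sc][0], None))
    return out


def _acceptor_positions(model, mask, resname):
    names = model.atom_names[mask]
    coords = model.coords[mask]
    out = []
    if "O" in names:
        out.append(coords[names == "O"][0])
    for nm in _SC_DONOR_ACCEPTOR.get(resname, set()):
        if nm in names and nm[0] == "O":
            out.append(coords[names == nm][0])
    sc = names == "SC"
    if sc.any() and model.elements[mask][sc][0] == "O":
        out.append(coords[sc][0])
    return out


def _has_hbond(model, m_donor, name_donor, m_acc, name_acc) -> bool:
    donors = _donor_positions(model, m_donor, name_donor)
    acceptors = _acceptor_positions(model, m_acc, name_acc)
    for d_xyz, h_xyz in donors:
        for a_xyz in acceptors:
            if np.linalg.norm(d_xyz - a_xyz) >= HBOND_CUTOFF:
                continue
            if h_xyz is None:
                return True   # distance-only when H is undefined
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle > HBOND_ANGLE:
                return True
    return False


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA

def _atom_radii(model: AtomicModel) -> np.ndarray:
    r = np.empty(model.n_atoms)
    for i in range(model.n_atoms):
        if model.atom_names[i] == "SC":
            r[i] = side_chain_radius(str(model.res_names[i]))
        else:
            r[i] = VDW_RADII.get(str(model.elements[i]).upper(), 0.170)
    return r


def shrake_rupley_sasa(model: AtomicModel, probe: float = DEFAULT_PROBE,
                       n_points: int = 960,
                       radii: np.ndarray | None = None) -> dict:
    """Per-residue solvent-accessible surface area (nm²).

    Quasi-uniform points on each atom's expanded sphere (radius + probe);
    a point is accessible if it lies outside every neighbor's expanded
    sphere. Returns {(chain, res_index): SASA}.
    """
    if n_points < 32:
        raise ValueError("need at least 32 sphere points")
    if radii is None:
        radii = _atom_radii(model)
    sphere = fibonacci_sphere(n_points)
    coords = model.coords
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max()
    per_atom = np.zeros(model.n_atoms)
    for i in range(model.n_atoms):
        pts = coords[i] + expanded[i] * sphere
        neigh = tree.query_ball_point(coords[i], expanded[i] + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            d = np.linalg.norm(pts[:, None] - coords[neigh][None], axis=2)
            buried = np.any(d < expanded[neigh][None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    out = {}
    for ch, ri in model.residues():
        m = model.atom_mask(chain=ch, res_index=ri)
        out[(ch, ri)] = float(per_atom[m].sum())
    return out


@dataclass
class SASAProfile:
    residues: list
    mean: np.ndarray       # nm², mean over conformations
    sd: np.ndarray
    probe: float
    n_conformations: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"chain": [r[0] for r in self.residues],
                             "res_index": [r[1] for r in self.residues],
                             "sasa_mean": self.mean, "sasa_sd": self.sd})


def ensemble_sasa(ensemble: Ensemble, probe: float = DEFAULT_PROBE,
                  n_points: int = 960, chains: list[str] | None = None,
                  context_chains: list[str] | None = None) -> SASAProfile:
    """Mean ± SD per-residue SASA over conformations. SASA is computed in
    the context of `context_chains` (default: whole model) and reported for
    the residues of `chains` (default: the two central chains)."""
    top = ensemble.topology
    if chains is None:
        chains = central_chains(top)
    ctx_mask = (np.isin(top.chain_ids, context_chains)
                if context_chains is not None else np.ones(top.n_atoms, bool))
    sub = top.select(ctx_mask)
    report = [r for r in sub.residues() if r[0] in chains]
    vals = np.empty((ensemble.n_frames, len(report)))
    for f in range(ensemble.n_frames):
        frame = sub.with_coords(ensemble.coords[f][ctx_mask])
        sasa = shrake_rupley_sasa(frame, probe=probe, n_points=n_points)
        vals[f] = [sasa[r] for r in report]
    w = ensemble.normalized_weights()
    mean = np.average(vals, axis=0, weights=w)
    sd = np.sqrt(np.average((vals - mean) ** 2, axis=0, weights=w))
    return SASAProfile(report, mean, sd, probe, ensemble.n_frames)


def sasa_shielding(ensemble: Ensemble, removed_residues,
                   probe: float = DEFAULT_PROBE, n_points: int = 960,
                   chains: list[str] | None = None) -> dict:
    """ΔSASA per retained residue: mean SASA with the removed residues'
    atoms deleted minus mean SASA with them present, over the same frames.
    Positive Δ = shielded by the removed region. `removed_residues` is a
    set of (chain, res_index) pairs (or bare residue indices, applied to
    every chain)."""
    removed = set()
    top = ensemble.topology
    for item in removed_residues:
        if isinstance(item, tuple):
            removed.add(item)
        else:
            for ch in top.chains:
                removed.add((ch, int(item)))
    if not removed:
        raise ValueError("removed set is empty")
    keep_mask = np.array([(str(c), int(r)) not in removed
                          for c, r in zip(top.chain_ids, top.res_indices)])
    if chains is None:
        chains = central_chains(top)
    report = [r for r in top.residues() if r[0] in chains and r not in removed]
    full = np.zeros(len(report))
    ablated = np.zeros(len(report))
    w = ensemble.normalized_weights()
    sub = top.select(keep_mask)
    for f in range(ensemble.n_frames):
        frame = ensemble.frame(f)
        s_full = shrake_rupley_sasa(frame, probe=probe, n_points=n_points)
        s_abl = shrake_rupley_sasa(sub.with_coords(ensemble.coords[f][keep_mask]),
                                   probe=probe, n_points=n_points)
        full += w[f] * np.array([s_full[r] for r in report])
        ablated += w[f] * np.array([s_abl[r] for r in report])
    return {r: float(ablated[i] - full[i]) for i, r in enumerate(report)}


# ---------------------------------------------------------------------------
# secondary structure (Kabsch–Sander, 3 states)

def _ks_hbond_matrix(model: AtomicModel, chains) -> dict:
    """Set of (donor, acceptor) residue-key pairs with Kabsch–Sander energy
    below −0.5 kcal/mol. Residue keys are (chain, res_index)."""
    residues = [r for r in model.residues() if r[0] in chains]
    pos = {}
    order = {}
    for k, (ch, ri) in enumerate(residues):
        m = model.atom_mask(chain=ch, res_index=ri)
        names = model.atom_names[m]
        entry = {}
        for a in ("N", "CA", "C", "O"):
            if a in names:
                entry[a] = model.coords[m][names == a][0]
        pos[(ch, ri)] = entry
        order[(ch, ri)] = k
    # geometric amide H from the preceding residue's carbonyl carbon
    H = {}
    for ch, ri in residues:
        prev = (ch, ri - 1)
        e = pos[(ch, ri)]
        if prev in pos and "C" in pos[prev] and "N" in e and "CA" in e:
            H[(ch, ri)] = amide_hydrogen(e["N"], e["CA"], pos[prev]["C"])
    bonds = set()
    for d in residues:
        if "N" not in pos[d] or d not in H:
            continue
        if str(model.res_names[model.atom_mask(chain=d[0], res_index=d[1])][0]) == "PRO":
            continue
        n_xyz, h_xyz = pos[d]["N"], H[d]
        for a in residues:
            if a[0] == d[0] and abs(a[1] - d[1]) <= 1:
                continue
            e = pos[a]
            if "C" not in e or "O" not in e:
                continue
            r_on = np.linalg.norm(e["O"] - n_xyz) * 10.0   # nm -> Å
            r_ch = np.linalg.norm(e["C"] - h_xyz) * 10.0
            r_oh = np.linalg.norm(e["O"] - h_xyz) * 10.0
            r_cn = np.linalg.norm(e["C"] - n_xyz) * 10.0
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9
            else:
                energy = KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < KABSCH_SANDER_CUTOFF:
                bonds.add((d, a))
    return bonds


def _assign_frame_ss(model: AtomicModel, chains) -> dict:
    """{residue: 'H'|'E'|'C'} for one conformation."""
    bonds = _ks_hbond_matrix(model, chains)
    residues = [r for r in model.residues() if r[0] in chains]
    by_chain = {}
    for ch, ri in residues:
        by_chain.setdefault(ch, []).append(ri)
    ss = {r: "C" for r in residues}

    def hb(d, a):
        return (d, a) in bonds

    # helices from n-turns: Hbond(i+n -> i), two consecutive turns
    for n in (4, 3, 5):
        for ch, ris in by_chain.items():
            ris_set = set(ris)
            for ri in ris:
                t0 = hb((ch, ri + n), (ch, ri)) if ri + n in ris_set else False
                t1 = hb((ch, ri + 1 + n), (ch, ri + 1)) if ri + 1 + n in ris_set else False
                if t0 and t1:
                    for k in range(1, n + 1):
                        if (ch, ri + k) in ss and ss[(ch, ri + k)] == "C":
                            ss[(ch, ri + k)] = "H"
    # bridges (parallel and antiparallel) -> strand; within a chain the
    # partners must be at least 3 apart, across chains any pair qualifies
    for bi, i in enumerate(residues):
        for j in residues[bi + 1:]:
            if i[0] == j[0] and abs(i[1] - j[1]) < 3:
                continue
            ip = (i[0], i[1] - 1)
            inx = (i[0], i[1] + 1)
            jp = (j[0], j[1] - 1)
            jn = (j[0], j[1] + 1)
            # hb(d, a) is donor→acceptor; the classic bridge patterns read
            # Hbond(a, d) as CO(a)←NH(d)
            para = (hb(j, ip) and hb(inx, j)) or (hb(i, jp) and hb(jn, i))
            anti = (hb(j, i) and hb(i, j)) or (hb(jn, ip) and hb(inx, jp))
            if para or anti:
                ss[i] = "E"
                ss[j] = "E"
    return ss


def assign_secondary_structure(ensemble: Ensemble,
                               chains: list[str] | None = None):
    """Per-residue populations over {helix, strand, coil}: weighted frame
    fractions from the Kabsch–Sander hydrogen-bond rule (E < −0.5 kcal/mol)
    with the 3-state reduction (n-turn patterns → helix, bridge patterns →
    strand, else coil). Residues missing backbone atoms are skipped."""
    top = ensemble.topology
    if chains is None:
        chains = central_chains(top)
    residues = [r for r in top.residues() if r[0] in chains]
    pops = {r: np.zeros(3) for r in residues}   # H, E, C
    w = ensemble.normalized_weights()
    states = "HEC"
    for f in range(ensemble.n_frames):
        ss = _assign_frame_ss(ensemble.frame(f), chains)
        for r in residues:
            pops[r][states.index(ss[r])] += w[f]
    return {r: {"helix": float(v[0]), "strand": float(v[1]), "coil": float(v[2])}
            for r, v in pops.items()}


# ---------------------------------------------------------------------------
# solubility aggregation

@dataclass
class SolubilitySummary:
    core_mean_with: float
    core_sd_with: float
    core_mean_without: float
    core_sd_without: float
    per_residue_with: dict        # residue -> (mean, sd)
    per_residue_without: dict
    n_conformations: int


def hydropathy_exposure_scorer(model: AtomicModel, probe: float = DEFAULT_PROBE,
                               n_points: int = 192) -> dict:
    """Built-in per-residue solubility stand-in (NOT CamSol): an intrinsic
    hydropathy/charge propensity scaled by the residue's solvent exposure,
    so that burial pulls scores toward zero.

        s = (−KD/4.5 + 0.8·|q|) · SASA / (SASA + 0.5 nm²)
    """
    sasa = shrake_rupley_sasa(model, probe=probe, n_points=n_points)
    out = {}
    for (ch, ri) in model.residues():
        name = str(model.res_names[model.atom_mask(chain=ch, res_index=ri)][0])
        s0 = -KYTE_DOOLITTLE.get(name, 0.0) / 4.5 \
            + 0.8 * abs(RESIDUE_CHARGE.get(name, 0))
        a = sasa[(ch, ri)]
        out[(ch, ri)] = s0 * a / (a + 0.5)
    return out


def aggregate_solubility(ensemble: Ensemble, per_residue_scorer=None,
                         core_range: tuple | None = None,
                         n_conformations: int = 20,
                         fuzzy_coat_residues=None, seed: int = 0,
                         chains: list[str] | None = None) -> SolubilitySummary:
    """Mean ± SD of a per-residue solubility score over randomly drawn
    conformations, scored with and without the fuzzy-coat atoms, averaged
    over the cross-β core residues of the analysis chains."""
    if n_conformations > ensemble.n_frames:
        raise ValueError("n_conformations exceeds the frame count")
    top = ensemble.topology
    spec = getattr(top, "filament_spec", None)
    if core_range is None:
        if spec is None:
            raise ValueError("no core_range given and model carries no spec")
        core_range = spec.core_range
    if fuzzy_coat_residues is None:
        if spec is None:
            raise ValueError("no fuzzy-coat residues given")
        fuzzy_coat_residues = spec.tail_residues
    if chains is None:
        chains = central_chains(top)
    scorer = per_residue_scorer or hydropathy_exposure_scorer
    rng = np.random.default_rng(seed)
    picks = rng.choice(ensemble.n_frames, size=n_conformations, replace=False)
    coat = set(int(r) for r in fuzzy_coat_residues)
    keep = ~np.isin(top.res_indices, list(coat))
    sub = top.select(keep)
    core = [(ch, ri) for (ch, ri) in top.residues()
            if ch in chains and core_range[0] <= ri <= core_range[1]]
    with_scores = {r: [] for r in core}
    without_scores = {r: [] for r in core}
    core_with, core_without = [], []
    for f in picks:
        s_with = scorer(ensemble.frame(int(f)))
        s_without = scorer(sub.with_coords(ensemble.coords[int(f)][keep]))
        core_with.append(np.mean([s_with[r] for r in core]))
        core_without.append(np.mean([s_without[r] for r in core]))
        for r in core:
            with_scores[r].append(s_with[r])
            without_scores[r].append(s_without[r])
    return SolubilitySummary(
        core_mean_with=float(np.mean(core_with)),
        core_sd_with=float(np.std(core_with, ddof=1)) if n_conformations > 1 else 0.0,
        core_mean_without=float(np.mean(core_without)),
        core_sd_without=float(np.std(core_without, ddof=1)) if n_conformations > 1 else 0.0,
        per_residue_with={r: (float(np.mean(v)), float(np.std(v))) for r, v in with_scores.items()},
        per_residue_without={r: (float(np.mean(v)), float(np.std(v))) for r, v in without_scores.items()},
        n_conformations=n_conformations)
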