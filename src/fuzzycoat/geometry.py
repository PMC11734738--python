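"""Internal-coordinate geometry helpers.

All lengths in nm, angles in radians unless noted. The backbone builder
uses standard peptide geometry (Engh–Huber-like bond lengths/angles) and
places atoms by the NeRF construction: a new atom D is defined relative
to three placed atoms A-B-C by (bond |CD|, angle B-C-D, dihedral A-B-C-D).
"""

from __future__ import annotations

import numpy as np

# peptide geometry, nm / degrees
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1229
BOND_CA_CB = 0.1530
BOND_N_H = 0.100
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom D given A, B, C and internal coordinates (NeRF)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:  # collinear reference: pick any perpendicular
        t = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            t = np.array([0.0, 1.0, 0.0])
        n = np.cross(t, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(phi_psi: np.ndarray, origin=(0.0, 0.0, 0.0)) -> dict:
    """Build an n-residue backbone (N, CA, C, O) from (phi, psi) pairs in degrees.

    phi of the first residue and psi of the last are still consumed to keep
    the array rectangular (psi of the last residue orients its carbonyl O).
    Returns dict of arrays keyed by atom name, each (n, 3) in nm.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n = phi_psi.shape[0]
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    origin = np.asarray(origin, dtype=float)
    # seed first residue in a canonical pose
    N[0] = origin
    CA[0] = origin + np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        phi, psi = phi_psi[i]
        if i > 0:
            N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                              BOND_C_N, ANGLE_CA_C_N, phi_psi[i - 1, 1])
            CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                               BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
            C[i] = place_atom(C[i - 1], N[i], CA[i],
                              BOND_CA_C, ANGLE_N_CA_C, phi)
        # carbonyl O: trans to the next N, i.e. dihedral N-CA-C-O = psi + 180
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def extend_backbone_forward(phi_psi: np.ndarray, psi_anchor: float,
                            N0: np.ndarray, CA0: np.ndarray, C0: np.ndarray) -> dict:
    """Grow residues *after* an anchor residue with placed atoms N0, CA0, C0.

    phi_psi[k] = (phi, psi) of the k-th appended residue; psi_anchor is the
    psi torsion of the anchor residue (it orients the first new N).
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n_new = phi_psi.shape[0]
    N = np.zeros((n_new, 3))
    CA = np.zeros((n_new, 3))
    C = np.zeros((n_new, 3))
    O = np.zeros((n_new, 3))
    pN, pCA, pC = (np.asarray(x, dtype=float) for x in (N0, CA0, C0))
    psi_prev = psi_anchor
    for k in range(n_new):
        phi, psi = phi_psi[k]
        N[k] = place_atom(pN, pCA, pC, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[k] = place_atom(pCA, pC, N[k], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C[k] = place_atom(pC, N[k], CA[k], BOND_CA_C, ANGLE_N_CA_C, phi)
        O[k] = place_atom(N[k], CA[k], C[k], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        pN, pCA, pC = N[k], CA[k], C[k]
        psi_prev = psi
    return {"N": N, "CA": CA, "C": C, "O": O}


def extend_backbone_reverse(phi_psi: np.ndarray, phi_anchor: float,
                            N1: np.ndarray, CA1: np.ndarray, C1: np.ndarray) -> dict:
    """Grow residues *before* an anchor residue with placed atoms N1, CA1, C1.

    phi_psi[k] = (phi, psi) of the k-th new residue in chain order (row -1 is
    the residue immediately preceding the anchor); phi_anchor is the phi
    torsion of the anchor residue, which the prepended carbonyl carbon sets.
    Returns backbone arrays of the new residues in chain order.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n_new = phi_psi.shape[0]
    N = np.zeros((n_new, 3))
    CA = np.zeros((n_new, 3))
    C = np.zeros((n_new, 3))
    O = np.zeros((n_new, 3))
    nxt_N, nxt_CA, nxt_C = (np.asarray(x, dtype=float) for x in (N1, CA1, C1))
    for k in range(n_new - 1, -1, -1):
        phi_next = phi_anchor if k == n_new - 1 else phi_psi[k + 1, 0]
        # C(k): dihedral C(k)-N(k+1)-CA(k+1)-C(k+1) is phi of residue k+1
        C[k] = place_atom(nxt_C, nxt_CA, nxt_N, BOND_C_N, ANGLE_C_N_CA, phi_next)
        CA[k] = place_atom(nxt_CA, nxt_N, C[k], BOND_CA_C, ANGLE_CA_C_N, OMEGA_TRANS)
        N[k] = place_atom(nxt_N, C[k], CA[k], BOND_N_CA, ANGLE_N_CA_C, phi_psi[k, 1])
        # carbonyl O opposite CA(k+1) across the peptide bond (cis: dihedral 0)
        O[k] = place_atom(nxt_CA, nxt_N, C[k], BOND_C_O, 123.0, 0.0)
        nxt_N, nxt_CA, nxt_C = N[k], CA[k], C[k]
    return {"N": N, "CA": CA, "C": C, "O": O}


def place_cb(N: np.ndarray, CA: np.ndarray, C: np.ndarray,
             bond: float = BOND_CA_CB) -> np.ndarray:
    """Place CB tetrahedrally off CA (works on (3,) or (n,3) arrays)."""
    N, CA, C = (np.atleast_2d(x) for x in (N, CA, C))
    b1 = N - CA
    b2 = C - CA
    b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
    b2 /= np.linalg.norm(b2, axis=1, keepdims=True)
    bisector = -(b1 + b2)
    bisector /= np.linalg.norm(bisector, axis=1, keepdims=True)
    perp = np.cross(b2, b1)
    perp /= np.linalg.norm(perp, axis=1, keepdims=True)
    half = np.deg2rad(54.75)  # half tetrahedral angle off the bisector plane
    direction = np.cos(half) * bisector + np.sin(half) * perp
    out = CA + bond * direction
    return out[0] if out.shape[0] == 1 else out


def amide_hydrogen(N: np.ndarray, CA: np.ndarray, C_prev: np.ndarray) -> np.ndarray:
    """Backbone amide H built geometrically: 0.1 nm from N, opposite the
    bisector of the N-CA and N-C(prev) bonds (DSSP-style construction)."""
    v1 = N - CA
    v2 = N - C_prev
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    d = v1 + v2
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:
        d = v1
        nrm = 1.0
    return N + BOND_N_H * d / nrm


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (golden-spiral lattice), (n, 3)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix; angle in radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
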