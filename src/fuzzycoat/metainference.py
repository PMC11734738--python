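"""Bayesian metainference with a Gaussian-mixture cryo-EM restraint.

The hybrid energy combines a structural prior with an ensemble-averaged
density restraint and inferred error parameters:

    E(X, σ) = E_prior(X)
            + (k_B T / 2) Σ_{r,i} [ov_DD,i − ov̄_MD,i]² / (σ_{r,i}² + σ_i_SEM²)
            + E_σ
            + Σ_r V_bias(s(X_r))

with E_σ = k_B T Σ_{r,i} [log σ_{r,i} + ½ log(σ_{r,i}² + σ_i_SEM²)], the
Jeffreys prior on each error parameter plus the Gaussian-likelihood
normalization that keeps the σ posterior proper,

where ov_MD,i is the overlap of a replica's model GMM with data component i,
ov̄_MD,i its mean over the N_R replicas, σ_i_SEM the standard error of that
mean, and ov_DD,i the overlap of the full data GMM with its component i.
Per-datapoint/per-replica error parameters σ_{r,i} are sampled by Metropolis
Monte Carlo under a Jeffreys prior (the k_B T Σ log σ term) with hard bounds
proportional to ov_DD,i.

A toy posterior sampler (`run_toy_metainference`) alternates Metropolis
moves on tail torsions of a toy filament with error-parameter Monte Carlo,
standing in for the replica molecular-dynamics engine of production-scale
runs: the rigid core and fixed bonded geometry of the torsion move set play
the role of the structural prior's hard terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .maps import DensityMap, GaussianMixture, fit_gmm
from .model import ATOMIC_NUMBER, AtomicModel, Ensemble

logger = logging.getLogger(__name__)

DEFAULT_ATOM_SIGMA = 0.15   # nm, model-GMM width per heavy atom
SIGMA_BOUNDS = (1e-4, 1e2)  # × ov_DD,i, hard bounds on σ_{r,i}


def model_to_gmm(model: AtomicModel, atom_sigma: float = DEFAULT_ATOM_SIGMA,
                 weight_table: dict | None = None) -> GaussianMixture:
    """One isotropic Gaussian per non-hydrogen atom; weight = scattering
    weight (default: atomic number) × occupancy-like atom weight."""
    if atom_sigma <= 0:
        raise ValueError("atom_sigma must be positive")
    heavy = model.elements != "H"
    if not heavy.any():
        raise ValueError("model has no heavy atoms")
    sub = model.select(heavy)
    if weight_table is None:
        w = sub.atomic_numbers()
    else:
        w = np.array([weight_table[str(e).upper()] for e in sub.elements], dtype=float)
    return GaussianMixture.isotropic(w * sub.weights, sub.coords, atom_sigma)


def gaussian_overlap(a, b) -> float:
    """Overlap integral ∫ φ_a φ_b dx = w_a w_b N(μ_a − μ_b; 0, Σ_a + Σ_b)."""
    wa, ma, ca = a
    wb, mb, cb = b
    cov = np.asarray(ca, dtype=float) + np.asarray(cb, dtype=float)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance in overlap") from exc
    d = np.asarray(ma, dtype=float) - np.asarray(mb, dtype=float)
    y = np.linalg.solve(L, d)
    q = float(y @ y)
    norm = (2 * np.pi) ** 1.5 * float(np.prod(np.diag(L)))
    return float(wa) * float(wb) * np.exp(-0.5 * q) / norm


def overlap_matrix(gmm_a: GaussianMixture, gmm_b: GaussianMixture,
                   distance_cutoff: float | None = 5.0,
                   magnitude_cutoff: float | None = 0.01) -> np.ndarray:
    """(K_a, K_b) overlaps, vectorized over the first mixture.

    Pairs farther apart than `distance_cutoff`·√(max eigenvalue of Σ_a+Σ_b)
    are skipped, and overlaps below `magnitude_cutoff` (absolute, same units
    as the overlaps) are zeroed — the neighbor-list shortcuts of production
    runs; pass None to disable either.
    """
    out = np.zeros((gmm_a.n_components, gmm_b.n_components))
    for j in range(gmm_b.n_components):
        wb, mb, cb = gmm_b.weights[j], gmm_b.means[j], gmm_b.covariances[j]
        cov = gmm_a.covariances + cb
        d = gmm_a.means - mb
        evals = np.linalg.eigvalsh(cov)
        L = np.linalg.cholesky(cov)
        y = np.linalg.solve(L, d[..., None])[..., 0]
        q = np.sum(y * y, axis=1)
        dets = np.prod(np.diagonal(L, axis1=1, axis2=2), axis=1)
        ov = gmm_a.weights * wb * np.exp(-0.5 * q) / ((2 * np.pi) ** 1.5 * dets)
        if distance_cutoff is not None:
            far = np.sum(d * d, axis=1) > distance_cutoff ** 2 * evals[:, -1]
            ov[far] = 0.0
        if magnitude_cutoff is not None:
            ov[ov < magnitude_cutoff] = 0.0
        out[:, j] = ov
    return out


def data_self_overlap(data_gmm: GaussianMixture, per_component_total: bool = True,
                      **cutoffs) -> np.ndarray:
    """ov_DD,i: overlap of the full data GMM with component i (default), or
    only the component's self-overlap when per_component_total=False."""
    ov = overlap_matrix(data_gmm, data_gmm, **cutoffs)
    return ov.sum(axis=0) if per_component_total else np.diag(ov).copy()


@dataclass
class MetainferenceState:
    """Replica coordinates plus error parameters and cached data overlaps."""

    replicas: Ensemble
    data_gmm: GaussianMixture
    sigma_b: np.ndarray            # (N_R, N_D)
    kBT: float = 1.0
    atom_sigma: float = DEFAULT_ATOM_SIGMA
    restraint_atoms: np.ndarray = None   # bool mask over topology atoms
    distance_cutoff: float | None = 5.0
    magnitude_cutoff: float | None = 0.01
    ov_dd: np.ndarray = None
    sigma_sem: np.ndarray = None

    def __post_init__(self):
        if self.ov_dd is None:
            self.ov_dd = data_self_overlap(
                self.data_gmm, distance_cutoff=self.distance_cutoff,
                magnitude_cutoff=self.magnitude_cutoff)
        if np.any(self.ov_dd <= 0):
            raise ValueError("ov_DD must be positive for every component")
        self.sigma_b = np.asarray(self.sigma_b, dtype=float)
        if self.sigma_b.ndim == 0 or self.sigma_b.ndim == 1:
            self.sigma_b = np.broadcast_to(
                self.sigma_b, (self.replicas.n_frames, len(self.ov_dd))).copy()
        if np.any(self.sigma_b <= 0):
            raise ValueError("sigma_b must be positive")

    @classmethod
    def create(cls, replicas: Ensemble, data_gmm: GaussianMixture,
               sigma_b_frac: float = 0.5, **kw) -> "MetainferenceState":
        st = cls(replicas, data_gmm, sigma_b=np.array(1.0), **kw)
        st.sigma_b = np.broadcast_to(sigma_b_frac * st.ov_dd,
                                     (replicas.n_frames, len(st.ov_dd))).copy()
        return st

    @property
    def n_replicas(self) -> int:
        return self.replicas.n_frames

    def replica_model_gmm(self, r: int) -> GaussianMixture:
        frame = self.replicas.frame(r)
        if self.restraint_atoms is not None:
            frame = frame.select(self.restraint_atoms)
        return model_to_gmm(frame, self.atom_sigma)

    def replica_overlaps(self) -> np.ndarray:
        """(N_R, N_D) matrix of per-replica ov_MD,i."""
        rows = []
        for r in range(self.n_replicas):
            ov = overlap_matrix(self.replica_model_gmm(r), self.data_gmm,
                                distance_cutoff=self.distance_cutoff,
                                magnitude_cutoff=self.magnitude_cutoff)
            rows.append(ov.sum(axis=0))
        return np.stack(rows)


def replica_averaged_overlap(state: MetainferenceState,
                             ov_rows: np.ndarray | None = None):
    """(ov̄_MD per component, σ_SEM per component). With a single replica the
    standard error is zero by convention (logged)."""
    if ov_rows is None:
        ov_rows = state.replica_overlaps()
    ov_bar = ov_rows.mean(axis=0)
    n_r = ov_rows.shape[0]
    if n_r == 1:
        logger.info("single replica: σ_SEM set to 0 by convention")
        sem = np.zeros_like(ov_bar)
    else:
        sem = ov_rows.std(axis=0, ddof=1) / np.sqrt(n_r)
    return ov_bar, sem


@dataclass
class EnergyReport:
    prior: float
    restraint: float
    error: float
    bias: float
    residuals: np.ndarray

    @property
    def total(self) -> float:
        return self.prior + self.restraint + self.error + self.bias


def restraint_energy(residuals: np.ndarray, sigma_b: np.ndarray,
                     sigma_sem: np.ndarray, kBT: float) -> float:
    """(k_B T / 2) Σ_{r,i} residual_i² / (σ_{r,i}² + σ_SEM,i²)."""
    if np.any(sigma_b <= 0):
        raise ValueError("sigma_b must be positive")
    denom = sigma_b ** 2 + sigma_sem[None, :] ** 2
    return float(0.5 * kBT * np.sum(residuals[None, :] ** 2 / denom))


def metainference_energy(state: MetainferenceState, bias: float = 0.0,
                         prior: float = 0.0,
                         ov_rows: np.ndarray | None = None) -> EnergyReport:
    """Evaluate the hybrid energy; prior and bias energies are supplied by
    their pluggable providers (plain numbers here)."""
    ov_bar, sem = replica_averaged_overlap(state, ov_rows)
    state.sigma_sem = sem
    residuals = state.ov_dd - ov_bar
    rest = restraint_energy(residuals, state.sigma_b, sem, state.kBT)
    err = error_energy(state.sigma_b, sem, state.kBT)
    return EnergyReport(prior=float(prior), restraint=rest, error=err,
                        bias=float(bias), residuals=residuals)


def error_energy(sigma_b: np.ndarray, sigma_sem: np.ndarray, kBT: float) -> float:
    """E_σ: Jeffreys prior (k_B T Σ log σ) plus the Gaussian-likelihood
    normalization ½ k_B T Σ log(σ² + σ_SEM²), which makes the σ posterior
    proper (without it the conditional is flat in log σ at large σ)."""
    s2 = sigma_b ** 2 + sigma_sem[None, :] ** 2
    return float(kBT * np.sum(np.log(sigma_b) + 0.5 * np.log(s2)))


def sample_error_parameters(state: MetainferenceState, n_mc_steps: int,
                            proposal_width: float = 0.5, seed: int = 0,
                            bounds: tuple = SIGMA_BOUNDS,
                            residuals: np.ndarray | None = None):
    """Metropolis sampling of every σ_{r,i} under its conditional posterior
    (Gaussian restraint likelihood × Jeffreys prior), with log-scale
    random-walk proposals and hard bounds ``bounds × ov_DD,i``.

    Returns (samples, acceptance_rate); state.sigma_b is left at the final
    sample.
    """
    if proposal_width <= 0:
        raise ValueError("proposal_width must be positive")
    if residuals is None:
        ov_bar, sem = replica_averaged_overlap(state)
        state.sigma_sem = sem
        residuals = state.ov_dd - ov_bar
    sem = state.sigma_sem if state.sigma_sem is not None else np.zeros_like(state.ov_dd)
    rng = np.random.default_rng(seed)
    lo = bounds[0] * state.ov_dd
    hi = bounds[1] * state.ov_dd
    sig = np.clip(state.sigma_b, lo, hi)
    res2 = residuals ** 2

    def log_target_u(s):
        # density in u = log σ: Jeffreys 1/σ × Jacobian σ cancel, leaving the
        # likelihood and its normalization
        s2 = s ** 2 + sem[None, :] ** 2
        return -0.5 * res2[None, :] / s2 - 0.5 * np.log(s2)

    samples = np.empty((n_mc_steps,) + sig.shape)
    n_acc = 0
    cur = log_target_u(sig)
    for t in range(n_mc_steps):
        prop = sig * np.exp(rng.normal(0.0, proposal_width, sig.shape))
        ok = (prop >= lo) & (prop <= hi)
        new = log_target_u(prop)
        accept = ok & (np.log(rng.random(sig.shape)) < new - cur)
        sig = np.where(accept, prop, sig)
        cur = np.where(accept, new, cur)
        n_acc += accept.sum()
        samples[t] = sig
    state.sigma_b = sig
    rate = n_acc / (n_mc_steps * sig.size)
    return samples, float(rate)


def relative_error_per_gaussian(state: MetainferenceState,
                                sigma_samples: np.ndarray | None = None,
                                normalization: str = "total") -> np.ndarray:
    """Per data component: ⟨√(σ_{r,i}² + σ_SEM,i²)⟩ / ov_DD,i, the mean taken
    over replicas (and MC samples when given). ``normalization="self"``
    divides by the component's own self-overlap instead of the total
    data-GMM overlap."""
    sem = state.sigma_sem if state.sigma_sem is not None else np.zeros_like(state.ov_dd)
    if sigma_samples is None:
        eff = np.sqrt(state.sigma_b ** 2 + sem[None, :] ** 2).mean(axis=0)
    else:
        eff = np.sqrt(sigma_samples ** 2 + sem[None, None, :] ** 2).mean(axis=(0, 1))
    if normalization == "total":
        denom = state.ov_dd
    elif normalization == "self":
        denom = data_self_overlap(state.data_gmm, per_component_total=False,
                                  distance_cutoff=state.distance_cutoff,
                                  magnitude_cutoff=state.magnitude_cutoff)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return eff / denom


# ---------------------------------------------------------------------------
# toy posterior sampler

@dataclass
class ToyRunResult:
    ensemble: Ensemble                 # post-burn-in frames, all replicas
    energy_trace: list                 # EnergyReport per recorded sweep
    sigma_trace: np.ndarray            # (n_recorded, N_R, N_D)
    acceptance: float                  # coordinate-move acceptance rate
    torsion_samples: np.ndarray        # (n_frames, n_chains, n_tail, 2)
    state: MetainferenceState


def run_toy_metainference(prior, data_map_or_gmm, n_replicas: int,
                          n_steps: int, model: AtomicModel,
                          seed: int = 0, chains: list[str] | None = None,
                          atom_sigma: float = DEFAULT_ATOM_SIGMA,
                          kBT: float = 1.0, move_deg: float = 20.0,
                          reference_conformers: np.ndarray | None = None,
                          reflect_prob: float = 0.2,
                          restraint: bool = True,
                          sigma_b_frac: float = 0.5,
                          sigma_mc_steps: int = 2,
                          sigma_bounds: tuple = SIGMA_BOUNDS,
                          data_n_components: int = 16,
                          burn_in: float = 0.25, thin: int = 5,
                          init_torsions: np.ndarray | None = None) -> ToyRunResult:
    """Alternate Metropolis moves on tail torsions with error-parameter MC.

    `prior` is a callable torsions(n_chains, n_tail, 2 deg) -> energy in kBT
    units, or None for a flat prior (the rigid core and fixed bond geometry
    are enforced by the move set itself). `reference_conformers` (2, n_tail,
    2) enables symmetric reflection proposals through the midpoint of the
    two torsion vectors, which lets replicas hop between well-separated
    conformers.
    """
    from . import synth

    if n_replicas < 1:
        raise ValueError("need at least one replica")
    spec = model.filament_spec
    if chains is None:
        all_chains = model.chains
        chains = [all_chains[(len(all_chains) + 1) // 2 - 1]]
    n_tail = len(spec.tail_residues)
    rng = np.random.default_rng(seed)

    if isinstance(data_map_or_gmm, DensityMap):
        data_gmm = fit_gmm(data_map_or_gmm, data_n_components, seed=seed).mixture
    else:
        data_gmm = data_map_or_gmm

    # restraint acts on the movable tails only (the core is identical in
    # every replica and would add a constant overlap)
    tail_mask = np.zeros(model.n_atoms, dtype=bool)
    for ch in chains:
        tail_mask |= synth.tail_atom_mask(model, spec, ch)
    heavy_tail = tail_mask & (model.elements != "H")

    base = np.array([synth.COIL_PHI, synth.COIL_PSI])
    tors = np.empty((n_replicas, len(chains), n_tail, 2))
    for r in range(n_replicas):
        if init_torsions is not None:
            tors[r] = init_torsions
        elif reference_conformers is not None:
            pick = reference_conformers[rng.integers(len(reference_conformers))]
            tors[r] = pick + rng.normal(0, move_deg, (len(chains), n_tail, 2))
        else:
            tors[r] = base + rng.normal(0, 3 * move_deg, (len(chains), n_tail, 2))

    def replica_coords(torsions_r):
        c = model.coords.copy()
        for ci, ch in enumerate(chains):
            mask = synth.tail_atom_mask(model, spec, ch)
            c[mask] = synth.tail_coords_from_torsions(model, ch, torsions_r[ci])
        return c

    coords = np.stack([replica_coords(tors[r]) for r in range(n_replicas)])
    state = MetainferenceState.create(
        Ensemble(model, coords), data_gmm, sigma_b_frac=sigma_b_frac,
        kBT=kBT, atom_sigma=atom_sigma, restraint_atoms=heavy_tail)
    ov_rows = state.replica_overlaps()
    prior_e = np.array([prior(tors[r]) if prior else 0.0 for r in range(n_replicas)])

    def total_restraint(rows, sigma_b, sem):
        ov_bar = rows.mean(axis=0)
        res = state.ov_dd - ov_bar
        return restraint_energy(res, sigma_b, sem, kBT), res

    frames, torsion_samples, e_trace, s_trace = [], [], [], []
    n_acc = n_prop = 0
    n_burn = int(burn_in * n_steps)
    for sweep in range(n_steps):
        _, sem = replica_averaged_overlap(state, ov_rows)
        state.sigma_sem = sem
        for r in range(n_replicas):
            ci = rng.integers(len(chains))
            prop = tors[r].copy()
            if (reference_conformers is not None and len(reference_conformers) == 2
                    and rng.random() < reflect_prob):
                mid = reference_conformers[0] + reference_conformers[1]
                prop[ci] = mid[ci] - prop[ci]     # symmetric involution
            else:
                prop[ci] = prop[ci] + rng.normal(0, move_deg, (n_tail, 2))
            new_coords = replica_coords(prop)
            new_rows = ov_rows.copy()
            if restraint:
                st_frame = model.with_coords(new_coords).select(heavy_tail)
                gm = model_to_gmm(st_frame, atom_sigma)
                new_rows[r] = overlap_matrix(
                    gm, data_gmm, distance_cutoff=state.distance_cutoff,
                    magnitude_cutoff=state.magnitude_cutoff).sum(axis=0)
                e_old, _ = total_restraint(ov_rows, state.sigma_b, sem)
                e_new, _ = total_restraint(new_rows, state.sigma_b, sem)
            else:
                e_old = e_new = 0.0
            p_new = prior(prop) if prior else 0.0
            de = (e_new - e_old) + (p_new - prior_e[r])
            n_prop += 1
            if de <= 0 or rng.random() < np.exp(-de / kBT):
                tors[r] = prop
                ov_rows = new_rows
                prior_e[r] = p_new
                state.replicas.coords[r] = new_coords
                n_acc += 1
            if not np.isfinite(de):
                raise FloatingPointError("diverging energy in toy sampler")
        if restraint and sigma_mc_steps > 0:
            _, sem = replica_averaged_overlap(state, ov_rows)
            state.sigma_sem = sem
            res = state.ov_dd - ov_rows.mean(axis=0)
            sample_error_parameters(state, sigma_mc_steps, seed=int(rng.integers(2 ** 31)),
                                    bounds=sigma_bounds, residuals=res)
        if sweep >= n_burn and (sweep - n_burn) % thin == 0:
            for r in range(n_replicas):
                frames.append(state.replicas.coords[r].copy())
                torsion_samples.append(tors[r].copy())
            rep = metainference_energy(state, prior=float(prior_e.sum()),
                                       ov_rows=ov_rows)
            e_trace.append(rep)
            s_trace.append(state.sigma_b.copy())
    ens = Ensemble(model, np.stack(frames))
    return ToyRunResult(ens, e_trace, np.stack(s_trace),
                        n_acc / max(n_prop, 1), np.stack(torsion_samples), state)


def assign_to_references(ensemble: Ensemble, references: list[np.ndarray],
                         atom_mask: np.ndarray) -> np.ndarray:
    """Label each frame with the index of the nearest reference coordinate
    set (RMSD over the masked atoms, no superposition — the core is fixed)."""
    labels = np.empty(ensemble.n_frames, dtype=int)
    refs = [np.asarray(r)[atom_mask] if len(r) == ensemble.topology.n_atoms else np.asarray(r)
            for r in references]
    for i in range(ensemble.n_frames):
        x = ensemble.coords[i][atom_mask]
        rmsd = [np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1))) for ref in refs]
        labels[i] = int(np.argmin(rmsd))
    return labels
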