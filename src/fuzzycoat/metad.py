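"""Collective variables, well-tempered / parallel-bias metadynamics,
unbiasing weights, free-energy profiles and block-averaging diagnostics.

Bias convention: per-CV Gaussian hills are accumulated in a shared list
(multiple walkers append to the same list, so alternating walkers and a
single walker depositing in the same order produce identical biases). In
well-tempered mode a deposited hill is scaled by exp(−V(s)/(k_B ΔT)) with
ΔT = (γ−1)T. Parallel-bias mode combines the per-CV biases as

    V_PB(s) = −k_B T ln[ (1/N_CV) Σ_j exp(−V_j(s_j)/k_B T) ]

(the 1/N_CV normalization keeps the zero-bias value at 0, so the bias
energy is everywhere ≥ 0; reweighting is invariant to the constant), and a
deposited hill on CV j is additionally scaled by the conditional weight
exp(−V_j/k_B T)/Σ_k exp(−V_k/k_B T). Reweighting uses the converged final
bias: w_t ∝ exp(+V_final(s_t)/k_B T); a time-dependent c(t) estimator is
out of scope of the toy pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AtomicModel


@dataclass
class CollectiveVariable:
    """A scalar function of coordinates: center-of-mass distance between two
    selections, radius of gyration of one selection, or a torsion over four
    atoms."""

    kind: str                      # "com_distance" | "radius_of_gyration" | "torsion"
    selections: list               # list of atom-index arrays
    periodic: bool = False
    label: str = ""

    def __post_init__(self):
        kinds = ("com_distance", "radius_of_gyration", "torsion")
        if self.kind not in kinds:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        self.selections = [np.asarray(s, dtype=int) for s in self.selections]
        for s in self.selections:
            if s.size == 0:
                raise ValueError("empty atom selection")
        if self.kind == "com_distance":
            if len(self.selections) != 2:
                raise ValueError("com_distance needs two selections")
            if np.intersect1d(self.selections[0], self.selections[1]).size:
                # identical selections give the trivial value 0; allow only
                # fully identical or fully disjoint sets
                if not np.array_equal(np.sort(self.selections[0]),
                                      np.sort(self.selections[1])):
                    raise ValueError("com_distance selections must be disjoint")
        if self.kind == "torsion":
            if sum(s.size for s in self.selections) != 4:
                raise ValueError("torsion needs exactly four atoms")
            self.periodic = True


def compute_cv(model: AtomicModel, cv: CollectiveVariable) -> float:
    masses = model.masses()
    if cv.kind == "com_distance":
        coms = [np.average(model.coords[s], axis=0, weights=masses[s])
                for s in cv.selections]
        return float(np.linalg.norm(coms[0] - coms[1]))
    if cv.kind == "radius_of_gyration":
        s = cv.selections[0]
        w = masses[s]
        com = np.average(model.coords[s], axis=0, weights=w)
        return float(np.sqrt(np.average(
            np.sum((model.coords[s] - com) ** 2, axis=1), weights=w)))
    # torsion
    from .geometry import dihedral
    idx = np.concatenate(cv.selections)
    p = model.coords[idx]
    return float(np.deg2rad(dihedral(p[0], p[1], p[2], p[3])))


@dataclass
class BiasState:
    """Shared hill lists per CV plus the well-tempered/parallel-bias knobs."""

    n_cvs: int
    gamma: float = 10.0            # well-tempered bias factor γ = (T+ΔT)/T
    kBT: float = 1.0
    mode: str = "pb"               # "pb" (parallel bias) | "single"
    well_tempered: bool = True
    periodic: list = None          # per-CV period (e.g. 2π) or None
    centers: list = field(default_factory=list)   # per CV: list of floats
    widths: list = field(default_factory=list)
    heights: list = field(default_factory=list)
    times: list = field(default_factory=list)

    def __post_init__(self):
        if self.well_tempered and self.gamma <= 1:
            raise ValueError("well-tempered mode needs gamma > 1")
        if not self.centers:
            self.centers = [[] for _ in range(self.n_cvs)]
            self.widths = [[] for _ in range(self.n_cvs)]
            self.heights = [[] for _ in range(self.n_cvs)]
            self.times = [[] for _ in range(self.n_cvs)]
        if self.periodic is None:
            self.periodic = [None] * self.n_cvs

    def _hill_arrays(self, j: int):
        cache = getattr(self, "_cache", None)
        if cache is None:
            cache = self._cache = {}
        key = (j, len(self.centers[j]))
        if key not in cache:
            cache.clear()
            cache[key] = (np.asarray(self.centers[j]), np.asarray(self.widths[j]),
                          np.asarray(self.heights[j]))
        return cache[key]

    def cv_bias(self, j: int, s) -> np.ndarray:
        """V_j(s): sum of deposited hills of CV j, vectorized over s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if not self.centers[j]:
            return np.zeros_like(s)
        c, w, h = self._hill_arrays(j)
        d = s[:, None] - c[None, :]
        if self.periodic[j]:
            per = self.periodic[j]
            d -= np.round(d / per) * per
        return np.sum(h * np.exp(-0.5 * (d / w) ** 2), axis=1)

    def bias_energy(self, cv_values) -> float:
        """Combined bias at one CV vector (length n_cvs)."""
        cv_values = np.atleast_1d(cv_values)
        v = np.array([self.cv_bias(j, cv_values[j])[0] for j in range(self.n_cvs)])
        if self.mode == "single" or self.n_cvs == 1:
            return float(v.sum())
        x = -v / self.kBT
        m = x.max()
        return float(-self.kBT * (m + np.log(np.mean(np.exp(x - m)))))

    def deposit(self, cv_values, hill_height: float, hill_width,
                time: float = 0.0, walker_id: int = 0) -> None:
        cv_values = np.atleast_1d(cv_values)
        hill_width = np.broadcast_to(np.atleast_1d(hill_width), (self.n_cvs,))
        v = np.array([self.cv_bias(j, cv_values[j])[0] for j in range(self.n_cvs)])
        if self.mode == "pb" and self.n_cvs > 1:
            x = -v / self.kBT
            cond = np.exp(x - x.max())
            cond = cond / cond.sum()
        else:
            cond = np.ones(self.n_cvs)
        for j in range(self.n_cvs):
            h = hill_height * cond[j]
            if self.well_tempered:
                h *= np.exp(-v[j] / (self.kBT * (self.gamma - 1.0)))
            if h <= 0:
                continue
            self.centers[j].append(float(cv_values[j]))
            self.widths[j].append(float(hill_width[j]))
            self.heights[j].append(float(h))
            self.times[j].append(float(time))

    def hills_table(self):
        """Tidy table of deposited hills: (cv, time, center, width, height)."""
        import pandas as pd
        rows = []
        for j in range(self.n_cvs):
            for t, c, w, h in zip(self.times[j], self.centers[j],
                                  self.widths[j], self.heights[j]):
                rows.append({"cv": j, "time": t, "center": c,
                             "width": w, "height": h})
        return pd.DataFrame(rows, columns=["cv", "time", "center", "width", "height"])


def well_tempered_bias(bias: BiasState, cv_values, deposit: bool,
                       hill_height: float, hill_width,
                       time: float = 0.0, walker_id: int = 0):
    """Evaluate (and optionally deposit at) the given CV values.
    Returns (bias energy, the updated BiasState)."""
    if deposit:
        bias.deposit(cv_values, hill_height, hill_width, time=time,
                     walker_id=walker_id)
    return bias.bias_energy(cv_values), bias


def unbias_weights(bias: BiasState, cv_trace: np.ndarray,
                   kBT: float | None = None) -> np.ndarray:
    """Final-bias reweighting: w_t ∝ exp(+V_final(s_t)/k_B T), normalized."""
    kBT = bias.kBT if kBT is None else kBT
    cv_trace = np.atleast_2d(np.asarray(cv_trace, dtype=float))
    if cv_trace.shape[1] != bias.n_cvs and cv_trace.shape[0] == bias.n_cvs:
        cv_trace = cv_trace.T
    v = np.array([bias.bias_energy(row) for row in cv_trace])
    x = v / kBT
    w = np.exp(x - x.max())
    return w / w.sum()


def free_energy_profile(cv_trace: np.ndarray, weights: np.ndarray | None,
                        n_bins: int, range_=None):
    """F(bin) = −log(weighted histogram) in k_B T units, shifted so the
    minimum is 0; empty bins are NaN (masked, not interpolated).
    Returns (bin_centers, free_energy)."""
    if n_bins < 2:
        raise ValueError("need at least two bins")
    cv_trace = np.asarray(cv_trace, dtype=float).ravel()
    hist, edges = np.histogram(cv_trace, bins=n_bins, range=range_,
                               weights=weights, density=True)
    with np.errstate(divide="ignore"):
        f = -np.log(hist)
    f[~np.isfinite(f)] = np.nan
    f -= np.nanmin(f)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, f


def block_average_error(trace: np.ndarray, block_sizes) -> dict:
    """Standard error of block means per block size (convergence diagnostic
    for correlated series): {block_size: SE}."""
    trace = np.asarray(trace, dtype=float).ravel()
    out = {}
    for b in block_sizes:
        b = int(b)
        n_blocks = len(trace) // b
        if n_blocks < 2:
            raise ValueError(f"series too short for block size {b}")
        means = trace[:n_blocks * b].reshape(n_blocks, b).mean(axis=1)
        out[b] = float(means.std(ddof=1) / np.sqrt(n_blocks))
    return out


def run_biased_mc_1d(energy_fn, x0: float, step_sd: float, n_steps: int,
                     kBT: float = 1.0, bias: BiasState | None = None,
                     deposit_stride: int = 0, hill_height: float = 0.3,
                     hill_width: float = 0.3, seed: int = 0):
    """Metropolis sampling of a 1D potential, optionally under a growing
    metadynamics bias (hills deposited every `deposit_stride` accepted-or-
    rejected steps). Returns (x trace, bias)."""
    rng = np.random.default_rng(seed)
    x = float(x0)
    e = energy_fn(x) + (bias.bias_energy([x]) if bias else 0.0)
    trace = np.empty(n_steps)
    for t in range(n_steps):
        xp = x + rng.normal(0.0, step_sd)
        ep = energy_fn(xp) + (bias.bias_energy([xp]) if bias else 0.0)
        if ep - e <= 0 or rng.random() < np.exp(-(ep - e) / kBT):
            x, e = xp, ep
        if bias is not None and deposit_stride and (t + 1) % deposit_stride == 0:
            bias.deposit([x], hill_height, hill_width, time=float(t + 1))
            e = energy_fn(x) + bias.bias_energy([x])
        trace[t] = x
    return trace, bias
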