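"""Region-restricted solvent diffusion analysis.

Mean-square displacement (MSD) of solvent-like particles selected inside a
cylindrical region (e.g. a groove along a filament surface), and diffusion
constants from the Einstein relation MSD(τ) = 2·d·D·τ in d dimensions.

Membership rule: a particle contributes displacements from time origin t if
it is inside the region at t, and is tracked even if it later leaves
(``membership="origin"``); an ``"endpoints"`` rule requiring the particle
inside at both ends of the lag is available behind a flag. Positions are
assumed unwrapped; a minimum-image unwrapping helper is provided for wrapped
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CylinderRegion:
    """Cylinder of given radius and height; the center is either a fixed
    point or recomputed per frame from an anchor residue selection's COM."""

    radius: float                      # nm
    height: float                      # nm
    center: np.ndarray | None = None   # (3,) nm; fixed center
    axis: np.ndarray = None            # unit 3-vector, default z
    anchor: tuple | None = None        # (model, [(chain, res_index), ...])

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("radius and height must be positive")
        if self.axis is None:
            self.axis = np.array([0.0, 0.0, 1.0])
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.center is None and self.anchor is None:
            raise ValueError("need a fixed center or an anchor selection")

    def center_at(self, frame_index: int = 0) -> np.ndarray:
        if self.anchor is not None:
            source, residues = self.anchor
            model = source.frame(frame_index) if hasattr(source, "frame") else source
            coms = [model.residue_com(c, r) for c, r in residues]
            return np.mean(coms, axis=0)
        return self.center

    def contains(self, points: np.ndarray, frame_index: int = 0) -> np.ndarray:
        points = np.atleast_2d(points)
        c = self.center_at(frame_index)
        d = points - c
        z = d @ self.axis
        radial = d - np.outer(z, self.axis)
        r = np.linalg.norm(radial, axis=1)
        return (r <= self.radius) & (np.abs(z) <= self.height / 2.0)


@dataclass
class SolventTrajectory:
    """Particle positions per frame with time step and kind labels."""

    positions: np.ndarray      # (n_frames, n_particles, 3) nm
    dt: float                  # ps between frames
    kinds: np.ndarray = None   # (n_particles,) str, e.g. "water" / "ion"
    box: np.ndarray = None     # (3,) nm, optional
    d_true: dict = None        # kind -> ground-truth D (nm^2/ps), optional

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_particles, 3)")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.kinds is None:
            self.kinds = np.full(self.positions.shape[1], "water")
        self.kinds = np.asarray(self.kinds)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def save(self, path) -> None:
        """HDF5 layout: /positions (F,N,3), /dt, /kinds, optional /box,
        /d_true as JSON attribute."""
        import json

        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions", data=self.positions)
            fh.attrs["dt"] = self.dt
            fh.create_dataset("kinds", data=np.char.encode(self.kinds.astype(str)))
            if self.box is not None:
                fh.create_dataset("box", data=self.box)
            if self.d_true:
                fh.attrs["d_true"] = json.dumps(self.d_true)

    @classmethod
    def load(cls, path) -> "SolventTrajectory":
        import json

        import h5py

        with h5py.File(path, "r") as fh:
            pos = fh["positions"][...]
            dt = float(fh.attrs["dt"])
            kinds = np.char.decode(fh["kinds"][...])
            box = fh["box"][...] if "box" in fh else None
            d_true = json.loads(fh.attrs["d_true"]) if "d_true" in fh.attrs else None
        return cls(pos, dt, kinds, box, d_true)


def unwrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image unwrapping: successive displacements are shifted by
    whole box vectors so no single step exceeds half the box."""
    positions = np.asarray(positions, dtype=float)
    steps = np.diff(positions, axis=0)
    steps -= np.round(steps / box) * box
    out = np.concatenate([positions[:1], positions[:1] + np.cumsum(steps, axis=0)])
    return out


def select_in_region(traj: SolventTrajectory, region: CylinderRegion,
                     frame: int, kind: str | None = None) -> np.ndarray:
    """Indices of particles inside the region at the given frame."""
    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range")
    inside = region.contains(traj.positions[frame], frame_index=frame)
    if kind is not None:
        inside &= traj.kinds == kind
    return np.nonzero(inside)[0]


@dataclass
class MSDResult:
    lag_times: np.ndarray        # ps
    msd: np.ndarray              # nm^2, mean over origins/particles(/replicas)
    msd_sd: np.ndarray           # per-lag SD across replicas (0 for single)
    counts: np.ndarray           # particle-origin pairs per lag
    diffusion: float = None      # nm^2/ps, filled by diffusion_coefficient
    diffusion_err: float = None
    fit_range: tuple = None
    slope_warning: bool = False


def mean_square_displacement(trajs, region: CylinderRegion | None = None,
                             max_lag: float | None = None,
                             origin_stride: int = 1, kind: str | None = None,
                             membership: str = "origin") -> MSDResult:
    """MSD(τ) averaged over time origins and particles inside the region at
    the origin frame; replica mean ± SD when several trajectories are given.
    """
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    dt = trajs[0].dt
    if max_lag is None:
        max_lag = (trajs[0].n_frames - 1) * dt / 2
    n_lag = int(round(max_lag / dt))
    if n_lag >= trajs[0].n_frames:
        raise ValueError("max lag exceeds trajectory length")
    if n_lag < 1:
        raise ValueError("max lag shorter than one frame")
    per_replica = []
    counts_total = np.zeros(n_lag + 1)
    for traj in trajs:
        pos = traj.positions
        if traj.box is not None:
            pos = unwrap_positions(pos, traj.box)
        acc = np.zeros(n_lag + 1)
        cnt = np.zeros(n_lag + 1)
        any_selected = False
        for t0 in range(0, traj.n_frames - 1, origin_stride):
            if region is not None:
                sel = select_in_region(traj, region, t0, kind=kind)
            else:
                sel = np.arange(traj.n_particles)
                if kind is not None:
                    sel = sel[traj.kinds[sel] == kind]
            if len(sel) == 0:
                continue
            any_selected = True
            tmax = min(n_lag, traj.n_frames - 1 - t0)
            disp = pos[t0 + 1:t0 + tmax + 1, sel] - pos[t0, sel]
            sq = np.sum(disp ** 2, axis=2)           # (tmax, n_sel)
            if membership == "endpoints" and region is not None:
                ok = np.stack([region.contains(traj.positions[t0 + k + 1, sel],
                                               frame_index=t0 + k + 1)
                               for k in range(tmax)])
                acc[1:tmax + 1] += np.sum(sq * ok, axis=1)
                cnt[1:tmax + 1] += ok.sum(axis=1)
            else:
                acc[1:tmax + 1] += sq.sum(axis=1)
                cnt[1:tmax + 1] += len(sel)
            cnt[0] += len(sel)
        if not any_selected:
            raise ValueError("empty selection at every time origin")
        with np.errstate(invalid="ignore"):
            per_replica.append(np.divide(acc, cnt, out=np.zeros_like(acc),
                                         where=cnt > 0))
        counts_total += cnt
    msd = np.mean(per_replica, axis=0)
    sd = (np.std(per_replica, axis=0, ddof=1) if len(per_replica) > 1
          else np.zeros_like(msd))
    lags = np.arange(n_lag + 1) * dt
    return MSDResult(lags, msd, sd, counts_total)


def diffusion_coefficient(msd: MSDResult, dimensionality: int = 3,
                          fit_range: tuple | None = None) -> MSDResult:
    """Least-squares slope of MSD vs lag over the fit range, divided by
    2·dimensionality (Einstein relation). Default fit range: 10–50% of the
    maximum lag, skipping the short-lag regime."""
    tmax = msd.lag_times[-1]
    if fit_range is None:
        fit_range = (0.1 * tmax, 0.5 * tmax)
    lo, hi = fit_range
    sel = (msd.lag_times >= lo) & (msd.lag_times <= hi)
    if np.sum(sel) < 2:
        raise ValueError("need at least two lags in the fit range")
    x = msd.lag_times[sel]
    y = msd.msd[sel]
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    slope_err = float(np.sqrt(cov[0, 0]))
    if np.any(msd.msd_sd[sel] > 0):
        # propagate replica scatter into the slope uncertainty
        rep_err = float(np.mean(msd.msd_sd[sel]) / (x[-1] - x[0]))
        slope_err = float(np.hypot(slope_err, rep_err))
    d = slope / (2.0 * dimensionality)
    out = MSDResult(msd.lag_times, msd.msd, msd.msd_sd, msd.counts,
                    diffusion=float(d),
                    diffusion_err=slope_err / (2.0 * dimensionality),
                    fit_range=(float(lo), float(hi)),
                    slope_warning=bool(slope <= 0))
    return out
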