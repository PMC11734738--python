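"""Voxel density maps and Gaussian-mixture representations.

A :class:`DensityMap` is a regular grid of density values with an origin and
voxel spacing, all in nm; ``values[i, j, k]`` is the density at the center of
voxel (i, j, k), located at ``origin + (i, j, k) * voxel_size``. Maps are
normalized to x, y, z axis order on load (MRC/CCP4 via gemmi, Å converted to
nm at the boundary).

A :class:`GaussianMixture` holds weighted anisotropic 3D Gaussians and serves
both as the data GMM (fit to an experimental/synthetic map) and the model GMM
(one component per heavy atom of an atomic model). Fitting a map uses
expectation-maximization over density-weighted voxel centers, seeded by
k-means++; rendering, real-space correlation and Fourier shell correlation
close the loop between maps and mixtures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0


class MapFormatError(ValueError):
    """Raised for malformed or unsupported density-map files."""


@dataclass
class DensityMap:
    values: np.ndarray        # (nx, ny, nz) float
    origin: np.ndarray        # (3,) nm, center of voxel (0, 0, 0)
    voxel_size: np.ndarray    # (3,) nm
    axis_order: str = "xyz"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel_size = np.atleast_1d(np.asarray(self.voxel_size, dtype=float))
        if self.voxel_size.size == 1:
            self.voxel_size = np.repeat(self.voxel_size, 3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite map values")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center coordinates, C order."""
        ax = [self.axis_coords(i) for i in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.origin.copy(),
                          self.voxel_size.copy(), self.axis_order)


@dataclass
class GaussianMixture:
    weights: np.ndarray       # (K,) >= 0
    means: np.ndarray         # (K, 3) nm
    covariances: np.ndarray   # (K, 3, 3) nm^2, symmetric positive-definite

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        self.means = np.asarray(self.means, dtype=float).reshape(-1, 3)
        self.covariances = np.asarray(self.covariances, dtype=float).reshape(-1, 3, 3)
        if np.any(self.weights < 0):
            raise ValueError("negative component weight")
        for c in self.covariances:
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariance not positive-definite")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @classmethod
    def isotropic(cls, weights, means, sigma: float) -> "GaussianMixture":
        k = len(weights)
        cov = np.broadcast_to(np.eye(3) * sigma ** 2, (k, 3, 3)).copy()
        return cls(weights, means, cov)

    def density(self, points: np.ndarray) -> np.ndarray:
        """Σ_i w_i N(x; μ_i, Σ_i) at each point, vectorized over components."""
        points = np.atleast_2d(points)
        out = np.zeros(len(points))
        for w, mu, cov in zip(self.weights, self.means, self.covariances):
            out += w * _gauss3(points, mu, cov)
        return out

    def scaled(self, factor: float) -> "GaussianMixture":
        return GaussianMixture(self.weights * factor, self.means, self.covariances)

    @classmethod
    def concatenate(cls, mixtures) -> "GaussianMixture":
        return cls(np.concatenate([g.weights for g in mixtures]),
                   np.concatenate([g.means for g in mixtures]),
                   np.concatenate([g.covariances for g in mixtures]))


def _gauss3(points, mu, cov):
    L = np.linalg.cholesky(cov)
    y = np.linalg.solve(L, (points - mu).T).T
    q = np.sum(y * y, axis=1)
    norm = (2 * np.pi) ** 1.5 * np.prod(np.diag(L))
    return np.exp(-0.5 * q) / norm


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O (gemmi; file coordinates in Å, internal in nm)

def save_mrc(path, dmap: DensityMap) -> None:
    import gemmi

    arr = np.ascontiguousarray(dmap.values, dtype=np.float32)
    grid = gemmi.FloatGrid(arr)
    cell = gemmi.UnitCell(
        dmap.shape[0] * dmap.voxel_size[0] * ANGSTROM_PER_NM,
        dmap.shape[1] * dmap.voxel_size[1] * ANGSTROM_PER_NM,
        dmap.shape[2] * dmap.voxel_size[2] * ANGSTROM_PER_NM,
        90.0, 90.0, 90.0)
    grid.set_unit_cell(cell)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)  # mode 2 = float32
    for i, word in enumerate((50, 51, 52)):
        m.set_header_float(word, float(dmap.origin[i] * ANGSTROM_PER_NM))
    m.write_ccp4_map(str(path))


def load_density_map(path) -> DensityMap:
    """Read an MRC/CCP4 map; axis order normalized, header honored."""
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc
    grid = m.grid
    values = np.array(grid, copy=True, dtype=float)
    cell = grid.unit_cell
    if grid.nu == 0 or grid.nv == 0 or grid.nw == 0:
        raise MapFormatError(f"map {path}: empty grid")
    voxel = np.array([cell.a / grid.nu, cell.b / grid.nv, cell.c / grid.nw])
    if np.any(voxel <= 0):
        raise MapFormatError(f"map {path}: non-positive voxel size {voxel}")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    if not np.all(np.isfinite(origin)):
        raise MapFormatError(f"map {path}: non-finite ORIGIN header {origin}")
    return DensityMap(values, origin / ANGSTROM_PER_NM, voxel / ANGSTROM_PER_NM)


# ---------------------------------------------------------------------------
# GMM serialization: one component per line (w mx my mz cxx cyy czz cxy cxz cyz)

def save_gmm(path, gmm: GaussianMixture, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# fuzzycoat GMM: w mean_x mean_y mean_z "
                 "cov_xx cov_yy cov_zz cov_xy cov_xz cov_yz (nm, nm^2)\n")
        if metadata:
            fh.write("# metadata: " + json.dumps(metadata, sort_keys=True) + "\n")
        for w, mu, c in zip(gmm.weights, gmm.means, gmm.covariances):
            row = [w, *mu, c[0, 0], c[1, 1], c[2, 2], c[0, 1], c[0, 2], c[1, 2]]
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def load_gmm(path) -> GaussianMixture:
    rows = np.atleast_2d(np.loadtxt(path, comments="#"))
    if rows.shape[1] != 10:
        raise MapFormatError(f"GMM table {path}: expected 10 columns, got {rows.shape[1]}")
    w = rows[:, 0]
    means = rows[:, 1:4]
    cov = np.zeros((len(rows), 3, 3))
    cov[:, 0, 0], cov[:, 1, 1], cov[:, 2, 2] = rows[:, 4], rows[:, 5], rows[:, 6]
    cov[:, 0, 1] = cov[:, 1, 0] = rows[:, 7]
    cov[:, 0, 2] = cov[:, 2, 0] = rows[:, 8]
    cov[:, 1, 2] = cov[:, 2, 1] = rows[:, 9]
    return GaussianMixture(w, means, cov)


# ---------------------------------------------------------------------------
# Map operations

def segment_map(dmap: DensityMap, model, cutoff: float) -> DensityMap:
    """Zero out voxels whose centers lie farther than `cutoff` (nm) from
    every atom of `model`; the grid extent is unchanged."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if model.n_atoms == 0:
        raise ValueError("empty model")
    tree = cKDTree(model.coords)
    centers = dmap.voxel_centers()
    dist, _ = tree.query(centers, k=1, distance_upper_bound=cutoff)
    keep = np.isfinite(dist).reshape(dmap.shape)
    out = dmap.copy()
    out.values[~keep] = 0.0
    return out


@dataclass
class GMMFitResult:
    mixture: GaussianMixture
    correlation: float
    n_iter: int
    converged: bool
    log_likelihood: float


def fit_gmm(dmap: DensityMap, n_components: int, seed: int = 0,
            threshold: float = 0.0, max_iter: int = 500,
            tol: float = 1e-6) -> GMMFitResult:
    """Fit a GMM to a density map by weighted EM over voxel centers.

    Voxels with density <= threshold are excluded; negative densities are
    clipped to zero (count logged). Initialization is seeded k-means++ on the
    weighted voxel centers; covariances are full thereafter. Component
    weights are scaled so the mixture integrates to the map's total mass
    (Σ density × voxel volume), making the rendered mixture directly
    comparable to the input map.
    """
    from sklearn.cluster import KMeans

    values = dmap.values.ravel().copy()
    n_neg = int(np.sum(values < 0))
    if n_neg:
        logger.info("fit_gmm: clipping %d negative voxels to zero", n_neg)
        values = np.clip(values, 0.0, None)
    mask = values > threshold
    X = dmap.voxel_centers()[mask]
    w = values[mask]
    if len(X) < n_components:
        raise ValueError(
            f"only {len(X)} voxels above threshold for {n_components} components")
    total_mass = float(w.sum() * dmap.voxel_volume)
    p = w / w.sum()

    km = KMeans(n_clusters=n_components, n_init=1, random_state=seed)
    labels = km.fit_predict(X, sample_weight=w)
    reg = 1e-4 * float(np.min(dmap.voxel_size)) ** 2
    pis = np.zeros(n_components)
    mus = np.array(km.cluster_centers_, dtype=float)
    covs = np.zeros((n_components, 3, 3))
    for k in range(n_components):
        sel = labels == k
        pk = p[sel].sum()
        pis[k] = max(pk, 1e-12)
        if pk > 0:
            d = X[sel] - mus[k]
            covs[k] = (d * p[sel, None]).T @ d / pk
        covs[k] += reg * np.eye(3)
    pis /= pis.sum()

    prev_ll = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step in log space
        log_prob = np.stack([np.log(pis[k]) + _log_gauss3(X, mus[k], covs[k])
                             for k in range(n_components)], axis=1)
        log_norm = _logsumexp(log_prob)
        ll = float(np.sum(p * log_norm))
        resp = np.exp(log_prob - log_norm[:, None])
        # M-step with per-point weights p
        wk = resp * p[:, None]
        nk = wk.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        pis = nk / nk.sum()
        mus = (wk.T @ X) / nk[:, None]
        for k in range(n_components):
            d = X - mus[k]
            covs[k] = (d * wk[:, k, None]).T @ d / nk[k] + reg * np.eye(3)
        if abs(ll - prev_ll) <= tol * max(abs(ll), 1.0):
            converged = True
            break
        prev_ll = ll

    gmm = GaussianMixture(pis * total_mass, mus, covs)
    rendered = render_map_from_gmm(gmm, like=dmap)
    cc = real_space_correlation(rendered, dmap)
    return GMMFitResult(gmm, cc, n_iter, converged, ll)


def _log_gauss3(points, mu, cov):
    L = np.linalg.cholesky(cov)
    y = np.linalg.solve(L, (points - mu).T).T
    q = np.sum(y * y, axis=1)
    return -0.5 * q - 1.5 * np.log(2 * np.pi) - np.log(np.diag(L)).sum()


def _logsumexp(a):
    m = a.max(axis=1)
    return m + np.log(np.sum(np.exp(a - m[:, None]), axis=1))


def grid_for_support(gmm: GaussianMixture, voxel_size: float,
                     n_sigma: float = 3.0) -> DensityMap:
    """Empty map whose grid covers every component mean ± n_sigma·σ_max."""
    sig = np.sqrt(np.max(np.linalg.eigvalsh(gmm.covariances), axis=1))
    lo = (gmm.means - n_sigma * sig[:, None]).min(axis=0)
    hi = (gmm.means + n_sigma * sig[:, None]).max(axis=0)
    vox = np.repeat(float(voxel_size), 3)
    shape = np.maximum(np.ceil((hi - lo) / vox).astype(int) + 1, 2)
    return DensityMap(np.zeros(shape), lo, vox)


def render_map_from_gmm(gmm: GaussianMixture, like: DensityMap | None = None,
                        voxel_size: float | None = None,
                        truncation_sigma: float = 6.0) -> DensityMap:
    """Evaluate Σ_i w_i N(x; μ_i, Σ_i) at voxel centers.

    Components are truncated beyond `truncation_sigma` standard deviations
    (largest covariance eigenvalue) for speed.
    """
    if like is None:
        if voxel_size is None:
            raise ValueError("provide a template map or a voxel size")
        like = grid_for_support(gmm, voxel_size, n_sigma=truncation_sigma / 2)
    out = like.copy()
    out.values = np.zeros_like(like.values)
    ax = [like.axis_coords(i) for i in range(3)]
    shape = like.shape
    for w, mu, cov in zip(gmm.weights, gmm.means, gmm.covariances):
        sig = float(np.sqrt(np.max(np.linalg.eigvalsh(cov))))
        r = truncation_sigma * sig
        sl = []
        for d in range(3):
            i0 = int(np.searchsorted(ax[d], mu[d] - r, side="left"))
            i1 = int(np.searchsorted(ax[d], mu[d] + r, side="right"))
            if i0 >= shape[d] or i1 <= 0:
                sl = None
                break
            sl.append(slice(max(i0, 0), min(i1, shape[d])))
        if sl is None:
            continue
        sub = np.meshgrid(ax[0][sl[0]], ax[1][sl[1]], ax[2][sl[2]], indexing="ij")
        pts = np.stack([g.ravel() for g in sub], axis=1)
        out.values[tuple(sl)] += (w * _gauss3(pts, mu, cov)).reshape(
            [s.stop - s.start for s in sl])
    return out


def real_space_correlation(m1: DensityMap, m2: DensityMap,
                           mask: np.ndarray | None = None) -> float:
    """Pearson correlation of voxel values over the mask (default: voxels
    where either map is positive)."""
    if m1.shape != m2.shape:
        raise ValueError(f"grid mismatch {m1.shape} vs {m2.shape}")
    a, b = m1.values, m2.values
    if mask is None:
        mask = (a > 0) | (b > 0)
    x = a[mask].ravel()
    y = b[mask].ravel()
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance over the mask")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class FSCCurve:
    frequencies: np.ndarray   # shell centers, nm^-1
    correlation: np.ndarray   # per shell, in [-1, 1]
    counts: np.ndarray        # Fourier voxels per shell

    def resolution_at(self, threshold: float = 0.5) -> float:
        """First frequency where FSC drops below `threshold` (nm^-1);
        returns the Nyquist frequency if it never does."""
        below = np.nonzero(self.correlation < threshold)[0]
        if len(below) == 0:
            return float(self.frequencies[-1])
        return float(self.frequencies[below[0]])


def fourier_shell_correlation(m1: DensityMap, m2: DensityMap,
                              n_shells: int | None = None) -> FSCCurve:
    """Normalized cross-correlation of Fourier coefficients in uniform
    frequency shells up to Nyquist. Non-cubic grids are zero-padded."""
    if m1.shape != m2.shape:
        raise ValueError(f"grid mismatch {m1.shape} vs {m2.shape}")
    if not np.allclose(m1.voxel_size, m2.voxel_size):
        raise ValueError("voxel size mismatch")
    a, b = m1.values, m2.values
    n = max(a.shape)
    if a.shape != (n, n, n):
        pa = np.zeros((n, n, n))
        pb = np.zeros((n, n, n))
        pa[:a.shape[0], :a.shape[1], :a.shape[2]] = a
        pb[:b.shape[0], :b.shape[1], :b.shape[2]] = b
        a, b = pa, pb
    vox = float(np.min(m1.voxel_size))
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    freq = np.fft.fftfreq(n, d=vox)
    kx, ky, kz = np.meshgrid(freq, freq, freq, indexing="ij")
    kr = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    nyquist = 1.0 / (2.0 * vox)
    if n_shells is None:
        n_shells = n // 2
    edges = np.linspace(0.0, nyquist, n_shells + 1)
    idx = np.clip(np.digitize(kr.ravel(), edges) - 1, 0, n_shells - 1)
    valid = kr.ravel() <= nyquist
    num = np.bincount(idx[valid], weights=(fa * np.conj(fb)).real.ravel()[valid],
                      minlength=n_shells)
    d1 = np.bincount(idx[valid], weights=(np.abs(fa) ** 2).ravel()[valid],
                     minlength=n_shells)
    d2 = np.bincount(idx[valid], weights=(np.abs(fb) ** 2).ravel()[valid],
                     minlength=n_shells)
    counts = np.bincount(idx[valid], minlength=n_shells)
    denom = np.sqrt(d1 * d2)
    fsc = np.divide(num, denom, out=np.zeros(n_shells), where=denom > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FSCCurve(centers, fsc, counts)
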