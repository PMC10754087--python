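"""Trajectory mode analysis.

Operations on (real or synthetic) protein trajectories:

* rigid-body superposition onto a reference (removal of global motion),
* leading inertia-axis time series with sign-flip correction and its
  component-averaged autocorrelation plus the exponential/cosine fit,
* mass-weighted cartesian PCA with per-mode RMSF and projection ACFs,
* a simplified grid accessible-volume (AV) dye model with flood-fill
  reachability and AV auto/cross-correlations,
* anisotropic network model (ANM) normal modes.

Coordinates are in Angstrom, masses in amu, frame intervals in ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy import ndimage

__all__ = [
    "load_trajectory",
    "Trajectory",
    "PrincipalAxisSeries",
    "RotFit",
    "PCAModel",
    "AVParams",
    "ANMModel",
    "superpose",
    "kabsch",
    "principal_axis_series",
    "rotation_acf",
    "normalized_acf",
    "fit_rotation",
    "cartesian_pca",
    "mode_rmsf",
    "projection_acf",
    "accessible_volume",
    "av_correlation",
    "fit_biexponential",
    "anm_modes",
]


@dataclass
class Trajectory:
    """Frames x particles x 3 coordinates with per-particle metadata."""

    coords: np.ndarray                    # (n_frames, n_atoms, 3), Angstrom
    masses: np.ndarray                    # (n_atoms,), amu
    frame_interval: float                 # ns
    residue_numbers: np.ndarray | None = None
    chain_ids: np.ndarray | None = None
    backbone: np.ndarray | None = None    # bool flags incl. C-beta
    structured: np.ndarray | None = None  # helix/sheet flags

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.size != self.coords.shape[1]:
            raise ValueError("masses must match atom count")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class PrincipalAxisSeries:
    axes: np.ndarray               # (n_frames, 3) unit vectors
    frame_interval: float          # ns
    flips: np.ndarray              # frame indices where the sign was flipped


@dataclass
class RotFit:
    a: float
    tau1: float                    # ns
    b: float
    omega: float                   # 1/ns
    theta: float                   # rad
    r2: float
    tau_single: float
    r2_single: float


@dataclass
class PCAModel:
    mean: np.ndarray               # (n_sel, 3)
    eigenvectors: np.ndarray       # (n_modes, n_sel, 3), mass-weighted basis
    eigenvalues: np.ndarray        # descending, A^2 amu
    projections: np.ndarray        # (n_frames, n_modes)
    masses: np.ndarray             # (n_sel,)
    frame_interval: float
    excluded_residues: tuple[int, int] | None = None
    selection_index: np.ndarray | None = None


@dataclass
class AVParams:
    """Simplified single-sphere dye accessible-volume parameters."""

    attachment: int
    linker_length: float = 20.0    # A
    linker_width: float = 4.5      # A
    dye_radius: float = 3.5        # A
    grid_spacing: float = 0.9      # A
    contact_radius: float = 2.0    # A, effective protein atom radius

    def __post_init__(self) -> None:
        if min(self.linker_length, self.dye_radius, self.grid_spacing) <= 0:
            raise ValueError("linker length, dye radius and grid spacing must be > 0")


@dataclass
class ANMModel:
    coords: np.ndarray
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray        # ascending
    eigenvectors: np.ndarray       # (3n, 3n) columns
    removed_residues: np.ndarray | None = None

    def mode_mobility(self, k: int) -> np.ndarray:
        """Per-node displacement magnitude of mode k (0-based over all 3N)."""
        v = self.eigenvectors[:, k].reshape(-1, 3)
        return np.linalg.norm(v, axis=1)


def load_trajectory(topology, trajectory=None, frame_interval: float = 0.1) -> Trajectory:
    """Read a structure/trajectory (PDB topology + XTC/DCD/...) into a
    Trajectory via MDAnalysis.

    Backbone flags cover protein backbone plus C-beta atoms; masses,
    residue numbers and chain identifiers come from the topology.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(
        str(topology), str(trajectory))
    atoms = u.atoms
    coords = np.array([atoms.positions.copy() for _ in u.trajectory])
    chains = np.array([getattr(a, "segid", "") or getattr(a, "chainID", "") for a in atoms])
    backbone = np.isin(atoms.names, ["N", "CA", "C", "O", "CB"])
    return Trajectory(
        coords,
        atoms.masses.astype(float),
        frame_interval,
        residue_numbers=atoms.resids.astype(int),
        chain_ids=chains,
        backbone=backbone,
    )


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None):
    """Optimal rotation + translation mapping ``mobile`` onto ``reference``.

    Returns (rotation matrix R, translation t) so that mobile @ R.T + t
    minimizes the (weighted) RMSD to reference.
    """
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    h = (w[:, None] * (mobile - mc)).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, d])
    rot = vt.T @ dmat @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose(traj: Trajectory, reference: np.ndarray, selection: np.ndarray | None = None,
              mass_weighted: bool = True) -> Trajectory:
    """Least-squares rigid superposition of every frame onto ``reference``.

    ``selection`` indexes the atoms used for the fit (typically structured
    backbone); the transform is applied to all atoms.
    """
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection)
    if selection.dtype == bool:
        selection = np.flatnonzero(selection)
    if selection.size < 3:
        raise ValueError("superposition needs at least 3 selected particles")
    ref_sel = np.asarray(reference, dtype=float)[selection]
    if mass_weighted:
        w = traj.masses[selection].astype(float)
    else:
        w = np.ones(selection.size)
    w = w / w.sum()

    # batched Kabsch over all frames
    mob = traj.coords[:, selection, :]                     # (n, k, 3)
    mc = np.einsum("k,nki->ni", w, mob)                    # weighted centroids
    rc = w @ ref_sel
    h = np.einsum("k,nki,kj->nij", w, mob - mc[:, None, :], ref_sel - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("nij,nkj->nik", vt.transpose(0, 2, 1), u)))
    vt[:, -1, :] *= d[:, None]
    rot = np.einsum("nji,nkj->nik", vt, u)                 # V @ diag @ U^T per frame
    out = np.einsum("nij,naj->nai", rot, traj.coords - mc[:, None, :]) + rc
    return Trajectory(out, traj.masses, traj.frame_interval,
                      traj.residue_numbers, traj.chain_ids, traj.backbone, traj.structured)


# --------------------------------------------------------------------------
# inertia axis & rotational ACF
# --------------------------------------------------------------------------

def principal_axis_series(traj: Trajectory, flip_threshold: float = 0.5) -> PrincipalAxisSeries:
    """Leading principal axis of the moment of inertia per frame.

    The inertia eigenvector carries no intrinsic sign, so consecutive
    frames can flip direction spuriously; the sign is inverted whenever any
    cartesian component changes by more than ``flip_threshold`` between
    consecutive frames.  Degenerate (near-spherical) tensors are resolved
    by continuity with the previous frame.
    """
    m = traj.masses
    axes = np.empty((traj.n_frames, 3))
    flips = []
    prev = None
    for i in range(traj.n_frames):
        x = traj.coords[i] - np.average(traj.coords[i], axis=0, weights=m)
        r2 = np.sum(x**2, axis=1)
        inertia = np.sum(m * r2) * np.eye(3) - np.einsum("a,ai,aj->ij", m, x, x)
        evals, evecs = np.linalg.eigh(inertia)
        # smallest inertia moment <-> longest axis
        axis = evecs[:, 0]
        if evals.size > 1 and (evals[1] - evals[0]) < 1e-9 * max(evals[-1], 1.0):
            warnings.warn(f"frame {i}: near-degenerate inertia tensor; using continuity")
            if prev is not None:
                # pick the eigenvector (of the degenerate pair) closest to previous
                cands = evecs[:, :2].T
                axis = cands[np.argmax(np.abs(cands @ prev))]
        axis = axis / np.linalg.norm(axis)
        if prev is not None and np.max(np.abs(axis - prev)) > flip_threshold:
            if np.max(np.abs(-axis - prev)) < np.max(np.abs(axis - prev)):
                axis = -axis
                flips.append(i)
        axes[i] = axis
        prev = axis
    return PrincipalAxisSeries(axes, traj.frame_interval, np.array(flips, dtype=int))


def normalized_acf(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Mean-subtracted, variance-normalized autocorrelation of a 1D series.

    Uses the FFT estimator with per-lag overlap normalization (divides by
    the number of overlapping pairs at each lag).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    xc = x - x.mean()
    var = np.mean(xc**2)
    if var <= 0:
        raise ValueError("series has zero variance")
    if max_lag is None:
        max_lag = n - 1
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return acov / counts / var


def rotation_acf(series: PrincipalAxisSeries, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Component-averaged axis autocorrelation.

    Each cartesian component of the axis is mean-subtracted and normalized
    by its variance; the three component ACFs are averaged, so the result
    is exactly 1 at zero lag.  Returns (lags_ns, acf).
    """
    axes = series.axes
    if axes.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if max_lag is None:
        max_lag = axes.shape[0] // 2
    acfs = [normalized_acf(axes[:, i], max_lag) for i in range(3)]
    acf = np.mean(acfs, axis=0)
    lags = np.arange(max_lag + 1) * series.frame_interval
    return lags, acf


def rotation_acf_ensemble(axes_list, frame_interval: float, max_lag: int | None = None):
    """Component-averaged axis ACF over replica trajectories.

    Means and variances per component are pooled over the ensemble (the
    replicas are treated as segments of one stationary series), which
    suppresses the finite-series mean-subtraction bias by 1/n_replicas.
    Returns (lags_ns, mean ACF, standard error over replicas).
    """
    axes = np.asarray(axes_list, dtype=float)
    if axes.ndim == 2:
        axes = axes[None, :, :]
    n_rep, n_frames, _ = axes.shape
    if max_lag is None:
        max_lag = n_frames // 4
    mean = axes.mean(axis=(0, 1))
    var = axes.var(axis=(0, 1))
    if np.any(var <= 0):
        raise ValueError("zero variance in an axis component")
    nfft = int(2 ** np.ceil(np.log2(2 * n_frames)))
    counts = n_frames - np.arange(max_lag + 1)
    per_rep = np.empty((n_rep, max_lag + 1))
    for r in range(n_rep):
        acc = np.zeros(max_lag + 1)
        for i in range(3):
            x = axes[r, :, i] - mean[i]
            f = np.fft.rfft(x, nfft)
            acc += np.fft.irfft(f * np.conj(f))[: max_lag + 1] / counts / var[i]
        per_rep[r] = acc / 3.0
    acf = per_rep.mean(axis=0)
    if n_rep > 1:
        sem = per_rep.std(axis=0, ddof=1) / np.sqrt(n_rep)
    else:
        sem = np.full(max_lag + 1, np.nan)
    lags = np.arange(max_lag + 1) * frame_interval
    return lags, acf, sem


def fit_rotation(lags: np.ndarray, acf: np.ndarray, prefer_threshold: float = 0.05,
                 n_omega_starts: int = 6, weights: np.ndarray | None = None) -> RotFit:
    """Fit the axis ACF with A exp(-tau/tau1) + B cos(2 pi omega tau + theta).

    Also fits a plain single exponential; both R^2 values are reported and
    the cosine model is preferred when its R^2 improves by more than
    ``prefer_threshold``.  Multi-start over omega avoids aliasing onto
    local minima.
    """
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    span = max(lags[-1], 1e-9)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)

    def single(tau, a, tau1):
        return a * np.exp(-tau / tau1)

    m1 = lmfit.Model(single)
    p1 = m1.make_params(a=1.0, tau1=span / 5)
    p1["tau1"].set(min=1e-9)
    r1 = m1.fit(acf, p1, tau=lags, weights=weights)
    ss_tot = np.sum((acf - acf.mean()) ** 2)
    r2_single = 1.0 - np.sum((r1.best_fit - acf) ** 2) / ss_tot

    def model(tau, a, tau1, b, omega, theta):
        return a * np.exp(-tau / tau1) + b * np.cos(2 * np.pi * omega * tau + theta)

    m2 = lmfit.Model(model)
    best = None
    # include a near-zero frequency start: the cosine then acts as a constant
    # offset, which absorbs the finite-series mean-subtraction bias of the ACF
    for om0 in np.concatenate([[1e-4 / span],
                               np.geomspace(0.25 / span, 8.0 / span, n_omega_starts)]):
        p2 = m2.make_params(a=r1.params["a"].value, tau1=r1.params["tau1"].value,
                            b=0.1, omega=om0, theta=0.0)
        p2["tau1"].set(min=1e-9)
        p2["b"].set(min=0.0)
        p2["omega"].set(min=0.0)
        p2["theta"].set(min=-np.pi, max=np.pi)
        try:
            r2 = m2.fit(acf, p2, tau=lags, weights=weights)
        except Exception:
            continue
        if best is None or r2.chisqr < best.chisqr:
            best = r2
    if best is None:
        raise RuntimeError("cosine-model fit failed to converge from all starts")
    r2_full = 1.0 - np.sum((best.best_fit - acf) ** 2) / ss_tot
    return RotFit(
        a=best.params["a"].value,
        tau1=best.params["tau1"].value,
        b=best.params["b"].value,
        omega=best.params["omega"].value,
        theta=best.params["theta"].value,
        r2=r2_full,
        tau_single=r1.params["tau1"].value,
        r2_single=r2_single,
    )


# --------------------------------------------------------------------------
# cartesian PCA
# --------------------------------------------------------------------------

def cartesian_pca(
    traj: Trajectory,
    exclude_residues: tuple[int, int] | None = (208, 280),
    selection: np.ndarray | None = None,
) -> PCAModel:
    """Mass-weighted cartesian PCA of a superposed trajectory.

    Diagonalizes the mass-weighted covariance of the selected coordinates
    (by default backbone + C-beta flags when present, all atoms otherwise),
    excluding the configured flexible-loop residue range.  Eigenvectors are
    orthonormal in the mass-weighted basis; eigenvalues (A^2 amu) are
    sorted descending and sum to the total weighted variance.
    """
    if selection is None:
        if traj.backbone is not None:
            selection = np.flatnonzero(np.asarray(traj.backbone, dtype=bool))
        else:
            selection = np.arange(traj.n_atoms)
    else:
        selection = np.asarray(selection)
        if selection.dtype == bool:
            selection = np.flatnonzero(selection)
    if exclude_residues is not None and traj.residue_numbers is not None:
        lo, hi = exclude_residues
        resn = np.asarray(traj.residue_numbers)[selection]
        selection = selection[(resn < lo) | (resn > hi)]

    x = traj.coords[:, selection, :]
    n_frames, n_sel, _ = x.shape
    if n_frames < 3 * n_sel:
        warnings.warn("fewer frames than coordinate dimensions; covariance is rank-deficient")
    m = traj.masses[selection]
    sqrtm = np.sqrt(m)
    mean = x.mean(axis=0)
    dx = (x - mean) * sqrtm[None, :, None]
    flat = dx.reshape(n_frames, 3 * n_sel)
    cov = flat.T @ flat / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = flat @ evecs
    return PCAModel(
        mean=mean,
        eigenvectors=evecs.T.reshape(-1, n_sel, 3),
        eigenvalues=evals,
        projections=projections,
        masses=m,
        frame_interval=traj.frame_interval,
        excluded_residues=exclude_residues,
        selection_index=selection,
    )


def mode_rmsf(model: PCAModel, k: int) -> np.ndarray:
    """Per-atom RMSF of mode k in real (unweighted) coordinates.

    RMSF_k(atom) = sqrt(lambda_k) |v_k(atom)| / sqrt(m_atom).
    """
    if not 0 <= k < model.eigenvalues.size:
        raise IndexError("mode index out of range")
    amp = np.linalg.norm(model.eigenvectors[k], axis=1)
    return np.sqrt(model.eigenvalues[k]) * amp / np.sqrt(model.masses)


def projection_acf(model: PCAModel, k: int, max_lag: int | None = None):
    """Normalized ACF of the mode-k projection and a single-exponential
    decay time estimate (ns). Returns (lags_ns, acf, tau_ns)."""
    if not 0 <= k < model.projections.shape[1]:
        raise IndexError("mode index out of range")
    p = model.projections[:, k]
    if max_lag is None:
        max_lag = p.size // 4
    acf = normalized_acf(p, max_lag)
    lags = np.arange(max_lag + 1) * model.frame_interval

    m = lmfit.Model(lambda tau, tau_c: np.exp(-tau / tau_c))
    params = m.make_params(tau_c=max(lags[-1] / 5, model.frame_interval))
    params["tau_c"].set(min=1e-9)
    res = m.fit(acf, params, tau=lags)
    return lags, acf, res.params["tau_c"].value


# --------------------------------------------------------------------------
# accessible volume
# --------------------------------------------------------------------------

def accessible_volume(coords: np.ndarray, params: AVParams) -> float:
    """Simplified grid accessible volume (A^3) of a tethered dye.

    Counts grid cells within the linker length of the attachment atom that
    do not clash with any protein atom (dye radius + contact radius) and
    that are geodesically reachable from the attachment through unclashed
    cells (26-connected flood fill).  The attachment atom itself is not
    treated as an obstacle.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not 0 <= params.attachment < len(coords):
        raise IndexError("attachment particle does not exist")
    if params.grid_spacing > params.dye_radius:
        warnings.warn("grid spacing exceeds dye radius; AV will be inaccurate")
    origin = coords[params.attachment]
    L = params.linker_length
    h = params.grid_spacing
    n = int(np.ceil(L / h))
    ax = np.arange(-n, n + 1) * h
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)                  # (m,m,m,3) rel. to origin
    within = np.sum(pts**2, axis=-1) <= L**2

    others = np.delete(coords, params.attachment, axis=0)
    clash_r2 = (params.dye_radius + params.contact_radius) ** 2
    free = within.copy()
    if len(others):
        rel = others - origin
        # only atoms that can reach the grid matter
        near = rel[np.sum(rel**2, axis=1) <= (L + params.dye_radius + params.contact_radius) ** 2]
        flat = pts.reshape(-1, 3)
        occ = np.zeros(flat.shape[0], dtype=bool)
        for atom in near:
            occ |= np.sum((flat - atom) ** 2, axis=1) <= clash_r2
        free &= ~occ.reshape(free.shape)

    # flood fill from the attachment cell
    labels, _ = ndimage.label(free, structure=np.ones((3, 3, 3), dtype=int))
    center = (n, n, n)
    lab = labels[center]
    if lab == 0:
        # attachment cell itself clashes; seed from nearest free cell within one dye radius
        idx = np.argwhere(free)
        if idx.size == 0:
            return 0.0
        d2 = np.sum((idx - np.array(center)) ** 2, axis=1)
        if d2.min() * h**2 > params.dye_radius**2:
            return 0.0
        lab = labels[tuple(idx[np.argmin(d2)])]
    return float(np.count_nonzero(labels == lab)) * h**3


def av_series(traj: Trajectory, params: AVParams) -> np.ndarray:
    """Accessible volume per frame (A^3)."""
    return np.array([accessible_volume(traj.coords[i], params) for i in range(traj.n_frames)])


def fit_biexponential(lags: np.ndarray, acf: np.ndarray, min_lag: float | None = None):
    """Unconstrained two-exponential fit a1 e^{-t/t1} + a2 e^{-t/t2}.

    Returns dict with amplitudes/times sorted slow-first plus a flag for
    components faster than the sampling interval (unresolved).
    """
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    span = max(lags[-1], 1e-9)
    dt = lags[1] - lags[0] if lags.size > 1 else span

    def model(t, a1, t1, a2, t2):
        return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)

    m = lmfit.Model(model)
    best = None
    scale = float(np.max(np.abs(acf))) or 1.0
    for a20, f1, f2 in [(0.5, 0.5, 0.05), (0.5, 0.3, 0.01), (0.0, 0.5, 0.02)]:
        p = m.make_params(a1=(1 - a20) * scale, t1=span * f1,
                          a2=a20 * scale, t2=span * f2)
        for name in ("t1", "t2"):
            p[name].set(min=dt * 1e-3)
        # amplitudes bounded near the data scale to exclude the degenerate
        # equal-time, opposite-sign solutions of single-exponential inputs
        for name in ("a1", "a2"):
            p[name].set(min=-2 * scale, max=2 * scale)
        try:
            r = m.fit(acf, p, t=lags)
        except Exception:
            continue
        if best is None or r.chisqr < best.chisqr:
            best = r
    if best is None:
        raise RuntimeError("bi-exponential fit did not converge")
    a1, t1 = best.params["a1"].value, best.params["t1"].value
    a2, t2 = best.params["a2"].value, best.params["t2"].value
    if t1 < t2:
        a1, t1, a2, t2 = a2, t2, a1, t1
    return {
        "amp_slow": a1, "tau_slow": t1,
        "amp_fast": a2, "tau_fast": t2,
        "fast_unresolved": bool(t2 < dt),
    }


def av_correlation(series_a: np.ndarray, series_b: np.ndarray | None = None,
                   frame_interval: float = 0.1, max_lag: int | None = None):
    """Normalized auto- or cross-correlation of AV time series + bi-exp fit.

    Cross-correlations are normalized by the geometric mean of the two
    variances.  Returns (lags_ns, correlation, fit dict).
    """
    a = np.asarray(series_a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 frames")
    if max_lag is None:
        max_lag = a.size // 4
    if series_b is None or series_b is series_a:
        corr = normalized_acf(a, max_lag)
    else:
        b = np.asarray(series_b, dtype=float)
        if b.size != a.size:
            raise ValueError("series lengths differ")
        ac = a - a.mean()
        bc = b - b.mean()
        va, vb = np.mean(ac**2), np.mean(bc**2)
        if va <= 0 or vb <= 0:
            raise ValueError("constant series")
        n = a.size
        corr = np.array([
            np.mean(ac[: n - k] * bc[k:]) for k in range(max_lag + 1)
        ]) / np.sqrt(va * vb)
    lags = np.arange(max_lag + 1) * frame_interval
    fit = fit_biexponential(lags, corr)
    return lags, corr, fit


# --------------------------------------------------------------------------
# anisotropic network model
# --------------------------------------------------------------------------

def anm_modes(coords: np.ndarray, cutoff: float = 15.0, gamma: float = 1.0,
              removed_residues: np.ndarray | None = None) -> ANMModel:
    """Anisotropic network model normal modes of a coarse-grained structure.

    Builds the standard 3N x 3N ANM Hessian with uniform springs between
    nodes within ``cutoff`` and diagonalizes it.  A connected network has
    exactly 6 near-zero rigid-body eigenvalues.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = np.sum(diff**2, axis=-1)
    contact = (dist2 <= cutoff**2) & ~np.eye(n, dtype=bool)

    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph

    ncomp, _ = csgraph.connected_components(sp.csr_matrix(contact))
    if ncomp > 1:
        warnings.warn(f"elastic network is disconnected ({ncomp} components)")

    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.flatnonzero(contact[i]):
            if j <= i:
                continue
            d = diff[i, j]
            d2 = dist2[i, j]
            block = -gamma * np.outer(d, d) / d2
            hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
            hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
            hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block

    evals, evecs = np.linalg.eigh(hessian)
    evals = np.where(np.abs(evals) < 1e-12 * max(abs(evals[-1]), 1.0), 0.0, evals)
    return ANMModel(coords, cutoff, gamma, evals, evecs, removed_residues)
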