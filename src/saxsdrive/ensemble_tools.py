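"""Ensemble-level statistics: chi^2, KL divergence, maximum-entropy
reweighting of conformational pools, and RMSD-based clustering.

A conformational ensemble is a weighted collection of frames, optionally
carrying one scattering curve per frame so that the weighted-mean curve
can be compared or fitted to a target.  Reweighting follows the maximum
entropy principle: among all weightings that reproduce the target curve
on average, prefer the one closest (minimal Kullback-Leibler divergence)
to the reference weights.  In practice this is a penalised trade-off,

    minimise  chi^2(weighted mean curve) / 2 + theta * D_KL(w || w0),

with the regularisation strength theta sweeping out a monotone
chi^2-vs-D_KL curve; theta -> 0 fits the data alone and theta -> inf
returns the reference weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InputError, SolverError

__all__ = [
    "Ensemble",
    "ClusterAssignment",
    "chi2",
    "kl_divergence",
    "maxent_reweight",
    "theta_lcurve",
    "cluster",
    "superpose_rmsd",
    "rmsd_matrix",
]


@dataclass
class Ensemble:
    """Weighted frame collection with optional per-frame scattering curves."""

    frames: np.ndarray                      # (F, N, 3)
    weights: np.ndarray | None = None       # (F,), sums to 1
    q: np.ndarray | None = None             # shared q grid of the profiles
    profiles: np.ndarray | None = None      # (F, nq)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InputError("frames must be a non-empty (F, N, 3) array")
        f = self.frames.shape[0]
        if self.weights is None:
            self.weights = np.full(f, 1.0 / f)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (f,) or np.any(self.weights < 0):
                raise InputError("weights must be non-negative, one per frame")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise InputError("weights must sum to 1 (tolerance 1e-9)")
        if self.profiles is not None:
            self.profiles = np.asarray(self.profiles, dtype=float)
            if self.profiles.shape[0] != f:
                raise InputError("need one profile per frame")
            if self.q is not None and self.profiles.shape[1] != np.size(self.q):
                raise InputError("profile grids must match q")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mean_profile(self, weights: np.ndarray | None = None) -> np.ndarray:
        if self.profiles is None:
            raise InputError("ensemble carries no per-frame profiles")
        w = self.weights if weights is None else np.asarray(weights, dtype=float)
        return w @ self.profiles


@dataclass
class ClusterAssignment:
    """Per-frame cluster labels with representative centers.

    Labels are canonical: clusters ordered by descending size, ties by
    lowest member index, so the labelling is invariant (up to this
    canonical form) under frame reordering.
    """

    labels: np.ndarray
    centers: np.ndarray
    cutoff: float
    method: str

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def chi2(I_com: np.ndarray, I_exp: np.ndarray, sigma: np.ndarray) -> float:
    """Error-weighted reduced chi^2 between two curves.

    chi^2 = 1/(n-1) sum_i ((I_exp_i - I_com_i) / sigma_i)^2
    """
    I_com = np.asarray(I_com, dtype=float)
    I_exp = np.asarray(I_exp, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (I_com.shape == I_exp.shape == sigma.shape):
        raise InputError("chi2 inputs must share one grid")
    n = I_com.shape[0]
    if n < 2:
        raise InputError("chi2 needs at least 2 points")
    if np.any(sigma <= 0):
        raise InputError("sigma must be positive")
    return float(np.sum(((I_exp - I_com) / sigma) ** 2) / (n - 1))


def kl_divergence(w_b: np.ndarray, w_ub: np.ndarray) -> float:
    """Kullback-Leibler divergence D_KL(w_b || w_ub), with 0 ln 0 = 0."""
    w_b = np.asarray(w_b, dtype=float)
    w_ub = np.asarray(w_ub, dtype=float)
    if w_b.shape != w_ub.shape:
        raise InputError("weight vectors must have equal length")
    support = w_b > 0
    if np.any(w_ub[support] <= 0):
        raise InputError("w_ub must be positive wherever w_b is positive")
    return float(np.sum(w_b[support] * np.log(w_b[support] / w_ub[support])))


def maxent_reweight(ensemble: Ensemble, target, theta: float = 0.0,
                    reference_weights: np.ndarray | None = None,
                    max_iter: int = 2000) -> tuple[np.ndarray, dict]:
    """Maximum-entropy reweighting of a precomputed pool against a target curve.

    Minimises chi^2(weighted mean profile)/2 + theta * D_KL(w || w0)
    over the simplex, parameterised by logits (softmax), solved with
    L-BFGS.  Returns (weights, diagnostics) where the diagnostics carry
    the final chi^2, the divergence from the reference weights and from
    uniform, and solver metadata.
    """
    if ensemble.profiles is None:
        raise InputError("reweighting needs per-frame profiles")
    if theta < 0:
        raise InputError("theta must be non-negative")
    if target.sigma is None:
        raise InputError("target profile needs a sigma column")
    I_exp = np.asarray(target.intensity, dtype=float)
    sigma = np.asarray(target.sigma, dtype=float)
    P = ensemble.profiles
    if P.shape[1] != I_exp.shape[0]:
        raise InputError("target grid does not match the per-frame profiles")
    f = ensemble.n_frames
    w0 = (np.full(f, 1.0 / f) if reference_weights is None
          else np.asarray(reference_weights, dtype=float))
    if np.any(w0 <= 0) or abs(w0.sum() - 1.0) > 1e-9:
        raise InputError("reference weights must be positive and sum to 1")
    n = I_exp.shape[0]
    inv_var = 1.0 / sigma ** 2
    log_w0 = np.log(w0)

    def objective(z: np.ndarray) -> tuple[float, np.ndarray]:
        z = z - z.max()
        ez = np.exp(z)
        w = ez / ez.sum()
        mean = w @ P
        resid = mean - I_exp
        chi = np.sum(resid ** 2 * inv_var) / (n - 1)
        kl = np.sum(w * (np.log(w) - log_w0))
        val = 0.5 * chi + theta * kl
        dval_dw = (P @ (resid * inv_var)) / (n - 1) \
            + theta * (np.log(w) - log_w0 + 1.0)
        grad = w * (dval_dw - np.dot(w, dval_dw))   # softmax Jacobian
        return float(val), grad

    res = minimize(objective, np.zeros(f), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12})
    z = res.x - res.x.max()
    w = np.exp(z)
    w /= w.sum()
    mean = w @ P
    chi_final = chi2(mean, I_exp, sigma)
    grad_norm = float(np.linalg.norm(res.jac))
    if not res.success and grad_norm > 1e-6:
        raise SolverError(
            f"maxent reweighting did not converge: {res.message} "
            f"(|grad| = {grad_norm:.3g}, last chi2 = {chi_final:.3g})")
    diagnostics = {
        "chi2": chi_final,
        "kl": kl_divergence(w, w0),
        "kl_uniform": kl_divergence(w, np.full(f, 1.0 / f)),
        "theta": theta,
        "n_iter": int(res.nit),
        "grad_norm": grad_norm,
    }
    return w, diagnostics


def theta_lcurve(ensemble: Ensemble, target,
                 thetas: np.ndarray | None = None) -> tuple[float, dict]:
    """Pick theta at the knee of the chi^2-vs-D_KL trade-off curve.

    The knee is the sweep point farthest from the chord joining the two
    endpoints of the (log chi^2, D_KL) curve — a standard L-curve
    criterion.  Returns (theta, sweep diagnostics).
    """
    if thetas is None:
        thetas = np.logspace(-4, 2, 13)
    chis, kls = [], []
    for th in thetas:
        _, diag = maxent_reweight(ensemble, target, theta=float(th))
        chis.append(diag["chi2"])
        kls.append(diag["kl"])
    chis = np.asarray(chis)
    kls = np.asarray(kls)
    x = np.log10(np.maximum(chis, 1e-300))
    y = kls
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        idx = len(thetas) // 2
    else:
        pts = np.column_stack([x, y]) - p0
        dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
        idx = int(np.argmax(dist))
    return float(thetas[idx]), {"thetas": np.asarray(thetas), "chi2": chis,
                                "kl": kls, "knee_index": idx}


def superpose_rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
                   weights: np.ndarray | None = None
                   ) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimal RMSD of ``frame_b`` onto ``frame_a`` over rigid transforms.

    Kabsch solution via SVD (proper rotation enforced).  Returns
    (rmsd, rotation, translation) such that frame_b @ R.T + t best
    matches frame_a.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError("frames must be matching (N, 3) arrays")
    n = a.shape[0]
    w = (np.full(n, 1.0 / n) if weights is None
         else np.asarray(weights, dtype=float) / np.sum(weights))
    ca = w @ a
    cb = w @ b
    a0 = a - ca
    b0 = b - cb
    h = (b0 * w[:, None]).T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    b_fit = b0 @ rot.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (b_fit - a0) ** 2)))
    trans = ca - cb @ rot.T
    return rmsd, rot, trans


def rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise minimal RMSDs after superposition."""
    frames = np.asarray(frames, dtype=float)
    f = frames.shape[0]
    mat = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            mat[i, j] = mat[j, i] = superpose_rmsd(frames[i], frames[j])[0]
    return mat


def _canonicalize(groups: list[np.ndarray], centers: list[int],
                  n_frames: int, cutoff: float, method: str) -> ClusterAssignment:
    order = sorted(range(len(groups)),
                   key=lambda g: (-len(groups[g]), int(np.min(groups[g]))))
    labels = np.empty(n_frames, dtype=int)
    new_centers = np.empty(len(groups), dtype=int)
    for new_id, g in enumerate(order):
        labels[groups[g]] = new_id
        new_centers[new_id] = centers[g]
    return ClusterAssignment(labels, new_centers, cutoff, method)


def cluster(frames: np.ndarray, cutoff: float,
            method: str = "gromos",
            precomputed: np.ndarray | None = None) -> ClusterAssignment:
    """Cluster frames by pairwise minimal RMSD.

    ``gromos``: repeatedly take the frame with the most neighbours
    within the cutoff as a cluster center (ties broken by lowest frame
    index), assign its neighbourhood, remove, repeat.
    ``single_linkage``: connected components of the graph joining frames
    at RMSD <= cutoff; centers are the medoids (lowest index on ties).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise InputError("frames must be a non-empty (F, N, 3) array")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    f = frames.shape[0]
    dmat = rmsd_matrix(frames) if precomputed is None else np.asarray(precomputed)
    adj = dmat <= cutoff
    np.fill_diagonal(adj, True)

    groups: list[np.ndarray] = []
    centers: list[int] = []
    if method == "gromos":
        remaining = np.arange(f)
        sub = adj.copy()
        while remaining.size:
            counts = sub[np.ix_(remaining, remaining)].sum(axis=1)
            best = int(remaining[np.argmax(counts)])  # argmax ties -> lowest index
            members = remaining[sub[best, remaining]]
            groups.append(members)
            centers.append(best)
            keep = ~np.isin(remaining, members)
            remaining = remaining[keep]
    elif method == "single_linkage":
        n_comp, comp = connected_components(csr_matrix(adj), directed=False)
        for cid in range(n_comp):
            members = np.nonzero(comp == cid)[0]
            sub = dmat[np.ix_(members, members)]
            medoid = members[int(np.argmin(sub.sum(axis=1)))]
            groups.append(members)
            centers.append(int(medoid))
    else:
        raise InputError(f"unknown clustering method: {method!r}")
    return _canonicalize(groups, centers, f, cutoff, method)
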