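"""Uncertainty-weighted SAXS coupling energy and its analytic forces.

The hybrid Hamiltonian of an experiment-driven run is E_FF + E_SAXS,
where the coupling term penalises deviation of the (memory-averaged)
computed curve from the target:

    E_SAXS = alpha(t) * k_c * kT / n_q * sum_i (I_com(q_i) - I_exp(q_i))^2 / sigma^2(q_i)

sigma^2 combines the experimental error, the statistical error of the
computed curve and a systematic buffer-density term in quadrature.  In
the parallel-replica (maximum-entropy) variant the same penalty acts on
the replica-mean curve with prefactor k_c * N^Omega (Omega = 1 by
default), so the data are satisfied by the ensemble average rather than
by every replica individually.

Forces are the exact negative gradient of the energy through either the
Debye intensity map (default, exact orientational average) or the
discrete direction-set estimator.  When least-squares intensity-scale
matching is enabled the scale factor is optimal at evaluation time, so
by the envelope theorem its implicit coordinate dependence drops out of
the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import ConfigError, InputError
from .scatter_core import FormFactorTable, ParticleSystem, QVectorSet

__all__ = [
    "RestraintConfig",
    "ErrorModel",
    "MemoryAverage",
    "switch_alpha",
    "update_memory",
    "scale_factor",
    "saxs_energy",
    "replica_saxs_energy",
    "saxs_forces",
    "shannon_nq",
]


@dataclass
class RestraintConfig:
    """All tunable parameters of the SAXS coupling term.

    k_c : dimensionless weight of the coupling potential relative to the
        force field (0.5 suits a well-structured single-replica target,
        1.0 a flexible multi-replica one).
    n_q : number of restrained q points (equally spaced over the target
        range; the Shannon channel count is a lower bound).
    tau : memory time for the exponentially decaying intensity average,
        in simulation time units.
    t_switch : ramp interval of the switch function alpha(t).
    omega : replica exponent; 1 recovers the optimal ensemble as the
        replica count grows.
    n_replicas : number of parallel replicas N.
    q_max : upper restraint cutoff in 1/A.
    sigma_buffer_frac : relative solvent-density uncertainty contributing
        sigma_buffer = frac * I_exp (default 0.5%).
    scale_matching : least-squares fit of the computed curve's overall
        scale onto the target before the penalty is evaluated.
    chi2_threshold : frame-admission chi^2 for the output pool.
    """

    k_c: float = 0.5
    n_q: int = 50
    tau: float = 2.0          # 100 default-size time steps
    t_switch: float = 0.0
    omega: float = 1.0
    n_replicas: int = 1
    q_max: float = 0.315
    sigma_buffer_frac: float = 0.005
    scale_matching: bool = True
    chi2_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.k_c < 0:
            raise ConfigError("k_c must be non-negative")
        if self.n_q < 2:
            raise ConfigError("n_q must be at least 2")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.t_switch < 0:
            raise ConfigError("t_switch must be non-negative")
        if self.n_replicas < 1:
            raise ConfigError("n_replicas must be at least 1")
        if self.sigma_buffer_frac < 0:
            raise ConfigError("sigma_buffer_frac must be non-negative")


@dataclass
class ErrorModel:
    """Per-q error budget: experimental, computed-curve and buffer terms."""

    sigma_exp: np.ndarray
    sigma_com: np.ndarray | None = None
    sigma_buffer: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma_exp = np.asarray(self.sigma_exp, dtype=float)
        if self.sigma_com is not None:
            self.sigma_com = np.asarray(self.sigma_com, dtype=float)
        if self.sigma_buffer is not None:
            self.sigma_buffer = np.asarray(self.sigma_buffer, dtype=float)

    @classmethod
    def from_target(cls, I_exp: np.ndarray, sigma_exp: np.ndarray,
                    cfg: RestraintConfig) -> "ErrorModel":
        """Build the default budget: experimental sigma plus the
        systematic buffer term sigma_buffer_frac * I_exp; the statistical
        error of the computed curve defaults to zero (pluggable)."""
        return cls(sigma_exp=np.asarray(sigma_exp, dtype=float),
                   sigma_com=None,
                   sigma_buffer=cfg.sigma_buffer_frac * np.asarray(I_exp, dtype=float))

    def variance(self) -> np.ndarray:
        var = self.sigma_exp ** 2
        if self.sigma_com is not None:
            var = var + self.sigma_com ** 2
        if self.sigma_buffer is not None:
            var = var + self.sigma_buffer ** 2
        if np.any(var <= 0):
            raise ConfigError("combined sigma^2 must be positive at every restrained q")
        return var


@dataclass
class MemoryAverage:
    """Exponentially decaying running average of on-the-fly intensities.

    Weights are w_k proportional to exp(-age_k / tau); the average is a
    convex combination of every submitted curve, with recent curves
    weighted most.
    """

    tau: float
    current: np.ndarray | None = None
    weight_sum: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InputError("tau must be positive")

    @property
    def newest_weight(self) -> float:
        """Normalized weight carried by the most recent submission."""
        if self.weight_sum == 0.0:
            return 1.0
        return 1.0 / self.weight_sum

    def copy(self) -> "MemoryAverage":
        cur = None if self.current is None else self.current.copy()
        return MemoryAverage(self.tau, cur, self.weight_sum)


def update_memory(avg: MemoryAverage, I_new: np.ndarray, dt: float) -> MemoryAverage:
    """Fold a new instantaneous curve into the memory average.

    ``dt`` is the age increment applied to everything already stored;
    the decay factor is exp(-dt / tau).  Updates in place and returns
    the same object.
    """
    if dt <= 0:
        raise InputError("dt must be positive")
    I_new = np.asarray(I_new, dtype=float)
    if avg.current is None:
        avg.current = I_new.copy()
        avg.weight_sum = 1.0
        return avg
    if I_new.shape != avg.current.shape:
        raise InputError("intensity grid mismatch in memory update")
    decay = float(np.exp(-dt / avg.tau))
    wsum = avg.weight_sum * decay
    avg.current = (avg.current * wsum + I_new) / (wsum + 1.0)
    avg.weight_sum = wsum + 1.0
    return avg


def switch_alpha(t: float, t_switch: float) -> float:
    """Linear ramp turning on the coupling: min(t / t_switch, 1)."""
    if t < 0:
        raise InputError("time must be non-negative")
    if t_switch < 0:
        raise InputError("t_switch must be non-negative")
    if t_switch == 0:
        return 1.0
    return min(t / t_switch, 1.0)


def scale_factor(I_com: np.ndarray, I_exp: np.ndarray,
                 variance: np.ndarray) -> float:
    """Least-squares scale c minimising sum (c I_com - I_exp)^2 / sigma^2."""
    num = float(np.sum(I_com * I_exp / variance))
    den = float(np.sum(I_com * I_com / variance))
    if den == 0.0:
        raise InputError("computed intensity is identically zero; cannot scale")
    return num / den


def _energy_core(I_model: np.ndarray, I_exp: np.ndarray, err: ErrorModel,
                 alpha: float, kT: float, prefactor_kc: float, n_q: int,
                 scale_matching: bool) -> tuple[float, float, np.ndarray]:
    """Shared kernel: returns (energy, scale c, dE/dI_model)."""
    var = err.variance()
    I_model = np.asarray(I_model, dtype=float)
    I_exp = np.asarray(I_exp, dtype=float)
    if I_model.shape != I_exp.shape or I_model.shape[0] != var.shape[0]:
        raise InputError("restrained arrays must share one grid")
    c = scale_factor(I_model, I_exp, var) if scale_matching else 1.0
    resid = c * I_model - I_exp
    pref = alpha * prefactor_kc * kT / n_q
    energy = pref * float(np.sum(resid ** 2 / var))
    # optimal c makes dc/dI terms vanish (envelope theorem)
    grad = pref * 2.0 * c * resid / var
    return energy, c, grad


def saxs_energy(I_com: np.ndarray, I_exp: np.ndarray, err: ErrorModel,
                alpha: float, cfg: RestraintConfig, kT: float) -> float:
    """Single-replica coupling energy (non-negative; zero iff exact match)."""
    n_q = np.asarray(I_com).shape[0]
    energy, _, _ = _energy_core(I_com, I_exp, err, alpha, kT,
                                cfg.k_c, n_q, cfg.scale_matching)
    return energy


def replica_saxs_energy(profiles: Sequence[np.ndarray], I_exp: np.ndarray,
                        err: ErrorModel, alpha: float, cfg: RestraintConfig,
                        kT: float) -> float:
    """Replica-averaged coupling energy on the mean curve.

    The penalty acts on I_mean = (1/N) sum_beta I_beta with prefactor
    k_c N^Omega; for N = 1 this is exactly :func:`saxs_energy`.
    """
    if len(profiles) != cfg.n_replicas:
        raise InputError(
            f"expected {cfg.n_replicas} replica profiles, got {len(profiles)}")
    stack = np.asarray([np.asarray(p, dtype=float) for p in profiles])
    if stack.ndim != 2:
        raise InputError("replica profiles must share one q grid")
    mean_profile = stack.mean(axis=0)
    n_q = mean_profile.shape[0]
    pref_kc = cfg.k_c * cfg.n_replicas ** cfg.omega
    energy, _, _ = _energy_core(mean_profile, I_exp, err, alpha, kT,
                                pref_kc, n_q, cfg.scale_matching)
    return energy


def _intensity_and_gradient(system: ParticleSystem, ff: FormFactorTable,
                            qgrid: np.ndarray,
                            qvectors: QVectorSet | None) -> tuple[np.ndarray, np.ndarray]:
    """Intensity on ``qgrid`` and its coordinate gradient.

    Returns (I, dI) with dI of shape (nq, N, 3).  ``qvectors=None``
    differentiates the exact Debye average; otherwise the discrete
    direction-set estimator is differentiated.
    """
    coords = system.coordinates
    n = system.n_particles
    qgrid = np.atleast_1d(np.asarray(qgrid, dtype=float))
    f = ff.evaluate(system.labels, qgrid)  # (nq, N)
    if qvectors is None:
        disp = coords[:, None, :] - coords[None, :, :]          # (N, N, 3)
        rmat = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
        inten = np.empty(qgrid.size)
        grad = np.zeros((qgrid.size, n, 3))
        with np.errstate(divide="ignore", invalid="ignore"):
            unit = np.where(rmat[:, :, None] > 0, disp / rmat[:, :, None], 0.0)
        for i, q in enumerate(qgrid):
            x = q * rmat
            sinc = np.sinc(x / np.pi)
            fpair = np.outer(f[i], f[i])
            inten[i] = float(np.sum(fpair * sinc))
            if q == 0.0:
                continue  # intensity stationary at q = 0
            # d sinc(qr)/dr = q (cos(qr) - sinc(qr)) / (qr); zero at r = 0
            with np.errstate(divide="ignore", invalid="ignore"):
                dker = np.where(x > 0, q * (np.cos(x) - sinc) / x, 0.0)
            # dI/dr_j = 2 sum_k f_j f_k dker_jk * unit_jk
            grad[i] = 2.0 * np.sum((fpair * dker)[:, :, None] * unit, axis=1)
        return inten, grad
    dirs = qvectors.directions                                   # (M, 3)
    proj = dirs @ coords.T                                       # (M, N)
    m = dirs.shape[0]
    inten = np.empty(qgrid.size)
    grad = np.empty((qgrid.size, n, 3))
    for i, q in enumerate(qgrid):
        phase = np.exp(-1j * q * proj)                           # (M, N)
        amp = phase @ f[i]                                       # (M,)
        inten[i] = float(np.mean(np.abs(amp) ** 2))
        # d|A_d|^2/dr_j = 2 q f_j Im[conj(A_d) e^{-i q u_d.r_j}] u_d
        w = np.imag(np.conj(amp)[:, None] * phase) * f[i]        # (M, N)
        grad[i] = (2.0 * q / m) * (w.T @ dirs)                   # (N, 3)
    return inten, grad


def saxs_forces(system: ParticleSystem, ff: FormFactorTable,
                qvectors: QVectorSet | None, I_exp: np.ndarray,
                err: ErrorModel, alpha: float, cfg: RestraintConfig,
                kT: float, qgrid: np.ndarray,
                memory: MemoryAverage | None = None
                ) -> tuple[np.ndarray, float]:
    """Analytic restraint forces -dE_SAXS/dr on the current configuration.

    When a memory average is supplied it is updated conceptually by the
    caller; here the average's stored curve is used for the residual and
    the current configuration contributes with its normalized newest
    weight, which scales the gradient accordingly.  Returns
    (forces (N, 3), energy).  The pairwise intensity model makes the net
    force exactly zero; with the exact Debye average the net torque
    about the centroid vanishes as well.
    """
    I_inst, dI = _intensity_and_gradient(system, ff, qgrid, qvectors)
    if memory is not None and memory.current is not None:
        # caller folds the instantaneous curve in first; the newest entry
        # carries normalized weight 1/weight_sum in the average
        I_model = memory.current
        grad_scale = memory.newest_weight
    else:
        I_model = I_inst
        grad_scale = 1.0
    n_q = np.atleast_1d(qgrid).size
    energy, c, dEdI = _energy_core(I_model, I_exp, err, alpha, kT,
                                   cfg.k_c, n_q, cfg.scale_matching)
    forces = -grad_scale * np.einsum("i,ijk->jk", dEdI, dI)
    return forces, energy


def shannon_nq(q_max: float, d_max: float) -> int:
    """Shannon channel count ceil(q_max D_max / pi) — a floor for n_q.

    Users may oversample; a typical production choice is n_q = 50.
    """
    if q_max <= 0 or d_max <= 0:
        raise InputError("q_max and d_max must be positive")
    return int(np.ceil(q_max * d_max / np.pi))
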