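"""Coarse-grained stochastic dynamics driven by a SAXS restraint.

A bead-spring helix-junction-helix (HJH) toy stands in for an RNA
two-way junction: two stiff arms of one bead per base pair joined by a
flexible single-stranded linker.  The force field is harmonic bonds and
angles plus a purely repulsive (WCA) excluded-volume term; the angle
stiffness contrast between arm and linker sets the persistence-length
contrast of the motif.

Dynamics use the BAOAB splitting of Langevin dynamics, which gives
accurate configurational sampling at large step sizes.  Units are
reduced: energies in units of kB*T at T = 1 (kB = 1 by default),
lengths in A, masses 1, so ``temperature`` is kT directly unless a
physical kB is configured.

The driven run evaluates the scattering curve of the instantaneous
configuration on the restrained q grid, folds it into an exponentially
decaying memory average, and applies the analytic restraint force
(refreshed every ``saxs_every`` steps and held constant in between)
ramped in by the switch function alpha(t).  Convergence is monitored
frame by frame with the error-weighted chi^2 metric; frames at or below
the admission threshold are flagged for the output pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from .errors import ConfigError, InputError, IntegrityError
from .ensemble_tools import chi2
from .restraint import (ErrorModel, MemoryAverage, RestraintConfig,
                        _energy_core, _intensity_and_gradient,
                        scale_factor, switch_alpha, update_memory)
from .scatter_core import (FormFactorTable, ParticleSystem, QVectorSet,
                           debye_intensity)

__all__ = [
    "ToyModel",
    "SDConfig",
    "RunRecord",
    "build_hjh_toy",
    "bend_arm",
    "ff_forces",
    "sd_step",
    "run_saxs_driven",
    "run_parallel_replica",
]


@dataclass
class ToyModel:
    """Bonded topology of a coarse-grained chain."""

    beads: ParticleSystem
    bond_idx: np.ndarray        # (nb, 2) int
    bond_r0: np.ndarray         # (nb,)
    bond_k: np.ndarray          # (nb,)
    angle_idx: np.ndarray       # (na, 3) int
    angle_theta0: np.ndarray    # (na,)
    angle_k: np.ndarray         # (na,)
    sigma_ev: float = 4.0       # excluded-volume diameter, A
    eps_ev: float = 1.0         # excluded-volume strength
    bead_label: str = "bead"
    groups: dict | None = None  # named bead index groups (arm_a, linker, arm_b)

    def __post_init__(self) -> None:
        self.bond_idx = np.asarray(self.bond_idx, dtype=int).reshape(-1, 2)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        self.bond_k = np.asarray(self.bond_k, dtype=float)
        self.angle_idx = np.asarray(self.angle_idx, dtype=int).reshape(-1, 3)
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=float)
        self.angle_k = np.asarray(self.angle_k, dtype=float)
        n = self.beads.n_particles
        if self.bond_idx.size and (self.bond_idx.min() < 0 or self.bond_idx.max() >= n):
            raise InputError("bond index out of range")
        if self.angle_idx.size and (self.angle_idx.min() < 0 or self.angle_idx.max() >= n):
            raise InputError("angle index out of range")
        if np.any(self.bond_idx[:, 0] == self.bond_idx[:, 1]):
            raise InputError("bond endpoints must be distinct")
        if np.any(self.bond_r0 <= 0):
            raise InputError("bond rest lengths must be positive")

    @property
    def n_beads(self) -> int:
        return self.beads.n_particles

    def excluded_pairs(self) -> np.ndarray:
        """Non-bonded pairs (separation >= 2 along the chain index)."""
        n = self.n_beads
        iu, ju = np.triu_indices(n, k=2)
        return np.column_stack([iu, ju])


@dataclass
class SDConfig:
    """Langevin (SD) integration parameters.

    ``temperature`` is multiplied by ``kB`` to give kT; with the default
    kB = 1 it is the thermal energy directly (reduced units).
    """

    dt: float = 0.02
    friction: float = 1.0
    temperature: float = 1.0
    n_steps: int = 10000
    seed: int = 0
    saxs_every: int = 10
    record_every: int = 50
    mass: float = 1.0
    kB: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction <= 0 or self.temperature < 0:
            raise ConfigError("dt and friction must be positive, temperature >= 0")
        if self.saxs_every < 1 or self.record_every < 1:
            raise ConfigError("strides must be >= 1")
        if self.mass <= 0:
            raise ConfigError("mass must be positive")

    @property
    def kT(self) -> float:
        return self.kB * self.temperature


@dataclass
class RunRecord:
    """Time series recorded during a (driven) run."""

    frames: np.ndarray          # (F, N, 3)
    times: np.ndarray           # (F,)
    chi2_series: np.ndarray     # (F,)
    e_ff_series: np.ndarray     # (F,)
    e_saxs_series: np.ndarray   # (F,)
    alpha_series: np.ndarray    # (F,)
    good_frames: np.ndarray     # indices into frames with chi2 <= threshold
    final_coords: np.ndarray = None
    final_velocities: np.ndarray = None


def build_hjh_toy(n_helix: int = 12, n_linker: int = 5, rise: float = 2.8,
                  k_bond: float = 100.0, k_angle_helix: float = 50.0,
                  k_angle_linker: float = 5.0, sigma_ev: float = 4.0,
                  eps_ev: float = 1.0) -> ToyModel:
    """Two stiff arms of ``n_helix`` beads joined by ``n_linker`` soft beads.

    One bead per base pair at ``rise`` A spacing, collinear start along
    z.  Angle triples lying entirely inside one arm are stiff; triples
    touching the linker are soft — exactly n_linker + 2 of them.  The
    default stiffness ratio gives a persistence-length contrast of about
    10:1 between arm and junction.
    """
    if n_helix < 2 or n_linker < 1:
        raise InputError("need n_helix >= 2 and n_linker >= 1")
    n = 2 * n_helix + n_linker
    coords = np.zeros((n, 3))
    coords[:, 2] = np.arange(n) * rise
    beads = ParticleSystem(coords, ["bead"] * n)
    bond_idx = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    bond_r0 = np.full(n - 1, rise)
    bond_k = np.full(n - 1, k_bond)
    centers = np.arange(1, n - 1)
    angle_idx = np.column_stack([centers - 1, centers, centers + 1])
    linker_lo, linker_hi = n_helix, n_helix + n_linker - 1
    touches_linker = (centers + 1 >= linker_lo) & (centers - 1 <= linker_hi)
    angle_k = np.where(touches_linker, k_angle_linker, k_angle_helix)
    angle_theta0 = np.full(centers.size, np.pi)
    groups = {"arm_a": np.arange(n_helix),
              "linker": np.arange(n_helix, n_helix + n_linker),
              "arm_b": np.arange(n_helix + n_linker, n)}
    return ToyModel(beads, bond_idx, bond_r0, bond_k,
                    angle_idx, angle_theta0, angle_k,
                    sigma_ev=sigma_ev, eps_ev=eps_ev, groups=groups)


def bend_arm(model: ToyModel, angle_deg: float) -> np.ndarray:
    """Coordinates with the second arm rotated by ``angle_deg`` about the junction.

    Rotation axis is x, pivot is the first bead of the second arm, so a
    collinear construct acquires the requested bend angle between arm
    axes.  Returns a new coordinate array.
    """
    if model.groups is None or "arm_b" not in model.groups:
        raise InputError("model has no arm_b group to bend")
    coords = model.beads.coordinates.copy()
    start = int(model.groups["arm_b"][0])
    theta = np.deg2rad(angle_deg)
    rot = np.array([[1.0, 0.0, 0.0],
                    [0.0, np.cos(theta), -np.sin(theta)],
                    [0.0, np.sin(theta), np.cos(theta)]])
    pivot = coords[start]
    coords[start:] = (coords[start:] - pivot) @ rot.T + pivot
    return coords


def ff_forces(model: ToyModel, coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Force-field forces and energy: bonds + angles + WCA repulsion.

    Conventions: E_bond = 1/2 k (r - r0)^2, E_angle = 1/2 k (theta -
    theta0)^2, and a WCA term truncated at ``sigma_ev`` acting on pairs
    at least two bonds apart.
    """
    coords = np.asarray(coords, dtype=float)
    n = model.n_beads
    if coords.shape != (n, 3):
        raise InputError("coordinate shape does not match bead count")
    forces = np.zeros_like(coords)
    energy = 0.0

    # bonds
    if model.bond_idx.size:
        i, j = model.bond_idx[:, 0], model.bond_idx[:, 1]
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0):
            raise IntegrityError("coincident bonded beads")
        delta = r - model.bond_r0
        energy += 0.5 * float(np.sum(model.bond_k * delta ** 2))
        fmag = (model.bond_k * delta / r)[:, None] * d   # force on i along +d
        np.add.at(forces, i, fmag)
        np.add.at(forces, j, -fmag)

    # angles
    if model.angle_idx.size:
        ia, ja, ka = (model.angle_idx[:, 0], model.angle_idx[:, 1],
                      model.angle_idx[:, 2])
        u = coords[ia] - coords[ja]
        v = coords[ka] - coords[ja]
        ru = np.linalg.norm(u, axis=1)
        rv = np.linalg.norm(v, axis=1)
        cos_t = np.clip(np.sum(u * v, axis=1) / (ru * rv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dtheta = theta - model.angle_theta0
        energy += 0.5 * float(np.sum(model.angle_k * dtheta ** 2))
        # clamped sin keeps the collinear minimum finite (true gradient -> 0)
        sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
        uhat = u / ru[:, None]
        vhat = v / rv[:, None]
        dth_di = (cos_t[:, None] * uhat - vhat) / (ru * sin_t)[:, None]
        dth_dk = (cos_t[:, None] * vhat - uhat) / (rv * sin_t)[:, None]
        coef = (model.angle_k * dtheta)[:, None]
        np.add.at(forces, ia, -coef * dth_di)
        np.add.at(forces, ka, -coef * dth_dk)
        np.add.at(forces, ja, coef * (dth_di + dth_dk))

    # excluded volume (WCA truncated at sigma_ev)
    if model.eps_ev > 0 and n > 2:
        pairs = model.excluded_pairs()
        i, j = pairs[:, 0], pairs[:, 1]
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0):
            raise IntegrityError("overlapping beads at zero distance in WCA term")
        s = model.sigma_ev / 2.0 ** (1.0 / 6.0)
        act = r < model.sigma_ev
        if np.any(act):
            ra = r[act]
            sr6 = (s / ra) ** 6
            energy += float(np.sum(4.0 * model.eps_ev * (sr6 ** 2 - sr6)
                                   + model.eps_ev))
            fmag = 24.0 * model.eps_ev * (2.0 * sr6 ** 2 - sr6) / ra
            fvec = (fmag / ra)[:, None] * d[act]   # repulsive: push j away from i
            np.add.at(forces, i[act], -fvec)
            np.add.at(forces, j[act], fvec)

    if not np.all(np.isfinite(forces)):
        raise IntegrityError("non-finite force encountered")
    return forces, energy


def check_stability(model: ToyModel, cfg: SDConfig) -> None:
    """Raise if dt exceeds the stability bound of the stiffest spring."""
    if model.bond_k.size:
        omega = np.sqrt(2.0 * model.bond_k.max() / cfg.mass)
        if cfg.dt * omega > 0.6:
            raise ConfigError(
                f"dt = {cfg.dt} too large for stiffest bond "
                f"(need dt < {0.6 / omega:.4g})")


def sd_step(coords: np.ndarray, velocities: np.ndarray, forces: np.ndarray,
            cfg: SDConfig, rng: np.random.Generator,
            force_fn: Callable[[np.ndarray], tuple[np.ndarray, float]] | None = None,
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One BAOAB Langevin step.

    ``forces`` are the forces at the current coordinates; ``force_fn``
    re-evaluates them at the new coordinates for the closing half-kick
    (``None`` means zero force).  Deterministic given the generator
    state.  Returns (coords, velocities, forces, potential_energy).
    """
    for arr in (coords, velocities, forces):
        if not np.all(np.isfinite(arr)):
            raise IntegrityError("non-finite state passed to sd_step")
    h = cfg.dt
    m = cfg.mass
    v = velocities + 0.5 * h * forces / m
    x = coords + 0.5 * h * v
    c1 = np.exp(-cfg.friction * h)
    c2 = np.sqrt(cfg.kT / m * (1.0 - c1 * c1))
    v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * h * v
    if force_fn is None:
        f_new, e_new = np.zeros_like(forces), 0.0
    else:
        f_new, e_new = force_fn(x)
    v = v + 0.5 * h * f_new / m
    return x, v, f_new, e_new


def _restrained_grid(target, rcfg: RestraintConfig
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n_q equally spaced points over the target range (capped at q_max),
    with target intensity and sigma linearly interpolated onto them."""
    if target.sigma is None:
        raise InputError("target profile needs a sigma column (or an ErrorModel)")
    q_lo = target.q[0]
    q_hi = min(target.q[-1], rcfg.q_max)
    if q_hi <= q_lo:
        raise ConfigError("q_max below the start of the target grid")
    qr = np.linspace(q_lo, q_hi, rcfg.n_q)
    I_exp = np.interp(qr, target.q, target.intensity)
    sig = np.interp(qr, target.q, target.sigma)
    return qr, I_exp, sig


def run_saxs_driven(model: ToyModel, target, rcfg: RestraintConfig | None,
                    scfg: SDConfig, error_model: ErrorModel | None = None,
                    ndir: int | None = None,
                    initial_coords: np.ndarray | None = None) -> RunRecord:
    """Single-replica SAXS-driven Langevin run.

    ``rcfg=None`` (or k_c = 0) runs unrestrained dynamics with an
    identical random-number stream, so null-coupling comparisons are
    exact.  ``ndir=None`` uses the exact Debye average for the on-the-fly
    curve and forces; a positive value switches to the discrete
    direction-set estimator with that many q-vectors.
    """
    check_stability(model, scfg)
    rng = np.random.default_rng(scfg.seed)
    coords = np.array(initial_coords if initial_coords is not None
                      else model.beads.coordinates, dtype=float)
    ff_table = FormFactorTable("constant")
    qvec = QVectorSet.fibonacci(ndir, seed=scfg.seed) if ndir else None

    restrained = rcfg is not None
    if restrained:
        qr, I_exp, sig_exp = _restrained_grid(target, rcfg)
        err = error_model or ErrorModel.from_target(I_exp, sig_exp, rcfg)
        memory = MemoryAverage(tau=rcfg.tau)
        coupling_on = rcfg.k_c > 0
    else:
        coupling_on = False

    velocities = np.sqrt(scfg.kT / scfg.mass) * rng.standard_normal(coords.shape)
    system = ParticleSystem(coords, [model.bead_label] * model.n_beads)
    saxs_F = np.zeros_like(coords)
    e_saxs = 0.0
    alpha = 0.0

    frames, times, chis, effs, esaxss, alphas = [], [], [], [], [], []
    forces, e_ff = ff_forces(model, coords)

    def total_force(x: np.ndarray) -> tuple[np.ndarray, float]:
        f, e = ff_forces(model, x)
        return f + saxs_F, e

    last_recorded = -1
    try:
        for step in range(scfg.n_steps + 1):
            t = step * scfg.dt
            if restrained and step % scfg.saxs_every == 0:
                system = ParticleSystem(coords, system.labels)
                alpha = switch_alpha(t, rcfg.t_switch)
                # fold the instantaneous curve into the memory first,
                # then differentiate the averaged penalty
                I_inst, dI = _intensity_and_gradient(system, ff_table, qr, qvec)
                update_memory(memory, I_inst, dt=scfg.saxs_every * scfg.dt)
                if coupling_on:
                    e_saxs, _, dEdI = _energy_core(
                        memory.current, I_exp, err, alpha, scfg.kT,
                        rcfg.k_c, rcfg.n_q, rcfg.scale_matching)
                    saxs_F = -memory.newest_weight * np.einsum(
                        "i,ijk->jk", dEdI, dI)
                else:
                    saxs_F = np.zeros_like(coords)
                    e_saxs = 0.0
            if step % scfg.record_every == 0:
                if restrained:
                    c = (scale_factor(memory.current, I_exp, sig_exp ** 2)
                         if rcfg.scale_matching else 1.0)
                    chi_val = chi2(c * memory.current, I_exp, sig_exp)
                else:
                    chi_val = np.nan
                frames.append(coords.copy())
                times.append(t)
                chis.append(chi_val)
                effs.append(e_ff)
                esaxss.append(e_saxs)
                alphas.append(alpha)
                last_recorded = len(frames) - 1
            if step == scfg.n_steps:
                break
            coords, velocities, forces, e_ff = sd_step(
                coords, velocities, forces, scfg, rng, total_force)
    except IntegrityError as exc:
        raise IntegrityError(
            f"{exc} (last valid recorded frame index: {last_recorded})") from exc

    chis = np.asarray(chis)
    threshold = rcfg.chi2_threshold if restrained else np.inf
    good = (np.nonzero(chis <= threshold)[0] if restrained
            else np.arange(len(frames)))
    return RunRecord(np.asarray(frames), np.asarray(times), chis,
                     np.asarray(effs), np.asarray(esaxss), np.asarray(alphas),
                     good, final_coords=coords, final_velocities=velocities)


def run_parallel_replica(model: ToyModel, target, rcfg: RestraintConfig,
                         scfg: SDConfig,
                         initial_coords: Sequence[np.ndarray],
                         ndir: int | None = None
                         ) -> tuple[list[RunRecord], np.ndarray]:
    """Parallel-replica run with the replica-averaged restraint.

    All replicas share the penalty on the memory-averaged replica-mean
    curve (prefactor k_c N^Omega); the force on replica beta is the
    exact gradient of that shared energy with respect to its own
    coordinates.  Returns per-replica records plus the ensemble chi^2
    series evaluated on the replica-mean curve at the record stride.
    """
    n_rep = rcfg.n_replicas
    if len(initial_coords) != n_rep:
        raise InputError(
            f"got {len(initial_coords)} initial conformations for {n_rep} replicas")
    check_stability(model, scfg)
    qr, I_exp, sig_exp = _restrained_grid(target, rcfg)
    err = ErrorModel.from_target(I_exp, sig_exp, rcfg)
    memory = MemoryAverage(tau=rcfg.tau)
    ff_table = FormFactorTable("constant")
    qvec = QVectorSet.fibonacci(ndir, seed=scfg.seed) if ndir else None
    labels = [model.bead_label] * model.n_beads

    rngs = [np.random.default_rng(scfg.seed + beta) for beta in range(n_rep)]
    coords = [np.array(c, dtype=float) for c in initial_coords]
    velocities = [np.sqrt(scfg.kT / scfg.mass) * rngs[b].standard_normal(coords[b].shape)
                  for b in range(n_rep)]
    saxs_F = [np.zeros_like(coords[b]) for b in range(n_rep)]
    e_saxs_shared = 0.0
    alpha = 0.0

    forces, e_ff = [], []
    for b in range(n_rep):
        f, e = ff_forces(model, coords[b])
        forces.append(f)
        e_ff.append(e)

    recs = [{"frames": [], "times": [], "chi2": [], "eff": [], "esaxs": [],
             "alpha": []} for _ in range(n_rep)]
    ens_chi2 = []
    coupling_on = rcfg.k_c > 0
    pref_kc = rcfg.k_c * n_rep ** rcfg.omega

    for step in range(scfg.n_steps + 1):
        t = step * scfg.dt
        if step % scfg.saxs_every == 0:
            alpha = switch_alpha(t, rcfg.t_switch)
            insts, grads = [], []
            for b in range(n_rep):
                sysb = ParticleSystem(coords[b], labels)
                I_b, dI_b = _intensity_and_gradient(sysb, ff_table, qr, qvec)
                insts.append(I_b)
                grads.append(dI_b)
            mean_inst = np.mean(insts, axis=0)
            update_memory(memory, mean_inst, dt=scfg.saxs_every * scfg.dt)
            if coupling_on:
                e_shared, c, dEdI = _energy_core(
                    memory.current, I_exp, err, alpha, scfg.kT,
                    pref_kc, rcfg.n_q, rcfg.scale_matching)
                w_new = memory.newest_weight
                for b in range(n_rep):
                    saxs_F[b] = -(w_new / n_rep) * np.einsum(
                        "i,ijk->jk", dEdI, grads[b])
                e_saxs_shared = e_shared
        if step % scfg.record_every == 0:
            c = (scale_factor(memory.current, I_exp, sig_exp ** 2)
                 if rcfg.scale_matching else 1.0)
            ens_chi2.append(chi2(c * memory.current, I_exp, sig_exp))
            for b in range(n_rep):
                sysb_I = debye_intensity(
                    ParticleSystem(coords[b], labels), ff_table, qr).intensity
                cb = (scale_factor(sysb_I, I_exp, sig_exp ** 2)
                      if rcfg.scale_matching else 1.0)
                recs[b]["frames"].append(coords[b].copy())
                recs[b]["times"].append(t)
                recs[b]["chi2"].append(chi2(cb * sysb_I, I_exp, sig_exp))
                recs[b]["eff"].append(e_ff[b])
                recs[b]["esaxs"].append(e_saxs_shared)
                recs[b]["alpha"].append(alpha)
        if step == scfg.n_steps:
            break
        for b in range(n_rep):
            def total_force(x, b=b):
                f, e = ff_forces(model, x)
                return f + saxs_F[b], e
            coords[b], velocities[b], forces[b], e_ff[b] = sd_step(
                coords[b], velocities[b], forces[b], scfg, rngs[b], total_force)

    records = []
    for b in range(n_rep):
        chis = np.asarray(recs[b]["chi2"])
        good = np.nonzero(chis <= rcfg.chi2_threshold)[0]
        records.append(RunRecord(
            np.asarray(recs[b]["frames"]), np.asarray(recs[b]["times"]), chis,
            np.asarray(recs[b]["eff"]), np.asarray(recs[b]["esaxs"]),
            np.asarray(recs[b]["alpha"]), good,
            final_coords=coords[b], final_velocities=velocities[b]))
    return records, np.asarray(ens_chi2)
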