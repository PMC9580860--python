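"""Real-space ensemble observables.

Radius of gyration, per-particle RMSF about the ensemble mean,
residue-residue contact frequencies, radial distribution functions with
the derived local cation concentration c(X) = g_max * c_bulk, FRET
efficiency averaged over a label-distance distribution with
E(r) = 1 / (1 + (r/R0)^6), and bend/twist coordinates of a
helix-junction-helix construct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError, IntegrityError
from .ensemble_tools import Ensemble, superpose_rmsd

__all__ = [
    "ContactMap",
    "RDFResult",
    "DistanceDistribution",
    "radius_of_gyration",
    "rmsf",
    "contact_map",
    "rdf",
    "local_concentration",
    "fret_efficiency",
    "bend_twist",
]


@dataclass
class ContactMap:
    """Ensemble contact frequencies between residues.

    ``frequency`` is symmetric with values in [0, 1]; the diagonal and
    sequence neighbours |i - j| <= 1 are flagged by ``excluded`` (and set
    to NaN) since they are trivially in contact.
    """

    frequency: np.ndarray
    excluded: np.ndarray
    cutoff: float


@dataclass
class RDFResult:
    """Normalized radial distribution function with its peak summary."""

    r_bins: np.ndarray     # bin centers, A
    g_r: np.ndarray
    g_max: float
    r_max: float


@dataclass
class DistanceDistribution:
    """Normalized distance density P(r) on a grid (trapezoid normalisation)."""

    r_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.r_grid.shape != self.density.shape or self.r_grid.ndim != 1:
            raise InputError("r_grid and density must be matching 1-D arrays")
        if np.any(self.density < 0):
            raise InputError("density must be non-negative")
        norm = np.trapezoid(self.density, self.r_grid)
        if abs(norm - 1.0) > 1e-9:
            raise InputError(f"P(r) must integrate to 1 (got {norm:.6g})")

    @classmethod
    def from_samples(cls, distances: np.ndarray, bins: int = 100,
                     r_range: tuple[float, float] | None = None
                     ) -> "DistanceDistribution":
        distances = np.asarray(distances, dtype=float)
        hist, edges = np.histogram(distances, bins=bins, range=r_range,
                                   density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        norm = np.trapezoid(hist, centers)
        if norm <= 0:
            raise InputError("empty distance sample")
        return cls(centers, hist / norm)


def radius_of_gyration(coords: np.ndarray,
                       weights: np.ndarray | None = None) -> float:
    """Weighted radius of gyration sqrt(sum w |r - rbar|^2 / sum w)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError("coords must be (N, 3)")
    n = coords.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise InputError("weights must be non-negative and not all zero")
    centroid = (w @ coords) / w.sum()
    return float(np.sqrt(np.sum(w * np.sum((coords - centroid) ** 2, axis=1))
                         / w.sum()))


def rmsf(ensemble: Ensemble, align_to: np.ndarray | None = None) -> np.ndarray:
    """Per-particle RMS fluctuation about the weighted mean structure.

    Frames are rigid-body superposed onto the reference (default: first
    frame) before deviations are accumulated, so rigid motion does not
    register as fluctuation.
    """
    frames = ensemble.frames
    w = ensemble.weights
    if frames.shape[0] < 2:
        warnings.warn("RMSF of a single frame is identically zero")
        return np.zeros(frames.shape[1])
    ref = frames[0] if align_to is None else np.asarray(align_to, dtype=float)
    aligned = np.empty_like(frames)
    for i, fr in enumerate(frames):
        _, rot, trans = superpose_rmsd(ref, fr)
        aligned[i] = fr @ rot.T + trans
    mean = np.einsum("f,fnd->nd", w, aligned)
    dev2 = np.sum((aligned - mean) ** 2, axis=2)     # (F, N)
    return np.sqrt(np.einsum("f,fn->n", w, dev2))


def contact_map(ensemble: Ensemble, residue_partition: Sequence[np.ndarray],
                cutoff: float = 6.0) -> ContactMap:
    """Weighted frequency of residue pairs within ``cutoff`` (A).

    A pair of residues is in contact in a frame if the minimum distance
    over their particle pairs is at or below the cutoff.
    """
    parts = [np.asarray(p, dtype=int) for p in residue_partition]
    if any(p.size == 0 for p in parts):
        raise InputError("every residue must contain at least one particle")
    nres = len(parts)
    freq = np.zeros((nres, nres))
    for fr, wt in zip(ensemble.frames, ensemble.weights):
        for a in range(nres):
            for b in range(a + 1, nres):
                dmin = cdist(fr[parts[a]], fr[parts[b]]).min()
                if dmin <= cutoff:
                    freq[a, b] += wt
                    freq[b, a] += wt
    excluded = np.abs(np.subtract.outer(np.arange(nres), np.arange(nres))) <= 1
    freq[excluded] = np.nan
    return ContactMap(freq, excluded, cutoff)


def rdf(reference_sites: np.ndarray, particle_frames: np.ndarray,
        bin_width: float, r_range: tuple[float, float],
        bulk_density: float | None = None) -> RDFResult:
    """Radial distribution function of particles around reference sites.

    Distances from every site to every particle, over all frames, are
    histogrammed and normalized by the spherical shell volume and the
    bulk number density.  If ``bulk_density`` is not given it is
    estimated from the outer 20% of the range (tail normalisation).
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    sites = np.atleast_2d(np.asarray(reference_sites, dtype=float))
    frames = np.asarray(particle_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0 or frames.shape[1] == 0:
        raise InputError("particle frames are empty")
    r_lo, r_hi = r_range
    edges = np.arange(r_lo, r_hi + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    for fr in frames:
        d = cdist(sites, fr).ravel()
        counts += np.histogram(d, bins=edges)[0]
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_obs = frames.shape[0] * sites.shape[0]
    density_profile = counts / (n_obs * shell_vol)
    if bulk_density is None:
        tail = density_profile[int(0.8 * density_profile.size):]
        if tail.size == 0 or tail.mean() == 0:
            raise InputError("cannot estimate bulk density from the tail; "
                             "pass bulk_density explicitly")
        bulk_density = float(tail.mean())
    g = density_profile / bulk_density
    centers = 0.5 * (edges[:-1] + edges[1:])
    imax = int(np.argmax(g))
    return RDFResult(centers, g, float(g[imax]), float(centers[imax]))


def local_concentration(rdf_result: RDFResult, c_bulk: float) -> float:
    """Local concentration c(X) = g_max * c_bulk (same units as c_bulk)."""
    if c_bulk <= 0:
        raise InputError("c_bulk must be positive")
    if rdf_result.g_max < 0:
        raise IntegrityError("negative RDF peak height")
    return float(rdf_result.g_max * c_bulk)


def _fret_e(r: np.ndarray, R0: float) -> np.ndarray:
    return 1.0 / (1.0 + (np.asarray(r, dtype=float) / R0) ** 6)


def fret_efficiency(dist, R0: float = 60.0,
                    weights: np.ndarray | None = None) -> float:
    """Ensemble FRET efficiency E = integral E(r) P(r) dr, E(r) = 1/(1+(r/R0)^6).

    ``dist`` may be a :class:`DistanceDistribution` (trapezoid
    quadrature on its grid) or an array of sampled distances (direct
    weighted average — exact for discrete mixtures).  The Forster radius
    R0 defaults to 60 A; dye orientation is assumed isotropic.
    """
    if R0 <= 0:
        raise InputError("R0 must be positive")
    if isinstance(dist, DistanceDistribution):
        e = float(np.trapezoid(_fret_e(dist.r_grid, R0) * dist.density,
                               dist.r_grid))
    else:
        r = np.atleast_1d(np.asarray(dist, dtype=float))
        if weights is None:
            w = np.full(r.size, 1.0 / r.size)
        else:
            w = np.asarray(weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise InputError("weights must sum to 1")
        e = float(np.sum(w * _fret_e(r, R0)))
    return min(max(e, 0.0), 1.0)


def _arm_axis(coords: np.ndarray) -> np.ndarray:
    """Principal axis of a bead set, oriented along increasing bead index."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if s[0] < 1e-10:
        warnings.warn("degenerate arm geometry; falling back to end-to-end vector")
        axis = coords[-1] - coords[0]
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            raise InputError("arm has zero spatial extent")
        return axis / nrm
    end_to_end = coords[-1] - coords[0]
    if np.dot(axis, end_to_end) < 0:
        axis = -axis
    return axis


def bend_twist(frame: np.ndarray, arm_a_indices: np.ndarray,
               arm_b_indices: np.ndarray
               ) -> tuple[float, float, np.ndarray]:
    """Bend and twist angles (degrees) between two arm axes.

    Arm axes are the index-order-oriented principal axes of each arm's
    beads.  Bend is the angle between them.  Twist is the azimuth of arm
    b's axis about arm a's axis, measured from a fixed in-plane reference
    (Gram-Schmidt of the lab x axis against the arm-a axis), so twist
    differences are meaningful between frames sharing the arm-a
    alignment.  The returned tip direction is arm b's axis in the arm-a
    frame (reference, binormal, axis) — the coordinate used for
    spherical occupancy maps.
    """
    frame = np.asarray(frame, dtype=float)
    ia = np.asarray(arm_a_indices, dtype=int)
    ib = np.asarray(arm_b_indices, dtype=int)
    if ia.size < 3 or ib.size < 3:
        raise InputError("each arm needs at least 3 particles")
    axis_a = _arm_axis(frame[ia])
    axis_b = _arm_axis(frame[ib])
    bend = float(np.degrees(np.arccos(np.clip(np.dot(axis_a, axis_b),
                                              -1.0, 1.0))))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_a)) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    e2 = ref - np.dot(ref, axis_a) * axis_a
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis_a, e2)
    twist = float(np.degrees(np.arctan2(np.dot(axis_b, e3),
                                        np.dot(axis_b, e2))))
    tip = np.array([np.dot(axis_b, e2), np.dot(axis_b, e3),
                    np.dot(axis_b, axis_a)])
    return bend, twist, tip
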