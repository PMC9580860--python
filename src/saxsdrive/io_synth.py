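"""File I/O and the synthetic target generator.

Profiles travel as 3-column whitespace-delimited ASCII (q, I, sigma)
with '#' comments — the common .dat convention of SAXS pipelines; q may
be given in 1/nm and is converted to the internal 1/A.  Structures are
read from PDB (via biotite) or XYZ; multi-frame XYZ files serve as the
trajectory format.

The synthetic generator fabricates target curves from known toy
conformations: a mixture of exact Debye profiles with multiplicative
Gaussian noise and a matching sigma column, so every stage of the
driven-simulation pipeline can be exercised against a target whose
ground truth is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import FormatError, InputError
from .scatter_core import (FormFactorTable, ParticleSystem, ScatteringProfile,
                           debye_intensity)

__all__ = [
    "SynthSpec",
    "read_profile",
    "write_profile",
    "read_structure",
    "read_trajectory",
    "write_xyz",
    "make_synthetic_target",
]

SIGMA_FLOOR_FRAC = 1e-6   # sigma floor relative to max intensity


@dataclass
class SynthSpec:
    """Recipe for a synthetic target profile.

    generator : 'single_conformer', 'two_state_mixture' or
        'perturbed_start' (naming the study design the target emulates).
    mixture_weights : one weight per supplied conformation, summing to 1.
    noise_frac : relative Gaussian noise on I(q); the sigma column is
        noise_frac * I (floored at a small positive value).
    """

    generator: str = "single_conformer"
    mixture_weights: Sequence[float] | None = None
    noise_frac: float = 0.02
    q_min: float = 0.01
    q_max: float = 0.315
    n_points: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in ("single_conformer", "two_state_mixture",
                                  "perturbed_start"):
            raise InputError(f"unknown generator: {self.generator!r}")
        if self.noise_frac < 0:
            raise InputError("noise_frac must be non-negative")
        if self.n_points < 2 or self.q_max <= self.q_min:
            raise InputError("need n_points >= 2 and q_max > q_min")


def read_profile(path, q_unit: str = "A") -> ScatteringProfile:
    """Read a 2- or 3-column ASCII profile; '#' comments skipped.

    ``q_unit='nm'`` divides q by 10 to convert 1/nm to the internal 1/A.
    """
    if q_unit not in ("A", "nm"):
        raise InputError("q_unit must be 'A' or 'nm'")
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse profile {path}: {exc}") from exc
    if data.shape[1] not in (2, 3):
        raise FormatError(f"profile {path} must have 2 or 3 columns, "
                          f"got {data.shape[1]}")
    q = data[:, 0]
    if q_unit == "nm":
        q = q / 10.0
    if q.size > 1 and np.any(np.diff(q) <= 0):
        raise FormatError(f"non-monotone q grid in {path}")
    sigma = None
    if data.shape[1] == 3:
        sigma = data[:, 2]
        if np.any(sigma < 0):
            raise FormatError(f"negative sigma in {path}")
        if np.any(sigma == 0):
            sigma = np.maximum(sigma, SIGMA_FLOOR_FRAC * np.abs(data[:, 1]).max())
    try:
        return ScatteringProfile(q, data[:, 1], sigma)
    except InputError as exc:
        raise FormatError(f"invalid profile {path}: {exc}") from exc


def write_profile(profile: ScatteringProfile, path,
                  kratky: bool = False) -> None:
    """Write a profile as 3-column (or 2-column) ASCII in 1/A.

    ``kratky=True`` writes I*q^2 instead of I (the Kratky representation
    used to highlight mid-q compactness features).
    """
    inten = profile.intensity * profile.q ** 2 if kratky else profile.intensity
    cols = [profile.q, inten]
    header = "q(1/A) I(q)q^2" if kratky else "q(1/A) I(q)"
    if profile.sigma is not None and not kratky:
        cols.append(profile.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.10g")


def read_structure(path) -> ParticleSystem:
    """Read a structure from PDB or XYZ into a particle system (A units)."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        import biotite.structure.io.pdb as pdbio
        try:
            pdb = pdbio.PDBFile.read(str(path))
            atoms = pdb.get_structure(model=1)
        except Exception as exc:
            raise FormatError(f"could not parse PDB {path}: {exc}") from exc
        labels = [el if el else name[:1]
                  for el, name in zip(atoms.element, atoms.atom_name)]
        return ParticleSystem(atoms.coord, labels)
    if path.suffix.lower() == ".xyz":
        frames = list(read_trajectory(path))
        if not frames:
            raise FormatError(f"no frames in {path}")
        return frames[0]
    raise FormatError(f"unsupported structure format: {path.suffix}")


def read_trajectory(path) -> Iterator[ParticleSystem]:
    """Iterate frames of a (multi-frame) XYZ file."""
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                if not header:
                    return
                continue
            try:
                n = int(header.split()[0])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: expected atom count, got {header!r}") from exc
            fh.readline()  # comment line
            lineno += 1
            coords = np.empty((n, 3))
            labels = []
            for i in range(n):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: malformed XYZ atom line")
                labels.append(parts[0])
                try:
                    coords[i] = [float(x) for x in parts[1:4]]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric coordinate") from exc
            yield ParticleSystem(coords, labels)


def write_xyz(path, frames: Sequence[np.ndarray],
              labels: Sequence[str], comment: str = "") -> None:
    """Write coordinate frames as multi-frame XYZ."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    with open(path, "w") as fh:
        for k, fr in enumerate(frames):
            fh.write(f"{fr.shape[0]}\n{comment} frame {k}\n")
            for lab, (x, y, z) in zip(labels, fr):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def make_synthetic_target(systems: Sequence[ParticleSystem], spec: SynthSpec,
                          ff: FormFactorTable | None = None
                          ) -> ScatteringProfile:
    """Synthetic target: weighted Debye mixture + relative Gaussian noise.

    I_target(q) = sum_s w_s I_s(q) * (1 + noise_frac * eps(q)),
    eps ~ N(0, 1) seeded by ``spec.seed``; the sigma column is
    noise_frac * I (floored at a small positive value so downstream
    error weighting never divides by zero).
    """
    if len(systems) == 0:
        raise InputError("need at least one conformation")
    weights = (np.full(len(systems), 1.0 / len(systems))
               if spec.mixture_weights is None
               else np.asarray(spec.mixture_weights, dtype=float))
    if weights.size != len(systems):
        raise InputError("one mixture weight per conformation required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InputError("mixture weights must sum to 1")
    if ff is None:
        ff = FormFactorTable("constant")
    q = np.linspace(spec.q_min, spec.q_max, spec.n_points)
    inten = np.zeros_like(q)
    for w, system in zip(weights, systems):
        inten += w * debye_intensity(system, ff, q).intensity
    sigma = np.maximum(spec.noise_frac * inten, SIGMA_FLOOR_FRAC * inten.max())
    if spec.noise_frac > 0:
        rng = np.random.default_rng(spec.seed)
        inten = inten + sigma * rng.standard_normal(q.shape)
    return ScatteringProfile(q, inten, sigma)
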