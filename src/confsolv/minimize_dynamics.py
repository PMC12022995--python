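"""Geometry optimization and Langevin dynamics over composite potentials.

Any object with an ``energy_forces(coords) -> (E, F)`` method is a potential
term; a :class:`CompositeSystem` sums an arbitrary list of them (typically
the intramolecular force field plus one implicit-solvent term).

The integrator is the middle-scheme Langevin splitting (LFMiddle): the
Ornstein-Uhlenbeck velocity randomisation is applied between two half drifts,
which gives accurate configurational sampling at 2 fs time steps.  With zero
friction it reduces to velocity Verlet.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .chem_core import KB, MoleculeGraph, T_DEFAULT

__all__ = ["CompositeSystem", "MinimizeResult", "Trajectory",
           "minimize", "langevin_run"]


@dataclass
class CompositeSystem:
    """A molecule, its potential terms, and thermostat settings."""

    mol: MoleculeGraph
    terms: list
    temperature: float = T_DEFAULT
    friction: float = 1.0        # ps^-1
    timestep: float = 0.002      # ps (2 fs)

    def __post_init__(self):
        if not self.terms:
            raise ValueError("at least one potential term is required")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        e_tot = 0.0
        f_tot = np.zeros_like(coords)
        for term in self.terms:
            e, f = term.energy_forces(coords)
            e_tot += e
            f_tot += f
        return e_tot, f_tot


@dataclass
class MinimizeResult:
    coords: np.ndarray
    energy: float
    rms_force: float
    converged: bool
    n_iter: int
    message: str = ""


def minimize(system: CompositeSystem, coords: np.ndarray,
             tol: float = 10.0, max_iter: int = 2000) -> MinimizeResult:
    """L-BFGS minimization to a root-mean-square force below ``tol``
    (kJ mol^-1 nm^-1, default 10).

    The optimizer restarts up to three times if the RMS-force criterion is
    not yet met; a non-finite energy anywhere returns ``converged=False``
    with diagnostics instead of raising.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite starting coordinates")
    shape = coords.shape

    def fun(x):
        # a transient overflow or degenerate geometry during line search is
        # mapped to a large finite penalty so the optimizer can back off
        try:
            e, f = system.energy_forces(x.reshape(shape))
        except (ValueError, ArithmeticError):
            return 1e12, np.zeros_like(x)
        if not np.isfinite(e) or not np.all(np.isfinite(f)):
            return 1e12, np.zeros_like(x)
        return e, -f.ravel()

    x = coords.ravel().copy()
    n_iter = 0
    for _ in range(3):
        res = _scipy_minimize(fun, x, jac=True, method="L-BFGS-B",
                              options={"maxiter": max_iter, "ftol": 1e-14,
                                       "gtol": tol * 1e-3})
        x = res.x
        n_iter += res.nit
        try:
            e, f = system.energy_forces(x.reshape(shape))
        except (ValueError, ArithmeticError) as exc:
            return MinimizeResult(x.reshape(shape), math.inf, math.inf, False,
                                  n_iter, f"degenerate final geometry: {exc}")
        rms = float(np.sqrt(np.mean(f ** 2)))
        if not np.isfinite(e) or not np.all(np.isfinite(f)):
            return MinimizeResult(x.reshape(shape), float(e), rms, False,
                                  n_iter, "non-finite energy during search")
        if rms <= tol:
            return MinimizeResult(x.reshape(shape), float(e), rms, True,
                                  n_iter, str(res.message))
    return MinimizeResult(x.reshape(shape), float(e), rms, False, n_iter,
                          f"RMS force {rms:.3g} above tolerance {tol}")


@dataclass
class Trajectory:
    """Frames (n_frames, n_atoms, 3) with per-frame potential energies
    and on-step velocities (nm/ps)."""

    frames: np.ndarray
    energies: np.ndarray
    times: np.ndarray            # ps
    velocities: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.frames)


def langevin_run(system: CompositeSystem, coords: np.ndarray, n_steps: int,
                 seed: int, write_freq: int = 100,
                 com_removal_interval: int = 100,
                 initial_velocities: np.ndarray | None = None) -> Trajectory:
    """Langevin dynamics with the LFMiddle splitting, deterministic per seed.

    Sequence per step: half kick, half drift, full Ornstein-Uhlenbeck
    velocity update, half drift, half kick.  Center-of-mass motion is removed
    every ``com_removal_interval`` steps.  Coordinates above 1e3 nm abort
    with a "simulation unstable" error, mirroring the exclusion of unstable
    runs from analysis.
    """
    x = np.array(coords, dtype=float)
    masses = system.mol.masses[:, None]
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    rng = np.random.default_rng(seed)
    dt = system.timestep
    kT = KB * system.temperature
    c1 = np.exp(-system.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT / masses)
    sigma_v = np.sqrt(kT / masses)
    if initial_velocities is None:
        v = rng.normal(size=x.shape) * sigma_v
    else:
        v = np.array(initial_velocities, dtype=float)

    frames, energies, times, vels = [], [], [], []
    e, f = system.energy_forces(x)
    for step in range(n_steps):
        v += 0.5 * dt * f / masses
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        e, f = system.energy_forces(x)
        v += 0.5 * dt * f / masses
        if com_removal_interval and (step + 1) % com_removal_interval == 0:
            p = (masses * v).sum(axis=0) / masses.sum()
            v -= p
        if np.max(np.abs(x)) > 1e3:
            raise RuntimeError(f"simulation unstable at step {step}")
        if (step + 1) % write_freq == 0:
            frames.append(x.copy())
            energies.append(e)
            times.append((step + 1) * dt)
            vels.append(v.copy())
    return Trajectory(np.array(frames), np.array(energies), np.array(times),
                      np.array(vels))
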