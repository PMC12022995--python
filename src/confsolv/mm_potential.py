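"""Minimal classical intramolecular potential.

Harmonic bonds and angles, periodic torsions, and Lennard-Jones + Coulomb
nonbonded interactions with 1-2/1-3 exclusions and scaled 1-4 pairs.  The
gas-phase convention applies throughout: no cutoff, no periodicity.

Energy conventions (documented prominently because parameter tables exported
from other toolkits may use a 1/2 prefactor):

* bond      E = k_b (r - r0)^2
* angle     E = k_a (theta - theta0)^2
* torsion   E = k_t (1 + cos(n phi - phase))
* LJ        E = 4 eps [(sigma/r)^12 - (sigma/r)^6], Lorentz-Berthelot mixing
* Coulomb   E = f_elec q_i q_j / r
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .chem_core import F_ELEC, MoleculeGraph, dihedral_angle

__all__ = [
    "ParametrizationError",
    "ForceFieldParams",
    "nonbonded_pairs",
    "mm_energy_forces",
    "MMTerm",
    "load_ff_params",
]


class ParametrizationError(ValueError):
    """A required force-field parameter is missing or inconsistent."""


@dataclass
class ForceFieldParams:
    """Parameter tables for one molecule.

    ``bonds``: (i, j, k_b, r0); ``angles``: (i, j, k, k_a, theta0);
    ``torsions``: (i, j, k, l, n, k_t, phase).  ``sigma``/``eps_lj``/
    ``charge`` are per-atom arrays.  ``pairs`` caches the nonbonded pair list
    with scale factors and is filled by :func:`nonbonded_pairs`.
    """

    n_atoms: int
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int, int, float, float]] = field(default_factory=list)
    sigma: np.ndarray | None = None
    eps_lj: np.ndarray | None = None
    charge: np.ndarray | None = None
    scale14_elec: float = 0.8333
    scale14_lj: float = 0.5
    pairs: list[tuple[int, int, float, float]] | None = None

    def __post_init__(self) -> None:
        for name in ("sigma", "eps_lj", "charge"):
            v = getattr(self, name)
            if v is None:
                v = np.zeros(self.n_atoms)
                if name == "sigma":
                    v = np.full(self.n_atoms, 0.3)
            v = np.asarray(v, dtype=float)
            if v.shape != (self.n_atoms,):
                raise ParametrizationError(
                    f"{name} has shape {v.shape}, expected ({self.n_atoms},)")
            setattr(self, name, v)
        if np.any(self.sigma <= 0):
            raise ParametrizationError("sigma must be positive")
        for terms, k_idx in ((self.bonds, 2), (self.angles, 3), (self.torsions, 5)):
            for t in terms:
                if t[k_idx] < 0:
                    raise ParametrizationError(f"negative force constant in {t}")


def nonbonded_pairs(mol: MoleculeGraph, params: ForceFieldParams
                    ) -> list[tuple[int, int, float, float]]:
    """Nonbonded pair list (i, j, elec_scale, lj_scale), i < j.

    1-2 and 1-3 pairs are excluded; 1-4 pairs get the scale factors from
    ``params``; everything more distant is unscaled.  Ordering is
    lexicographic, hence deterministic.
    """
    n = mol.n_atoms
    nbrs = mol.neighbor_sets()
    excluded: set[tuple[int, int]] = set()
    one_four: set[tuple[int, int]] = set()
    for i in range(n):
        for j in nbrs[i]:
            excluded.add((min(i, j), max(i, j)))
            for k in nbrs[j] - {i}:
                excluded.add((min(i, k), max(i, k)))
                for l in nbrs[k] - {i, j}:
                    if l != i:
                        one_four.add((min(i, l), max(i, l)))
    one_four -= excluded
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            if (i, j) in one_four:
                pairs.append((i, j, params.scale14_elec, params.scale14_lj))
            else:
                pairs.append((i, j, 1.0, 1.0))
    return pairs


def _bond_ef(coords, terms, forces):
    e = 0.0
    for i, j, k, r0 in terms:
        d = coords[i] - coords[j]
        r = np.linalg.norm(d)
        e += k * (r - r0) ** 2
        f = -2.0 * k * (r - r0) * d / r
        forces[i] += f
        forces[j] -= f
    return e


def _angle_ef(coords, terms, forces):
    e = 0.0
    for i, j, k, ka, t0 in terms:
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        ct = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        theta = np.arccos(ct)
        e += ka * (theta - t0) ** 2
        st = np.sqrt(max(1.0 - ct * ct, 1e-14))
        dedt = 2.0 * ka * (theta - t0)
        dti = (ct * u / nu - v / nv) / (nu * st)
        dtk = (ct * v / nv - u / nu) / (nv * st)
        forces[i] -= dedt * dti
        forces[k] -= dedt * dtk
        forces[j] += dedt * (dti + dtk)
    return e


def _torsion_ef(coords, terms, forces):
    e = 0.0
    for i, j, k, l, n, kt, phase in terms:
        phi = dihedral_angle(coords, (i, j, k, l))
        e += kt * (1.0 + np.cos(n * phi - phase))
        dedphi = -kt * n * np.sin(n * phi - phase)
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        dphi_d1 = -nb2 / (n1 @ n1) * n1
        dphi_d4 = nb2 / (n2 @ n2) * n2
        t = (b1 @ b2) / (nb2 * nb2)
        s = (b3 @ b2) / (nb2 * nb2)
        dphi_d2 = -(1.0 + t) * dphi_d1 + s * dphi_d4
        dphi_d3 = t * dphi_d1 - (1.0 + s) * dphi_d4
        forces[i] -= dedphi * dphi_d1
        forces[j] -= dedphi * dphi_d2
        forces[k] -= dedphi * dphi_d3
        forces[l] -= dedphi * dphi_d4
    return e


def _nonbonded_ef(coords, params, forces):
    e = 0.0
    for i, j, s_el, s_lj in params.pairs:
        d = coords[i] - coords[j]
        r2 = d @ d
        r = np.sqrt(r2)
        qq = s_el * F_ELEC * params.charge[i] * params.charge[j]
        e_el = qq / r
        eps = np.sqrt(params.eps_lj[i] * params.eps_lj[j])
        sig = 0.5 * (params.sigma[i] + params.sigma[j])
        sr6 = (sig * sig / r2) ** 3
        e_lj = s_lj * 4.0 * eps * (sr6 * sr6 - sr6)
        e += e_el + e_lj
        # dE/dr terms
        de = -e_el / r + s_lj * 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        f = -de * d / r
        forces[i] += f
        forces[j] -= f
    return e


def mm_energy_forces(coords: np.ndarray, params: ForceFieldParams
                     ) -> tuple[float, np.ndarray]:
    """Total intramolecular energy (kJ/mol) and forces (kJ mol^-1 nm^-1)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (params.n_atoms, 3):
        raise ParametrizationError(
            f"coords shape {coords.shape} does not match {params.n_atoms} atoms")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if params.pairs is None:
        raise ParametrizationError(
            "pair list missing: call nonbonded_pairs() or MMTerm first")
    forces = np.zeros_like(coords)
    e = _bond_ef(coords, params.bonds, forces)
    e += _angle_ef(coords, params.angles, forces)
    e += _torsion_ef(coords, params.torsions, forces)
    e += _nonbonded_ef(coords, params, forces)
    return float(e), forces


class MMTerm:
    """PotentialTerm adapter: the intramolecular force-field energy."""

    def __init__(self, mol: MoleculeGraph, params: ForceFieldParams):
        if params.n_atoms != mol.n_atoms:
            raise ParametrizationError("params do not cover all atoms")
        self.mol = mol
        self.params = params
        if params.pairs is None:
            params.pairs = nonbonded_pairs(mol, params)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return mm_energy_forces(coords, self.params)


def load_ff_params(path: str) -> ForceFieldParams:
    """Read a parameter table from a YAML/JSON config.

    Schema (all keys optional except ``n_atoms``)::

        n_atoms: 4
        bonds:    [[0, 1, 100000.0, 0.15], ...]
        angles:   [[0, 1, 2, 300.0, 1.911], ...]
        torsions: [[0, 1, 2, 3, 3, 4.0, 0.0], ...]
        sigma:    [0.35, ...]
        eps_lj:   [0.4, ...]
        charge:   [0.1, ...]
        scale14_elec: 0.8333
        scale14_lj: 0.5

    The same schema doubles as the import format for per-molecule parameter
    dumps exported from external parametrization toolkits.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "n_atoms" not in cfg:
        raise ParametrizationError(f"{path}: missing n_atoms")
    return ForceFieldParams(
        n_atoms=int(cfg["n_atoms"]),
        bonds=[tuple(t) for t in cfg.get("bonds", [])],
        angles=[tuple(t) for t in cfg.get("angles", [])],
        torsions=[tuple(t) for t in cfg.get("torsions", [])],
        sigma=cfg.get("sigma"),
        eps_lj=cfg.get("eps_lj"),
        charge=cfg.get("charge"),
        scale14_elec=float(cfg.get("scale14_elec", 0.8333)),
        scale14_lj=float(cfg.get("scale14_lj", 0.5)),
    )
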