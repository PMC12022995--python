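"""Deterministic toy systems, oracle-labelled training data, and synthetic
trajectories.

The training-data oracle is a *perturbed GB-SA model*: hidden per-element
rescalings of the intrinsic radii and of the surface tension define a ground
truth the graph network can genuinely represent, mirroring the delta-learning
premise at desk scale.  Labels are the analytic forces of that hidden model
(plus optional Gaussian noise), so parameter-recovery experiments are fully
self-contained and reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem_core import ATOMIC_MASSES, AtomSpec, Conformer, MoleculeGraph, SolventSpec
from .gb_solvent import GBParams, GBSATerm
from .gnn_solvent import TrainingRecord
from .minimize_dynamics import CompositeSystem, minimize
from .mm_potential import ForceFieldParams, MMTerm

__all__ = ["OracleSolvent", "make_toy_molecule", "oracle_training_set",
           "synthetic_trajectory", "default_oracle_solvents",
           "GB_ELEMENT_TABLE"]

# element -> (intrinsic GB radius nm, HCT descreening scale); Bondi-type
GB_ELEMENT_TABLE = {
    "H": (0.12, 0.85), "C": (0.17, 0.72), "N": (0.155, 0.79),
    "O": (0.15, 0.85), "F": (0.15, 0.88), "P": (0.185, 0.86),
    "S": (0.18, 0.96), "Cl": (0.17, 0.80),
}

_THETA_TET = 1.9106332  # tetrahedral angle, rad


def _atom(element: str, charge: float = 0.0) -> AtomSpec:
    rho, scale = GB_ELEMENT_TABLE[element]
    return AtomSpec(element, ATOMIC_MASSES[element], charge, rho, scale)


def _zigzag(bond_lengths, theta=_THETA_TET, phi=math.pi) -> np.ndarray:
    """Chain coordinates from bond lengths, a common angle, and a common
    dihedral (default all-trans)."""
    n = len(bond_lengths) + 1
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1] = [bond_lengths[0], 0.0, 0.0]
    if n > 2:
        r = bond_lengths[1]
        coords[2] = coords[1] + [-r * math.cos(theta), r * math.sin(theta), 0.0]
    for i in range(3, n):
        r = bond_lengths[i - 1]
        b1 = coords[i - 1] - coords[i - 2]
        b2 = coords[i - 2] - coords[i - 3]
        # place with given angle and dihedral via local frame
        e1 = b1 / np.linalg.norm(b1)
        nvec = np.cross(b2, b1)
        if np.linalg.norm(nvec) < 1e-12:
            nvec = np.array([0.0, 0.0, 1.0])
        nvec = nvec / np.linalg.norm(nvec)
        m1 = np.cross(nvec, e1)
        d = np.array([-math.cos(theta),
                      math.sin(theta) * math.cos(phi),
                      math.sin(theta) * math.sin(phi)])
        coords[i] = coords[i - 1] + r * (d[0] * e1 + d[1] * m1 + d[2] * nvec)
    return coords


def make_toy_molecule(kind: str, **params
                      ) -> tuple[MoleculeGraph, ForceFieldParams, Conformer]:
    """Fully parametrized toy with documented closed-form properties.

    Kinds: ``diatomic`` (one harmonic bond), ``chain_n`` (n-carbon chain
    with one torsion per quadruple), ``ring6`` (planar six-ring), and
    ``hbond_probe`` (H-O-C-C-O chain whose H...O contact provides an
    intramolecular distance coordinate).
    """
    if kind == "diatomic":
        k = params.get("k", 1000.0)
        r0 = params.get("r0", 0.15)
        q = params.get("q", 0.0)
        atoms = [_atom("C", q), _atom("C", -q)]
        mol = MoleculeGraph(atoms, [(0, 1)], name="diatomic")
        ff = ForceFieldParams(2, bonds=[(0, 1, k, r0)],
                              charge=[q, -q], eps_lj=[0.0, 0.0])
        conf = Conformer(np.array([[0.0, 0, 0], [r0, 0, 0]]))
        return mol, ff, conf

    if kind == "chain_n":
        n = int(params.get("n", 4))
        if n < 2:
            raise ValueError("chain needs at least 2 atoms")
        r0, kb = 0.153, 100000.0
        ka, t0 = 250.0, _THETA_TET
        kt = params.get("kt", 4.0)
        charges = np.array([0.1 * (-1) ** i for i in range(n)])
        charges -= charges.mean()
        atoms = [_atom("C", qi) for qi in charges]
        bonds = [(i, i + 1) for i in range(n - 1)]
        named = {}
        if n >= 4:
            named["main"] = (0, 1, 2, 3)
        mol = MoleculeGraph(atoms, bonds, named, name=f"chain{n}")
        ff = ForceFieldParams(
            n,
            bonds=[(i, i + 1, kb, r0) for i in range(n - 1)],
            angles=[(i, i + 1, i + 2, ka, t0) for i in range(n - 2)],
            torsions=[(i, i + 1, i + 2, i + 3, 3, kt, 0.0)
                      for i in range(n - 3)],
            sigma=np.full(n, 0.34), eps_lj=np.full(n, 0.35), charge=charges)
        conf = Conformer(_zigzag([r0] * (n - 1)))
        return mol, ff, conf

    if kind == "ring6":
        r0, kb = 0.14, 120000.0
        ka, t0 = 400.0, 2.0 * math.pi / 3.0
        kt = 15.0
        atoms = [_atom("C") for _ in range(6)]
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        mol = MoleculeGraph(atoms, bonds, name="ring6")
        quads = [(i, (i + 1) % 6, (i + 2) % 6, (i + 3) % 6) for i in range(6)]
        ff = ForceFieldParams(
            6,
            bonds=[(i, (i + 1) % 6, kb, r0) for i in range(6)],
            angles=[(i, (i + 1) % 6, (i + 2) % 6, ka, t0) for i in range(6)],
            # k(1 + cos(2 phi - pi)) is minimal at phi = 0: planar ring
            torsions=[(a, b, c, d, 2, kt, math.pi) for a, b, c, d in quads],
            eps_lj=np.zeros(6))
        rad = r0 / (2.0 * math.sin(math.pi / 6.0))
        ang = np.arange(6) * math.pi / 3.0
        conf = Conformer(np.stack([rad * np.cos(ang), rad * np.sin(ang),
                                   np.zeros(6)], axis=1))
        return mol, ff, conf

    if kind == "hbond_probe":
        # H(0)-O(1)-C(2)-C(3)-O(4); the 0...4 contact is the reporter
        charges = [0.40, -0.50, 0.15, 0.35, -0.40]
        elements = ["H", "O", "C", "C", "O"]
        atoms = [_atom(e, q) for e, q in zip(elements, charges)]
        bonds = [(0, 1), (1, 2), (2, 3), (3, 4)]
        mol = MoleculeGraph(atoms, bonds, {"main": (1, 2, 3, 4)},
                            name="hbond_probe")
        blens = [0.096, 0.143, 0.153, 0.143]
        ff = ForceFieldParams(
            5,
            bonds=[(i, j, 150000.0, b) for (i, j), b in zip(bonds, blens)],
            angles=[(0, 1, 2, 300.0, _THETA_TET),
                    (1, 2, 3, 250.0, _THETA_TET),
                    (2, 3, 4, 250.0, _THETA_TET)],
            torsions=[(0, 1, 2, 3, 3, 2.0, 0.0),
                      (1, 2, 3, 4, 3, 2.0, 0.0),
                      (1, 2, 3, 4, 1, 1.0, 0.0)],
            sigma=np.array([0.10, 0.30, 0.34, 0.34, 0.30]),
            eps_lj=np.array([0.06, 0.70, 0.35, 0.35, 0.70]),
            charge=np.array(charges))
        conf = Conformer(_zigzag(blens, phi=math.pi / 3.0))
        return mol, ff, conf

    raise ValueError(f"unknown toy kind {kind!r}")


@dataclass
class OracleSolvent:
    """Hidden ground truth for one solvent: perturbed GB-SA parameters."""

    solvent: SolventSpec
    rho_factors: dict[str, float] = field(default_factory=dict)
    sa_factor: float = 1.0

    def __post_init__(self):
        for el, f in self.rho_factors.items():
            if not (0.7 <= f <= 1.3):
                raise ValueError(f"perturbation for {el} outside [0.7, 1.3]")
        if not (0.7 <= self.sa_factor <= 1.3):
            raise ValueError("sa_factor outside [0.7, 1.3]")

    def gb_params(self, mol: MoleculeGraph) -> GBParams:
        rho = np.array([a.gb_radius * self.rho_factors.get(a.element, 1.0)
                        for a in mol.atoms])
        gb = GBParams(rho=rho, scale=mol.gb_scales)
        gb.gamma_sa = gb.gamma_sa * self.sa_factor
        return gb

    def forces(self, mol: MoleculeGraph, coords: np.ndarray) -> np.ndarray:
        """Analytic solvent forces of the hidden model."""
        term = GBSATerm(mol, self.solvent.dielectric, self.gb_params(mol))
        return term.energy_forces(coords)[1]


def default_oracle_solvents(seed: int = 7) -> list[OracleSolvent]:
    """Three toy solvents with seeded hidden perturbations."""
    rng = np.random.default_rng(seed)
    specs = [SolventSpec("oracle_polar", 78.5, 0),
             SolventSpec("oracle_mid", 20.0, 1),
             SolventSpec("oracle_apolar", 4.8, 2)]
    out = []
    for spec in specs:
        factors = {el: float(rng.uniform(0.8, 1.25))
                   for el in ("H", "C", "O")}
        out.append(OracleSolvent(spec, factors,
                                 sa_factor=float(rng.uniform(0.8, 1.25))))
    return out


def oracle_training_set(mols: list[tuple[MoleculeGraph, ForceFieldParams, Conformer]],
                        solvents: list[OracleSolvent], n_conf_per: int,
                        seed: int, noise_sd: float = 1.0
                        ) -> list[TrainingRecord]:
    """Training records labelled by the hidden perturbed-GB oracle.

    Conformers are drawn by seeded coordinate jitter around the reference
    geometry followed by a force-field minimization; the per-atom labels are
    the oracle's analytic forces plus Gaussian noise of width ``noise_sd``
    (kJ mol^-1 nm^-1, default 1).  Record count is
    ``len(mols) * len(solvents) * n_conf_per``.
    """
    rng = np.random.default_rng(seed)
    records: list[TrainingRecord] = []
    for mol, ff, conf in mols:
        system = CompositeSystem(mol, [MMTerm(mol, ff)])
        confs = []
        for _ in range(n_conf_per):
            start = conf.coords + rng.normal(0.0, 0.03, conf.coords.shape)
            confs.append(minimize(system, start, tol=20.0).coords)
        for osol in solvents:
            for coords in confs:
                labels = osol.forces(mol, coords)
                if noise_sd > 0:
                    labels = labels + rng.normal(0.0, noise_sd, labels.shape)
                records.append(TrainingRecord(mol, coords, osol.solvent, labels))
    return records


def synthetic_trajectory(conformers: list[Conformer], proportions,
                         jitter_sd: float, n_frames: int, seed: int
                         ) -> np.ndarray:
    """Frames drawn i.i.d. from a jittered conformer mixture."""
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(conformers), size=n_frames, p=proportions)
    frames = np.array([conformers[i].coords for i in picks])
    if jitter_sd > 0:
        frames = frames + rng.normal(0.0, jitter_sd, frames.shape)
    return frames
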