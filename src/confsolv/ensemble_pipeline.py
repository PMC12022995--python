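"""Conformational-ensemble workflow.

Steps: (i) distance-geometry conformer generation, (ii) minimization of
every conformer with the chosen composite potential, (iii) sorting by
potential energy, (iv) greedy heavy-atom-RMSD pruning keeping the
lowest-energy representative of each cluster, (v) quasi-RRHO free energies
from finite-difference normal modes, followed by a median/4-SD outlier
exclusion and Boltzmann weighting of the survivors.

Conformers whose minimization fails, or that keep imaginary frequencies
after up to 100 perturb-and-reminimize repeats, get their energies set to
infinity and are ignored downstream; every generated conformer ends in
exactly one terminal status bucket.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .chem_core import (KB, Conformer, MoleculeGraph, SolventSpec, T_DEFAULT,
                        boltzmann_weights, heavy_atom_rmsd)
from .gb_solvent import GBParams, GBSATerm
from .minimize_dynamics import CompositeSystem, minimize
from .mm_potential import ForceFieldParams, MMTerm

__all__ = ["PipelineConfig", "NormalModes", "Ensemble",
           "generate_conformers", "sort_and_prune", "normal_modes",
           "qrrho_free_energy", "handle_imaginary", "exclude_outliers",
           "run_ensemble", "ImaginaryFrequencyError"]

# physical constants for statistical thermodynamics (SI)
_H = 6.62607015e-34        # J s
_C_CM = 2.99792458e10      # cm/s
_KB_SI = 1.380649e-23      # J/K
_NA = 6.02214076e23
_U_KG = 1.66053906660e-27
_P_STD = 1.0e5             # Pa (1 bar)
_B_AV = 1.0e-44            # kg m^2, averaging moment for the free rotor
_OMEGA0 = 100.0            # cm^-1, damping crossover


class ImaginaryFrequencyError(RuntimeError):
    """Raised when quasi-RRHO is asked to handle imaginary modes directly."""


@dataclass
class PipelineConfig:
    """Workflow settings.

    Presets mirror the study conditions for the three compound classes:
    small flexible compounds (5120 conformers, 0.075 nm pruning), large
    drug-like compounds (51200, 0.15 nm), and rotamer-population compounds
    (256, 0.05 nm).
    """

    n_confs: int = 256
    rmsd_threshold: float = 0.05
    assignment_threshold: float = 0.1
    outlier_sd: float = 4.0
    max_remin_repeats: int = 100
    temperature: float = T_DEFAULT
    min_tol: float = 10.0
    seed: int = 0

    PRESETS = {
        "small": (5120, 0.075),
        "large": (51200, 0.15),
        "rotamer": (256, 0.05),
    }

    def __post_init__(self):
        if self.n_confs < 1:
            raise ValueError("n_confs must be >= 1")
        if min(self.rmsd_threshold, self.assignment_threshold) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def preset(cls, name: str, **kwargs) -> "PipelineConfig":
        n, thr = cls.PRESETS[name]
        return cls(n_confs=n, rmsd_threshold=thr, **kwargs)


# ---------------------------------------------------------------------------
# conformer generation (distance geometry)
# ---------------------------------------------------------------------------

def _to_rdkit(mol: MoleculeGraph):
    from rdkit import Chem
    rw = Chem.RWMol()
    for atom in mol.atoms:
        a = Chem.Atom(atom.element)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j in mol.bonds:
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    m = rw.GetMol()
    m.UpdatePropertyCache(strict=False)
    Chem.GetSymmSSSR(m)
    return m


def generate_conformers(mol: MoleculeGraph, n: int, seed: int,
                        ff_params: ForceFieldParams | None = None
                        ) -> list[Conformer]:
    """``n`` randomized distance-geometry conformers, deterministic per seed.

    Embedding uses basic distance geometry (bounds from connectivity) via
    RDKit; if embedding yields fewer conformers than requested the shorter
    list is returned.  When ``ff_params`` is supplied, each embedded
    structure is relaxed on the bonded terms only, which brings bond lengths
    to their ideal values without biasing torsions.
    """
    if n == 0:
        return []
    from rdkit.Chem import rdDistGeom
    rdmol = _to_rdkit(mol)
    params = rdDistGeom.ETKDGv3()
    params.useBasicKnowledge = False        # plain KDG: no torsion library
    params.useExpTorsionAnglePrefs = False
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.numThreads = 1
    ids = rdDistGeom.EmbedMultipleConfs(rdmol, numConfs=n, params=params)
    confs = []
    for cid in ids:
        pos = rdmol.GetConformer(cid).GetPositions() * 0.1   # A -> nm
        confs.append(Conformer(pos, status="raw"))
    if ff_params is not None and confs:
        bonded = ForceFieldParams(n_atoms=ff_params.n_atoms,
                                  bonds=ff_params.bonds,
                                  angles=ff_params.angles)
        system = CompositeSystem(mol, [MMTerm(mol, bonded)])
        confs = [Conformer(minimize(system, c.coords, tol=50.0).coords,
                           status="raw") for c in confs]
    if len(confs) < n:
        warnings.warn(f"embedding produced {len(confs)}/{n} conformers")
    return confs


# ---------------------------------------------------------------------------
# sorting and pruning
# ---------------------------------------------------------------------------

def sort_and_prune(confs: list[Conformer], rmsd_threshold: float,
                   mol: MoleculeGraph) -> list[Conformer]:
    """Energy-sort then greedy RMSD-prune.

    Conformers are sorted ascending by potential energy (stable, ties keep
    input order; infinite energies are dropped first).  A conformer survives
    iff its heavy-atom RMSD to every already-kept conformer exceeds the
    threshold, so each cluster is represented by its lowest-energy member.
    Pruned conformers are marked ``pruned_out`` in place.
    """
    finite = [c for c in confs if math.isfinite(c.e_pot)]
    order = sorted(range(len(finite)), key=lambda i: finite[i].e_pot)
    kept: list[Conformer] = []
    for i in order:
        c = finite[i]
        if all(heavy_atom_rmsd(c, k, mol) > rmsd_threshold for k in kept):
            kept.append(c)
        else:
            c.status = "pruned_out"
    return kept


# ---------------------------------------------------------------------------
# normal modes and quasi-RRHO
# ---------------------------------------------------------------------------

@dataclass
class NormalModes:
    """Frequencies in cm^-1 (ascending; imaginary modes stored negative),
    mass-weighted eigenvectors, and the rigid-mode bookkeeping."""

    frequencies: np.ndarray        # all 3N, signed (negative = imaginary)
    eigenvectors: np.ndarray       # columns, mass-weighted
    n_rigid: int                   # removed near-zero modes (6, 5 if linear)
    zero_threshold: float          # cm^-1
    coords: np.ndarray | None = None   # geometry the modes were computed at

    @property
    def vibrational(self) -> np.ndarray:
        """Real vibrational frequencies after removing rigid modes."""
        mags = np.abs(self.frequencies)
        order = np.argsort(mags)
        vib = np.sort(self.frequencies[order[self.n_rigid:]])
        return vib

    @property
    def has_imaginary(self) -> bool:
        return bool(np.any(self.vibrational < -self.zero_threshold))


def _rigid_body_space(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis of mass-weighted rigid translations/rotations.

    Returns a (3N, k) matrix with k = 6 (5 for linear, 3 for a single
    atom): the Eckart subspace projected out before frequency analysis.
    """
    n = len(coords)
    sqm = np.sqrt(np.repeat(masses, 3))
    com = np.average(coords, axis=0, weights=masses)
    rel = coords - com
    vecs = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = 1.0
        vecs.append(v.ravel() * sqm)
    for axis in np.eye(3):
        v = np.cross(np.broadcast_to(axis, (n, 3)), rel)
        vecs.append(v.ravel() * sqm)
    basis = np.stack(vecs, axis=1)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-8 * np.abs(np.diag(r)).max()
    return q[:, keep]


def normal_modes(system: CompositeSystem, coords: np.ndarray,
                 step: float = 1e-4, zero_threshold: float = 10.0
                 ) -> NormalModes:
    """Mass-weighted normal modes from a central-finite-difference Hessian.

    The Hessian is built from analytic forces (step 1e-4 nm), symmetrized,
    and mass-weighted; the exact rigid-body subspace (6 modes, 5 for linear
    geometries) is projected out before diagonalisation, so soft internal
    modes cannot be mistaken for rigid ones.  Negative eigenvalues outside
    the zero threshold are reported as imaginary frequencies (negative
    cm^-1 values).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for a in range(3):
            cp = coords.copy(); cp[i, a] += step
            cm = coords.copy(); cm[i, a] -= step
            _, fp = system.energy_forces(cp)
            _, fm = system.energy_forces(cm)
            hess[3 * i + a] = -((fp - fm) / (2.0 * step)).ravel()
    hess = 0.5 * (hess + hess.T)
    m = np.repeat(system.mol.masses, 3)
    hess_mw = hess / np.sqrt(np.outer(m, m))
    rigid = _rigid_body_space(coords, system.mol.masses)
    proj = np.eye(3 * n) - rigid @ rigid.T
    hess_proj = proj @ hess_mw @ proj
    evals, evecs = eigh(hess_proj)
    # kJ/mol/nm^2/u -> s^-2 conversion factor is exactly 1e24
    freqs = np.sign(evals) * np.sqrt(np.abs(evals) * 1e24) / (2 * np.pi * _C_CM)
    n_rigid = rigid.shape[1]
    return NormalModes(freqs, evecs, n_rigid, zero_threshold, coords.copy())


def qrrho_weight(omega_cm: np.ndarray, omega0: float = _OMEGA0) -> np.ndarray:
    """Head-Gordon damping w = 1/(1 + (omega0/omega)^4), omega0 = 100 cm^-1."""
    return 1.0 / (1.0 + (omega0 / np.asarray(omega_cm, float)) ** 4)


def qrrho_free_energy(e_pot: float, modes: NormalModes, mol: MoleculeGraph,
                      T: float = T_DEFAULT, omega0: float = _OMEGA0) -> float:
    """Quasi-RRHO free energy (kJ/mol).

    G = E_pot + sum_modes U_HO(omega)  -  T (S_trans + S_rot + S_vib), with
    the vibrational entropy per mode interpolated between harmonic
    oscillator and free rotor, S = w S_HO + (1 - w) S_FR.  The vibrational
    enthalpy (including ZPE) is kept harmonic.  Translational and rotational
    entropies are ideal-gas Sackur-Tetrode / rigid-rotor values at 1 bar;
    they cancel in conformer free-energy differences.
    """
    if modes.has_imaginary:
        raise ImaginaryFrequencyError(
            "imaginary vibrational modes present; use handle_imaginary()")
    freqs = modes.vibrational
    freqs = freqs[freqs > modes.zero_threshold]
    R = KB  # kJ/mol/K
    u_vib = s_vib = 0.0
    for nu in freqs:
        theta = _H * _C_CM * nu / _KB_SI      # K
        x = theta / T
        u_vib += R * (theta / 2.0 + theta / math.expm1(x))
        s_ho = R * (x / math.expm1(x) - math.log1p(-math.exp(-x)))
        mu = _H / (8.0 * math.pi ** 2 * _C_CM * nu)
        mu_p = mu * _B_AV / (mu + _B_AV)
        s_fr = R * (0.5 + math.log(math.sqrt(
            8.0 * math.pi ** 3 * mu_p * _KB_SI * T) / _H))
        w = float(qrrho_weight(nu, omega0))
        s_vib += w * s_ho + (1.0 - w) * s_fr
    # translational entropy (Sackur-Tetrode, 1 bar)
    m_kg = mol.masses.sum() * _U_KG
    q_trans = (2.0 * math.pi * m_kg * _KB_SI * T / _H ** 2) ** 1.5 \
        * _KB_SI * T / _P_STD
    s_trans = R * (math.log(q_trans) + 2.5)
    # rotational entropy (rigid rotor, sigma = 1)
    s_rot = _rotational_entropy(mol, modes, T) if mol.n_atoms > 1 else 0.0
    return float(e_pot + u_vib - T * (s_trans + s_rot + s_vib))


def _rotational_entropy(mol: MoleculeGraph, modes: NormalModes, T: float) -> float:
    coords = modes.coords
    if coords is None:
        return 0.0
    c = coords - np.average(coords, axis=0, weights=mol.masses)
    m = mol.masses
    c_m = c * 1e-9                                  # nm -> m
    inertia = np.zeros((3, 3))
    for mi, ri in zip(m * _U_KG, c_m):
        inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    moments = np.sort(np.linalg.eigvalsh(inertia))
    R = KB
    if moments[0] < 1e-52:                          # linear
        I = moments[-1]
        q_rot = 8.0 * math.pi ** 2 * I * _KB_SI * T / _H ** 2
        return R * (math.log(q_rot) + 1.0)
    q_rot = math.sqrt(math.pi * np.prod(moments)) \
        * (8.0 * math.pi ** 2 * _KB_SI * T / _H ** 2) ** 1.5
    return R * (math.log(q_rot) + 1.5)


def handle_imaginary(conf: Conformer, system: CompositeSystem,
                     max_repeats: int = 100, tol: float = 10.0,
                     jitter: float = 1e-3, seed: int = 0) -> Conformer:
    """Perturb-and-reminimize loop for conformers with imaginary modes.

    Adds a small seeded coordinate jitter (1e-3 nm), re-minimizes, and
    re-analyzes, up to ``max_repeats`` times.  Persistent imaginary modes or
    non-convergence set both energies to +inf and the status to ``failed``.
    """
    modes = normal_modes(system, conf.coords)
    if not modes.has_imaginary:
        return conf
    rng = np.random.default_rng(seed)
    coords = conf.coords
    for _ in range(max_repeats):
        trial = coords + rng.normal(0.0, jitter, coords.shape)
        res = minimize(system, trial, tol=tol)
        if not res.converged:
            continue
        modes = normal_modes(system, res.coords)
        if not modes.has_imaginary:
            conf.coords = res.coords
            conf.e_pot = res.energy
            conf.status = "minimized"
            return conf
        coords = res.coords
    conf.e_pot = math.inf
    conf.g_free = math.inf
    conf.status = "failed"
    return conf


def exclude_outliers(confs: list[Conformer], n_sd: float = 4.0
                     ) -> list[Conformer]:
    """Drop conformers with |g - median(g)| > n_sd * sd(g) (finite g only).

    Removed conformers are marked ``excluded_outlier``; with fewer than two
    finite free energies the list is returned unchanged.
    """
    g = np.array([c.g_free for c in confs])
    finite = np.isfinite(g)
    if finite.sum() < 2:
        return confs
    med = float(np.median(g[finite]))
    sd = float(np.std(g[finite]))
    kept = []
    for c, gi, fin in zip(confs, g, finite):
        if fin and abs(gi - med) > n_sd * sd:
            c.status = "excluded_outlier"
        else:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# the full workflow
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """All conformers of a run (every status) plus run provenance."""

    mol: MoleculeGraph
    conformers: list[Conformer]
    final: list[Conformer]
    metadata: dict = field(default_factory=dict)

    def attrition(self) -> dict:
        counts = {s: 0 for s in ("minimized", "pruned_out",
                                 "excluded_outlier", "failed")}
        for c in self.conformers:
            counts[c.status] = counts.get(c.status, 0) + 1
        counts["generated"] = len(self.conformers)
        return counts


def _solvent_term(solvent_model: str, mol: MoleculeGraph,
                  solvent: SolventSpec | None, gnn_model):
    if solvent_model == "vacuum":
        return None
    if solvent is None:
        raise ValueError(f"solvent required for model {solvent_model!r}")
    if solvent_model == "gbneck2":
        gb = GBParams.from_molecule(mol).with_neck()
        return GBSATerm(mol, solvent.dielectric, gb)
    if solvent_model == "gnnis":
        if gnn_model is None:
            raise ValueError("gnnis model requires trained weights")
        from .gnn_solvent import GNNISTerm
        return GNNISTerm(gnn_model, mol, solvent)
    raise ValueError(f"unknown solvent model {solvent_model!r}")


def run_ensemble(mol: MoleculeGraph, solvent: SolventSpec | None,
                 solvent_model: str, config: PipelineConfig,
                 ff_params: ForceFieldParams, gnn_model=None) -> Ensemble:
    """Execute the full workflow and Boltzmann-weight the survivors."""
    terms = [MMTerm(mol, ff_params)]
    sterm = _solvent_term(solvent_model, mol, solvent, gnn_model)
    if sterm is not None:
        terms.append(sterm)
    system = CompositeSystem(mol, terms)

    confs = generate_conformers(mol, config.n_confs, config.seed, ff_params)
    for c in confs:
        res = minimize(system, c.coords, tol=config.min_tol)
        if res.converged:
            c.coords = res.coords
            c.e_pot = res.energy
            c.status = "minimized"
        else:
            c.e_pot = math.inf
            c.g_free = math.inf
            c.status = "failed"

    survivors = sort_and_prune(confs, config.rmsd_threshold, mol)
    for k, c in enumerate(survivors):
        c = handle_imaginary(c, system, config.max_remin_repeats,
                             tol=config.min_tol,
                             seed=(config.seed * 1009 + k) % (2 ** 31))
        if c.status == "failed":
            continue
        modes = normal_modes(system, c.coords)
        try:
            c.g_free = qrrho_free_energy(c.e_pot, modes, mol,
                                         config.temperature)
        except ImaginaryFrequencyError:
            c.e_pot = math.inf
            c.g_free = math.inf
            c.status = "failed"

    alive = [c for c in survivors if c.status == "minimized"]
    final = exclude_outliers(alive, config.outlier_sd)
    final = [c for c in final if math.isfinite(c.g_free)]
    if not final:
        raise RuntimeError(
            "no conformers survived the workflow; attrition: "
            f"{Ensemble(mol, confs, []).attrition()}")
    w = boltzmann_weights([c.g_free for c in final], config.temperature)
    for c, wi in zip(final, w):
        c.weight = float(wi)

    meta = {
        "seed": config.seed,
        "n_confs": config.n_confs,
        "rmsd_threshold": config.rmsd_threshold,
        "solvent_model": solvent_model,
        "solvent": solvent.name if solvent else None,
        "temperature": config.temperature,
        "model_hash": _model_hash(gnn_model),
    }
    ens = Ensemble(mol, confs, final, meta)
    meta["attrition"] = ens.attrition()
    return ens


def _model_hash(gnn_model) -> str | None:
    if gnn_model is None:
        return None
    h = hashlib.sha256()
    for k in sorted(gnn_model.params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(gnn_model.params[k].data).tobytes())
    return h.hexdigest()[:16]
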