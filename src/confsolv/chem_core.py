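"""Core domain types, physical constants, and geometry primitives.

Units are fixed package-wide: lengths in nm, energies in kJ/mol, charges in
elementary charges (e), masses in unified atomic mass units (u), temperatures
in K, angles in rad.  Forces are kJ mol^-1 nm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB",
    "F_ELEC",
    "T_DEFAULT",
    "AtomSpec",
    "MoleculeGraph",
    "Conformer",
    "SolventSpec",
    "DegenerateGeometryError",
    "dihedral_angle",
    "kabsch_superpose",
    "heavy_atom_rmsd",
    "boltzmann_weights",
]

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.00831446
#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
F_ELEC = 138.935456
#: Default temperature, K.
T_DEFAULT = 300.0

# Standard atomic masses (u) for the elements the toy systems use.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


class DegenerateGeometryError(ValueError):
    """Raised when a geometric primitive is evaluated on degenerate input."""


@dataclass
class AtomSpec:
    """Per-atom static properties.

    ``gb_radius`` is the intrinsic (Bondi-type) radius entering the
    generalized-Born model; ``gb_scale`` the dimensionless descreening scale.
    """

    element: str
    mass: float
    partial_charge: float = 0.0
    gb_radius: float = 0.15
    gb_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.gb_radius <= 0:
            raise ValueError(f"gb_radius must be positive, got {self.gb_radius}")
        if not (0.0 < self.gb_scale <= 2.0):
            raise ValueError(f"gb_scale must be in (0, 2], got {self.gb_scale}")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class MoleculeGraph:
    """Molecular topology: atoms, bonds, and named dihedrals of interest."""

    atoms: list[AtomSpec]
    bonds: list[tuple[int, int]]
    named_dihedrals: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    name: str = "molecule"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
        for dname, idx in self.named_dihedrals.items():
            if len(set(idx)) != 4 or any(not 0 <= k < n for k in idx):
                raise ValueError(f"dihedral {dname!r}: invalid indices {idx}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def gb_radii(self) -> np.ndarray:
        return np.array([a.gb_radius for a in self.atoms])

    @property
    def gb_scales(self) -> np.ndarray:
        return np.array([a.gb_scale for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def neighbor_sets(self) -> list[set[int]]:
        nbrs: list[set[int]] = [set() for _ in self.atoms]
        for i, j in self.bonds:
            nbrs[i].add(j)
            nbrs[j].add(i)
        return nbrs


#: Conformer life-cycle states used by the ensemble pipeline.
STATUS_VALUES = ("raw", "minimized", "pruned_out", "excluded_outlier", "failed")


@dataclass
class Conformer:
    """Coordinates (nm) plus bookkeeping accumulated along the pipeline.

    ``e_pot`` and ``g_free`` may be ``+inf`` for conformers whose minimization
    failed or whose normal-mode analysis kept imaginary frequencies; such
    conformers carry zero Boltzmann weight.
    """

    coords: np.ndarray
    e_pot: float = math.nan
    g_free: float = math.nan
    weight: float = math.nan
    status: str = "raw"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.status not in STATUS_VALUES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != "failed" and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates on a non-failed conformer")

    def copy(self) -> "Conformer":
        return Conformer(self.coords.copy(), self.e_pot, self.g_free,
                         self.weight, self.status)


@dataclass(frozen=True)
class SolventSpec:
    """A solvent: name, relative dielectric permittivity, embedding index."""

    name: str
    dielectric: float
    embedding_index: int

    def __post_init__(self) -> None:
        if self.dielectric <= 1.0:
            raise ValueError(f"dielectric must exceed 1, got {self.dielectric}")
        if self.embedding_index < 0:
            raise ValueError("embedding_index must be non-negative")


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def dihedral_angle(coords: np.ndarray, indices: tuple[int, int, int, int]) -> float:
    """Signed torsion angle (IUPAC convention) in (-pi, pi].

    The sign follows the standard convention: looking down the central bond
    j->k, a clockwise rotation of l relative to i is positive.  Collinear
    triples make the torsion undefined and raise
    :class:`DegenerateGeometryError`.
    """
    coords = np.asarray(coords, dtype=float)
    i, j, k, l = indices
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral indices must be distinct")
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < 1e-10 or n2n < 1e-10:
        raise DegenerateGeometryError("three consecutive atoms are collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    phi = math.atan2(y, x)
    # map -pi to +pi so the range is (-pi, pi] and trans sits at +pi
    if phi <= -math.pi + 1e-15:
        phi = math.pi
    return phi


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superposition of ``mobile`` onto ``target`` (Kabsch).

    Both arrays are (n, 3); returns the transformed copy of ``mobile``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    return mc @ rot + target.mean(axis=0)


def heavy_atom_rmsd(a: Conformer, b: Conformer, mol: MoleculeGraph) -> float:
    """Minimal heavy-atom RMSD (nm) over rigid-body superposition.

    Hydrogens are excluded; the two conformers must belong to the same
    molecule.  Symmetric in its arguments.
    """
    mask = mol.heavy_mask
    if mask.sum() < 3:
        raise ValueError("heavy-atom RMSD requires at least 3 heavy atoms")
    xa = a.coords[mask]
    xb = b.coords[mask]
    if xa.shape != xb.shape:
        raise ValueError("conformers have inconsistent atom counts")
    xa_fit = kabsch_superpose(xa, xb)
    return float(np.sqrt(np.mean(np.sum((xa_fit - xb) ** 2, axis=1))))


def boltzmann_weights(g: "list[float] | np.ndarray", T: float = T_DEFAULT) -> np.ndarray:
    """Normalized Boltzmann weights for free energies ``g`` (kJ/mol) at ``T``.

    Infinite free energies receive exactly zero weight.  The computation is
    shift-invariant: the finite minimum is subtracted before exponentiation.
    """
    g = np.asarray(g, dtype=float)
    finite = np.isfinite(g)
    if not finite.any():
        raise ValueError("boltzmann_weights requires at least one finite free energy")
    w = np.zeros_like(g)
    gmin = g[finite].min()
    w[finite] = np.exp(-(g[finite] - gmin) / (KB * T))
    return w / w.sum()
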