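"""Downstream statistics on ensembles and trajectories.

Free-energy profiles by direct counting (with the 4 pi r^2 Jacobian
correction for distance coordinates), trajectory-to-conformer assignment,
confusion-matrix balanced accuracy with the zero-TNR convention,
gauche/trans state populations, mean-centred molecular-balance free-energy
differences, and PCA of the learned solvent embeddings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .chem_core import (KB, Conformer, MoleculeGraph, T_DEFAULT,
                        boltzmann_weights, dihedral_angle, heavy_atom_rmsd)
from .ensemble_pipeline import Ensemble

__all__ = ["FreeEnergyProfile", "ConfusionCounts", "profile_from_samples",
           "delta_g_between", "assign_frames", "balanced_accuracy",
           "classify_gauche_trans", "state_populations", "balance_ddg",
           "embedding_pca", "GAUCHE_CUTOFF_RAD"]

#: Dihedral window (rad): |phi| <= 2.1 is gauche, the rest is trans.
GAUCHE_CUTOFF_RAD = 2.1


@dataclass
class FreeEnergyProfile:
    """Binned free energies (kJ/mol), minimum shifted to zero.

    Empty bins carry G = +inf.  ``kind`` is "distance" (Jacobian-corrected)
    or "dihedral" (periodic, no Jacobian).
    """

    bin_centers: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    kind: str


def profile_from_samples(samples: np.ndarray, kind: str, bins: int = None,
                         T: float = T_DEFAULT,
                         range_: tuple[float, float] | None = None
                         ) -> FreeEnergyProfile:
    """Free-energy profile by direct counting, G(x) = -kB T ln N(x).

    Distance profiles additionally receive the Jacobian correction
    +kB T ln(4 pi r^2) at the bin centers, removing the volume-element bias
    of radial histograms.  Dihedral profiles are binned periodically over
    (-pi, pi].  The minimum is shifted to zero.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise ValueError("at least one sample required")
    if kind not in ("distance", "dihedral"):
        raise ValueError(f"unknown profile kind {kind!r}")
    if bins is None:
        bins = 72 if kind == "dihedral" else 100
    if bins < 2:
        raise ValueError("at least two bins required")
    if kind == "dihedral":
        lo, hi = -math.pi, math.pi
    elif range_ is not None:
        lo, hi = range_
    else:
        lo, hi = samples.min(), samples.max() * (1 + 1e-12)
    counts, edges = np.histogram(samples, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        g = -KB * T * np.log(counts.astype(float))
    if kind == "distance":
        g = g + KB * T * np.log(4.0 * math.pi * centers ** 2)
    finite = np.isfinite(g)
    g = g - g[finite].min()
    g[~finite] = math.inf
    return FreeEnergyProfile(centers, g, counts, kind)


def delta_g_between(profile: FreeEnergyProfile, x_global: float,
                    x_local: float) -> float:
    """G(bin of x_local) - G(bin of x_global).

    The minimum positions are supplied externally (e.g. from a reference
    simulation); positive values mean the local minimum lies above the
    global one.  An empty bin at either position gives +inf with a warning.
    """
    def bin_of(x):
        i = int(np.argmin(np.abs(profile.bin_centers - x)))
        lo, hi = profile.bin_centers[0], profile.bin_centers[-1]
        if not (lo - _bin_width(profile) <= x <= hi + _bin_width(profile)):
            raise ValueError(f"position {x} outside profile range")
        return i

    gi = profile.g[bin_of(x_local)]
    gg = profile.g[bin_of(x_global)]
    if not (np.isfinite(gi) and np.isfinite(gg)):
        warnings.warn("empty bin at a requested minimum position")
        return math.inf
    return float(gi - gg)


def _bin_width(profile: FreeEnergyProfile) -> float:
    return float(profile.bin_centers[1] - profile.bin_centers[0])


def assign_frames(frames: np.ndarray, conformers: list[Conformer],
                  mol: MoleculeGraph, cutoff: float = 0.1
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Assign each trajectory frame to its closest conformer below ``cutoff``.

    Returns (populations, assignments): populations are normalized over
    assigned frames; ``assignments[k]`` is the conformer index or -1 when no
    conformer lies within the RMSD cutoff.  Ties go to the lowest conformer
    index.  Raises if no frame can be assigned.
    """
    if not conformers:
        raise ValueError("conformer list is empty")
    assignments = np.full(len(frames), -1, dtype=int)
    for k, frame in enumerate(frames):
        fc = Conformer(frame)
        rmsds = np.array([heavy_atom_rmsd(fc, c, mol) for c in conformers])
        best = int(np.argmin(rmsds))   # argmin takes the first == lowest index
        if rmsds[best] < cutoff:
            assignments[k] = best
    assigned = assignments >= 0
    if not assigned.any():
        raise ValueError("no frame lies within the RMSD cutoff of any conformer")
    pops = np.bincount(assignments[assigned], minlength=len(conformers))
    return pops / pops.sum(), assignments


def populations_to_free_energies(populations: np.ndarray,
                                 T: float = T_DEFAULT) -> np.ndarray:
    """G_i = -kB T ln p_i, shifted so the most populated state is zero."""
    p = np.asarray(populations, dtype=float)
    with np.errstate(divide="ignore"):
        g = -KB * T * np.log(p)
    return g - g[np.isfinite(g)].min()


@dataclass
class ConfusionCounts:
    """Counts of the four 1-kBT free-energy classes."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def balanced_accuracy(g_pred, g_ref, T: float = T_DEFAULT,
                      cutoff_kt: float = 1.0
                      ) -> tuple[ConfusionCounts, float]:
    """Balanced accuracy of low-free-energy conformer identification.

    A conformer is "positive" when its free energy lies below
    ``cutoff_kt * kB T``.  BA = (TPR + TNR)/2; when a class is absent the
    corresponding rate is set to zero rather than undefined (so a predictor
    facing only positives cannot score above 0.5).
    """
    g_pred = np.asarray(g_pred, dtype=float)
    g_ref = np.asarray(g_ref, dtype=float)
    if g_pred.shape != g_ref.shape or g_pred.size < 1:
        raise ValueError("g_pred and g_ref must be equal-length, non-empty")
    cut = cutoff_kt * KB * T
    pred_pos = g_pred < cut
    ref_pos = g_ref < cut
    counts = ConfusionCounts(
        tp=int(np.sum(pred_pos & ref_pos)),
        tn=int(np.sum(~pred_pos & ~ref_pos)),
        fp=int(np.sum(pred_pos & ~ref_pos)),
        fn=int(np.sum(~pred_pos & ref_pos)),
    )
    tpr = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    tnr = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else 0.0
    return counts, 0.5 * (tpr + tnr)


def classify_gauche_trans(dihedral: float) -> str:
    """Gauche for |phi| <= 2.1 rad (boundary inclusive), trans otherwise."""
    if not (-math.pi - 1e-9 < dihedral <= math.pi + 1e-9):
        raise ValueError("dihedral must lie in (-pi, pi]")
    return "gauche" if abs(dihedral) <= GAUCHE_CUTOFF_RAD else "trans"


def state_populations(ensemble: Ensemble, dihedral_name: str,
                      T: float = T_DEFAULT) -> dict[str, float]:
    """Boltzmann-weighted gauche/trans populations of the final ensemble."""
    idx = ensemble.mol.named_dihedrals.get(dihedral_name)
    if idx is None:
        raise KeyError(f"no named dihedral {dihedral_name!r}")
    confs = [c for c in ensemble.final if math.isfinite(c.g_free)]
    if not confs:
        raise ValueError("no conformers with finite free energies")
    w = boltzmann_weights([c.g_free for c in confs], T)
    pops = {"gauche": 0.0, "trans": 0.0}
    for c, wi in zip(confs, w):
        phi = dihedral_angle(c.coords, idx)
        pops[classify_gauche_trans(phi)] += float(wi)
    return pops


def balance_ddg(pred_dg: dict[str, float], exp_dg: dict[str, float]
                ) -> tuple[list[tuple[str, float, float]], float]:
    """Mean-centred (prediction, experiment) pairs for a molecular balance.

    ``pred_dg``/``exp_dg`` map solvent name to the rotamer free-energy
    difference G(A) - G(B) in kJ/mol.  Each series is centred on its own
    mean (removing the per-balance offset) while the pairing is preserved;
    the least-squares slope of prediction vs experiment through the centred
    pairs is returned as a diagnostic.
    """
    if set(pred_dg) != set(exp_dg):
        raise ValueError("prediction and experiment must cover the same solvents")
    if len(pred_dg) < 2:
        raise ValueError("at least two solvents required")
    names = sorted(pred_dg)
    p = np.array([pred_dg[k] for k in names])
    e = np.array([exp_dg[k] for k in names])
    p = p - p.mean()
    e = e - e.mean()
    denom = float(e @ e)
    slope = float(p @ e / denom) if denom > 0 else math.nan
    return [(k, float(pi), float(ei)) for k, pi, ei in zip(names, p, e)], slope


def embedding_pca(vectors: np.ndarray, n_components: int = 3
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centred PCA of the solvent-embedding matrix.

    Returns (components, explained-variance ratios, projections); the ratios
    are sorted descending and sum to at most 1.  Zero-variance input yields
    all-zero ratios with a warning.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        warnings.warn("zero-variance embedding matrix")
        ratios = np.zeros_like(var)
    else:
        ratios = var / total
    k = min(n_components, vt.shape[0])
    return vt[:k], ratios, xc @ vt[:k].T
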