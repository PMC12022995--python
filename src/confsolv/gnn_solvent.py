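"""Invariant graph-network solvent model with learned solvent embeddings.

The network is a delta-learning correction on top of the GB-SA physics: node
outputs rescale the per-atom intrinsic Born radius and the per-atom surface
tension, and the solvent energy is the GB-SA expression evaluated with the
corrected parameters.  Because inputs are interatomic distances only, the
energy is invariant under rigid motions and the forces (the negative
coordinate gradient of the whole expression, network included) are
equivariant.

Each solvent is represented by a learnable 64-dimensional embedding vector
looked up by solvent index and concatenated to every node feature, so one set
of message-passing weights serves all registered solvents.  Training matches
predicted per-atom solvent forces to reference labels (mean squared error,
Adam, gradient-norm clipping), which requires differentiating the force
expression with respect to the weights — second-order gradients supplied by
:mod:`confsolv.autodiff`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem_core import Conformer, MoleculeGraph, SolventSpec
from .gb_solvent import GBParams, gb_sa_energy_tensor

__all__ = ["GNNConfig", "TrainHyper", "TrainingRecord", "MolGraphBatch",
           "GNNISModel", "featurize", "predict_energy_forces", "train",
           "embedding_vectors"]

DEFAULT_ELEMENTS = ("H", "C", "N", "O", "F", "P", "S", "Cl")

# softplus(x0) = 1, so zero-initialised heads give identity corrections
_SOFTPLUS_ONE = math.log(math.e - 1.0)


@dataclass(frozen=True)
class GNNConfig:
    """Architecture hyperparameters (all configurable; defaults documented
    in the methods note)."""

    hidden: int = 128
    n_passes: int = 3
    n_rbf: int = 32
    cutoff: float = 0.6          # nm
    embed_dim: int = 64
    dropout: float = 0.1
    elements: tuple = DEFAULT_ELEMENTS


@dataclass(frozen=True)
class TrainHyper:
    """Training protocol: 50 epochs, exponentially decaying learning rate
    5e-4 -> 5e-6, MSE force loss, Adam, gradient clipping at norm 1,
    dropout 0.1, 95/5 train/validation split."""

    epochs: int = 50
    batch_size: int = 256
    lr_start: float = 5e-4
    lr_end: float = 5e-6
    grad_clip_norm: float = 1.0
    dropout: float = 0.1
    val_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if min(self.epochs, self.batch_size, self.lr_start, self.lr_end,
               self.grad_clip_norm) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class TrainingRecord:
    """One (conformer, solvent) pair with per-atom solvent-force labels."""

    mol: MoleculeGraph
    coords: np.ndarray
    solvent: SolventSpec
    forces: np.ndarray           # kJ mol^-1 nm^-1, shape (n_atoms, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.forces = np.asarray(self.forces, float)
        n = self.mol.n_atoms
        if self.coords.shape != (n, 3) or self.forces.shape != (n, 3):
            raise ValueError("coords/forces shape mismatch with molecule")


@dataclass
class MolGraphBatch:
    """Featurized (possibly multi-molecule) graph batch.

    ``edges`` are directed and symmetric (both orientations present);
    distances are recomputed from coordinates inside the forward pass so
    that forces flow through the radial features.
    """

    node_feats: np.ndarray       # (n, F) constants
    edges: np.ndarray            # (E, 2) int, receiver first
    coords: np.ndarray           # (n, 3)
    solvent_of_node: np.ndarray  # (n,) embedding index per node
    mol_slices: list[tuple[int, int]]
    mols: list[MoleculeGraph]
    eps_by_mol: list[float]
    ref_forces: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.node_feats.shape[0]


def _node_features(mol: MoleculeGraph, elements: tuple) -> np.ndarray:
    feats = np.zeros((mol.n_atoms, len(elements) + 2))
    for i, atom in enumerate(mol.atoms):
        if atom.element in elements:
            feats[i, elements.index(atom.element)] = 1.0
        feats[i, -2] = atom.partial_charge
        feats[i, -1] = atom.gb_radius
    return feats


def featurize(mol: MoleculeGraph, conformer: Conformer, solvent: SolventSpec,
              cutoff: float = 0.6, elements: tuple = DEFAULT_ELEMENTS
              ) -> MolGraphBatch:
    """Build a single-molecule batch with edges below the radial cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(conformer.coords, float)
    n = mol.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    ii, jj = np.nonzero((dist < cutoff) & ~np.eye(n, dtype=bool))
    if n > 1 and len(set(ii)) < n:
        import warnings
        warnings.warn("isolated node(s) under cutoff; kept without edges")
    return MolGraphBatch(
        node_feats=_node_features(mol, elements),
        edges=np.stack([ii, jj], axis=1) if len(ii) else np.zeros((0, 2), int),
        coords=coords,
        solvent_of_node=np.full(n, solvent.embedding_index, dtype=int),
        mol_slices=[(0, n)],
        mols=[mol],
        eps_by_mol=[solvent.dielectric],
    )


def collate(batches: list[MolGraphBatch]) -> MolGraphBatch:
    """Concatenate single-molecule batches with node-index offsets."""
    offset = 0
    feats, edges, coords, sol, slices, mols, eps, refs = [], [], [], [], [], [], [], []
    have_ref = all(b.ref_forces is not None for b in batches)
    for b in batches:
        feats.append(b.node_feats)
        if len(b.edges):
            edges.append(b.edges + offset)
        coords.append(b.coords)
        sol.append(b.solvent_of_node)
        for a, z in b.mol_slices:
            slices.append((a + offset, z + offset))
        mols.extend(b.mols)
        eps.extend(b.eps_by_mol)
        if have_ref:
            refs.append(b.ref_forces)
        offset += b.n_atoms
    return MolGraphBatch(
        node_feats=np.concatenate(feats),
        edges=np.concatenate(edges) if edges else np.zeros((0, 2), int),
        coords=np.concatenate(coords),
        solvent_of_node=np.concatenate(sol),
        mol_slices=slices,
        mols=mols,
        eps_by_mol=eps,
        ref_forces=np.concatenate(refs) if have_ref else None,
    )


class GNNISModel:
    """Message-passing network producing per-atom GB-SA parameter corrections."""

    def __init__(self, solvents: list[SolventSpec], config: GNNConfig = GNNConfig(),
                 seed: int = 0):
        idx = [s.embedding_index for s in solvents]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate solvent embedding indices")
        if sorted(idx) != list(range(len(idx))):
            raise ValueError("embedding indices must be 0..n_solvents-1")
        self.solvents = sorted(solvents, key=lambda s: s.embedding_index)
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        c = config
        feat_dim = len(c.elements) + 2
        self._add("embed", rng.normal(0.0, 0.1, (len(solvents), c.embed_dim)))
        self._glorot(rng, "enc_W", feat_dim + c.embed_dim, c.hidden)
        self._add("enc_b", np.zeros(c.hidden))
        for t in range(c.n_passes):
            self._glorot(rng, f"msg{t}_W1", 2 * c.hidden + c.n_rbf, c.hidden)
            self._add(f"msg{t}_b1", np.zeros(c.hidden))
            self._glorot(rng, f"msg{t}_W2", c.hidden, c.hidden)
            self._add(f"msg{t}_b2", np.zeros(c.hidden))
            self._glorot(rng, f"upd{t}_W1", 2 * c.hidden, c.hidden)
            self._add(f"upd{t}_b1", np.zeros(c.hidden))
            self._glorot(rng, f"upd{t}_W2", c.hidden, c.hidden)
            self._add(f"upd{t}_b2", np.zeros(c.hidden))
        self._glorot(rng, "head_W1", c.hidden, c.hidden)
        self._add("head_b1", np.zeros(c.hidden))
        # zero-initialised final head => exact identity corrections
        self._add("head_W2", np.zeros((c.hidden, 2)))
        self._add("head_b2", np.zeros(2))
        self._rbf_centers = np.linspace(0.0, c.cutoff, c.n_rbf)
        self._rbf_width = c.cutoff / c.n_rbf

    def _add(self, name, data):
        self.params[name] = Tensor(np.asarray(data, float))

    def _glorot(self, rng, name, fan_in, fan_out):
        s = math.sqrt(2.0 / (fan_in + fan_out))
        self._add(name, rng.normal(0.0, s, (fan_in, fan_out)))

    # -- forward ------------------------------------------------------------
    def corrections(self, coords: Tensor, batch: MolGraphBatch,
                    dropout_masks: list[np.ndarray] | None = None
                    ) -> tuple[Tensor, Tensor]:
        """Per-atom (rho, gamma_sa) correction factors, softplus-positive."""
        p = self.params
        c = self.config
        n = batch.n_atoms
        if batch.solvent_of_node.max(initial=0) >= p["embed"].shape[0]:
            raise KeyError("solvent index outside the embedding table")
        emb = ad.take_rows(p["embed"], batch.solvent_of_node)
        x = ad.concat_cols([Tensor(batch.node_feats), emb])
        h = ad.silu(x @ p["enc_W"] + p["enc_b"])
        if len(batch.edges):
            ei, ej = batch.edges[:, 0], batch.edges[:, 1]
            d = ad.take_rows(coords, ei) - ad.take_rows(coords, ej)
            r = (d * d).sum(axis=1, keepdims=True).sqrt()     # (E, 1)
            rbf = (-((r - Tensor(self._rbf_centers[None, :])) ** 2)
                   * (0.5 / self._rbf_width ** 2)).exp()
            u = r * (1.0 / c.cutoff)
            env = (1.0 - u * u) ** 2                          # smooth at cutoff
        for t in range(c.n_passes):
            if len(batch.edges):
                hi, hj = ad.take_rows(h, ei), ad.take_rows(h, ej)
                m_in = ad.concat_cols([hi, hj, rbf])
                m = ad.silu(m_in @ p[f"msg{t}_W1"] + p[f"msg{t}_b1"]) \
                    @ p[f"msg{t}_W2"] + p[f"msg{t}_b2"]
                m = m * env
                agg = ad.scatter_add_rows(m, ei, n)
            else:
                agg = Tensor(np.zeros((n, c.hidden)))
            upd = ad.silu(ad.concat_cols([h, agg]) @ p[f"upd{t}_W1"]
                          + p[f"upd{t}_b1"]) @ p[f"upd{t}_W2"] + p[f"upd{t}_b2"]
            h = h + upd
            if dropout_masks is not None:
                h = h * Tensor(dropout_masks[t])
        out = ad.silu(h @ p["head_W1"] + p["head_b1"]) @ p["head_W2"] + p["head_b2"]
        corr = ad.softplus(out + _SOFTPLUS_ONE)
        n_rows = out.shape[0]
        return (corr.slice_cols(0, 1).reshape((n_rows,)),
                corr.slice_cols(1, 2).reshape((n_rows,)))

    def energy_tensor(self, coords: Tensor, batch: MolGraphBatch,
                      gb_by_mol: list[GBParams],
                      dropout_masks=None) -> Tensor:
        """Summed corrected GB-SA energy over all molecules in the batch."""
        from .gb_solvent import gb_sa_energy_batch
        c_rho, c_sa = self.corrections(coords, batch, dropout_masks)
        rho_base = np.concatenate([gb.rho for gb in gb_by_mol])
        gsa_base = np.concatenate([np.full(len(gb.rho), gb.gamma_sa)
                                   for gb in gb_by_mol])
        scales = np.concatenate([gb.scale for gb in gb_by_mol])
        charges = np.concatenate([mol.charges for mol in batch.mols])
        rho = Tensor(rho_base) * c_rho
        gsa = Tensor(gsa_base) * c_sa
        return gb_sa_energy_batch(coords, charges, rho, gsa, scales,
                                  batch.mol_slices, batch.eps_by_mol,
                                  gb_by_mol[0])


def predict_energy_forces(model: GNNISModel, batch: MolGraphBatch,
                          gb: GBParams | list[GBParams], eps_solvent=None
                          ) -> tuple[float, np.ndarray]:
    """Solvent energy (kJ/mol) and per-atom forces for a featurized batch.

    ``eps_solvent`` overrides the dielectric stored in the batch when given.
    """
    gb_list = gb if isinstance(gb, list) else [gb] * len(batch.mols)
    if eps_solvent is not None:
        batch.eps_by_mol = [float(eps_solvent)] * len(batch.mols)
    x = Tensor(batch.coords)
    e = model.energy_tensor(x, batch, gb_list)
    (g,) = ad.grad(e, [x])
    return float(e.data), -g.data


def embedding_vectors(model: GNNISModel) -> np.ndarray:
    """Copy of the solvent-embedding table, rows in registration order."""
    return model.params["embed"].data.copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _global_clip(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads))
    if total > max_norm:
        s = max_norm / total
        grads = [g * s for g in grads]
    return grads


def train(dataset: list[TrainingRecord], hyper: TrainHyper = TrainHyper(),
          config: GNNConfig = GNNConfig(), model: GNNISModel | None = None
          ) -> tuple[GNNISModel, dict]:
    """Force-matching training; returns the model and per-epoch loss history.

    Deterministic for a fixed ``hyper.seed``: the split, batching order,
    dropout masks, and initialisation all derive from it.
    """
    if not dataset:
        raise ValueError("empty training set")
    solvents = {}
    for rec in dataset:
        solvents[rec.solvent.embedding_index] = rec.solvent
    sol_list = [solvents[k] for k in sorted(solvents)]
    if model is None:
        model = GNNISModel(sol_list, config, seed=hyper.seed)
    cfg = model.config
    for rec in dataset:
        if rec.solvent.embedding_index not in solvents:
            raise KeyError(f"solvent {rec.solvent.name!r} not registered")

    feats = []
    for rec in dataset:
        b = featurize(rec.mol, Conformer(rec.coords), rec.solvent,
                      cutoff=cfg.cutoff, elements=cfg.elements)
        b.ref_forces = rec.forces
        feats.append((b, GBParams.from_molecule(rec.mol)))

    rng = np.random.default_rng(hyper.seed)
    order = rng.permutation(len(feats))
    n_val = max(1, int(round(hyper.val_fraction * len(feats))))
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("training split is empty; dataset too small")

    names = sorted(model.params)
    adam_m = {k: np.zeros_like(model.params[k].data) for k in names}
    adam_v = {k: np.zeros_like(model.params[k].data) for k in names}
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    history = {"train_loss": [], "val_loss": [], "val_rmse": [],
               "init_val_rmse": None}

    def batch_loss(idx, dropout_rng=None):
        batch = collate([feats[i][0] for i in idx])
        gb_list = [feats[i][1] for i in idx]
        masks = None
        if dropout_rng is not None and hyper.dropout > 0:
            keep = 1.0 - hyper.dropout
            masks = [(dropout_rng.random((batch.n_atoms, cfg.hidden)) < keep)
                     / keep for _ in range(cfg.n_passes)]
        x = Tensor(batch.coords)
        e = model.energy_tensor(x, batch, gb_list, masks)
        (gx,) = ad.grad(e, [x])
        force = -gx
        resid = force - Tensor(batch.ref_forces)
        return (resid * resid).mean(), batch.ref_forces.size

    v0, _ = batch_loss(val_idx)
    history["init_val_rmse"] = float(np.sqrt(v0.data))

    for epoch in range(hyper.epochs):
        if hyper.epochs > 1:
            lr = hyper.lr_start * (hyper.lr_end / hyper.lr_start) ** (
                epoch / (hyper.epochs - 1))
        else:
            lr = hyper.lr_start
        perm = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(perm), hyper.batch_size):
            idx = perm[start:start + hyper.batch_size]
            loss, _ = batch_loss(idx, dropout_rng=rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch starting {start}; "
                    f"records {list(idx)}")
            step += 1
            params = [model.params[k] for k in names]
            grads_t = ad.grad(loss, params)
            grads = _global_clip([g.data for g in grads_t], hyper.grad_clip_norm)
            for k, g in zip(names, grads):
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                mhat = adam_m[k] / (1 - beta1 ** step)
                vhat = adam_v[k] / (1 - beta2 ** step)
                model.params[k].data -= lr * mhat / (np.sqrt(vhat) + eps_adam)
            epoch_losses.append(float(loss.data))
        vloss, _ = batch_loss(val_idx)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(vloss.data))
        history["val_rmse"].append(float(np.sqrt(vloss.data)))
    return model, history


def validation_rmse(model: GNNISModel, records: list[TrainingRecord]) -> float:
    """Root-mean-square force error (kJ mol^-1 nm^-1) over records."""
    sq, n = 0.0, 0
    for rec in records:
        b = featurize(rec.mol, Conformer(rec.coords), rec.solvent,
                      cutoff=model.config.cutoff, elements=model.config.elements)
        _, f = predict_energy_forces(model, b, GBParams.from_molecule(rec.mol))
        sq += float(((f - rec.forces) ** 2).sum())
        n += rec.forces.size
    return math.sqrt(sq / n)


class GNNISTerm:
    """PotentialTerm adapter: learned solvent energy for one molecule.

    The edge set is rebuilt from the current coordinates on every call, so
    the term can drive minimization and dynamics.
    """

    def __init__(self, model: GNNISModel, mol: MoleculeGraph,
                 solvent: SolventSpec, gb: GBParams | None = None):
        self.model = model
        self.mol = mol
        self.solvent = solvent
        self.gb = gb if gb is not None else GBParams.from_molecule(mol)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        batch = featurize(self.mol, Conformer(coords), self.solvent,
                          cutoff=self.model.config.cutoff,
                          elements=self.model.config.elements)
        return predict_energy_forces(self.model, batch, self.gb)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: GNNISModel, path: str) -> None:
    """Single-file checkpoint: weights + config + solvent registry."""
    meta = {
        "config": {**asdict(model.config), "elements": list(model.config.elements)},
        "solvents": [{"name": s.name, "dielectric": s.dielectric,
                      "embedding_index": s.embedding_index}
                     for s in model.solvents],
    }
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path: str) -> GNNISModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        cfg = meta["config"]
        cfg["elements"] = tuple(cfg["elements"])
        solvents = [SolventSpec(**s) for s in meta["solvents"]]
        model = GNNISModel(solvents, GNNConfig(**cfg), seed=0)
        for k in model.params:
            model.params[k] = Tensor(npz[k])
    return model
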