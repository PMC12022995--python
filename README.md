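# confsolv

Conformer ensembles of small molecules in solution, computed with implicit
solvent models — from the classical generalized-Born/surface-area (GB-SA)
baseline to a graph-network solvent model that learns per-solvent
corrections from reference forces.

## Who this is for

Computational and medicinal chemists who need solution-phase conformer
populations — rotamer ratios against NMR, free-energy differences of
molecular balances, low-energy conformer identification — without running
explicit-solvent molecular dynamics for every molecule–solvent pair.

## What it computes

**Energy model.**  `E(x) = E_MM(x) + E_solv(x)`.  The solvent term is
either classical GB-SA,

    E_GB = -½ f_elec (1/ε_in − 1/ε_s) Σ_ij q_i q_j / f_GB(r_ij; R_i, R_j),
    f_GB = sqrt(r² + R_i R_j exp(−r²/4R_iR_j)),

with effective Born radii `R_i` from pairwise descreening and OBC
rescaling plus a surface-area term `γ_SA·SASA`, or a learned variant in
which an invariant message-passing network — fed element, charge, radius,
interatomic distances, and a learnable 64-dimensional embedding vector per
solvent — rescales the per-atom Born radii and surface tensions
(Δ-learning: the untrained network *is* the GB-SA baseline).  The network
is trained by force matching: MSE between predicted and reference per-atom
solvent forces, Adam, gradient clipping, 95/5 validation split.

**Workflow.**  Random distance-geometry conformers → L-BFGS minimization
(RMS force ≤ 10 kJ mol⁻¹ nm⁻¹) → energy sorting → greedy heavy-atom-RMSD
pruning → quasi-RRHO free energies (Grimme damping of low-frequency
vibrational entropy toward a free rotor, ω₀ = 100 cm⁻¹) → 4-SD outlier
exclusion → Boltzmann weights

    w_i = exp(−G_i/k_B T) / Σ_j exp(−G_j/k_B T).

**Analyses.**  Free-energy profiles by direct counting (with the 4πr²
Jacobian correction for distances), trajectory-frame assignment at a
0.1 nm RMSD cutoff, balanced accuracy over 1-k_BT confusion classes (with
the zero-rate convention for absent classes), gauche/trans populations at
the ±2.1 rad window, mean-centred molecular-balance ΔΔG with slope
diagnostics, and PCA of the learned solvent embeddings.

See `docs/methods.md` for formulas, defaults, and limitations.

## Worked example

Build a Boltzmann-weighted ensemble of the bundled hydrogen-bond probe
(an H–O–C–C=O chain whose H···O contact reports on intramolecular
hydrogen bonding) in water with the GB-SA model:

```
$ confsolv ensemble --toy hbond_probe --model gbneck2 --solvent water \
      --n-confs 24 --rmsd-prune 0.04 --seed 7 \
      --out demo.sdf --report demo.json
3 conformers kept of 24 generated
```

The report shows where the other conformers went — every generated
conformer lands in exactly one bucket:

```
"attrition": {"generated": 24, "minimized": 3, "pruned_out": 14,
              "failed": 7, "excluded_outlier": 0}
```

and the final ensemble with potential energies, quasi-RRHO free energies
(kJ/mol), and Boltzmann weights:

```
{'e_pot': 2.78, 'g_free': -24.27, 'weight': 0.46}
{'e_pot': 2.78, 'g_free': -24.27, 'weight': 0.46}
{'e_pot': 7.81, 'g_free': -19.63, 'weight': 0.07}
```

The two degenerate conformers are mirror-image torsions of the same
hydrogen-bonded ring (identical energies, distinct geometries); the third,
open conformer lies ~4.6 kJ/mol higher in free energy and carries 7% of
the population.  `demo.sdf` holds all 24 conformers with SD tags
`E_POT_KJMOL`, `G_QRRHO_KJMOL`, `BOLTZMANN_WEIGHT`, `STATUS`.

Other entry points: `confsolv train` (force-matching on a JSON-lines
training set), `confsolv mdrun` (Langevin dynamics, LFMiddle splitting,
2 fs), `confsolv analyze profile|pca`, `confsolv fixtures` (deterministic
toy data).  Everything is also available as a library:

```python
from confsolv.synthetic_fixtures import make_toy_molecule
from confsolv.ensemble_pipeline import PipelineConfig, run_ensemble

mol, ff, _ = make_toy_molecule("chain_n", n=4)
ens = run_ensemble(mol, None, "vacuum",
                   PipelineConfig(n_confs=64, rmsd_threshold=0.05, seed=1), ff)
print(ens.attrition(), [c.weight for c in ens.final])
```

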