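# Methods

`confsolv` computes solution-phase conformer ensembles of small molecules
with an implicit representation of the solvent.  This note documents the
models, the numerical choices, and what the synthetic test data can and
cannot show.

## Energy model

The total potential of a solvated molecule is

    E(x) = E_MM(x) + E_solv(x)

where `E_MM` is a minimal classical intramolecular force field and `E_solv`
is one of three interchangeable solvent terms (`vacuum` = none, `gbneck2` =
classical GB-SA, `gnnis` = the learned correction).  Any object exposing
`energy_forces(coords) -> (E, F)` can participate; forces are always the
exact negative gradient of the energy actually evaluated.

### Intramolecular force field (`mm_potential`)

Harmonic bonds and angles without the 1/2 prefactor, `E = k (r - r0)^2` and
`E = k (θ - θ0)^2`, periodic torsions `E = k (1 + cos(nφ - δ))`, and
Lennard-Jones + Coulomb nonbonded terms with 1-2/1-3 exclusions and 1-4
scaling (electrostatic 0.8333, LJ 0.5 — common small-molecule conventions,
overridable per parameter table).  The harmonic convention is stated
prominently because externally exported tables often carry the 1/2.  No
cutoff and no periodicity: implicit-solvent energies use the gas-phase
convention throughout.  Parameter tables are plain YAML/JSON
(`mm_potential.load_ff_params`), which doubles as the import path for
per-molecule dumps from external parametrization toolkits.

### Generalized Born / surface area (`gb_solvent`)

Effective Born radii use the Hawkins–Cramer–Truhlar pairwise-descreening
integral in closed form with the OBC tanh rescaling,

    1/R_i = 1/ρ̃_i − tanh(αΨ − βΨ² + γΨ³)/ρ_i ,   ρ̃_i = ρ_i − offset ,

with defaults α, β, γ = 1.0, 0.8, 4.85 (OBC model II) and offset 0.009 nm.
The polar energy is the Still interpolation with the self term included, so
a single ion reproduces the Born equation exactly.  The nonpolar term is
γ_SA · SASA with γ_SA = 2.26 kJ mol⁻¹ nm⁻² (≈ 0.0054 kcal mol⁻¹ Å⁻²),
probe radius 0.14 nm, and a pairwise spherical-cap SASA: the buried cap of
each neighbour is exact for two spheres, and multiple neighbours combine as
a product of exposed fractions.  The cap term is C⁰ at sphere contact (a
gradient kink on a measure-zero set); force tests sample away from it.

An interstitial "neck" correction in the published functional form is
available behind `neck_enabled` (used by the `gbneck2` preset together with
α, β, γ = 1.095, 1.908, 2.508 and offset 0.0195141 nm).  Its position and
magnitude use an analytic approximation (contact distance + 0.03 nm,
uniform magnitude) rather than tabulated per-radii-pair fits; it is off by
default and no quantitative result in this package depends on it.

Intrinsic radii and descreening scales come from a bundled Bondi-type
element table (`data/gb_radii.csv`), editable by the user.

### Differentiation strategy

All solvent energies are written once as expressions over a small in-repo
reverse-mode autodiff engine (`autodiff.py`) whose backward rules are
themselves composed of differentiable operations.  This buys two things:
the Born-radii chain rule in the forces is exact by construction, and the
force expression can be differentiated a second time with respect to
network weights — which is what force-matching training requires.  The
engine implements only the primitives the package needs (broadcasted
arithmetic, exp/log/tanh/sqrt/pow, reductions, 2-D matmul, row
gather/scatter, column concatenation, and a constant-condition `where` for
piecewise formulas) and is validated against finite differences to first
and second order.  The intramolecular force field uses hand-coded analytic
gradients instead, keeping molecular dynamics cheap.

### Learned solvent model (`gnn_solvent`)

The network is an invariant message-passing model operating on interatomic
distances only.  Node inputs are an element one-hot, the partial charge,
and the intrinsic GB radius; each registered solvent contributes a
learnable 64-dimensional embedding vector, looked up by index and
concatenated to every node before the first pass.  Defaults (configurable):
3 message passes, hidden width 128, SiLU activations, 32 Gaussian radial
basis functions on a 0.6 nm cutoff with a smooth `(1 − (r/c)²)²` envelope
so the fixed edge set does not introduce force discontinuities, dropout 0.1
during training.

The model is a delta-correction on the physics: two node-wise heads emit
factors (softplus-shifted so a zero-initialised head gives exactly 1.0)
that rescale the per-atom intrinsic radius and surface tension, and the
solvent energy is the GB-SA expression evaluated with the corrected
parameters.  Consequences: an untrained model *is* the GB-SA baseline
(asserted to 1e-8 in the tests); rigid-motion invariance and permutation
equivariance hold by construction; and the GB-SA functional form acts as
the inductive bias, so the network only has to learn deviations from it.

Training matches predicted per-atom solvent forces to reference labels:
MSE loss, Adam, gradients clipped to global norm 1, 50 epochs, batch size
256, exponential learning-rate decay from 5e-4 to 5e-6, a 95/5
train/validation split by seeded shuffle.  Energies carry no absolute
reference, so the loss is force-only.  Training is bitwise deterministic
given the seed.  Batches concatenate molecules into one block-diagonal
graph (network and GB-SA evaluation both vectorised across the batch;
per-molecule dielectrics enter through per-pair prefactors).

## Conformer workflow (`ensemble_pipeline`)

1. **Generation** — distance-geometry embedding (plain KDG: connectivity
   bounds, no torsion library) via RDKit, deterministic per seed, followed
   by a bonded-terms-only relaxation that restores ideal bond lengths
   without biasing torsions.
2. **Minimization** — L-BFGS on the composite potential to a
   root-mean-square force of 10 kJ mol⁻¹ nm⁻¹; non-convergent conformers
   get `E = +inf` and are dropped.
3. **Sort + prune** — stable ascending energy sort, then a greedy scan that
   keeps a conformer iff its heavy-atom RMSD (Kabsch superposition,
   hydrogens excluded) to every kept conformer exceeds the threshold, so
   each cluster is represented by its lowest-energy member.  Preset
   conditions: 5120 conformers / 0.075 nm for small flexible compounds,
   51200 / 0.15 nm for large drug-like compounds, 256 / 0.05 nm for
   rotamer-population studies.
4. **Free energies** — normal modes from a central-finite-difference
   Hessian of the analytic forces (step 1e-4 nm), mass-weighted, with the
   exact rigid-body subspace (Eckart projection; 6 modes, 5 for linear)
   projected out before diagonalisation so soft internal modes cannot be
   misclassified as rigid.  Quasi-RRHO free energy:
   `G = E + Σ U_HO(ω) − T (S_trans + S_rot + S_vib)` with per-mode
   `S = w S_HO + (1−w) S_FR`, `w(ω) = 1/(1 + (ω0/ω)^4)`, ω0 = 100 cm⁻¹,
   free-rotor moment damped with B = 1e-44 kg m².  The vibrational enthalpy
   (including ZPE) is kept harmonic; damping applies to the entropy only —
   a documented choice, switchable via `omega0`.  Translational
   (Sackur–Tetrode, 1 bar) and rotational (rigid rotor, σ = 1) entropies
   are included; they cancel in conformer ΔG.
5. **Imaginary modes** — conformers with imaginary frequencies are
   perturbed by a 1e-3 nm seeded jitter, re-minimized and re-analyzed, up
   to 100 times; persistent failures get `G = E = +inf`, status `failed`.
6. **Outliers** — conformers with `|G − median(G)| > 4·sd(G)` (finite G
   only) are excluded.
7. **Weights** — Boltzmann weights over the survivors at 300 K, computed
   shift-invariantly.

Every generated conformer ends in exactly one terminal status
(`minimized` / `pruned_out` / `excluded_outlier` / `failed`); the attrition
report asserts the conservation.

## Dynamics (`minimize_dynamics`)

Langevin dynamics with the middle-scheme splitting (half kick, half drift,
full Ornstein–Uhlenbeck velocity randomisation, half drift, half kick),
which reduces to velocity Verlet at zero friction and gives accurate
configurational averages at 2 fs steps.  Default friction 1 ps⁻¹ (a
conventional value; the thermostat target, not a physical observable),
write-out every 100 steps, center-of-mass motion removed at a fixed
interval.  Coordinates exceeding 1e3 nm abort as "simulation unstable".
No constraints are applied, so unconstrained toy systems use 0.5 fs steps
where needed; 2 fs is the exposed production default.

## Analyses (`ensemble_analysis`)

* Free-energy profiles by direct counting, `G = −kBT ln N`, with the
  `+kBT ln 4πr²` Jacobian correction for distance coordinates and periodic
  binning (72 bins default) for dihedrals (100 bins for distances; both
  configurable — the counts, not the physics, set the resolution).
* ΔG between externally supplied minimum positions, read off the bins.
* Trajectory-frame assignment to the closest conformer below a heavy-atom
  RMSD of 0.1 nm (ties to the lowest index), populations over assigned
  frames, convertible to free energies.
* Balanced accuracy over the four 1-kBT confusion classes, with the rate
  of an absent class defined as zero — so a predictor that never produces
  true negatives is capped at 0.5 rather than rewarded.
* Gauche/trans classification at |φ| ≤ 2.1 rad (boundary inclusive to
  gauche, making the closed interval explicit); state populations are
  Boltzmann-weighted sums over the final ensemble.
* Molecular-balance ΔΔG: per-solvent rotamer free-energy differences,
  each series mean-centred independently, with the least-squares slope of
  prediction against experiment as the accuracy diagnostic.
* PCA of the solvent-embedding matrix (centred SVD), explained-variance
  ratios and projections on the first three components.

## Synthetic data: what it shows and what it does not

The fixtures module generates four toy molecules with closed-form
properties (a harmonic diatomic, an n-carbon torsional chain, a planar
six-ring, and an H-bond probe whose H···O contact provides a reporter
distance), plus training data and trajectories.

The training oracle is a *perturbed GB-SA model*: hidden per-element
rescalings of the intrinsic radii (drawn once per toy solvent from
[0.8, 1.25]) and of the surface tension define the ground truth, and
labels are its analytic forces plus 1 kJ mol⁻¹ nm⁻¹ Gaussian noise.
Because the network's output space is exactly per-atom radius/γ_SA
corrections, this tests the full training machinery (second-order
gradients, batching, scheduling) and the delta-learning premise — the
desk-scale recovery experiment (2 molecules × 2 solvents × 50 conformers =
200 records, hidden width 64, 50 epochs) drives the validation force RMSE
to a few percent of the label RMS.  What it does **not** show: that the
architecture can represent solvent physics *outside* the GB-SA functional
form (hydrogen-bond network effects, dielectric saturation), since the
oracle lives inside that form; nor anything about transferability across
chemistry, since train and validation conformers come from the same toy
molecules.  Those claims would require explicit-solvent reference forces
at scale.

Problem sizes throughout the test-suite and the acceptance script (toy
molecules of 2–6 atoms, 200-record training sets, 16-conformer ensembles,
10⁶-step thermostat runs, 10⁶-sample histograms) are chosen as the
smallest sizes at which each property is statistically decidable; all are
configurable upward.

## Numerical choices and degenerate inputs

* Torsion geometry with three collinear atoms raises a explicit
  degenerate-geometry error; the minimizer maps such transient geometries
  (and energy overflows) to a large finite penalty so line searches can
  back off.
* Dihedrals live in (−π, π] with +π on the trans side, making the ±2.1 rad
  gauche window well defined.
* RMSD always superposes (Kabsch with centroid removal) and always
  excludes hydrogens; symmetry-equivalent atom permutations are not
  considered.
* Boltzmann weights subtract the finite minimum before exponentiation;
  `+inf` free energies get exactly zero weight.
* The SASA exposed fraction is clipped at 1 − 1e-12 before the log; fully
  buried atoms therefore contribute a finite, tiny exposed area.
* Assignment ties, pruning ties (equal energies), and PCA sign
  indeterminacy are all resolved deterministically (lowest index / input
  order / SVD convention).
* All stochastic paths (embedding, jitter, thermostat, dropout, splits)
  draw from `numpy` Generators seeded from a single user seed.

## Known limitations

* The GB radii table and OBC coefficients are conventional defaults, not
  refit to any particular explicit-solvent reference.
* The neck correction is a functional-form approximation (see above).
* The pairwise SASA overcounts multi-sphere overlap less than a summation
  would, but is still approximate beyond two bodies.
* The quasi-RRHO enthalpy treatment (harmonic, undamped) is one of the two
  common conventions; switching the damping into the enthalpy would shift
  conformer ΔG by fractions of kBT for low-frequency modes.
* Training on CPU with the in-repo engine is intended for desk-scale
  datasets (10²–10⁴ records); it is vectorised per batch but not
  parallelised.
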