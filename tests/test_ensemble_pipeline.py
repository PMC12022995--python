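import math

import numpy as np
import pytest

from confsolv.chem_core import KB, Conformer, heavy_atom_rmsd
from confsolv.ensemble_pipeline import (ImaginaryFrequencyError, NormalModes,
                                        PipelineConfig, exclude_outliers,
                                        generate_conformers, handle_imaginary,
                                        normal_modes, qrrho_free_energy,
                                        qrrho_weight, run_ensemble,
                                        sort_and_prune)
from confsolv.minimize_dynamics import CompositeSystem, minimize
from confsolv.mm_potential import MMTerm

_H = 6.62607015e-34
_C_CM = 2.99792458e10
_KB_SI = 1.380649e-23


class TestGenerateConformers:
    def test_zero_requested_gives_empty_list(self, chain4):
        mol, ff, _ = chain4
        assert generate_conformers(mol, 0, seed=1) == []

    def test_rigid_ring_has_no_conformational_spread(self, ring6):
        mol, ff, _ = ring6
        confs = generate_conformers(mol, 20, seed=2, ff_params=ff)
        assert len(confs) == 20
        rmsds = [heavy_atom_rmsd(a, b, mol)
                 for i, a in enumerate(confs) for b in confs[i + 1:]]
        assert max(rmsds) < 0.05

    def test_bond_lengths_near_ideal(self, chain5):
        mol, ff, _ = chain5
        confs = generate_conformers(mol, 10, seed=3, ff_params=ff)
        for c in confs:
            for i, j, k, r0 in ff.bonds:
                r = np.linalg.norm(c.coords[i] - c.coords[j])
                assert abs(r - r0) / r0 < 0.15

    def test_seed_determinism_and_seed_sensitivity(self, chain5):
        mol, ff, _ = chain5
        a = generate_conformers(mol, 8, seed=4, ff_params=ff)
        b = generate_conformers(mol, 8, seed=4, ff_params=ff)
        c = generate_conformers(mol, 8, seed=5, ff_params=ff)
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))
        assert not all(np.allclose(x.coords, y.coords) for x, y in zip(a, c))


def _greedy_reference(confs, threshold, mol):
    """Exhaustive reimplementation of the sort-then-scan pruning rule."""
    idx = sorted(range(len(confs)), key=lambda i: confs[i].e_pot)
    kept = []
    for i in idx:
        if math.isinf(confs[i].e_pot):
            continue
        ok = True
        for j in kept:
            if heavy_atom_rmsd(confs[i], confs[j], mol) <= threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return [confs[i] for i in kept]


class TestSortAndPrune:
    def test_identical_copies_keep_first(self, chain4, rng):
        mol, _, conf = chain4
        confs = [Conformer(conf.coords.copy(), e_pot=1.0) for _ in range(5)]
        kept = sort_and_prune(confs, 0.05, mol)
        assert kept == [confs[0]]
        assert all(c.status == "pruned_out" for c in confs[1:])

    def test_all_distant_all_survive_sorted(self, chain4, rng):
        mol, _, conf = chain4
        confs = []
        for k in range(4):
            c = conf.coords + rng.normal(0, 0.5, conf.coords.shape)
            confs.append(Conformer(c, e_pot=float(3 - k)))
        kept = sort_and_prune(confs, 1e-6, mol)
        assert [c.e_pot for c in kept] == [0.0, 1.0, 2.0, 3.0]

    def test_matches_independent_greedy_oracle(self, chain4, rng):
        mol, _, conf = chain4
        confs = [Conformer(conf.coords + rng.normal(0, 0.05, conf.coords.shape),
                           e_pot=float(rng.normal()))
                 for _ in range(20)]
        ref = _greedy_reference([c.copy() for c in confs], 0.04, mol)
        got = sort_and_prune(confs, 0.04, mol)
        assert len(got) == len(ref)
        for a, b in zip(got, ref):
            np.testing.assert_array_equal(a.coords, b.coords)
        # survivors are pairwise separated
        for i, a in enumerate(got):
            for b in got[i + 1:]:
                assert heavy_atom_rmsd(a, b, mol) > 0.04

    def test_infinite_energies_dropped(self, chain4, rng):
        mol, _, conf = chain4
        good = Conformer(conf.coords.copy(), e_pot=1.0)
        bad = Conformer(conf.coords + 1.0, e_pot=math.inf)
        assert sort_and_prune([bad, good], 0.01, mol) == [good]


class TestNormalModes:
    def test_diatomic_frequency_closed_form(self, diatomic):
        # E = k (r - r0)^2 gives omega = sqrt(2k/mu)
        mol, ff, conf = diatomic
        system = CompositeSystem(mol, [MMTerm(mol, ff)])
        modes = normal_modes(system, conf.coords)
        mu = 12.011 / 2.0
        ref = math.sqrt(2 * 1000.0 / mu * 1e24) / (2 * math.pi * _C_CM)
        vib = modes.vibrational
        assert len(vib) == 1
        assert vib[0] == pytest.approx(ref, rel=1e-3)

    def test_six_rigid_modes_near_zero(self, chain4):
        mol, ff, conf = chain4
        system = CompositeSystem(mol, [MMTerm(mol, ff)])
        res = minimize(system, conf.coords, tol=1e-3)
        modes = normal_modes(system, res.coords)
        assert modes.n_rigid == 6
        rigid = np.sort(np.abs(modes.frequencies))[:6]
        assert np.all(rigid < modes.zero_threshold)

    def test_bent_triatomic_matches_energy_hessian_oracle(self):
        from confsolv.synthetic_fixtures import make_toy_molecule
        mol, ff, conf = make_toy_molecule("chain_n", n=3)
        system = CompositeSystem(mol, [MMTerm(mol, ff)])
        res = minimize(system, conf.coords, tol=1e-4)
        modes = normal_modes(system, res.coords)
        # oracle: Hessian from second differences of the energy itself
        n = 3
        h = 2e-4
        hess = np.zeros((9, 9))
        x0 = res.coords.ravel()

        def e_at(v):
            return system.energy_forces(v.reshape(3, 3))[0]

        for a in range(9):
            for b in range(a, 9):
                xpp = x0.copy(); xpp[a] += h; xpp[b] += h
                xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
                xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
                xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
                hess[a, b] = hess[b, a] = (
                    e_at(xpp) - e_at(xpm) - e_at(xmp) + e_at(xmm)) / (4 * h * h)
        m = np.repeat(mol.masses, 3)
        w = np.linalg.eigvalsh(hess / np.sqrt(np.outer(m, m)))
        ref = np.sqrt(np.abs(w) * 1e24) / (2 * math.pi * _C_CM)
        ref_vib = np.sort(ref)[-3:]   # 3 vibrations for a bent triatomic
        got = modes.vibrational
        np.testing.assert_allclose(got, ref_vib, rtol=5e-3)


def _oracle_qrrho(e_pot, freqs, mol_masses, coords, T):
    """Term-by-term summation oracle built directly from the textbook
    formulas, independent of the implementation."""
    R = KB
    u = s_vib = 0.0
    for nu in freqs:
        theta = _H * _C_CM * nu / _KB_SI
        x = theta / T
        u += R * (theta / 2 + theta / (math.exp(x) - 1))
        s_ho = R * (x / (math.exp(x) - 1) - math.log(1 - math.exp(-x)))
        mu = _H / (8 * math.pi ** 2 * _C_CM * nu)
        mu_p = mu * 1e-44 / (mu + 1e-44)
        s_fr = R * (0.5 + math.log(math.sqrt(8 * math.pi ** 3 * mu_p
                                             * _KB_SI * T) / _H))
        w = 1.0 / (1.0 + (100.0 / nu) ** 4)
        s_vib += w * s_ho + (1 - w) * s_fr
    m_kg = mol_masses.sum() * 1.66053906660e-27
    q_t = (2 * math.pi * m_kg * _KB_SI * T / _H ** 2) ** 1.5 * _KB_SI * T / 1e5
    s = R * (math.log(q_t) + 2.5)
    c = coords - np.average(coords, axis=0, weights=mol_masses)
    inertia = np.zeros((3, 3))
    for mi, ri in zip(mol_masses * 1.66053906660e-27, c * 1e-9):
        inertia += mi * (float(ri @ ri) * np.eye(3) - np.outer(ri, ri))
    mom = np.sort(np.linalg.eigvalsh(inertia))
    if mom[0] < 1e-52:
        s += R * (math.log(8 * math.pi ** 2 * mom[-1] * _KB_SI * T / _H ** 2) + 1)
    else:
        q_r = math.sqrt(math.pi * mom.prod()) * (
            8 * math.pi ** 2 * _KB_SI * T / _H ** 2) ** 1.5
        s += R * (math.log(q_r) + 1.5)
    return e_pot + u - T * (s + s_vib)


class TestQuasiRrho:
    def test_damping_half_at_crossover(self):
        assert qrrho_weight(100.0) == 0.5

    def test_high_frequency_limit_is_harmonic(self):
        assert qrrho_weight(1000.0) == pytest.approx(1.0 / (1 + 1e-4))

    def test_three_mode_toy_matches_summation_oracle(self, chain4):
        mol, _, conf = chain4
        freqs = np.array([80.0, 450.0, 1700.0])
        n = mol.n_atoms
        all_freqs = np.concatenate([np.zeros(3 * n - 3 - 6 + 6)[:6] * 0,
                                    freqs])
        modes = NormalModes(
            frequencies=np.concatenate([np.zeros(3 * n - 3), freqs]),
            eigenvectors=np.eye(3 * n), n_rigid=3 * n - 3,
            zero_threshold=10.0, coords=conf.coords)
        got = qrrho_free_energy(-25.0, modes, mol, 300.0)
        ref = _oracle_qrrho(-25.0, freqs, mol.masses, conf.coords, 300.0)
        assert got == pytest.approx(ref, abs=1e-6)

    def test_reduces_to_rrho_when_damping_removed(self, chain4):
        mol, _, conf = chain4
        freqs = np.array([50.0, 300.0])
        n = mol.n_atoms
        modes = NormalModes(np.concatenate([np.zeros(3 * n - 2), freqs]),
                            np.eye(3 * n), 3 * n - 2, 10.0, conf.coords)
        g_qr = qrrho_free_energy(0.0, modes, mol, 300.0, omega0=1e-9)
        # pure RRHO oracle: w = 1 for every mode
        R = KB
        u = s = 0.0
        for nu in freqs:
            theta = _H * _C_CM * nu / _KB_SI
            x = theta / 300.0
            u += R * (theta / 2 + theta / (math.exp(x) - 1))
            s += R * (x / (math.exp(x) - 1) - math.log(1 - math.exp(-x)))
        base = _oracle_qrrho(0.0, np.array([]), mol.masses, conf.coords, 300.0)
        assert g_qr == pytest.approx(base + u - 300.0 * s, abs=1e-9)

    def test_imaginary_modes_rejected(self, chain4):
        mol, _, conf = chain4
        n = mol.n_atoms
        freqs = np.concatenate([np.zeros(3 * n - 2), [-120.0, 500.0]])
        modes = NormalModes(freqs, np.eye(3 * n), 3 * n - 2, 10.0, conf.coords)
        with pytest.raises(ImaginaryFrequencyError):
            qrrho_free_energy(0.0, modes, chain4[0], 300.0)


class TestHandleImaginary:
    def _saddle_start(self, chain4):
        # eclipsed torsion (phi = 0) is a maximum of k(1 + cos 3 phi):
        # minimizing from the exactly symmetric start converges to the ridge
        from confsolv.synthetic_fixtures import _zigzag
        mol, ff, _ = chain4
        coords = _zigzag([0.153] * 3, phi=0.0)
        system = CompositeSystem(mol, [MMTerm(mol, ff)])
        res = minimize(system, coords, tol=1e-5)
        return mol, system, res

    def test_clean_conformer_returned_unchanged(self, chain4):
        mol, ff, conf = chain4
        system = CompositeSystem(mol, [MMTerm(mol, ff)])
        res = minimize(system, conf.coords, tol=1e-3)
        c = Conformer(res.coords, e_pot=res.energy, status="minimized")
        before = c.coords.copy()
        out = handle_imaginary(c, system, max_repeats=5, seed=0)
        np.testing.assert_array_equal(out.coords, before)

    def test_saddle_resolves_to_real_minimum(self, chain4):
        mol, system, res = self._saddle_start(chain4)
        modes = normal_modes(system, res.coords)
        assert modes.has_imaginary  # the start is a genuine saddle
        c = Conformer(res.coords, e_pot=res.energy, status="minimized")
        out = handle_imaginary(c, system, max_repeats=100, tol=1e-3, seed=1)
        assert out.status == "minimized"
        final = normal_modes(system, out.coords)
        assert not final.has_imaginary

    def test_hopeless_potential_marks_failed(self, chain4):
        class AntiBond:
            # negative curvature along the 0-1 stretch that overwhelms the
            # harmonic bond (k = 1e5): every geometry keeps an imaginary
            # stretch mode and the energy is unbounded below
            def energy_forces(self, coords):
                d = coords[0] - coords[1]
                r = np.linalg.norm(d)
                e = -1.5e5 * (r - 0.153) ** 2
                g = -3.0e5 * (r - 0.153) * d / r
                f = np.zeros_like(coords)
                f[0] = -g
                f[1] = g
                return e, f

        mol, ff, conf = chain4
        system = CompositeSystem(mol, [MMTerm(mol, ff), AntiBond()])
        c = Conformer(conf.coords.copy(), e_pot=0.0, status="minimized")
        out = handle_imaginary(c, system, max_repeats=3, seed=0)
        assert out.status == "failed"
        assert math.isinf(out.g_free) and math.isinf(out.e_pot)


class TestExcludeOutliers:
    def _confs(self, gs):
        return [Conformer(np.zeros((1, 3)), g_free=g, status="minimized")
                for g in gs]

    def test_all_equal_none_removed(self):
        confs = self._confs([2.0] * 5)
        assert exclude_outliers(confs) == confs

    def test_rule_matches_hand_evaluation(self):
        # median 0, sd 40: |−100| < 4*40, so nothing is removed
        confs = self._confs([0.0, 0.0, 0.0, 0.0, -100.0])
        assert len(exclude_outliers(confs)) == 5
        # with 20 zeros the sd shrinks enough that −100 is excluded
        confs = self._confs([0.0] * 20 + [-100.0])
        g = np.array([0.0] * 20 + [-100.0])
        assert abs(-100.0 - np.median(g)) > 4 * np.std(g)  # hand check
        kept = exclude_outliers(confs)
        assert len(kept) == 20
        assert confs[-1].status == "excluded_outlier"

    def test_single_finite_value_unchanged(self):
        confs = self._confs([1.0, math.inf])
        assert exclude_outliers(confs) == confs


class TestRunEnsemble:
    def test_rigid_toy_single_conformer_weight_one(self, ring6):
        mol, ff, _ = ring6
        cfg = PipelineConfig(n_confs=6, rmsd_threshold=0.05, seed=1)
        ens = run_ensemble(mol, None, "vacuum", cfg, ff)
        assert len(ens.final) == 1
        assert ens.final[0].weight == pytest.approx(1.0)

    def test_bookkeeping_conserved_across_models(self, chain4):
        from confsolv.cli_io import load_solvent_registry
        mol, ff, _ = chain4
        water = load_solvent_registry()["water"]
        cfg = PipelineConfig(n_confs=12, rmsd_threshold=0.03, seed=7)
        for model, sol in (("vacuum", None), ("gbneck2", water)):
            ens = run_ensemble(mol, sol, model, cfg, ff)
            att = ens.attrition()
            assert att["generated"] == (att["minimized"] + att["pruned_out"]
                                        + att["excluded_outlier"] + att["failed"])
            for i, a in enumerate(ens.final):
                for b in ens.final[i + 1:]:
                    assert heavy_atom_rmsd(a, b, mol) > cfg.rmsd_threshold

    def test_same_seed_identical_ensembles(self, chain4):
        mol, ff, _ = chain4
        cfg = PipelineConfig(n_confs=10, rmsd_threshold=0.03, seed=3)
        e1 = run_ensemble(mol, None, "vacuum", cfg, ff)
        e2 = run_ensemble(mol, None, "vacuum", cfg, ff)
        assert len(e1.final) == len(e2.final)
        for a, b in zip(e1.final, e2.final):
            np.testing.assert_array_equal(a.coords, b.coords)
            assert a.g_free == b.g_free and a.weight == b.weight

    def test_pruning_monotone_in_threshold(self, chain4, rng):
        mol, _, conf = chain4
        confs = [Conformer(conf.coords + rng.normal(0, 0.05, conf.coords.shape),
                           e_pot=float(rng.normal())) for _ in range(15)]
        counts = []
        for thr in (0.01, 0.03, 0.06, 0.12):
            fresh = [c.copy() for c in confs]
            for c in fresh:
                c.status = "minimized"
            counts.append(len(sort_and_prune(fresh, thr, mol)))
        assert counts == sorted(counts, reverse=True)
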