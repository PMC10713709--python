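"""Toy simulator: geometry, RMSD/bias machinery, integrator, mock tables.

Long biased-dynamics behaviour (water expulsion statistics) lives in the
acceptance suite; here we cover the deterministic contracts and short
runs.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conjscan import toy_exchange_sim as sim
from conjscan.fmo_energetics import eta6_segment_stats
from conjscan.toy_exchange_sim import (
    BiasState,
    MtdParams,
    bias_energy,
    bias_gradient,
    build_toy_system,
    confinement_energy,
    confinement_gradient,
    generate_mock_pie_table,
    rmsd_superposed,
    run_dynamics,
)
from conjscan.traj_io import Frame, Trajectory


def quaternion_rmsd_oracle(a, b):
    """Independent minimum-RMSD via the quaternion key-matrix eigenvalue."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = ac.T @ bc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    d2 = max((np.sum(ac**2) + np.sum(bc**2) - 2 * lam) / len(a), 0.0)
    return np.sqrt(d2)


class TestBuildSystem:
    def test_ligand_site_inventory(self):
        t = build_toy_system("T-like", 1)
        assert t.het_sites == {}
        pc = build_toy_system("pC-like", 1)
        (o_idx, kind), = pc.het_sites.items()
        assert kind == "O"
        assert o_idx in pc.acceptors            # donor and acceptor
        assert any(d == o_idx for d, _ in pc.donors)
        mi = build_toy_system("3MI", 1)
        (n_idx, kind), = mi.het_sites.items()
        assert kind == "N"
        assert n_idx not in mi.acceptors        # NH is donor-only
        assert set(mi.ring_atoms) == {"phenyl", "pyrrole"}

    def test_same_seed_reproduces_coordinates(self):
        a = build_toy_system("pC", 7)
        b = build_toy_system("pC", 7)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_unknown_ligand_rejected(self):
        with pytest.raises(ValueError, match="unknown ligand"):
            build_toy_system("His-like", 0)

    def test_starts_as_encounter_complex(self):
        for lig in ("pC", "3MI", "T"):
            s = build_toy_system(lig, 0)
            rw = np.linalg.norm(s.coords[s.water_oxygens] - s.coords[s.rh],
                                axis=1)
            assert np.all(rw < 2.5)             # waters in the first shell
            ring = [a for atoms in s.ring_atoms.values() for a in atoms]
            rr = np.linalg.norm(s.coords[ring] - s.coords[s.rh], axis=1)
            assert np.all(rr > 3.0)             # arene outside it

    def test_scheme_partitions_all_atoms(self):
        s = build_toy_system("3MI", 2)
        scheme = s.scheme()
        atoms = sorted(a for f in scheme.fragments.values() for a in f.atoms)
        assert atoms == list(range(s.n_atoms))
        assert scheme.fragments[5].label == "X"


class TestRmsd:
    def test_identical_sets_zero(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        assert rmsd_superposed(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_gives_zero(self):
        x = np.random.default_rng(1).normal(size=(6, 3))
        rot = Rotation.from_euler("zyx", [0.4, -1.2, 2.2])
        y = rot.apply(x) + np.array([3.0, -1.0, 7.0])
        assert rmsd_superposed(x, y) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert rmsd_superposed(a, b) == pytest.approx(
            quaternion_rmsd_oracle(a, b), abs=1e-8)

    def test_symmetry_and_common_motion_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        assert rmsd_superposed(a, b) == pytest.approx(
            rmsd_superposed(b, a), abs=1e-10)
        rot = Rotation.from_euler("xyz", [1.0, 0.2, -0.7])
        shift = np.array([5.0, 5.0, -2.0])
        assert rmsd_superposed(rot.apply(a) + shift, rot.apply(b) + shift) \
            == pytest.approx(rmsd_superposed(a, b), abs=1e-8)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            rmsd_superposed(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_batch_path_agrees_with_single(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(4, 3))
        refs = rng.normal(size=(20, 4, 3))
        fast = sim._batch_rmsd_fast(x, refs)
        expect = [rmsd_superposed(x, r) for r in refs]
        np.testing.assert_allclose(fast, expect, atol=1e-9)


class TestBias:
    def params(self, **kw):
        kw.setdefault("k_push", 0.05)
        kw.setdefault("alpha", 0.9)
        return MtdParams(**kw)

    def test_empty_history_is_zero(self):
        x = np.zeros((3, 3))
        assert bias_energy(x, BiasState(), self.params()) == 0.0
        np.testing.assert_array_equal(
            bias_gradient(x, BiasState(), self.params()), 0.0)

    def test_value_at_stored_reference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 3))
        bias = BiasState()
        bias.deposit(x)
        p = self.params()
        expect = p.k_push * 3 * p.energy_scale
        assert bias_energy(x, bias, p) == pytest.approx(expect)

    def test_monotone_decay_with_distance(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(4, 3)) * 2.0
        bias = BiasState()
        bias.deposit(ref)
        p = self.params()
        # stretch progressively away from the reference
        vals = [bias_energy(ref * (1 + eps), bias, p)
                for eps in (0.0, 0.2, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_additive_in_snapshots(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 3))
        refs = [rng.normal(size=(4, 3)) for _ in range(4)]
        p = self.params()
        joint = BiasState()
        total = 0.0
        for r in refs:
            single = BiasState()
            single.deposit(r)
            total += bias_energy(x, single, p)
            joint.deposit(r)
        assert bias_energy(x, joint, p) == pytest.approx(total)
        assert bias_energy(x, joint, p) >= 0.0

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 3))
        bias = BiasState()
        for _ in range(3):
            bias.deposit(x + 0.3 * rng.normal(size=(4, 3)))
        p = self.params()
        g = bias_gradient(x, bias, p)
        h = 1e-5
        for i in range(4):
            for k in range(3):
                xp = x.copy(); xp[i, k] += h
                xm = x.copy(); xm[i, k] -= h
                num = (bias_energy(xp, bias, p)
                       - bias_energy(xm, bias, p)) / (2 * h)
                assert g[i, k] == pytest.approx(num, abs=1e-6)


class TestConfinement:
    def test_deep_inside_is_negligible(self):
        assert confinement_energy(np.zeros((1, 3)), 15.0, 298.15) < 1e-3

    def test_monotone_wall(self):
        r = 8.0
        at = lambda d: confinement_energy(np.array([[d, 0.0, 0.0]]), r, 298.15)
        assert at(r + 2) > at(r) > at(r - 2)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-9, 9, size=(6, 3))
        g = confinement_gradient(x, 8.0, 298.15)
        h = 1e-6
        for i in range(6):
            for k in range(3):
                xp = x.copy(); xp[i, k] += h
                xm = x.copy(); xm[i, k] -= h
                num = (confinement_energy(xp, 8.0, 298.15)
                       - confinement_energy(xm, 8.0, 298.15)) / (2 * h)
                assert g[i, k] == pytest.approx(num, abs=1e-6)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            confinement_energy(np.zeros((1, 3)), -1.0, 298.15)


class TestDynamics:
    def test_symplectic_limit_conserves_energy(self):
        """No bias, no friction, zero temperature: the integrator reduces
        to velocity Verlet and, started from a relaxed structure, total
        energy must not drift over 10^4 steps."""
        system = build_toy_system("T", 0)
        params = MtdParams(sim_length=20.0, temperature=0.0, friction=0.0,
                           seed=0, snapshot_interval=100.0)
        relaxed = sim.minimize_energy(system, params)
        # nudge off the minimum so the check is not vacuous
        system.coords = relaxed + 1e-3 * np.random.default_rng(0) \
            .standard_normal(relaxed.shape)
        traj, ledger = run_dynamics(system, params, biased=False)
        total = ledger["potential"] + ledger["kinetic"]
        drift = abs(np.polyfit(np.arange(len(total)), total, 1)[0]) \
            * len(total)
        assert drift < 1e-4
        assert total.max() - total.min() < 1e-3   # bounded oscillation too

    def test_kpush_zero_biased_equals_unbiased(self):
        system = build_toy_system("pC", 4)
        params = MtdParams(sim_length=0.5, k_push=0.0, seed=4)
        t1, _ = run_dynamics(system, params, biased=True)
        system2 = build_toy_system("pC", 4)
        t2, _ = run_dynamics(system2, params, biased=False)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_determinism_from_seed(self):
        params = MtdParams(sim_length=0.5, seed=11)
        t1, l1 = run_dynamics(build_toy_system("3MI", 11), params)
        t2, l2 = run_dynamics(build_toy_system("3MI", 11), params)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.coords, b.coords)
        assert l1.equals(l2)

    def test_snapshot_bookkeeping(self):
        params = MtdParams(sim_length=2.0, seed=1)
        traj, ledger = run_dynamics(build_toy_system("T", 1), params)
        assert len(traj) == 40                     # 2 ps / 50 fs
        assert traj[0].time == pytest.approx(0.05)
        assert traj[-1].time == pytest.approx(2.0)
        assert len(ledger) == len(traj)


class FakeState:
    def __init__(self, hapticity, waters=0, het=()):
        self.hapticity = hapticity
        self.bound_water_count = waters
        self.bound_heteroatoms = frozenset(het)


def make_flat_traj(n):
    frames = [Frame(index=i, time=0.05 * (i + 1), elements=["C"],
                    coords=np.zeros((1, 3))) for i in range(n)]
    return Trajectory(frames=frames)


class TestMockPieTable:
    def test_noise_free_eta6_is_constant_at_the_mean(self):
        traj = make_flat_traj(5)
        states = [FakeState(6) for _ in range(5)]
        table = generate_mock_pie_table(traj, states, noise_sd=0.0, seed=0)
        series = table.pair_series((1, 5))
        assert set(np.round(series, 10)) == {sim.HAPTICITY_PIE_MEANS[6]}

    def test_components_close_exactly(self):
        traj = make_flat_traj(20)
        states = [FakeState(h % 7) for h in range(20)]
        table = generate_mock_pie_table(traj, states, noise_sd=2.0, seed=3)
        for rec in table.records():
            assert rec.closure_error < 1e-9

    def test_bound_vs_unbound_water_pairs(self):
        traj = make_flat_traj(50)
        states = [FakeState(0, waters=2) for _ in range(50)]
        table = generate_mock_pie_table(traj, states, noise_sd=1.0, seed=1)
        wat1 = table.pair_series((1, 2)).mean()   # bound
        wat3 = table.pair_series((1, 4)).mean()   # expelled
        assert wat1 == pytest.approx(-25.0, abs=1.0)
        assert wat3 == pytest.approx(0.0, abs=1.0)

    def test_eta6_mean_recovery(self):
        traj = make_flat_traj(100)
        states = [FakeState(6) for _ in range(100)]
        table = generate_mock_pie_table(traj, states, noise_sd=1.5, seed=2)
        series = table.pair_series((1, 5)).tolist()
        mean, sd, n = eta6_segment_stats(series, [6] * 100)
        assert n == 100
        # 2·noise_sd/√n recovery window
        assert mean == pytest.approx(sim.HAPTICITY_PIE_MEANS[6], abs=0.3)

    def test_charge_anticorrelates_with_charge_transfer(self):
        traj = make_flat_traj(60)
        states = [FakeState(h) for h in
                  np.random.default_rng(0).integers(0, 7, size=60)]
        table = generate_mock_pie_table(traj, states, noise_sd=1.0, seed=5)
        q3 = table.charges[table.charges.frag == 1].charge.to_numpy()
        ct = np.abs(table.pair_series((1, 5), "E_ct").to_numpy())
        corr = np.corrcoef(q3, ct)[0, 1]
        assert corr < -0.9

    def test_misaligned_series_rejected(self):
        traj = make_flat_traj(3)
        with pytest.raises(ValueError, match="frames"):
            generate_mock_pie_table(traj, [FakeState(6)] * 2)
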