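"""Langevin filament simulator: energies, units, thermostat, rupture."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from tipbond import langevin as L


class TestEnergies:
    def test_straight_chain_is_ground_state(self):
        pos = np.column_stack([np.arange(10.0), np.zeros(10)])
        es, fs = L.stretching_energy(pos, 5e3)
        eb, fb = L.bending_energy(pos, 5.1)
        assert es == 0.0 and eb == 0.0
        assert np.allclose(fs, 0) and np.allclose(fb, 0)

    def test_single_stretched_bond(self):
        pos = np.array([[0.0, 0.0], [1.1, 0.0]])
        e, _ = L.stretching_energy(pos, 100.0)
        assert e == pytest.approx(100.0 / 2 * 0.1**2, rel=1e-12)

    def test_right_angle_kink(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        e, _ = L.bending_energy(pos, 5.1)
        # |t2 - t1|^2 = 2 for orthogonal unit tangents
        assert e == pytest.approx(5.1 / 2 * 2.0, rel=1e-12)

    def test_wca_reference_points(self):
        cut = 2 ** (1 / 6)
        e_cut, f_cut = L.wca_energy(np.array([[0.0, 0.0], [cut, 0.0]]), 1.0)
        assert e_cut == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f_cut, 0.0, atol=1e-10)
        e_sigma, _ = L.wca_energy(np.array([[0.0, 0.0], [1.0, 0.0]]), 1.0)
        assert e_sigma == pytest.approx(1.0, rel=1e-12)

    def test_coincident_beads_rejected(self):
        pos = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            L.stretching_energy(pos, 1.0)
        with pytest.raises(ValueError):
            L.wca_energy(pos, 1.0)

    @pytest.mark.parametrize("which", ["stretch", "bend", "wca"])
    def test_forces_match_finite_differences(self, which):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(0, 0.3, (8, 2)), axis=0) + \
            np.arange(8)[:, None] * [1.0, 0.0]
        fns = {
            "stretch": lambda x: L.stretching_energy(x, 100.0),
            "bend": lambda x: L.bending_energy(x, 5.1),
            "wca": lambda x: L.wca_energy(
                x, 1.0, exclude={(i, i + 1) for i in range(7)}
            ),
        }
        fn = fns[which]
        _, analytic = fn(pos)
        h = 1e-6
        numeric = np.zeros_like(analytic)
        for i in range(8):
            for k in range(2):
                p_plus, p_minus = pos.copy(), pos.copy()
                p_plus[i, k] += h
                p_minus[i, k] -= h
                numeric[i, k] = -(fn(p_plus)[0] - fn(p_minus)[0]) / (2 * h)
        scale = max(np.abs(numeric).max(), 1.0)
        assert np.abs(analytic - numeric).max() / scale < 1e-6

    def test_kernel_matches_reference_assembly(self, default_lparams):
        """The compiled force kernel agrees with the numpy energies on a
        full dimer (stretch + bend + WCA + springs + pulling)."""
        p = default_lparams
        system = L.build_arrangement("dimer", p, pull_force=10.0)
        rng = np.random.default_rng(1)
        system.positions += rng.normal(0, 0.02, system.positions.shape)
        F = L.compute_forces(system, p)
        N = p.N
        ref = np.zeros_like(system.positions)
        for f in range(2):
            seg = slice(f * N, (f + 1) * N)
            ref[seg] += L.stretching_energy(system.positions[seg], p.A)[1]
            ref[seg] += L.bending_energy(system.positions[seg], p.kappa)[1]
        excl = {(i, i + 1) for f in range(2) for i in range(f * N, (f + 1) * N - 1)}
        ref += L.wca_energy(system.positions, p.epsilon_wca, exclude=excl)[1]
        for (a, b), rest in zip(system.breakable_bonds, system.bond_rest):
            d = system.positions[b] - system.positions[a]
            dist = np.linalg.norm(d)
            fv = p.k_m * (dist - rest) * d / dist
            ref[a] += fv
            ref[b] -= fv
        ref += system.pull_force
        assert np.abs(F - ref).max() < 1e-9


class TestCatchSlipRate:
    def test_zero_force_sum_of_bare_rates(self, default_lparams):
        assert L.catch_slip_rate(0.0, default_lparams) == pytest.approx(
            0.100004, abs=1e-9
        )

    def test_rate_minimum_location(self, default_lparams):
        fstar = L.optimal_bond_force(default_lparams)
        assert fstar == pytest.approx(math.log(12500) / 0.3, rel=1e-12)
        eps = 1e-3
        w = L.catch_slip_rate
        assert w(fstar, default_lparams) < w(fstar - eps, default_lparams)
        assert w(fstar, default_lparams) < w(fstar + eps, default_lparams)

    def test_slip_asymptotics(self, default_lparams):
        p = default_lparams
        f = 200.0
        ratio = L.catch_slip_rate(f, p) / (p.omega0_1 * math.exp(f / p.f_d1))
        assert ratio == pytest.approx(1.0, rel=1e-6)

    def test_negative_force_rejected(self, default_lparams):
        with pytest.raises(ValueError):
            L.catch_slip_rate(-1.0, default_lparams)


class TestUnitMap:
    def test_printed_conversions(self):
        u = L.ReducedUnits()
        assert L.to_physical(1.0, "force", u) == pytest.approx(0.42)
        assert L.to_physical(1.0, "time", u) == pytest.approx(2.38e-3, rel=0.005)
        assert L.to_physical(5.1, "bending", u) == pytest.approx(2.142e-4)
        assert L.to_physical(5e3, "force", u) == pytest.approx(2.1e3)
        assert L.to_physical(15.0, "stiffness", u) == pytest.approx(0.63)
        assert L.to_physical(10.0, "force", u) == pytest.approx(4.2)
        assert L.to_physical(4e-6, "rate", u) == pytest.approx(1.68e-3, rel=0.005)
        assert L.to_physical(0.1, "rate", u) == pytest.approx(42.0)

    def test_zero_maps_to_zero(self):
        for q in ("length", "time", "force", "rate", "stiffness", "bending",
                  "energy"):
            assert L.to_physical(0.0, q) == 0.0

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            L.to_physical(1.0, "volume")


class TestArrangements:
    def test_dimer_construction(self, default_lparams):
        s = L.build_arrangement("dimer", default_lparams, pull_force=5.0)
        assert len(s.breakable_bonds) == default_lparams.n_bonds
        assert s.tethered.sum() == 1
        assert (np.abs(s.pull_force).sum(axis=1) > 0).sum() == 1

    def test_tetramer_free_doubles_bonds(self, default_lparams):
        s = L.build_arrangement("tetramer_free", default_lparams, pull_force=5.0)
        assert len(s.breakable_bonds) == 2 * default_lparams.n_bonds
        assert s.tethered.sum() == 2
        # total external force is shared between the two pulled ends
        np.testing.assert_allclose(s.pull_force.sum(axis=0), [5.0, 0.0])

    def test_crosslinks_add_three_permanent_links(self, default_lparams):
        free = L.build_arrangement("tetramer_free", default_lparams)
        xl = L.build_arrangement("tetramer_crosslinked", default_lparams)
        assert len(xl.permanent_links) == len(free.permanent_links) + 3

    def test_unknown_tag_rejected(self, default_lparams):
        with pytest.raises(ValueError):
            L.build_arrangement("trimer", default_lparams)


class TestDynamics:
    def test_zero_temperature_equilibrium_fixed_point(self, free_filament):
        p = replace(L.LangevinParams(), kBT=1e-30)
        start = free_filament.positions.copy()
        sp, _ = L.simulate_trajectory(free_filament, p, 2000, 2000, seed=1)
        assert np.abs(sp[-1] - start).max() < 1e-6

    def test_trajectory_deterministic_under_seed(self, free_filament,
                                                 default_lparams):
        a, va = L.simulate_trajectory(free_filament, default_lparams, 5000,
                                      500, seed=42)
        b, vb = L.simulate_trajectory(free_filament, default_lparams, 5000,
                                      500, seed=42)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(va, vb)

    def test_equipartition(self, free_filament, default_lparams):
        """Time-averaged kinetic energy per degree of freedom is kBT/2
        within 5% for a thermalised free filament."""
        _, sv = L.simulate_trajectory(
            free_filament, default_lparams, n_steps=100000, sample_every=50,
            seed=3, n_equil=5000,
        )
        ke_per_dof = 0.5 * default_lparams.mass * np.mean(sv**2)
        assert ke_per_dof == pytest.approx(0.5, rel=0.05)

    def test_persistence_length(self, free_filament, default_lparams):
        """Tangent correlations of the u = 3.33 filament decay with
        lambda = 2 kappa / kBT within 10% (initial-decay fit; chain
        discreteness and excluded volume bend the tail upward)."""
        sp, _ = L.simulate_trajectory(
            free_filament, default_lparams, n_steps=1500000, sample_every=500,
            seed=7, n_equil=100000,
        )
        corr = []
        for s in (1, 2, 3):
            acc = []
            for snap in sp:
                b = np.diff(snap, axis=0)
                t = b / np.linalg.norm(b, axis=1)[:, None]
                acc.append(np.mean(np.sum(t[s:] * t[:-s], axis=1)))
            corr.append(np.mean(acc))
        slope = np.polyfit([1, 2, 3], np.log(corr), 1)[0]
        lam = -1.0 / slope
        expected = 2 * default_lparams.kappa / default_lparams.kBT
        assert lam == pytest.approx(expected, rel=0.10)


class TestRupture:
    def test_no_bonds_means_zero_lifetime(self, free_filament, default_lparams):
        tau, censored = L.run_lifetime(free_filament, default_lparams, seed=1)
        assert tau == 0.0 and not censored

    def test_single_bond_rupture_statistics(self, rigid_single_bond,
                                            default_lparams):
        """With both beads frozen the bond load is constant and rupture
        times are exponential with the analytic catch-slip rate."""
        p = default_lparams
        load = 60.0
        system = rigid_single_bond(load, p)
        taus = np.array([
            L.run_lifetime(system, p, seed=1000 + i, t_max=100.0, n_equil=0)[0]
            for i in range(2000)
        ])
        w_true = L.catch_slip_rate(load, p)
        rate = 1.0 / taus.mean()
        assert abs(rate - w_true) / w_true < 0.05
        ks = stats.kstest(taus, "expon", args=(0, 1 / w_true))
        assert ks.pvalue > 0.05

    def test_lifetime_decreases_with_higher_bare_slip_rate(
            self, rigid_single_bond, default_lparams):
        p_fast = replace(default_lparams, omega0_1=default_lparams.omega0_1 * 50)
        load = 60.0
        taus_slow = np.mean([
            L.run_lifetime(rigid_single_bond(load, default_lparams),
                           default_lparams, seed=i, t_max=100.0, n_equil=0)[0]
            for i in range(300)
        ])
        taus_fast = np.mean([
            L.run_lifetime(rigid_single_bond(load, p_fast), p_fast,
                           seed=i, t_max=100.0, n_equil=0)[0]
            for i in range(300)
        ])
        assert taus_fast < taus_slow

    def test_ensemble_requires_replicates(self, default_lparams):
        with pytest.raises(ValueError):
            L.lifetime_vs_force("dimer", [10.0], n_runs=1)
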