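"""Wigner sampling, Verlet integration, LZBL hopping, swarm analysis."""

import numpy as np
import pytest

from photopot import model_systems as ms
from photopot.chemio import Geometry
from photopot.constants import EV_PER_AMU_A2_FS2, HBAR_EV_FS
from photopot.dynamics import (
    PhaseSpacePoint,
    TSHConfig,
    attempt_hop,
    bonded_pairs,
    cis_trans_classifier,
    detect_dissociation,
    detect_gap_minimum,
    dihedral_angle,
    kinetic_energy,
    lzbl_probability,
    populations,
    propagate_tsh,
    quantum_yield,
    summarize_swarm,
    verlet_step,
    wigner_mode_sigmas,
    wigner_sample,
)


class TestWigner:
    def test_zero_temperature_limit(self):
        """T -> 0: coth -> 1, so var(Q) -> hbar/(2 omega)."""
        sq, _ = wigner_mode_sigmas(1000.0, 0.0)
        omega = 2 * np.pi * 2.99792458e-5 * 1000.0
        hbar_int = HBAR_EV_FS / EV_PER_AMU_A2_FS2
        assert sq**2 == pytest.approx(hbar_int / (2 * omega), rel=1e-12)

    def test_sample_mean_near_equilibrium(self, osc3_pes):
        spec = ms.diatomic_wigner_spec(osc3_pes)
        pts = wigner_sample(spec, 400, seed=3)
        mean = np.mean([p.coords for p in pts], axis=0)
        sq, _ = wigner_mode_sigmas(float(spec.frequencies_cm[0]), spec.temperature)
        # 3 sigma / sqrt(n) tolerance on the bond length
        d = np.linalg.norm(mean[1] - mean[0])
        mu = osc3_pes.masses.prod() / osc3_pes.masses.sum()
        tol = 3 * (sq / np.sqrt(mu)) / np.sqrt(400)
        assert abs(d - osc3_pes.r0) < tol

    def test_empirical_variance_matches_coth_formula(self, osc3_pes):
        """1e5 samples of a single-mode diatomic reproduce both variances within 2%."""
        spec = ms.diatomic_wigner_spec(osc3_pes, temperature=298.0)
        pts = wigner_sample(spec, 100_000, seed=7)
        mu = osc3_pes.masses.prod() / osc3_pes.masses.sum()
        q = np.array([np.linalg.norm(p.coords[1] - p.coords[0]) - osc3_pes.r0 for p in pts])
        v_rel = np.array([p.velocities[1, 2] - p.velocities[0, 2] for p in pts])
        sq, sp = wigner_mode_sigmas(float(spec.frequencies_cm[0]), 298.0)
        assert np.var(q) == pytest.approx(sq**2 / mu, rel=0.02)
        assert np.var(v_rel) == pytest.approx(sp**2 / mu, rel=0.02)

    def test_deterministic_per_seed(self, osc3_pes):
        spec = ms.diatomic_wigner_spec(osc3_pes)
        a = wigner_sample(spec, 5, seed=11)
        b = wigner_sample(spec, 5, seed=11)
        for p, q in zip(a, b):
            np.testing.assert_array_equal(p.coords, q.coords)
            np.testing.assert_array_equal(p.velocities, q.velocities)

    def test_net_momentum_projected_out(self, osc3_pes):
        spec = ms.diatomic_wigner_spec(osc3_pes)
        for p in wigner_sample(spec, 10, seed=2):
            mom = (p.masses[:, None] * p.velocities).sum(axis=0)
            np.testing.assert_allclose(mom, 0.0, atol=1e-10)

    def test_nonpositive_frequency_rejected(self, osc3_pes):
        with pytest.raises(ValueError):
            wigner_mode_sigmas(-100.0, 298.0)


class TestVerlet:
    def test_zero_force_uniform_motion(self):
        p = PhaseSpacePoint(np.zeros((1, 3)), np.array([[0.1, 0, 0]]), np.array([1.0]))
        p2 = verlet_step(p, lambda c: np.zeros((1, 3)), 0.5)
        np.testing.assert_allclose(p2.coords, [[0.05, 0, 0]])
        np.testing.assert_allclose(p2.velocities, p.velocities)

    def test_harmonic_oscillator_energy_and_period(self):
        """1D harmonic oscillator at dt = T/1000: relative drift < 1e-6 over 10 periods,
        numerical period within 0.1% of 2 pi/omega."""
        k, m = 5.0, 2.0  # eV/A^2, amu
        # omega^2 = (k / EV_PER_AMU_A2_FS2) / m with k converted to amu/fs^2
        omega = np.sqrt(k / EV_PER_AMU_A2_FS2 / m)
        period = 2 * np.pi / omega
        dt = period / 1000
        x0 = 0.3
        p = PhaseSpacePoint(np.array([[x0, 0, 0]]), np.zeros((1, 3)), np.array([m]))

        def force(c):
            f = np.zeros((1, 3))
            f[0, 0] = -k * c[0, 0]
            return f

        def energy(pt):
            return kinetic_energy(pt) + 0.5 * k * pt.coords[0, 0] ** 2

        e0 = energy(p)
        crossings = []
        prev_x = p.coords[0, 0]
        t = 0.0
        for _ in range(10_000):
            p = verlet_step(p, force, dt)
            t += dt
            x = p.coords[0, 0]
            if prev_x < 0 <= x:
                # linear interpolation of the upward zero crossing
                crossings.append(t - dt * x / (x - prev_x))
            prev_x = x
        assert abs(energy(p) - e0) / e0 < 1e-6
        measured_period = np.mean(np.diff(crossings))
        assert measured_period == pytest.approx(period, rel=1e-3)


class TestGapMinimum:
    @pytest.mark.parametrize(
        "hist, expected",
        [((3, 1, 2), True), ((1, 2, 3), False), ((2, 1, 1), True), ((1, 1, 1), False),
         ((2, 1), False)],
    )
    def test_rule(self, hist, expected):
        assert detect_gap_minimum(hist) is expected


class TestLZBLProbability:
    def test_degenerate_gap_hops_with_certainty(self):
        assert lzbl_probability(0.0, 1.0) == 1.0

    def test_formula_value(self):
        """Direct evaluation of exp(-(pi/2 hbar) sqrt(Z^3/Zdd)) for Z=0.02 eV,
        Zdd = alpha^2/(2V) with alpha=0.01 eV/fs, V=0.01 eV (so sqrt = 4V^2/alpha)."""
        Z, V, alpha = 0.02, 0.01, 0.01
        zdd = alpha**2 / (2 * V)
        expected = np.exp(-np.pi / (2 * HBAR_EV_FS) * 4 * V**2 / alpha)
        assert lzbl_probability(Z, zdd) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_gap(self):
        probs = [lzbl_probability(z, 0.01) for z in np.linspace(0, 0.2, 20)]
        assert all(np.diff(probs) < 0)

    def test_nonpositive_curvature_means_no_hop(self):
        assert lzbl_probability(0.1, 0.0) == 0.0
        assert lzbl_probability(0.1, -1.0) == 0.0


class TestAttemptHop:
    @pytest.fixture()
    def point(self):
        return PhaseSpacePoint(
            np.zeros((1, 3)), np.array([[0.02, 0, 0]]), np.array([10.0])
        )

    def test_downward_hop_conserves_total_energy(self, point):
        ke = kinetic_energy(point)
        accepted, new = attempt_hop(point, e_current=2.0, e_target=1.0, probability=1.0, u=0.0)
        assert accepted
        assert kinetic_energy(new) + 1.0 == pytest.approx(ke + 2.0, abs=1e-9)

    def test_frustrated_upward_hop(self, point):
        ke = kinetic_energy(point)
        accepted, new = attempt_hop(point, 0.0, ke + 0.5, probability=1.0, u=0.0)
        assert not accepted
        np.testing.assert_array_equal(new.velocities, point.velocities)

    def test_u_boundaries(self, point):
        assert attempt_hop(point, 2.0, 1.0, probability=0.7, u=0.0)[0]
        assert not attempt_hop(point, 2.0, 1.0, probability=0.7, u=1.0)[0]


class TestPropagation:
    def test_single_state_never_hops(self):
        pes = ms.DiatomicPES(ms.multistate_oscillator(1))
        init = PhaseSpacePoint(
            pes.geometry_at(0.1).coords, np.zeros((2, 3)), pes.masses
        )
        traj = propagate_tsh(init, pes, 0, TSHConfig(dt=0.1, t_max=20.0), seed=0)
        assert traj.hops == [] and np.all(traj.states == 0)

    def test_energy_conservation_on_smooth_surface(self, osc3_pes):
        """No hops: total-energy drift below 1e-5 eV over 60 fs at dt = 0.1 fs."""
        init = PhaseSpacePoint(
            osc3_pes.geometry_at(0.02).coords, np.zeros((2, 3)), osc3_pes.masses
        )
        traj = propagate_tsh(init, osc3_pes, 0, TSHConfig(dt=0.1, t_max=60.0), seed=0)
        e = traj.total_energy()
        assert traj.hops == []
        assert np.max(np.abs(e - e[0])) < 1e-5

    def test_deterministic_per_seed(self, lz_reference):
        _, model = lz_reference
        init = model.initial_conditions(-0.25, 0.017215)
        cfg = TSHConfig(dt=0.1, t_max=25.0)
        t1 = propagate_tsh(init, model, 1, cfg, seed=4)
        t2 = propagate_tsh(init, model, 1, cfg, seed=4)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_hop_bookkeeping_matches_state_changes(self, lz_reference):
        _, model = lz_reference
        cfg = TSHConfig(dt=0.1, t_max=25.0)
        init = model.initial_conditions(-0.25, 0.053468)
        n_changes = 0
        n_hops = 0
        for seed in range(30):
            traj = propagate_tsh(init, model, 1, cfg, seed=seed)
            n_changes += int(np.sum(np.abs(np.diff(traj.states)) > 0))
            n_hops += len(traj.hops)
        assert n_hops == n_changes
        assert n_hops > 0

    def test_lz_hop_fraction_sanity(self, lz_reference):
        """Single-passage hop fraction at P=0.5 within 3 sigma at N=500 (full grid
        runs in the acceptance suite)."""
        params, model = lz_reference
        v = 0.017215
        p_true = model.analytic_hop_probability(v)
        init = model.initial_conditions(-0.25, v)
        cfg = TSHConfig(dt=0.1, t_max=1.4 * 0.25 / v)
        n = 500
        hops = sum(
            len(propagate_tsh(init, model, 1, cfg, seed=50_000 + i).hops) > 0
            for i in range(n)
        )
        assert abs(hops / n - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)


class TestDissociation:
    def test_equilibrium_not_dissociated(self, osc3_pes):
        g = osc3_pes.equilibrium_geometry()
        assert not detect_dissociation(g, bonded_pairs(g))

    def test_stretched_bond_detected(self, osc3_pes):
        g = osc3_pes.equilibrium_geometry()
        ref = bonded_pairs(g)
        stretched = g.with_coords(np.array([[0.0, 0, 0], [0, 0, 4 * 2 * 0.71]]))
        assert detect_dissociation(stretched, ref)

    def test_threshold_monotone(self, osc3_pes):
        g = osc3_pes.equilibrium_geometry()
        ref = bonded_pairs(g)
        stretched = g.with_coords(np.array([[0.0, 0, 0], [0, 0, 3.0]]))
        results = [
            detect_dissociation(stretched, ref, bond_scale_break=s)
            for s in (1.5, 2.5, 5.0, 50.0)
        ]
        assert results == sorted(results, reverse=True)  # True ... False


class TestSwarmAnalysis:
    def _mock_traj(self, states, n_states=2):
        n = len(states)
        from photopot.dynamics import Trajectory

        return Trajectory(
            times=np.arange(n, dtype=float),
            coords=np.zeros((n, 1, 3)),
            velocities=np.zeros((n, 1, 3)),
            states=np.asarray(states),
            energies=np.zeros((n, n_states)),
            masses=np.ones(1),
            hops=[],
            hop_evaluations=[],
            termination="time_limit",
        )

    def test_all_in_ground_state(self):
        trajs = [self._mock_traj([0, 0, 0]) for _ in range(5)]
        pop, ci = populations(trajs, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(pop[0], 1.0)
        np.testing.assert_allclose(ci[0], 0.0)

    def test_populations_sum_to_one(self):
        trajs = [self._mock_traj([1, 1, 0]), self._mock_traj([1, 0, 0]),
                 self._mock_traj([1, 1, 1])]
        pop, _ = populations(trajs, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(pop.sum(axis=0), 1.0)

    def test_ci_halfwidth_formula(self):
        """N=100, p=0.3 -> 1.96 sqrt(0.21/100) ~ 0.0898."""
        trajs = [self._mock_traj([1]) for _ in range(30)] + [
            self._mock_traj([0]) for _ in range(70)
        ]
        _, ci = populations(trajs, np.array([0.0]))
        assert ci[1, 0] == pytest.approx(1.96 * np.sqrt(0.3 * 0.7 / 100), abs=1e-12)

    def test_quantum_yield_and_ci(self):
        trajs = [self._mock_traj([0]) for _ in range(100)]
        flags = [i < 30 for i in range(100)]
        phi, ci = quantum_yield(trajs, lambda p, it=iter(flags): next(it))
        assert phi == pytest.approx(0.30)
        assert ci == pytest.approx(0.0898, abs=1e-3)

    def test_zero_yield_zero_ci(self):
        trajs = [self._mock_traj([0]) for _ in range(10)]
        phi, ci = quantum_yield(trajs, lambda p: False)
        assert phi == 0.0 and ci == 0.0

    def test_empty_swarm_rejected(self):
        with pytest.raises(ValueError):
            populations([], np.array([0.0]))
        with pytest.raises(ValueError):
            quantum_yield([], lambda p: True)

    def test_summarize_stability(self):
        ok = self._mock_traj([0, 0])
        bad = self._mock_traj([0, 0])
        bad.termination = "dissociation"
        res = summarize_swarm([ok, ok, bad])
        assert res.stability_fraction == pytest.approx(2 / 3)


class TestDihedral:
    def test_planar_trans_is_180(self):
        coords = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert dihedral_angle(coords, 0, 1, 2, 3) == pytest.approx(180.0)

    def test_cis_classifier(self):
        cis = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        trans = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        clf = cis_trans_classifier((0, 1, 2, 3))
        assert clf(PhaseSpacePoint(cis, np.zeros((4, 3)), np.ones(4)))
        assert not clf(PhaseSpacePoint(trans, np.zeros((4, 3)), np.ones(4)))
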