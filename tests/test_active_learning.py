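"""Active-learning loop, gapMD, uncertainty selection, and screening, at toy scale."""

import numpy as np
import pytest

from photopot import model_systems as ms
from photopot.active_learning import (
    ALConfig,
    ModelPES,
    ScreeningConfig,
    al_converged,
    gapmd_trajectory,
    init_al,
    run_al,
    run_screening,
    select_hop_uncertain_points,
    select_uncertain_points,
)
from photopot.chemio import Geometry
from photopot.descriptor import AEVConfig
from photopot.dynamics import HopEvaluation, PhaseSpacePoint
from photopot.potential import calibrate_uq
from photopot.training import TrainConfig, train_model


@pytest.fixture(scope="module")
def crossing_pes():
    """Two-state diatomic whose sorted diabats cross inside the sampled range."""
    return ms.DiatomicPES(
        ms.multistate_oscillator(2, displacements=[0.0, 0.5], offsets=[0.0, 1.5])
    )


@pytest.fixture(scope="module")
def toy_train_cfg():
    return TrainConfig(
        descriptor=AEVConfig.desk(),
        hidden_layers=(32, 32),
        n_states_max=2,
        max_epochs=200,
        learning_rate=1e-2,
        patience=60,
        seed=0,
    )


@pytest.fixture(scope="module")
def toy_al_cfg(toy_train_cfg):
    return ALConfig(
        n_initial=16,
        n_tsh_traj=4,
        n_gapmd_traj=4,
        n_hop_uncertain=3,
        new_point_cap=20,
        t_max=10.0,
        dt=0.1,
        max_iterations=3,
        frame_stride=10,
        start_state=1,
        train=toy_train_cfg,
    )


class TestInitAL:
    def test_pool_size_and_validity(self, crossing_pes, toy_al_cfg):
        spec = ms.diatomic_wigner_spec(crossing_pes)
        pool = init_al(spec, ms.PESOracle(crossing_pes), toy_al_cfg, seed=1)
        assert len(pool) == toy_al_cfg.n_initial
        for r in pool:
            assert r.state_energies == tuple(sorted(r.state_energies))

    def test_deterministic(self, crossing_pes, toy_al_cfg):
        spec = ms.diatomic_wigner_spec(crossing_pes)
        oracle = ms.PESOracle(crossing_pes)
        a = init_al(spec, oracle, toy_al_cfg, seed=2)
        b = init_al(spec, oracle, toy_al_cfg, seed=2)
        for ra, rb in zip(a, b):
            assert ra.state_energies == rb.state_energies

    def test_oracle_failures_are_skipped(self, crossing_pes, toy_al_cfg):
        spec = ms.diatomic_wigner_spec(crossing_pes)
        inner = ms.PESOracle(crossing_pes)
        calls = {"n": 0}

        def flaky(geometry):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("oracle hiccup")
            return inner(geometry)

        pool = init_al(spec, flaky, toy_al_cfg, seed=3)
        assert len(pool) == toy_al_cfg.n_initial


class TestGapMD:
    def test_lambda_zero_reduces_to_plain_dynamics(self, crossing_pes, toy_al_cfg):
        from photopot.dynamics import TSHConfig, propagate_tsh

        spec = ms.diatomic_wigner_spec(crossing_pes)
        from photopot.dynamics import wigner_sample

        init = wigner_sample(spec, 1, seed=5)[0]
        cfg0 = ALConfig(**{**toy_al_cfg.__dict__, "gapmd_lambda": 0.0})
        biased = gapmd_trajectory(init, crossing_pes, (0, 1), cfg0, seed=0, active_state=1)
        # plain single-surface propagation on state 1 never hops for a 1-traj check
        plain = propagate_tsh(
            init, crossing_pes, 1, TSHConfig(dt=cfg0.dt, t_max=cfg0.t_max), seed=0
        )
        # compare the first stretch before any hop in the plain trajectory
        n = min(len(biased.times), len(plain.times))
        first_hop = plain.hops[0].time if plain.hops else plain.times[-1]
        mask = plain.times[:n] <= first_hop
        np.testing.assert_allclose(
            biased.coords[:n][mask], plain.coords[:n][mask], atol=1e-10
        )

    def test_bias_drives_toward_smaller_gaps(self, crossing_pes, toy_al_cfg):
        from photopot.dynamics import wigner_sample

        spec = ms.diatomic_wigner_spec(crossing_pes)
        inits = wigner_sample(spec, 12, seed=6)
        cfg_b = ALConfig(**{**toy_al_cfg.__dict__, "gapmd_lambda": 0.5, "t_max": 6.0})
        cfg_0 = ALConfig(**{**toy_al_cfg.__dict__, "gapmd_lambda": 0.0, "t_max": 6.0})

        def mean_final_gap(cfg):
            gaps = []
            for i, init in enumerate(inits):
                traj = gapmd_trajectory(init, crossing_pes, (0, 1), cfg, seed=i,
                                        active_state=0)
                e = crossing_pes.energies(traj.coords[-1])
                gaps.append(e[1] - e[0])
            return np.mean(gaps)

        assert mean_final_gap(cfg_b) < mean_final_gap(cfg_0)

    def test_effective_energy_conserved(self, toy_al_cfg):
        """Kinetic + E_active + lambda*Z is conserved on a smooth biased surface.

        (At a true crossing the gap has a kink and stepping across it breaks
        strict conservation; the contract applies where Z is smooth.)
        """
        from photopot.dynamics import kinetic_energy, wigner_sample

        smooth = ms.DiatomicPES(
            ms.multistate_oscillator(2, displacements=[0.0, 0.2], offsets=[0.0, 4.0])
        )
        spec = ms.diatomic_wigner_spec(smooth)
        init = wigner_sample(spec, 1, seed=7)[0]
        cfg = ALConfig(**{**toy_al_cfg.__dict__, "gapmd_lambda": 0.5, "t_max": 6.0})
        traj = gapmd_trajectory(init, smooth, (0, 1), cfg, seed=0, active_state=0)
        crossing_pes = smooth
        totals = []
        for i in range(len(traj.times)):
            pt = PhaseSpacePoint(traj.coords[i], traj.velocities[i], traj.masses)
            e = crossing_pes.energies(traj.coords[i])
            totals.append(kinetic_energy(pt) + e[0] + 0.5 * (e[1] - e[0]))
        totals = np.array(totals)
        assert np.max(np.abs(totals - totals[0])) < 1e-4


class TestSelection:
    def test_confident_frames_give_empty_selection(self, quick_ensemble, osc3_pes):
        cal = calibrate_uq([[10.0]] * 3)  # absurdly loose thresholds
        frames = [osc3_pes.geometry_at(q) for q in (-0.1, 0.0, 0.1)]
        assert select_uncertain_points(frames, quick_ensemble, cal, cap=5) == []

    def test_cap_respected_and_ranked(self, quick_ensemble, osc3_pes):
        cal = calibrate_uq([[0.0, 0.0, 1e-12]] * 3)  # everything exceeds
        frames = [osc3_pes.geometry_at(q) for q in np.linspace(-0.3, 0.3, 9)]
        sel = select_uncertain_points(frames, quick_ensemble, cal, cap=4)
        assert len(sel) == 4

    def _ev(self, probs, t):
        return HopEvaluation(
            time=t, state_from=1, state_to=0, gap=0.1, gap_second_derivative=0.01,
            probability=float(np.mean(probs)), accepted=False,
            coords=np.array([[0.0, 0, 0], [0, 0, 1.1 + t]]),
            member_probabilities=np.asarray(probs, dtype=float),
        )

    def test_wide_spread_outranks_agreement(self):
        evs = [self._ev([0.5, 0.5], 0.0), self._ev([0.1, 0.9], 1.0)]
        sel = select_hop_uncertain_points(evs, 1, ("N", "N"))
        assert sel[0].coords[1, 2] == pytest.approx(2.1)  # the {0.1, 0.9} frame

    def test_ties_resolved_chronologically(self):
        evs = [self._ev([0.4, 0.4], 0.0), self._ev([0.6, 0.6], 1.0)]
        sel = select_hop_uncertain_points(evs, 2, ("N", "N"))
        assert sel[0].coords[1, 2] == pytest.approx(1.1)

    def test_n_larger_than_candidates(self):
        evs = [self._ev([0.2, 0.8], 0.0)]
        assert len(select_hop_uncertain_points(evs, 15, ("N", "N"))) == 1

    def test_no_member_probabilities_empty(self):
        ev = HopEvaluation(0.0, 1, 0, 0.1, 0.01, 0.5, False, np.zeros((2, 3)), None)
        assert select_hop_uncertain_points([ev], 5, ("N", "N")) == []


class TestConvergence:
    def test_zero_flagged_converged(self, toy_al_cfg):
        log = [{"flagged_fraction": 0.0, "n_error_terminations": 0}]
        assert al_converged(log, toy_al_cfg)

    def test_five_percent_flagged_not_converged(self, toy_al_cfg):
        log = [{"flagged_fraction": 0.05, "n_error_terminations": 0}]
        assert not al_converged(log, toy_al_cfg)

    def test_error_terminations_block_convergence(self, toy_al_cfg):
        log = [{"flagged_fraction": 0.0, "n_error_terminations": 1}]
        assert not al_converged(log, toy_al_cfg)

    def test_threshold_configurable_monotone(self, toy_al_cfg):
        loose = ALConfig(**{**toy_al_cfg.__dict__, "flagged_fraction_threshold": 0.10})
        log = [{"flagged_fraction": 0.05, "n_error_terminations": 0}]
        assert al_converged(log, loose) and not al_converged(log, toy_al_cfg)


class TestRunAL:
    def test_labeled_set_grows_with_provenance(self, crossing_pes, toy_al_cfg):
        spec = ms.diatomic_wigner_spec(crossing_pes)
        cfg = ALConfig(**{**toy_al_cfg.__dict__, "max_iterations": 1})
        res = run_al(ms.PESOracle(crossing_pes), spec, pretrained=None, config=cfg, seed=4)
        assert len(res.records) == len(res.provenance)
        assert len(res.records) >= cfg.n_initial
        assert set(res.provenance) <= {"initial", "uq", "hop"}
        assert res.provenance[: cfg.n_initial] == ["initial"] * cfg.n_initial
        sizes = [e["n_labeled"] for e in res.log if "n_labeled" in e]
        assert sizes == sorted(sizes)


@pytest.fixture(scope="module")
def screening_world(toy_train_cfg):
    """Smooth 2-state surfaces without a crossing in range, plus a slightly
    offset pretraining surface for the base model."""
    pes = ms.DiatomicPES(
        ms.multistate_oscillator(2, displacements=[0.0, 0.2], offsets=[0.0, 4.0])
    )
    pes0 = ms.DiatomicPES(
        ms.multistate_oscillator(2, displacements=[0.0, 0.15], offsets=[0.2, 4.3])
    )
    cfg = TrainConfig(**{**toy_train_cfg.__dict__, "max_epochs": 500, "patience": 200})
    rec0, reg0 = ms.make_synthetic_dataset(pes0, n_geometries=150,
                                           coordinate_spread=0.3, seed=5)
    base = train_model(rec0, reg0, cfg)
    rng = np.random.default_rng(3)
    candidates = [pes.geometry_at(float(q)) for q in rng.uniform(-0.3, 0.3, 120)]
    return pes, base, candidates, cfg


class TestScreening:
    def test_converges_and_ranks_red_shifted_first(self, screening_world):
        pes, base, candidates, train_cfg = screening_world
        cfg = ScreeningConfig(batch_size=15, audit_size=25, max_iterations=4,
                              train=train_cfg)
        res = run_screening(candidates, ms.PESOracle(pes), base, cfg, seed=2)
        assert res.converged
        true_exc = np.array([pes.label(g)[1] - pes.label(g)[0] for g in candidates])
        overlap = set(np.argsort(true_exc)[:10]) & set(res.ranked_candidates[:10])
        assert len(overlap) >= 7
        assert np.all(np.diff(res.predicted_excitations) >= 0)

    def test_identical_copies_zero_uncertainty(self, screening_world):
        pes, base, candidates, _ = screening_world
        pred = [base.predict_states(g, 0, 2) for g in candidates[:5]]
        # the selection uncertainty |copy1 - copy2| vanishes for shared parameters
        diff = [np.abs((p[1] - p[0]) - (p[1] - p[0])) for p in pred]
        assert np.max(diff) == 0.0

    def test_default_stopping_thresholds(self):
        cfg = ScreeningConfig()
        assert cfg.stop_correlation == 0.78
        assert cfg.stop_mae == 0.25
        assert cfg.batch_size == 1000
        assert cfg.n_model_copies == 2

    def test_oracle_equal_to_base_stops_immediately(self, screening_world):
        """A noise-free oracle that already matches the base model converges in
        the first iteration."""
        pes, base, candidates, train_cfg = screening_world
        from photopot.chemio import DatasetRecord

        def model_oracle(geometry):
            e = base.predict_states(geometry, 0, 2)
            return DatasetRecord(geometry, "A", tuple(np.sort(e)))

        cfg = ScreeningConfig(batch_size=15, audit_size=25, max_iterations=3,
                              train=TrainConfig(**{**train_cfg.__dict__, "max_epochs": 40}))
        res = run_screening(candidates, model_oracle, base, cfg, seed=1)
        assert res.converged
        assert len([e for e in res.log if "iteration" in e]) == 1
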