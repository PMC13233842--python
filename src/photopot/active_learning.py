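"""Uncertainty-driven active learning for dynamics and screening.

Two protocols, both runnable at toy scale against synthetic oracles:

* :func:`run_al` — fine-tune-in-the-loop active learning for surface-hopping
  dynamics: train (or fine-tune) the 3-member ensemble on the labeled pool,
  run ML surface-hopping and gap-biased (gapMD) trajectories, flag frames
  whose ensemble uncertainty exceeds the calibrated median + 3*MAD
  threshold, add the most uncertain frames plus the frames with the largest
  ensemble spread in hopping probability, label them with the oracle, and
  repeat until fewer than a threshold fraction of frames are flagged.
  Defaults: 250 initial Wigner points, 50 TSH + 50 gapMD trajectories per
  iteration, 15 hop-uncertainty points, a 300-point cap, 60 fs at 0.1 fs.

* :func:`run_screening` — iterative uncertainty-driven screening: two copies
  of one energy model are fine-tuned on the labeled set with different
  train/validation splits; candidate uncertainty is the absolute deviation
  between the copies; the most uncertain batch (default 1000) is labeled
  each iteration until a random audit sample reaches the stopping rule
  (correlation >= 0.78 and MAE <= 0.25 eV); candidates are returned ranked
  by predicted first excitation, most red-shifted first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chemio import DatasetRecord, Geometry, LevelRegistry
from .dynamics import (
    HopEvaluation,
    PhaseSpacePoint,
    Trajectory,
    TSHConfig,
    WignerSpec,
    propagate_tsh,
    verlet_step,
    wigner_sample,
)
from .potential import EnsemblePotential, MultiStateModel, UQCalibration, calibrate_uq
from .training import TrainConfig, fine_tune, train_ensemble, train_model

__all__ = [
    "ALConfig",
    "ScreeningConfig",
    "ModelPES",
    "init_al",
    "gapmd_trajectory",
    "select_uncertain_points",
    "select_hop_uncertain_points",
    "al_converged",
    "run_al",
    "ALResult",
    "run_screening",
    "ScreeningResult",
]


class ModelPES:
    """Adapter exposing a trained ensemble as a dynamics potential.

    Provides ensemble-mean energies and forces plus per-member energies, so
    the propagator can record per-member hopping probabilities.
    """

    def __init__(self, ensemble: EnsemblePotential, elements: tuple[str, ...],
                 n_states: int | None = None, level_index: int = 0):
        self.ensemble = ensemble
        self.elements = tuple(elements)
        self.n_states = n_states or ensemble.n_states_max
        self.level_index = level_index

    def _geometry(self, coords: np.ndarray) -> Geometry:
        return Geometry(self.elements, coords)

    def energies(self, coords: np.ndarray) -> np.ndarray:
        pred = self.ensemble.predict(self._geometry(coords), self.level_index, self.n_states)
        return pred.state_energies_mean

    def member_energies(self, coords: np.ndarray) -> np.ndarray:
        pred = self.ensemble.predict(self._geometry(coords), self.level_index, self.n_states)
        return pred.member_energies

    def force(self, coords: np.ndarray, state: int) -> np.ndarray:
        return self.ensemble.predict_forces(self._geometry(coords), state, self.level_index)


@dataclass(frozen=True)
class ALConfig:
    """Active-learning settings; defaults are the production protocol constants."""

    n_initial: int = 250
    n_tsh_traj: int = 50
    n_gapmd_traj: int = 50
    n_hop_uncertain: int = 15
    new_point_cap: int = 300
    t_max: float = 60.0
    dt: float = 0.1
    gapmd_lambda: float = 0.5
    flagged_fraction_threshold: float = 0.01
    max_iterations: int = 10
    frame_stride: int = 10
    start_state: int = 1
    level_index: int = 0
    calibration_fraction: float = 0.2
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if min(self.n_initial, self.n_tsh_traj, self.n_gapmd_traj,
               self.n_hop_uncertain, self.new_point_cap) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_hop_uncertain > self.new_point_cap:
            raise ValueError("n_hop_uncertain must not exceed the new-point cap")


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening-loop settings; stopping rule per the production protocol."""

    batch_size: int = 1000
    stop_correlation: float = 0.78
    stop_mae: float = 0.25  # eV
    audit_size: int = 100
    max_iterations: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)

    #: two fine-tuned copies measure the selection uncertainty
    n_model_copies: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.stop_correlation <= 1):
            raise ValueError("stop correlation must be in (0, 1]")
        if self.stop_mae <= 0:
            raise ValueError("stop MAE must be positive")
        if self.n_model_copies != 2:
            raise ValueError("the screening protocol uses exactly two model copies")


def init_al(
    wigner_spec: WignerSpec,
    oracle: Callable[[Geometry], DatasetRecord],
    config: ALConfig,
    seed: int,
) -> list[DatasetRecord]:
    """Label ``n_initial`` Wigner-sampled geometries; oracle failures are skipped and logged."""
    elements = wigner_spec.equilibrium.elements
    records: list[DatasetRecord] = []
    attempt = 0
    while len(records) < config.n_initial:
        n_need = config.n_initial - len(records)
        points = wigner_sample(wigner_spec, n_need, seed + attempt)
        for p in points:
            try:
                records.append(oracle(Geometry(elements, p.coords)))
            except Exception:
                continue
        attempt += 1
        if attempt > 50:
            raise RuntimeError("oracle failed too often to fill the initial pool")
    return records[: config.n_initial]


def gapmd_trajectory(
    initial: PhaseSpacePoint,
    potential,
    state_pair: tuple[int, int] = (0, 1),
    config: ALConfig | None = None,
    seed: int = 0,
    active_state: int | None = None,
) -> Trajectory:
    """Biased dynamics on E_active + lambda * Z_jk, driving toward small gaps.

    The bias force -lambda * grad Z points downhill in the interstate gap;
    no hopping is performed. With lambda = 0 this reduces to single-surface
    dynamics. Energy on the effective surface is conserved.
    """
    config = config or ALConfig()
    j, k = state_pair
    lam = config.gapmd_lambda
    if active_state is None:
        active_state = max(j, k)

    class _Biased:
        n_states = potential.n_states

        def energies(self, coords):
            e = np.asarray(potential.energies(coords), dtype=float)
            z = abs(e[j] - e[k])
            out = e.copy()
            out[active_state] = e[active_state] + lam * z
            return out

        def force(self, coords, state):
            f = np.asarray(potential.force(coords, state))
            if lam == 0.0:
                return f
            e = np.asarray(potential.energies(coords), dtype=float)
            sign = np.sign(e[j] - e[k]) or 1.0
            fj = np.asarray(potential.force(coords, j))
            fk = np.asarray(potential.force(coords, k))
            # grad Z = sign * (grad E_j - grad E_k) = sign * (f_k - f_j)
            return f - lam * sign * (fk - fj)

    biased = _Biased()
    tsh = TSHConfig(dt=config.dt, t_max=config.t_max)
    n_steps = int(round(tsh.t_max / tsh.dt))
    point = initial
    times = [0.0]
    coords = [point.coords.copy()]
    vels = [point.velocities.copy()]
    energies = [biased.energies(point.coords)]
    termination = "time_limit"
    for step in range(n_steps):
        try:
            point = verlet_step(point, lambda c: biased.force(c, active_state), tsh.dt)
        except FloatingPointError:
            termination = "error"
            break
        times.append((step + 1) * tsh.dt)
        coords.append(point.coords.copy())
        vels.append(point.velocities.copy())
        energies.append(biased.energies(point.coords))
    n = len(times)
    return Trajectory(
        times=np.asarray(times),
        coords=np.asarray(coords),
        velocities=np.asarray(vels),
        states=np.full(n, active_state, dtype=int),
        energies=np.asarray(energies),
        masses=initial.masses,
        hops=[],
        hop_evaluations=[],
        termination=termination,
    )


def _frame_exceedances(
    frames: Sequence[Geometry],
    ensemble: EnsemblePotential,
    calibration: UQCalibration,
    level_index: int,
    n_states: int | None,
) -> np.ndarray:
    out = np.empty(len(frames))
    for i, g in enumerate(frames):
        pred = ensemble.predict(g, level_index, n_states)
        n = min(len(pred.state_uq), len(calibration.thresholds))
        out[i] = float(np.max(pred.state_uq[:n] - calibration.thresholds[:n]))
    return out


def select_uncertain_points(
    frames: Sequence[Geometry],
    ensemble: EnsemblePotential,
    calibration: UQCalibration,
    cap: int,
    level_index: int = 0,
    n_states: int | None = None,
) -> list[Geometry]:
    """Frames whose max per-state UQ exceeds its threshold, ranked by exceedance.

    Ties (equal exceedance) keep first-occurrence order; the result is
    truncated to ``cap``.
    """
    exceedances = _frame_exceedances(frames, ensemble, calibration, level_index, n_states)
    order = np.argsort(-exceedances, kind="stable")
    return [frames[i] for i in order if exceedances[i] > 0][:cap]


def select_hop_uncertain_points(
    evaluations: Sequence[HopEvaluation], n: int, elements: tuple[str, ...]
) -> list[Geometry]:
    """Geometries of the ``n`` hop evaluations with the largest member spread in P.

    Spread is the sample standard deviation of the per-member hop
    probabilities; ties keep chronological order. Evaluations lacking member
    probabilities, or an empty input, yield fewer (possibly zero) points.
    """
    scored = [
        (float(np.std(ev.member_probabilities, ddof=1)), i, ev)
        for i, ev in enumerate(evaluations)
        if ev.member_probabilities is not None and len(ev.member_probabilities) > 1
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [Geometry(elements, ev.coords) for _, _, ev in scored[:n]]


def al_converged(iteration_log: Sequence[dict], config: ALConfig) -> bool:
    """True iff the last iteration flagged < threshold of frames and had no error terminations."""
    if not iteration_log:
        return False
    last = iteration_log[-1]
    return (
        last["flagged_fraction"] < config.flagged_fraction_threshold
        and last["n_error_terminations"] == 0
    )


@dataclass
class ALResult:
    ensemble: EnsemblePotential
    records: list[DatasetRecord]
    provenance: list[str]  # "initial" | "uq" | "hop", aligned with records
    log: list[dict]
    converged: bool


def run_al(
    oracle: Callable[[Geometry], DatasetRecord],
    wigner_spec: WignerSpec,
    pretrained: EnsemblePotential | None = None,
    config: ALConfig | None = None,
    seed: int = 0,
    registry: LevelRegistry | None = None,
) -> ALResult:
    """Active-learning loop for surface-hopping dynamics.

    Each iteration: (re)train or fine-tune the ensemble, run TSH and gapMD
    swarms from fresh Wigner samples, select UQ-flagged frames (up to the
    cap) and the most hop-uncertain frames, label them, append. Stops when
    converged or after ``max_iterations`` (returning the best state with a
    warning entry in the log).
    """
    config = config or ALConfig()
    elements = wigner_spec.equilibrium.elements
    records = init_al(wigner_spec, oracle, config, seed)
    provenance = ["initial"] * len(records)
    if registry is None:
        registry = LevelRegistry(tuple(dict.fromkeys(r.level_tag for r in records)))
    log: list[dict] = []
    ensemble = pretrained
    for it in range(config.max_iterations):
        if pretrained is not None:
            ensemble = fine_tune(pretrained, records, registry, config.train)
        else:
            ensemble = train_ensemble(records, registry, config.train)
        # calibrate the UQ threshold on a held-out slice of the labeled pool
        rng = np.random.default_rng(seed + 1000 + it)
        n_cal = max(20, int(config.calibration_fraction * len(records)))
        cal_idx = rng.choice(len(records), size=min(n_cal, len(records)), replace=False)
        n_states = min(ensemble.n_states_max, min(r.n_states for r in records))
        uqs = np.stack(
            [
                ensemble.predict(records[i].geometry, config.level_index, n_states).state_uq
                for i in cal_idx
            ]
        )
        calibration = calibrate_uq(uqs.T)

        pes = ModelPES(ensemble, elements, n_states, config.level_index)
        tsh_cfg = TSHConfig(dt=config.dt, t_max=config.t_max)
        inits = wigner_sample(
            wigner_spec, config.n_tsh_traj + config.n_gapmd_traj, seed + 2000 + it
        )
        frames: list[Geometry] = []
        hop_evals: list[HopEvaluation] = []
        n_error = 0
        trajectories = []
        for i in range(config.n_tsh_traj):
            traj = propagate_tsh(
                inits[i], pes, min(config.start_state, n_states - 1), tsh_cfg,
                seed=seed + 3000 + 17 * it + i,
            )
            trajectories.append(traj)
            hop_evals.extend(traj.hop_evaluations)
        for i in range(config.n_gapmd_traj):
            pair = (max(0, config.start_state - 1), min(config.start_state, n_states - 1))
            traj = gapmd_trajectory(
                inits[config.n_tsh_traj + i], pes, pair, config,
                seed=seed + 4000 + 17 * it + i,
            )
            trajectories.append(traj)
        for traj in trajectories:
            if traj.termination == "error":
                n_error += 1
            for k in range(0, len(traj.times), config.frame_stride):
                frames.append(Geometry(elements, traj.coords[k]))

        exceedances = _frame_exceedances(
            frames, ensemble, calibration, config.level_index, n_states
        )
        order = np.argsort(-exceedances, kind="stable")
        flagged = [frames[i] for i in order if exceedances[i] > 0][: config.new_point_cap]
        hop_points = select_hop_uncertain_points(hop_evals, config.n_hop_uncertain, elements)
        flagged_fraction = float(np.mean(exceedances > 0)) if frames else 0.0
        entry = {
            "iteration": it,
            "n_labeled": len(records),
            "n_frames": len(frames),
            "flagged_fraction": flagged_fraction,
            "n_new_uq": len(flagged),
            "n_new_hop": len(hop_points),
            "n_error_terminations": n_error,
        }
        log.append(entry)
        if al_converged(log, config):
            return ALResult(ensemble, records, provenance, log, converged=True)
        for g in flagged:
            records.append(oracle(g))
            provenance.append("uq")
        for g in hop_points:
            records.append(oracle(g))
            provenance.append("hop")
    log.append({"warning": "active learning did not converge within max_iterations"})
    return ALResult(ensemble, records, provenance, log, converged=False)


@dataclass
class ScreeningResult:
    ranked_candidates: list[int]  # candidate indices, most red-shifted first
    predicted_excitations: np.ndarray  # eV, aligned with candidate order
    models: tuple[MultiStateModel, MultiStateModel]
    log: list[dict]
    converged: bool


def _first_excitation(model: MultiStateModel, geometry: Geometry) -> float:
    e = model.predict_states(geometry, 0, 2)
    return float(e[1] - e[0])


def run_screening(
    candidates: Sequence[Geometry],
    oracle: Callable[[Geometry], DatasetRecord],
    base_model: MultiStateModel,
    config: ScreeningConfig | None = None,
    seed: int = 0,
) -> ScreeningResult:
    """Iterative uncertainty-driven screening for the most red-shifted absorbers.

    Fine-tunes two copies of ``base_model`` on the labeled set with
    different train/validation splits, measures candidate uncertainty as the
    absolute deviation between the copies' predicted first excitations,
    labels the most uncertain batch each iteration, and stops once a random
    audit sample meets both the correlation and the MAE threshold.
    """
    config = config or ScreeningConfig()
    rng = np.random.default_rng(seed)
    candidates = list(candidates)
    registry = LevelRegistry((oracle(candidates[0]).level_tag,))
    labeled: dict[int, DatasetRecord] = {}
    log: list[dict] = []
    copies = (base_model, base_model)
    converged = False

    def label(indices):
        for i in indices:
            if i not in labeled:
                labeled[i] = oracle(candidates[i])

    # first batch: random sample, as in the production protocol
    first = rng.choice(len(candidates), size=min(config.batch_size, len(candidates)),
                       replace=False)
    label(first)
    for it in range(config.max_iterations):
        recs = [labeled[i] for i in sorted(labeled)]
        cfgs = [
            TrainConfig(**{**config.train.__dict__, "seed": config.train.seed + 100 * it + k})
            for k in range(2)
        ]
        copies = tuple(fine_tune(base_model, recs, registry, c) for c in cfgs)
        pred = np.array(
            [[_first_excitation(m, g) for g in candidates] for m in copies]
        )
        uncertainty = np.abs(pred[0] - pred[1])
        mean_pred = pred.mean(axis=0)

        audit_idx = rng.choice(len(candidates), size=min(config.audit_size, len(candidates)),
                               replace=False)
        label(audit_idx)
        truth = np.array(
            [labeled[i].state_energies[1] - labeled[i].state_energies[0] for i in audit_idx]
        )
        est = mean_pred[audit_idx]
        mae = float(np.mean(np.abs(est - truth)))
        corr = float(np.corrcoef(est, truth)[0, 1]) if est.std() > 0 and truth.std() > 0 else 0.0
        log.append({"iteration": it, "n_labeled": len(labeled), "audit_mae": mae,
                    "audit_correlation": corr})
        if corr >= config.stop_correlation and mae <= config.stop_mae:
            converged = True
            break
        unlabeled = [i for i in range(len(candidates)) if i not in labeled]
        if not unlabeled:
            log.append({"warning": "candidate pool exhausted before convergence"})
            break
        order = sorted(unlabeled, key=lambda i: (-uncertainty[i], i))
        label(order[: config.batch_size])
    pred = np.array([[_first_excitation(m, g) for g in candidates] for m in copies])
    mean_pred = pred.mean(axis=0)
    ranked = list(np.argsort(mean_pred, kind="stable"))
    return ScreeningResult(
        ranked_candidates=[int(i) for i in ranked],
        predicted_excitations=mean_pred[ranked],
        models=copies,
        log=log,
        converged=converged,
    )
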