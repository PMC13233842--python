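"""Multi-state, multi-fidelity atomic neural-network potential.

One feed-forward subnetwork per chemical element maps the augmented atomic
features (AEV + state ordinal + fidelity one-hot) to an atomic energy;
molecular state energies are the atom-wise sums. An ensemble of such models
(default three members) provides the prediction mean and, via the member
standard deviation, an uncertainty estimate that is calibrated against a
test set with a median + 3*MAD threshold per electronic state.

A second, MS-ANI-type network of the same shape — but without the fidelity
one-hot — predicts oscillator strengths of the S0 -> Sn transitions, clamped
at zero.

The estimators follow the scikit-learn idiom (constructor hyperparameters,
``fit`` returning ``self``, trailing-underscore fitted attributes,
``get_params``/``set_params``); ``fit`` consumes dataset records rather than
an (X, y) pair because molecules are variable-size structured objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .chemio import DatasetRecord, Geometry, LevelRegistry
from .constants import COVALENT_RADII, SUPPORTED_ELEMENTS
from .descriptor import AEVConfig, augment, compute_aev, compute_aev_jacobian
from .nn import MLP, Adam

__all__ = [
    "MultiStateModel",
    "OscillatorStrengthModel",
    "EnsemblePotential",
    "EnsemblePrediction",
    "UQCalibration",
    "TransitionSet",
    "AtomicContributionMap",
    "predict_states",
    "predict_forces",
    "ensemble_predict",
    "calibrate_uq",
    "predict_oscillator_strengths",
    "fragment_partition",
    "fragment_corrected_predict",
    "atomic_contributions",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TransitionSet:
    """Vertical transitions: excitation energies x_i (eV) and oscillator strengths f_i."""

    energies: tuple[float, ...]
    strengths: tuple[float, ...]

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.energies)
        f = tuple(float(x) for x in self.strengths)
        if len(e) != len(f):
            raise ValueError("energies and strengths must align")
        if any(x <= 0 for x in e):
            raise ValueError("excitation energies must be positive")
        if any(x < 0 for x in f):
            raise ValueError("oscillator strengths must be non-negative")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "strengths", f)

    def __len__(self) -> int:
        return len(self.energies)


@dataclass(frozen=True)
class EnsemblePrediction:
    """Per-state ensemble mean energies, member spread (the UQ), and warning flags."""

    state_energies_mean: np.ndarray  # (n_states,), eV
    state_uq: np.ndarray  # (n_states,), eV, sample std across members
    member_energies: np.ndarray  # (n_members, n_states), eV
    warnings: np.ndarray  # (n_states,), bool


@dataclass(frozen=True)
class UQCalibration:
    """Per-state warning thresholds: median + 3*MAD of test-set uncertainties."""

    medians: np.ndarray
    mads: np.ndarray
    thresholds: np.ndarray

    def flag(self, uq: np.ndarray) -> np.ndarray:
        uq = np.asarray(uq, dtype=float)
        n = min(len(uq), len(self.thresholds))
        flags = np.zeros(len(uq), dtype=bool)
        flags[:n] = uq[:n] > self.thresholds[:n]
        return flags


@dataclass(frozen=True)
class AtomicContributionMap:
    """Signed per-atom excitation-energy contributions and their fractions |dE_i|/dE."""

    delta_e_per_atom: np.ndarray  # (n_atoms,), eV
    delta_e: float  # eV
    fractions: np.ndarray  # (n_atoms,)


def calibrate_uq(test_uqs: Sequence[Sequence[float]]) -> UQCalibration:
    """Build per-state thresholds = median + 3*MAD from test-set uncertainty lists."""
    medians, mads = [], []
    for state, values in enumerate(test_uqs):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"state {state}: empty UQ list")
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        medians.append(med)
        mads.append(mad)
    medians = np.asarray(medians)
    mads = np.asarray(mads)
    return UQCalibration(medians=medians, mads=mads, thresholds=medians + 3.0 * mads)


class _AtomicSumRegressor(BaseEstimator):
    """Shared machinery: atom-wise subnetworks summed to a molecular scalar.

    Subclasses define how training items (state ordinal, target) are
    extracted from a record and whether the fidelity one-hot is appended.
    """

    _uses_level_onehot: bool

    def __init__(
        self,
        descriptor: AEVConfig | None = None,
        hidden_layers: tuple[int, ...] = (160, 128, 96),
        n_states_max: int = 11,
        learning_rate: float = 1e-3,
        max_epochs: int = 400,
        batch_size: int | None = None,
        val_fraction: float = 0.1,
        patience: int = 50,
        seed: int = 0,
        warm_start: bool = False,
        level_weights: dict | None = None,
    ):
        self.descriptor = descriptor
        self.hidden_layers = hidden_layers
        self.n_states_max = n_states_max
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed
        self.warm_start = warm_start
        self.level_weights = level_weights

    # -- hooks -------------------------------------------------------------
    def _items(self, rec: DatasetRecord) -> list[tuple[int, float]]:
        raise NotImplementedError

    def _n_levels(self) -> int:
        raise NotImplementedError

    # -- fitting -----------------------------------------------------------
    @property
    def _config(self) -> AEVConfig:
        return self.descriptor if self.descriptor is not None else AEVConfig()

    def _input_dim(self) -> int:
        return self._config.length + 1 + self._n_levels()

    def _init_nets(self, rng: np.random.Generator) -> None:
        dim = self._input_dim()
        self.nets_ = {
            el: MLP((dim, *self.hidden_layers, 1), rng) for el in SUPPORTED_ELEMENTS
        }

    def _design(self, records: Sequence[DatasetRecord], registry: LevelRegistry):
        """Per-element stacked input rows plus row -> item bookkeeping."""
        cfg = self._config
        n_levels = self._n_levels()
        rows: dict[str, list[np.ndarray]] = {el: [] for el in SUPPORTED_ELEMENTS}
        row_item: dict[str, list[int]] = {el: [] for el in SUPPORTED_ELEMENTS}
        targets: list[float] = []
        item_record: list[int] = []
        for ri, rec in enumerate(records):
            aev = compute_aev(rec.geometry, cfg)
            level = registry.index(rec.level_tag) if n_levels else None
            for state, target in self._items(rec):
                item = len(targets)
                targets.append(target)
                item_record.append(ri)
                for ai, el in enumerate(rec.geometry.elements):
                    rows[el].append(augment(aev[ai], state, level, n_levels))
                    row_item[el].append(item)
        X = {el: (np.array(v) if v else np.zeros((0, self._input_dim()))) for el, v in rows.items()}
        idx = {el: np.array(v, dtype=int) for el, v in row_item.items()}
        return X, idx, np.asarray(targets), np.asarray(item_record, dtype=int)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if X.shape[0] == 0:
            return X
        return (X - self.feature_mean_) / self.feature_scale_

    def _forward_items(self, X, idx, n_items, cache=False):
        """Atom-sum predictions per item; optionally keep activation caches."""
        pred = np.zeros(n_items)
        caches = {}
        for el, Xe in X.items():
            if Xe.shape[0] == 0:
                continue
            if cache:
                out, acts = self.nets_[el].forward(Xe, cache=True)
                caches[el] = acts
            else:
                out = self.nets_[el].forward(Xe)
            np.add.at(pred, idx[el], out)
        return (pred, caches) if cache else pred

    def fit(self, records: Sequence[DatasetRecord], registry: LevelRegistry | None = None):
        """Minimize the MSE loss over all (record, state) items by Adam.

        Keeps the parameters of the best validation epoch; logs the training
        curve to ``history_``. With ``warm_start`` and an already fitted
        model, optimization continues from the current parameters
        (fine-tuning) instead of re-initializing.
        """
        from .training import split_train_val  # local import to avoid a cycle

        records = list(records)
        if registry is None:
            seen: list[str] = []
            for r in records:
                if r.level_tag not in seen:
                    seen.append(r.level_tag)
            registry = LevelRegistry(tuple(seen))
        self.registry_ = registry
        rng = np.random.default_rng(self.seed)
        resume = self.warm_start and hasattr(self, "nets_")
        if resume and self.nets_[SUPPORTED_ELEMENTS[0]].layer_sizes[0] != self._input_dim():
            raise ValueError("warm start: descriptor/level configuration mismatch")
        self.descriptor_ = self._config

        train_recs, val_recs = (
            split_train_val(records, self.val_fraction, self.seed)
            if len(records) >= 2
            else (records, records)
        )
        Xt, idx_t, y_t, _ = self._design(train_recs, registry)
        if not resume:
            self.self_energies_ = self._fit_self_energies(records)
            # feature standardization and target scale, frozen at first fit
            all_rows = np.vstack([x for x in Xt.values() if x.shape[0]])
            mu = all_rows.mean(axis=0)
            sd = all_rows.std(axis=0)
            self.feature_mean_ = mu
            self.feature_scale_ = np.where(sd > 1e-8, sd, 1.0)
            self._init_nets(rng)
        Xv, idx_v, y_v, _ = self._design(val_recs, registry)
        Xt = {el: self._standardize(x) for el, x in Xt.items()}
        Xv = {el: self._standardize(x) for el, x in Xv.items()}
        y_t = y_t - self._self_energy_offsets(train_recs, registry)
        y_v = y_v - self._self_energy_offsets(val_recs, registry)
        if not resume:
            self.target_scale_ = float(max(np.std(y_t), 1e-6)) if len(y_t) else 1.0
        y_t = y_t / self.target_scale_
        y_v = y_v / self.target_scale_
        # per-level sampling weights (default: proportional representation)
        weights = self.level_weights or {}
        w_t = np.array(
            [
                float(weights.get(rec.level_tag, 1.0))
                for rec in train_recs
                for _ in self._items(rec)
            ]
        )
        w_v = np.array(
            [
                float(weights.get(rec.level_tag, 1.0))
                for rec in val_recs
                for _ in self._items(rec)
            ]
        )
        if w_v.sum() <= 0:
            w_v = np.ones_like(w_v)

        elements = [el for el in SUPPORTED_ELEMENTS if Xt[el].shape[0] > 0]
        params = [p for el in elements for p in self.nets_[el].parameters()]
        opt = Adam(params, lr=self.learning_rate)
        # baseline: the initialization (or pretrained state) itself, so the
        # best checkpoint can never be worse than where optimization started
        if len(y_v):
            init_pred = self._forward_items(Xv, idx_v, len(y_v))
            best_val = float(np.sum(w_v * (init_pred - y_v) ** 2) / w_v.sum())
        else:
            best_val = np.inf
        best_params = [p.copy() for p in params]
        self.history_ = []
        since_best = 0
        n_items = len(y_t)
        item_order = np.arange(n_items)
        for epoch in range(self.max_epochs):
            lr = self.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / max(1, self.max_epochs)))
            if self.batch_size is None or self.batch_size >= n_items:
                batches = [item_order]
            else:
                perm = rng.permutation(n_items)
                batches = np.array_split(perm, int(np.ceil(n_items / self.batch_size)))
            train_loss = 0.0
            for batch in batches:
                in_batch = np.zeros(n_items, dtype=bool)
                in_batch[batch] = True
                pred = np.zeros(n_items)
                caches = {}
                masks = {}
                for el in elements:
                    m = in_batch[idx_t[el]]
                    masks[el] = m
                    if not m.any():
                        continue
                    out, acts = self.nets_[el].forward(Xt[el][m], cache=True)
                    caches[el] = acts
                    np.add.at(pred, idx_t[el][m], out)
                resid = pred[batch] - y_t[batch]
                wb = w_t[batch]
                wsum = float(wb.sum())
                loss = float(np.sum(wb * resid**2) / wsum)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; reduce the learning rate"
                    )
                train_loss += loss * len(batch) / n_items
                dE = np.zeros(n_items)
                dE[batch] = 2.0 * wb * resid / wsum
                grads = []
                for el in elements:
                    m = masks[el]
                    if not m.any():
                        grads.extend(np.zeros_like(p) for p in self.nets_[el].parameters())
                        continue
                    g, _ = self.nets_[el].backward(caches[el], dE[idx_t[el][m]])
                    grads.extend(g)
                opt.step(params, grads, lr=lr)
                # Adam mutates arrays in place; re-point the net parameters
                k = 0
                for el in elements:
                    npar = len(self.nets_[el].parameters())
                    self.nets_[el].set_parameters(params[k : k + npar])
                    params[k : k + npar] = self.nets_[el].parameters()
                    k += npar
            val_pred = self._forward_items(Xv, idx_v, len(y_v))
            val_loss = (
                float(np.sum(w_v * (val_pred - y_v) ** 2) / w_v.sum())
                if len(y_v)
                else train_loss
            )
            self.history_.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
            )
            if val_loss < best_val:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best > self.patience:
                    break
        k = 0
        for el in elements:
            npar = len(self.nets_[el].parameters())
            self.nets_[el].set_parameters(best_params[k : k + npar])
            k += npar
        self.best_val_loss_ = best_val if np.isfinite(best_val) else float("nan")
        return self

    def _fit_self_energies(self, records) -> dict[str, float]:
        return {el: 0.0 for el in SUPPORTED_ELEMENTS}

    def _self_energy_offsets(self, records, registry) -> np.ndarray:
        offsets = []
        for rec in records:
            off = sum(self.self_energies_[el] for el in rec.geometry.elements)
            offsets.extend([off] * len(self._items(rec)))
        return np.asarray(offsets)

    # -- prediction --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "nets_"):
            raise RuntimeError("model is not fitted")

    def _atomic_outputs(self, geometry: Geometry, state: int, level_index: int | None):
        cfg = self.descriptor_
        aev = compute_aev(geometry, cfg)
        out = np.empty(geometry.n_atoms)
        n_levels = self._n_levels()
        for i, el in enumerate(geometry.elements):
            x = augment(aev[i], state, level_index if n_levels else None, n_levels)
            x = self._standardize(x[None, :])
            out[i] = (
                self.nets_[el].forward(x)[0] * self.target_scale_ + self.self_energies_[el]
            )
        return out

    def _input_gradients(self, geometry: Geometry, state: int, level_index: int | None):
        """d(atomic output)/d(AEV row) for every atom, shape (n_atoms, D)."""
        cfg = self.descriptor_
        aev = compute_aev(geometry, cfg)
        D = cfg.length
        n_levels = self._n_levels()
        G = np.empty((geometry.n_atoms, D))
        for i, el in enumerate(geometry.elements):
            x = augment(aev[i], state, level_index if n_levels else None, n_levels)
            x = self._standardize(x[None, :])
            raw = self.nets_[el].input_gradient(x)[0, :D]
            G[i] = raw / self.feature_scale_[:D] * self.target_scale_
        return G


class MultiStateModel(_AtomicSumRegressor):
    """Energy model: one target per electronic state, fidelity one-hot appended.

    ``fit`` learns all states of all records at their recorded fidelity
    level; ``predict_states`` evaluates an arbitrary (state, level)
    combination on a new geometry. Per-element self-energies are removed by
    least squares before fitting and restored at prediction time.
    """

    _uses_level_onehot = True

    def __init__(
        self,
        descriptor: AEVConfig | None = None,
        hidden_layers: tuple[int, ...] = (160, 128, 96),
        n_states_max: int = 11,
        n_levels: int = 1,
        learning_rate: float = 1e-3,
        max_epochs: int = 400,
        batch_size: int | None = None,
        val_fraction: float = 0.1,
        patience: int = 50,
        seed: int = 0,
        warm_start: bool = False,
        level_weights: dict | None = None,
    ):
        super().__init__(
            descriptor=descriptor,
            hidden_layers=hidden_layers,
            n_states_max=n_states_max,
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            batch_size=batch_size,
            val_fraction=val_fraction,
            patience=patience,
            seed=seed,
            warm_start=warm_start,
            level_weights=level_weights,
        )
        self.n_levels = n_levels

    def _n_levels(self) -> int:
        return self.n_levels

    def _items(self, rec: DatasetRecord) -> list[tuple[int, float]]:
        return [
            (s, e) for s, e in enumerate(rec.state_energies) if s < self.n_states_max
        ]

    def _fit_self_energies(self, records) -> dict[str, float]:
        counts = np.array(
            [[r.geometry.elements.count(el) for el in SUPPORTED_ELEMENTS] for r in records],
            dtype=float,
        )
        targets = np.array([r.state_energies[0] for r in records])
        present = counts.sum(axis=0) > 0
        sae = np.zeros(len(SUPPORTED_ELEMENTS))
        if present.any() and len(records) > 0:
            sol, *_ = np.linalg.lstsq(counts[:, present], targets, rcond=None)
            sae[present] = sol
        return dict(zip(SUPPORTED_ELEMENTS, sae))

    def predict_states(
        self,
        geometry: Geometry,
        level_index: int = 0,
        n_states: int | None = None,
        return_atomic: bool = False,
    ):
        """State energies (eV) of one geometry at one fidelity level.

        With ``return_atomic`` also returns the (n_states, n_atoms) matrix of
        atomic contributions whose rows sum to the state energies exactly.
        """
        self._check_fitted()
        n_states = self.n_states_max if n_states is None else n_states
        if not (1 <= n_states <= self.n_states_max):
            raise ValueError(f"n_states must be in [1, {self.n_states_max}]")
        if not (0 <= level_index < self.n_levels):
            raise ValueError(f"level index {level_index} out of range")
        atomic = np.stack(
            [self._atomic_outputs(geometry, s, level_index) for s in range(n_states)]
        )
        energies = atomic.sum(axis=1)
        if return_atomic:
            return energies, atomic
        return energies

    def predict_forces(self, geometry: Geometry, state: int = 0, level_index: int = 0) -> np.ndarray:
        """Forces -dE_state/dR (eV/A) by exact differentiation through net and AEV."""
        self._check_fitted()
        if not (0 <= state < self.n_states_max):
            raise ValueError(f"state {state} out of range")
        G = self._input_gradients(geometry, state, level_index)
        J = compute_aev_jacobian(geometry, self.descriptor_)
        return -np.einsum("id,idax->ax", G, J)


class OscillatorStrengthModel(_AtomicSumRegressor):
    """Oscillator-strength model: targets f(S0->Sn) keyed by the state ordinal n.

    Carries no fidelity one-hot (single-level training data) and clamps the
    atom-wise sum at zero so predicted strengths are always non-negative.
    """

    _uses_level_onehot = False

    def _n_levels(self) -> int:
        return 0

    def _items(self, rec: DatasetRecord) -> list[tuple[int, float]]:
        if rec.oscillator_strengths is None:
            return []
        return [
            (n, f)
            for n, f in enumerate(rec.oscillator_strengths, start=1)
            if n < self.n_states_max
        ]

    def predict_strengths(self, geometry: Geometry, n_states: int) -> np.ndarray:
        """f for transitions S0->S1 ... S0->S(n_states-1), each clamped at >= 0."""
        self._check_fitted()
        if n_states < 2:
            raise ValueError("need n_states >= 2 for at least one transition")
        raw = np.array(
            [self._atomic_outputs(geometry, n, None).sum() for n in range(1, n_states)]
        )
        return np.maximum(raw, 0.0)


class EnsemblePotential(BaseEstimator):
    """Ensemble of multi-state models: averaged energies with member-spread UQ."""

    def __init__(self, members: Sequence[MultiStateModel]):
        members = list(members)
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    @property
    def descriptor_(self) -> AEVConfig:
        return self.members[0].descriptor_

    @property
    def n_states_max(self) -> int:
        return min(m.n_states_max for m in self.members)

    def predict(
        self,
        geometry: Geometry,
        level_index: int = 0,
        n_states: int | None = None,
        calibration: UQCalibration | None = None,
    ) -> EnsemblePrediction:
        n_states = self.n_states_max if n_states is None else n_states
        member = np.stack(
            [m.predict_states(geometry, level_index, n_states) for m in self.members]
        )
        mean = member.mean(axis=0)
        uq = member.std(axis=0, ddof=1) if len(self.members) > 1 else np.zeros(n_states)
        warnings = (
            calibration.flag(uq) if calibration is not None else np.zeros(n_states, dtype=bool)
        )
        return EnsemblePrediction(
            state_energies_mean=mean, state_uq=uq, member_energies=member, warnings=warnings
        )

    def predict_forces(self, geometry: Geometry, state: int = 0, level_index: int = 0) -> np.ndarray:
        return np.mean(
            [m.predict_forces(geometry, state, level_index) for m in self.members], axis=0
        )

    def atomic_energies(self, geometry: Geometry, state: int, level_index: int = 0) -> np.ndarray:
        """Ensemble-averaged atomic energies for one state."""
        return np.mean(
            [m._atomic_outputs(geometry, state, level_index) for m in self.members], axis=0
        )


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over the estimators)


def predict_states(model: MultiStateModel, geometry: Geometry, level_index: int = 0,
                   n_states: int | None = None) -> np.ndarray:
    return model.predict_states(geometry, level_index, n_states)


def predict_forces(model, geometry: Geometry, state: int = 0, level_index: int = 0) -> np.ndarray:
    return model.predict_forces(geometry, state, level_index)


def ensemble_predict(
    ensemble: EnsemblePotential,
    geometry: Geometry,
    level_index: int = 0,
    n_states: int | None = None,
    calibration: UQCalibration | None = None,
) -> EnsemblePrediction:
    return ensemble.predict(geometry, level_index, n_states, calibration)


def predict_oscillator_strengths(
    f_model: OscillatorStrengthModel,
    geometry: Geometry,
    n_states: int,
    ensemble: EnsemblePotential,
    level_index: int = 0,
) -> TransitionSet:
    """Transitions S0->Sn with f from the strength net and x from the energy ensemble."""
    pred = ensemble.predict(geometry, level_index, n_states)
    exc = pred.state_energies_mean[1:] - pred.state_energies_mean[0]
    f = f_model.predict_strengths(geometry, n_states)
    return TransitionSet(energies=tuple(exc), strengths=tuple(f))


def fragment_partition(geometry: Geometry, bond_scale: float = 1.2) -> list[set[int]]:
    """Connected components of the covalent-bond graph.

    Atoms i, j are bonded when d(i,j) <= bond_scale * (r_cov(i) + r_cov(j)).
    """
    n = geometry.n_atoms
    radii = np.array([COVALENT_RADII[el] for el in geometry.elements])
    d = np.linalg.norm(geometry.coords[:, None, :] - geometry.coords[None, :, :], axis=-1)
    bonded = d <= bond_scale * (radii[:, None] + radii[None, :])
    np.fill_diagonal(bonded, False)
    _, labels = connected_components(csr_matrix(bonded), directed=False)
    return [set(np.flatnonzero(labels == c)) for c in range(labels.max() + 1)]


def _min_interfragment_distance(geometry: Geometry, fragments: list[set[int]]) -> float:
    d = np.linalg.norm(geometry.coords[:, None, :] - geometry.coords[None, :, :], axis=-1)
    best = np.inf
    for a in range(len(fragments)):
        for b in range(a + 1, len(fragments)):
            ia, ib = sorted(fragments[a]), sorted(fragments[b])
            best = min(best, float(d[np.ix_(ia, ib)].min()))
    return best


def _subgeometry(geometry: Geometry, indices: Sequence[int]) -> Geometry:
    idx = sorted(indices)
    return Geometry(
        tuple(geometry.elements[i] for i in idx), geometry.coords[idx]
    )


def fragment_corrected_predict(
    ensemble: EnsemblePotential,
    f_model: OscillatorStrengthModel | None,
    geometry: Geometry,
    n_states: int,
    level_index: int = 0,
    bond_scale: float = 1.2,
) -> tuple[np.ndarray, TransitionSet | None]:
    """Intensive excitation energies for non-covalently bound fragments.

    When fragments are separated by more than the descriptor radial cutoff,
    the composite ground state is the sum of fragment ground states and the
    excited manifold is the sorted union of fragment excitations (each added
    to the composite ground energy, carrying its fragment's oscillator
    strength), truncated to ``n_states``. Below the trigger distance the
    plain full-system prediction is returned unchanged.
    """
    fragments = fragment_partition(geometry, bond_scale)
    trigger = ensemble.descriptor_.radial_cutoff
    if len(fragments) < 2 or _min_interfragment_distance(geometry, fragments) <= trigger:
        pred = ensemble.predict(geometry, level_index, n_states)
        ts = (
            predict_oscillator_strengths(f_model, geometry, n_states, ensemble, level_index)
            if f_model is not None
            else None
        )
        return pred.state_energies_mean, ts

    ground = 0.0
    excitations: list[tuple[float, float]] = []  # (excitation energy, f)
    for frag in fragments:
        sub = _subgeometry(geometry, frag)
        pred = ensemble.predict(sub, level_index, n_states)
        ground += float(pred.state_energies_mean[0])
        exc = pred.state_energies_mean[1:] - pred.state_energies_mean[0]
        if f_model is not None:
            f = f_model.predict_strengths(sub, n_states)
        else:
            f = np.zeros(len(exc))
        excitations.extend(zip(exc.tolist(), f.tolist()))
    excitations.sort(key=lambda t: t[0])
    kept = excitations[: n_states - 1]
    energies = np.array([ground] + [ground + e for e, _ in kept])
    ts = (
        TransitionSet(tuple(e for e, _ in kept), tuple(f for _, f in kept))
        if f_model is not None and kept
        else None
    )
    return energies, ts


def atomic_contributions(
    ensemble: EnsemblePotential, geometry: Geometry, level_index: int, state: int
) -> AtomicContributionMap:
    """Per-atom excitation-energy decomposition dE_i with fractions |dE_i|/dE.

    dE_i is the ensemble-averaged difference between the excited- and
    ground-state atomic energies; the signed contributions sum to the
    ensemble excitation energy by construction.
    """
    if state < 1:
        raise ValueError("atomic contributions are defined for excited states (state >= 1)")
    excited = ensemble.atomic_energies(geometry, state, level_index)
    ground = ensemble.atomic_energies(geometry, 0, level_index)
    delta = excited - ground
    total = float(delta.sum())
    if total <= 0:
        raise ValueError(f"non-physical excitation energy {total:.6f} eV for state {state}")
    return AtomicContributionMap(
        delta_e_per_atom=delta, delta_e=total, fractions=np.abs(delta) / total
    )


# ---------------------------------------------------------------------------
# Checkpoints

_FORMAT_VERSION = 1


def _model_arrays(model: _AtomicSumRegressor, prefix: str, arrays: dict) -> dict:
    meta = {
        "kind": type(model).__name__,
        "params": {
            k: (v.to_dict() if isinstance(v, AEVConfig) else v)
            for k, v in model.get_params().items()
            if k != "descriptor"
        },
        "descriptor": model.descriptor_.to_dict(),
        "self_energies": model.self_energies_,
        "target_scale": model.target_scale_,
        "levels": list(model.registry_.levels) if hasattr(model, "registry_") else None,
    }
    arrays[f"{prefix}feature_mean"] = model.feature_mean_
    arrays[f"{prefix}feature_scale"] = model.feature_scale_
    for el, net in model.nets_.items():
        for li, w in enumerate(net.weights):
            arrays[f"{prefix}net_{el}_W{li}"] = w
        for li, b in enumerate(net.biases):
            arrays[f"{prefix}net_{el}_b{li}"] = b
    return meta


def _model_from_arrays(meta: dict, prefix: str, data) -> _AtomicSumRegressor:
    cls = {"MultiStateModel": MultiStateModel, "OscillatorStrengthModel": OscillatorStrengthModel}[
        meta["kind"]
    ]
    params = dict(meta["params"])
    for key in ("hidden_layers",):
        if key in params:
            params[key] = tuple(params[key])
    model = cls(descriptor=AEVConfig.from_dict(meta["descriptor"]), **params)
    model.descriptor_ = model._config
    model.self_energies_ = {k: float(v) for k, v in meta["self_energies"].items()}
    model.target_scale_ = float(meta["target_scale"])
    model.feature_mean_ = np.array(data[f"{prefix}feature_mean"])
    model.feature_scale_ = np.array(data[f"{prefix}feature_scale"])
    if meta.get("levels"):
        model.registry_ = LevelRegistry(tuple(meta["levels"]))
    rng = np.random.default_rng(0)
    model._init_nets(rng)
    for el, net in model.nets_.items():
        net.weights = [np.array(data[f"{prefix}net_{el}_W{li}"]) for li in range(len(net.weights))]
        net.biases = [np.array(data[f"{prefix}net_{el}_b{li}"]) for li in range(len(net.biases))]
    return model


def save_checkpoint(obj, path: str | Path) -> None:
    """Save a model, an ensemble, or a (ensemble, f_model) pair to one .npz archive."""
    arrays: dict = {}
    if isinstance(obj, EnsemblePotential):
        meta = {
            "format_version": _FORMAT_VERSION,
            "type": "ensemble",
            "members": [
                _model_arrays(m, f"member{i}_", arrays) for i, m in enumerate(obj.members)
            ],
        }
    elif isinstance(obj, _AtomicSumRegressor):
        meta = {
            "format_version": _FORMAT_VERSION,
            "type": "model",
            "model": _model_arrays(obj, "m_", arrays),
        }
    else:
        raise TypeError(f"cannot checkpoint object of type {type(obj).__name__}")
    arrays["__meta__"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["type"] == "ensemble":
            members = [
                _model_from_arrays(m, f"member{i}_", data)
                for i, m in enumerate(meta["members"])
            ]
            return EnsemblePotential(members)
        return _model_from_arrays(meta["model"], "m_", data)
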