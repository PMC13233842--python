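"""ANI-style atomic environment vectors (AEVs) with analytic Cartesian Jacobians.

The AEV of atom *i* concatenates, in canonical element order, radial blocks

    G_r[e, s] = sum_{j: elem_j = e} exp(-eta_r (R_ij - R_s)^2) f_c(R_ij, R_cr)

and, for every unordered element pair, angular blocks over neighbor pairs
(j, k) within the angular cutoff

    G_a[(e1,e2), t, s] = sum_{j<k} 2^(1-zeta) (1 + cos(theta_ijk - theta_t))^zeta
                         exp(-eta_a ((R_ij + R_ik)/2 - R_s)^2)
                         f_c(R_ij, R_ca) f_c(R_ik, R_ca)

with the cosine cutoff f_c(R, Rc) = 0.5 cos(pi R / Rc) + 0.5 for R <= Rc and
0 beyond. Following common ANI practice the angle is evaluated as
theta = arccos(0.95 cos(theta)) so its gradient stays finite for collinear
triples; the constant is part of the descriptor definition here.

On top of the geometric descriptor, :func:`augment` appends the electronic
state ordinal (a raw non-negative float) and a one-hot fidelity-level
encoding, yielding the per-atom network input.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from .chemio import Geometry
from .constants import SUPPORTED_ELEMENTS

__all__ = ["AEVConfig", "cutoff", "radial_features", "angular_features",
           "compute_aev", "compute_aev_jacobian", "augment"]

_ANGLE_SAFETY = 0.95


def _default_radial_shifts() -> tuple[float, ...]:
    return tuple(np.linspace(0.9, 5.2, 17)[:-1])


def _default_angular_shifts() -> tuple[float, ...]:
    return tuple(np.linspace(0.9, 3.5, 5)[:-1])


def _default_angle_sections() -> tuple[float, ...]:
    # midpoints of 8 equal sections of [0, pi]
    return tuple((2 * np.arange(1, 9) - 1) * np.pi / 16)


@dataclass(frozen=True)
class AEVConfig:
    """Hyperparameters of the atomic environment vector.

    Defaults follow the ANI-1x convention: radial cutoff 5.2 A with 16
    shifts, angular cutoff 3.5 A with 4 radial shifts and 8 angle sections,
    eta_r = 16, eta_a = 8, zeta = 32. Every value is configurable;
    :meth:`desk` returns a reduced configuration for fast desk-scale runs.
    """

    radial_cutoff: float = 5.2
    angular_cutoff: float = 3.5
    radial_eta: float = 16.0
    radial_shifts: tuple[float, ...] = field(default_factory=_default_radial_shifts)
    angular_eta: float = 8.0
    angular_shifts: tuple[float, ...] = field(default_factory=_default_angular_shifts)
    angle_sections: tuple[float, ...] = field(default_factory=_default_angle_sections)
    zeta: float = 32.0
    elements: tuple[str, ...] = SUPPORTED_ELEMENTS

    def __post_init__(self) -> None:
        if not (0 < self.angular_cutoff <= self.radial_cutoff):
            raise ValueError("need 0 < angular_cutoff <= radial_cutoff")
        if self.radial_eta <= 0 or self.angular_eta <= 0 or self.zeta <= 0:
            raise ValueError("width parameters must be positive")
        if sorted(self.elements) != sorted(set(self.elements)) or set(self.elements) - set(
            SUPPORTED_ELEMENTS
        ):
            raise ValueError(f"elements must be unique members of {SUPPORTED_ELEMENTS}")

    @classmethod
    def desk(cls) -> "AEVConfig":
        """Small configuration (8 radial shifts, 2x4 angular terms) for fast tests/demos."""
        return cls(
            radial_shifts=tuple(np.linspace(0.8, 5.2, 9)[:-1]),
            angular_shifts=tuple(np.linspace(0.8, 3.5, 3)[:-1]),
            angle_sections=tuple((2 * np.arange(1, 5) - 1) * np.pi / 8),
        )

    # -- layout -----------------------------------------------------------
    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def radial_block_len(self) -> int:
        return len(self.radial_shifts)

    @property
    def angular_block_len(self) -> int:
        return len(self.angle_sections) * len(self.angular_shifts)

    @property
    def n_pairs(self) -> int:
        n = self.n_elements
        return n * (n + 1) // 2

    @property
    def radial_len(self) -> int:
        return self.n_elements * self.radial_block_len

    @property
    def length(self) -> int:
        """Total AEV length D."""
        return self.radial_len + self.n_pairs * self.angular_block_len

    def element_index(self, symbol: str) -> int:
        return self.elements.index(symbol)

    def pair_index(self, e1: int, e2: int) -> int:
        """Index of the unordered element pair (e1, e2) in row-major upper-triangle order."""
        a, b = min(e1, e2), max(e1, e2)
        n = self.n_elements
        return a * n - a * (a - 1) // 2 + (b - a)

    def to_dict(self) -> dict:
        return {
            "radial_cutoff": self.radial_cutoff,
            "angular_cutoff": self.angular_cutoff,
            "radial_eta": self.radial_eta,
            "radial_shifts": list(self.radial_shifts),
            "angular_eta": self.angular_eta,
            "angular_shifts": list(self.angular_shifts),
            "angle_sections": list(self.angle_sections),
            "zeta": self.zeta,
            "elements": list(self.elements),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AEVConfig":
        d = dict(d)
        for key in ("radial_shifts", "angular_shifts", "angle_sections", "elements"):
            d[key] = tuple(d[key])
        return cls(**d)


def cutoff(R, Rc: float):
    """Cosine cutoff: 0.5 cos(pi R/Rc) + 0.5 for R <= Rc, exactly 0 beyond."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("distances must be non-negative")
    if Rc <= 0:
        raise ValueError("cutoff radius must be positive")
    out = np.where(R <= Rc, 0.5 * np.cos(np.pi * np.minimum(R, Rc) / Rc) + 0.5, 0.0)
    return out if out.ndim else float(out)


def _cutoff_deriv(R, Rc: float):
    R = np.asarray(R, dtype=float)
    out = np.where(R <= Rc, -0.5 * np.pi / Rc * np.sin(np.pi * np.minimum(R, Rc) / Rc), 0.0)
    return out if out.ndim else float(out)


def radial_features(geometry: Geometry, atom_index: int, config: AEVConfig) -> np.ndarray:
    """Radial AEV block of one atom, shape (n_elements, n_radial_shifts)."""
    out = np.zeros((config.n_elements, config.radial_block_len))
    ri = geometry.coords[atom_index]
    shifts = np.asarray(config.radial_shifts)
    for j in range(geometry.n_atoms):
        if j == atom_index:
            continue
        R = float(np.linalg.norm(geometry.coords[j] - ri))
        if R > config.radial_cutoff:
            continue
        e = config.element_index(geometry.elements[j])
        out[e] += np.exp(-config.radial_eta * (R - shifts) ** 2) * cutoff(R, config.radial_cutoff)
    return out


def angular_features(geometry: Geometry, atom_index: int, config: AEVConfig) -> np.ndarray:
    """Angular AEV block of one atom, shape (n_pairs, n_angle_sections * n_angular_shifts)."""
    out = np.zeros((config.n_pairs, config.angular_block_len))
    ri = geometry.coords[atom_index]
    neighbors = []
    for j in range(geometry.n_atoms):
        if j == atom_index:
            continue
        v = geometry.coords[j] - ri
        R = float(np.linalg.norm(v))
        if R <= config.angular_cutoff:
            neighbors.append((j, v, R))
    th_s = np.asarray(config.angle_sections)
    r_s = np.asarray(config.angular_shifts)
    pref = 2.0 ** (1.0 - config.zeta)
    for a in range(len(neighbors)):
        j, v1, R1 = neighbors[a]
        for b in range(a + 1, len(neighbors)):
            k, v2, R2 = neighbors[b]
            cos_t = float(np.dot(v1, v2) / (R1 * R2))
            theta = np.arccos(_ANGLE_SAFETY * np.clip(cos_t, -1.0, 1.0))
            ang = pref * (1.0 + np.cos(theta - th_s)) ** config.zeta
            rad = np.exp(-config.angular_eta * ((R1 + R2) / 2.0 - r_s) ** 2)
            fc = cutoff(R1, config.angular_cutoff) * cutoff(R2, config.angular_cutoff)
            block = np.outer(ang, rad).ravel() * fc
            p = config.pair_index(
                config.element_index(geometry.elements[j]),
                config.element_index(geometry.elements[k]),
            )
            out[p] += block
    return out


_aev_cache: "OrderedDict[tuple, np.ndarray]" = OrderedDict()
_jac_cache: "OrderedDict[tuple, np.ndarray]" = OrderedDict()
_CACHE_SIZE = 16


def _cache_key(geometry: Geometry, config: AEVConfig) -> tuple:
    return (geometry.elements, geometry.coords.tobytes(), config)


def _cache_get(cache: OrderedDict, key: tuple):
    if key in cache:
        cache.move_to_end(key)
        return cache[key]
    return None


def _cache_put(cache: OrderedDict, key: tuple, value: np.ndarray) -> None:
    cache[key] = value
    if len(cache) > _CACHE_SIZE:
        cache.popitem(last=False)


def compute_aev(geometry: Geometry, config: AEVConfig | None = None) -> np.ndarray:
    """Full AEV matrix, shape (n_atoms, D). Recent results are memoized."""
    config = config or AEVConfig()
    key = _cache_key(geometry, config)
    hit = _cache_get(_aev_cache, key)
    if hit is not None:
        return hit
    rows = np.empty((geometry.n_atoms, config.length))
    for i in range(geometry.n_atoms):
        rows[i] = np.concatenate(
            [radial_features(geometry, i, config).ravel(),
             angular_features(geometry, i, config).ravel()]
        )
    rows.setflags(write=False)
    _cache_put(_aev_cache, key, rows)
    return rows


def compute_aev_jacobian(geometry: Geometry, config: AEVConfig | None = None) -> np.ndarray:
    """Analytic Jacobian d AEV[i, d] / d r[a, x], shape (n_atoms, D, n_atoms, 3).

    Exact derivative of :func:`compute_aev`; used to turn network input
    gradients into Cartesian forces. Recent results are memoized.
    """
    config = config or AEVConfig()
    key = _cache_key(geometry, config)
    hit = _cache_get(_jac_cache, key)
    if hit is not None:
        return hit
    n = geometry.n_atoms
    D = config.length
    J = np.zeros((n, D, n, 3))
    r_shifts = np.asarray(config.radial_shifts)
    th_s = np.asarray(config.angle_sections)
    a_shifts = np.asarray(config.angular_shifts)
    pref = 2.0 ** (1.0 - config.zeta)
    nt, ns = len(th_s), len(a_shifts)

    for i in range(n):
        ri = geometry.coords[i]
        # radial part
        for j in range(n):
            if j == i:
                continue
            v = geometry.coords[j] - ri
            R = float(np.linalg.norm(v))
            if R > config.radial_cutoff or R == 0.0:
                continue
            u = v / R
            e = config.element_index(geometry.elements[j])
            gauss = np.exp(-config.radial_eta * (R - r_shifts) ** 2)
            fc = cutoff(R, config.radial_cutoff)
            dfc = _cutoff_deriv(R, config.radial_cutoff)
            dg = gauss * (-2.0 * config.radial_eta * (R - r_shifts) * fc + dfc)
            sl = slice(e * config.radial_block_len, (e + 1) * config.radial_block_len)
            J[i, sl, j, :] += dg[:, None] * u[None, :]
            J[i, sl, i, :] -= dg[:, None] * u[None, :]
        # angular part
        neighbors = []
        for j in range(n):
            if j == i:
                continue
            v = geometry.coords[j] - ri
            R = float(np.linalg.norm(v))
            if R <= config.angular_cutoff and R > 0.0:
                neighbors.append((j, v, R))
        for a in range(len(neighbors)):
            j, v1, R1 = neighbors[a]
            for b in range(a + 1, len(neighbors)):
                k, v2, R2 = neighbors[b]
                cos_t = float(np.dot(v1, v2) / (R1 * R2))
                cc = np.clip(cos_t, -1.0, 1.0)
                theta = np.arccos(_ANGLE_SAFETY * cc)
                ang = pref * (1.0 + np.cos(theta - th_s)) ** config.zeta
                dang_dtheta = pref * config.zeta * (1.0 + np.cos(theta - th_s)) ** (
                    config.zeta - 1.0
                ) * (-np.sin(theta - th_s))
                dtheta_dcos = -_ANGLE_SAFETY / np.sqrt(1.0 - (_ANGLE_SAFETY * cc) ** 2)
                rad = np.exp(-config.angular_eta * ((R1 + R2) / 2.0 - a_shifts) ** 2)
                drad = rad * (-config.angular_eta * ((R1 + R2) / 2.0 - a_shifts))
                fc1 = cutoff(R1, config.angular_cutoff)
                fc2 = cutoff(R2, config.angular_cutoff)
                dfc1 = _cutoff_deriv(R1, config.angular_cutoff)
                dfc2 = _cutoff_deriv(R2, config.angular_cutoff)
                u1, u2 = v1 / R1, v2 / R2
                dcos_dv1 = v2 / (R1 * R2) - cos_t * v1 / R1**2
                dcos_dv2 = v1 / (R1 * R2) - cos_t * v2 / R2**2
                # g[t, s] = ang[t] * rad[s] * fc1 * fc2
                # d/dv1 = dang*dtheta_dcos*dcos_dv1 * rad * fc1fc2
                #       + ang * drad * u1 * fc1 fc2  + ang * rad * dfc1 * u1 * fc2
                term_ang1 = np.einsum(
                    "t,s,x->tsx", dang_dtheta * dtheta_dcos, rad * fc1 * fc2, dcos_dv1
                )
                term_rad1 = np.einsum("t,s,x->tsx", ang, drad * fc1 * fc2 + rad * dfc1 * fc2, u1)
                dg_dv1 = (term_ang1 + term_rad1).reshape(nt * ns, 3)
                term_ang2 = np.einsum(
                    "t,s,x->tsx", dang_dtheta * dtheta_dcos, rad * fc1 * fc2, dcos_dv2
                )
                term_rad2 = np.einsum("t,s,x->tsx", ang, drad * fc1 * fc2 + rad * fc1 * dfc2, u2)
                dg_dv2 = (term_ang2 + term_rad2).reshape(nt * ns, 3)
                p = config.pair_index(
                    config.element_index(geometry.elements[j]),
                    config.element_index(geometry.elements[k]),
                )
                off = config.radial_len + p * config.angular_block_len
                sl = slice(off, off + config.angular_block_len)
                J[i, sl, j, :] += dg_dv1
                J[i, sl, k, :] += dg_dv2
                J[i, sl, i, :] -= dg_dv1 + dg_dv2
    J.setflags(write=False)
    _cache_put(_jac_cache, key, J)
    return J


def augment(
    aev_row: np.ndarray, state_ordinal: int, level_index: int | None, n_levels: int
) -> np.ndarray:
    """Append the state ordinal and a level one-hot to one AEV row.

    ``level_index=None`` with ``n_levels=0`` omits the one-hot entirely (the
    oscillator-strength network carries no level feature).
    """
    if state_ordinal < 0:
        raise ValueError("state ordinal must be non-negative")
    if n_levels == 0:
        if level_index is not None:
            raise ValueError("level_index given but n_levels == 0")
        return np.concatenate([aev_row, [float(state_ordinal)]])
    if level_index is None or not (0 <= level_index < n_levels):
        raise ValueError(f"level index {level_index} out of range for {n_levels} levels")
    onehot = np.zeros(n_levels)
    onehot[level_index] = 1.0
    return np.concatenate([aev_row, [float(state_ordinal)], onehot])
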