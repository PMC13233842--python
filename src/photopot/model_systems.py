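"""Analytic multi-state model systems and synthetic dataset generators.

These stand in for quantum-chemistry reference data at desk scale. They
emulate the statistical structure the method assumes: smooth adiabatic
surfaces with ascending state energies, non-negative oscillator strengths,
and fidelity levels related by a smooth offset.

Two families of systems:

* a 1-D linear Landau-Zener two-state model (a free particle crossing an
  avoided intersection) with the classical closed-form transition
  probability as an independent oracle for the LZBL hopping machinery, and
* displaced multi-state harmonic oscillators mapped onto the bond length of
  a diatomic molecule, used for training, fine-tuning, spectra, and
  active-learning fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .chemio import DatasetRecord, Geometry, LevelRegistry
from .constants import ATOMIC_MASSES, EV_PER_AMU_A2_FS2, HBAR_EV_FS, SUPPORTED_ELEMENTS
from .dynamics import PhaseSpacePoint, WignerSpec

__all__ = [
    "LZModelParams",
    "LZModel",
    "lz_model",
    "ScalarPES",
    "multistate_oscillator",
    "DiatomicPES",
    "PESOracle",
    "diatomic_wigner_spec",
    "make_synthetic_dataset",
    "make_toy_geometries",
    "softplus_f_generator",
    "lz_numerical_probability",
]

_C_CM_PER_FS = 2.99792458e-5


# ---------------------------------------------------------------------------
# Landau-Zener linear model


@dataclass(frozen=True)
class LZModelParams:
    """Two-state linear crossing: diabatic energies +-slope*x, coupling V.

    Traversed at velocity v the diabatic gap grows at the rate
    alpha = 2*slope*v (eV/fs), which is the alpha of the classical
    Landau-Zener formula P = exp(-2 pi V^2 / (hbar alpha)).
    """

    coupling: float = 0.05  # V, eV
    slope: float = 1.0  # eV/A
    mass: float = 12.0  # amu

    def __post_init__(self) -> None:
        if self.coupling <= 0 or self.slope == 0 or self.mass <= 0:
            raise ValueError("need V > 0, slope != 0, mass > 0")


class LZModel:
    """Adiabatic two-state PES E_-+(x) = -+ sqrt((slope*x)^2 + V^2), 1-D in x.

    The system is a single particle; only the x coordinate of atom 0 enters.
    The minimum adiabatic gap is 2V at the crossing x = 0.
    """

    n_states = 2

    def __init__(self, params: LZModelParams):
        self.params = params

    def _e_pair(self, x: float) -> tuple[float, float]:
        root = np.hypot(self.params.slope * x, self.params.coupling)
        return -root, root

    def energies(self, coords: np.ndarray) -> np.ndarray:
        x = float(np.atleast_2d(coords)[0, 0])
        lo, hi = self._e_pair(x)
        return np.array([lo, hi])

    def force(self, coords: np.ndarray, state: int) -> np.ndarray:
        coords = np.atleast_2d(coords)
        x = float(coords[0, 0])
        a, V = self.params.slope, self.params.coupling
        root = np.hypot(a * x, V)
        dE = a * a * x / root  # d(+root)/dx
        if state == 0:
            dE = -dE
        f = np.zeros_like(coords)
        f[0, 0] = -dE
        return f

    def analytic_hop_probability(self, v: float) -> float:
        """Classical single-passage LZ probability at crossing velocity v (A/fs)."""
        alpha = 2.0 * abs(self.params.slope) * abs(v)
        return float(np.exp(-2.0 * np.pi * self.params.coupling**2 / (HBAR_EV_FS * alpha)))

    def initial_conditions(self, x0: float, v_crossing: float) -> PhaseSpacePoint:
        """Phase-space point on the upper surface that reaches x = 0 at ``v_crossing``.

        The launch velocity accounts for the potential-energy difference
        between x0 and the crossing so the velocity at the crossing equals
        ``v_crossing`` exactly (energy conservation on the upper surface).
        """
        e0 = self._e_pair(x0)[1]
        ec = self.params.coupling
        v0_sq = v_crossing**2 - 2.0 * (e0 - ec) / (self.params.mass * EV_PER_AMU_A2_FS2)
        if v0_sq <= 0:
            raise ValueError("v_crossing too small to surmount the upper-surface barrier")
        sign = 1.0 if x0 < 0 else -1.0
        coords = np.array([[x0, 0.0, 0.0]])
        vel = np.array([[sign * np.sqrt(v0_sq), 0.0, 0.0]])
        return PhaseSpacePoint(coords, vel, np.array([self.params.mass]))


def lz_model(params: LZModelParams | None = None) -> LZModel:
    return LZModel(params or LZModelParams())


def lz_numerical_probability(
    params: LZModelParams, v: float, t_span: float = 400.0, n_eval: int = 8000
) -> float:
    """Brute-force oracle: integrate the two-state TDSE through the crossing.

    The diabatic Hamiltonian H(t) = [[slope*v*t, V], [V, -slope*v*t]] is
    integrated from -t_span/2 to +t_span/2 starting in diabat 1; the
    returned transition probability is the final population left in diabat 1
    (the diabat-following = adiabatic-switching channel).
    """
    from scipy.integrate import solve_ivp

    a, V = params.slope * v, params.coupling

    def rhs(t, y):
        c = y[:2] + 1j * y[2:]
        dc = -1j / HBAR_EV_FS * np.array([a * t * c[0] + V * c[1], V * c[0] - a * t * c[1]])
        return np.concatenate([dc.real, dc.imag])

    y0 = np.array([1.0, 0.0, 0.0, 0.0])
    sol = solve_ivp(
        rhs, (-t_span / 2, t_span / 2), y0, rtol=1e-10, atol=1e-12, dense_output=False
    )
    c = sol.y[:2, -1] + 1j * sol.y[2:, -1]
    return float(np.abs(c[0]) ** 2)


# ---------------------------------------------------------------------------
# Multi-state displaced harmonic oscillators


class ScalarPES:
    """Multi-state PES of one scalar coordinate q: sorted diabatic parabolas.

    State n diabat: offset_n + 0.5 * k_n * (q - d_n)^2. Adiabatic energies
    are the ascending sort of the diabats (surfaces may cross; sorting
    produces the adiabatic ordering with a gap of zero at crossings).
    """

    def __init__(
        self,
        force_constants: Sequence[float],
        displacements: Sequence[float],
        offsets: Sequence[float],
    ):
        self.k = np.asarray(force_constants, dtype=float)
        self.d = np.asarray(displacements, dtype=float)
        self.off = np.asarray(offsets, dtype=float)
        if not (self.k.shape == self.d.shape == self.off.shape):
            raise ValueError("force_constants, displacements, offsets must align")
        if np.any(self.k <= 0):
            raise ValueError("force constants must be positive")
        self.n_states = self.k.size

    def diabats(self, q: float) -> np.ndarray:
        return self.off + 0.5 * self.k * (q - self.d) ** 2

    def energies_q(self, q: float) -> np.ndarray:
        return np.sort(self.diabats(q))

    def gradients_q(self, q: float) -> np.ndarray:
        """dE_n/dq for the ascending-ordered states."""
        order = np.argsort(self.diabats(q), kind="stable")
        grads = self.k * (q - self.d)
        return grads[order]


def multistate_oscillator(
    n_states: int,
    frequencies: Sequence[float] | float = 8.0,
    displacements: Sequence[float] | None = None,
    offsets: Sequence[float] | None = None,
) -> ScalarPES:
    """Displaced harmonic manifold; ``frequencies`` are sqrt(force constant) in sqrt(eV)/A.

    Defaults give well-separated non-crossing surfaces: offsets 0, 4, 6, 7.5,
    ... eV with displacements alternating around the ground-state minimum.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    freqs = np.broadcast_to(np.asarray(frequencies, dtype=float), (n_states,))
    if displacements is None:
        displacements = 0.15 * np.array([0.0] + [(-1) ** n * 1.0 for n in range(1, n_states)])
    if offsets is None:
        offsets = np.concatenate([[0.0], 4.0 + 1.5 * np.arange(n_states - 1)])
    return ScalarPES(freqs**2, displacements, offsets)


class DiatomicPES:
    """Maps a scalar multi-state PES onto the bond length of a diatomic.

    q = r - r0 where r is the interatomic distance. Implements the dynamics
    potential protocol (``energies``/``force``) and serves as the labeling
    oracle for synthetic datasets.
    """

    def __init__(self, scalar_pes: ScalarPES, elements: tuple[str, str] = ("N", "N"),
                 r0: float = 1.1):
        self.pes = scalar_pes
        self.elements = elements
        self.r0 = r0
        self.n_states = scalar_pes.n_states

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    def equilibrium_geometry(self) -> Geometry:
        return Geometry(self.elements, np.array([[0.0, 0.0, 0.0], [0.0, 0.0, self.r0]]))

    def _q(self, coords: np.ndarray) -> float:
        coords = np.atleast_2d(coords)
        return float(np.linalg.norm(coords[1] - coords[0])) - self.r0

    def energies(self, coords: np.ndarray) -> np.ndarray:
        return self.pes.energies_q(self._q(coords))

    def force(self, coords: np.ndarray, state: int) -> np.ndarray:
        coords = np.atleast_2d(coords)
        v = coords[1] - coords[0]
        r = float(np.linalg.norm(v))
        u = v / r
        dEdq = self.pes.gradients_q(r - self.r0)[state]
        f = np.zeros_like(coords)
        f[1] = -dEdq * u
        f[0] = dEdq * u
        return f

    def label(self, geometry: Geometry) -> np.ndarray:
        """Adiabatic state energies (eV) of a diatomic geometry."""
        return self.pes.energies_q(self._q(geometry.coords))

    def geometry_at(self, q: float) -> Geometry:
        return Geometry(
            self.elements, np.array([[0.0, 0.0, 0.0], [0.0, 0.0, self.r0 + q]])
        )


class PESOracle:
    """Labeling oracle: geometry -> validated DatasetRecord at one fidelity level."""

    def __init__(self, pes: DiatomicPES, level_tag: str = "A",
                 offset: float | Callable[[float], float] = 0.0,
                 f_generator: Callable[[float], Sequence[float]] | None = None):
        self.pes = pes
        self.level_tag = level_tag
        self.offset = offset
        self.f_generator = f_generator

    def __call__(self, geometry: Geometry) -> DatasetRecord:
        q = self.pes._q(geometry.coords)
        energies = self.pes.label(geometry)
        off = self.offset(q) if callable(self.offset) else self.offset
        osc = tuple(self.f_generator(q)) if self.f_generator is not None else None
        return DatasetRecord(
            geometry=geometry,
            level_tag=self.level_tag,
            state_energies=tuple(energies + off),
            oscillator_strengths=osc,
        )


def diatomic_wigner_spec(
    pes: DiatomicPES, temperature: float = 298.0
) -> WignerSpec:
    """Harmonic Wigner spec of the diatomic's ground-state stretch mode."""
    m1, m2 = pes.masses
    mu = m1 * m2 / (m1 + m2)
    k_int = pes.pes.k[0] / EV_PER_AMU_A2_FS2  # amu/fs^2
    omega = np.sqrt(k_int / mu)  # rad/fs
    freq_cm = omega / (2.0 * np.pi * _C_CM_PER_FS)
    e_z = np.array([0.0, 0.0, 1.0])
    mode = np.stack([-np.sqrt(mu / m1) * e_z, np.sqrt(mu / m2) * e_z])
    return WignerSpec(
        equilibrium=pes.equilibrium_geometry(),
        frequencies_cm=np.array([freq_cm]),
        modes=mode[None, :, :],
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# Synthetic datasets


def softplus_f_generator(n_transitions: int, seed: int = 0) -> Callable[[float], np.ndarray]:
    """Smooth non-negative oscillator-strength surfaces f_n(q) = softplus(a_n + b_n q)."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 0.5, size=n_transitions)
    b = rng.uniform(-1.5, 1.5, size=n_transitions)

    def f(q: float) -> np.ndarray:
        return np.log1p(np.exp(a + b * q)) * 0.1

    return f


def make_synthetic_dataset(
    pes: DiatomicPES,
    n_geometries: int = 800,
    coordinate_spread: float = 0.25,
    level_offsets: dict[str, float | Callable[[float], float]] | None = None,
    f_generator: Callable[[float], Sequence[float]] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[DatasetRecord], LevelRegistry]:
    """Sample labeled records around the equilibrium bond length.

    ``n_geometries`` records in total, assigned cyclically to the levels of
    ``level_offsets`` (default a single level "A" with zero offset). Level
    energies are PES + offset + Gaussian noise of ``noise_sigma`` eV applied
    as a common per-record shift so the ascending state order is preserved.
    """
    if level_offsets is None:
        level_offsets = {"A": 0.0}
    registry = LevelRegistry(tuple(level_offsets))
    rng = np.random.default_rng(seed)
    records = []
    tags = list(level_offsets)
    for i in range(n_geometries):
        q = float(rng.uniform(-coordinate_spread, coordinate_spread))
        tag = tags[i % len(tags)]
        geometry = pes.geometry_at(q)
        energies = pes.label(geometry)
        off = level_offsets[tag]
        off = off(q) if callable(off) else off
        if noise_sigma > 0:
            off += rng.normal(0.0, noise_sigma)
        osc = tuple(np.asarray(f_generator(q), dtype=float)) if f_generator else None
        records.append(
            DatasetRecord(
                geometry=geometry,
                level_tag=tag,
                state_energies=tuple(energies + off),
                oscillator_strengths=osc,
            )
        )
    return records, registry


def make_toy_geometries(n: int, seed: int = 0) -> list[Geometry]:
    """Random small molecules (3-8 atoms) with all pair distances >= 0.7 A."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    geometries = []
    while len(geometries) < n:
        n_atoms = int(rng.integers(3, 9))
        elements = tuple(rng.choice(SUPPORTED_ELEMENTS, size=n_atoms))
        coords = np.zeros((n_atoms, 3))
        ok = True
        for i in range(1, n_atoms):
            placed = False
            for _ in range(200):
                candidate = coords[rng.integers(0, i)] + rng.normal(0.0, 1.2, size=3)
                d = np.linalg.norm(coords[:i] - candidate, axis=1)
                if np.all(d >= 0.7):
                    coords[i] = candidate
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            geometries.append(Geometry(elements, coords))
    return geometries
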