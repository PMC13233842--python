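"""Wigner initial conditions and Landau-Zener-Belyaev-Lebedev surface hopping.

The LZBL formalism needs no nonadiabatic coupling vectors: along a
trajectory on the active adiabatic surface, the gap Z to each adjacent state
is monitored; at a local gap minimum the hop probability

    P = exp( -(pi / 2 hbar) * sqrt(Z^3 / Zdd) )

is evaluated from the minimum gap Z and its second time derivative Zdd
(3-point central difference), and a hop is attempted by drawing one uniform
random number. Accepted hops rescale the velocities uniformly (equivalent to
rescaling along the momentum vector) so total energy is conserved; upward
hops without sufficient kinetic energy are frustrated and rejected.

Units: eV, Angstrom, fs, amu; hbar = 0.6582119569 eV fs.

A potential for dynamics is any object with ``n_states``,
``energies(coords) -> (S,)`` (eV) and ``force(coords, state) -> (N, 3)``
(eV/A); an optional ``member_energies(coords) -> (M, S)`` enables
per-ensemble-member hop probabilities for active learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chemio import Geometry
from .constants import EV_PER_AMU_A2_FS2, HBAR_EV_FS, KB_EV
from .potential import fragment_partition

__all__ = [
    "WignerSpec",
    "PhaseSpacePoint",
    "HopEvaluation",
    "Trajectory",
    "SwarmResult",
    "TSHConfig",
    "wigner_mode_sigmas",
    "wigner_sample",
    "kinetic_energy",
    "verlet_step",
    "detect_gap_minimum",
    "lzbl_probability",
    "attempt_hop",
    "propagate_tsh",
    "bonded_pairs",
    "detect_dissociation",
    "populations",
    "quantum_yield",
    "summarize_swarm",
    "dihedral_angle",
    "cis_trans_classifier",
]

_C_CM_PER_FS = 2.99792458e-5  # speed of light in cm/fs
_HBAR_INT = HBAR_EV_FS / EV_PER_AMU_A2_FS2  # hbar in amu A^2 / fs


@dataclass(frozen=True)
class PhaseSpacePoint:
    """Coordinates (A), velocities (A/fs), masses (amu)."""

    coords: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coords, dtype=float))
        v = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        m = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if c.shape != v.shape or c.shape[0] != m.shape[0] or c.shape[1] != 3:
            raise ValueError("inconsistent phase-space shapes")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "masses", m)


@dataclass(frozen=True)
class WignerSpec:
    """Harmonic Wigner distribution: equilibrium geometry, modes, temperature."""

    equilibrium: Geometry
    frequencies_cm: np.ndarray  # (M,), cm^-1, all positive
    modes: np.ndarray  # (M, N, 3), orthonormal in mass-weighted coordinates
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        freqs = np.atleast_1d(np.asarray(self.frequencies_cm, dtype=float))
        modes = np.asarray(self.modes, dtype=float)
        if np.any(freqs <= 0):
            raise ValueError("all frequencies must be positive")
        if modes.shape != (freqs.size, self.equilibrium.n_atoms, 3):
            raise ValueError(f"modes shape {modes.shape} inconsistent")
        flat = modes.reshape(freqs.size, -1)
        if not np.allclose(flat @ flat.T, np.eye(freqs.size), atol=1e-6):
            raise ValueError("mode vectors must be orthonormal in mass-weighted coordinates")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        object.__setattr__(self, "frequencies_cm", freqs)
        object.__setattr__(self, "modes", modes)


def wigner_mode_sigmas(frequency_cm: float, temperature: float) -> tuple[float, float]:
    """Std devs of the mass-weighted mode coordinate and momentum.

    sigma_Q^2 = (hbar / 2 omega) coth(hbar omega / 2 kT)   [amu A^2]
    sigma_P^2 = (hbar omega / 2) coth(hbar omega / 2 kT)   [amu A^2/fs^2]
    """
    if frequency_cm <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * _C_CM_PER_FS * frequency_cm  # rad/fs
    if temperature <= 0:
        coth = 1.0
    else:
        arg = HBAR_EV_FS * omega / (2.0 * KB_EV * temperature)
        coth = 1.0 / np.tanh(arg)
    var_q = _HBAR_INT / (2.0 * omega) * coth
    var_p = _HBAR_INT * omega / 2.0 * coth
    return float(np.sqrt(var_q)), float(np.sqrt(var_p))


def _project_momenta(point: PhaseSpacePoint) -> PhaseSpacePoint:
    """Remove net linear and angular momentum from the velocities."""
    m = point.masses
    v = point.velocities - np.average(point.velocities, axis=0, weights=m)
    if point.coords.shape[0] > 1:
        com = np.average(point.coords, axis=0, weights=m)
        r = point.coords - com
        L = np.sum(m[:, None] * np.cross(r, v), axis=0)
        inertia = np.zeros((3, 3))
        for mi, ri in zip(m, r):
            inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
        omega = np.linalg.pinv(inertia, rcond=1e-10) @ L
        v = v - np.cross(omega, r)
    return PhaseSpacePoint(point.coords, v, m)


def wigner_sample(spec: WignerSpec, n: int, seed: int) -> list[PhaseSpacePoint]:
    """Draw ``n`` phase-space points from the harmonic Wigner distribution.

    Mode coordinates and momenta are independent zero-mean Gaussians with
    the coth variances, transformed to Cartesian space; net linear and
    angular momentum are projected out afterwards.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    masses = spec.equilibrium.masses
    inv_sqrt_m = 1.0 / np.sqrt(masses)[:, None]
    sigmas = np.array([wigner_mode_sigmas(f, spec.temperature) for f in spec.frequencies_cm])
    Q = rng.normal(0.0, sigmas[:, 0], size=(n, sigmas.shape[0]))
    P = rng.normal(0.0, sigmas[:, 1], size=(n, sigmas.shape[0]))
    dr = np.einsum("nm,maj->naj", Q, spec.modes) * inv_sqrt_m
    dv = np.einsum("nm,maj->naj", P, spec.modes) * inv_sqrt_m
    return [
        _project_momenta(
            PhaseSpacePoint(spec.equilibrium.coords + dr[i], dv[i], masses)
        )
        for i in range(n)
    ]


def kinetic_energy(point: PhaseSpacePoint) -> float:
    """Kinetic energy in eV."""
    return 0.5 * EV_PER_AMU_A2_FS2 * float(
        np.sum(point.masses[:, None] * point.velocities**2)
    )


def verlet_step(
    point: PhaseSpacePoint, force_provider: Callable[[np.ndarray], np.ndarray], dt: float
) -> PhaseSpacePoint:
    """One velocity-Verlet step on a single surface; forces in eV/A."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    inv_m = 1.0 / (point.masses[:, None] * EV_PER_AMU_A2_FS2)
    a0 = np.asarray(force_provider(point.coords)) * inv_m
    if not np.all(np.isfinite(a0)):
        raise FloatingPointError("non-finite force")
    v_half = point.velocities + 0.5 * dt * a0
    coords = point.coords + dt * v_half
    a1 = np.asarray(force_provider(coords)) * inv_m
    if not np.all(np.isfinite(a1)):
        raise FloatingPointError("non-finite force")
    return PhaseSpacePoint(coords, v_half + 0.5 * dt * a1, point.masses)


def detect_gap_minimum(gap_history: Sequence[float]) -> bool:
    """True iff the middle of three consecutive gaps is a local minimum.

    Rule: Z(t-dt) > Z(t) <= Z(t+dt); fewer than three values -> False.
    """
    if len(gap_history) < 3:
        return False
    z0, z1, z2 = gap_history[-3], gap_history[-2], gap_history[-1]
    return z0 > z1 <= z2


def lzbl_probability(Z: float, Zdd: float) -> float:
    """LZBL hop probability exp(-(pi/2 hbar) sqrt(Z^3/Zdd)); Zdd <= 0 -> 0."""
    if Z < 0:
        raise ValueError("gap must be non-negative")
    if Zdd <= 0:
        return 0.0
    return float(np.exp(-(np.pi / (2.0 * HBAR_EV_FS)) * np.sqrt(Z**3 / Zdd)))


def attempt_hop(
    point: PhaseSpacePoint,
    e_current: float,
    e_target: float,
    probability: float,
    u: float,
) -> tuple[bool, PhaseSpacePoint]:
    """Accept iff u < P and kinetic energy suffices; rescale velocities uniformly.

    The scale kappa = sqrt((KE + E_j - E_k)/KE) conserves total energy;
    upward hops with KE < E_k - E_j are frustrated (rejected, velocities
    untouched).
    """
    if u >= probability:
        return False, point
    ke = kinetic_energy(point)
    reservoir = ke + e_current - e_target
    if reservoir <= 0 or ke <= 0:
        return False, point  # frustrated
    kappa = np.sqrt(reservoir / ke)
    return True, PhaseSpacePoint(point.coords, kappa * point.velocities, point.masses)


@dataclass(frozen=True)
class HopEvaluation:
    """One LZBL evaluation at a detected gap minimum."""

    time: float  # fs, time of the gap minimum
    state_from: int
    state_to: int
    gap: float  # eV, minimum gap Z
    gap_second_derivative: float  # eV/fs^2
    probability: float
    accepted: bool
    coords: np.ndarray  # geometry at the minimum
    member_probabilities: np.ndarray | None = None  # per ensemble member


@dataclass
class Trajectory:
    """Time series of one surface-hopping trajectory (fixed time step)."""

    times: np.ndarray  # (T,), fs
    coords: np.ndarray  # (T, N, 3)
    velocities: np.ndarray  # (T, N, 3)
    states: np.ndarray  # (T,), active state
    energies: np.ndarray  # (T, S), eV
    masses: np.ndarray  # (N,), amu
    hops: list[HopEvaluation]  # accepted hops
    hop_evaluations: list[HopEvaluation]  # all evaluations, accepted or not
    termination: str  # "time_limit" | "dissociation" | "error"

    @property
    def final_point(self) -> PhaseSpacePoint:
        return PhaseSpacePoint(self.coords[-1], self.velocities[-1], self.masses)

    def total_energy(self) -> np.ndarray:
        ke = 0.5 * EV_PER_AMU_A2_FS2 * np.sum(
            self.masses[None, :, None] * self.velocities**2, axis=(1, 2)
        )
        pot = self.energies[np.arange(len(self.times)), self.states]
        return ke + pot


@dataclass(frozen=True)
class TSHConfig:
    """Propagation settings. Defaults: dt = 0.1 fs, t_max = 60 fs."""

    dt: float = 0.1
    t_max: float = 60.0
    allow_upward: bool = True
    check_dissociation: bool = False
    elements: tuple[str, ...] | None = None  # needed for dissociation checks
    bond_scale_break: float = 2.5

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")


def bonded_pairs(geometry: Geometry, bond_scale: float = 1.2) -> set[tuple[int, int]]:
    """Covalently bonded atom pairs at the reference geometry."""
    from .constants import COVALENT_RADII

    pairs = set()
    radii = [COVALENT_RADII[el] for el in geometry.elements]
    for i in range(geometry.n_atoms):
        for j in range(i + 1, geometry.n_atoms):
            if geometry.distance(i, j) <= bond_scale * (radii[i] + radii[j]):
                pairs.add((i, j))
    return pairs


def detect_dissociation(
    geometry: Geometry,
    reference_bonds: set[tuple[int, int]],
    bond_scale_break: float = 2.5,
) -> bool:
    """True iff any initially bonded pair exceeds bond_scale_break * covalent sum."""
    from .constants import COVALENT_RADII

    radii = [COVALENT_RADII[el] for el in geometry.elements]
    for i, j in reference_bonds:
        if geometry.distance(i, j) > bond_scale_break * (radii[i] + radii[j]):
            return True
    return False


def propagate_tsh(
    initial: PhaseSpacePoint,
    potential,
    start_state: int,
    config: TSHConfig | None = None,
    seed: int = 0,
) -> Trajectory:
    """Propagate one LZBL surface-hopping trajectory.

    Velocity-Verlet on the active surface; at each detected gap minimum
    between the active state and its adjacent states (lower-gap partner
    attempted first), Zdd is estimated by the 3-point central difference and
    one hop is attempted with a seeded uniform draw. Terminates at t_max,
    on dissociation (when configured), or on a non-finite energy.
    """
    config = config or TSHConfig()
    rng = np.random.default_rng(seed)
    dt = config.dt
    n_steps = int(round(config.t_max / dt))
    inv_m = 1.0 / (initial.masses[:, None] * EV_PER_AMU_A2_FS2)
    has_members = hasattr(potential, "member_energies")

    state = int(start_state)
    coords = initial.coords.copy()
    vel = initial.velocities.copy()
    n_states = potential.n_states

    times = [0.0]
    traj_coords = [coords.copy()]
    traj_vel = [vel.copy()]
    traj_states = [state]
    energies = potential.energies(coords)
    traj_E = [np.asarray(energies, dtype=float).copy()]
    member_hist: list[np.ndarray] = (
        [np.asarray(potential.member_energies(coords), dtype=float)] if has_members else []
    )
    hops: list[HopEvaluation] = []
    evaluations: list[HopEvaluation] = []
    termination = "time_limit"

    ref_bonds: set[tuple[int, int]] | None = None
    if config.check_dissociation:
        if config.elements is None:
            raise ValueError("dissociation check requires elements in the config")
        ref_bonds = bonded_pairs(Geometry(config.elements, coords))

    force = np.asarray(potential.force(coords, state))
    t = 0.0
    for _ in range(n_steps):
        v_half = vel + 0.5 * dt * force * inv_m
        coords = coords + dt * v_half
        energies = np.asarray(potential.energies(coords), dtype=float)
        if not np.all(np.isfinite(energies)):
            termination = "error"
            break
        force = np.asarray(potential.force(coords, state))
        vel = v_half + 0.5 * dt * force * inv_m
        t += dt

        times.append(t)
        traj_coords.append(coords.copy())
        traj_vel.append(vel.copy())
        traj_E.append(energies.copy())
        if has_members:
            member_hist.append(np.asarray(potential.member_energies(coords), dtype=float))
            member_hist = member_hist[-3:]

        # LZBL: check the last three frames for a gap minimum per adjacent pair
        if len(traj_E) >= 3:
            E3 = traj_E[-3:]
            partners = [s for s in (state - 1, state + 1) if 0 <= s < n_states]
            partners.sort(key=lambda s: abs(energies[s] - energies[state]))
            hopped = False
            for partner in partners:
                if not config.allow_upward and energies[partner] > energies[state]:
                    continue
                z3 = [abs(E[partner] - E[state]) for E in E3]
                if not detect_gap_minimum(z3):
                    continue
                zdd = (z3[2] - 2.0 * z3[1] + z3[0]) / dt**2
                prob = lzbl_probability(z3[1], zdd)
                member_probs = None
                if has_members and len(member_hist) == 3:
                    mp = []
                    for mi in range(member_hist[0].shape[0]):
                        mz = [abs(member_hist[k][mi, partner] - member_hist[k][mi, state])
                              for k in range(3)]
                        mzdd = (mz[2] - 2.0 * mz[1] + mz[0]) / dt**2
                        mp.append(lzbl_probability(mz[1], mzdd))
                    member_probs = np.array(mp)
                u = rng.random()
                point = PhaseSpacePoint(coords, vel, initial.masses)
                accepted, new_point = attempt_hop(
                    point, float(energies[state]), float(energies[partner]), prob, u
                )
                ev = HopEvaluation(
                    time=t - dt,
                    state_from=state,
                    state_to=partner,
                    gap=z3[1],
                    gap_second_derivative=zdd,
                    probability=prob,
                    accepted=accepted,
                    coords=coords.copy(),
                    member_probabilities=member_probs,
                )
                evaluations.append(ev)
                if accepted:
                    hops.append(ev)
                    state = partner
                    vel = new_point.velocities
                    traj_vel[-1] = vel.copy()
                    force = np.asarray(potential.force(coords, state))
                    hopped = True
                if hopped:
                    break
        traj_states.append(state)
        if len(traj_states) < len(times):  # pragma: no cover - defensive
            raise AssertionError

        if ref_bonds is not None and detect_dissociation(
            Geometry(config.elements, coords), ref_bonds, config.bond_scale_break
        ):
            termination = "dissociation"
            break

    n = len(times)
    return Trajectory(
        times=np.asarray(times),
        coords=np.asarray(traj_coords),
        velocities=np.asarray(traj_vel),
        states=np.asarray(traj_states[:n], dtype=int),
        energies=np.asarray(traj_E),
        masses=initial.masses,
        hops=hops,
        hop_evaluations=evaluations,
        termination=termination,
    )


# ---------------------------------------------------------------------------
# Swarm analysis


def populations(
    trajectories: Sequence[Trajectory], time_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state population fractions and 95% CI half-widths on a time grid.

    Returns ``(pop, ci)`` with shape (n_states, n_times); the CI half-width
    is the normal (Wald) approximation 1.96 sqrt(p(1-p)/N).
    """
    if not trajectories:
        raise ValueError("empty trajectory swarm")
    time_grid = np.asarray(time_grid, dtype=float)
    n_states = int(max(t.energies.shape[1] for t in trajectories))
    counts = np.zeros((n_states, time_grid.size))
    for traj in trajectories:
        idx = np.clip(
            np.searchsorted(traj.times, time_grid, side="right") - 1, 0, len(traj.times) - 1
        )
        st = traj.states[idx]
        for k, s in enumerate(st):
            counts[s, k] += 1
    n = len(trajectories)
    pop = counts / n
    ci = 1.96 * np.sqrt(pop * (1.0 - pop) / n)
    return pop, ci


def quantum_yield(
    trajectories: Sequence[Trajectory],
    product_classifier: Callable[[PhaseSpacePoint], bool],
) -> tuple[float, float]:
    """Quantum yield Phi = N_reactive/N_traj with its 95% binomial CI half-width."""
    if not trajectories:
        raise ValueError("empty trajectory swarm")
    n = len(trajectories)
    n_reactive = sum(bool(product_classifier(t.final_point)) for t in trajectories)
    phi = n_reactive / n
    ci = 1.96 * np.sqrt(phi * (1.0 - phi) / n)
    return phi, ci


@dataclass(frozen=True)
class SwarmResult:
    """Aggregate of a trajectory swarm: populations, quantum yield, stability."""

    n_traj: int
    n_reactive: int
    quantum_yield: float
    quantum_yield_ci: float
    time_grid: np.ndarray
    populations: np.ndarray  # (n_states, n_times)
    populations_ci: np.ndarray
    stability_fraction: float  # fraction finishing without dissociation or error


def summarize_swarm(
    trajectories: Sequence[Trajectory],
    product_classifier: Callable[[PhaseSpacePoint], bool] | None = None,
    time_grid: np.ndarray | None = None,
) -> SwarmResult:
    if time_grid is None:
        time_grid = trajectories[0].times
    pop, ci = populations(trajectories, time_grid)
    if product_classifier is not None:
        phi, phi_ci = quantum_yield(trajectories, product_classifier)
        n_reactive = int(round(phi * len(trajectories)))
    else:
        phi, phi_ci, n_reactive = 0.0, 0.0, 0
    stable = sum(t.termination == "time_limit" for t in trajectories)
    return SwarmResult(
        n_traj=len(trajectories),
        n_reactive=n_reactive,
        quantum_yield=phi,
        quantum_yield_ci=phi_ci,
        time_grid=np.asarray(time_grid),
        populations=pop,
        populations_ci=ci,
        stability_fraction=stable / len(trajectories),
    )


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Dihedral angle i-j-k-l in degrees, in [0, 180]."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cos = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def cis_trans_classifier(indices: tuple[int, int, int, int], cis_below: float = 90.0):
    """Dihedral-based photoproduct classifier (e.g. the CNNC angle of azobenzene-like switches).

    Returns a callable mapping a final frame to True (cis product, dihedral
    below the threshold) or False (trans, dihedral at or above it).
    """

    def classify(point: PhaseSpacePoint) -> bool:
        return dihedral_angle(point.coords, *indices) < cis_below

    return classify
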