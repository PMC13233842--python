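"""Readers and writers for geometries, multi-state datasets, and spectra.

The dataset dialect is a small JSON schema with explicit units in the key
names::

    {"levels": ["tddft", "cc"],
     "records": [{"elements": ["H", "H"],
                  "coords_angstrom": [[0,0,0],[0,0,0.74]],
                  "level": "tddft",
                  "energies_ev": [0.0, 10.2, 11.5],
                  "forces_ev_per_angstrom": ...,      # optional, per state
                  "oscillator_strengths": [...]}]}    # optional, S0->Sn

Energies are adiabatic state energies in eV, index 0 the ground state,
sorted non-decreasing. Oscillator strengths are dimensionless and
non-negative, one per transition S0->Sn (n >= 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import ATOMIC_MASSES, SUPPORTED_ELEMENTS

__all__ = [
    "Geometry",
    "DatasetRecord",
    "LevelRegistry",
    "ParseError",
    "ValidationError",
    "read_xyz",
    "write_xyz",
    "read_dataset",
    "write_dataset",
    "read_spectrum",
    "write_spectrum",
]


class ParseError(ValueError):
    """Malformed input text (XYZ or dataset JSON)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


_CANONICAL = {s.lower(): s for s in SUPPORTED_ELEMENTS}


def _normalize_symbol(sym: str) -> str:
    try:
        return _CANONICAL[sym.strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unsupported element {sym!r}; supported: {', '.join(SUPPORTED_ELEMENTS)}"
        ) from None


@dataclass(frozen=True)
class Geometry:
    """One neutral singlet molecule: element symbols plus Cartesian coordinates in Angstrom."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3), Angstrom
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        elements = tuple(_normalize_symbol(s) for s in self.elements)
        object.__setattr__(self, "elements", elements)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape != (len(elements), 3):
            raise ValidationError(
                f"coords shape {coords.shape} does not match {len(elements)} atoms x 3"
            )
        if len(elements) < 1:
            raise ValidationError("geometry needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        if self.charge != 0 or self.multiplicity != 1:
            raise ValidationError("only neutral singlets (charge 0, multiplicity 1) are supported")
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[s] for s in self.elements])

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.elements, coords, self.charge, self.multiplicity)


@dataclass(frozen=True)
class LevelRegistry:
    """Ordered registry of fidelity-level tags mapped to one-hot indices."""

    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        levels = tuple(str(t) for t in self.levels)
        if len(set(levels)) != len(levels):
            raise ValidationError(f"duplicate level tags in {levels}")
        if not levels:
            raise ValidationError("registry needs at least one level")
        object.__setattr__(self, "levels", levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def index(self, tag: str) -> int:
        try:
            return self.levels.index(tag)
        except ValueError:
            raise ValidationError(f"level tag {tag!r} not in registry {self.levels}") from None


@dataclass(frozen=True)
class DatasetRecord:
    """One labeled geometry: fidelity tag, state energies, optional forces and oscillator strengths."""

    geometry: Geometry
    level_tag: str
    state_energies: tuple[float, ...]  # eV, ascending, index 0 = ground state
    state_forces: tuple[np.ndarray, ...] | None = None  # per state, (N,3) eV/A
    oscillator_strengths: tuple[float, ...] | None = None  # S0->Sn, n>=1

    def __post_init__(self) -> None:
        energies = tuple(float(e) for e in self.state_energies)
        if not energies:
            raise ValidationError("record needs at least one state energy")
        if not np.all(np.isfinite(energies)):
            raise ValidationError("non-finite state energy")
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise ValidationError(f"state energies not sorted non-decreasing: {energies}")
        object.__setattr__(self, "state_energies", energies)
        if self.state_forces is not None:
            forces = tuple(np.asarray(f, dtype=float) for f in self.state_forces)
            if len(forces) != len(energies):
                raise ValidationError(
                    f"forces given for {len(forces)} states but record has {len(energies)}"
                )
            for f in forces:
                if f.shape != (self.geometry.n_atoms, 3):
                    raise ValidationError(f"force array shape {f.shape} invalid")
            object.__setattr__(self, "state_forces", forces)
        if self.oscillator_strengths is not None:
            osc = tuple(float(f) for f in self.oscillator_strengths)
            if any(f < 0 for f in osc):
                raise ValidationError(f"negative oscillator strength in {osc}")
            object.__setattr__(self, "oscillator_strengths", osc)

    @property
    def n_states(self) -> int:
        return len(self.state_energies)


# ---------------------------------------------------------------------------
# XYZ


def read_xyz(source: str | Path) -> list[Geometry]:
    """Parse (multi-)XYZ text or a path to it into a list of geometries.

    Strings containing a newline are treated as XYZ text, anything else as a
    file path.
    """
    if isinstance(source, Path) or "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    lines = text.splitlines()
    geometries: list[Geometry] = []
    i = 0
    # skip trailing blank lines between frames
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}") from None
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise ParseError(
                f"line {i + 1}: header declares {natoms} atoms but only "
                f"{len(atom_lines)} atom lines follow"
            )
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for k, ln in enumerate(atom_lines):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + k}: expected 'El x y z', got {ln!r}")
            elements.append(parts[0])
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {i + 3 + k}: non-numeric coordinate in {ln!r}") from None
        geometries.append(Geometry(tuple(elements), coords))
        i += 2 + natoms
    return geometries


def write_xyz(geometries: Iterable[Geometry], path: str | Path | None = None, comment: str = "") -> str:
    """Serialize geometries to multi-XYZ text; optionally also write it to ``path``."""
    frames = []
    for g in geometries:
        rows = [str(g.n_atoms), comment]
        for sym, (x, y, z) in zip(g.elements, g.coords):
            rows.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
        frames.append("\n".join(rows))
    text = "\n".join(frames)
    if frames:
        text += "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Dataset JSON


def _record_to_obj(rec: DatasetRecord) -> dict:
    obj: dict = {
        "elements": list(rec.geometry.elements),
        "coords_angstrom": rec.geometry.coords.tolist(),
        "level": rec.level_tag,
        "energies_ev": list(rec.state_energies),
    }
    if rec.state_forces is not None:
        obj["forces_ev_per_angstrom"] = [f.tolist() for f in rec.state_forces]
    if rec.oscillator_strengths is not None:
        obj["oscillator_strengths"] = list(rec.oscillator_strengths)
    return obj


def _record_from_obj(obj: dict, index: int, registry: LevelRegistry) -> DatasetRecord:
    try:
        geometry = Geometry(tuple(obj["elements"]), np.asarray(obj["coords_angstrom"], dtype=float))
        level = str(obj["level"])
        registry.index(level)  # raises for unknown tags
        forces = obj.get("forces_ev_per_angstrom")
        return DatasetRecord(
            geometry=geometry,
            level_tag=level,
            state_energies=tuple(obj["energies_ev"]),
            state_forces=tuple(np.asarray(f, float) for f in forces) if forces is not None else None,
            oscillator_strengths=(
                tuple(obj["oscillator_strengths"]) if "oscillator_strengths" in obj else None
            ),
        )
    except KeyError as exc:
        raise ValidationError(f"record {index}: missing key {exc}") from None
    except ValidationError as exc:
        raise ValidationError(f"record {index}: {exc}") from None


def read_dataset(path: str | Path) -> tuple[list[DatasetRecord], LevelRegistry]:
    """Load and validate a dataset file; returns the records and the level registry."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(payload, dict) or "levels" not in payload or "records" not in payload:
        raise ValidationError(f"{path}: expected top-level keys 'levels' and 'records'")
    registry = LevelRegistry(tuple(payload["levels"]))
    records = [_record_from_obj(obj, i, registry) for i, obj in enumerate(payload["records"])]
    return records, registry


def write_dataset(
    records: Sequence[DatasetRecord], registry: LevelRegistry, path: str | Path
) -> None:
    """Write a schema-conformant dataset file with stable key ordering."""
    for rec in records:
        registry.index(rec.level_tag)
    payload = {
        "levels": list(registry.levels),
        "records": [_record_to_obj(r) for r in records],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# Spectrum TSV


def write_spectrum(curve, path: str | Path, unit: str = "eV") -> None:
    """Write a two-column spectrum (energy-or-wavelength, intensity) TSV with a unit header."""
    grid = np.asarray(curve.grid, dtype=float)
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValidationError("spectrum grid must be strictly increasing")
    lines = [f"# x[{unit}]\tintensity"]
    for x, y in zip(grid, curve.intensities):
        lines.append(f"{x:.12g}\t{y:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path):
    """Read a spectrum TSV written by :func:`write_spectrum`."""
    from .spectra import SpectrumCurve

    rows = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        x, y = ln.split("\t")
        rows.append((float(x), float(y)))
    arr = np.asarray(rows, dtype=float)
    return SpectrumCurve(grid=arr[:, 0], intensities=arr[:, 1])
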