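"""Atoms, molecular systems and XYZ I/O.

Positions are stored in Bohr; XYZ files follow the conventional dialect
(count line, comment line, ``El x y z`` rows in Angstrom).  The comment
line carries ``charge=<int> mult=<int>`` tokens so a file round-trips the
full system definition, not just the geometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .units import AMU_TO_ME, BOHR_ANGSTROM

# Standard atomic weights (amu) for the elements appearing in the studied
# systems (H, C, N, O, P) plus He for the one-electron benchmark cations.
_ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "He": (2, 4.002602),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "P": (15, 30.973761998),
}
_Z_TO_SYMBOL = {z: sym for sym, (z, _) in _ELEMENTS.items()}


def element_data(symbol: str) -> tuple[int, float]:
    """Return (Z, mass in electron masses) for a supported element."""
    try:
        z, amu = _ELEMENTS[symbol.capitalize()]
    except KeyError:
        raise ValueError(f"unknown element {symbol!r}") from None
    return z, amu * AMU_TO_ME


@dataclass
class Atom:
    """A nucleus carrying travelling basis functions in the dynamics.

    position is in Bohr; mass in electron masses (isotope-averaged standard
    atomic weight, except where a caller installs the bare proton mass for
    an H+ projectile).
    """

    symbol: str
    position: np.ndarray
    mass: float | None = None
    z: int = field(init=False)

    def __post_init__(self) -> None:
        self.symbol = self.symbol.capitalize()
        z, default_mass = element_data(self.symbol)
        self.z = z
        if self.mass is None:
            self.mass = default_mass
        if self.mass <= 0:
            raise ValueError("atomic mass must be positive")
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class MolecularSystem:
    """An ordered list of atoms with total charge and spin multiplicity."""

    atoms: list[Atom]
    charge: int = 0
    multiplicity: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        n = self.n_electrons
        if n < 0:
            raise ValueError("negative electron count")
        # N_alpha - N_beta = mult - 1 and N_alpha + N_beta = n must have an
        # integer solution.
        if (n - self.multiplicity + 1) % 2 or n - self.multiplicity + 1 < 0:
            raise ValueError(
                f"charge {self.charge} / multiplicity {self.multiplicity} "
                f"inconsistent with {n} electrons"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_electrons(self) -> int:
        return sum(a.z for a in self.atoms) - self.charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of positions in Bohr."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        """Nuclear charges Z_A."""
        return np.array([a.z for a in self.atoms], dtype=float)

    def with_positions(self, positions: np.ndarray) -> "MolecularSystem":
        positions = np.asarray(positions, float).reshape(self.n_atoms, 3)
        atoms = [
            Atom(a.symbol, p, mass=a.mass)
            for a, p in zip(self.atoms, positions)
        ]
        return MolecularSystem(atoms, self.charge, self.multiplicity, self.name)

    def nuclear_repulsion(self) -> float:
        e = 0.0
        pos, zs = self.positions, self.charges
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += zs[i] * zs[j] / np.linalg.norm(pos[i] - pos[j])
        return e


def combine(
    fragments: Sequence[MolecularSystem], name: str = ""
) -> MolecularSystem:
    """Concatenate fragments (already placed in a common frame)."""
    atoms = [a for frag in fragments for a in frag.atoms]
    charge = sum(f.charge for f in fragments)
    n_unpaired = sum(f.multiplicity - 1 for f in fragments)
    return MolecularSystem(atoms, charge, n_unpaired + 1, name=name)


_KV_RE = re.compile(r"(\w+)=(-?\d+)")


def read_xyz(path: str | Path) -> MolecularSystem:
    """Read an XYZ file (coordinates in Angstrom, converted to Bohr)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ValueError(f"{path}: malformed atom-count line") from None
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < count:
        raise ValueError(
            f"{path}: header promises {count} atoms, found {len(body)}"
        )
    tokens = dict(_KV_RE.findall(comment))
    charge = int(tokens.get("charge", 0))
    mult = int(tokens.get("mult", 1))
    atoms = []
    for ln in body[:count]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {ln!r}")
        sym = parts[0]
        xyz = np.array([float(v) for v in parts[1:4]]) / BOHR_ANGSTROM
        atoms.append(Atom(sym, xyz))
    return MolecularSystem(atoms, charge, mult, name=Path(path).stem)


def write_xyz(
    system: MolecularSystem, path: str | Path, comment_extra: str = ""
) -> None:
    """Write a system to XYZ (Angstrom) with charge/mult in the comment."""
    lines = [str(system.n_atoms)]
    comment = f"charge={system.charge} mult={system.multiplicity}"
    if comment_extra:
        comment += " " + comment_extra
    lines.append(comment)
    for a in system.atoms:
        x, y, z = a.position * BOHR_ANGSTROM
        lines.append(f"{a.symbol:2s} {x: 18.10f} {y: 18.10f} {z: 18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_multi_xyz(
    frames: Iterable[tuple[float, MolecularSystem]], path: str | Path
) -> None:
    """Write a multi-frame XYZ trajectory; each comment carries the time."""
    chunks = []
    for t, system in frames:
        chunks.append(str(system.n_atoms))
        chunks.append(
            f"charge={system.charge} mult={system.multiplicity} t_au={t:.8f}"
        )
        for a in system.atoms:
            x, y, z = a.position * BOHR_ANGSTROM
            chunks.append(f"{a.symbol:2s} {x: 18.10f} {y: 18.10f} {z: 18.10f}")
    Path(path).write_text("\n".join(chunks) + "\n")
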