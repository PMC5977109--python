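"""Gaussian basis sets.

Basis parameters live in plain-text tables under ``basis_data/``
(see the file headers for provenance).  ``build_basis`` expands them over
a molecular system into an ordered list of contracted Cartesian Gaussian
functions — atom-major, shells in table order, Cartesian components in
the fixed order x,y,z (p) and xx,xy,xz,yy,yz,zz (d).  Every contracted
function is normalized to unit self-overlap.

The polarization variants 6-31G* (d on heavy atoms) and 6-31G**
(additionally p on hydrogens) are assembled from the 6-31G table plus the
standard polarization exponents (d = 0.8 on C/N/O, p = 1.1 on H/He).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ..chem_system.system import MolecularSystem

_ANGULAR = {"S": 0, "P": 1, "D": 2}
# Cartesian component orders.
_CART = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

_POLARIZATION_D = {"C": 0.8, "N": 0.8, "O": 0.8}
_POLARIZATION_P_H = {"H": 1.1, "He": 1.1}


class BasisError(KeyError):
    """Missing element/basis combination or malformed basis table."""


def _double_factorial(n: int) -> float:
    if n <= 0:
        return 1.0
    out = 1.0
    while n > 0:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, powers: tuple[int, int, int]) -> float:
    """Normalization constant of a primitive Cartesian Gaussian."""
    i, j, k = powers
    l = i + j + k
    num = (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = math.sqrt(
        _double_factorial(2 * i - 1)
        * _double_factorial(2 * j - 1)
        * _double_factorial(2 * k - 1)
    )
    return num / den


def _contracted_self_overlap(
    alphas: np.ndarray, coeffs: np.ndarray, powers: tuple[int, int, int]
) -> float:
    """Closed-form self-overlap of a same-center contraction (primitive
    coefficients already carrying their primitive norms)."""
    i, j, k = powers
    dfac = (
        _double_factorial(2 * i - 1)
        * _double_factorial(2 * j - 1)
        * _double_factorial(2 * k - 1)
    )
    p = alphas[:, None] + alphas[None, :]
    s = (math.pi / p) ** 1.5 * dfac / (2.0 * p) ** (i + j + k)
    return float(coeffs @ s @ coeffs)


@dataclass
class BasisShell:
    """One contracted shell on one atomic center."""

    atom_index: int
    angular: int  # 0=s, 1=p, 2=d
    exponents: np.ndarray
    coefficients: np.ndarray  # raw contraction coefficients from the table

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, float)
        self.coefficients = np.asarray(self.coefficients, float)
        if np.any(self.exponents <= 0):
            raise BasisError("shell exponents must be positive")
        if self.exponents.shape != self.coefficients.shape:
            raise BasisError("exponent/coefficient length mismatch")


@dataclass
class ContractedGaussian:
    """A single normalized contracted Cartesian Gaussian basis function."""

    atom_index: int
    powers: tuple[int, int, int]
    alphas: np.ndarray
    coeffs: np.ndarray  # primitive-normalized and contraction-normalized

    @property
    def l(self) -> int:
        return sum(self.powers)


@dataclass
class BasisSet:
    """An expanded basis over a molecular system.

    ``functions[mu]`` is the mu-th contracted Cartesian Gaussian;
    ``ao_atom[mu]`` maps it to its atom.  ``K`` is the total count — the
    size of the electronic basis the dynamical spin-orbitals span.
    """

    name: str
    system: MolecularSystem
    shells: list[BasisShell]
    functions: list[ContractedGaussian] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.functions)

    @property
    def ao_atom(self) -> np.ndarray:
        return np.array([f.atom_index for f in self.functions], dtype=int)

    def centers(self) -> np.ndarray:
        """(K, 3) array of basis-function centers (current atom positions)."""
        pos = self.system.positions
        return pos[self.ao_atom]


def _parse_table(text: str) -> dict[str, list[tuple[str, list[list[float]]]]]:
    table: dict[str, list[tuple[str, list[list[float]]]]] = {}
    element: str | None = None
    shell_kind: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal shell_kind, rows
        if element is not None and shell_kind is not None:
            table[element].append((shell_kind, rows))
        shell_kind, rows = None, []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0].lower() == "element":
            flush()
            element = parts[1].capitalize()
            table[element] = []
        elif parts[0].lower() == "shell":
            flush()
            shell_kind = parts[1].upper()
        else:
            rows.append([float(v) for v in parts])
    flush()
    return table


def _load_table(basis_file: str) -> dict:
    ref = resources.files("slend.electronic_structure") / "basis_data" / basis_file
    return _parse_table(ref.read_text())


def _canonical(name: str) -> tuple[str, bool, bool]:
    """Return (table file stem, add heavy-atom d, add hydrogen p)."""
    key = name.lower().replace(" ", "")
    if key in ("sto-3g", "sto3g"):
        return "sto-3g", False, False
    if key in ("3-21g", "321g"):
        return "3-21g", False, False
    if key in ("6-31g", "631g"):
        return "6-31g", False, False
    if key in ("6-31g*", "6-31gs", "631g*"):
        return "6-31g", True, False
    if key in ("6-31g**", "6-31gss", "631g**"):
        return "6-31g", True, True
    raise BasisError(f"unknown basis set {name!r}")


def build_basis(system: MolecularSystem, name: str) -> BasisSet:
    """Expand a named basis over a system.

    Raises :class:`BasisError` when the table lacks parameters for an
    element in the system (e.g. phosphorus outside STO-3G).
    """
    stem, add_d, add_p = _canonical(name)
    table = _load_table(stem + ".txt")
    shells: list[BasisShell] = []
    for ia, atom in enumerate(system.atoms):
        try:
            entries = table[atom.symbol]
        except KeyError:
            raise BasisError(
                f"basis {name!r} has no parameters for element {atom.symbol}"
            ) from None
        for kind, rows in entries:
            arr = np.array(rows, float)
            if kind == "S":
                shells.append(BasisShell(ia, 0, arr[:, 0], arr[:, 1]))
            elif kind == "SP":
                shells.append(BasisShell(ia, 0, arr[:, 0], arr[:, 1]))
                shells.append(BasisShell(ia, 1, arr[:, 0], arr[:, 2]))
            elif kind == "P":
                shells.append(BasisShell(ia, 1, arr[:, 0], arr[:, 1]))
            elif kind == "D":
                shells.append(BasisShell(ia, 2, arr[:, 0], arr[:, 1]))
            else:
                raise BasisError(f"unsupported shell kind {kind!r}")
        if add_d and atom.symbol in _POLARIZATION_D:
            a = _POLARIZATION_D[atom.symbol]
            shells.append(BasisShell(ia, 2, np.array([a]), np.array([1.0])))
        if add_p and atom.symbol in _POLARIZATION_P_H:
            a = _POLARIZATION_P_H[atom.symbol]
            shells.append(BasisShell(ia, 1, np.array([a]), np.array([1.0])))

    basis = BasisSet(name=name, system=system, shells=shells)
    for shell in shells:
        for powers in _CART[shell.angular]:
            coeffs = shell.coefficients * np.array(
                [primitive_norm(a, powers) for a in shell.exponents]
            )
            s = _contracted_self_overlap(shell.exponents, coeffs, powers)
            coeffs = coeffs / math.sqrt(s)
            basis.functions.append(
                ContractedGaussian(
                    shell.atom_index, powers, shell.exponents.copy(), coeffs
                )
            )
    return basis
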