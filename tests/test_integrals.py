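"""Molecular integrals: closed forms, quadrature oracles, and agreement
between the two independent in-repo routes (reference McMurchie-Davidson
engine vs the accelerated static kernels)."""

import numpy as np
import pytest

from slend.chem_system import Atom, MolecularSystem, build_fixture
from slend.electronic_structure import engine
from slend.electronic_structure.basis import build_basis
from slend.electronic_structure.boys import boys_complex, boys_real
from slend.electronic_structure.integrals import compute_integrals


# ---- closed-form anchors -------------------------------------------

def test_h2_sto3g_matrix_elements(h2):
    """The standard textbook H2/STO-3G values at R = 1.4 Bohr."""
    b = build_basis(h2, "sto-3g")
    fns = engine.basis_terms(b, h2.positions)
    S = engine.overlap_matrix(fns, fns).real
    T = engine.kinetic_matrix(fns, fns).real
    eri = engine.eri_tensor(fns).real
    assert S[0, 1] == pytest.approx(0.6593, abs=1e-4)
    assert T[0, 0] == pytest.approx(0.7600, abs=1e-4)
    assert eri[0, 0, 0, 0] == pytest.approx(0.7746, abs=1e-4)
    assert eri[0, 0, 1, 1] == pytest.approx(0.5697, abs=1e-4)
    assert eri[0, 1, 0, 1] == pytest.approx(0.2970, abs=1e-4)


def test_single_s_function_overlap_is_one():
    h = MolecularSystem([Atom("H", [0.3, -0.2, 0.9])], 0, 2)
    fns = engine.basis_terms(build_basis(h, "sto-3g"), h.positions)
    assert engine.overlap(fns[0], fns[0]) == pytest.approx(1.0, abs=1e-12)


def test_far_separated_functions_do_not_overlap():
    sys = MolecularSystem(
        [Atom("H", [0, 0, 0]), Atom("H", [0, 0, 50.0])], 0, 1
    )
    fns = engine.basis_terms(build_basis(sys, "sto-3g"), sys.positions)
    assert abs(engine.overlap(fns[0], fns[1])) < 1e-12


def test_ss_eri_closed_form():
    """(ss|ss) over two unit-exponent primitives at separation d has the
    closed form 2 pi^2.5 / (p q sqrt(p+q)) F0(alpha d^2) x norms."""
    a = 0.9
    d = 1.7
    na = (2 * a / np.pi) ** 0.75
    t1 = engine.Term(np.zeros(3), np.zeros(3, int), np.array([a]),
                     np.array([na + 0j]), np.zeros(3))
    t2 = engine.Term(np.array([0, 0, d]), np.zeros(3, int), np.array([a]),
                     np.array([na + 0j]), np.zeros(3))
    val = engine.eri([t1], [t1], [t2], [t2]).real
    p = q = 2 * a
    alpha = p * q / (p + q)
    f0 = boys_real(0, np.array(alpha * d * d))[0]
    expect = (
        2 * np.pi**2.5 / (p * q * np.sqrt(p + q)) * f0 * na**4
        * (np.pi / p) ** 0.0
    )
    assert val == pytest.approx(float(expect), rel=1e-12)


# ---- quadrature oracle for p/d functions ---------------------------

def _grid_value(fns, i, j, n=101, L=6.5):
    x = np.linspace(-L, L, n)
    dx = x[1] - x[0]
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")

    def val(f):
        tot = np.zeros_like(X, dtype=complex)
        for t in f:
            poly = (
                (X - t.center[0]) ** t.powers[0]
                * (Y - t.center[1]) ** t.powers[1]
                * (Z - t.center[2]) ** t.powers[2]
            )
            r2 = (
                (X - t.center[0]) ** 2
                + (Y - t.center[1]) ** 2
                + (Z - t.center[2]) ** 2
            )
            ph = np.exp(
                1j * (t.phase[0] * X + t.phase[1] * Y + t.phase[2] * Z)
            )
            for a, c in zip(t.alphas, t.coeffs):
                tot += c * poly * np.exp(-a * r2) * ph
        return tot

    return complex(np.sum(np.conj(val(fns[i])) * val(fns[j])) * dx**3)


def test_p_function_overlap_against_quadrature(h2o):
    b = build_basis(h2o, "sto-3g")
    fns = engine.basis_terms(b, h2o.positions)
    # p_z on O against 1s on H (indices: O 1s,2s,2px,2py,2pz,H,H)
    got = engine.overlap(fns[4], fns[5])
    ref = _grid_value(fns, 4, 5)
    assert got == pytest.approx(ref, abs=2e-6)


def test_travelling_overlap_against_quadrature(h2o):
    b = build_basis(h2o, "sto-3g")
    vel = np.array([[0.3, -0.1, 0.2], [0.0, 0.5, -0.2], [0.1, 0.0, 0.0]])
    fns = engine.basis_terms(b, h2o.positions, velocities=vel)
    got = engine.overlap(fns[4], fns[6])
    ref = _grid_value(fns, 4, 6)
    assert got == pytest.approx(ref, abs=2e-6)


# ---- travelling mode reduces to static at zero momentum -------------

def test_travelling_reduces_to_static(h2o):
    static = compute_integrals(build_basis(h2o, "sto-3g"), mode="static")
    trav = compute_integrals(
        build_basis(h2o, "sto-3g"),
        velocities=np.zeros((3, 3)),
        mode="travelling",
    )
    assert np.abs(trav.S - static.S).max() < 1e-12
    assert np.abs(trav.hcore - static.hcore).max() < 1e-12
    assert np.abs(trav.eri - static.eri).max() < 1e-12


# ---- fast static kernels vs the reference engine --------------------

@pytest.mark.parametrize("basis_name", ["sto-3g", "6-31g*"])
def test_fast_kernels_match_reference_engine(basis_name):
    rng = np.random.default_rng(5)
    sys = MolecularSystem(
        [
            Atom("O", rng.standard_normal(3) * 0.3),
            Atom("H", [0.2, 1.6, -0.4]),
            Atom("H", [-1.5, -0.3, 0.6]),
        ],
        0,
        1,
    )
    b = build_basis(sys, basis_name)
    vals = compute_integrals(b, mode="static")
    fns = engine.basis_terms(b, sys.positions)
    assert np.abs(
        vals.S - engine.overlap_matrix(fns, fns).real
    ).max() < 1e-11
    assert np.abs(
        vals.T - engine.kinetic_matrix(fns, fns).real
    ).max() < 1e-11
    assert np.abs(
        vals.V
        - engine.nuclear_matrix(fns, fns, sys.charges, sys.positions).real
    ).max() < 1e-10
    if basis_name == "sto-3g":  # engine ERI on 19 functions is slow
        assert np.abs(vals.eri - engine.eri_tensor(fns).real).max() < 1e-11


# ---- structural invariants ------------------------------------------

def test_overlap_hermitian_positive_definite(h2o):
    vals = compute_integrals(build_basis(h2o, "6-31g*"), mode="static")
    assert np.abs(vals.S - vals.S.T).max() < 1e-12
    assert np.linalg.eigvalsh(vals.S).min() > 0
    assert np.abs(vals.hcore - vals.hcore.T).max() < 1e-10


def test_eri_permutational_symmetry(h2o):
    eri = compute_integrals(build_basis(h2o, "sto-3g"), mode="static").eri
    assert np.abs(eri - eri.transpose(1, 0, 2, 3)).max() < 1e-10
    assert np.abs(eri - eri.transpose(0, 1, 3, 2)).max() < 1e-10
    assert np.abs(eri - eri.transpose(2, 3, 0, 1)).max() < 1e-10


def test_boys_complex_matches_real_axis():
    t = np.array([0.0, 0.3, 2.7, 15.0, 60.0])
    fr = boys_real(6, t)
    fc = boys_complex(6, t.astype(complex))
    assert np.abs(fr - fc.real).max() < 1e-13
    assert np.abs(fc.imag).max() < 1e-13
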