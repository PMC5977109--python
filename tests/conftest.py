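"""Shared fixtures: converged reference determinants are expensive
enough to cache per session."""

import numpy as np
import pytest

from slend.chem_system import Atom, MolecularSystem, build_fixture
from slend.electronic_structure.scf import run_uhf


@pytest.fixture(scope="session")
def h2():
    return build_fixture("h2")


@pytest.fixture(scope="session")
def h2o():
    return build_fixture("h2o")


@pytest.fixture(scope="session")
def h2_plus():
    return build_fixture("h2_plus")


@pytest.fixture(scope="session")
def h2_det(h2):
    return run_uhf(h2, "sto-3g")


@pytest.fixture(scope="session")
def h2o_det(h2o):
    return run_uhf(h2o, "sto-3g")


@pytest.fixture(scope="session")
def h2p_det(h2_plus):
    return run_uhf(h2_plus, "sto-3g")


@pytest.fixture(scope="session")
def h_atom():
    return MolecularSystem([Atom("H", [0.0, 0.0, 0.0])], 0, 2, "h")


@pytest.fixture(scope="session")
def h_atom_det(h_atom):
    return run_uhf(h_atom, "sto-3g")


@pytest.fixture(scope="session")
def h2_equilibrium_det():
    """H2 at the STO-3G energy minimum (needed for stationarity checks:
    at the fixture default 1.4 Bohr there is a small residual force)."""
    from scipy.optimize import minimize_scalar

    def energy(r):
        sys = MolecularSystem(
            [Atom("H", [0, 0, 0]), Atom("H", [0, 0, r])], 0, 1, "h2"
        )
        return run_uhf(sys, "sto-3g").energy

    res = minimize_scalar(energy, bracket=(1.2, 1.4, 1.6), options={"xtol": 1e-10})
    r0 = float(res.x)
    sys = MolecularSystem(
        [Atom("H", [0, 0, 0]), Atom("H", [0, 0, r0])], 0, 1, "h2eq"
    )
    return run_uhf(sys, "sto-3g")


def zero_state(det, **kw):
    """Thouless state with z = 0 and nuclei at rest over a determinant."""
    from slend.thouless_dynamics import ThoulessState, nuclear_from_system

    K = det.basis.K
    z = [
        np.zeros((K - det.n_occ[s], det.n_occ[s]), dtype=complex)
        for s in range(2)
    ]
    return ThoulessState(
        det, nuclear_from_system(det.basis.system), z, **kw
    )
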