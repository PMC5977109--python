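"""Boys function F_m for real and complex arguments.

The travelling-basis (electron-translation-factor) integrals lead to
Hermite-Coulomb recurrences whose Boys argument is complex (the Gaussian
product center acquires an imaginary shift proportional to the relative
center velocities).  Real arguments take the fast incomplete-gamma route;
complex arguments use a convergent downward-recursion series for moderate
|z| and the erf closed form with upward recursion for large |z|.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, gammainc, gammaln


def boys_real(mmax: int, t: np.ndarray) -> np.ndarray:
    """F_m(t) for m = 0..mmax, real t >= 0.  Returns (mmax+1, ...)."""
    t = np.asarray(t, dtype=float)
    out = np.empty((mmax + 1,) + t.shape)
    small = t < 1e-13
    ts = np.where(small, 1.0, t)
    for m in range(mmax + 1):
        a = m + 0.5
        # F_m(t) = gamma(a) P(a, t) / (2 t^a) with P the regularized
        # lower incomplete gamma.
        val = np.exp(gammaln(a)) * gammainc(a, ts) / (2.0 * ts**a)
        out[m] = np.where(small, 1.0 / (2 * m + 1) - t / (2 * m + 3), val)
    return out


def _boys_series_complex(m: int, z: np.ndarray) -> np.ndarray:
    """Convergent series e^{-z} sum_k (2z)^k (2m-1)!! / (2m+2k+1)!!."""
    term = np.ones_like(z)
    total = np.zeros_like(z)
    denom = 2 * m + 1
    total += term / denom
    k = 0
    while True:
        k += 1
        term = term * (2.0 * z) / (2 * m + 2 * k + 1)
        total += term / denom  # denom constant: (2m+2k+1) folded into term
        if np.all(np.abs(term) / max(1e-300, float(np.max(np.abs(total))))
                  < 1e-17) or k > 300:
            break
    return np.exp(-z) * total / 1.0


def boys_complex(mmax: int, z: np.ndarray) -> np.ndarray:
    """F_m(z) for m = 0..mmax, complex z with Re z >= 0."""
    z = np.asarray(z, dtype=complex)
    out = np.empty((mmax + 1,) + z.shape, dtype=complex)
    az = np.abs(z)
    small = az < 1e-13
    moderate = (~small) & (az <= 40.0)
    large = az > 40.0

    if np.any(small):
        for m in range(mmax + 1):
            out[m][small] = 1.0 / (2 * m + 1) - z[small] / (2 * m + 3)
    if np.any(moderate):
        zm = z[moderate]
        # downward recursion from a series start well above mmax
        top = _boys_series_complex(mmax, zm)
        out[mmax][moderate] = top
        fm1 = top
        ez = np.exp(-zm)
        for m in range(mmax - 1, -1, -1):
            fm1 = (2.0 * zm * fm1 + ez) / (2 * m + 1)
            out[m][moderate] = fm1
    if np.any(large):
        zl = z[large]
        rz = np.sqrt(zl)
        f0 = 0.5 * np.sqrt(np.pi) / rz * erf(rz)
        out[0][large] = f0
        ez = np.exp(-zl)
        fm = f0
        for m in range(mmax):
            fm = ((2 * m + 1) * fm - ez) / (2.0 * zl)
            out[m + 1][large] = fm
    return out
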