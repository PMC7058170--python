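"""Box-Cox (LMS) transforms between anthropometric measurements and Z-scores.

The LMS method summarises the distribution of an anthropometric measurement
at a given age by three parameters: **L**, the Box-Cox power that normalises
skewness; **M**, the median of the measurement; and **S**, its coefficient of
variation.  A measurement ``x`` converts to a Z-score via

.. math::

    z = \\frac{(x/M)^L - 1}{L \\cdot S} \\quad (L \\ne 0), \\qquad
    z = \\frac{\\ln(x/M)}{S} \\quad (L = 0)

and back via the exact inverse

.. math::

    x = M (1 + L S z)^{1/L} \\quad (L \\ne 0), \\qquad
    x = M e^{S z} \\quad (L = 0).

Percentiles are obtained from the standard normal CDF using the classical
rational approximation of Abramowitz & Stegun (eq. 26.2.17), whose absolute
error is below 7.5e-8; the inverse (percentile to Z) is solved by bracketed
root finding on that same approximation.

All four transforms accept scalars or aligned array-likes.  Scalar calls
raise :class:`~pedigrowth.errors.DomainError` on invalid input; vectorised
calls propagate invalid or missing elements as NaN so that cohort pipelines
survive partial records.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "LMSTriple",
    "x_to_z",
    "z_to_x",
    "z_to_percentile",
    "percentile_to_z",
    "normal_cdf",
]

#: below this magnitude L is treated as exactly zero (log branch), avoiding
#: catastrophic cancellation in ((x/M)**L - 1) / L as L -> 0.
L_ZERO_TOL = 1e-12

# Abramowitz & Stegun 26.2.17 constants.
_AS_P = 0.2316419
_AS_B = (0.319381530, -0.356563782, 1.781477937, -1.821255978, 1.330274429)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class LMSTriple(NamedTuple):
    """One (L, M, S) parameter set of a growth reference at a single age.

    ``L`` is the dimensionless Box-Cox skewness power (any finite real,
    including 0), ``M`` the median in measurement units (strictly positive)
    and ``S`` the dimensionless coefficient of variation (strictly positive).
    """

    L: float
    M: float
    S: float

    def validate(self) -> "LMSTriple":
        if not (math.isfinite(self.L)):
            raise DomainError(f"L must be finite, got {self.L!r}")
        if not (math.isfinite(self.M) and self.M > 0):
            raise DomainError(f"M must be a positive number, got {self.M!r}")
        if not (math.isfinite(self.S) and self.S > 0):
            raise DomainError(f"S must be a positive number, got {self.S!r}")
        return self


def _coerce(lms) -> LMSTriple:
    if isinstance(lms, LMSTriple):
        return lms
    return LMSTriple(*lms)


def _all_scalar(*vals) -> bool:
    return all(np.ndim(v) == 0 for v in vals)


def x_to_z(x, lms):
    """Convert measurement(s) to Z-score(s) under Box-Cox LMS parameters.

    Parameters
    ----------
    x : float or array-like
        Measurement value(s), strictly positive, in the units of ``M``.
    lms : LMSTriple or (L, M, S) of scalars/arrays
        LMS parameters, broadcastable against ``x``.

    Returns
    -------
    float or ndarray
        Z-score(s).  Vectorised calls return NaN where an element of the
        input is missing or invalid.
    """
    L, M, S = _coerce(lms)
    if _all_scalar(x, L, M, S):
        LMSTriple(float(L), float(M), float(S)).validate()
        xf = float(x)
        if not (math.isfinite(xf) and xf > 0):
            raise DomainError(f"measurement must be positive, got {x!r}")
        return float(_box_cox_z(xf, float(L), float(M), float(S)))
    xv, Lv, Mv, Sv = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (x, L, M, S))
    )
    bad = ~(np.isfinite(xv) & (xv > 0) & np.isfinite(Lv)
            & np.isfinite(Mv) & (Mv > 0) & np.isfinite(Sv) & (Sv > 0))
    with np.errstate(all="ignore"):
        z = _box_cox_z(xv, Lv, Mv, Sv)
    return np.where(bad, np.nan, z)


def _box_cox_z(x, L, M, S):
    ratio = np.true_divide(x, M)
    log_branch = np.log(ratio) / S
    Ls = np.where(np.abs(L) < L_ZERO_TOL, 1.0, L)
    pow_branch = (np.power(ratio, Ls) - 1.0) / (Ls * S)
    return np.where(np.abs(L) < L_ZERO_TOL, log_branch, pow_branch)


def z_to_x(z, lms):
    """Convert Z-score(s) back to measurement value(s); exact inverse of
    :func:`x_to_z`.

    For ``L != 0`` the transform is only defined while ``1 + L*S*z > 0``;
    a scalar Z outside that range raises :class:`DomainError`, an array
    element outside it becomes NaN.
    """
    L, M, S = _coerce(lms)
    if _all_scalar(z, L, M, S):
        LMSTriple(float(L), float(M), float(S)).validate()
        zf = float(z)
        if not math.isfinite(zf):
            raise DomainError(f"z must be finite, got {z!r}")
        if abs(float(L)) >= L_ZERO_TOL and 1.0 + float(L) * float(S) * zf <= 0.0:
            raise DomainError(
                f"z={zf} is outside the representable Box-Cox range for "
                f"L={float(L)}, S={float(S)} (requires 1 + L*S*z > 0)"
            )
        return float(_box_cox_x(zf, float(L), float(M), float(S)))
    zv, Lv, Mv, Sv = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (z, L, M, S))
    )
    base = 1.0 + Lv * Sv * zv
    bad = ~(np.isfinite(zv) & np.isfinite(Lv) & np.isfinite(Mv) & (Mv > 0)
            & np.isfinite(Sv) & (Sv > 0))
    bad |= (np.abs(Lv) >= L_ZERO_TOL) & (base <= 0)
    with np.errstate(all="ignore"):
        x = _box_cox_x(zv, Lv, Mv, Sv)
    return np.where(bad, np.nan, x)


def _box_cox_x(z, L, M, S):
    log_branch = M * np.exp(S * z)
    Ls = np.where(np.abs(L) < L_ZERO_TOL, 1.0, L)
    base = 1.0 + Ls * S * z
    pow_branch = M * np.power(np.where(base > 0, base, np.nan), 1.0 / Ls)
    return np.where(np.abs(L) < L_ZERO_TOL, log_branch, pow_branch)


def normal_cdf(z):
    """Standard normal CDF via the Abramowitz-Stegun 26.2.17 rational
    approximation (absolute error < 7.5e-8), on the [0, 1] scale.

    The approximation is evaluated at ``|z|`` and reflected through the
    symmetry ``Phi(-z) = 1 - Phi(z)``.
    """
    zv = np.asarray(z, dtype=float)
    az = np.abs(zv)
    t = 1.0 / (1.0 + _AS_P * az)
    b1, b2, b3, b4, b5 = _AS_B
    poly = t * (b1 + t * (b2 + t * (b3 + t * (b4 + t * b5))))
    with np.errstate(all="ignore"):
        upper = 1.0 - _INV_SQRT_2PI * np.exp(-0.5 * az * az) * poly
    out = np.where(zv >= 0, upper, 1.0 - upper)
    if np.ndim(z) == 0:
        return float(out)
    return out


def z_to_percentile(z):
    """Convert Z-score(s) to percentile(s) on the open 0-100 scale."""
    if np.ndim(z) == 0:
        zf = float(z)
        if not math.isfinite(zf):
            raise DomainError(f"z must be finite, got {z!r}")
        return 100.0 * normal_cdf(zf)
    zv = np.asarray(z, dtype=float)
    out = np.where(np.isfinite(zv), 100.0 * normal_cdf(zv), np.nan)
    return out


# percentiles achievable within the bracket used by percentile_to_z
_Z_BRACKET = 13.0


def percentile_to_z(p):
    """Invert :func:`z_to_percentile` by bracketed root search.

    Accurate to better than 1e-6 in the fixed point
    ``|z_to_percentile(z) - p|`` for percentiles away from the extreme
    tails (roughly 1e-30 < p/100 < 1 - 1e-9, the resolution limit of the
    underlying CDF approximation).
    """
    if np.ndim(p) != 0:
        return np.array([percentile_to_z(pi) for pi in np.asarray(p).ravel()]).reshape(
            np.shape(p)
        )
    pf = float(p)
    if not (math.isfinite(pf) and 0.0 < pf < 100.0):
        raise DomainError(f"percentile must lie strictly between 0 and 100, got {p!r}")
    lo, hi = -_Z_BRACKET, _Z_BRACKET
    flo = z_to_percentile(lo) - pf
    fhi = z_to_percentile(hi) - pf
    if flo > 0 or fhi < 0:
        raise DomainError(
            f"percentile {pf} is too extreme for the CDF approximation's range"
        )
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    return float(brentq(lambda zz: z_to_percentile(zz) - pf, lo, hi,
                        xtol=1e-12, rtol=8.9e-16))
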