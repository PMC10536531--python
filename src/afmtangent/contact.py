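"""Forward models of rigid-sphere indentation of an elastic half-space.

Three force-indentation laws are provided:

* ``sneddon_force`` — the exact parametric solution, evaluated by numerically
  inverting the depth/contact-radius relation;
* ``polynomial_force`` — the closed-form polynomial approximation built on a
  :class:`~afmtangent.coefficients.CoefficientSet`;
* ``hertz_force`` — the classical small-depth law F = (4/3) E* sqrt(R) h^(3/2).

All lengths are SI meters, forces newtons, moduli pascals.  Unit conversion
happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .coefficients import CoefficientSet, DomainError

__all__ = [
    "ContactParameters",
    "sneddon_depth",
    "sneddon_contact_radius",
    "sneddon_force",
    "polynomial_force",
    "hertz_force",
    "contact_stiffness",
]


@dataclass(frozen=True)
class ContactParameters:
    """Sample and indenter description.

    Parameters
    ----------
    E : float
        Young's modulus of the sample, Pa.
    v : float
        Poisson ratio (0.5 for incompressible, water-rich gels and cells).
    R : float
        Spherical tip radius, m.
    """

    E: float
    v: float
    R: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.v <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.R <= 0:
            raise ValueError("tip radius must be positive")

    @property
    def E_star(self) -> float:
        """Reduced modulus E / (1 - v^2), Pa."""
        return self.E / (1.0 - self.v**2)


def sneddon_depth(rc, R):
    """Indentation depth h for a given contact radius (exact relation).

    h = (rc / 2) * ln((R + rc) / (R - rc)); monotone increasing in rc,
    h -> 0 as rc -> 0 and h -> infinity as rc -> R.
    """
    rc = np.asarray(rc, dtype=float)
    if np.any(rc < 0):
        raise ValueError("contact radius must be non-negative")
    if np.any(rc >= R):
        raise ValueError("contact radius must be smaller than the tip radius")
    with np.errstate(invalid="ignore"):
        h = 0.5 * rc * np.log((R + rc) / (R - rc))
    return np.where(rc == 0, 0.0, h)[()] if np.ndim(h) else float(h)


def sneddon_contact_radius(h: float, R: float) -> float:
    """Contact radius rc solving the exact depth relation for a given h.

    Bracketed root search on rc/R in [0, 1); rc/R -> 1 only asymptotically,
    so any finite depth has a solution.
    """
    if R <= 0:
        raise ValueError("tip radius must be positive")
    if h < 0:
        raise ValueError("indentation depth must be non-negative")
    if h == 0:
        return 0.0
    x = h / R

    def f(t: float) -> float:
        return 0.5 * t * np.log((1.0 + t) / (1.0 - t)) - x

    t = brentq(f, 0.0, 1.0 - 1e-12, xtol=1e-15, rtol=1e-14)
    return t * R


def sneddon_force(h, params: ContactParameters):
    """Exact spherical-indentation force at depth h (scalar or array).

    Evaluates F = (E*/2) [ (rc^2 + R^2) ln((R+rc)/(R-rc)) - 2 rc R ] with rc
    obtained by numerical inversion of the depth relation.
    """
    R = params.R
    scalar = np.ndim(h) == 0
    hs = np.atleast_1d(np.asarray(h, dtype=float))
    rc = np.array([sneddon_contact_radius(float(hi), R) for hi in hs])
    with np.errstate(invalid="ignore", divide="ignore"):
        F = 0.5 * params.E_star * (
            (rc**2 + R**2) * np.log((R + rc) / (R - rc)) - 2.0 * rc * R
        )
    F = np.where(rc == 0, 0.0, F)
    return float(F[0]) if scalar else F


def polynomial_force(h, params: ContactParameters, coeffs: CoefficientSet):
    """Closed-form polynomial force law.

    F = 2 E* [ (2/3) c1 R^(1/2) h^(3/2) + (1/2) c2 h^2 + (1/3) c3 R^(-1) h^3
               + ... + (1/N) cN R^(2-N) h^N ]

    i.e. the integral of 2 E* rc(h) with rc from the coefficient expansion.
    Valid for 0 <= h/R <= ``coeffs.domain_max``.
    """
    h = np.asarray(h, dtype=float)
    R = params.R
    coeffs.check_ratio(h / R)
    x = h / R
    total = (2.0 / 3.0) * coeffs.c[0] * x**1.5
    for k, ck in enumerate(coeffs.c[1:], start=2):
        total = total + (ck / k) * x**k
    F = 2.0 * params.E_star * R**2 * total
    return float(F) if np.ndim(F) == 0 else F


def hertz_force(h, params: ContactParameters):
    """Hertzian small-depth force F = (4/3) E* R^(1/2) h^(3/2)."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth must be non-negative")
    F = (4.0 / 3.0) * params.E_star * np.sqrt(params.R) * h**1.5
    return float(F) if np.ndim(F) == 0 else F


def contact_stiffness(h, params: ContactParameters, coeffs: CoefficientSet):
    """Contact stiffness dF/dh of the polynomial law.

    S = 2 E* [ c1 R^(1/2) h^(1/2) + c2 h + c3 R^(-1) h^2 + ...
               + cN R^(2-N) h^(N-1) ]  =  2 E* rc(h),

    the analytic derivative of :func:`polynomial_force`.
    """
    h = np.asarray(h, dtype=float)
    R = params.R
    coeffs.check_ratio(h / R)
    S = 2.0 * params.E_star * R * coeffs.contact_radius_ratio(h / R)
    return float(S) if np.ndim(S) == 0 else S
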