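"""Polynomial coefficient sets for the deep spherical-indentation force law.

The exact spherical (Sneddon) contact solution relates force and depth only
parametrically through the contact radius ``rc``.  A practical closed form is
obtained by expanding the normalized contact radius in powers of the
normalized depth,

    rc/R = c1 (h/R)^(1/2) + c2 (h/R) + c3 (h/R)^2 + ... + cN (h/R)^(N-1),

which, inserted into the axisymmetric stiffness relation dF/dh = 2 E* rc,
yields an explicit polynomial force-indentation law.  Each coefficient set is
valid up to a maximum depth-to-radius ratio ``domain_max``.

Two sets are built in: a three-term set for routine experiments
(hmax/R <= 1.32) and a six-term set covering essentially any physical
indentation depth (hmax/R <= 4.9512).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DomainError(ValueError):
    """Raised when a depth ratio falls outside a coefficient set's validity."""


@dataclass(frozen=True)
class CoefficientSet:
    """Expansion constants c1..cN with their validity domain in hmax/R.

    Parameters
    ----------
    c : tuple of float
        Coefficients c1..cN of the rc/R expansion. c1 must be positive
        (the small-depth limit rc ~ sqrt(h R) requires it).
    domain_max : float
        Upper bound on h/R for which the expansion is accurate.
    name : str
        Short identifier used in reports ("N3", "N6", or custom).
    """

    c: tuple[float, ...]
    domain_max: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.c) < 2:
            raise ValueError("coefficient set needs at least two terms (N >= 2)")
        if self.c[0] <= 0:
            raise ValueError("c1 must be positive (Hertzian small-depth limit)")
        if self.domain_max <= 0:
            raise ValueError("domain_max must be positive")

    @property
    def order(self) -> int:
        """Number of terms N."""
        return len(self.c)

    #: Relative grace on the domain bound: published lookup tables for the
    #: six-term set extend to h/R = 5.00, ~1% beyond its nominal 4.9512.
    _DOMAIN_RTOL = 0.01

    def check_ratio(self, ratio: float) -> None:
        """Validate a depth ratio h/R against this set's domain."""
        if np.any(np.asarray(ratio) < 0):
            raise DomainError("indentation depth must be non-negative")
        if np.any(np.asarray(ratio) > self.domain_max * (1 + self._DOMAIN_RTOL)):
            raise DomainError(
                f"h/R = {np.max(ratio):.4g} exceeds domain_max = "
                f"{self.domain_max} of coefficient set {self.name!r}; "
                "use a wider set (e.g. the six-term set, valid to 4.9512)"
            )

    def contact_radius_ratio(self, ratio):
        """rc/R from the expansion at depth ratio h/R (no domain check)."""
        x = np.asarray(ratio, dtype=float)
        out = self.c[0] * np.sqrt(x)
        for k, ck in enumerate(self.c[1:], start=1):
            out = out + ck * x**k
        return out


#: Three-term set, valid for hmax/R <= 1.32 (routine experiments).
COEFFS_N3 = CoefficientSet(c=(1.022, -0.1133, -0.0742), domain_max=1.32, name="N3")

#: Six-term set, valid for hmax/R <= 4.9512 (any realistic scenario).
COEFFS_N6 = CoefficientSet(
    c=(1.0100000, -0.0730300, -0.1357000, 0.0359800, -0.0040240, 0.0001653),
    domain_max=4.9512,
    name="N6",
)

BUILTIN_SETS = {"N3": COEFFS_N3, "N6": COEFFS_N6}


@dataclass(frozen=True)
class FittedCoefficientSet(CoefficientSet):
    """A coefficient set produced by :func:`fit_coefficient_set`.

    Carries least-squares diagnostics alongside the coefficients.
    """

    condition_number: float = field(default=float("nan"))
    max_residual: float = field(default=float("nan"))


def fit_coefficient_set(
    domain_max: float, order: int, n_grid: int = 2000
) -> FittedCoefficientSet:
    """Fit a fresh coefficient set to the exact parametric contact relation.

    Samples ``n_grid`` evenly spaced contact-radius ratios rc/R, maps each to
    its exact depth ratio h/R through the parametric depth relation, then
    least-squares fits rc/R on the basis {(h/R)^(1/2), (h/R), ...,
    (h/R)^(order-1)}.

    Parameters
    ----------
    domain_max : float
        Upper h/R bound of the fitted set's validity.
    order : int
        Number of terms N (>= 2).
    n_grid : int
        Grid density; uniform in rc/R, deterministic.

    Returns
    -------
    FittedCoefficientSet
        Fitted coefficients plus the design-matrix condition number and the
        maximum absolute residual of rc/R over the grid.
    """
    from .contact import sneddon_contact_radius  # local import avoids cycle

    if domain_max <= 0:
        raise ValueError("domain_max must be positive")
    if order < 2:
        raise ValueError("order must be >= 2")

    # rc/R value at which h/R hits domain_max
    rc_max = sneddon_contact_radius(domain_max, 1.0)
    rc = np.linspace(1e-6, rc_max, n_grid)
    with np.errstate(divide="ignore"):
        h = 0.5 * rc * np.log((1.0 + rc) / (1.0 - rc))

    powers = [0.5] + [float(k) for k in range(1, order)]
    design = np.column_stack([h**p for p in powers])
    coef, _, _, sv = np.linalg.lstsq(design, rc, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    resid = float(np.max(np.abs(design @ coef - rc)))
    return FittedCoefficientSet(
        c=tuple(float(v) for v in coef),
        domain_max=float(domain_max),
        name=f"fitted-N{order}",
        condition_number=cond,
        max_residual=resid,
    )
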