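"""Tangent-line calibration: tip radius and modulus from one force curve.

The tangent to the force-indentation curve at maximum depth,
F = S h + b, has two informative intercepts:

* the indentation-axis intercept hcom = -b/S depends only on the ratio
  hmax/R — never on the Young's modulus — so it determines the tip radius;
* the force-axis intercept b is proportional to the reduced modulus E*, so
  once R is known, E follows in closed form.

In the Hertzian small-depth limit hcom/hmax -> 1/3 exactly, independent of R:
shallow curves carry no radius information and are flagged degenerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .coefficients import BUILTIN_SETS, CoefficientSet, COEFFS_N6, DomainError

__all__ = [
    "TangentLine",
    "CalibrationResult",
    "DegenerateCurveError",
    "hcom_over_hmax",
    "b_dimensionless",
    "tangent_from_polyfit",
    "solve_radius",
    "solve_modulus",
    "naive_coefficient_recovery",
    "fit_inverse_quartic",
    "QuarticInverseMap",
    "build_lookup_table",
]

#: hcom/hmax within this distance of the Hertzian 1/3 limit is treated as
#: carrying no radius information.  Chosen against the lookup-table
#: granularity (~0.0005 of hcom/hmax per 0.01 of hmax/R at small ratios).
DEFAULT_DEGENERACY_TOL = 0.005


class DegenerateCurveError(ValueError):
    """Curve is in the Hertz regime: hcom ~= hmax/3, radius unidentifiable."""


@dataclass(frozen=True)
class TangentLine:
    """Tangent to the force curve at h = hmax: F = S h + b.

    Attributes
    ----------
    S : float
        Contact stiffness dF/dh at hmax, N/m.
    b_intercept : float
        Force-axis intercept b = Fmax - S hmax, N (negative for physical
        spherical-contact curves).
    hmax, Fmax : float
        Maximum indentation depth (m) and force there (N).
    """

    S: float
    b_intercept: float
    hmax: float
    Fmax: float

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("contact stiffness must be positive")
        if self.hmax <= 0:
            raise ValueError("hmax must be positive")
        resid = abs(self.Fmax - (self.S * self.hmax + self.b_intercept))
        if resid > 1e-9 * max(abs(self.Fmax), self.S * self.hmax):
            raise ValueError("inconsistent tangent: Fmax != S*hmax + b")

    @property
    def hcom(self) -> float:
        """Indentation-axis intercept -b/S, m."""
        return -self.b_intercept / self.S


@dataclass
class CalibrationResult:
    """Outcome of a tangent-line calibration."""

    R: float
    E: float
    ratio: float  # hmax / R
    hcom_ratio: float  # hcom / hmax
    coeff_set: str
    degenerate: bool = False
    S: float = float("nan")
    b: float = float("nan")
    hcom: float = float("nan")
    hmax: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, **extra) -> str:
        """Serialize per the calibration-report schema."""
        payload = {
            "R_m": self.R,
            "E_Pa": self.E,
            "S_N_per_m": self.S,
            "b_N": self.b,
            "hcom_m": self.hcom,
            "hmax_over_R": self.ratio,
            "coeff_set": self.coeff_set,
            "degenerate": self.degenerate,
        }
        payload.update(extra)
        return json.dumps(payload, indent=2, allow_nan=True)


def _numerator_terms(ratio, coeffs: CoefficientSet):
    """Sum_k w_k c_k ratio^p_k with w = (1/3, 1/2, 2/3, ..., (N-1)/N)
    and powers (3/2, 2, 3, ..., N): equals -b / (2 E* R^2)."""
    x = np.asarray(ratio, dtype=float)
    total = (1.0 / 3.0) * coeffs.c[0] * x**1.5
    for k, ck in enumerate(coeffs.c[1:], start=2):
        total = total + ((k - 1.0) / k) * ck * x**k
    return total


def hcom_over_hmax(ratio, coeffs: CoefficientSet = COEFFS_N6):
    """hcom/hmax as a function of the depth ratio hmax/R.

    Strictly decreasing; -> 1/3 as ratio -> 0 (Hertz limit) and ~0.1 at
    ratio 5 (where hcom/R approaches its limiting value 0.5).
    """
    x = np.asarray(ratio, dtype=float)
    if np.any(x <= 0):
        raise DomainError("hmax/R must be positive")
    coeffs.check_ratio(x)
    out = _numerator_terms(x, coeffs) / (x * coeffs.contact_radius_ratio(x))
    return float(out) if np.ndim(out) == 0 else out


def b_dimensionless(ratio, coeffs: CoefficientSet = COEFFS_N6):
    """Force-axis intercept normalized as b / (2 E* R^2).

    Negative for all physical ratios; tends to -0.5 at large hmax/R.
    """
    x = np.asarray(ratio, dtype=float)
    if np.any(x <= 0):
        raise DomainError("hmax/R must be positive")
    coeffs.check_ratio(x)
    out = -_numerator_terms(x, coeffs)
    return float(out) if np.ndim(out) == 0 else out


def tangent_from_polyfit(fit, hmax: float) -> TangentLine:
    """Tangent line at hmax of the fitted cubic-in-sqrt force law.

    ``fit`` provides coefficients (a, b, c) of F = a h^(3/2) + b h^2 + c h^3;
    S and Fmax follow analytically.
    """
    a, b, c = fit.a, fit.b, fit.c
    Fmax = a * hmax**1.5 + b * hmax**2 + c * hmax**3
    S = 1.5 * a * np.sqrt(hmax) + 2.0 * b * hmax + 3.0 * c * hmax**2
    if S <= 0:
        raise ValueError("non-positive contact stiffness at hmax: invalid curve")
    return TangentLine(S=float(S), b_intercept=float(Fmax - S * hmax),
                       hmax=float(hmax), Fmax=float(Fmax))


def solve_radius(
    hcom: float,
    hmax: float,
    coeffs: CoefficientSet = COEFFS_N6,
    degeneracy_tol: float = DEFAULT_DEGENERACY_TOL,
) -> float:
    """Tip radius from the tangent line's indentation-axis intercept.

    Solves hcom_over_hmax(hmax/R) = hcom/hmax for the depth ratio by
    bracketed root search (the mapping is strictly decreasing) and returns
    R = hmax / ratio.  The mapping contains no modulus, so the result is
    independent of E.

    Raises
    ------
    DegenerateCurveError
        If hcom/hmax is within ``degeneracy_tol`` of the Hertzian limit 1/3
        (or above it): the curve is too shallow to encode R.
    DomainError
        If hcom/hmax is below the value reachable within the coefficient
        set's domain (the indentation is deeper than the set supports).
    """
    if not 0 < hcom < hmax:
        raise ValueError("hcom must lie strictly between 0 and hmax")
    target = hcom / hmax
    if target >= 1.0 / 3.0 - degeneracy_tol:
        raise DegenerateCurveError(
            f"hcom/hmax = {target:.4f} is within {degeneracy_tol} of the "
            "Hertzian limit 1/3: the curve is too shallow relative to the tip "
            "radius for R to be identifiable"
        )
    lo = 1e-4
    floor = hcom_over_hmax(coeffs.domain_max, coeffs)
    if target < floor:
        raise DomainError(
            f"hcom/hmax = {target:.4f} is below {floor:.4f}, the value at the "
            f"domain limit of coefficient set {coeffs.name!r}; re-run with the "
            "six-term set (domain_max 4.9512)"
        )
    ratio = brentq(
        lambda x: hcom_over_hmax(x, coeffs) - target,
        lo,
        coeffs.domain_max,
        xtol=1e-14,
        rtol=1e-12,
    )
    return hmax / ratio


def solve_modulus(
    tangent: TangentLine,
    R: float,
    v: float = 0.5,
    coeffs: CoefficientSet = COEFFS_N6,
) -> float:
    """Young's modulus from the tangent's force-axis intercept.

    Inverts b = -2 E* [ (1/3) c1 R^(1/2) hmax^(3/2) + (1/2) c2 hmax^2 +
    (2/3) c3 R^(-1) hmax^3 + ... ]:  E = -b (1 - v^2) / (2 B).
    """
    if R <= 0:
        raise ValueError("tip radius must be positive")
    hmax = tangent.hmax
    coeffs.check_ratio(hmax / R)
    bracket = R**2 * _numerator_terms(hmax / R, coeffs)
    if bracket <= 0:
        raise ValueError("non-positive intercept bracket: outside model domain")
    E = -tangent.b_intercept * (1.0 - v**2) / (2.0 * bracket)
    if E < 0:
        raise ValueError("negative modulus: tangent intercept has the wrong sign")
    return float(E)


def naive_coefficient_recovery(fit, v: float, coeffs: CoefficientSet):
    """(E, R) read directly off the cubic-fit coefficients — the pitfall.

    For data exactly on the three-term model, a = 4 c1 E R^(1/2)/(3(1-v^2)),
    b = c2 E/(1-v^2) and c = 2 c3 E/(3 R (1-v^2)), so E and R seem to follow
    from (a, b) alone.  On real (noisy) curves many (a, b, c) triples produce
    near-identical curves, making this mapping wildly unstable; it exists
    here to document the failure mode, not for use.

    Returns
    -------
    (E, R) : tuple of float
        Modulus from the h^2 coefficient, radius from the h^(3/2) one.
    """
    E = fit.b * (1.0 - v**2) / coeffs.c[1]
    R = (3.0 * fit.a * (1.0 - v**2) / (4.0 * coeffs.c[0] * E)) ** 2
    return float(E), float(R)


@dataclass(frozen=True)
class QuarticInverseMap:
    """Quartic polynomial approximation of hmax/R as a function of hcom/hmax."""

    p: tuple[float, float, float, float, float]  # p4..p0, numpy polyval order
    r_squared: float
    domain: tuple[float, float]

    def __call__(self, hcom_ratio):
        return np.polyval(self.p, hcom_ratio)


def fit_inverse_quartic(
    domain_max: float,
    coeffs: CoefficientSet = COEFFS_N6,
    step: float = 0.01,
) -> QuarticInverseMap:
    """Least-squares quartic of hmax/R against hcom/hmax on a uniform grid.

    A convenience inverse of :func:`hcom_over_hmax`, regenerated from the
    exact relation rather than stored: rounded printed coefficients of such
    quartics suffer catastrophic cancellation near the Hertz limit.
    """
    if domain_max > coeffs.domain_max:
        raise DomainError(
            f"requested domain {domain_max} exceeds coefficient set domain "
            f"{coeffs.domain_max}"
        )
    n = int(round(domain_max / step))
    ratios = step * np.arange(1, n + 1)
    ratios = ratios[ratios <= domain_max + 1e-12]
    t = hcom_over_hmax(ratios, coeffs)
    p = np.polyfit(t, ratios, 4)
    pred = np.polyval(p, t)
    ss_res = float(np.sum((ratios - pred) ** 2))
    ss_tot = float(np.sum((ratios - ratios.mean()) ** 2))
    return QuarticInverseMap(
        p=tuple(float(v) for v in p),
        r_squared=1.0 - ss_res / ss_tot,
        domain=(float(ratios[0]), float(ratios[-1])),
    )


def build_lookup_table(
    ratio_min: float,
    ratio_max: float,
    step: float,
    coeffs: CoefficientSet = COEFFS_N6,
    decimals: int = 4,
) -> pd.DataFrame:
    """Tabulate (hmax/R, hcom/hmax) on a uniform grid, rounded half-even.

    The second column is strictly decreasing; interpolating in it inverts
    the relation graphically, as practitioners do at the bench.
    """
    if not 0 < ratio_min <= ratio_max:
        raise ValueError("need 0 < ratio_min <= ratio_max")
    if step <= 0 or step > ratio_max - ratio_min + 1e-15:
        raise ValueError("step must be positive and no larger than the range")
    n = int(round((ratio_max - ratio_min) / step))
    ratios = np.round(ratio_min + step * np.arange(n + 1), 12)
    values = hcom_over_hmax(ratios, coeffs)
    return pd.DataFrame(
        {
            "hmax_over_R": ratios,
            "hcom_over_hmax": np.round(values, decimals),
        }
    )
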