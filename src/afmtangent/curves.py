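"""Force-curve processing: contact point, force conversion, model fitting.

Takes a raw approach curve (piezo displacement z, cantilever deflection d)
or an already-converted force-indentation curve through to the quantities
the tangent-line calibration needs: the cubic-in-sqrt fit
F = a h^(3/2) + b h^2 + c h^3 and the derived tangent at hmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coefficients import CoefficientSet
from .contact import ContactParameters, polynomial_force

__all__ = [
    "RawCurve",
    "ForceCurve",
    "PolyFit",
    "ContactPoint",
    "find_contact_point",
    "to_force_indentation",
    "fit_force_curve",
    "fit_hertz_modulus",
    "calibrate_curve",
]


@dataclass(frozen=True)
class RawCurve:
    """Approach segment of a raw AFM curve.

    z : piezo displacement toward the sample, m (increasing).
    d : cantilever deflection, m.
    k : cantilever spring constant, N/m.
    """

    z: np.ndarray
    d: np.ndarray
    k: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        if self.z.shape != self.d.shape or self.z.ndim != 1:
            raise ValueError("z and d must be 1-D arrays of equal length")
        if len(self.z) < 20:
            raise ValueError("raw curve needs at least 20 samples")
        if self.k <= 0:
            raise ValueError("spring constant must be positive")


@dataclass(frozen=True)
class ForceCurve:
    """Post-contact force-indentation samples, h ascending from ~0."""

    h: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        if self.h.shape != self.F.shape or self.h.ndim != 1:
            raise ValueError("h and F must be 1-D arrays of equal length")
        if np.any(np.diff(self.h) < 0):
            raise ValueError(
                "indentation depth must be sorted ascending; extract the "
                "approach segment before constructing a ForceCurve"
            )
        if np.any(self.h < 0):
            raise ValueError("indentation depth must be non-negative")

    @property
    def hmax(self) -> float:
        return float(self.h[-1])

    @property
    def Fmax(self) -> float:
        return float(self.F[-1])


@dataclass(frozen=True)
class PolyFit:
    """Least-squares coefficients of F = a h^(3/2) + b h^2 + c h^3.

    For physical spherical-contact curves a > 0, b < 0, c < 0; violations are
    reported through ``signs_ok``, never enforced by constrained fitting.
    """

    a: float
    b: float
    c: float
    r_squared: float
    residual_norm: float

    @property
    def signs_ok(self) -> bool:
        return self.a > 0 and self.b < 0 and self.c < 0

    def predict(self, h):
        h = np.asarray(h, dtype=float)
        return self.a * h**1.5 + self.b * h**2 + self.c * h**3


@dataclass(frozen=True)
class ContactPoint:
    """Trial-scan contact point: sample index plus (z, d) offsets there."""

    index: int
    z_contact: float
    d_contact: float
    total_ss: float


def find_contact_point(
    raw: RawCurve, precontact_degree: int = 1
) -> ContactPoint:
    """Locate the tip-sample contact point by exhaustive trial scanning.

    Every admissible sample index is taken as a trial contact point: a
    polynomial of ``precontact_degree`` is fitted to the pre-contact
    deflection and the spherical-contact basis {h^(3/2), h^2, h^3} to the
    post-contact force-indentation data.  The index minimizing the combined
    sum of squared residuals wins.  Curves longer than 5000 points are
    scanned with stride 2.

    Raises
    ------
    ValueError
        If no trial index leaves enough points on both sides.
    """
    if not 0 <= precontact_degree <= 3:
        raise ValueError("precontact_degree must be in 0..3")
    z, d, k = raw.z, raw.d, raw.k
    n = len(z)
    stride = 2 if n > 5000 else 1
    min_pre = precontact_degree + 2
    min_post = 5  # 3 basis functions + slack

    best: ContactPoint | None = None
    for i in range(min_pre, n - min_post, stride):
        baseline = np.polyfit(z[:i], d[:i], precontact_degree)
        r_pre = k * (d[:i] - np.polyval(baseline, z[:i]))
        ss_pre = float(r_pre @ r_pre)
        # anchor the contact offset at the baseline fit, not the noisy
        # single sample, and convert the trailing segment relative to it
        d0 = float(np.polyval(baseline, z[i]))
        dz = z[i:] - z[i]
        dd = d[i:] - d0
        h = dz - dd
        F = k * dd
        ok = h > 0
        if ok.sum() < min_post:
            continue
        design = np.column_stack([h[ok] ** 1.5, h[ok] ** 2, h[ok] ** 3])
        norms = np.linalg.norm(design, axis=0)
        coef, _, _, _ = np.linalg.lstsq(design / norms, F[ok], rcond=None)
        r = F[ok] - (design / norms) @ coef
        # points at non-positive depth see zero model force
        total = ss_pre + float(r @ r) + float(F[~ok] @ F[~ok])
        if best is None or total < best.total_ss:
            best = ContactPoint(
                index=i, z_contact=float(z[i]), d_contact=d0, total_ss=total,
            )
    if best is None:
        raise ValueError("no admissible trial contact point; curve too short")
    return best


def to_force_indentation(raw: RawCurve, contact: ContactPoint) -> ForceCurve:
    """Convert the post-contact raw segment to force vs indentation.

    F = k (d - d_contact);  h = (z - z_contact) - (d - d_contact).
    """
    i = contact.index
    dz = raw.z[i:] - contact.z_contact
    dd = raw.d[i:] - contact.d_contact
    h = dz - dd
    F = raw.k * dd
    keep = h >= 0
    h, F = h[keep], F[keep]
    if h.size < 2:
        raise ValueError("no post-contact samples at positive depth")
    # genuine depth reversal (retract segment) vs noise jitter: flag when the
    # depth falls more than 5% of its range below its running maximum
    drawdown = np.max(np.maximum.accumulate(h) - h)
    if drawdown > 0.05 * (h.max() - h.min()):
        raise ValueError(
            "indentation depth reverses after conversion; supply the "
            "approach segment only (retract data must be removed first)"
        )
    order = np.argsort(h, kind="stable")
    return ForceCurve(h=h[order], F=F[order])


def fit_force_curve(curve: ForceCurve) -> PolyFit:
    """Linear least squares of F on the basis {h^(3/2), h^2, h^3}.

    The force law is linear in (a, b, c), so an ordinary unweighted,
    unconstrained solve reproduces bench practice exactly.  Sign violations
    of the physical expectation (a > 0, b < 0, c < 0) are reported via
    ``PolyFit.signs_ok``.
    """
    h, F = curve.h, curve.F
    if len(h) < 10:
        raise ValueError("need at least 10 post-contact points to fit")
    design = np.column_stack([h**1.5, h**2, h**3])
    # basis columns span many orders of magnitude at nanometer depths;
    # normalize columns so the rank test and solve are scale-free
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0) or np.linalg.matrix_rank(design / norms) < 3:
        raise ValueError("singular design matrix: indentation values degenerate")
    coef, _, _, _ = np.linalg.lstsq(design / norms, F, rcond=None)
    coef = coef / norms
    pred = design @ coef
    ss_res = float(np.sum((F - pred) ** 2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PolyFit(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        r_squared=r2, residual_norm=float(np.sqrt(ss_res)),
    )


def fit_hertz_modulus(curve: ForceCurve, R: float, v: float = 0.5) -> float:
    """Least-squares Young's modulus under the Hertz law at known R.

    The conventional comparator: F = (4/3) E/(1-v^2) R^(1/2) h^(3/2) is
    linear in E, so the solution is a single projection.
    """
    if R <= 0:
        raise ValueError("tip radius must be positive")
    basis = (4.0 / 3.0) / (1.0 - v**2) * np.sqrt(R) * curve.h**1.5
    denom = float(basis @ basis)
    if denom == 0:
        raise ValueError("degenerate curve: all depths zero")
    return float(basis @ curve.F / denom)


def calibrate_curve(curve: ForceCurve, v: float = 0.5, **options):
    """End-to-end tangent-line calibration of one force curve.

    Thin wrapper over :class:`afmtangent.estimator.TangentCalibrator`; see
    that class for the options.  Returns a
    :class:`~afmtangent.tangent.CalibrationResult`.
    """
    from .estimator import TangentCalibrator

    cal = TangentCalibrator(poisson_ratio=v, **options)
    cal.fit(curve.h.reshape(-1, 1), curve.F)
    return cal.result_
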