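"""scikit-learn style estimator for tangent-line tip calibration."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .coefficients import BUILTIN_SETS, COEFFS_N3, COEFFS_N6, CoefficientSet
from .curves import ForceCurve, PolyFit, fit_force_curve
from .tangent import (
    DEFAULT_DEGENERACY_TOL,
    CalibrationResult,
    DegenerateCurveError,
    hcom_over_hmax,
    solve_modulus,
    solve_radius,
    tangent_from_polyfit,
)

__all__ = ["TangentCalibrator"]


class TangentCalibrator(RegressorMixin, BaseEstimator):
    """Simultaneous tip-radius and Young's-modulus estimation from one curve.

    Fits the spherical-contact force law F = a h^(3/2) + b h^2 + c h^3 to the
    post-contact samples, takes the tangent line at the maximum depth, and
    inverts its two intercepts: the indentation-axis intercept hcom = -b/S
    yields the tip radius R (independently of the modulus), and the
    force-axis intercept then yields E.

    Parameters
    ----------
    poisson_ratio : float, default=0.5
        Sample Poisson ratio; 0.5 for incompressible, water-rich materials.
    coefficients : {"auto", "N3", "N6"} or CoefficientSet, default="auto"
        Expansion constants used for the inversion. "auto" solves with the
        wide six-term set first and, when the recovered depth ratio lies in
        the three-term set's domain (<= 1.32), re-solves and reports with
        the simpler set — the one practitioners use at the bench.
    degeneracy_tol : float, default=0.005
        Half-width around hcom/hmax = 1/3 flagged as the Hertz regime,
        where R is unidentifiable.

    Attributes
    ----------
    polyfit_ : PolyFit
        Least-squares coefficients (a, b, c) with fit diagnostics.
    tangent_ : TangentLine
        Tangent at hmax: stiffness S, intercept b, hcom.
    tip_radius_ : float
        Recovered tip radius, m (NaN when degenerate).
    youngs_modulus_ : float
        Recovered Young's modulus, Pa (NaN when degenerate).
    depth_ratio_ : float
        Recovered hmax/R (NaN when degenerate).
    degenerate_ : bool
        True when hcom/hmax is indistinguishable from the Hertzian 1/3.
    result_ : CalibrationResult
        Full structured result including diagnostics.

    Examples
    --------
    >>> import numpy as np
    >>> from afmtangent.simulate import SimulationSpec, generate_curve
    >>> curve, truth = generate_curve(SimulationSpec(noise_sd_fraction=0.0))
    >>> cal = TangentCalibrator().fit(curve.h.reshape(-1, 1), curve.F)
    >>> bool(abs(cal.tip_radius_ - truth["R"]) / truth["R"] < 1e-3)
    True
    """

    def __init__(
        self,
        poisson_ratio: float = 0.5,
        coefficients="auto",
        degeneracy_tol: float = DEFAULT_DEGENERACY_TOL,
    ):
        self.poisson_ratio = poisson_ratio
        self.coefficients = coefficients
        self.degeneracy_tol = degeneracy_tol

    def _resolve_coeffs(self) -> tuple[CoefficientSet, bool]:
        """Return (initial set, auto flag)."""
        if isinstance(self.coefficients, CoefficientSet):
            return self.coefficients, False
        if self.coefficients == "auto":
            return COEFFS_N6, True
        try:
            return BUILTIN_SETS[self.coefficients], False
        except KeyError:
            raise ValueError(
                f"unknown coefficient set {self.coefficients!r}; expected "
                "'auto', 'N3', 'N6' or a CoefficientSet"
            ) from None

    def fit(self, X, y):
        """Calibrate from indentation depths X (n, 1) and forces y (n,), SI.

        Degenerate (Hertz-regime) curves do not raise: ``degenerate_`` is set
        and the radius/modulus attributes are NaN.
        """
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.degeneracy_tol <= 0:
            raise ValueError("degeneracy_tol must be positive")
        X, y = check_X_y(X, y, ensure_min_samples=10)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of indentation depths")
        self.n_features_in_ = 1
        h = X[:, 0]
        order = np.argsort(h, kind="stable")
        curve = ForceCurve(h=h[order], F=y[order])

        self.polyfit_ = fit_force_curve(curve)
        self.tangent_ = tangent_from_polyfit(self.polyfit_, curve.hmax)
        coeffs, auto = self._resolve_coeffs()

        hcom = self.tangent_.hcom
        diagnostics = {
            "fit_r_squared": self.polyfit_.r_squared,
            "fit_signs_ok": self.polyfit_.signs_ok,
        }
        try:
            R = solve_radius(hcom, curve.hmax, coeffs, self.degeneracy_tol)
            if auto and curve.hmax / R <= COEFFS_N3.domain_max:
                coeffs = COEFFS_N3
                R = solve_radius(hcom, curve.hmax, coeffs, self.degeneracy_tol)
            E = solve_modulus(self.tangent_, R, self.poisson_ratio, coeffs)
            ratio = curve.hmax / R
            degenerate = False
        except DegenerateCurveError as exc:
            R = E = ratio = float("nan")
            degenerate = True
            diagnostics["degeneracy_reason"] = str(exc)

        self.tip_radius_ = R
        self.youngs_modulus_ = E
        self.depth_ratio_ = ratio
        self.hcom_ratio_ = hcom / curve.hmax
        self.degenerate_ = degenerate
        self.coefficients_ = coeffs
        if not degenerate:
            diagnostics["radius_equation_residual"] = float(
                self.hcom_ratio_ - hcom_over_hmax(ratio, coeffs)
            )
        self.result_ = CalibrationResult(
            R=R,
            E=E,
            ratio=ratio,
            hcom_ratio=self.hcom_ratio_,
            coeff_set=coeffs.name,
            degenerate=degenerate,
            S=self.tangent_.S,
            b=self.tangent_.b_intercept,
            hcom=hcom,
            hmax=curve.hmax,
            diagnostics=diagnostics,
        )
        return self

    def predict(self, X):
        """Model force at the given indentation depths (fitted cubic law)."""
        check_is_fitted(self, "polyfit_")
        X = check_array(X)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of indentation depths")
        return self.polyfit_.predict(X[:, 0])
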