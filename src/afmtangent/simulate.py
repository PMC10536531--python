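"""Synthetic force curves with known ground truth.

Every pipeline stage is testable without instrument data: curves are drawn
from one of the forward contact models (exact parametric, polynomial
three/six-term, or Hertz), optionally with additive Gaussian force noise and
a pre-contact baseline, so recovered parameters can be compared against the
generating truth.

Default conditions mirror a typical soft-gel experiment with a borosilicate
microsphere probe: E = 132.5 kPa, v = 0.5 (high water content), R = 0.921 um,
hmax = 432 nm — a depth ratio hmax/R of about 0.47, comfortably inside the
three-term model domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coefficients import COEFFS_N3, COEFFS_N6
from .contact import ContactParameters, hertz_force, polynomial_force, sneddon_force
from .curves import ForceCurve, RawCurve

__all__ = [
    "SimulationSpec",
    "generate_curve",
    "generate_raw_curve",
    "generate_batch",
]

_MODELS = ("sneddon", "polynomial-N3", "polynomial-N6", "hertz")


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of one synthetic indentation experiment.

    noise_sd_fraction is the force-noise standard deviation as a fraction of
    the maximum force (photodiode noise dominates real curves, so noise is
    additive on force only).  baseline_tilt is the deflection drift per meter
    of piezo travel before contact, expressed as force (N per m of z).
    """

    E: float = 132.5e3
    v: float = 0.5
    R: float = 0.921e-6
    hmax: float = 4.32e-7
    n_points: int = 200
    noise_sd_fraction: float = 0.0
    baseline_points: int = 200
    baseline_tilt: float = 0.0
    seed: int | None = None
    model: str = "polynomial-N3"

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.n_points < 20:
            raise ValueError("n_points must be at least 20")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be non-negative")
        if self.noise_sd_fraction > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise is requested")
        ratio = self.hmax / self.R
        bound = self._domain_bound()
        if bound is not None and ratio > bound:
            raise ValueError(
                f"hmax/R = {ratio:.4g} exceeds the {self.model} model bound "
                f"{bound}"
            )

    def _domain_bound(self) -> float | None:
        if self.model == "polynomial-N3":
            return COEFFS_N3.domain_max
        if self.model == "polynomial-N6":
            return COEFFS_N6.domain_max
        return None  # sneddon and hertz are unbounded in h/R

    def contact_parameters(self) -> ContactParameters:
        return ContactParameters(E=self.E, v=self.v, R=self.R)

    def force(self, h):
        """Noiseless model force at depth h."""
        params = self.contact_parameters()
        if self.model == "sneddon":
            return sneddon_force(h, params)
        if self.model == "polynomial-N3":
            return polynomial_force(h, params, COEFFS_N3)
        if self.model == "polynomial-N6":
            return polynomial_force(h, params, COEFFS_N6)
        return hertz_force(h, params)


def generate_curve(spec: SimulationSpec) -> tuple[ForceCurve, dict]:
    """One force-indentation curve plus its ground-truth record.

    Depths are uniform on [0, hmax]; Gaussian force noise with standard
    deviation ``noise_sd_fraction * Fmax`` is added when requested.
    Deterministic under a fixed seed.
    """
    h = np.linspace(0.0, spec.hmax, spec.n_points)
    F = np.asarray(spec.force(h), dtype=float)
    if spec.noise_sd_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        F = F + rng.normal(0.0, spec.noise_sd_fraction * F[-1], size=F.shape)
    truth = {
        "E": spec.E,
        "v": spec.v,
        "R": spec.R,
        "hmax": spec.hmax,
        "ratio": spec.hmax / spec.R,
        "model": spec.model,
        "seed": spec.seed,
    }
    return ForceCurve(h=h, F=F), truth


def generate_raw_curve(spec: SimulationSpec, k: float) -> tuple[RawCurve, dict]:
    """Raw piezo/deflection curve with a pre-contact baseline.

    Post-contact kinematics: the piezo travel splits into indentation and
    cantilever bending, z = h + d with d = F/k.  The baseline covers one
    hmax of travel before contact (deflection zero plus optional tilt and
    the same noise level as the force signal).  The true contact index is
    returned in the ground-truth record.
    """
    if k <= 0:
        raise ValueError("spring constant must be positive")
    curve, truth = generate_curve(spec)
    d_post = curve.F / k
    z_post = curve.h + d_post

    nb = spec.baseline_points
    if nb > 0:
        z_pre = np.linspace(-spec.hmax, 0.0, nb, endpoint=False)
        d_pre = (spec.baseline_tilt / k) * z_pre
        if spec.noise_sd_fraction > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), 1]).generate_state(1)[0]
            )
            d_pre = d_pre + rng.normal(
                0.0, spec.noise_sd_fraction * curve.Fmax / k, size=nb
            )
        z = np.concatenate([z_pre, z_post])
        d = np.concatenate([d_pre, d_post])
    else:
        z, d = z_post, d_post
    truth = dict(truth, contact_index=nb, k=k)
    return RawCurve(z=z, d=d, k=k), truth


def generate_batch(
    n: int,
    spec: SimulationSpec = SimulationSpec(),
    seed: int = 0,
    E_range: tuple[float, float] = (102e3, 174e3),
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """A batch of curves with per-curve moduli and a truth table.

    Moduli are drawn uniformly from ``E_range`` (default spans the spread
    observed on a 2.5% agarose gel); the tip radius is held fixed, as in a
    real session where one probe indents many points.  Child seeds are
    spawned deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    curves: list[ForceCurve] = []
    rows = []
    for i in range(n):
        E_i = float(rng.uniform(*E_range))
        spec_i = replace(spec, E=E_i, seed=int(child_seeds[i]))
        curve, truth = generate_curve(spec_i)
        curves.append(curve)
        rows.append(dict(truth, curve_id=i))
    return curves, pd.DataFrame(rows).set_index("curve_id")
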