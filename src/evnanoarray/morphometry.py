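"""Per-vesicle computations: aspect ratio, suspension diameter,
classification, the AR ~ c*d^-3 law, and array occupancy.

An adsorbed vesicle's deformation is quantified by the aspect ratio

    AR = h / d,

with ``d`` the footprint diameter (mean of the equivalent-ellipse major
and minor axis lengths) and ``h`` the apex height. Treating the adsorbed
shape as an oblate ellipsoid of the same volume as the original sphere,
the suspension diameter follows from

    pi/6 * D^3 = pi/6 * d^2 * h      =>      D = (d^2 * h)^(1/3),

which also explains why, at roughly constant D within a population, the
aspect ratio falls off as AR = D^3 * d^-3: larger-footprint vesicles are
flatter. The coefficient of that power law is fitted by least squares
through the origin in the variable x = d^-3.

Classification uses the morphological acceptance rules: a particle is an
EV when both its diameter and height strictly exceed 30 nm and 7 nm
(the height floor being a few bilayer thicknesses); small co-purifying
lipoprotein-like particles are identified by d < 20 nm together with an
aspect ratio in [0.3, 0.6]; everything else is left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Particle

__all__ = [
    "ClassThresholds",
    "FitResult",
    "aspect_ratio",
    "estimate_suspension_diameter",
    "classify_particle",
    "classify_particles",
    "fit_ar_model",
    "occupancy_fraction",
]


@dataclass(frozen=True)
class ClassThresholds:
    """Morphological class boundaries (nm / dimensionless)."""

    ev_min_d_nm: float = 30.0
    ev_min_h_nm: float = 7.0
    ldl_max_d_nm: float = 20.0
    ldl_ar_low: float = 0.3
    ldl_ar_high: float = 0.6

    def __post_init__(self) -> None:
        if min(self.ev_min_d_nm, self.ev_min_h_nm, self.ldl_max_d_nm,
               self.ldl_ar_low, self.ldl_ar_high) <= 0:
            raise ValueError("thresholds must be positive")
        if self.ldl_ar_low >= self.ldl_ar_high:
            raise ValueError("ldl_ar_low must be below ldl_ar_high")


@dataclass(frozen=True)
class FitResult:
    """Least-squares coefficient of AR = c * d^-3 (c in nm^3)."""

    c: float
    n_points: int
    rms_residual: float

    def predict(self, d_nm: np.ndarray) -> np.ndarray:
        return self.c * np.asarray(d_nm, dtype=float) ** -3


def aspect_ratio(d_nm: float, h_nm: float) -> float:
    """AR = h/d; requires d > 0."""
    if not (d_nm > 0):
        raise ValueError(f"footprint diameter must be > 0, got {d_nm}")
    return h_nm / d_nm


def estimate_suspension_diameter(d_nm: float, h_nm: float) -> float:
    """Suspension diameter D = (d^2 h)^(1/3) by volume conservation."""
    if not (d_nm > 0 and h_nm > 0):
        raise ValueError("d and h must be > 0")
    return float((d_nm ** 2 * h_nm) ** (1 / 3))


def classify_particle(p: Particle, t: ClassThresholds = ClassThresholds()) -> str:
    """EV if d and h strictly exceed their floors; else lipoprotein-like
    if d < 20 nm with AR in [0.3, 0.6]; else unclassified."""
    if p.d_nm > t.ev_min_d_nm and p.h_nm > t.ev_min_h_nm:
        return "EV"
    if p.d_nm < t.ldl_max_d_nm and t.ldl_ar_low <= p.ar <= t.ldl_ar_high:
        return "LDL_like"
    return "unclassified"


def classify_particles(
    particles: list[Particle], t: ClassThresholds = ClassThresholds()
) -> list[Particle]:
    """Classify in place (also refreshing D from the measured d, h)."""
    for p in particles:
        p.klass = classify_particle(p, t)
        if p.d_nm > 0 and p.h_nm > 0:
            p.ar = aspect_ratio(p.d_nm, p.h_nm)
            p.D_nm = estimate_suspension_diameter(p.d_nm, p.h_nm)
    return particles


def fit_ar_model(particles: list[Particle], through_origin: bool = True) -> FitResult:
    """Fit AR = c * d^-3 by ordinary least squares on x = d^-3.

    Through the origin (the default, matching the power law's lack of an
    intercept) the closed form is c = sum(x*AR) / sum(x^2). With
    ``through_origin=False`` an intercept is allowed as a sensitivity
    check and only the slope is reported as ``c``.
    """
    if not particles:
        raise ValueError("no particles to fit")
    d = np.array([p.d_nm for p in particles], dtype=float)
    ar = np.array([p.ar for p in particles], dtype=float)
    if np.any(d <= 0):
        raise ValueError("fit requires d > 0")
    x = d ** -3
    if through_origin:
        c = float(np.sum(x * ar) / np.sum(x * x))
        resid = ar - c * x
    else:
        slope, intercept = np.polyfit(x, ar, 1)
        c = float(slope)
        resid = ar - (slope * x + intercept)
    return FitResult(c=c, n_points=d.size, rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def occupancy_fraction(occupancy) -> float:
    """Occupied-spot fraction from a per-spot occupancy table
    (DataFrame with an ``occupied`` column, or a boolean array)."""
    occ = np.asarray(occupancy["occupied"] if hasattr(occupancy, "columns") else occupancy,
                     dtype=bool)
    if occ.size == 0:
        raise ValueError("layout has no spots")
    return float(occ.mean())
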