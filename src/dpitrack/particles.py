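"""Formulation records, Rosin-Rammler size distributions, particle quantities.

A powder formulation is described by its laser-diffraction volume quantiles
d_v10 < d_v50 < d_v90 (um), the span (d_v90 - d_v10)/d_v50, and the true
(pycnometric) density.  Powder dispersion is assumed instantaneous with sizes
following a Rosin-Rammler (Weibull) law F(d) = 1 - exp[-(d/delta)^n], the
conventional choice for dispersed sprays and powders; the two parameters are
fitted to the three volume quantiles by least squares on log-quantiles.

Because the quantiles are volume-based, the fitted law is the volume-weighted
size distribution and inverse-CDF samples from it are volume-weighted draws;
downstream summaries can re-weight by number or by particle mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FitError, ValidationError

#: span printed alongside quantiles must agree with the recomputed value
SPAN_CONSISTENCY_TOL = 0.005


def compute_span(d_v10: float, d_v50: float, d_v90: float) -> float:
    """Distribution span (d_v90 - d_v10)/d_v50 from the volume quantiles."""
    _check_quantiles(d_v10, d_v50, d_v90)
    return (d_v90 - d_v10) / d_v50


def _check_quantiles(d_v10: float, d_v50: float, d_v90: float) -> None:
    if not (0.0 < d_v10 < d_v50 < d_v90):
        raise ValidationError(
            f"quantiles must satisfy 0 < d_v10 < d_v50 < d_v90, got "
            f"({d_v10}, {d_v50}, {d_v90})"
        )


@dataclass(frozen=True)
class FormulationRecord:
    """Micromeritic inputs for one powder formulation.

    Diameters in um, density in g/cm^3.  The stored span must agree with the
    value recomputed from the quantiles to within +/-0.005.
    """

    name: str
    d_v10: float
    d_v50: float
    d_v90: float
    span: float
    true_density: float

    def __post_init__(self) -> None:
        _check_quantiles(self.d_v10, self.d_v50, self.d_v90)
        if not self.true_density > 0:
            raise ValidationError(f"true_density must be positive, got {self.true_density}")
        recomputed = compute_span(self.d_v10, self.d_v50, self.d_v90)
        if abs(recomputed - self.span) > SPAN_CONSISTENCY_TOL:
            raise ValidationError(
                f"{self.name}: span {self.span} inconsistent with quantiles "
                f"(recomputed {recomputed:.4f})"
            )

    @property
    def density_kg_m3(self) -> float:
        return self.true_density * 1000.0


@dataclass(frozen=True)
class RosinRammlerParams:
    """Rosin-Rammler law F(d) = 1 - exp[-(d/scale)^spread], truncated.

    ``scale`` (delta) is the 63.2% size in um; ``spread`` (n) is the
    dimensionless shape exponent; samples are restricted to
    [d_min, d_max] um.  ``residual`` is the sum of squared log-quantile
    errors left by the fit.
    """

    scale: float
    spread: float
    d_min: float
    d_max: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.spread > 0):
            raise ValidationError("scale and spread must be positive")
        if not 0.0 < self.d_min < self.d_max:
            raise ValidationError("truncation must satisfy 0 < d_min < d_max")

    def cdf(self, d):
        d = np.asarray(d, dtype=float)
        return 1.0 - np.exp(-((d / self.scale) ** self.spread))

    def quantile(self, q):
        q = np.asarray(q, dtype=float)
        return self.scale * (-np.log1p(-q)) ** (1.0 / self.spread)


def fit_rosin_rammler(
    d_v10: float,
    d_v50: float,
    d_v90: float,
    d_min: float | None = None,
    d_max: float | None = None,
) -> RosinRammlerParams:
    """Fit (scale, spread) to the three volume quantiles.

    The quantile relation ln d(q) = ln(scale) + (1/spread) * ln(-ln(1-q)) is
    linear in the log-quantiles, so the two parameters come from an ordinary
    least-squares line through the three points; the residual is reported.
    For quantiles exactly consistent with a Rosin-Rammler law the fit
    round-trips to machine precision.

    Truncation defaults to [d_v10/2, 1.5*d_v90], the min/max-diameter
    convention of solver-style Rosin-Rammler injections.
    """
    _check_quantiles(d_v10, d_v50, d_v90)
    probs = np.array([0.10, 0.50, 0.90])
    x = np.log(-np.log1p(-probs))
    y = np.log(np.array([d_v10, d_v50, d_v90]))
    design = np.column_stack([np.ones_like(x), x])
    coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2 or not np.all(np.isfinite(coef)):
        raise FitError("degenerate least-squares system for Rosin-Rammler fit")
    intercept, slope = coef
    if slope <= 0:
        raise FitError(f"non-physical fitted spread (slope {slope})")
    residual = float(res[0]) if res.size else 0.0
    return RosinRammlerParams(
        scale=float(np.exp(intercept)),
        spread=float(1.0 / slope),
        d_min=float(d_min if d_min is not None else d_v10 / 2.0),
        d_max=float(d_max if d_max is not None else 1.5 * d_v90),
        residual=residual,
    )


def sample_diameters(params: RosinRammlerParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` diameters (um) by inverse-CDF sampling with truncation.

    Draws outside [d_min, d_max] are rejected and redrawn, so the accepted
    samples follow the truncated law.  ``seed`` may be an int or a
    ``numpy.random.Generator``; identical seeds give identical samples.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValidationError(f"sample count must be a positive integer, got {n!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo = float(params.cdf(params.d_min))
    hi = float(params.cdf(params.d_max))
    if hi - lo < 1e-12:
        raise ValidationError("truncation interval has negligible probability mass")
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = params.quantile(rng.uniform(size=2 * (n - filled)))
        keep = draw[(draw >= params.d_min) & (draw <= params.d_max)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


#: reference density of the aerodynamic-diameter convention, g/cm^3
UNIT_DENSITY = 1.0


def aerodynamic_diameter(d_g, rho_p):
    """Aerodynamic diameter d_ae = d_g * sqrt(rho_p / rho_0), rho_0 = 1 g/cm^3.

    ``d_g`` is the geometric diameter (um) and ``rho_p`` the true density in
    g/cm^3: the diameter of a unit-density sphere with the same settling
    velocity (slip and shape factors taken as unity).
    """
    d_g = np.asarray(d_g, dtype=float)
    if np.any(d_g <= 0) or not np.all(np.isfinite(d_g)):
        raise ValidationError("geometric diameter must be positive and finite")
    if not rho_p > 0:
        raise ValidationError(f"true density must be positive, got {rho_p}")
    result = d_g * math.sqrt(rho_p / UNIT_DENSITY)
    return float(result) if result.ndim == 0 else result


def relaxation_time(d_p: float, rho_p: float, mu: float, c_u: float = 1.0) -> float:
    """Stokes relaxation time tau = rho_p d_p^2 C_u / (18 mu), SI units."""
    if min(d_p, rho_p, mu, c_u) <= 0:
        raise ValidationError("relaxation_time requires positive inputs")
    return rho_p * d_p * d_p * c_u / (18.0 * mu)


IN_FLIGHT = "in_flight"
STUCK = "stuck"
EMITTED = "emitted"
TIMED_OUT = "in_domain_at_timeout"

_STATUSES = frozenset({IN_FLIGHT, STUCK, EMITTED, TIMED_OUT})


@dataclass
class ParticleState:
    """Mutable state of one tracked particle (SI units)."""

    id: int
    position: np.ndarray
    velocity: np.ndarray
    d_p: float  # geometric diameter, m
    rho_p: float  # kg/m^3
    status: str = IN_FLIGHT
    region: str | None = None  # deposition region once stuck

    def __post_init__(self) -> None:
        if self.d_p <= 0:
            raise ValidationError(f"particle diameter must be positive, got {self.d_p}")
        if self.rho_p <= 0:
            raise ValidationError(f"particle density must be positive, got {self.rho_p}")
        if self.status not in _STATUSES:
            raise ValidationError(f"unknown particle status {self.status!r}")
        self.position = np.asarray(self.position, dtype=float).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).copy()

    @property
    def mass(self) -> float:
        """Sphere mass rho_p * pi * d_p^3 / 6 (kg), always consistent with d_p."""
        return self.rho_p * math.pi * self.d_p**3 / 6.0
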