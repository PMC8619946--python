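"""Independent oracles used by the test suite.

These deliberately do not share code with the package: the capture-velocity
oracle composes the published relations in exact rational arithmetic through
sympy and evaluates to 50 significant digits; the Rosin-Rammler oracle is a
brute-force grid search over (scale, spread).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import sympy as sp

# material constants as exact rationals (wall/particle elastic pairing)
_E_S = sp.Integer(41) * 10**8  # 4.1e9 Pa
_E_P = sp.Integer(10) ** 9  # 1e9 Pa
_V_S = sp.Rational(35, 100)
_V_P = sp.Rational(40, 100)


def _to_rational(x) -> sp.Rational:
    return sp.Rational(Fraction(x).limit_denominator(10**12))


def el_batch_oracle(rho_p) -> sp.Expr:
    """Exact symbolic El Batch parameter for the default elastic pairing."""
    rho = _to_rational(rho_p)
    k1 = (1 - _V_S**2) / (sp.pi * _E_S)
    k2 = (1 - _V_P**2) / (sp.pi * _E_P)
    return sp.Rational(51, 100) * (
        5 * sp.pi**2 * (k1 + k2) / (4 * rho ** sp.Rational(3, 2))
    ) ** sp.Rational(2, 5)


def capture_velocity_oracle(d_p_m, rho_p, digits: int = 50) -> float:
    """Capture velocity by arbitrary-precision evaluation (m/s)."""
    d_p = _to_rational(d_p_m)
    expr = (2 * el_batch_oracle(rho_p) / d_p) ** sp.Rational(10, 7)
    return float(expr.evalf(digits))


def rosin_rammler_grid_oracle(quantiles, probs=(0.1, 0.5, 0.9)):
    """Best (scale, spread, residual) by brute-force grid search.

    Minimizes the summed squared log-quantile error over a fine 2-d grid,
    refined once around the coarse optimum.
    """
    quantiles = np.asarray(quantiles, dtype=float)
    probs = np.asarray(probs, dtype=float)
    target = np.log(quantiles)

    def residual(scale, spread):
        pred = np.log(scale) + np.log(-np.log1p(-probs)) / spread
        return float(((pred - target) ** 2).sum())

    scales = np.linspace(quantiles[0], quantiles[-1], 400)
    spreads = np.linspace(0.3, 8.0, 400)
    best = min(
        ((residual(sc, sp_), sc, sp_) for sc in scales for sp_ in spreads),
        key=lambda t: t[0],
    )
    # one refinement pass around the coarse optimum
    _, sc0, sp0 = best
    scales = np.linspace(sc0 * 0.95, sc0 * 1.05, 200)
    spreads = np.linspace(sp0 * 0.95, sp0 * 1.05, 200)
    best = min(
        ((residual(sc, sp_), sc, sp_) for sc in scales for sp_ in spreads),
        key=lambda t: t[0],
    )
    return best[1], best[2], best[0]
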