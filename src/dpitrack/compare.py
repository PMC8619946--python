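"""Cross-method agreement statistics: R^2, RMSE, NRMSE.

Used to compare paired outputs of two measurement/simulation methods over a
set of formulations:

    RMSE  = sqrt( sum_i (P_i - O_i)^2 / N )
    NRMSE = RMSE / mean(O)           (O is the reference method)
    R^2   = squared Pearson correlation of the plotted (P, O) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement panel between a test and a reference value sequence."""

    r_squared: float
    rmse: float
    nrmse: float
    n: int
    test_label: str = "test"
    reference_label: str = "reference"

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.nrmse < 0:
            raise ValidationError("RMSE and NRMSE cannot be negative")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError(f"R^2 must lie in [0, 1], got {self.r_squared}")


def _paired(p, o, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    o = np.asarray(o, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValidationError(
            f"sequences must be 1-d and equal length, got shapes {p.shape} and {o.shape}"
        )
    if p.size < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {p.size}")
    return p, o


def rmse(p, o) -> float:
    """Root mean square error between predicted and observed sequences."""
    p, o = _paired(p, o)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def nrmse(p, o) -> float:
    """RMSE normalized by the mean of the observed (reference) sequence."""
    p, o = _paired(p, o)
    o_mean = float(np.mean(o))
    if o_mean == 0.0:
        raise ValidationError("reference mean is zero; NRMSE undefined")
    return rmse(p, o) / o_mean


def r_squared(p, o) -> float:
    """Squared Pearson correlation between the paired sequences."""
    p, o = _paired(p, o, min_n=2)
    if np.ptp(p) == 0.0 or np.ptp(o) == 0.0:
        raise ValidationError("correlation undefined for a constant sequence")
    r = stats.pearsonr(p, o).statistic
    return float(r * r)


def compare_methods(
    p,
    o,
    test_label: str = "test",
    reference_label: str = "reference",
) -> ComparisonResult:
    """Full agreement panel for a pair of method outputs."""
    p, o = _paired(p, o, min_n=2)
    return ComparisonResult(
        r_squared=min(r_squared(p, o), 1.0),
        rmse=rmse(p, o),
        nrmse=nrmse(p, o),
        n=int(p.size),
        test_label=test_label,
        reference_label=reference_label,
    )
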