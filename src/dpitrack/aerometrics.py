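"""Aerodynamic performance metrics: EF, FPD, FPF, MMAD, GSD, stage binning.

The same machinery serves two data paths: cascade-impactor stage-deposition
tables measured in vitro, and simulated aerosols binned at impactor stage
cut-off diameters.  MMAD and GSD come from the log-probability analysis of
the cumulative undersize curve: the cumulative mass fraction below each
stage cut-off is mapped through the probit (inverse standard normal) and
interpolated piecewise-linearly against log10(diameter); the MMAD is the
diameter at probit 0 (the 50th mass percentile) and

    GSD = sqrt(d_84.13 / d_15.87)

uses the diameters one probit unit either side of the median.  For an
exactly lognormal aerosol the construction is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ExtrapolationError, ValidationError

#: standard stage cut-off diameters (um) of the next generation impactor at
#: 60 L/min, stages S1-S7; the micro-orifice collector below S7 has no cut-off
NGI_CUTOFFS_60LPM = {
    "S1": 8.06,
    "S2": 4.46,
    "S3": 2.82,
    "S4": 1.66,
    "S5": 0.94,
    "S6": 0.55,
    "S7": 0.34,
}

#: default respirable cut-off (um); the twin stage impinger convention is 6.4
FPF_CUTOFF_UM = 5.0
TSI_CUTOFF_UM = 6.4

#: stage labels counted on the device side of the emitted-dose split
DEVICE_LABELS = frozenset({"device", "capsule", "adapter", "mouthpiece_adapter"})


@dataclass(frozen=True)
class StageRow:
    """One collection surface: label, cut-off diameter (um or None), mass."""

    label: str
    cutoff_um: float | None
    mass: float

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValidationError(f"stage {self.label!r}: mass cannot be negative")
        if self.cutoff_um is not None and self.cutoff_um <= 0:
            raise ValidationError(f"stage {self.label!r}: cut-off must be positive")


@dataclass(frozen=True)
class StageTable:
    """Ordered impactor deposition table (upstream to downstream).

    Rows without a cut-off upstream of the first sized stage (device,
    induction port, pre-separator) collect un-fractionated material; rows
    without a cut-off downstream (micro-orifice collector, filter) collect
    everything below the last cut-off.  Cut-offs must decrease downstream.
    """

    rows: tuple[StageRow, ...]
    flow_rate_lpm: float | None = None

    def __post_init__(self) -> None:
        cutoffs = [r.cutoff_um for r in self.rows if r.cutoff_um is not None]
        if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValidationError("stage cut-offs must be strictly decreasing downstream")

    # -- mass accounting ----------------------------------------------------
    def device_mass(self) -> float:
        return sum(r.mass for r in self.rows if r.label.lower() in DEVICE_LABELS)

    def emitted_mass(self) -> float:
        """ED: everything collected past the device (IP + stages + MOC)."""
        return sum(r.mass for r in self.rows if r.label.lower() not in DEVICE_LABELS)

    def metered_mass(self) -> float:
        """MD: device residue plus everything in the impactor."""
        return sum(r.mass for r in self.rows)

    def sized_rows(self) -> list[StageRow]:
        return [r for r in self.rows if r.cutoff_um is not None]

    # -- cumulative undersize curve ------------------------------------------
    def undersize_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(cutoffs um desc, cumulative mass fraction below each cutoff).

        The denominator is the emitted aerosol mass (device rows excluded):
        material on the induction port counts as failing the top cut-off.
        """
        sized = self.sized_rows()
        if len(sized) < 2:
            raise ValidationError("need at least two cut-off-bearing stages")
        total = self.emitted_mass()
        if total <= 0:
            raise ValidationError("no aerosol mass in the impactor")
        cutoffs = np.array([r.cutoff_um for r in sized])
        aerosol = [r for r in self.rows if r.label.lower() not in DEVICE_LABELS]
        masses = np.array([r.mass for r in aerosol])
        strictly_below = np.concatenate([np.cumsum(masses[::-1])[::-1][1:], [0.0]])
        below = np.array(
            [strictly_below[i] for i, r in enumerate(aerosol) if r.cutoff_um is not None]
        )
        return cutoffs, below / total

    # -- I/O ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, flow_rate_lpm: float | None = None) -> "StageTable":
        """Read ``stage,label,cutoff_um,mass`` CSV (empty cutoff = none)."""
        df = pd.read_csv(path)
        required = {"label", "cutoff_um", "mass"}
        if not required.issubset(df.columns):
            raise ValidationError(f"{path}: stage table needs columns {sorted(required)}")
        rows = tuple(
            StageRow(
                label=str(r.label),
                cutoff_um=None if pd.isna(r.cutoff_um) else float(r.cutoff_um),
                mass=float(r.mass),
            )
            for r in df.itertuples()
        )
        return cls(rows, flow_rate_lpm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": np.arange(len(self.rows)),
                "label": [r.label for r in self.rows],
                "cutoff_um": [r.cutoff_um for r in self.rows],
                "mass": [r.mass for r in self.rows],
            }
        )


@dataclass(frozen=True)
class AeroSummary:
    """Headline aerodynamic performance numbers for one measurement."""

    MD: float
    ED: float
    EF: float  # %
    FPD: float
    FPF: float  # %
    MMAD: float  # um
    GSD: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.EF <= 100.0 + 1e-9:
            raise ValidationError(f"EF must lie in [0, 100]%, got {self.EF}")
        if not 0.0 <= self.FPF <= 100.0 + 1e-9:
            raise ValidationError(f"FPF must lie in [0, 100]%, got {self.FPF}")
        if not (math.isnan(self.GSD) or self.GSD >= 1.0 - 1e-12):
            raise ValidationError(f"GSD cannot be below 1, got {self.GSD}")


def compute_ef(ed: float, md: float) -> float:
    """Emitted fraction EF = 100 * ED / MD (%)."""
    if md <= 0:
        raise ValidationError(f"metered dose must be positive, got {md}")
    if not 0.0 <= ed <= md:
        raise ValidationError(f"emitted dose {ed} must lie in [0, MD={md}]")
    return 100.0 * ed / md


def compute_fpf(fpd: float, ed: float) -> float:
    """Fine particle fraction FPF = 100 * FPD / ED (%)."""
    if ed <= 0:
        raise ValidationError(f"emitted dose must be positive, got {ed}")
    if not 0.0 <= fpd <= ed:
        raise ValidationError(f"fine particle dose {fpd} must lie in [0, ED={ed}]")
    return 100.0 * fpd / ed


def bin_to_stages(
    d_ae_um,
    masses,
    cutoffs: dict[str, float] | None = None,
    flow_rate_lpm: float | None = None,
) -> StageTable:
    """Bin aerosol particles into impactor stages by aerodynamic diameter.

    A particle lands on the first (largest-cut-off) stage whose cut-off is
    <= its d_ae, i.e. stage i collects the half-open bin
    [cutoff_i, cutoff_{i-1}) with the top stage unbounded above, matching an
    impactor where everything too coarse to pass a stage deposits on it.
    Anything below the last cut-off lands on the collector (MOC) row; an
    induction-port row is emitted (empty) so the layout matches measured
    tables.  Total mass is conserved exactly.
    """
    cutoffs = dict(cutoffs or NGI_CUTOFFS_60LPM)
    values = list(cutoffs.values())
    if any(b >= a for a, b in zip(values, values[1:])):
        raise ValidationError("stage cut-offs must be strictly decreasing")
    d_ae_um = np.asarray(d_ae_um, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if d_ae_um.shape != masses.shape:
        raise ValidationError("diameters and masses must have matching shapes")
    edges = np.array(values)  # descending
    # idx i = number of cut-offs strictly above d -> stage index (len -> MOC)
    idx = np.searchsorted(-edges, -d_ae_um, side="left")
    rows = [StageRow("IP", None, 0.0)]
    for i, (label, cut) in enumerate(cutoffs.items()):
        rows.append(StageRow(label, float(cut), float(masses[idx == i].sum())))
    rows.append(StageRow("MOC", None, float(masses[idx == len(edges)].sum())))
    return StageTable(tuple(rows), flow_rate_lpm)


class _ProbitInterpolant:
    """Piecewise-linear probit(undersize) vs log10(diameter) interpolant."""

    def __init__(self, cutoffs_desc: np.ndarray, undersize: np.ndarray):
        interior = (undersize > 0.0) & (undersize < 1.0)
        if interior.sum() < 2:
            raise ExtrapolationError(
                "need at least two stages with undersize strictly between 0 and 1"
            )
        logd = np.log10(cutoffs_desc[interior])[::-1]  # ascending diameter
        z = norm.ppf(undersize[interior])[::-1]
        if np.any(np.diff(logd) <= 0) or np.any(np.diff(z) < 0):
            raise ValidationError("cumulative undersize curve must be non-decreasing in size")
        self.logd = logd
        self.z = z

    def diameter_at_z(self, z_target: float) -> float:
        if not self.z[0] <= z_target <= self.z[-1]:
            raise ExtrapolationError(
                f"probit {z_target:.3f} outside the interpolable range "
                f"[{self.z[0]:.3f}, {self.z[-1]:.3f}]"
            )
        return float(10.0 ** np.interp(z_target, self.z, self.logd))

    def undersize_at(self, d_um: float) -> float:
        logd = math.log10(d_um)
        if not self.logd[0] <= logd <= self.logd[-1]:
            raise ExtrapolationError(
                f"diameter {d_um} um outside the interpolable range "
                f"[{10 ** self.logd[0]:.3g}, {10 ** self.logd[-1]:.3g}] um"
            )
        return float(norm.cdf(np.interp(logd, self.logd, self.z)))


def mmad_gsd(table: StageTable) -> tuple[float, float]:
    """MMAD (um) and GSD from the log-probability analysis of a stage table.

    The MMAD interpolates linearly between the nearest stages either side of
    the 50th cumulative mass percentile (probit scale vs log diameter); an
    :class:`ExtrapolationError` is raised if 50% is not bracketed.  The GSD
    is sqrt(d_84.13/d_15.87) on the same interpolant, or NaN when either
    flanking percentile falls outside the measured stages.
    """
    cutoffs, undersize = table.undersize_curve()
    interp = _ProbitInterpolant(cutoffs, undersize)
    mmad = interp.diameter_at_z(0.0)
    try:
        gsd = math.sqrt(interp.diameter_at_z(1.0) / interp.diameter_at_z(-1.0))
    except ExtrapolationError:
        gsd = float("nan")
    return mmad, gsd


def fpd_from_curve(table: StageTable, cutoff_um: float = FPF_CUTOFF_UM) -> float:
    """Fine particle dose: ED times the cumulative undersize at ``cutoff_um``.

    The undersize fraction comes from the probit-log interpolant, so a cutoff
    equal to a stage cut-off returns that stage's tabulated undersize exactly.
    """
    cutoffs, undersize = table.undersize_curve()
    interp = _ProbitInterpolant(cutoffs, undersize)
    return table.emitted_mass() * interp.undersize_at(cutoff_um)


def aero_summary(table: StageTable, fpf_cutoff_um: float = FPF_CUTOFF_UM) -> AeroSummary:
    """Full metric panel (MD, ED, EF, FPD, FPF, MMAD, GSD) for one table."""
    md = table.metered_mass()
    ed = table.emitted_mass()
    mmad, gsd = mmad_gsd(table)
    fpd = fpd_from_curve(table, fpf_cutoff_um)
    return AeroSummary(
        MD=md,
        ED=ed,
        EF=compute_ef(ed, md),
        FPD=fpd,
        FPF=compute_fpf(fpd, ed),
        MMAD=mmad,
        GSD=gsd,
    )
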