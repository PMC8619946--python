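"""Run configuration: TOML loading, validation, and object assembly.

A run configuration describes everything needed to reproduce a simulation:
the formulation, geometry overrides (mm), the flow provider, particle count
and seed, material overrides, and metric options.  Unknown keys anywhere in
the file are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .aerometrics import FPF_CUTOFF_UM, NGI_CUTOFFS_60LPM
from .errors import ValidationError
from .fixtures import FORMULATIONS, get_formulation
from .flowfield import LPM_TO_M3S, FlowField, analytic_swirl_field, load_gridded_field
from .geometry import InhalerGeometry, build_geometry
from .particles import FormulationRecord
from .wallmodel import MaterialParams

_MATERIAL_KEYS = {
    "E_s",
    "E_p",
    "v_s",
    "v_p",
    "W_A",
    "k_s",
    "f",
    "C_u",
    "mu",
    "rho_air",
    "e_n",
    "lift_enabled",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated simulation/analysis settings with defaults applied.

    Defaults reflect the reference operating point: 60 L/min through the
    default geometry, 100 injected particles, mass-weighted summaries, a
    5 um respirable cut-off at the standard 60 L/min stage cut-offs.
    """

    formulation: str | FormulationRecord = "F1"
    geometry_overrides: dict = dc_field(default_factory=dict)
    q_lpm: float = 60.0
    swirl_number: float = 2.0
    gridded_field_path: str | None = None
    interpolation: str = "trilinear"
    n_particles: int = 100
    seed: int | None = None
    max_time_s: float = 0.5
    gravity: bool = False
    material_overrides: dict = dc_field(default_factory=dict)
    fpf_cutoff_um: float = FPF_CUTOFF_UM
    ngi_cutoffs: dict = dc_field(default_factory=lambda: dict(NGI_CUTOFFS_60LPM))
    weighting: str = "mass"
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.q_lpm <= 0:
            raise ValidationError(f"flow.q_lpm must be positive, got {self.q_lpm}")
        if self.n_particles < 1:
            raise ValidationError(f"simulation.n_particles must be >= 1, got {self.n_particles}")
        if self.max_time_s <= 0:
            raise ValidationError("simulation.max_time_s must be positive")
        if self.weighting not in ("number", "mass"):
            raise ValidationError(f"weighting must be 'number' or 'mass', got {self.weighting!r}")
        if self.fpf_cutoff_um <= 0:
            raise ValidationError("metrics.fpf_cutoff_um must be positive")
        unknown = set(self.material_overrides) - _MATERIAL_KEYS
        if unknown:
            raise ValidationError(f"unknown material override(s): {sorted(unknown)}")

    # -- object assembly -----------------------------------------------------
    def formulation_record(self) -> FormulationRecord:
        if isinstance(self.formulation, FormulationRecord):
            return self.formulation
        return get_formulation(self.formulation)

    def geometry(self) -> InhalerGeometry:
        return build_geometry(self.geometry_overrides)

    def materials(self) -> MaterialParams:
        return MaterialParams(**self.material_overrides)

    def flow_field(self, geometry: InhalerGeometry | None = None) -> FlowField:
        if self.gridded_field_path is not None:
            return load_gridded_field(self.gridded_field_path, self.interpolation)
        geometry = geometry or self.geometry()
        return analytic_swirl_field(geometry, self.q_lpm * LPM_TO_M3S, self.swirl_number)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (reproducibility manifest)."""
        payload = {
            k: (v if not isinstance(v, FormulationRecord) else vars(v))
            for k, v in vars(self).items()
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


_SECTION_KEYS = {
    "formulation": {"name", "dv10_um", "dv50_um", "dv90_um", "span", "true_density_g_cm3"},
    "geometry": {
        "chamber_radius",
        "grid_z",
        "total_height",
        "outlet_diameter",
        "inlet_width",
        "inlet_height",
        "injection_z",
        "grid_porosity",
    },
    "flow": {"q_lpm", "swirl_number", "gridded_field_path", "interpolation"},
    "simulation": {"n_particles", "seed", "max_time_s", "gravity", "weighting"},
    "materials": _MATERIAL_KEYS,
    "metrics": {"fpf_cutoff_um", "ngi_cutoffs"},
    "output": {"out_dir"},
}


def _reject_unknown(section: str, table: dict) -> None:
    unknown = set(table) - _SECTION_KEYS[section]
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in config section [{section}]"
        )


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration.

    An empty file yields all defaults.  The formulation may be selected by
    name (one of F1-F5) or given explicitly with its quantiles and density.
    """
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    unknown_sections = set(raw) - set(_SECTION_KEYS)
    if unknown_sections:
        raise ValidationError(f"unknown config section(s): {sorted(unknown_sections)}")

    kwargs: dict = {}

    form = raw.get("formulation", {})
    _reject_unknown("formulation", form)
    if {"dv10_um", "dv50_um", "dv90_um", "true_density_g_cm3"} <= set(form):
        quantiles = (form["dv10_um"], form["dv50_um"], form["dv90_um"])
        span = form.get("span", (quantiles[2] - quantiles[0]) / quantiles[1])
        kwargs["formulation"] = FormulationRecord(
            form.get("name", "custom"), *quantiles, span, form["true_density_g_cm3"]
        )
    elif "name" in form:
        if form["name"] not in FORMULATIONS:
            raise ValidationError(
                f"unknown formulation {form['name']!r}; known: {sorted(FORMULATIONS)}"
            )
        kwargs["formulation"] = form["name"]
    elif form:
        raise ValidationError(
            "[formulation] needs either a name or the full quantile/density set"
        )

    geom = raw.get("geometry", {})
    _reject_unknown("geometry", geom)
    kwargs["geometry_overrides"] = dict(geom)

    flow = raw.get("flow", {})
    _reject_unknown("flow", flow)
    if "q_lpm" in flow:
        kwargs["q_lpm"] = float(flow["q_lpm"])
    if "swirl_number" in flow:
        kwargs["swirl_number"] = float(flow["swirl_number"])
    if "gridded_field_path" in flow:
        kwargs["gridded_field_path"] = str(flow["gridded_field_path"])
    if "interpolation" in flow:
        kwargs["interpolation"] = str(flow["interpolation"])

    sim = raw.get("simulation", {})
    _reject_unknown("simulation", sim)
    if "n_particles" in sim:
        kwargs["n_particles"] = int(sim["n_particles"])
    if "seed" in sim:
        kwargs["seed"] = int(sim["seed"])
    if "max_time_s" in sim:
        kwargs["max_time_s"] = float(sim["max_time_s"])
    if "gravity" in sim:
        kwargs["gravity"] = bool(sim["gravity"])
    if "weighting" in sim:
        kwargs["weighting"] = str(sim["weighting"])

    mats = raw.get("materials", {})
    _reject_unknown("materials", mats)
    kwargs["material_overrides"] = dict(mats)

    metrics = raw.get("metrics", {})
    _reject_unknown("metrics", metrics)
    if "fpf_cutoff_um" in metrics:
        kwargs["fpf_cutoff_um"] = float(metrics["fpf_cutoff_um"])
    if "ngi_cutoffs" in metrics:
        kwargs["ngi_cutoffs"] = {str(k): float(v) for k, v in metrics["ngi_cutoffs"].items()}

    out = raw.get("output", {})
    _reject_unknown("output", out)
    if "out_dir" in out:
        kwargs["out_dir"] = str(out["out_dir"])

    return RunConfig(**kwargs)
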