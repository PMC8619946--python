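"""Reference fixtures: formulation micromeritics, material constants, and a
synthetic impactor stage-table generator.

The five solid-lipid-microparticle formulations F1-F5 carry the published
laser-diffraction volume quantiles, spans and pycnometric true densities
used as simulation inputs; the material constants are the tabulated sticking
parameters.  The synthetic stage generator emulates what a next generation
impactor would collect from a lognormal aerosol: it draws equal-mass samples
from the lognormal, bins them at the stage cut-offs, and prepends a device
residue so the emitted fraction is well defined.  It is a synthetic stand-in
for measured deposition data (which is published only graphically), useful
for exercising the analysis path end to end.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aerometrics import NGI_CUTOFFS_60LPM, StageRow, StageTable, bin_to_stages
from .errors import ValidationError
from .particles import FormulationRecord
from .wallmodel import MaterialParams

#: published micromeritic inputs per formulation (um, um, um, -, g/cm^3)
FORMULATIONS: dict[str, FormulationRecord] = {
    rec.name: rec
    for rec in (
        FormulationRecord("F1", 2.24, 4.42, 8.84, 1.492, 1.050),
        FormulationRecord("F2", 2.43, 4.67, 8.51, 1.304, 1.060),
        FormulationRecord("F3", 2.20, 4.03, 7.10, 1.217, 1.170),
        FormulationRecord("F4", 1.87, 5.13, 12.21, 2.016, 1.230),
        FormulationRecord("F5", 2.26, 3.94, 6.63, 1.110, 1.030),
    )
}

DEFAULT_MATERIALS = MaterialParams()


def get_formulation(name: str) -> FormulationRecord:
    try:
        return FORMULATIONS[name]
    except KeyError:
        raise ValidationError(
            f"unknown formulation {name!r}; known: {sorted(FORMULATIONS)}"
        ) from None


def formulations_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": list(FORMULATIONS),
            "dv10_um": [f.d_v10 for f in FORMULATIONS.values()],
            "dv50_um": [f.d_v50 for f in FORMULATIONS.values()],
            "dv90_um": [f.d_v90 for f in FORMULATIONS.values()],
            "span": [f.span for f in FORMULATIONS.values()],
            "true_density_g_cm3": [f.true_density for f in FORMULATIONS.values()],
        }
    )


def synthetic_stage_table(
    median_um: float = 4.0,
    gsd: float = 2.0,
    n_samples: int = 20_000,
    emitted_mass: float = 12.0,
    device_mass: float = 3.0,
    cutoffs: dict[str, float] | None = None,
    seed: int = 0,
) -> StageTable:
    """Impactor output emulated from a lognormal aerosol (masses arbitrary).

    ``n_samples`` equal-mass draws from lognormal(median_um, gsd) are binned
    at the stage cut-offs; each sample carries emitted_mass / n_samples, so
    the mass distribution over stages is the sampled lognormal with shot
    noise.  A device row with ``device_mass`` precedes the impactor rows.
    """
    if median_um <= 0 or gsd < 1.0:
        raise ValidationError("need median > 0 and GSD >= 1")
    rng = np.random.default_rng(seed)
    d_ae = np.exp(rng.normal(np.log(median_um), np.log(gsd), size=n_samples))
    masses = np.full(n_samples, emitted_mass / n_samples)
    binned = bin_to_stages(d_ae, masses, cutoffs or NGI_CUTOFFS_60LPM, flow_rate_lpm=60.0)
    rows = (StageRow("device", None, device_mass),) + binned.rows
    return StageTable(rows, flow_rate_lpm=60.0)


def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the fixture files into ``out_dir``; returns path per fixture.

    Files: ``formulations.csv`` (micromeritic table), ``materials.json``
    (sticking-model constants), ``ngi_stage_table_synthetic.csv`` plus a
    sidecar JSON recording the generator parameters.  Regeneration with the
    same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["formulations"] = out_dir / "formulations.csv"
    formulations_frame().to_csv(paths["formulations"], index=False)

    paths["materials"] = out_dir / "materials.json"
    materials = {
        "E_s": DEFAULT_MATERIALS.E_s,
        "E_p": DEFAULT_MATERIALS.E_p,
        "v_s": DEFAULT_MATERIALS.v_s,
        "v_p": DEFAULT_MATERIALS.v_p,
        "W_A": DEFAULT_MATERIALS.W_A,
        "k_s": DEFAULT_MATERIALS.k_s,
        "f": DEFAULT_MATERIALS.f,
        "C_u": DEFAULT_MATERIALS.C_u,
        "mu": DEFAULT_MATERIALS.mu,
        "rho_air": DEFAULT_MATERIALS.rho_air,
        "e_n": DEFAULT_MATERIALS.e_n,
    }
    paths["materials"].write_text(json.dumps(materials, indent=2, sort_keys=True) + "\n")

    params = {
        "median_um": 4.0,
        "gsd": 2.0,
        "n_samples": 20_000,
        "emitted_mass": 12.0,
        "device_mass": 3.0,
        "seed": seed,
        "flow_rate_lpm": 60.0,
        "synthetic": True,
    }
    table = synthetic_stage_table(
        params["median_um"],
        params["gsd"],
        params["n_samples"],
        params["emitted_mass"],
        params["device_mass"],
        seed=seed,
    )
    paths["stage_table"] = out_dir / "ngi_stage_table_synthetic.csv"
    table.to_frame().to_csv(paths["stage_table"], index=False)
    paths["stage_table_meta"] = out_dir / "ngi_stage_table_synthetic.meta.json"
    paths["stage_table_meta"].write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
    return paths
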