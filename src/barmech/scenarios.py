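"""Scenario configuration, named parameter sets, and reproducible runs.

A scenario is a YAML-serializable mapping with an ``electrolyte`` block and
one task block (``planar``, ``arc`` or ``bending``), plus an optional
``run`` block with tolerances and a seed for randomized studies.  Every run
writes a manifest JSON capturing all resolved parameters so that re-running
a manifest reproduces the outputs bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edl_core import ElectrolyteModel, bulk_permittivity
from .edl_planar import Grid1D, solve_planar, surface_layer_permittivity
from .edl_arc import field_vs_radius

NM = 1.0e-9


class ConfigError(ValueError):
    """Configuration problem; the message names the offending field path."""


@dataclass
class ScenarioConfig:
    """A validated scenario: electrolyte plus exactly one task block."""

    name: str
    electrolyte: dict[str, float]
    planar: dict[str, Any] | None = None
    arc: dict[str, Any] | None = None
    bending: dict[str, Any] | None = None
    run: dict[str, Any] = dc_field(default_factory=dict)
    assumed: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return {k: v for k, v in d.items() if v not in (None, [], {})}

    def electrolyte_model(self) -> ElectrolyteModel:
        e = self.electrolyte
        return ElectrolyteModel.from_molar(
            e["salt_mol_l"], e["water_mol_l"], e["dipole_debye"], e["temperature_K"]
        )


def _require(block: dict, path: str, key: str, types=(int, float)) -> Any:
    if key not in block:
        raise ConfigError(f"{path}.{key}: missing required field")
    v = block[key]
    if types and not isinstance(v, types) or isinstance(v, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {v!r}")
    return v


def parse_config(data: dict[str, Any], name: str = "scenario") -> ScenarioConfig:
    """Validate a raw mapping; errors carry the offending field path."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    name = data.get("name", name)
    if "electrolyte" not in data:
        raise ConfigError("electrolyte: missing required block")
    e = data["electrolyte"]
    for key in ("salt_mol_l", "water_mol_l", "dipole_debye", "temperature_K"):
        v = _require(e, "electrolyte", key)
        if v < 0:
            raise ConfigError(f"electrolyte.{key}: must be non-negative, got {v}")
    if e["water_mol_l"] <= 0:
        raise ConfigError("electrolyte.water_mol_l: must be positive")
    if e["temperature_K"] <= 0:
        raise ConfigError("electrolyte.temperature_K: must be positive")

    tasks = [k for k in ("planar", "arc", "bending") if k in data]
    if len(tasks) != 1:
        raise ConfigError(
            f"exactly one task block of planar/arc/bending required, found {tasks}"
        )
    task = tasks[0]
    block = data[task]
    if task == "planar":
        sigma = _require(block, "planar", "sigma_As_m2")
        if abs(sigma) > 1.0:
            raise ConfigError("planar.sigma_As_m2: |sigma| must be <= 1")
    elif task == "arc":
        _require(block, "arc", "sigma_As_m2")
        _require(block, "arc", "arc_length_nm")
        _require(block, "arc", "layer_nm")
        _require(block, "arc", "eps_ord")
        radii = block.get("radii_nm")
        if not isinstance(radii, list) or not radii:
            raise ConfigError("arc.radii_nm: a non-empty list is required")
        if any(not isinstance(r, (int, float)) for r in radii):
            raise ConfigError("arc.radii_nm: entries must be numbers")

    return ScenarioConfig(
        name=name,
        electrolyte={k: float(e[k]) for k in ("salt_mol_l", "water_mol_l", "dipole_debye", "temperature_K")},
        planar=data.get("planar"),
        arc=data.get("arc"),
        bending=data.get("bending"),
        run=data.get("run", {}),
        assumed=list(data.get("assumed", [])),
    )


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh), name=Path(path).stem)


# ---------------------------------------------------------------------------
# Named parameter sets
# ---------------------------------------------------------------------------

#: Reference electrolyte: physiological monovalent salt with the standard
#: water dipole parameterization of the Langevin-Bikerman literature.
REFERENCE_ELECTROLYTE = {
    "salt_mol_l": 0.15,
    "water_mol_l": 55.0,
    "dipole_debye": 4.79,
    "temperature_K": 298.0,
}


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Named, ready-to-run parameter sets.

    ``planar_reference`` — the charged flat membrane-binding face at
    sigma = 0.2 As/m^2 in 0.15 mol/l salt; its converged profile defines
    the ordered-layer permittivity.  ``arc_scan`` — the BAR-domain arc at
    the same surface charge with the step-function permittivity
    (eps_ord = 54.5 over a = 0.32 nm) scanned over curvature radii at
    fixed arc length.  Values not fixed by the reference conditions
    (temperature, arc length, probe distance) are listed under
    ``assumed`` and flagged in the manifest.
    """
    planar = ScenarioConfig(
        name="planar_reference",
        electrolyte=dict(REFERENCE_ELECTROLYTE),
        planar={"sigma_As_m2": 0.2, "layer_nm": 0.32},
        assumed=["electrolyte.temperature_K"],
    )
    arc = ScenarioConfig(
        name="arc_scan",
        electrolyte=dict(REFERENCE_ELECTROLYTE),
        arc={
            "sigma_As_m2": 0.2,
            "arc_length_nm": 15.0,
            "layer_nm": 0.32,
            "eps_ord": 54.5,
            "eps_b": 78.5,
            "point_distance_nm": 0.5,
            "radii_nm": [5.0, 7.5, 11.0, 16.0, 25.0, 40.0],
            "mode": "full",
        },
        assumed=[
            "electrolyte.temperature_K",
            "arc.arc_length_nm",
            "arc.point_distance_nm",
        ],
    )
    return {"planar_reference": planar, "arc_scan": arc}


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------


def _manifest(config: ScenarioConfig, extra: dict[str, Any]) -> dict[str, Any]:
    return {
        "package": "barmech",
        "version": __version__,
        "config": config.to_dict(),
        "assumed": config.assumed,
        **extra,
    }


def run_scenario(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the scenario's task and write CSV + manifest into ``outdir``.

    Returns a mapping of artifact names to paths.  Deterministic: the same
    config produces byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = config.electrolyte_model()
    paths: dict[str, Path] = {}

    if config.planar is not None:
        block = config.planar
        profile = solve_planar(model, float(block["sigma_As_m2"]))
        df = pd.DataFrame(
            {
                "x_nm": profile.grid.x / NM,
                "phi_mV": profile.potential * 1e3,
                "E_V_per_m": profile.field,
                "eps_r": profile.permittivity,
                "rho_C_per_m3": profile.charge_density,
            }
        )
        csv = outdir / f"{config.name}_profile.csv"
        df.to_csv(csv, index=False, float_format="%.10g")
        paths["profile"] = csv
        extra: dict[str, Any] = {"convergence": _jsonable(profile.convergence)}
        if "layer_nm" in block:
            at_surface, layer_avg = surface_layer_permittivity(
                profile, float(block["layer_nm"]) * NM
            )
            extra["surface_permittivity"] = at_surface
            extra["layer_average_permittivity"] = layer_avg
        extra["bulk_permittivity"] = bulk_permittivity(model)
    elif config.arc is not None:
        block = config.arc
        df = field_vs_radius(
            model,
            float(block["sigma_As_m2"]),
            float(block["arc_length_nm"]) * NM,
            float(block["layer_nm"]) * NM,
            float(block["eps_ord"]),
            float(block["eps_b"]) if "eps_b" in block else None,
            [float(r) * NM for r in block["radii_nm"]],
            float(block.get("point_distance_nm", 0.5)) * NM,
            mode=block.get("mode", "full"),
        )
        out = pd.DataFrame(
            {"R_nm": df["R_m"] / NM, "E_point1_V_per_m": df["E_point1_V_per_m"]}
        )
        csv = outdir / f"{config.name}_field_vs_radius.csv"
        out.to_csv(csv, index=False, float_format="%.10g")
        paths["field_vs_radius"] = csv
        extra = {"monotonic_increasing": bool(df.attrs["monotonic_increasing"])}
    else:
        raise ConfigError("bending scenarios are run through the CLI subcommands")

    manifest = outdir / f"{config.name}_manifest.json"
    with open(manifest, "w") as fh:
        json.dump(_manifest(config, extra), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest
    return paths


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
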