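"""Run configuration: YAML/JSON files with unit-carrying quantities.

Every dimensional field is a ``{value, unit}`` mapping so a config is
unambiguous about units; unknown keys are rejected rather than ignored so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import SutureflowError, UnitError
from .geometry import FluidProperties, ImplantGeometry, Placement, SutureConfig
from .shape_factor import Resolution
from .steady_state import EyeParameters
from .units import Quantity


class ConfigError(SutureflowError):
    """Malformed run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """One scenario: eye, fluid, implant, and the question being asked."""

    scenario: str = "unnamed"
    eye: EyeParameters = field(default_factory=EyeParameters)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    implant: Optional[ImplantGeometry] = None
    suture: Optional[SutureConfig] = None
    p_c1_mmhg: Optional[float] = None
    target_p_c_mmhg: Optional[float] = None
    output_dir: str = "."
    resolution: Resolution = field(default_factory=Resolution)
    seed: int = 0  # reserved: the model has no stochastic component


def _q(node, dimension_unit: str, where: str) -> float:
    """Read a {value, unit} node and return the magnitude in ``dimension_unit``."""
    if not isinstance(node, dict):
        raise ConfigError(f"{where}: expected a {{value, unit}} mapping, got {node!r}")
    try:
        return Quantity.from_dict(node).to(dimension_unit).magnitude
    except UnitError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def _check_keys(node: dict, allowed: set, where: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def parse_config(data: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML/JSON mapping."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(
        data,
        {"scenario", "eye", "fluid", "implant", "suture", "p_c1",
         "target_p_c", "output_dir", "solver", "seed"},
        "config",
    )
    kwargs: dict = {}
    kwargs["scenario"] = str(data.get("scenario", "unnamed"))
    if "eye" in data:
        node = data["eye"]
        _check_keys(node, {"p_g", "p_ev", "p_r", "q_cb", "uveoscleral_fraction"}, "eye")
        kwargs["eye"] = EyeParameters(
            p_g_mmhg=_q(node["p_g"], "mmHg", "eye.p_g") if "p_g" in node else 35.0,
            p_ev_mmhg=_q(node["p_ev"], "mmHg", "eye.p_ev") if "p_ev" in node else 10.5,
            p_r_mmhg=_q(node["p_r"], "mmHg", "eye.p_r") if "p_r" in node else 0.0,
            q_cb_ul_min=(
                _q(node["q_cb"], "ul/min", "eye.q_cb") if "q_cb" in node else 2.0
            ),
            uveoscleral_fraction=float(node.get("uveoscleral_fraction", 0.15)),
        )
    if "fluid" in data:
        node = data["fluid"]
        _check_keys(node, {"viscosity"}, "fluid")
        kwargs["fluid"] = FluidProperties(
            viscosity_mpa_s=_q(node["viscosity"], "mPa*s", "fluid.viscosity")
        )
    if "implant" in data:
        node = data["implant"]
        _check_keys(node, {"inner_diameter", "length"}, "implant")
        kwargs["implant"] = ImplantGeometry(
            inner_diameter_um=_q(node["inner_diameter"], "um", "implant.inner_diameter"),
            length_mm=_q(node["length"], "mm", "implant.length"),
        )
    if "suture" in data:
        node = data["suture"]
        _check_keys(node, {"diameter", "placement"}, "suture")
        kwargs["suture"] = SutureConfig(
            diameter_um=_q(node["diameter"], "um", "suture.diameter"),
            placement=Placement(node.get("placement", "wall_touching")),
        )
    if "p_c1" in data:
        kwargs["p_c1_mmhg"] = _q(data["p_c1"], "mmHg", "p_c1")
    if "target_p_c" in data:
        kwargs["target_p_c_mmhg"] = _q(data["target_p_c"], "mmHg", "target_p_c")
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    if "solver" in data:
        node = data["solver"]
        _check_keys(node, {"cells_per_gap", "min_cells", "max_cells", "rtol"}, "solver")
        kwargs["resolution"] = Resolution(
            cells_per_gap=int(node.get("cells_per_gap", 24)),
            min_cells=int(node.get("min_cells", 96)),
            max_cells=int(node.get("max_cells", 3072)),
            rtol=float(node.get("rtol", 5e-3)),
        )
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return RunConfig(**kwargs)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML (or JSON) run configuration from disk."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return parse_config(data)


def dump_config(cfg: RunConfig) -> dict:
    """Serialize a :class:`RunConfig` back to its mapping form.

    ``parse_config(dump_config(cfg))`` is an identity; the CLI's JSON output
    mode uses this so results can be re-fed as configs.
    """
    out: dict = {"scenario": cfg.scenario}
    out["eye"] = {
        "p_g": Quantity(cfg.eye.p_g_mmhg, "mmHg").as_dict(),
        "p_ev": Quantity(cfg.eye.p_ev_mmhg, "mmHg").as_dict(),
        "p_r": Quantity(cfg.eye.p_r_mmhg, "mmHg").as_dict(),
        "q_cb": Quantity(cfg.eye.q_cb_ul_min, "ul/min").as_dict(),
        "uveoscleral_fraction": cfg.eye.uveoscleral_fraction,
    }
    out["fluid"] = {"viscosity": Quantity(cfg.fluid.viscosity_mpa_s, "mPa*s").as_dict()}
    if cfg.implant is not None:
        out["implant"] = {
            "inner_diameter": Quantity(cfg.implant.inner_diameter_um, "um").as_dict(),
            "length": Quantity(cfg.implant.length_mm, "mm").as_dict(),
        }
    if cfg.suture is not None:
        out["suture"] = {
            "diameter": Quantity(cfg.suture.diameter_um, "um").as_dict(),
            "placement": cfg.suture.placement.value,
        }
    if cfg.p_c1_mmhg is not None:
        out["p_c1"] = Quantity(cfg.p_c1_mmhg, "mmHg").as_dict()
    if cfg.target_p_c_mmhg is not None:
        out["target_p_c"] = Quantity(cfg.target_p_c_mmhg, "mmHg").as_dict()
    out["output_dir"] = cfg.output_dir
    out["solver"] = {
        "cells_per_gap": cfg.resolution.cells_per_gap,
        "min_cells": cfg.resolution.min_cells,
        "max_cells": cfg.resolution.max_cells,
        "rtol": cfg.resolution.rtol,
    }
    out["seed"] = cfg.seed
    return out


def dump_config_json(cfg: RunConfig) -> str:
    return json.dumps(dump_config(cfg), indent=2)
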