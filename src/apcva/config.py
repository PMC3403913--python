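"""Scenario configuration files (YAML or TOML).

A config file mirrors :class:`~apcva.scenarios.ScenarioConfig`; concentration
fields accept unit-suffixed strings ("20nM", "1.4uM").  Example (YAML)::

    preset: fig9_pt_fxa     # optional base preset
    apc_total: 2nM
    t_end: 1200
    variant:
      arg306_rate: current
      include_R18: true
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .kinetics import SolverSettings
from .network import NetworkVariant
from .scenarios import ScenarioConfig, preset
from .units import parse_concentration

__all__ = ["load_config"]

_CONC_FIELDS = ("fva_total", "fxa_total", "pt_total", "apc_total", "lipid_total")
_PLAIN_FIELDS = (
    "name",
    "fva_form",
    "apc_mode",
    "preincubate",
    "t_end",
    "sample_dt",
)


def _read(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        return tomllib.loads(text)
    import yaml

    return yaml.safe_load(text)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML or TOML file."""
    path = Path(path)
    raw = _read(path)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    raw = dict(raw)

    base = preset(raw.pop("preset")) if "preset" in raw else ScenarioConfig()
    changes: dict = {}
    for key in _CONC_FIELDS:
        if key in raw:
            changes[key] = parse_concentration(raw.pop(key))
    for key in _PLAIN_FIELDS:
        if key in raw:
            changes[key] = raw.pop(key)
    if "outputs" in raw:
        changes["outputs"] = tuple(raw.pop("outputs"))
    if "variant" in raw:
        vd = dict(raw.pop("variant"))
        changes["variant"] = replace(base.variant, **vd)
    if "solver" in raw:
        sd = dict(raw.pop("solver"))
        changes["solver"] = replace(base.solver, **sd)
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return replace(base, **changes)
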