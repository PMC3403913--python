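"""Scenario presets, execution, and parameter scans.

Each preset reproduces one simulated experimental condition: which
proteins are present at what totals, whether they are pre-incubated to
equilibrium before the protease is added, which rate-constant variant
applies, and how the effective APC concentration is determined.  The model
is fully deterministic — rerunning a scenario with the same configuration
and solver settings is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import equilibria, kinetics, observables
from .equilibria import (
    MembraneCompetition,
    PairwiseProblem,
    TernaryPreincubation,
    default_ligands,
    effective_apc,
    pairwise_complex,
    ternary_preincubation,
)
from .kinetics import SolverSettings, TimeCourse, simulate, state_vector
from .network import NetworkVariant, ReactionNetwork, build_network
from .observables import (
    ObservableSeries,
    band_series,
    cofactor_activity,
    initial_rate,
    normalize_rmv,
    prothrombinase_activity,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "ScanSpec",
    "PRESET_NAMES",
    "preset",
    "run_scenario",
    "run_scan",
]

_DEFAULT_OUTPUTS = ("HC", "1-506", "307-679/709", "307-506", "cofactor_activity")


@dataclass(frozen=True)
class ScenarioConfig:
    """One figure-level experiment.

    Totals are molar.  ``fva_form`` selects the starting cofactor species
    (intact FVa or the Arg506-cleaved intermediate).  With ``preincubate``
    the FVa/FXa/PT binding equilibria set the initial condition; APC always
    enters free at t = 0 and is never part of the pre-incubation.
    ``apc_mode`` is ``raw``, ``fixed_fraction`` (11 % membrane-bound), or
    ``computed`` (solve the membrane competition).
    """

    name: str = "custom"
    fva_total: float = 20e-9
    fxa_total: float = 0.0
    pt_total: float = 0.0
    apc_total: float = 0.5e-9
    lipid_total: float = 20e-6
    fva_form: str = "FVa"
    variant: NetworkVariant = field(default_factory=NetworkVariant)
    apc_mode: str = "raw"
    preincubate: bool = False
    t_end: float = 1200.0
    sample_dt: float = 1.0
    outputs: tuple[str, ...] = _DEFAULT_OUTPUTS
    solver: SolverSettings = field(default_factory=SolverSettings)
    membrane: Optional[MembraneCompetition] = None

    def __post_init__(self) -> None:
        if self.fva_form not in ("FVa", "FVai506"):
            raise ValueError("fva_form must be 'FVa' or 'FVai506'")
        if self.apc_mode not in ("raw", "fixed_fraction", "computed"):
            raise ValueError(f"unknown apc_mode {self.apc_mode!r}")
        if self.preincubate:
            partners = sum(t > 0 for t in (self.fva_total, self.fxa_total, self.pt_total))
            if partners < 2:
                raise ValueError(
                    "preincubation requires at least two binding partners "
                    "with positive totals"
                )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "fva_total": self.fva_total,
            "fxa_total": self.fxa_total,
            "pt_total": self.pt_total,
            "apc_total": self.apc_total,
            "lipid_total": self.lipid_total,
            "fva_form": self.fva_form,
            "variant": self.variant.to_dict(),
            "apc_mode": self.apc_mode,
            "preincubate": self.preincubate,
            "t_end": self.t_end,
            "sample_dt": self.sample_dt,
            "outputs": list(self.outputs),
        }
        return d


@dataclass
class ScenarioResult:
    """TimeCourse plus requested observables and provenance."""

    config: ScenarioConfig
    network: ReactionNetwork
    timecourse: TimeCourse
    observables: dict[str, ObservableSeries]
    initial_state: dict[str, float]
    apc_effective: float

    @property
    def provenance(self) -> dict:
        net_hash = hashlib.sha256(
            self.network.to_json(indent=None).encode()
        ).hexdigest()[:16]
        return {
            "config": self.config.to_dict(),
            "network_sha256": net_hash,
            "solver": {
                "method": self.timecourse.settings.method,
                "rtol": self.timecourse.settings.rtol,
                "atol": self.timecourse.settings.atol,
                "step": self.timecourse.settings.step,
            },
            "apc_effective_M": self.apc_effective,
            "conservation_drift": kinetics.conservation_report(self.timecourse),
        }

    def observable(self, name: str) -> ObservableSeries:
        return self.observables[name]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for name, s in self.observables.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": s.times,
                        "analyte": name,
                        "value": s.values,
                        "normalized": s.normalized,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _presets() -> dict[str, ScenarioConfig]:
    # final rate set: current Arg306 constant, k_on 1.5e8 / K_D 0.5 nM, R18 on
    final = NetworkVariant()
    no_r18 = NetworkVariant(include_R18=False)
    return {
        # APC acting on free FVa (no FXa, no PT); exposes the hockin/current
        # comparison through variant overrides.
        "fig3_fva_only": ScenarioConfig(
            name="fig3_fva_only",
            fva_total=20e-9,
            apc_total=0.5e-9,
            variant=final,
            outputs=_DEFAULT_OUTPUTS + ("prothrombinase_activity",),
        ),
        # APC acting on the Arg506-cleaved intermediate; no intact heavy
        # chain exists, so only fragment bands are monitored.
        "fig3_fvai506": ScenarioConfig(
            name="fig3_fvai506",
            fva_total=20e-9,
            fva_form="FVai506",
            apc_total=0.5e-9,
            variant=final,
            outputs=("1-506", "307-506", "507-679/709", "prothrombinase_activity"),
        ),
        # Non-saturating prothrombinase: 200 pM FVa + 100 pM FXa preformed.
        "fig4_nonsat": ScenarioConfig(
            name="fig4_nonsat",
            fva_total=0.2e-9,
            fxa_total=0.1e-9,
            apc_total=0.5e-9,
            preincubate=True,
            variant=no_r18,
            outputs=("HC", "prothrombinase_activity"),
        ),
        # Saturating FXa*: 20 nM FVa + 30 nM FXa* preformed, 2 nM APC.
        "fig4c_sat": ScenarioConfig(
            name="fig4c_sat",
            fva_total=20e-9,
            fxa_total=30e-9,
            apc_total=2e-9,
            preincubate=True,
            variant=no_r18,
            t_end=360.0,
        ),
        # As fig4c but with the FXa-bound Arg306 cleavage (R18) enabled.
        "fig5_sat": ScenarioConfig(
            name="fig5_sat",
            fva_total=20e-9,
            fxa_total=30e-9,
            apc_total=2e-9,
            preincubate=True,
            variant=final,
            t_end=1200.0,
        ),
        # Prothrombin protection: 20 nM FVa + 1.4 uM PT, 11 % effective APC.
        "fig7_pt": ScenarioConfig(
            name="fig7_pt",
            fva_total=20e-9,
            pt_total=1.4e-6,
            apc_total=2e-9,
            preincubate=True,
            apc_mode="fixed_fraction",
            variant=final,
        ),
        # Combined protection: FVa + FXa* + PT ternary pre-incubation.
        "fig9_pt_fxa": ScenarioConfig(
            name="fig9_pt_fxa",
            fva_total=20e-9,
            fxa_total=30e-9,
            pt_total=1.4e-6,
            apc_total=2e-9,
            preincubate=True,
            apc_mode="fixed_fraction",
            variant=final,
        ),
    }


PRESET_NAMES: tuple[str, ...] = tuple(_presets())


def preset(name: str, **overrides) -> ScenarioConfig:
    """Return a named scenario configuration, optionally overridden.

    Overrides replace dataclass fields, e.g. ``preset("fig3_fva_only",
    apc_total=2e-9, variant=NetworkVariant(arg306_rate="hockin"))``.
    """
    table = _presets()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(table)}")
    return replace(table[name], **overrides)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def _initial_condition(cfg: ScenarioConfig, network: ReactionNetwork) -> dict[str, float]:
    rates = network.rates
    init: dict[str, float] = {}
    if cfg.preincubate and cfg.fxa_total > 0 and cfg.pt_total > 0:
        state = ternary_preincubation(
            TernaryPreincubation(
                cfg.fva_total,
                cfg.fxa_total,
                cfg.pt_total,
                kd_xv=rates.kd_XV,
                kd_v_pt=rates.kd_V_PT,
                kd_xv_pt=rates.kd_XV_PT,
            )
        )
        init.update(state)
    elif cfg.preincubate and cfg.fxa_total > 0:
        xv = pairwise_complex(
            PairwiseProblem(cfg.fva_total, cfg.fxa_total, rates.kd_XV)
        )
        init["FXa:FVa"] = xv
        init["FVa"] = cfg.fva_total - xv
        init["FXa"] = cfg.fxa_total - xv
    elif cfg.preincubate and cfg.pt_total > 0:
        vpt = pairwise_complex(
            PairwiseProblem(cfg.fva_total, cfg.pt_total, rates.kd_V_PT)
        )
        init["FVa:PT"] = vpt
        init["FVa"] = cfg.fva_total - vpt
        init["PT"] = cfg.pt_total - vpt
    else:
        init["FVa"] = cfg.fva_total
        init["FXa"] = cfg.fxa_total
        init["PT"] = cfg.pt_total
    if cfg.fva_form == "FVai506":
        # the cofactor pool starts as the Arg506-cleaved intermediate
        init["FVai506"] = init.pop("FVa", cfg.fva_total)
    return {k: v for k, v in init.items() if v != 0.0}


def _membrane_for(cfg: ScenarioConfig) -> MembraneCompetition:
    if cfg.membrane is not None:
        return cfg.membrane
    return MembraneCompetition(
        lipid_total=cfg.lipid_total,
        ligands=(
            equilibria.Ligand("PT", cfg.pt_total, 230e-9),
            equilibria.Ligand("FVa", cfg.fva_total, 2.72e-9),
            equilibria.Ligand("APC", cfg.apc_total, 500e-9),
        ),
    )


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Equilibrium pre-processing, integration, and observable extraction."""
    network = build_network(cfg.variant)
    init = _initial_condition(cfg, network)
    apc_eff = effective_apc(
        cfg.apc_total,
        mode=cfg.apc_mode,
        m=_membrane_for(cfg) if cfg.apc_mode == "computed" else None,
    )
    if apc_eff > 0:
        init["APC"] = apc_eff
    n_steps = int(round(cfg.t_end / cfg.sample_dt))
    grid = np.linspace(0.0, cfg.t_end, n_steps + 1)
    tc = simulate(network, init, cfg.t_end, settings=cfg.solver, sample_times=grid)

    obs: dict[str, ObservableSeries] = {}
    for name in cfg.outputs:
        if name == "cofactor_activity":
            obs[name] = cofactor_activity(tc)
        elif name == "prothrombinase_activity":
            obs[name] = prothrombinase_activity(tc)
        else:
            obs[name] = band_series(tc, name)
    return ScenarioResult(cfg, network, tc, obs, init, apc_eff)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSpec:
    """Sweep one parameter over a list of values on a base scenario.

    ``parameter`` is one of ``kd_XV`` (prothrombinase K_D, molar; k_on held
    fixed), ``k_R18`` (M⁻¹s⁻¹), ``apc_total`` (molar) or ``site_total``
    (molar, recomputes the effective APC from the membrane competition).
    """

    parameter: str
    values: tuple[float, ...]
    base: ScenarioConfig

    def __post_init__(self) -> None:
        if self.parameter not in ("kd_XV", "k_R18", "apc_total", "site_total"):
            raise ValueError(f"unknown scan parameter {self.parameter!r}")
        if not self.values:
            raise ValueError("scan requires at least one value")


def _apply(cfg: ScenarioConfig, parameter: str, value: float) -> ScenarioConfig:
    if parameter == "kd_XV":
        return replace(cfg, variant=replace(cfg.variant, kd_XV_override=value))
    if parameter == "k_R18":
        return replace(
            cfg, variant=replace(cfg.variant, include_R18=value > 0, k_R18=value)
        )
    if parameter == "apc_total":
        return replace(cfg, apc_total=value)
    # site_total: switch to computed APC with an explicit site pool
    m = _membrane_for(cfg).with_site_total(value)
    return replace(cfg, apc_mode="computed", membrane=m)


def run_scan(spec: ScanSpec, landmarks: Sequence[float] = (360.0,)) -> "pd.DataFrame":
    """Run the base scenario at each parameter value; summarize each run.

    Returns a tidy table with one row per value: the monoexponential
    initial rate of heavy-chain disappearance (pM/s), the percentage of
    intact heavy chain remaining at each landmark time, and the 1-506 band
    peak time (minutes).
    """
    import pandas as pd

    rows = []
    for value in spec.values:
        cfg = _apply(spec.base, spec.parameter, value)
        result = run_scenario(cfg)
        hc = band_series(result.timecourse, "HC")
        row: dict[str, float] = {spec.parameter: value}
        try:
            row["initial_rate_pM_s"] = initial_rate(
                hc, starting_conc=cfg.fva_total,
                fit_window=min(360.0, cfg.t_end),
            )
        except (RuntimeError, ValueError):
            row["initial_rate_pM_s"] = float("nan")
        for t in landmarks:
            if t <= cfg.t_end:
                row[f"pct_HC_at_{t:g}s"] = 100.0 * hc.value_at(t) / hc.values[0]
        band506 = band_series(result.timecourse, "1-506")
        row["band_1_506_peak_min"] = band506.peak_time() / 60.0
        rows.append(row)
    return pd.DataFrame(rows)
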