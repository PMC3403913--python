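"""Pre-incubation equilibria and membrane binding-site competition.

The modelled experiments pre-form complexes before the protease is added:
FXa (active-site blocked) and/or prothrombin are equilibrated with FVa, and
the equilibrium species concentrations become the ODE initial conditions.
APC is added at t = 0 and is never part of the pre-incubation.

A separate static calculation handles competition for a finite pool of
phospholipid binding sites.  PC:PS vesicles supply roughly one protein site
per 30–60 phospholipids on the accessible outer leaflet; at plasma
prothrombin levels most sites are occupied by prothrombin, which crowds APC
off the membrane.  The membrane-bound APC fraction (~11 % under the
modelled conditions) is the catalytically relevant population fed into the
kinetic model as the "effective" APC concentration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "PairwiseProblem",
    "TernaryPreincubation",
    "Ligand",
    "MembraneCompetition",
    "MembraneResult",
    "pairwise_complex",
    "ternary_preincubation",
    "ternary_report",
    "membrane_bound_fractions",
    "effective_apc",
]


# ---------------------------------------------------------------------------
# Pairwise binding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseProblem:
    """A + B ⇌ AB with totals and dissociation constant, all molar."""

    a_total: float
    b_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.a_total < 0 or self.b_total < 0:
            raise ValueError("totals must be non-negative")
        if self.kd <= 0:
            raise ValueError("kd must be positive")


def pairwise_complex(p: PairwiseProblem) -> float:
    """Equilibrium complex concentration for a single binding pair.

    Solves ``(a_total − x)(b_total − x) = kd·x`` on
    ``[0, min(a_total, b_total)]`` via the numerically stable quadratic
    branch ``x = 2ab / (s + sqrt(s² − 4ab))`` with ``s = a + b + kd``,
    which avoids cancellation when the complex is a small fraction of the
    totals.
    """
    a, b, kd = p.a_total, p.b_total, p.kd
    if a == 0 or b == 0:
        return 0.0
    s = a + b + kd
    disc = s * s - 4.0 * a * b
    return 2.0 * a * b / (s + math.sqrt(disc))


# ---------------------------------------------------------------------------
# Ternary pre-incubation: FVa + FXa + PT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TernaryPreincubation:
    """Simultaneous equilibrium of FVa, FXa* and prothrombin (no lipid term).

    ``kd_xv`` governs FXa·FVa, ``kd_v_pt`` the FVa·PT complex, and
    ``kd_xv_pt`` prothrombin binding to the assembled prothrombinase
    (the Michaelis-like ratio k_off/k_on = 1.03 µM in the final rate set).
    """

    fva_total: float
    fxa_total: float
    pt_total: float
    kd_xv: float = 0.5e-9
    kd_v_pt: float = 700e-9
    kd_xv_pt: float = 1.03e-6

    def __post_init__(self) -> None:
        if min(self.fva_total, self.fxa_total, self.pt_total) < 0:
            raise ValueError("totals must be non-negative")
        if min(self.kd_xv, self.kd_v_pt, self.kd_xv_pt) <= 0:
            raise ValueError("dissociation constants must be positive")


def _ternary_residual_v(v_free: float, p: TernaryPreincubation) -> float:
    """FVa mass-balance residual with free FVa and free PT as the unknowns.

    For a trial free-FVa value the free FXa and free PT follow from their
    own (monotone) mass balances, solved exactly / by inner bracketing.
    """
    pt = _free_pt(v_free, p)
    x = _free_fxa(v_free, pt, p)
    xv = x * v_free / p.kd_xv
    return (
        v_free
        + xv
        + v_free * pt / p.kd_v_pt
        + xv * pt / p.kd_xv_pt
        - p.fva_total
    )


def _free_fxa(v_free: float, pt_free: float, p: TernaryPreincubation) -> float:
    # X_t = X (1 + V/K1 + V·PT/(K1·K3)) — linear in free FXa.
    return p.fxa_total / (
        1.0 + v_free / p.kd_xv + v_free * pt_free / (p.kd_xv * p.kd_xv_pt)
    )


def _free_pt(v_free: float, p: TernaryPreincubation) -> float:
    """Free PT satisfying the PT mass balance at fixed free FVa."""
    if p.pt_total == 0:
        return 0.0

    def g(pt):
        x = _free_fxa(v_free, pt, p)
        xv = x * v_free / p.kd_xv
        return pt + v_free * pt / p.kd_v_pt + xv * pt / p.kd_xv_pt - p.pt_total

    lo, hi = 0.0, p.pt_total
    if g(hi) <= 0:
        return hi
    return brentq(g, lo, hi, xtol=1e-30, rtol=1e-15)


def ternary_preincubation(p: TernaryPreincubation) -> dict[str, float]:
    """Solve the three-component pre-incubation equilibrium.

    Returns the six-species state {FVa, FXa, PT, FXa:FVa, FVa:PT,
    FXa:FVa:PT} in molar, satisfying the three mass-action relations and
    three conservation totals to relative residual < 1e-10.  The result is
    used verbatim as the simulation initial condition.
    """
    if p.fva_total == 0:
        xv = 0.0
        vpt = 0.0
        return {
            "FVa": 0.0,
            "FXa": p.fxa_total,
            "PT": p.pt_total,
            "FXa:FVa": xv,
            "FVa:PT": vpt,
            "FXa:FVa:PT": 0.0,
        }
    lo, hi = 0.0, p.fva_total
    # residual is -fva_total at v=0 and > 0 at v=fva_total: guaranteed bracket
    v = brentq(_ternary_residual_v, lo, hi, args=(p,), xtol=1e-30, rtol=1e-15)
    pt = _free_pt(v, p)
    x = _free_fxa(v, pt, p)
    xv = x * v / p.kd_xv
    state = {
        "FVa": v,
        "FXa": x,
        "PT": pt,
        "FXa:FVa": xv,
        "FVa:PT": v * pt / p.kd_v_pt,
        "FXa:FVa:PT": xv * pt / p.kd_xv_pt,
    }
    _check_ternary_residuals(p, state)
    return state


def _check_ternary_residuals(p: TernaryPreincubation, s: dict[str, float]) -> None:
    scale = max(p.fva_total, p.fxa_total, p.pt_total)
    res = {
        "FVa": s["FVa"] + s["FXa:FVa"] + s["FVa:PT"] + s["FXa:FVa:PT"] - p.fva_total,
        "FXa": s["FXa"] + s["FXa:FVa"] + s["FXa:FVa:PT"] - p.fxa_total,
        "PT": s["PT"] + s["FVa:PT"] + s["FXa:FVa:PT"] - p.pt_total,
    }
    worst = max(abs(r) for r in res.values()) / scale
    if worst > 1e-10:
        raise RuntimeError(
            f"ternary equilibrium did not converge; residuals {res} (rel {worst:.2e})"
        )


def ternary_report(p: TernaryPreincubation) -> dict:
    """Solve the ternary equilibrium and return an audit record as a dict
    (problem, solution, conservation residuals), JSON-serializable."""
    s = ternary_preincubation(p)
    residuals = {
        "FVa": s["FVa"] + s["FXa:FVa"] + s["FVa:PT"] + s["FXa:FVa:PT"] - p.fva_total,
        "FXa": s["FXa"] + s["FXa:FVa"] + s["FXa:FVa:PT"] - p.fxa_total,
        "PT": s["PT"] + s["FVa:PT"] + s["FXa:FVa:PT"] - p.pt_total,
    }
    return {
        "problem": {
            "fva_total_M": p.fva_total,
            "fxa_total_M": p.fxa_total,
            "pt_total_M": p.pt_total,
            "kd_xv_M": p.kd_xv,
            "kd_v_pt_M": p.kd_v_pt,
            "kd_xv_pt_M": p.kd_xv_pt,
        },
        "solution_M": s,
        "residuals_M": residuals,
    }


# ---------------------------------------------------------------------------
# Membrane binding-site competition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ligand:
    name: str
    total: float
    kd_membrane: float

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError("ligand total must be non-negative")
        if self.kd_membrane <= 0:
            raise ValueError("membrane kd must be positive")


def default_ligands(apc_total: float = 2e-9) -> tuple[Ligand, ...]:
    """The modelled plasma-level ligand panel: PT, FVa, APC."""
    return (
        Ligand("PT", 1.4e-6, 230e-9),
        Ligand("FVa", 20e-9, 2.72e-9),
        Ligand("APC", apc_total, 500e-9),
    )


@dataclass(frozen=True)
class MembraneCompetition:
    """Competition of several ligands for a shared pool of membrane sites.

    ``site_total`` may be given directly; otherwise it is derived as
    ``lipid_total × accessible_fraction / lipids_per_site``.  Only the
    outer leaflet (2/3 of the lipid) is accessible; one protein site per
    30–60 phospholipids brackets the plausible density, so 20 µM lipid
    yields 222–444 nM sites.
    """

    lipid_total: float = 20e-6
    lipids_per_site: float = 45.0
    accessible_fraction: float = 2.0 / 3.0
    ligands: tuple[Ligand, ...] = field(default_factory=default_ligands)
    site_total_override: float | None = None

    LIPIDS_PER_SITE_RANGE = (30.0, 60.0)

    @property
    def site_total(self) -> float:
        if self.site_total_override is not None:
            st = self.site_total_override
        else:
            st = self.lipid_total * self.accessible_fraction / self.lipids_per_site
        if st <= 0:
            raise ValueError("site_total must be positive")
        return st

    def site_range(self) -> tuple[float, float]:
        """Site totals at the sparse (60) and dense (30) packing bounds."""
        lo_ratio, hi_ratio = self.LIPIDS_PER_SITE_RANGE
        base = self.lipid_total * self.accessible_fraction
        return base / hi_ratio, base / lo_ratio

    def with_site_total(self, site_total: float) -> "MembraneCompetition":
        from dataclasses import replace

        return replace(self, site_total_override=site_total)


@dataclass(frozen=True)
class MembraneResult:
    site_total: float
    free_sites: float
    bound: dict[str, float]        # molar ligand bound
    bound_fraction: dict[str, float]   # bound / ligand total
    site_occupancy: dict[str, float]   # bound / site_total

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {
                "site_total_M": self.site_total,
                "free_sites_M": self.free_sites,
                "bound_M": self.bound,
                "bound_fraction": self.bound_fraction,
                "site_occupancy": self.site_occupancy,
            },
            indent=indent,
        )


def membrane_bound_fractions(m: MembraneCompetition) -> MembraneResult:
    """Solve the shared-site competitive binding equilibrium.

    With free sites S, each ligand binds ``bound_i = L_i·S/(kd_i + S)``
    (from bound_i = S·free_i/kd_i and free_i = L_i − bound_i); S is the
    root of ``S + Σ bound_i(S) = site_total`` on [0, site_total], found by
    bracketed root finding.
    """
    st = m.site_total

    def g(s: float) -> float:
        return s + sum(l.total * s / (l.kd_membrane + s) for l in m.ligands) - st

    s = brentq(g, 0.0, st, xtol=1e-30, rtol=1e-15)
    bound = {l.name: l.total * s / (l.kd_membrane + s) for l in m.ligands}
    frac = {l.name: s / (l.kd_membrane + s) for l in m.ligands}
    occ = {name: b / st for name, b in bound.items()}
    return MembraneResult(st, s, bound, frac, occ)


def effective_apc(
    apc_total: float,
    mode: str = "fixed_fraction",
    m: MembraneCompetition | None = None,
    fixed_fraction: float = 0.11,
) -> float:
    """Catalytically relevant (membrane-bound) APC concentration.

    ``fixed_fraction`` applies the modelled 11 % bound fraction directly;
    ``computed`` solves the membrane competition (``m`` required, with APC
    among its ligands); ``raw`` returns the total unchanged.
    """
    if apc_total < 0:
        raise ValueError("apc_total must be non-negative")
    if mode == "raw":
        return apc_total
    if mode == "fixed_fraction":
        return fixed_fraction * apc_total
    if mode == "computed":
        if m is None:
            raise ValueError("computed mode requires a MembraneCompetition")
        result = membrane_bound_fractions(m)
        if "APC" not in result.bound_fraction:
            raise ValueError("membrane competition must include an APC ligand")
        return result.bound_fraction["APC"] * apc_total
    raise ValueError(f"unknown effective-APC mode {mode!r}")
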