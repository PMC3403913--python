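"""Reaction network for APC inactivation of factor Va and prothrombinase.

The model tracks 24 species: free activated protein C (APC), intact factor Va
(FVa) and its partially proteolyzed forms (cleaved at Arg506, Arg306, or both),
the fully inactivated cofactor (the FVa(1-306)·light-chain dimer, written
``FVai``), free heavy-chain fragments, factor Xa (FXa, active-site blocked in
all modelled experiments), prothrombin (PT), and every binary/ternary complex
among them that the model permits.  24 reactions (counting each reversible
equilibrium once) connect them under mass-action kinetics with 14 named rate
constants.

Cleavage is random-order: APC cleaves FVa heavy chain at Arg506 (fast) and
Arg306 (slow) independently.  Partially cleaved species retain their fragments
non-covalently; the Arg306-cleaved forms spontaneously shed their C-terminal
fragments, which is the step that destroys cofactor activity.  FXa and PT
protect FVa by sequestering it in complexes that APC cannot attack — with one
exception, the reaction labelled ``R18``: APC can cleave Arg306 of the
Arg506-cleaved cofactor while it remains bound to FXa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SPECIES",
    "MOIETIES",
    "FRAGMENTS",
    "Reaction",
    "RateConstantSet",
    "NetworkVariant",
    "ReactionNetwork",
    "build_network",
    "moiety_matrix",
]

# ---------------------------------------------------------------------------
# Species inventory
# ---------------------------------------------------------------------------

#: The 24 model species, in canonical order.  ``FVai506`` etc. denote FVa
#: cleaved at Arg506 with all heavy-chain fragments still associated;
#: ``FVai`` is the inactive FVa(1-306)·FVa(LC) dimer left after fragment
#: dissociation; ``frag*`` are free heavy-chain fragments.
SPECIES: tuple[str, ...] = (
    "APC",
    "FVa",
    "APC:FVa",
    "FVai506",
    "FVai306",
    "APC:FVai506",
    "APC:FVai306",
    "FVai306/506",
    "FVai",
    "APC:FVai",
    "frag307-679/709",
    "frag307-506",
    "frag507-679/709",
    "FXa",
    "FXa:FVa",
    "FXa:FVai506",
    "FXa:FVai306",
    "FXa:FVai306/506",
    "PT",
    "FVa:PT",
    "FXa:FVa:PT",
    "FXa:FVai506:PT",
    "FXa:FVai306:PT",
    "FXa:FVai306/506:PT",
)

SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: Conserved moieties.  The heavy chain is tracked as its three proteolytic
#: segments (1-306, 307-506, 507-679/709): cleavage rearranges fragments but
#: never creates or destroys a segment, so each segment total is conserved.
MOIETIES: tuple[str, ...] = (
    "APC",
    "FXa",
    "PT",
    "LC",
    "seg1-306",
    "seg307-506",
    "seg507-709",
)

# Core cofactor forms: (LC, seg A, seg B, seg C), and the Western-blot
# fragments each form carries (associated fragments are still detected).
_CORES: dict[str, tuple[tuple[int, int, int, int], dict[str, int]]] = {
    "FVa": ((1, 1, 1, 1), {"HC": 1}),
    "FVai506": ((1, 1, 1, 1), {"1-506": 1, "507-679/709": 1}),
    "FVai306": ((1, 1, 1, 1), {"1-306": 1, "307-679/709": 1}),
    "FVai306/506": ((1, 1, 1, 1), {"1-306": 1, "307-506": 1, "507-679/709": 1}),
    "FVai": ((1, 1, 0, 0), {"1-306": 1}),
}

#: Western-blot band identities (fragment classes detected on reducing gels).
FRAGMENTS: tuple[str, ...] = (
    "HC",
    "1-506",
    "1-306",
    "307-679/709",
    "307-506",
    "507-679/709",
)


def _species_record(name: str) -> tuple[dict[str, int], dict[str, int]]:
    """Return (moiety composition, fragment content) for one species name."""
    comp = {m: 0 for m in MOIETIES}
    frags: dict[str, int] = {}
    parts = name.split(":")
    core = None
    for part in parts:
        if part == "APC":
            comp["APC"] += 1
        elif part == "FXa":
            comp["FXa"] += 1
        elif part == "PT":
            comp["PT"] += 1
        elif part in _CORES:
            core = part
        elif part.startswith("frag"):
            frags[part[4:]] = 1
            seg = part[4:]
            if seg == "307-679/709":
                comp["seg307-506"] += 1
                comp["seg507-709"] += 1
            elif seg == "307-506":
                comp["seg307-506"] += 1
            elif seg == "507-679/709":
                comp["seg507-709"] += 1
        else:  # pragma: no cover - species table is static
            raise ValueError(f"unrecognized species component {part!r}")
    if core is not None:
        (lc, a, b, c), corefrags = _CORES[core]
        comp["LC"] += lc
        comp["seg1-306"] += a
        comp["seg307-506"] += b
        comp["seg507-709"] += c
        for f, n in corefrags.items():
            frags[f] = frags.get(f, 0) + n
    return comp, frags


COMPOSITION: dict[str, dict[str, int]] = {}
SPECIES_FRAGMENTS: dict[str, dict[str, int]] = {}
for _name in SPECIES:
    COMPOSITION[_name], SPECIES_FRAGMENTS[_name] = _species_record(_name)
del _name


# ---------------------------------------------------------------------------
# Rate constants and variants
# ---------------------------------------------------------------------------

RATE_CONSTANT_NAMES: tuple[str, ...] = (
    "k_on_APC_FVa",
    "k_off_APC_FVa",
    "k_cat_506",
    "k_cat_306",
    "k_dis_free",
    "k_on_XV",
    "k_off_XV",
    "k_off_XVi",
    "k_dis_bound",
    "k_on_V_PT",
    "k_off_V_PT",
    "k_on_XV_PT",
    "k_off_XV_PT",
    "k_R18",
)


@dataclass(frozen=True)
class RateConstantSet:
    """The 14 named rate constants of the full model.

    Association constants (``k_on_*``) are in M⁻¹ s⁻¹; everything else in
    s⁻¹ except ``k_R18`` which is the second-order constant (M⁻¹ s⁻¹) for APC
    cleavage of Arg306 in the FXa-bound Arg506-cleaved cofactor.
    """

    k_on_APC_FVa: float = 1e8
    k_off_APC_FVa: float = 0.7
    k_cat_506: float = 1.0
    k_cat_306: float = 0.192
    k_dis_free: float = 0.028
    k_on_XV: float = 1.5e8
    k_off_XV: float = 0.075
    k_off_XVi: float = 0.15
    k_dis_bound: float = 0.0035
    k_on_V_PT: float = 1e8
    k_off_V_PT: float = 70.0
    k_on_XV_PT: float = 1.0e8
    k_off_XV_PT: float = 103.0
    k_R18: float = 5.0e6

    def __post_init__(self) -> None:
        for name in RATE_CONSTANT_NAMES:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"rate constant {name} must be non-negative, got {v}")

    def __getitem__(self, name: str) -> float:
        if name not in RATE_CONSTANT_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_CONSTANT_NAMES}

    # Derived equilibrium constants (M) -----------------------------------
    @property
    def kd_APC_FVa(self) -> float:
        return self.k_off_APC_FVa / self.k_on_APC_FVa

    @property
    def kd_XV(self) -> float:
        return self.k_off_XV / self.k_on_XV

    @property
    def kd_XVi(self) -> float:
        return self.k_off_XVi / self.k_on_XV

    @property
    def kd_V_PT(self) -> float:
        return self.k_off_V_PT / self.k_on_V_PT

    @property
    def kd_XV_PT(self) -> float:
        return self.k_off_XV_PT / self.k_on_XV_PT

    def second_order_cleavage_rate(self, site: str) -> float:
        """Lumped second-order constant k_cat / K_D for a cleavage site.

        For the enzyme-substrate equilibrium being fast relative to
        catalysis, the overall cleavage process APC + FVa -> APC + product
        behaves as a bimolecular reaction with rate k_cat * k_on / k_off.
        """
        kcat = {"Arg506": self.k_cat_506, "Arg306": self.k_cat_306}[site]
        return kcat / self.kd_APC_FVa


_XV_RATE_SETS = {
    # k_on (M-1 s-1), k_off intact (s-1), k_off partially cleaved (s-1)
    "initial_a": (4.0e8, 0.2, 0.4),
    "final_b": (1.5e8, 0.075, 0.15),
}

_ARG306_RATES = {"hockin": 0.064, "current": 0.192}


@dataclass(frozen=True)
class NetworkVariant:
    """Selects among the published rate-constant alternatives.

    Parameters
    ----------
    arg306_rate:
        ``"current"`` uses the human-adjusted Arg306 catalytic constant
        0.192 s⁻¹; ``"hockin"`` the original bovine-derived 0.064 s⁻¹.
    xv_rate_set:
        ``"final_b"``: prothrombinase assembly with k_on 1.5e8 M⁻¹s⁻¹ and
        k_off 0.075 s⁻¹ (K_D 0.5 nM); ``"initial_a"``: k_on 4e8, k_off 0.2.
        The FVa_i complexes always carry a K_D twice the intact value.
    include_R18:
        Whether APC may cleave Arg306 of FXa-bound FVai506.
    k_R18:
        Second-order constant for that reaction (M⁻¹ s⁻¹).
    kd_XV_override:
        If set (molar), rescale k_off to give this prothrombinase K_D while
        holding the variant's k_on fixed; the FVa_i-complex k_off is scaled
        to keep its K_D at twice the intact value.
    """

    arg306_rate: str = "current"
    xv_rate_set: str = "final_b"
    include_R18: bool = True
    k_R18: float = 5.0e6
    kd_XV_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.arg306_rate not in _ARG306_RATES:
            raise ValueError(
                f"unknown arg306_rate {self.arg306_rate!r}; "
                f"expected one of {sorted(_ARG306_RATES)}"
            )
        if self.xv_rate_set not in _XV_RATE_SETS:
            raise ValueError(
                f"unknown xv_rate_set {self.xv_rate_set!r}; "
                f"expected one of {sorted(_XV_RATE_SETS)}"
            )
        if self.k_R18 < 0:
            raise ValueError("k_R18 must be non-negative")
        if self.kd_XV_override is not None and self.kd_XV_override <= 0:
            raise ValueError("kd_XV_override must be positive")

    def rate_constants(self) -> RateConstantSet:
        k_on_xv, k_off_xv, k_off_xvi = _XV_RATE_SETS[self.xv_rate_set]
        if self.kd_XV_override is not None:
            k_off_xv = self.kd_XV_override * k_on_xv
            k_off_xvi = 2.0 * self.kd_XV_override * k_on_xv
        return RateConstantSet(
            k_cat_306=_ARG306_RATES[self.arg306_rate],
            k_on_XV=k_on_xv,
            k_off_XV=k_off_xv,
            k_off_XVi=k_off_xvi,
            k_R18=self.k_R18 if self.include_R18 else 0.0,
        )

    def to_dict(self) -> dict:
        return {
            "arg306_rate": self.arg306_rate,
            "xv_rate_set": self.xv_rate_set,
            "include_R18": self.include_R18,
            "k_R18": self.k_R18,
            "kd_XV_override": self.kd_XV_override,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkVariant":
        return cls(**d)


# ---------------------------------------------------------------------------
# Reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action step.

    Reversible equilibria from the tables are stored as two ``Reaction``
    objects sharing a ``table_id`` (suffixes ``.f``/``.r``); the model's
    headline count of 24 reactions counts each table row once.
    """

    id: str
    table_id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_name: str
    catalysts: tuple[str, ...] = ()

    @property
    def order(self) -> int:
        return len(self.reactants) + len(self.catalysts)

    def stoichiometry(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for s in self.reactants:
            net[s] = net.get(s, 0) - 1
        for s in self.products:
            net[s] = net.get(s, 0) + 1
        return net


def _rev(table_id, a, b, ab, k_on, k_off):
    return [
        Reaction(f"{table_id}.f", table_id, (a, b), (ab,), k_on),
        Reaction(f"{table_id}.r", table_id, (ab,), (a, b), k_off),
    ]


def _irr(table_id, reactants, products, k, catalysts=()):
    return [Reaction(table_id, table_id, tuple(reactants), tuple(products), k, tuple(catalysts))]


def _reaction_table(include_R18: bool) -> list[Reaction]:
    rxns: list[Reaction] = []
    # --- APC cleavage of the free cofactor species ---
    rxns += _rev("R1", "APC", "FVa", "APC:FVa", "k_on_APC_FVa", "k_off_APC_FVa")
    rxns += _irr("R2", ["APC:FVa"], ["APC", "FVai506"], "k_cat_506")
    rxns += _irr("R3", ["APC:FVa"], ["APC", "FVai306"], "k_cat_306")
    rxns += _rev("R4", "APC", "FVai506", "APC:FVai506", "k_on_APC_FVa", "k_off_APC_FVa")
    rxns += _rev("R5", "APC", "FVai306", "APC:FVai306", "k_on_APC_FVa", "k_off_APC_FVa")
    rxns += _irr("R6", ["APC:FVai506"], ["APC", "FVai306/506"], "k_cat_306")
    rxns += _irr("R7", ["APC:FVai306"], ["APC", "FVai306/506"], "k_cat_506")
    rxns += _irr("R8", ["FVai306"], ["FVai", "frag307-679/709"], "k_dis_free")
    rxns += _irr(
        "R9", ["FVai306/506"], ["FVai", "frag307-506", "frag507-679/709"], "k_dis_free"
    )
    rxns += _rev("R10", "APC", "FVai", "APC:FVai", "k_on_APC_FVa", "k_off_APC_FVa")
    # --- prothrombinase assembly and fragment shedding while FXa-bound ---
    rxns += _rev("R11", "FXa", "FVa", "FXa:FVa", "k_on_XV", "k_off_XV")
    rxns += _rev("R12", "FXa", "FVai506", "FXa:FVai506", "k_on_XV", "k_off_XVi")
    rxns += _rev("R13", "FXa", "FVai306", "FXa:FVai306", "k_on_XV", "k_off_XVi")
    rxns += _rev("R14", "FXa", "FVai306/506", "FXa:FVai306/506", "k_on_XV", "k_off_XVi")
    rxns += _irr("R15", ["FXa:FVai306"], ["FXa", "FVai", "frag307-679/709"], "k_dis_bound")
    rxns += _irr(
        "R16",
        ["FXa:FVai306/506"],
        ["FXa", "FVai", "frag307-506", "frag507-679/709"],
        "k_dis_bound",
    )
    # --- prothrombin binding ---
    rxns += _rev("R17", "FVa", "PT", "FVa:PT", "k_on_V_PT", "k_off_V_PT")
    if include_R18:
        # The reaction identified in this model: APC cleaves Arg306 of the
        # Arg506-cleaved cofactor while bound to FXa; single bimolecular step
        # with APC acting catalytically (no Michaelis complex).
        rxns += _irr(
            "R18",
            ["FXa:FVai506"],
            ["FXa:FVai306/506"],
            "k_R18",
            catalysts=["APC"],
        )
    rxns += _rev("R19", "FXa:FVa", "PT", "FXa:FVa:PT", "k_on_XV_PT", "k_off_XV_PT")
    rxns += _rev("R20", "FXa:FVai506", "PT", "FXa:FVai506:PT", "k_on_XV_PT", "k_off_XV_PT")
    rxns += _rev("R21", "FXa:FVai306", "PT", "FXa:FVai306:PT", "k_on_XV_PT", "k_off_XV_PT")
    rxns += _rev(
        "R22", "FXa:FVai306/506", "PT", "FXa:FVai306/506:PT", "k_on_XV_PT", "k_off_XV_PT"
    )
    rxns += _irr(
        "R23",
        ["FXa:FVai306:PT"],
        ["FXa", "FVai", "frag307-679/709", "PT"],
        "k_dis_bound",
    )
    rxns += _irr(
        "R24",
        ["FXa:FVai306/506:PT"],
        ["FXa", "PT", "FVai", "frag307-506", "frag507-679/709"],
        "k_dis_bound",
    )
    return rxns


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionNetwork:
    """The assembled mass-action system: species, elementary steps, rates."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    rates: RateConstantSet
    variant: NetworkVariant

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        """Number of reactions counting each reversible pair once."""
        return len({r.table_id for r in self.reactions})

    @property
    def n_unique_rate_constants(self) -> int:
        """Number of distinct named rate constants the network references."""
        return len({r.rate_name for r in self.reactions})

    def species_index(self, name: str) -> int:
        return SPECIES_INDEX[name]

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (n_species, n_elementary_steps)."""
        n = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s, nu in rxn.stoichiometry().items():
                n[SPECIES_INDEX[s], j] += nu
        return n

    # -- serialization ----------------------------------------------------
    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "species": list(self.species),
            "reactions": [
                {
                    "id": r.id,
                    "table_id": r.table_id,
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "rate_name": r.rate_name,
                    "catalysts": list(r.catalysts),
                }
                for r in self.reactions
            ],
            "rate_constants": self.rates.as_dict(),
            "variant": self.variant.to_dict(),
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        payload = json.loads(text)
        reactions = tuple(
            Reaction(
                id=r["id"],
                table_id=r["table_id"],
                reactants=tuple(r["reactants"]),
                products=tuple(r["products"]),
                rate_name=r["rate_name"],
                catalysts=tuple(r.get("catalysts", ())),
            )
            for r in payload["reactions"]
        )
        return cls(
            species=tuple(payload["species"]),
            reactions=reactions,
            rates=RateConstantSet(**payload["rate_constants"]),
            variant=NetworkVariant.from_dict(payload["variant"]),
        )

    def with_variant(self, **changes) -> "ReactionNetwork":
        return build_network(replace(self.variant, **changes))


def build_network(variant: NetworkVariant | None = None) -> ReactionNetwork:
    """Assemble the full reaction network for a rate-constant variant.

    With ``include_R18`` the network has 24 species, 24 reactions and 14
    named rate constants; without it, 23 reactions.  Every reaction is
    mass-balanced at the moiety level (checked on construction).
    """
    if variant is None:
        variant = NetworkVariant()
    rates = variant.rate_constants()
    reactions = tuple(_reaction_table(variant.include_R18))
    net = ReactionNetwork(SPECIES, reactions, rates, variant)
    _check_moiety_balance(net)
    return net


def moiety_matrix(network: ReactionNetwork) -> tuple[tuple[str, ...], np.ndarray]:
    """Matrix mapping species to conserved moieties.

    Returns ``(moiety_names, M)`` with ``M`` of shape
    (n_moieties, n_species); ``M @ stoichiometry_matrix() == 0``.
    """
    m = np.zeros((len(MOIETIES), len(network.species)))
    for j, sp in enumerate(network.species):
        for i, moi in enumerate(MOIETIES):
            m[i, j] = COMPOSITION[sp][moi]
    return MOIETIES, m


def _check_moiety_balance(net: ReactionNetwork) -> None:
    _, m = moiety_matrix(net)
    imbalance = m @ net.stoichiometry_matrix()
    if not np.allclose(imbalance, 0):  # pragma: no cover - static table
        bad = np.argwhere(np.abs(imbalance) > 0)
        raise AssertionError(f"moiety imbalance in reactions {bad}")
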