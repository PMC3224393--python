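"""Reaction network for EGFR-ERK signal transduction in H1299-derived cells.

The model tracks signal flow from EGF binding at the receptor down to doubly
phosphorylated ERK through 27 reaction steps over 29 components: 27 dynamic
states (including a terminal degradation sink that keeps receptor mass
auditable) plus two constitutively constant phosphatases (PP2A, MKP3) whose
abundance enters the MEK/ERK dephosphorylation Vmax terms.

Receptor-proximal steps (ligand binding, dimerization, autophosphorylation,
adaptor recruitment) follow mass-action kinetics; receptor dephosphorylation
(step 4), ShcP dephosphorylation (step 11) and the whole Ras/Raf/MEK/ERK
cascade (steps 15-27) follow Michaelis-Menten kinetics.

Units: concentrations in nM, time in minutes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RateLaw",
    "Species",
    "Reaction",
    "ParameterSet",
    "ModelVariant",
    "ReactionNetwork",
    "build_reference_network",
    "make_variant",
    "rate",
    "conservation_pools",
    "receptor_pool_weights",
    "VARIANT_NAMES",
    "DEFAULT_VARIANT_SETTINGS",
    "reference_variants",
    "MIG6_PARAMETERS",
]

# A phosphorylated dimer carries two receptor equivalents but is counted ONCE
# toward the phospho-EGFR observable (densitometry sees one band per dimer).
# Set to 2 to adopt the per-receptor-equivalent convention instead.
DIMER_OBSERVABLE_WEIGHT = 1

#: The four rate constants reduced by Mig6 in the L858R model A.
MIG6_PARAMETERS = ("k3", "k5", "k7", "k8")

VARIANT_NAMES = ("WT", "EGFR_WT", "L858R_A", "L858R_B")


class RateLaw(str, enum.Enum):
    MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
    MASS_ACTION_REVERSIBLE = "mass_action_reversible"
    MICHAELIS_MENTEN = "michaelis_menten"


@dataclass(frozen=True)
class Species:
    """A model component.

    ``is_dynamic`` distinguishes ODE states from constitutively constant
    entities (the PP2A and MKP3 phosphatase pools).
    """

    id: str
    display_name: str = ""
    initial_concentration: float = 0.0
    is_dynamic: bool = True

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValueError(
                f"species {self.id!r}: negative initial concentration"
            )
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id)


@dataclass(frozen=True)
class Reaction:
    """One numbered reaction step.

    ``reactants``/``products`` map species id -> stoichiometric coefficient.
    Mass action uses parameters ``kf`` (and ``kr`` when reversible); MM uses
    either ``V``+``Km`` (phosphatase folded into the Vmax) or ``kcat``+``Km``
    with ``modifier`` naming the catalytic species.
    """

    step_index: int
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    law: RateLaw
    parameters: Mapping[str, str]  # role -> parameter name, roles: kf/kr/V/kcat/Km
    modifier: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.step_index <= 27:
            raise ValueError(f"step_index {self.step_index} outside 1..27")
        if self.law is RateLaw.MICHAELIS_MENTEN:
            if "Km" not in self.parameters:
                raise ValueError(f"step {self.step_index}: MM law needs Km")
            if ("kcat" in self.parameters) != (self.modifier is not None):
                raise ValueError(
                    f"step {self.step_index}: kcat requires a modifier species"
                )
            if "kcat" not in self.parameters and "V" not in self.parameters:
                raise ValueError(f"step {self.step_index}: MM law needs V or kcat")
            if len(self.reactants) != 1:
                raise ValueError(f"step {self.step_index}: MM law needs one substrate")
        else:
            # mass action may carry a modifier multiplying the forward rate
            # (used for the undepleted extracellular EGF bath in step 1)
            if "kf" not in self.parameters:
                raise ValueError(f"step {self.step_index}: mass action needs kf")
            if (self.law is RateLaw.MASS_ACTION_REVERSIBLE) != (
                "kr" in self.parameters
            ):
                raise ValueError(
                    f"step {self.step_index}: kr iff reversible mass action"
                )


class ParameterSet:
    """Positive kinetic constants plus optional (low, high) search bounds."""

    def __init__(
        self,
        values: Mapping[str, float],
        bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        self.values: dict[str, float] = dict(values)
        self.bounds: dict[str, tuple[float, float]] = dict(bounds or {})
        for name, v in self.values.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be positive finite, got {v}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi):
                raise ValueError(f"bad bounds for {name!r}: ({lo}, {hi})")
            if name in self.values and not (lo <= self.values[name] <= hi):
                raise ValueError(
                    f"parameter {name!r}={self.values[name]} outside bounds ({lo}, {hi})"
                )

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise KeyError(f"missing parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.bounds))

    def updated(self, overrides: Mapping[str, float]) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(overrides)
        # widen bounds where an override falls outside the original box
        bounds = {
            n: (min(lo, vals.get(n, lo)), max(hi, vals.get(n, hi)))
            for n, (lo, hi) in self.bounds.items()
        }
        return ParameterSet(vals, bounds)

    def scaled(self, multipliers: Mapping[str, float]) -> "ParameterSet":
        vals = dict(self.values)
        for name, f in multipliers.items():
            if name not in vals:
                raise KeyError(f"missing parameter {name!r}")
            if not f > 0:
                raise ValueError(f"multiplier for {name!r} must be positive")
            vals[name] = vals[name] * f
        # Multiplied values may leave the original search box on purpose
        # (e.g. Mig6-slowed constants); drop bounds checks by widening.
        bounds = {
            n: (min(lo, vals.get(n, lo)), max(hi, vals.get(n, hi)))
            for n, (lo, hi) in self.bounds.items()
        }
        return ParameterSet(vals, bounds)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ParameterSet)
            and self.values == other.values
            and self.bounds == other.bounds
        )

    def __repr__(self) -> str:
        return f"ParameterSet({len(self.values)} values, {len(self.bounds)} bounds)"


@dataclass(frozen=True)
class ModelVariant:
    """A cell-line model: shared network + initial/parameter overrides.

    Variants never mutate the shared base; simulation applies overrides on
    copies.
    """

    name: str
    network: "ReactionNetwork"
    initial_overrides: Mapping[str, float] = field(default_factory=dict)
    parameter_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant name {self.name!r}")
        for sid, c in self.initial_overrides.items():
            if c < 0:
                raise ValueError(f"negative concentration override for {sid!r}")
        for pname, f in self.parameter_multipliers.items():
            if not f > 0:
                raise ValueError(f"non-positive multiplier for {pname!r}")

    def effective_parameters(self) -> ParameterSet:
        if not self.parameter_multipliers:
            return self.network.parameters.copy()
        return self.network.parameters.scaled(self.parameter_multipliers)

    def effective_initials(self) -> dict[str, float]:
        init = {s.id: s.initial_concentration for s in self.network.species}
        init.update(self.initial_overrides)
        return init


class ReactionNetwork:
    """Species, 27 numbered reactions, and the shared kinetic parameters."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        parameters: ParameterSet,
    ) -> None:
        self.species = list(species)
        self.reactions = sorted(reactions, key=lambda r: r.step_index)
        self.parameters = parameters
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        steps = [r.step_index for r in self.reactions]
        if steps != list(range(1, len(steps) + 1)):
            raise ValueError("step indices must cover 1..n without gaps")
        self._index = {sid: i for i, sid in enumerate(ids)}
        known = set(ids)
        for r in self.reactions:
            for sid in (*r.reactants, *r.products):
                if sid not in known:
                    raise ValueError(f"step {r.step_index}: unknown species {sid!r}")
            if r.modifier is not None and r.modifier not in known:
                raise ValueError(f"step {r.step_index}: unknown modifier {r.modifier!r}")
            for pname in r.parameters.values():
                if pname not in parameters:
                    raise ValueError(
                        f"step {r.step_index}: parameter {pname!r} not in ParameterSet"
                    )

    # -- structure ---------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def dynamic_species_ids(self) -> list[str]:
        return [s.id for s in self.species if s.is_dynamic]

    def index_of(self, species_id: str) -> int:
        return self._index[species_id]

    def initial_state(self) -> dict[str, float]:
        return {s.id: s.initial_concentration for s in self.species}

    def stoichiometry_matrix(self) -> np.ndarray:
        """Species x reactions net-stoichiometry matrix (modifiers excluded)."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, nu in r.reactants.items():
                S[self._index[sid], j] -= nu
            for sid, nu in r.products.items():
                S[self._index[sid], j] += nu
        return S

    def with_parameters(self, parameters: ParameterSet) -> "ReactionNetwork":
        return ReactionNetwork(self.species, self.reactions, parameters)


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def rate(
    reaction: Reaction,
    state: Mapping[str, float],
    params: ParameterSet,
) -> float:
    """Net flux (nM/min) of one reaction at the given concentrations.

    Mass action: kf * prod(reactants) - kr * prod(products) (kr = 0 when
    irreversible). MM: V * S / (Km + S) with V = kcat * [modifier] when a
    catalytic species is declared. Concentrations are clamped at zero so
    solver undershoot cannot generate spurious negative fluxes.
    """
    conc = lambda sid: max(float(state[sid]), 0.0)
    if reaction.law is RateLaw.MICHAELIS_MENTEN:
        Km = params[reaction.parameters["Km"]]
        if Km <= 0:
            raise ValueError(f"step {reaction.step_index}: Km <= 0")
        (substrate, nu), = reaction.reactants.items()
        S = conc(substrate)
        if "kcat" in reaction.parameters:
            V = params[reaction.parameters["kcat"]] * conc(reaction.modifier)
        else:
            V = params[reaction.parameters["V"]]
        return V * S / (Km + S)
    fwd = params[reaction.parameters["kf"]]
    if reaction.modifier is not None:
        fwd *= conc(reaction.modifier)
    for sid, nu in reaction.reactants.items():
        fwd *= conc(sid) ** nu
    rev = 0.0
    if "kr" in reaction.parameters:
        rev = params[reaction.parameters["kr"]]
        for sid, nu in reaction.products.items():
            rev *= conc(sid) ** nu
    return fwd - rev


# ---------------------------------------------------------------------------
# Reference network
# ---------------------------------------------------------------------------

def _ma(step, reactants, products, name, reversible=True, modifier=None):
    params = {"kf": f"k{step}"}
    law = RateLaw.MASS_ACTION_IRREVERSIBLE
    if reversible:
        params["kr"] = f"k{step}r"
        law = RateLaw.MASS_ACTION_REVERSIBLE
    return Reaction(step, reactants, products, law, params,
                    modifier=modifier, name=name)


def _mm(step, substrate, product, name, modifier=None):
    if modifier is None:
        params = {"V": f"V{step}", "Km": f"Km{step}"}
    else:
        params = {"kcat": f"kcat{step}", "Km": f"Km{step}"}
    return Reaction(
        step, {substrate: 1}, {product: 1}, RateLaw.MICHAELIS_MENTEN,
        params, modifier=modifier, name=name,
    )


#: Reference initial concentrations (nM) for the H1299 wild-type model.
#: Adaptor/kinase pools are shared by all cell lines; only EGFR (EGFR-WT,
#: L858R) and Cbl (L858R model B) differ between variants.
_REFERENCE_INITIALS = {
    "EGF": 0.0,       # set by the stimulus protocol at t = 0
    "EGFR": 90.0,     # low endogenous receptor level in H1299 WT
    "Cbl": 85.0,
    "GAP": 70.0,
    "Shc": 150.0,
    "GS": 40.0,       # pre-formed Grb2/SOS pool
    "RasGDP": 120.0,
    "Raf1": 100.0,
    "MEK": 120.0,
    "ERK": 300.0,
    "PP2A": 11.0,
    "MKP3": 2.4,
}

_CONSTANT_SPECIES = ("PP2A", "MKP3")

_DISPLAY = {
    "EGFR": "EGFR monomer",
    "Ra": "EGF/EGFR complex",
    "E11": "EGFR homodimer",
    "E11P": "phosphorylated EGFR homodimer",
    "E11deg": "degraded receptor sink",
    "GS": "Grb2/SOS",
    "E11P_Cbl": "E11P/Cbl",
    "E11P_GAP": "E11P/GAP",
    "E11P_Shc": "E11P/Shc",
    "E11P_ShcP": "E11P/ShcP",
    "E11P_ShcP_GS": "E11P/ShcP/Grb2/SOS",
    "ShcP_GS": "ShcP/Grb2/SOS",
    "Raf1A": "activated Raf1",
    "MEKP": "singly phosphorylated MEK",
    "MEKPP": "doubly phosphorylated MEK",
    "ERKP": "singly phosphorylated ERK",
    "ERKPP": "doubly phosphorylated ERK",
}

_SPECIES_ORDER = [
    "EGF", "EGFR", "Ra", "E11", "E11P", "Cbl", "E11P_Cbl", "E11deg",
    "GAP", "E11P_GAP", "Shc", "E11P_Shc", "E11P_ShcP", "ShcP", "GS",
    "E11P_ShcP_GS", "ShcP_GS", "RasGDP", "RasGTP", "Raf1", "Raf1A",
    "MEK", "MEKP", "MEKPP", "ERK", "ERKP", "ERKPP", "PP2A", "MKP3",
]


#: Reference kinetic constants (nM, min). Receptor-block values descend from
#: the classic EGFR short-term-signaling model, the MAPK-block values from
#: the canonical MAPK-cascade model, both rescaled to this unit system and
#: adjusted so the reference cell-line variants reproduce the qualitative
#: H1299 behaviors the package documents (see docs/methods.md).
_REFERENCE_PARAMETERS = {
    # 1: EGF + EGFR <-> Ra (EGF as undepleted bath)
    "k1": 0.0075, "k1r": 0.24,
    # 2: Ra + Ra <-> E11
    "k2": 0.06, "k2r": 0.6,
    # 3: E11 <-> E11P (autophosphorylation; gefitinib and Mig6 slow k3)
    "k3": 30.0, "k3r": 0.6,
    # 4: E11P -> E11 (receptor PTP, Vmax form; Km above working range so
    # dephosphorylation stays near first order and upstream responses to
    # gefitinib remain proportional across cell lines)
    "V4": 60000.0, "Km4": 1000.0,
    # 5: E11P + Cbl <-> E11P/Cbl
    "k5": 0.012, "k5r": 0.12,
    # 6: E11P/Cbl -> Cbl + degraded receptor
    "k6": 0.3,
    # 7: E11P + GAP <-> E11P/GAP
    "k7": 0.06, "k7r": 3.0,
    # 8: E11P + Shc <-> E11P/Shc
    "k8": 0.002, "k8r": 3.6,
    # 9: E11P/Shc <-> E11P/ShcP (Shc phosphorylation on the receptor)
    "k9": 360.0, "k9r": 36.0,
    # 10: E11P/ShcP <-> E11P + ShcP
    "k10": 18.0, "k10r": 0.0054,
    # 11: ShcP -> Shc (cytosolic PTP, Vmax form)
    "V11": 102.0, "Km11": 340.0,
    # 12: E11P/ShcP + Grb2/SOS <-> E11P/ShcP/Grb2/SOS
    "k12": 0.06, "k12r": 2.4,
    # 13: E11P/ShcP/Grb2/SOS <-> E11P + ShcP/Grb2/SOS
    "k13": 6.0, "k13r": 0.0012,
    # 14: ShcP/Grb2/SOS <-> ShcP + Grb2/SOS
    "k14": 6.0, "k14r": 0.3,
    # 15: RasGDP -> RasGTP (SOS exchange, catalyzed by E11P/ShcP/Grb2/SOS)
    "kcat15": 750.0, "Km15": 600.0,
    # 16: RasGTP -> RasGDP (catalyzed by receptor-bound GAP)
    "kcat16": 4.0, "Km16": 600.0,
    # 17: RasGTP -> RasGDP (basal GTPase)
    "V17": 240.0, "Km17": 600.0,
    # 18: Raf1 -> Raf1A (catalyzed by RasGTP)
    "kcat18": 150.0, "Km18": 160.0,
    # 19: Raf1A -> Raf1 (Vmax form)
    "V19": 30.0, "Km19": 20.0,
    # 20/22: MEK -> MEKP -> MEKPP (catalyzed by Raf1A)
    "kcat20": 35.0, "Km20": 50.0,
    "kcat22": 35.0, "Km22": 50.0,
    # 21/23: MEKPP/MEKP dephosphorylation (PP2A)
    "kcat21": 12.5, "Km21": 50.0,
    "kcat23": 12.5, "Km23": 50.0,
    # 24/26: ERK -> ERKP -> ERKPP (catalyzed by MEKPP)
    "kcat24": 60.0, "Km24": 300.0,
    "kcat26": 60.0, "Km26": 300.0,
    # 25/27: ERKP/ERKPP dephosphorylation (MKP3)
    "kcat25": 125.0, "Km25": 300.0,
    "kcat27": 125.0, "Km27": 300.0,
}

_BOUNDS_DECADES = 2.0


def _reference_bounds() -> dict[str, tuple[float, float]]:
    f = 10.0 ** _BOUNDS_DECADES
    return {
        n: (v / f, v * f)
        for n, v in _REFERENCE_PARAMETERS.items()
        if v > 0
    }


def build_reference_network(
    parameter_values: Mapping[str, float] | None = None,
    initial_concentrations: Mapping[str, float] | None = None,
) -> ReactionNetwork:
    """Assemble the canonical 27-reaction EGFR-ERK network.

    Optional overrides replace individual reference parameter values or
    initial concentrations without touching the built-in defaults.
    """
    initials = dict(_REFERENCE_INITIALS)
    if initial_concentrations:
        initials.update(initial_concentrations)
    species = [
        Species(
            sid,
            _DISPLAY.get(sid, sid),
            initials.get(sid, 0.0),
            is_dynamic=sid not in _CONSTANT_SPECIES,
        )
        for sid in _SPECIES_ORDER
    ]
    reactions = [
        # EGF enters as a forward-rate multiplier: the extracellular ligand
        # reservoir is vastly larger than the per-cell receptor pool, so
        # binding does not deplete it (dEGF/dt = 0; the bath approximation).
        _ma(1, {"EGFR": 1}, {"Ra": 1}, "EGF binding", modifier="EGF"),
        _ma(2, {"Ra": 2}, {"E11": 1}, "receptor dimerization"),
        _ma(3, {"E11": 1}, {"E11P": 1}, "receptor autophosphorylation"),
        _mm(4, "E11P", "E11", "receptor dephosphorylation"),
        _ma(5, {"E11P": 1, "Cbl": 1}, {"E11P_Cbl": 1}, "Cbl binding"),
        _ma(6, {"E11P_Cbl": 1}, {"Cbl": 1, "E11deg": 1},
            "internalization and degradation", reversible=False),
        _ma(7, {"E11P": 1, "GAP": 1}, {"E11P_GAP": 1}, "GAP binding"),
        _ma(8, {"E11P": 1, "Shc": 1}, {"E11P_Shc": 1}, "Shc binding"),
        _ma(9, {"E11P_Shc": 1}, {"E11P_ShcP": 1}, "Shc phosphorylation"),
        _ma(10, {"E11P_ShcP": 1}, {"E11P": 1, "ShcP": 1}, "ShcP release"),
        _mm(11, "ShcP", "Shc", "ShcP dephosphorylation"),
        _ma(12, {"E11P_ShcP": 1, "GS": 1}, {"E11P_ShcP_GS": 1},
            "Grb2/SOS recruitment"),
        _ma(13, {"E11P_ShcP_GS": 1}, {"E11P": 1, "ShcP_GS": 1},
            "ShcP/Grb2/SOS release"),
        _ma(14, {"ShcP_GS": 1}, {"ShcP": 1, "GS": 1},
            "ShcP/Grb2/SOS dissociation"),
        _mm(15, "RasGDP", "RasGTP", "Ras GDP->GTP exchange",
            modifier="E11P_ShcP_GS"),
        _mm(16, "RasGTP", "RasGDP", "GAP-accelerated Ras deactivation",
            modifier="E11P_GAP"),
        _mm(17, "RasGTP", "RasGDP", "basal Ras deactivation"),
        _mm(18, "Raf1", "Raf1A", "Raf1 activation", modifier="RasGTP"),
        _mm(19, "Raf1A", "Raf1", "Raf1 deactivation"),
        _mm(20, "MEK", "MEKP", "MEK phosphorylation", modifier="Raf1A"),
        _mm(21, "MEKP", "MEK", "MEKP dephosphorylation", modifier="PP2A"),
        _mm(22, "MEKP", "MEKPP", "MEKP phosphorylation", modifier="Raf1A"),
        _mm(23, "MEKPP", "MEKP", "MEKPP dephosphorylation", modifier="PP2A"),
        _mm(24, "ERK", "ERKP", "ERK phosphorylation", modifier="MEKPP"),
        _mm(25, "ERKP", "ERK", "ERKP dephosphorylation", modifier="MKP3"),
        _mm(26, "ERKP", "ERKPP", "ERKP phosphorylation", modifier="MEKPP"),
        _mm(27, "ERKPP", "ERKP", "ERKPP dephosphorylation", modifier="MKP3"),
    ]
    values = dict(_REFERENCE_PARAMETERS)
    if parameter_values:
        values.update(parameter_values)
    bounds = _reference_bounds()
    for n in list(bounds):
        if n in values:
            lo, hi = bounds[n]
            bounds[n] = (min(lo, values[n]), max(hi, values[n]))
    # zero-valued constants (e.g. a reverse rate pinned to ~0) are kept
    # strictly positive for the positivity invariant
    values = {n: (v if v > 0 else 1e-12) for n, v in values.items()}
    return ReactionNetwork(species, reactions, ParameterSet(values, bounds))


# ---------------------------------------------------------------------------
# Cell-line variants
# ---------------------------------------------------------------------------

#: Reference variant settings. EGFR-overexpressing lines share a raised EGFR
#: initial concentration; L858R model A additionally slows the four
#: Mig6-affected rate constants, L858R model B instead raises Cbl.
DEFAULT_VARIANT_SETTINGS: dict[str, dict] = {
    "WT": {},
    "EGFR_WT": {"EGFR": 700.0},
    "L858R_A": {
        "EGFR": 700.0,
        "multipliers": {"k3": 0.15, "k5": 0.45, "k7": 0.45, "k8": 0.12},
    },
    "L858R_B": {"EGFR": 700.0, "Cbl_factor": 5.0},
}


def make_variant(
    name: str,
    network: ReactionNetwork,
    settings: Mapping | None = None,
) -> ModelVariant:
    """Construct one of the four cell-line variants.

    ``settings`` supplies the EGFR initial concentration (EGFR-overexpressing
    lines), the four Mig6 multipliers (L858R_A, each strictly < 1), or the
    Cbl fold-increase (L858R_B). Missing entries fall back to the reference
    settings.
    """
    if name not in VARIANT_NAMES:
        raise ValueError(f"unknown variant name {name!r}")
    cfg = dict(DEFAULT_VARIANT_SETTINGS[name])
    if settings:
        cfg.update(settings)
    if name == "WT":
        return ModelVariant("WT", network)
    overrides: dict[str, float] = {}
    egfr = float(cfg["EGFR"])
    base_egfr = next(s for s in network.species if s.id == "EGFR").initial_concentration
    if egfr < 0:
        raise ValueError("negative EGFR concentration")
    if egfr <= base_egfr:
        raise ValueError(
            f"EGFR-overexpressing variants need EGFR above the WT level "
            f"({egfr} <= {base_egfr})"
        )
    overrides["EGFR"] = egfr
    if name == "EGFR_WT":
        return ModelVariant(name, network, overrides)
    if name == "L858R_A":
        mult = {str(k): float(v) for k, v in cfg["multipliers"].items()}
        if set(mult) != set(MIG6_PARAMETERS):
            raise ValueError(
                f"L858R_A multipliers must cover exactly {MIG6_PARAMETERS}"
            )
        bad = {k: v for k, v in mult.items() if not 0 < v < 1}
        if bad:
            raise ValueError(
                f"Mig6 multipliers must lie in (0, 1) (slowed rates): {bad}"
            )
        return ModelVariant(name, network, overrides, mult)
    # L858R_B
    factor = float(cfg["Cbl_factor"])
    if factor <= 1:
        raise ValueError("L858R_B requires a Cbl fold-increase > 1")
    base_cbl = next(s for s in network.species if s.id == "Cbl").initial_concentration
    overrides["Cbl"] = base_cbl * factor
    return ModelVariant(name, network, overrides)


def reference_variants(
    network: ReactionNetwork | None = None,
) -> dict[str, ModelVariant]:
    """All four cell-line variants with reference settings."""
    net = network if network is not None else build_reference_network()
    return {name: make_variant(name, net) for name in VARIANT_NAMES}


# ---------------------------------------------------------------------------
# Conservation structure
# ---------------------------------------------------------------------------

_POOLS: dict[str, frozenset[str]] = {
    "Shc": frozenset({"Shc", "ShcP", "E11P_Shc", "E11P_ShcP",
                      "E11P_ShcP_GS", "ShcP_GS"}),
    "Grb2/SOS": frozenset({"GS", "E11P_ShcP_GS", "ShcP_GS"}),
    "Ras": frozenset({"RasGDP", "RasGTP"}),
    "Raf1": frozenset({"Raf1", "Raf1A"}),
    "MEK": frozenset({"MEK", "MEKP", "MEKPP"}),
    "ERK": frozenset({"ERK", "ERKP", "ERKPP"}),
    "Cbl": frozenset({"Cbl", "E11P_Cbl"}),
    "GAP": frozenset({"GAP", "E11P_GAP"}),
}


def conservation_pools(
    network: ReactionNetwork,
) -> list[tuple[str, frozenset[str]]]:
    """Closed moiety pools of the network.

    Each returned pool's total concentration is invariant under the ODE flow.
    The receptor pool is deliberately absent: degradation (step 6) drains
    receptor mass into the sink, so it is audited separately with
    :func:`receptor_pool_weights`.
    """
    known = set(network.species_ids)
    return [(name, ids) for name, ids in _POOLS.items() if ids <= known]


def receptor_pool_weights(network: ReactionNetwork) -> dict[str, float]:
    """Receptor-equivalent weights: EGFR-mass + sink is conserved even
    though the receptor pool itself is not (step 6 degradation)."""
    weights = {"EGFR": 1.0, "Ra": 1.0}
    for sid in network.species_ids:
        if sid.startswith("E11"):
            weights[sid] = 2.0
    return weights
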