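"""Stoichiometric model data structures, balance checking and pathway-variant edits.

The in-memory representation is deliberately explicit: a model is a list of
metabolites (with elemental formulas and charges) and a list of reactions whose
stoichiometries are exact rationals (:class:`fractions.Fraction`).  This keeps
mass/charge audits and net-conversion arithmetic exact, which floating-point
stoichiometries cannot guarantee.

Flux sign convention (used throughout the package): for an exchange reaction a
*negative* flux is uptake from the environment and a *positive* flux is
secretion.  Bounds are in mmol gCDW^-1 h^-1; the biomass reaction's flux is the
specific growth rate in h^-1.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ModelEditError, ValidationError

#: default flux bounds (mmol gCDW^-1 h^-1) used when a file omits explicit ones
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation chemical formula like ``C10H12N5O13P3``."""
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValidationError(f"cannot parse formula {formula!r}")
    return counts


def formula_to_string(counts: Mapping[str, int]) -> str:
    """Render an element-count map in Hill-ish sorted order."""
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items()) if n
    )


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` is an element -> count map; ``None`` means the composition is
    unknown (balance checks involving this species report *indeterminate*).
    """

    id: str
    name: str = ""
    formula: dict[str, int] | None = None
    charge: int = 0
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be nonempty")
        if self.formula is not None:
            for el, n in self.formula.items():
                if n < 0:
                    raise ValidationError(
                        f"negative count for element {el} in metabolite {self.id}"
                    )


def _as_fraction(x) -> Fraction:
    """Exact coefficient from int/Fraction, or decimal-text conversion of a float."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        # repr() of a float is the shortest decimal that round-trips, so this
        # is exact for coefficients that were written as decimals.
        return Fraction(repr(x))
    if isinstance(x, str):
        return Fraction(x)
    raise ValidationError(f"cannot interpret stoichiometric coefficient {x!r}")


@dataclass
class Reaction:
    """A (possibly reversible) reaction with exact rational stoichiometry.

    ``stoichiometry`` maps metabolite id -> signed coefficient, negative for
    consumption.  ``is_exchange`` marks boundary reactions, which by convention
    touch exactly one metabolite and whose negative flux is uptake.
    """

    id: str
    stoichiometry: dict[str, Fraction]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id} has empty stoichiometry")
        self.stoichiometry = {
            met: _as_fraction(coeff) for met, coeff in self.stoichiometry.items()
        }
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValidationError(
                f"exchange reaction {self.id} must touch exactly one metabolite"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


class StoichiometricModel:
    """A metabolic network: metabolites, reactions and a biomass reaction.

    The stoichiometric matrix S implied by ``reactions`` has one row per
    metabolite and one column per reaction (see :func:`stoichiometric_matrix`).
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        biomass_reaction_id: str | None = None,
        objective_reaction_id: str | None = None,
        name: str = "",
    ):
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.name = name
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        self.biomass_reaction_id = biomass_reaction_id
        self.objective_reaction_id = objective_reaction_id
        if biomass_reaction_id is not None and biomass_reaction_id not in self.reactions:
            raise ValidationError(
                f"biomass reaction {biomass_reaction_id!r} not in model"
            )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ValidationError(
                f"reaction {rxn.id} references unknown metabolites: {missing}"
            )
        self.reactions[rxn.id] = rxn

    # -- convenience -------------------------------------------------------
    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction with id {reaction_id!r}") from None

    def copy(self) -> "StoichiometricModel":
        return copy.deepcopy(self)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StoichiometricModel {self.name or 'unnamed'}: "
            f"{len(self.metabolites)} metabolites, {len(self.reactions)} reactions>"
        )


def stoichiometric_matrix(model: StoichiometricModel):
    """Dense S (metabolites x reactions) as float numpy array, plus orderings."""
    import numpy as np

    met_index = {m: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions.values()):
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], j] = float(coeff)
    return S, list(model.metabolites), list(model.reactions)


# ---------------------------------------------------------------------------
# pathway variants
# ---------------------------------------------------------------------------

class Variant(str, Enum):
    CBB = "cbb"
    RGLYP = "rglyp"


@dataclass
class PathwayVariantSpec:
    """Model-edit recipe selecting one formate-assimilation route.

    CBB: the glycine cleavage reaction ('GLYAMT', written in the
    glycine-cleaving direction) is made irreversible, i.e. its lower bound is
    raised to 0 so that the glycine-*producing* (reductive) direction is
    blocked and no flux can pass through the reductive glycine pathway.

    RGLYP: formate-THF ligase ('Ftl') and methenyl-THF cyclohydrolase ('Fch')
    are added, 'GLYAMT' is made reversible (negative = reductive flux
    allowed), and RuBisCO ('RBPC') is fixed to zero flux to silence the
    Calvin cycle.
    """

    variant: Variant
    reactions_to_add: list[Reaction] = field(default_factory=list)
    reversibility_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    knockouts: dict[str, float] = field(default_factory=dict)


# canonical -> model-id defaults target the RehMBEL1391 / core-model dialect
DEFAULT_ID_MAP: dict[str, str] = {
    "formate": "for_c",
    "thf": "thf_c",
    "10fthf": "10fthf_c",
    "methf": "methf_c",
    "atp": "atp_c",
    "adp": "adp_c",
    "pi": "pi_c",
    "h2o": "h2o_c",
    "h": "h_c",
    "glyamt": "GLYAMT",
    "rbpc": "RBPC",
    "formate_exchange": "EX_formate_e",
    "atp_maintenance": "ATPM",
    "biomass": "Biomass",
}


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited id-mapping table (canonical-name, model-id).

    Lines starting with '#' are comments; tab or comma separated.  Entries
    override :data:`DEFAULT_ID_MAP`.
    """
    mapping = dict(DEFAULT_ID_MAP)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,]", line)
        if len(parts) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected two columns, got {len(parts)}"
            )
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def cbb_variant(id_map: Mapping[str, str] | None = None) -> PathwayVariantSpec:
    """The Calvin-cycle recipe: block the reductive direction of GLYAMT."""
    ids = dict(DEFAULT_ID_MAP, **(id_map or {}))
    return PathwayVariantSpec(
        variant=Variant.CBB,
        reversibility_overrides={ids["glyamt"]: (0.0, DEFAULT_BOUND)},
    )


def rglyp_variant(id_map: Mapping[str, str] | None = None) -> PathwayVariantSpec:
    """The reductive glycine pathway recipe.

    Adds the two missing C1-module reactions (equations follow the
    Methylorubrum extorquens enzymes: FtfL activates formate onto THF at the
    cost of one ATP; FchA cyclizes 10-formyl-THF to 5,10-methenyl-THF,
    releasing water), reopens GLYAMT in the reductive direction and knocks
    out RuBisCO flux.
    """
    ids = dict(DEFAULT_ID_MAP, **(id_map or {}))
    ftl = Reaction(
        id="Ftl",
        stoichiometry={
            ids["formate"]: Fraction(-1),
            ids["thf"]: Fraction(-1),
            ids["atp"]: Fraction(-1),
            ids["10fthf"]: Fraction(1),
            ids["adp"]: Fraction(1),
            ids["pi"]: Fraction(1),
        },
        lower_bound=-DEFAULT_BOUND,
        upper_bound=DEFAULT_BOUND,
        label="formate-tetrahydrofolate ligase (FtfL)",
    )
    fch = Reaction(
        id="Fch",
        stoichiometry={
            ids["10fthf"]: Fraction(-1),
            ids["h"]: Fraction(-1),
            ids["methf"]: Fraction(1),
            ids["h2o"]: Fraction(1),
        },
        lower_bound=-DEFAULT_BOUND,
        upper_bound=DEFAULT_BOUND,
        label="methenyl-tetrahydrofolate cyclohydrolase (FchA)",
    )
    return PathwayVariantSpec(
        variant=Variant.RGLYP,
        reactions_to_add=[ftl, fch],
        reversibility_overrides={ids["glyamt"]: (-DEFAULT_BOUND, DEFAULT_BOUND)},
        knockouts={ids["rbpc"]: 0.0},
    )


def variant_spec(
    variant: Variant | str, id_map: Mapping[str, str] | None = None
) -> PathwayVariantSpec:
    """Recipe lookup by variant name."""
    v = Variant(variant)
    return cbb_variant(id_map) if v is Variant.CBB else rglyp_variant(id_map)


def apply_variant(
    model: StoichiometricModel, spec: PathwayVariantSpec
) -> StoichiometricModel:
    """Return an edited copy of ``model`` implementing the variant recipe.

    The input model is never mutated.  Reaction ids named by bound overrides
    and knockouts must exist; reactions to add must not.
    """
    out = model.copy()
    missing = [
        rid
        for rid in list(spec.reversibility_overrides) + list(spec.knockouts)
        if rid not in out.reactions
    ]
    if missing:
        raise ModelEditError(f"variant edit references missing reactions: {missing}")
    conflicts = [r.id for r in spec.reactions_to_add if r.id in out.reactions]
    if conflicts:
        raise ModelEditError(
            f"variant adds reactions already present in the model: {conflicts}"
        )
    for rxn in spec.reactions_to_add:
        out.add_reaction(copy.deepcopy(rxn))
    for rid, (lb, ub) in spec.reversibility_overrides.items():
        rxn = out.reactions[rid]
        rxn.lower_bound, rxn.upper_bound = lb, ub
    for rid, value in spec.knockouts.items():
        rxn = out.reactions[rid]
        rxn.lower_bound = rxn.upper_bound = value
    return out


# ---------------------------------------------------------------------------
# balance checking
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    """Element and charge audit of one reaction (products minus reactants)."""

    reaction_id: str
    element_imbalance: dict[str, Fraction]
    charge_imbalance: Fraction
    balanced: bool
    indeterminate: bool = False
    reason: str = ""


def check_balance(model: StoichiometricModel, reaction_id: str) -> BalanceReport:
    """Audit elemental and charge balance of one reaction.

    Sign convention: positive imbalance means the element appears in excess on
    the product side.  Exchange reactions are indeterminate by design (mass
    crosses the system boundary); so is any reaction touching a metabolite
    with unknown formula.
    """
    rxn = model.reaction(reaction_id)
    if rxn.is_exchange:
        return BalanceReport(
            reaction_id, {}, Fraction(0), balanced=False,
            indeterminate=True, reason="exchange reaction: indeterminate by design",
        )
    totals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for met_id, coeff in rxn.stoichiometry.items():
        met = model.metabolites[met_id]
        if met.formula is None or not met.formula:
            return BalanceReport(
                reaction_id, {}, Fraction(0), balanced=False,
                indeterminate=True,
                reason=f"metabolite {met_id} has unknown formula",
            )
        for el, n in met.formula.items():
            totals[el] = totals.get(el, Fraction(0)) + coeff * n
        charge += coeff * met.charge
    imbalance = {el: v for el, v in totals.items() if v != 0}
    return BalanceReport(
        reaction_id,
        imbalance,
        charge,
        balanced=(not imbalance and charge == 0),
    )


def balance_biomass_atp(
    model: StoichiometricModel, id_map: Mapping[str, str] | None = None
) -> StoichiometricModel:
    """Balance the ATP-hydrolysis part of the biomass reaction with H2O and H+.

    The growth-associated maintenance (GAM) appears in the biomass reaction as
    ``g ATP + g H2O -> g ADP + g Pi + g H+``.  Many reconstructions omit the
    water and proton; this edit adds exactly the missing amounts so the
    hydrolysis sub-stoichiometry is element- and charge-balanced, leaving the
    GAM magnitude (the ATP coefficient) unchanged.  Existing H2O/H+
    stoichiometry at least as large as the GAM amount is taken to already
    include the hydrolysis share, and the reaction is returned unchanged.
    """
    ids = dict(DEFAULT_ID_MAP, **(id_map or {}))
    if model.biomass_reaction_id is None:
        raise ModelEditError("model has no biomass reaction")
    out = model.copy()
    biomass = out.reactions[model.biomass_reaction_id]
    atp, adp = ids["atp"], ids["adp"]
    if atp not in biomass.stoichiometry or adp not in biomass.stoichiometry:
        raise ModelEditError(
            f"biomass reaction lacks ATP ({atp}) or ADP ({adp}) species"
        )
    gam = -biomass.stoichiometry[atp]
    if gam <= 0:
        raise ModelEditError("biomass reaction does not consume ATP")
    h2o, h = ids["h2o"], ids["h"]
    # water consumed must reach -gam; protons produced must reach +gam
    h2o_coeff = biomass.stoichiometry.get(h2o, Fraction(0))
    if h2o_coeff > -gam:
        deficit = -gam - h2o_coeff
        biomass.stoichiometry[h2o] = h2o_coeff + deficit
    h_coeff = biomass.stoichiometry.get(h, Fraction(0))
    if h_coeff < gam:
        biomass.stoichiometry[h] = h_coeff + (gam - h_coeff)
    return out
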