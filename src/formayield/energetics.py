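"""Net stoichiometry and cofactor-cost accounting for the two formate routes.

The reductive glycine pathway (rGlyP) and the Calvin-Benson-Bassham (CBB)
cycle are compared as *routes*: ordered reaction lists with exact integer
stoichiometries.  Internal intermediates (THF species, glycine, serine, sugar
phosphates, ammonia) are eliminated by exact rational arithmetic, yielding
the net conversion per mole of pyruvate and its cofactor tallies - ATP,
NAD(P)H, formate assimilated, CO2 fixed.

Per pyruvate the bundled routes reduce to

    rGlyP: 2 formate + CO2 + 2 ATP + 2 NADPH + NADH -> pyruvate
    CBB:   3 CO2 + 7 ATP + 5 NAD(P)H -> pyruvate

and converting every cofactor back to formate equivalents (NADH from formate
dehydrogenase, NADPH via transhydrogenase, ATP from respiration at a P/O-like
ratio) gives the total formate demand per pyruvate, which is strictly lower
for the rGlyP at any positive ATP-per-NADH ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction

import pandas as pd

from .errors import RouteError
from .metnet import Metabolite, Reaction, parse_formula

# -- compound registry for the bundled routes (formulas in route context) ----

_ROUTE_COMPOUNDS: dict[str, tuple[str, int]] = {
    # id: (formula, charge)
    "formate": ("CHO2", -1),
    "co2": ("CO2", 0),
    "nh3": ("H3N", 0),
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "pyr": ("C3H3O3", -1),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "pi": ("HO4P", -2),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "nadp": ("C21H25N7O17P3", -3),
    "nadph": ("C21H26N7O17P3", -4),
    "thf": ("C19H21N7O6", -2),
    "10fthf": ("C20H21N7O7", -2),
    "methf": ("C20H20N7O6", -1),
    "mlthf": ("C20H21N7O6", -2),
    "gly": ("C2H5NO2", 0),
    "ser": ("C3H7NO3", 0),
    "ru5p": ("C5H9O8P", -2),
    "rubp": ("C5H8O11P2", -4),
    "3pg": ("C3H4O7P", -3),
    "13dpg": ("C3H4O10P2", -4),
    "g3p": ("C3H5O6P", -2),
}


def route_compound(cid: str) -> Metabolite:
    formula, charge = _ROUTE_COMPOUNDS[cid]
    return Metabolite(id=cid, formula=parse_formula(formula), charge=charge)


def degree_of_reduction(cid: str) -> int:
    """Available electrons: 4C + H - 2O - 3N + 5P - charge.

    Gives 2 for formate, 0 for CO2/NH3/H2O/H+, 10 for pyruvate, and makes the
    NAD(P)H/NAD(P)+ couples differ by exactly 2, ATP hydrolysis by 0.
    """
    formula, charge = _ROUTE_COMPOUNDS[cid]
    counts = parse_formula(formula)
    return (
        4 * counts.get("C", 0) + counts.get("H", 0) - 2 * counts.get("O", 0)
        - 3 * counts.get("N", 0) + 5 * counts.get("P", 0) - charge
    )


class RouteName(str, Enum):
    RGLYP = "rglyp"
    CBB = "cbb"


@dataclass
class RouteDefinition:
    """An ordered reaction set with internal compounds to eliminate."""

    name: RouteName
    reactions: list[Reaction]
    internal_compounds: set[str]
    target: str = "pyr"

    def __post_init__(self) -> None:
        if self.target in self.internal_compounds:
            raise RouteError("target compound cannot be internal")


def _rxn(rid: str, stoich: dict[str, int], label: str = "") -> Reaction:
    return Reaction(
        id=rid,
        stoichiometry={c: Fraction(v) for c, v in stoich.items()},
        lower_bound=0.0,
        label=label,
    )


def rglyp_route() -> RouteDefinition:
    """Formate -> pyruvate through the reductive glycine pathway.

    The C1 module (FtfL, FchA, MtdA) activates and reduces formate to
    5,10-methylene-THF; the glycine cleavage system runs reductively to make
    glycine; serine hydroxymethyltransferase condenses glycine with a second
    methylene-THF; serine deaminase yields pyruvate.
    """
    reactions = [
        _rxn("FtfL", {"formate": -1, "thf": -1, "atp": -1,
                      "10fthf": 1, "adp": 1, "pi": 1},
             "formate-THF ligase"),
        _rxn("FchA", {"10fthf": -1, "h": -1, "methf": 1, "h2o": 1},
             "methenyl-THF cyclohydrolase"),
        _rxn("MtdA", {"methf": -1, "nadph": -1, "mlthf": 1, "nadp": 1},
             "methylene-THF dehydrogenase (NADP)"),
        _rxn("GCS", {"mlthf": -1, "co2": -1, "nh3": -1, "nadh": -1, "h": -1,
                     "gly": 1, "thf": 1, "nad": 1},
             "glycine cleavage system, reductive direction"),
        _rxn("GlyA", {"gly": -1, "mlthf": -1, "h2o": -1, "ser": 1, "thf": 1},
             "serine hydroxymethyltransferase"),
        _rxn("SdaA", {"ser": -1, "pyr": 1, "nh3": 1, "h": 1},
             "serine deaminase"),
    ]
    return RouteDefinition(
        name=RouteName.RGLYP,
        reactions=reactions,
        internal_compounds={"thf", "10fthf", "methf", "mlthf", "gly", "ser", "nh3"},
    )


def cbb_route(gapdh_cofactor: str = "nad") -> RouteDefinition:
    """3 CO2 -> pyruvate through the Calvin cycle (lumped regeneration).

    Three Ru5P are phosphorylated (Prk) and carboxylated (RuBisCO) into six
    3PG; five are reduced to triose phosphate (PGK + GAPDH) and recycled to
    Ru5P (lumped PPREGEN); the sixth leaves as pyruvate (lumped PYKL).  The
    GAPDH cofactor is a parameter; the comparison default is the NAD couple.
    Switching to NADP moves cost between the NADH and NADPH tallies without
    changing carbon or electron totals.
    """
    if gapdh_cofactor not in {"nad", "nadp"}:
        raise ValueError("gapdh_cofactor must be 'nad' or 'nadp'")
    red, ox = (("nadh", "nad") if gapdh_cofactor == "nad" else ("nadph", "nadp"))
    reactions = [
        _rxn("Prk", {"ru5p": -1, "atp": -1, "rubp": 1, "adp": 1, "h": 1},
             "phosphoribulokinase"),
        _rxn("RBPC", {"rubp": -1, "co2": -1, "h2o": -1, "3pg": 2, "h": 2},
             "RuBisCO"),
        _rxn("PGK", {"3pg": -1, "atp": -1, "13dpg": 1, "adp": 1},
             "phosphoglycerate kinase"),
        _rxn("GAPDH", {"13dpg": -1, red: -1, "h": -1, "g3p": 1, ox: 1, "pi": 1},
             f"glyceraldehyde-3P dehydrogenase ({gapdh_cofactor.upper()})"),
        _rxn("PPREGEN", {"g3p": -5, "h2o": -2, "ru5p": 3, "pi": 2},
             "lumped pentose-phosphate regeneration"),
        _rxn("PYKL", {"3pg": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1, "h2o": 1},
             "lumped lower glycolysis (3PG -> pyruvate)"),
    ]
    return RouteDefinition(
        name=RouteName.CBB,
        reactions=reactions,
        internal_compounds={"ru5p", "rubp", "3pg", "13dpg", "g3p"},
    )


def bundled_route(name: RouteName | str, **kwargs) -> RouteDefinition:
    name = RouteName(name)
    return rglyp_route() if name is RouteName.RGLYP else cbb_route(**kwargs)


# ---------------------------------------------------------------------------
# exact elimination
# ---------------------------------------------------------------------------

@dataclass
class NetConversion:
    """Exact net conversion of a route, normalized to +1 target compound."""

    route: RouteName
    flux_multipliers: dict[str, Fraction]
    net_stoichiometry: dict[str, Fraction]
    tallies: dict[str, Fraction] = field(default_factory=dict)


def _rref(matrix: list[list[Fraction]], rhs: list[Fraction]):
    """In-place reduced row echelon form over Fractions; returns pivot columns."""
    n_rows, n_cols = len(matrix), len(matrix[0]) if matrix else 0
    pivots: list[int] = []
    row = 0
    for col in range(n_cols):
        pivot = next(
            (r for r in range(row, n_rows) if matrix[r][col] != 0), None
        )
        if pivot is None:
            continue
        matrix[row], matrix[pivot] = matrix[pivot], matrix[row]
        rhs[row], rhs[pivot] = rhs[pivot], rhs[row]
        scale = matrix[row][col]
        matrix[row] = [v / scale for v in matrix[row]]
        rhs[row] = rhs[row] / scale
        for r in range(n_rows):
            if r != row and matrix[r][col] != 0:
                factor = matrix[r][col]
                matrix[r] = [a - factor * b for a, b in zip(matrix[r], matrix[row])]
                rhs[r] = rhs[r] - factor * rhs[row]
        pivots.append(col)
        row += 1
        if row == n_rows:
            break
    return pivots, row


def net_conversion(route: RouteDefinition) -> NetConversion:
    """Eliminate internal intermediates exactly; normalize to +1 target.

    Solves, in exact rational arithmetic, for non-negative flux multipliers
    x such that every internal compound nets to zero and the target nets to
    +1.  Free multipliers (if the system is underdetermined) are set to zero,
    which together with left-to-right pivoting makes the result the
    minimal-support solution under lexicographic reaction order.
    """
    if not route.reactions:
        raise RouteError(f"route {route.name.value} has no reactions")
    rxn_ids = [r.id for r in route.reactions]
    constraints = sorted(route.internal_compounds) + [route.target]
    matrix = [
        [r.stoichiometry.get(cid, Fraction(0)) for r in route.reactions]
        for cid in constraints
    ]
    rhs = [Fraction(0)] * len(route.internal_compounds) + [Fraction(1)]
    pivots, rank = _rref(matrix, rhs)
    # consistency: zero rows must have zero rhs
    for r in range(rank, len(matrix)):
        if rhs[r] != 0:
            bad = [
                cid for cid, row_ in zip(constraints, matrix)
                if all(v == 0 for v in row_)
            ]
            raise RouteError(
                f"route {route.name.value}: intermediates cannot be balanced "
                f"(unsatisfiable constraints near {bad or constraints})"
            )
    x = [Fraction(0)] * len(rxn_ids)
    for row_idx, col in enumerate(pivots):
        # free variables are zero, so the pivot value is the rhs
        x[col] = rhs[row_idx]
    if any(v < 0 for v in x):
        raise RouteError(
            f"route {route.name.value}: no non-negative flux multipliers "
            f"eliminate the internal compounds (got {dict(zip(rxn_ids, x))})"
        )
    net: dict[str, Fraction] = {}
    for multiplier, rxn in zip(x, route.reactions):
        if multiplier == 0:
            continue
        for cid, coeff in rxn.stoichiometry.items():
            net[cid] = net.get(cid, Fraction(0)) + multiplier * coeff
    net = {cid: v for cid, v in net.items() if v != 0}
    tallies = {
        "atp_cost": -net.get("atp", Fraction(0)),
        "nadph_cost": -net.get("nadph", Fraction(0)),
        "nadh_cost": -net.get("nadh", Fraction(0)),
        "formate_assimilated": -net.get("formate", Fraction(0)),
        "co2_fixed": -net.get("co2", Fraction(0)),
        "reaction_count": Fraction(sum(1 for v in x if v != 0)),
    }
    return NetConversion(
        route=route.name,
        flux_multipliers=dict(zip(rxn_ids, x)),
        net_stoichiometry=net,
        tallies=tallies,
    )


class NadphSource(str, Enum):
    TRANSHYDROGENASE = "transhydrogenase"
    DIRECT = "direct"


def total_formate_per_pyruvate(
    net: NetConversion,
    atp_per_nadh: float | Fraction = 2,
    nadph_source: NadphSource | str = NadphSource.TRANSHYDROGENASE,
    transhydrogenase_overhead: float | Fraction = 1,
) -> Fraction:
    """Total formate demand per pyruvate, cofactors converted to formate.

    NADH is regenerated 1:1 from formate (formate dehydrogenase); NADPH costs
    ``transhydrogenase_overhead`` formate each when sourced through the
    membrane-bound transhydrogenase (PntAB; the proton cost per NADPH is this
    overhead parameter, default 1) or exactly 1 when generated directly; ATP
    costs 1/``atp_per_nadh`` formate each (respiration at a P/O-like ratio).
    """
    apn = Fraction(atp_per_nadh) if not isinstance(atp_per_nadh, float) \
        else Fraction(repr(atp_per_nadh))
    if apn <= 0:
        raise ValueError("atp_per_nadh must be positive")
    overhead = Fraction(transhydrogenase_overhead) \
        if not isinstance(transhydrogenase_overhead, float) \
        else Fraction(repr(transhydrogenase_overhead))
    if NadphSource(nadph_source) is NadphSource.DIRECT:
        overhead = Fraction(1)
    t = net.tallies
    return (
        t["formate_assimilated"]
        + t["nadh_cost"]
        + t["nadph_cost"] * overhead
        + t["atp_cost"] / apn
    )


def compare_routes(
    rglyp: RouteDefinition | None = None,
    cbb: RouteDefinition | None = None,
    atp_per_nadh: float | Fraction = 2,
    nadph_source: NadphSource | str = NadphSource.TRANSHYDROGENASE,
    transhydrogenase_overhead: float | Fraction = 1,
    include_mdf: bool = False,
) -> pd.DataFrame:
    """Side-by-side route comparison table (one row per route)."""
    routes = {
        "rglyp": rglyp if rglyp is not None else rglyp_route(),
        "cbb": cbb if cbb is not None else cbb_route(),
    }
    mdf_values: dict[str, float] = {}
    if include_mdf:
        from .mdf import route_mdf_comparison

        mdf_values = {
            name: res.mdf for name, res in route_mdf_comparison().items()
        }
    rows = []
    for name, route in routes.items():
        net = net_conversion(route)
        total = total_formate_per_pyruvate(
            net, atp_per_nadh, nadph_source, transhydrogenase_overhead
        )
        row = {
            "route": name,
            "reaction_count": int(net.tallies["reaction_count"]),
            "atp_cost": float(net.tallies["atp_cost"]),
            "nadph_cost": float(net.tallies["nadph_cost"]),
            "nadh_cost": float(net.tallies["nadh_cost"]),
            "formate_assimilated": float(net.tallies["formate_assimilated"]),
            "co2_fixed": float(net.tallies["co2_fixed"]),
            "formate_total_per_pyruvate": float(total),
        }
        if include_mdf:
            row["mdf_kj_mol"] = mdf_values.get(name)
        rows.append(row)
    return pd.DataFrame(rows)


def carbon_in_net(net: NetConversion) -> Fraction:
    """Substrate carbon (formate + CO2) consumed per mole target; 3 for pyruvate."""
    return net.tallies["formate_assimilated"] + net.tallies["co2_fixed"]


def electron_balance(net: NetConversion) -> tuple[Fraction, Fraction]:
    """(electrons consumed, electrons produced) over the net conversion."""
    consumed = produced = Fraction(0)
    for cid, coeff in net.net_stoichiometry.items():
        gamma = degree_of_reduction(cid)
        if coeff < 0:
            consumed += -coeff * gamma
        else:
            produced += coeff * gamma
    return consumed, produced
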