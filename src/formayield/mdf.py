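"""Max-min driving force (MDF) analysis over log-concentrations.

For a pathway of reactions with transformed standard Gibbs energies dG'0_j
(kJ/mol, at stated pH/ionic strength/Mg), the MDF is the largest B such that
every reaction can simultaneously have driving force

    -dG'_j = -(dG'0_j + RT * sum_i s_ij * ln c_i) >= B

with each metabolite concentration c_i inside its allowed range.  This is a
linear program in (B, ln c).  Water and protons are not concentration
variables: their contributions are folded into dG'0 at the stated pH, the
standard convention of transformed Gibbs energies.

Concentration handling:

* default box 1 uM to 10 mM for every compound,
* fixed concentrations (e.g. dissolved CO2 at 3.4 mM) override the box,
* fixed ratios (e.g. NADH/NAD+ = 0.1) are exact linear equalities
  ln c_num - ln c_den = ln(ratio); ratio-tied compounds keep the box, so
  dropping a ratio constraint is a pure relaxation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import ConstraintError, FormatError

#: gas constant, kJ mol^-1 K^-1
R_KJ = 8.314462618e-3
#: compounds whose activity is taken as 1 (folded into dG'0)
IGNORED_COMPOUNDS = frozenset({"h2o", "h"})


@dataclass
class ThermoReaction:
    """One pathway step: stoichiometry plus transformed standard Gibbs energy."""

    id: str
    stoichiometry: dict[str, float]
    dg0_prime: float  # kJ mol^-1

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ConstraintError(f"thermo reaction {self.id} has empty stoichiometry")
        if not math.isfinite(self.dg0_prime):
            raise ConstraintError(f"thermo reaction {self.id} has non-finite dG'0")


@dataclass
class ConcentrationConstraintSet:
    """Concentration ranges, fixes, ratios and physicochemical conditions."""

    default_range: tuple[float, float] = (1e-6, 1e-2)  # M
    fixed_concentrations: dict[str, float] = field(default_factory=dict)
    fixed_ratios: list[tuple[str, str, float]] = field(default_factory=list)
    temperature: float = 298.15  # K
    ph: float = 7.5
    ionic_strength: float = 0.25  # M
    mg_conc: float = 1e-3  # M

    def __post_init__(self) -> None:
        lo, hi = self.default_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ConstraintError(f"invalid concentration range {self.default_range}")
        for cid, c in self.fixed_concentrations.items():
            if c <= 0:
                raise ConstraintError(f"fixed concentration of {cid} must be positive")
        for num, den, ratio in self.fixed_ratios:
            if ratio <= 0:
                raise ConstraintError(f"ratio {num}/{den} must be positive")

    @property
    def rt(self) -> float:
        """RT in kJ mol^-1 (2.479 at 298.15 K)."""
        return R_KJ * self.temperature


def study_constraints(
    co2_mM: float | None = 3.4, nadh_nad_ratio: float | None = 0.1
) -> ConcentrationConstraintSet:
    """The study comparison conditions: 1 uM - 10 mM box, pH 7.5, I = 0.25 M,
    1 mM Mg2+, dissolved CO2 fixed (3.4 mM at 10 % headspace CO2) and the
    standard NADH/NAD+ ratio of 0.1."""
    fixed = {} if co2_mM is None else {"co2": co2_mM * 1e-3}
    ratios = [] if nadh_nad_ratio is None else [("nadh", "nad", nadh_nad_ratio)]
    return ConcentrationConstraintSet(
        fixed_concentrations=fixed, fixed_ratios=ratios
    )


@dataclass
class MdfResult:
    mdf: float  # B, kJ mol^-1
    optimal_log_concentrations: dict[str, float]  # ln(M)
    per_reaction_driving_force: dict[str, float]  # kJ mol^-1
    limiting_reactions: set[str]


def _free_and_fixed(
    pathway: list[ThermoReaction], constraints: ConcentrationConstraintSet
) -> tuple[list[str], dict[str, float]]:
    compounds = sorted({c for rxn in pathway for c in rxn.stoichiometry})
    fixed: dict[str, float] = {}
    for cid, conc in constraints.fixed_concentrations.items():
        fixed[cid] = math.log(conc)
    free = [c for c in compounds if c not in fixed and c not in IGNORED_COMPOUNDS]
    return free, fixed


def compute_mdf(
    pathway: list[ThermoReaction], constraints: ConcentrationConstraintSet
) -> MdfResult:
    """Solve the MDF linear program for one pathway."""
    if not pathway:
        raise ConstraintError("empty pathway")
    ids = [r.id for r in pathway]
    if len(set(ids)) != len(ids):
        raise ConstraintError("duplicate reaction ids in pathway")
    rt = constraints.rt
    free, fixed = _free_and_fixed(pathway, constraints)
    lo, hi = constraints.default_range
    log_lo, log_hi = math.log(lo), math.log(hi)
    idx = {c: i for i, c in enumerate(free)}
    n = len(free) + 1  # + B
    j_b = len(free)

    # constraints: RT * sum s_i x_i + B <= -dg0 - RT * sum_fixed s_i ln(c_i)
    A_ub, b_ub = [], []
    for rxn in pathway:
        row = np.zeros(n)
        rhs = -rxn.dg0_prime
        for cid, s in rxn.stoichiometry.items():
            if cid in IGNORED_COMPOUNDS:
                continue
            if cid in fixed:
                rhs -= rt * s * fixed[cid]
            else:
                row[idx[cid]] = rt * s
        row[j_b] = 1.0
        A_ub.append(row)
        b_ub.append(rhs)

    A_eq, b_eq = [], []
    for num, den, ratio in constraints.fixed_ratios:
        row = np.zeros(n)
        rhs = math.log(ratio)
        known = 0.0
        for cid, sign in ((num, 1.0), (den, -1.0)):
            if cid in fixed:
                known += sign * fixed[cid]
            elif cid in idx:
                row[idx[cid]] = sign
            else:
                continue  # ratio on a compound absent from the pathway: inert
        if not row.any():
            if abs(known - rhs) > 1e-9:
                raise ConstraintError(
                    f"fixed concentrations contradict ratio {num}/{den} = {ratio}"
                )
            continue
        A_eq.append(row)
        b_eq.append(rhs - known)

    bounds = [(log_lo, log_hi)] * len(free) + [(None, None)]
    for cid, value in fixed.items():
        # a fix outside the box is allowed by design (it is an override), but
        # a non-positive or non-finite value is not
        if not math.isfinite(value):
            raise ConstraintError(f"fixed concentration of {cid} is not finite")

    res = linprog(
        c=np.eye(n)[j_b] * -1.0,  # maximize B
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise ConstraintError(
            "MDF problem infeasible: concentration constraints are contradictory"
        )
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"MDF LP failed: {res.message}")

    x = res.x
    log_conc = {c: float(x[idx[c]]) for c in free}
    log_conc.update(fixed)
    driving_forces = {}
    for rxn in pathway:
        dg = rxn.dg0_prime
        for cid, s in rxn.stoichiometry.items():
            if cid in IGNORED_COMPOUNDS:
                continue
            dg += rt * s * log_conc[cid]
        driving_forces[rxn.id] = -dg
    b_value = float(x[j_b])
    limiting = {rid for rid, df in driving_forces.items() if df <= b_value + 1e-6}
    return MdfResult(
        mdf=b_value,
        optimal_log_concentrations=log_conc,
        per_reaction_driving_force=driving_forces,
        limiting_reactions=limiting,
    )


# ---------------------------------------------------------------------------
# route fixture tables and the two-route comparison
# ---------------------------------------------------------------------------

THERMO_TABLE_COLUMNS = [
    "reaction_id", "equation", "dg0_prime_kj_mol",
    "ph", "ionic_strength_M", "mg_M", "provenance",
]


def parse_equation(equation: str) -> dict[str, float]:
    """Parse '2 a + b -> c' style equations into a signed-coefficient map."""
    if "->" in equation:
        left, right = equation.split("->")
    elif "=" in equation:
        left, right = equation.split("=")
    else:
        raise FormatError(f"equation {equation!r} has no '->'")
    stoich: dict[str, float] = {}
    for side, sign in ((left, -1.0), (right, 1.0)):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, cid = 1.0, parts[0]
            elif len(parts) == 2:
                coeff, cid = float(parts[0]), parts[1]
            else:
                raise FormatError(f"cannot parse equation term {term!r}")
            stoich[cid] = stoich.get(cid, 0.0) + sign * coeff
    return {c: v for c, v in stoich.items() if v != 0}


def load_thermo_table(path: str | Path) -> list[ThermoReaction]:
    """Load a dG'0 fixture table (tab-separated, commented header lines)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(THERMO_TABLE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        ThermoReaction(
            id=row["reaction_id"],
            stoichiometry=parse_equation(row["equation"]),
            dg0_prime=float(row["dg0_prime_kj_mol"]),
        )
        for _, row in df.iterrows()
    ]


def bundled_route_table(route: str) -> list[ThermoReaction]:
    """The packaged, reconstructed dG'0 table for 'rglyp' or 'cbb'."""
    route = route.lower()
    if route not in {"rglyp", "cbb"}:
        raise ValueError(f"unknown route {route!r}")
    ref = resources.files("formayield.data") / f"{route}_dg0.tsv"
    with resources.as_file(ref) as path:
        return load_thermo_table(path)


def route_mdf_comparison(
    constraints: ConcentrationConstraintSet | None = None,
    routes: dict[str, list[ThermoReaction]] | None = None,
) -> dict[str, MdfResult]:
    """MDF for the rGlyP and CBB formate-to-pyruvate routes side by side.

    Defaults to the bundled reconstructed dG'0 tables and the comparison
    conditions (CO2 fixed at 3.4 mM, NADH/NAD+ = 0.1, NAD-dependent GAPDH on
    the CBB side — the bundled CBB table already encodes the NAD couple).
    """
    if constraints is None:
        constraints = study_constraints()
    if routes is None:
        routes = {name: bundled_route_table(name) for name in ("rglyp", "cbb")}
    return {name: compute_mdf(pathway, constraints) for name, pathway in routes.items()}


def comparison_report(results: dict[str, MdfResult]) -> pd.DataFrame:
    """Flat per-reaction report (route, reaction, driving force, limiting)."""
    rows = []
    for route, result in results.items():
        for rid, df_val in result.per_reaction_driving_force.items():
            rows.append({
                "route": route, "reaction_id": rid,
                "driving_force_kj_mol": df_val,
                "mdf_kj_mol": result.mdf,
                "limiting": rid in result.limiting_reactions,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dissolved CO2
# ---------------------------------------------------------------------------

#: CO2 solubility (concentration/pressure form of the Henry constant) at
#: 298.15 K: 1/29.41 atm M^-1 = 0.0340 M atm^-1 (standard tabulated value)
KH_CO2_REF = 1.0 / 29.41  # M atm^-1
KH_CO2_REF_TEMPERATURE = 298.15  # K
#: van 't Hoff temperature coefficient -dln(kH)/d(1/T) for CO2 in water
KH_CO2_VANT_HOFF = 2400.0  # K


def dissolved_co2(
    co2_fraction: float,
    temperature: float = KH_CO2_REF_TEMPERATURE,
    pressure: float = 1.0,
) -> float:
    """Equilibrium dissolved CO2 concentration (M) by Henry's law.

    c = kH(T) * fraction * pressure with kH(T) in van 't Hoff form around the
    standard 25 C value.  At 10 % (v/v) CO2 and 1 atm the reference
    conditions give 3.4 mM.
    """
    if not 0.0 <= co2_fraction <= 1.0:
        raise ValueError("CO2 fraction must be within [0, 1]")
    if temperature <= 0 or pressure < 0:
        raise ValueError("temperature must be positive and pressure non-negative")
    kh = KH_CO2_REF * math.exp(
        KH_CO2_VANT_HOFF * (1.0 / temperature - 1.0 / KH_CO2_REF_TEMPERATURE)
    )
    return kh * co2_fraction * pressure
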