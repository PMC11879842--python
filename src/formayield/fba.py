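"""Flux balance analysis as an explicit linear program (scipy HiGHS).

FBA solves max/min c.v subject to S.v = 0 and lb <= v <= ub.  The biomass
yield on formate is computed the way a chemostat defines it: fix the growth
rate mu (= ln2 / doubling time), make the formate exchange flux the objective
in the sense that minimizes uptake magnitude (exchange uptake is negative, so
this is a maximization), and report Y = 1000 * mu / q in g CDW per mol
formate, with q the uptake magnitude in mmol gCDW^-1 h^-1.

Maintenance enters in the standard two places: the growth-associated
maintenance (GAM, mmol ATP gCDW^-1) is the ATP-hydrolysis coefficient inside
the biomass reaction, and the non-growth-associated maintenance (NGAM,
mmol ATP gCDW^-1 h^-1) is a fixed flux through the ATP-maintenance reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import ModelEditError, YieldError
from .metnet import (
    DEFAULT_ID_MAP,
    PathwayVariantSpec,
    StoichiometricModel,
    apply_variant,
    stoichiometric_matrix,
)

#: feasibility tolerance handed to the solver
SOLVER_TOL = 1e-9
#: tolerance for reported-solution checks (S.v residual, bound violations)
CHECK_TOL = 1e-6


class Sense(str, Enum):
    MAXIMIZE = "maximize"
    MINIMIZE = "minimize"


class SolutionStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class FbaProblem:
    """One FBA instance: a model plus objective, fixes and maintenance.

    ``fixed_fluxes`` pin reactions to exact values (both bounds).  ``mu``
    fixes the biomass reaction flux.  ``gam``, if given, rewrites the ATP
    hydrolysis part of the biomass reaction (see :func:`set_gam`); ``ngam``
    is applied as a fixed flux through the ATP-maintenance reaction.
    """

    model: StoichiometricModel
    objective_reaction_id: str
    objective_sense: Sense = Sense.MAXIMIZE
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    mu: float | None = None
    gam: float | None = None
    ngam: float | None = None
    id_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective_reaction_id not in self.model.reactions:
            raise KeyError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        if self.mu is not None and self.mu < 0:
            raise ValueError("growth rate mu must be >= 0")
        if self.gam is not None and self.gam < 0:
            raise ValueError("GAM must be >= 0")
        if self.ngam is not None and self.ngam < 0:
            raise ValueError("NGAM must be >= 0")


@dataclass
class FluxSolution:
    status: SolutionStatus
    objective_value: float | None
    fluxes: dict[str, float]


def set_gam(
    model: StoichiometricModel,
    gam: float,
    id_map: Mapping[str, str] | None = None,
) -> StoichiometricModel:
    """Return a copy with the biomass ATP-hydrolysis coefficient set to ``gam``.

    The five hydrolysis species (ATP, H2O, ADP, Pi, H+) are shifted by the
    same delta so the hydrolysis part stays balanced; non-hydrolysis use of
    these species in the biomass reaction is untouched.
    """
    ids = dict(DEFAULT_ID_MAP, **(id_map or {}))
    if model.biomass_reaction_id is None:
        raise ModelEditError("model has no biomass reaction")
    out = model.copy()
    biomass = out.reactions[model.biomass_reaction_id]
    atp = ids["atp"]
    hydrolysis_species = [ids[k] for k in ("atp", "h2o", "adp", "pi", "h")]
    missing = [m for m in hydrolysis_species if m not in out.metabolites]
    if missing:
        raise ModelEditError(
            f"cannot rewrite GAM: model lacks hydrolysis species {missing}"
        )
    old_gam = -biomass.stoichiometry.get(atp, Fraction(0))
    delta = Fraction(repr(float(gam))) - old_gam
    if delta == 0:
        return out
    for met, sign in (
        (ids["atp"], -1), (ids["h2o"], -1),
        (ids["adp"], +1), (ids["pi"], +1), (ids["h"], +1),
    ):
        biomass.stoichiometry[met] = (
            biomass.stoichiometry.get(met, Fraction(0)) + sign * delta
        )
    return out


def _prepared_model(problem: FbaProblem) -> tuple[StoichiometricModel, dict[str, float]]:
    """Apply GAM rewrite and collect all fixed fluxes (mu, NGAM, user fixes)."""
    ids = dict(DEFAULT_ID_MAP, **problem.id_map)
    model = problem.model
    if problem.gam is not None:
        model = set_gam(model, problem.gam, ids)
    fixed = dict(problem.fixed_fluxes)
    if problem.mu is not None:
        if model.biomass_reaction_id is None:
            raise ModelEditError("cannot fix mu: model has no biomass reaction")
        fixed[model.biomass_reaction_id] = problem.mu
    if problem.ngam is not None:
        maintenance = ids["atp_maintenance"]
        if maintenance not in model.reactions:
            raise ModelEditError(
                f"cannot apply NGAM: no maintenance reaction {maintenance!r}"
            )
        fixed[maintenance] = problem.ngam
    return model, fixed


def solve_fba(problem: FbaProblem) -> FluxSolution:
    """Solve one FBA linear program.

    The objective *value* is unique at the optimum; the flux vector may be one
    of several degenerate alternative optima and is reported as such.
    """
    model, fixed = _prepared_model(problem)
    S, _, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    for rid, value in fixed.items():
        if rid not in model.reactions:
            raise KeyError(f"fixed flux names unknown reaction {rid!r}")
        j = rxn_ids.index(rid)
        lb[j] = ub[j] = value
    c = np.zeros(n)
    j_obj = rxn_ids.index(problem.objective_reaction_id)
    c[j_obj] = -1.0 if problem.objective_sense is Sense.MAXIMIZE else 1.0

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    if res.status == 2:
        return FluxSolution(SolutionStatus.INFEASIBLE, None, {})
    if res.status == 3:
        return FluxSolution(SolutionStatus.UNBOUNDED, None, {})
    if not res.success:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"LP solver failed: {res.message}")
    v = res.x
    residual = np.abs(S @ v).max() if n else 0.0
    if residual > CHECK_TOL:  # pragma: no cover - defensive
        raise RuntimeError(f"steady-state residual {residual:.2e} exceeds {CHECK_TOL}")
    objective = float(v[j_obj])
    return FluxSolution(
        SolutionStatus.OPTIMAL, objective, dict(zip(rxn_ids, map(float, v)))
    )


# ---------------------------------------------------------------------------
# yield prediction
# ---------------------------------------------------------------------------

@dataclass
class YieldPrediction:
    """Predicted biomass yield on formate for one pathway variant."""

    variant: str
    doubling_time: float            # h
    mu: float                       # h^-1
    formate_uptake: float           # mmol gCDW^-1 h^-1, magnitude (q > 0)
    yield_gcdw_per_mol: float       # Y = 1000 * mu / q
    fluxes: dict[str, float] = field(default_factory=dict)


def mu_from_doubling_time(doubling_time: float) -> float:
    """Growth rate mu = ln(2) / Td; exact, not the rounded chemostat label."""
    if doubling_time <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / doubling_time


def predict_yield(
    model: StoichiometricModel,
    variant: PathwayVariantSpec | None,
    doubling_time: float = 14.0,
    gam: float | None = 135.0,
    ngam: float | None = 3.0,
    id_map: Mapping[str, str] | None = None,
) -> YieldPrediction:
    """Predict the biomass yield on formate for one pathway variant.

    Applies the variant edits, fixes the biomass flux to mu = ln2/Td, applies
    GAM/NGAM, and maximizes the formate exchange flux.  Under the
    uptake-negative sign convention maximization drives the exchange flux as
    close to zero as growth allows, i.e. it minimizes the uptake magnitude —
    the only objective sense with a finite, biologically meaningful optimum
    at fixed growth rate.

    If the model is infeasible at the requested mu, the largest feasible mu
    is located by bisection (8 steps) and reported in the raised error.
    """
    ids = dict(DEFAULT_ID_MAP, **(id_map or {}))
    mu = mu_from_doubling_time(doubling_time)
    edited = apply_variant(model, variant) if variant is not None else model
    exchange_id = ids["formate_exchange"]
    if exchange_id not in edited.reactions:
        raise KeyError(f"model has no formate exchange reaction {exchange_id!r}")

    def _solve(mu_value: float) -> FluxSolution:
        problem = FbaProblem(
            model=edited,
            objective_reaction_id=exchange_id,
            objective_sense=Sense.MAXIMIZE,
            mu=mu_value,
            gam=gam,
            ngam=ngam,
            id_map=dict(ids),
        )
        return solve_fba(problem)

    solution = _solve(mu)
    if solution.status is not SolutionStatus.OPTIMAL:
        lo, hi = 0.0, mu
        for _ in range(8):
            mid = 0.5 * (lo + hi)
            if _solve(mid).status is SolutionStatus.OPTIMAL:
                lo = mid
            else:
                hi = mid
        raise YieldError(
            f"model infeasible at mu = {mu:.4g} h^-1 "
            f"(largest feasible mu found by bisection: {lo:.4g} h^-1)",
            max_feasible_mu=lo,
        )
    q = -solution.objective_value
    if q <= 0:
        raise YieldError(
            f"no net formate uptake at mu = {mu:.4g} h^-1 (q = {q:.4g})"
        )
    return YieldPrediction(
        variant=variant.variant.value if variant is not None else "as-is",
        doubling_time=doubling_time,
        mu=mu,
        formate_uptake=q,
        yield_gcdw_per_mol=1000.0 * mu / q,
        fluxes=solution.fluxes,
    )


def yield_vs_maintenance(
    model: StoichiometricModel,
    variant: PathwayVariantSpec,
    doubling_time: float,
    gam_grid,
    ngam_grid,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Sweep GAM and NGAM; one row per grid point.

    Yield is non-increasing in both maintenance parameters at fixed doubling
    time.  Per-point failures are recorded in the ``error`` column instead of
    aborting the sweep.
    """
    gam_grid, ngam_grid = list(gam_grid), list(ngam_grid)
    if not gam_grid or not ngam_grid:
        raise ValueError("gam_grid and ngam_grid must be nonempty")
    rows = []
    for gam in gam_grid:
        for ngam in ngam_grid:
            row = {"variant": str(variant.variant.value), "gam": gam, "ngam": ngam,
                   "doubling_time": doubling_time}
            try:
                pred = predict_yield(model, variant, doubling_time, gam, ngam, id_map)
                row.update(
                    mu=pred.mu, formate_uptake=pred.formate_uptake,
                    yield_gcdw_per_mol=pred.yield_gcdw_per_mol, error="",
                )
            except (YieldError, ModelEditError, KeyError) as exc:
                row.update(mu=math.nan, formate_uptake=math.nan,
                           yield_gcdw_per_mol=math.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)
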