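"""Generators for every input the pipeline needs, without downloads.

* :func:`build_core_model` - a ~30-reaction, fully element- and
  charge-balanced reduced network of formatotrophic *C. necator* metabolism:
  formate exchange and formate dehydrogenase, the complete reductive glycine
  pathway reaction set, a lumped Calvin-cycle module, transhydrogenase,
  lumped respiration, ATP maintenance and a single-precursor biomass
  reaction.  Both pathway-variant recipes apply to it cleanly.
* :func:`build_toy_yield_model` - a chain model with a closed-form optimal
  yield, for oracle tests.
* :func:`simulate_chemostat` - seeded replicate yield tables emulating
  steady-state chemostat sampling.
* :func:`random_network` - small random LP instances for solver
  cross-validation.

The core model's biomass is a single pyruvate + ATP + NADPH pseudo-reaction,
far simpler than a genome-scale biomass; its yields are therefore meaningful
for *ordering* (rGlyP vs CBB) and balance audits, not for reproducing
genome-scale yield values.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metnet import (
    DEFAULT_BOUND,
    Metabolite,
    Reaction,
    StoichiometricModel,
    parse_formula,
)

F = Fraction


@dataclass
class CoreModelSpec:
    """Parameters of the reduced core network.

    biomass_precursor_demand: mmol pyruvate-equivalent per gCDW (default 13,
    about 39 mmol biomass carbon per gCDW).  biomass_nadph_demand /
    biomass_nh4_demand: anabolic NADPH and nitrogen per gCDW.  gam: growth
    associated maintenance ATP (mmol gCDW^-1).  eta: ATP per NADH from
    lumped respiration (P/O-like, default 2).
    """

    include_variant_hooks: bool = True
    biomass_precursor_demand: float = 13.0
    biomass_nadph_demand: float = 10.0
    biomass_nh4_demand: float = 8.0
    gam: float = 135.0
    eta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("biomass_precursor_demand", "biomass_nadph_demand",
                     "biomass_nh4_demand", "gam", "eta"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"core-model spec: {name} must be positive")


_CORE_COMPOUNDS = {
    # cytosolic
    "for_c": ("CHO2", -1), "co2_c": ("CO2", 0), "o2_c": ("O2", 0),
    "nh4_c": ("H4N", 1), "h_c": ("H", 1), "h2o_c": ("H2O", 0),
    "pi_c": ("HO4P", -2),
    "atp_c": ("C10H12N5O13P3", -4), "adp_c": ("C10H12N5O10P2", -3),
    "nad_c": ("C21H26N7O14P2", -1), "nadh_c": ("C21H27N7O14P2", -2),
    "nadp_c": ("C21H25N7O17P3", -3), "nadph_c": ("C21H26N7O17P3", -4),
    "thf_c": ("C19H21N7O6", -2), "10fthf_c": ("C20H21N7O7", -2),
    "methf_c": ("C20H20N7O6", -1), "mlthf_c": ("C20H21N7O6", -2),
    "gly_c": ("C2H5NO2", 0), "ser_c": ("C3H7NO3", 0), "pyr_c": ("C3H3O3", -1),
    "ru5p_c": ("C5H9O8P", -2), "rubp_c": ("C5H8O11P2", -4),
    "3pg_c": ("C3H4O7P", -3), "13dpg_c": ("C3H4O10P2", -4),
    "g3p_c": ("C3H5O6P", -2),
    # external
    "for_e": ("CHO2", -1), "co2_e": ("CO2", 0), "o2_e": ("O2", 0),
    "nh4_e": ("H4N", 1), "h_e": ("H", 1), "h2o_e": ("H2O", 0),
    "pi_e": ("HO4P", -2),
}


def _frac(x: float) -> Fraction:
    return F(repr(float(x)))


def build_core_model(spec: CoreModelSpec | None = None) -> StoichiometricModel:
    """Build the reduced formatotrophic core network.

    Every non-exchange reaction is element- (C, H, O, N, P) and
    charge-balanced, including the biomass reaction, whose product pseudo-
    metabolite carries the composite formula implied by its precursor demand.
    The model is feasible on formate under both the CBB recipe and (after
    adding Ftl/Fch) the rGlyP recipe.
    """
    spec = spec or CoreModelSpec()
    mets = [
        Metabolite(mid, formula=parse_formula(formula), charge=charge,
                   compartment=mid.rsplit("_", 1)[-1])
        for mid, (formula, charge) in _CORE_COMPOUNDS.items()
    ]
    d = _frac(spec.biomass_precursor_demand)
    b = _frac(spec.biomass_nadph_demand)
    nn = _frac(spec.biomass_nh4_demand)
    g = _frac(spec.gam)
    eta = _frac(spec.eta)

    # biomass pseudo-metabolite: elements of d pyruvate + b (NADPH - NADP)
    # + nn NH4; charge follows so the synthesis reaction balances exactly.
    bio_formula = {
        "C": 3 * d,
        "H": 3 * d + b + 4 * nn,
        "O": 3 * d,
        "N": nn,
    }
    bio_charge = -d - b + nn
    # Metabolite formulas are integer maps; scale to integers if needed.
    if any(v.denominator != 1 for v in bio_formula.values()) or \
            bio_charge.denominator != 1:
        raise ValidationError(
            "core-model spec: biomass demands must give integer composition"
        )
    mets.append(
        Metabolite("biomass_c", name="biomass pseudo-species",
                   formula={k: int(v) for k, v in bio_formula.items()},
                   charge=int(bio_charge), compartment="c")
    )

    def ex(mid: str, lb: float = -DEFAULT_BOUND) -> Reaction:
        # formate exchange carries the genome-scale id so the default id map
        # applies unchanged to both the core model and the full GEM
        rid = "EX_formate_e" if mid == "for_e" else f"EX_{mid}"
        return Reaction(id=rid, stoichiometry={mid: F(-1)},
                        lower_bound=lb, upper_bound=DEFAULT_BOUND,
                        is_exchange=True, label=f"{mid} exchange")

    def tr(base: str) -> Reaction:
        return Reaction(id=f"T_{base}", stoichiometry={f"{base}_e": F(-1),
                                                       f"{base}_c": F(1)},
                        lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND,
                        label=f"{base} transport")

    rxns = [
        # boundary
        ex("for_e"), ex("co2_e"), ex("o2_e"), ex("nh4_e"),
        ex("h_e"), ex("h2o_e"), ex("pi_e"),
        tr("for"), tr("co2"), tr("o2"), tr("nh4"), tr("h"), tr("h2o"), tr("pi"),
        # formate dehydrogenase
        Reaction("FDH", {"for_c": F(-1), "nad_c": F(-1),
                         "co2_c": F(1), "nadh_c": F(1)},
                 lower_bound=0, label="formate dehydrogenase"),
        # rGlyP members present in the base network (Ftl/Fch are the variant
        # additions; methf_c/10fthf_c are their hook metabolites)
        Reaction("MtdA", {"methf_c": F(-1), "nadph_c": F(-1),
                          "mlthf_c": F(1), "nadp_c": F(1)},
                 lower_bound=-DEFAULT_BOUND,
                 label="methylene-THF dehydrogenase (NADP)"),
        # written in the glycine-cleaving direction; negative flux is the
        # reductive, glycine-synthesizing direction used by the rGlyP
        Reaction("GLYAMT", {"gly_c": F(-1), "thf_c": F(-1), "nad_c": F(-1),
                            "mlthf_c": F(1), "co2_c": F(1), "nh4_c": F(1),
                            "nadh_c": F(1)},
                 lower_bound=-DEFAULT_BOUND, label="glycine cleavage system"),
        Reaction("GlyA", {"gly_c": F(-1), "mlthf_c": F(-1), "h2o_c": F(-1),
                          "ser_c": F(1), "thf_c": F(1)},
                 lower_bound=-DEFAULT_BOUND,
                 label="serine hydroxymethyltransferase"),
        Reaction("SdaA", {"ser_c": F(-1), "pyr_c": F(1), "nh4_c": F(1)},
                 lower_bound=0, label="serine deaminase"),
        # Calvin module
        Reaction("Prk", {"ru5p_c": F(-1), "atp_c": F(-1),
                         "rubp_c": F(1), "adp_c": F(1), "h_c": F(1)},
                 lower_bound=0, label="phosphoribulokinase"),
        Reaction("RBPC", {"rubp_c": F(-1), "co2_c": F(-1), "h2o_c": F(-1),
                          "3pg_c": F(2), "h_c": F(2)},
                 lower_bound=0, label="RuBisCO"),
        Reaction("PGK", {"3pg_c": F(-1), "atp_c": F(-1),
                         "13dpg_c": F(1), "adp_c": F(1)},
                 lower_bound=-DEFAULT_BOUND, label="phosphoglycerate kinase"),
        Reaction("GAPDH", {"13dpg_c": F(-1), "nadh_c": F(-1), "h_c": F(-1),
                           "g3p_c": F(1), "nad_c": F(1), "pi_c": F(1)},
                 lower_bound=-DEFAULT_BOUND,
                 label="glyceraldehyde-3P dehydrogenase (NAD)"),
        Reaction("PPREGEN", {"g3p_c": F(-5), "h2o_c": F(-2),
                             "ru5p_c": F(3), "pi_c": F(2)},
                 lower_bound=0, label="lumped pentose-phosphate regeneration"),
        Reaction("PYKL", {"3pg_c": F(-1), "adp_c": F(-1), "h_c": F(-1),
                          "pyr_c": F(1), "atp_c": F(1), "h2o_c": F(1)},
                 lower_bound=0, label="lumped lower glycolysis"),
        # cofactor machinery
        Reaction("PntAB", {"nadh_c": F(-1), "nadp_c": F(-1),
                           "nad_c": F(1), "nadph_c": F(1)},
                 lower_bound=-DEFAULT_BOUND,
                 label="membrane-bound transhydrogenase"),
        Reaction("RESP", {"nadh_c": F(-1), "o2_c": F(-1) / 2,
                          "adp_c": -eta, "pi_c": -eta, "h_c": -(1 + eta),
                          "nad_c": F(1), "atp_c": eta, "h2o_c": 1 + eta},
                 lower_bound=0,
                 label=f"lumped respiration (eta = {spec.eta} ATP/NADH)"),
        Reaction("ATPM", {"atp_c": F(-1), "h2o_c": F(-1),
                          "adp_c": F(1), "pi_c": F(1), "h_c": F(1)},
                 lower_bound=0, label="ATP maintenance"),
        # biomass synthesis (GAM inside) and its drain
        Reaction("Biomass", {"pyr_c": -d, "nadph_c": -b, "nh4_c": -nn,
                             "atp_c": -g, "h2o_c": -g,
                             "biomass_c": F(1), "nadp_c": b,
                             "adp_c": g, "pi_c": g, "h_c": g},
                 lower_bound=0, label="biomass synthesis (single precursor)"),
        Reaction("DM_biomass", {"biomass_c": F(-1)},
                 lower_bound=0, upper_bound=DEFAULT_BOUND,
                 is_exchange=True, label="biomass drain"),
    ]
    if not spec.include_variant_hooks:
        hooks = {"MtdA", "GLYAMT", "RBPC", "Prk"}
        rxns = [r for r in rxns if r.id not in hooks]

    return StoichiometricModel(
        metabolites=mets, reactions=rxns,
        biomass_reaction_id="Biomass", objective_reaction_id="EX_formate_e",
        name="formayield_core",
    )


def build_toy_yield_model(
    substrate_per_biomass: float = 10.0, atp_per_substrate: float = 0.0
) -> StoichiometricModel:
    """Chain model with closed-form yield 1000/substrate_per_biomass.

    A_e is taken up, transported, and consumed by biomass at
    ``substrate_per_biomass`` mmol gCDW^-1; with zero maintenance the optimal
    yield equals 1000/substrate_per_biomass g CDW mol^-1 at any growth rate.
    With ``atp_per_substrate`` > 0 an ATP-producing catabolic branch and an
    ATP-maintenance reaction are added so NGAM > 0 lowers the yield.
    """
    if substrate_per_biomass <= 0:
        raise ValidationError("substrate_per_biomass must be positive")
    mets = [
        Metabolite("A_e", compartment="e"), Metabolite("A_c", compartment="c"),
        Metabolite("biomass_c", compartment="c"),
    ]
    s = _frac(substrate_per_biomass)
    rxns = [
        Reaction("EX_formate_e", {"A_e": F(-1)}, lower_bound=-DEFAULT_BOUND,
                 is_exchange=True, label="substrate exchange"),
        Reaction("T_A", {"A_e": F(-1), "A_c": F(1)},
                 lower_bound=-DEFAULT_BOUND),
        Reaction("Biomass", {"A_c": -s, "biomass_c": F(1)}, lower_bound=0),
        Reaction("DM_biomass", {"biomass_c": F(-1)}, lower_bound=0,
                 is_exchange=True),
    ]
    if atp_per_substrate > 0:
        # full hydrolysis quartet so GAM rewriting works on the toy as well
        mets += [Metabolite(m, compartment="c")
                 for m in ("atp_c", "adp_c", "pi_c", "h2o_c", "h_c")]
        a = _frac(atp_per_substrate)
        rxns += [
            Reaction("CAT", {"A_c": F(-1), "adp_c": -a, "pi_c": -a, "h_c": -a,
                             "atp_c": a, "h2o_c": a},
                     lower_bound=0, label="catabolism"),
            Reaction("ATPM", {"atp_c": F(-1), "h2o_c": F(-1), "adp_c": F(1),
                              "pi_c": F(1), "h_c": F(1)}, lower_bound=0),
        ]
    return StoichiometricModel(
        metabolites=mets, reactions=rxns,
        biomass_reaction_id="Biomass", name="toy_yield_chain",
    )


# ---------------------------------------------------------------------------
# chemostat simulation
# ---------------------------------------------------------------------------

@dataclass
class ChemostatSimSpec:
    """Replicate-sampling conditions of the chemostat yield comparison.

    Defaults are the study conditions: mean +/- SD yields of
    3.88 +/- 0.19 (CBB) and 4.52 +/- 0.17 (rGlyP) g CDW mol^-1, n = 9
    steady-state samples per strain over 3 days, 80 mM formate fed.
    """

    mean_yield_cbb: float = 3.88
    sd_yield_cbb: float = 0.19
    mean_yield_rglyp: float = 4.52
    sd_yield_rglyp: float = 0.17
    n_per_strain: int = 9
    formate_fed: float = 0.08  # mol l^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_yield_cbb < 0 or self.sd_yield_rglyp < 0:
            raise ValidationError("yield SDs must be >= 0")
        if self.n_per_strain < 2:
            raise ValidationError("need n >= 2 samples per strain")
        if self.formate_fed <= 0:
            raise ValidationError("formate fed must be positive")


def simulate_chemostat(spec: ChemostatSimSpec | None = None):
    """Draw per-sample yields (normal, truncated at 0) and build the table.

    CDW is yield * formate_fed; samples are spread evenly over 3 days.
    Bit-reproducible for a given seed.
    """
    from .chemostat import ChemostatSampleTable

    spec = spec or ChemostatSimSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for strain, mean, sd in (
        ("cbb", spec.mean_yield_cbb, spec.sd_yield_cbb),
        ("rglyp", spec.mean_yield_rglyp, spec.sd_yield_rglyp),
    ):
        yields = np.empty(spec.n_per_strain)
        for i in range(spec.n_per_strain):
            y = rng.normal(mean, sd)
            while y <= 0:  # truncate at 0; practically never triggers here
                y = rng.normal(mean, sd)
            yields[i] = y
        for i, y in enumerate(yields):
            rows.append({
                "strain": strain,
                "sample_id": f"{strain}_{i + 1:02d}",
                "cdw_g_per_l": y * spec.formate_fed,
                "formate_mol_per_l": spec.formate_fed,
                "day": i * 3 // spec.n_per_strain + 1,
            })
    return ChemostatSampleTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# random LP instances for solver cross-validation
# ---------------------------------------------------------------------------

def random_network(
    rng: np.random.Generator, n_metabolites: int = 8, n_reactions: int = 12
) -> StoichiometricModel:
    """A small random network with finite bounds (always feasible, bounded).

    A few single-metabolite exchanges plus random internal columns with
    coefficients in {-2, -1, 1, 2}; all bounds within [-10, 10], so v = 0 is
    feasible and every LP over it is bounded.
    """
    mets = [Metabolite(f"m{i}") for i in range(n_metabolites)]
    rxns: list[Reaction] = []
    n_exchanges = max(2, n_metabolites // 3)
    for j in range(n_exchanges):
        target = int(rng.integers(0, n_metabolites))
        rxns.append(Reaction(
            f"EX_{j}", {f"m{target}": F(-1)},
            lower_bound=float(rng.integers(-10, 0)),
            upper_bound=float(rng.integers(0, 11)),
            is_exchange=True,
        ))
    for j in range(n_reactions - n_exchanges):
        size = int(rng.integers(2, min(5, n_metabolites) + 1))
        members = rng.choice(n_metabolites, size=size, replace=False)
        coeffs = rng.choice([-2, -1, 1, 2], size=size)
        if (coeffs > 0).all() or (coeffs < 0).all():
            coeffs[0] = -coeffs[0]
        lb = float(rng.integers(-10, 1))
        ub = float(rng.integers(0, 11))
        rxns.append(Reaction(
            f"R_{j}", {f"m{m}": F(int(c)) for m, c in zip(members, coeffs)},
            lower_bound=lb, upper_bound=max(lb, ub),
        ))
    return StoichiometricModel(metabolites=mets, reactions=rxns,
                               name="random_network")
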