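# Methods

This note documents the models, numerical choices and limitations behind
`formayield`.  Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## The scientific question

Formate produced by electrochemical CO₂ reduction is an attractive microbial
feedstock, but assimilating it through the Calvin–Benson–Bassham (CBB) cycle
is energetically wasteful: all formate is first oxidized to CO₂ and NADH, and
carbon re-enters metabolism through RuBisCO at a high ATP price.  The
synthetic reductive glycine pathway (rGlyP) instead condenses formate-derived
C1 units (on tetrahydrofolate, THF) with CO₂ and ammonia into glycine via the
reverse glycine cleavage system, then serine, then pyruvate, assimilating two
of three pyruvate carbons directly from formate.  The package quantifies this
comparison three independent ways — net stoichiometry, thermodynamic driving
force, and constraint-based growth yield — and provides the statistics used
to compare measured chemostat yields between strains.

## Flux balance analysis and yield prediction

FBA is solved as an explicit LP with scipy's HiGHS backend: max/min c·v
subject to S·v = 0 and lb ≤ v ≤ ub, with feasibility tolerance 1e-9 and all
reported solutions re-checked to a steady-state residual ≤ 1e-6.  Only the
objective *value* is contractually reproducible; flux vectors may be one of
several degenerate optima and are reported as such.

Sign convention: exchange fluxes are negative for uptake, positive for
secretion.  Yield prediction fixes the biomass flux to μ = ln 2 / T_d
(the chemostat identity; μ for "14 h" is ln 2/14 ≈ 0.0495 h⁻¹, not the
rounded 0.05, and the CLI exposes both `--doubling-time` and
`--dilution-rate` framings) and *maximizes* the formate exchange flux.
Under the uptake-negative convention this is the only objective sense with a
finite, biologically meaningful optimum at fixed growth: it drives uptake
magnitude q to its minimum.  Then Y = 1000·μ/q in g CDW mol⁻¹ formate.

Maintenance enters in the standard two places.  GAM (default 135 mmol ATP
gCDW⁻¹) is the ATP-hydrolysis coefficient of the biomass reaction; the
`set_gam` rewrite shifts the five hydrolysis species (ATP, H₂O → ADP, Pi, H⁺)
by a common delta so maintenance sweeps stay balanced.  NGAM (default
3 mmol gCDW⁻¹ h⁻¹) is a fixed flux through the ATP-maintenance reaction.
`balance_biomass_atp` adds any missing water/proton stoichiometry to the
biomass hydrolysis part without touching the GAM magnitude.  If a requested μ
is infeasible, the largest feasible μ is bracketed by 8 bisection steps and
reported in the error.

Pathway variants are model edits, not separate models: the CBB recipe raises
the lower bound of the glycine cleavage reaction (`GLYAMT`, written in the
glycine-*cleaving* direction) to zero, blocking the reductive direction; the
rGlyP recipe adds formate–THF ligase (`Ftl`: formate + THF + ATP → 10-formyl-
THF + ADP + Pi) and methenyl-THF cyclohydrolase (`Fch`: 10-formyl-THF + H⁺ →
5,10-methenyl-THF + H₂O), reopens `GLYAMT` in both directions, and pins
RuBisCO (`RBPC`) to zero flux.  A two-column id-mapping table translates the
canonical species/reaction names to other model dialects; the defaults target
the RehMBEL1391 naming.  CO₂ exchange is left unbounded by default,
consistent with a CO₂-enriched headspace; users modelling CO₂-limited
regimes should bound it explicitly.

## Max–min driving force analysis

For reactions with transformed standard Gibbs energies ΔG′° (kJ mol⁻¹ at
pH 7.5, ionic strength 0.25 M, 1 mM Mg²⁺), the MDF is the optimum of the LP

    max B   s.t.  −(ΔG′°_j + RT Σᵢ s_ij ln cᵢ) ≥ B  for every reaction j,
                  ln(1 µM) ≤ ln cᵢ ≤ ln(10 mM)     for boxed compounds,

with water and protons excluded from the concentration variables (their
contributions are part of ΔG′° at the stated pH — the transformed-energy
convention).  Fixed concentrations (dissolved CO₂ at 3.4 mM by default)
override the box; fixed ratios (NADH/NAD⁺ = 0.1 by default) are exact linear
equalities ln c_num − ln c_den = ln r.  Ratio-tied compounds deliberately
*keep* the box, so removing a ratio is a pure relaxation and the relaxation-
monotonicity property (B never decreases when constraints are loosened) holds
by construction.  RT uses the constraint set's temperature, default 298.15 K.
Reversing every reaction and negating every ΔG′° does **not** preserve B in
general (it negates every driving force pointwise, turning the max–min into a
negated min–max); the suite documents the actual fwd/rev relationship on a
closed-form case and pins the true invariant B(k·pathway) = k·B(pathway),
k > 0.

The bundled ΔG′° tables for the two formate→pyruvate routes are
**reconstructed** values on the literature scale of component-contribution
estimates, shipped as labelled TSVs (`src/formayield/data/*_dg0.tsv`) with a
provenance column; the package does not implement the component-contribution
estimator.  MDF numbers computed from them characterize those tables —
useful for orderings, limiting-step identification and all LP properties —
and are validated against an exhaustive grid-search oracle, not against
published per-route values.  The CBB table uses the NAD couple at GAPDH; the
route scope is formate→pyruvate only (no electron transport chain).

Dissolved CO₂ uses Henry's law, c = k_H(T)·x·p, with the standard 25 °C
solubility k_H = 1/29.41 atm M⁻¹ = 0.0340 M atm⁻¹ and a van 't Hoff
temperature coefficient of 2400 K.  At 10 % CO₂ and 1 atm the reference
temperature gives 3.4 mM — the value used to fix CO₂ in the MDF comparison;
at 30 °C the same law gives ~3.0 mM.  The 3.4 mM figure is tied to the 25 °C
solubility and the MDF default temperature, which is why 298.15 K is the
package default despite cultivation temperatures being higher.

## Exact route energetics

Routes are ordered reaction lists with integer stoichiometries over compounds
with real elemental formulas and charges.  `net_conversion` finds
non-negative rational flux multipliers that zero every internal intermediate
and produce exactly +1 target (pyruvate), by Gaussian elimination over
`fractions.Fraction` — no floating point, so internal elimination is exact
and the audits are equalities, not tolerances: substrate carbon
(formate + CO₂) is exactly 3 per pyruvate, and the degree-of-reduction
balance (γ = 4C + H − 2O − 3N + 5P − charge; 2 for formate, 10 for pyruvate,
2 per NAD(P)H couple) closes exactly.  Free multipliers are set to zero with
left-to-right pivoting, a deterministic minimal-support, lexicographic
tie-break.  An independent sympy exact solve serves as the oracle in tests.

The bundled rGlyP route is FtfL, FchA, MtdA (NADP-dependent), the glycine
cleavage system written reductively (methylene-THF + CO₂ + NH₃ + NADH + H⁺ →
glycine + THF + NAD⁺), serine hydroxymethyltransferase, and serine deaminase
(ATP-neutral dehydration to pyruvate + NH₃).  The CBB route lumps
triose-phosphate recycling (5 GAP + 2 H₂O → 3 Ru5P + 2 Pi) and lower
glycolysis (3PG + ADP → pyruvate + ATP + H₂O) into one reaction each, so its
`reaction_count` of 6 counts lumped steps, not individual enzymes.  The GAPDH
cofactor is a route parameter (default NAD); switching to NADP moves cost
between the NADH and NADPH tallies without changing carbon or electron
totals.

`total_formate_per_pyruvate` converts cofactors to formate equivalents:
NADH 1:1 via formate dehydrogenase; NADPH via the membrane-bound
transhydrogenase PntAB at an overhead parameter (default 1 formate per
NADPH — the proton-translocation cost is a parameter, not a mechanistic
membrane model) or 1:1 when sourced directly; ATP at 1/η with η a P/O-like
ATP-per-NADH ratio.  At η = 2 this gives 6 (rGlyP) vs 8.5 (CBB) formate per
pyruvate, and the rGlyP total is strictly lower for every η > 0 because the
two routes differ by exactly 5 ATP at equal total reducing equivalents.

## Chemostat statistics

Per-sample yield is CDW (g l⁻¹) divided by formate consumed (mol l⁻¹).
Doubling time is ln 2/D; n reactor turnovers take n/D hours; plate-reader
OD₆₀₀ converts to cuvette OD₆₀₀ with the factor 4.35.  The two-strain
comparison offers pooled-variance and Welch unpaired t-tests (and a paired
variant), two-tailed p from the t survival function, and a 95 % CI on the
difference of means; both pooled and Welch degrees of freedom are always
reported because published legends are sometimes ambiguous about which was
used (for n = 9 + 9 the pooled df is 16, and the published CI for this
comparison is reproduced by df = 16, not by the legend's "d.f. = 8").
`two_sample_t_from_summary` applies the same machinery to printed means, SDs
and n.  Display rounding: yields to 2 decimals, percents to 1 decimal, hours
to the nearest integer; full precision is kept internally.

## Synthetic data

`build_core_model` emulates the formatotrophic *C. necator* network at desk
scale: formate/CO₂/O₂/NH₄⁺/Pi/H⁺/H₂O exchanges and transporters, formate
dehydrogenase, the rGlyP reaction set (with `Ftl`/`Fch` left for the variant
edit to add, as in the genome-scale workflow), a Calvin module (Prk, RuBisCO,
PGK, GAPDH, lumped regeneration, lumped lower glycolysis), transhydrogenase,
lumped respiration (NADH + ½O₂ → η ATP; η default 2, a typical bacterial
P/O-like value), ATP maintenance, and a biomass reaction consuming 13 mmol
pyruvate, 10 mmol NADPH, 8 mmol NH₄⁺ and GAM ATP per gCDW.  The precursor
demand corresponds to ~39 mmol biomass carbon gCDW⁻¹, a realistic cell carbon
content; the biomass pseudo-metabolite carries the composite formula implied
by its inputs so that *every* non-exchange reaction — biomass included — is
element- (C, H, O, N, P) and charge-balanced, which the suite audits
exactly.  Because the biomass is a single-precursor pseudo-reaction, the core
model's yields are contractually about ordering (rGlyP > CBB at the study
maintenance values) and limits (the η → ∞ redox bound
1000/(5·13 + 10) ≈ 13.3 g CDW mol⁻¹ for both variants), not about
reproducing genome-scale yield magnitudes.

`simulate_chemostat` draws per-sample yields from strain-specific normals
truncated at zero (defaults: 3.88 ± 0.19 and 4.52 ± 0.17 g CDW mol⁻¹, n = 9
per strain over 3 days, 0.08 mol l⁻¹ formate fed) with a seeded generator;
identical seeds give bit-identical tables.  It emulates steady-state
replicate sampling only — no bioreactor dynamics, lag, pH control or
wash-out.  Passing tests on these tables therefore demonstrates the
statistical machinery and power at the stated effect size, not robustness to
autocorrelated or drifting real reactor data.

`random_network` builds small random stoichiometric LPs with finite bounds
(always feasible, always bounded) for cross-validating the FBA solver against
an independent LP implementation; problem size defaults to 8 metabolites ×
12 reactions, and the suites use 30 instances.

## Numerical and I/O choices

* Stoichiometric coefficients are exact rationals in memory and serialized to
  SBML as decimals with 12 significant digits; short decimals (e.g. 1/2)
  round-trip exactly.
* SBML L3V1 is read/written via libsbml with COBRA-style `M_`/`R_` id
  prefixes added on write and stripped on read; fbc bounds are written, and
  fbc, legacy kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters, or the
  `reversible` flag (±1000 / 0–1000 defaults) are accepted on read.
* CLI tables are written with `repr` float formatting and sample tables are
  parsed with round-trip float precision, so CLI results equal direct module
  calls bit-for-bit.
* LP tolerances: solver feasibility 1e-9; reported-solution checks 1e-6;
  MDF limiting-reaction slack 1e-6.  Deterministic solver settings, no
  random restarts.

## Known limitations

* The ΔG′° fixtures are reconstructed, not the component-contribution output
  for the exact published conditions; MDF magnitudes depend on them.
* The core model's absolute yields are not calibrated to a genome-scale
  biomass; genome-scale yield checks require the external RehMBEL1391 file.
* No flux variability, parsimonious or dynamic FBA; no gap-filling or GPR
  logic; no membrane proton bookkeeping (PntAB overhead is a parameter).
* Formate consumption is an input to the statistics; chromatography
  processing is out of scope.
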