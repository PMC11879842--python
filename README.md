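# formayield

Tools for asking a quantitative question in one-carbon metabolic engineering:
**does the synthetic reductive glycine pathway (rGlyP) support a higher
biomass yield on formate than the native Calvin–Benson–Bassham (CBB) cycle in
*Cupriavidus necator*?**  The package covers the full computational side of
that comparison:

* **Constraint-based yield prediction** (`formayield.fba`, `formayield.metnet`) —
  flux balance analysis as an explicit linear program
  (max c·v s.t. S·v = 0, lb ≤ v ≤ ub), with the pathway-variant model edits
  (make the glycine cleavage reaction `GLYAMT` reversible and add the C1-module
  reactions `Ftl`/`Fch` for the rGlyP; force `GLYAMT` irreversible for the CBB;
  pin RuBisCO `RBPC` to zero flux to silence the Calvin cycle).  The biomass
  yield on formate is Y = 1000·μ/q (g CDW mol⁻¹), with the growth rate
  μ = ln 2 / T_d fixed (chemostat framing) and the formate uptake magnitude
  q (mmol gCDW⁻¹ h⁻¹) minimized, under growth-associated (GAM, ATP in the
  biomass reaction) and non-growth-associated (NGAM, fixed ATP-hydrolysis
  flux) maintenance.
* **Max–min driving force analysis** (`formayield.mdf`) — the largest B such
  that every pathway reaction can simultaneously have driving force
  −ΔG′ = −(ΔG′° + RT·Σᵢ sᵢ ln cᵢ) ≥ B with metabolite concentrations inside
  1 µM–10 mM (CO₂ fixed at its dissolved equilibrium value, NADH/NAD⁺ held at
  0.1), solved as a linear program in (B, ln c).
* **Exact pathway energetics** (`formayield.energetics`) — rational-arithmetic
  elimination of route intermediates, giving the net conversions
  `2 formate + CO₂ + 2 ATP + 2 NADPH + NADH → pyruvate` (rGlyP) and
  `3 CO₂ + 7 ATP + 5 NADH → pyruvate` (CBB), and the total formate demand per
  pyruvate once NADH (formate dehydrogenase), NADPH (transhydrogenase) and ATP
  (respiration at a P/O-like ratio η) are converted to formate equivalents.
* **Chemostat statistics** (`formayield.chemostat`) — dilution/doubling-time
  arithmetic, reactor-turnover times, per-sample yield computation
  (CDW / formate consumed), percent increase, and pooled/Welch two-sample
  t-tests, from sample tables or from published summary statistics.
* **Synthetic data** (`formayield.synth`) — a fully mass- and charge-balanced
  ~30-reaction *C. necator* core network that supports both pathway variants,
  closed-form toy models, seeded chemostat replicate tables, and random LP
  instances for solver cross-validation.

SBML Level 3 Version 1 models (fbc or legacy kinetic-law bounds) are read and
written via libsbml, so the analysis also runs directly on the published
genome-scale reconstruction of *C. necator* (RehMBEL1391) when that file is
available locally.

## Worked example

Predicted yields on the bundled core network at the chemostat condition
(doubling time 14 h, GAM = 135 mmol gCDW⁻¹, NGAM = 3 mmol gCDW⁻¹ h⁻¹):

```text
$ formayield predict-yield
variant  doubling_time_h  mu_per_h  formate_uptake_mmol_gcdw_h  yield_gcdw_per_mol
    cbb             14.0    0.0495                     10.8080              4.5809
  rglyp             14.0    0.0495                      9.1989              5.3822
```

The rGlyP variant needs ~15 % less formate at the same growth rate, so its
yield is higher — the same ordering measured in chemostats and predicted by
the genome-scale model.  (The core network's biomass is a single
pyruvate+ATP+NADPH pseudo-reaction, so its absolute yields are deliberately
not calibrated to genome-scale values; the contract is the ordering and the
exact balances.)

Thermodynamics of the two formate→pyruvate routes under the comparison
conditions (10 % CO₂ ⇒ 3.4 mM dissolved, NADH/NAD⁺ = 0.1, NAD-dependent
GAPDH for the CBB route):

```text
$ formayield mdf --no-per-reaction
route  mdf_kj_mol        limiting_reactions
rglyp       11.87                  GCS;MtdA
  cbb       25.33 PGK;PPREGEN;PYKL;Prk;RBPC
```

Both routes are thermodynamically feasible (B > 0); the rGlyP's driving force
is pinched at the reductive glycine cleavage step, the classic bottleneck of
that pathway.  The ΔG′° inputs are bundled, clearly-labelled reconstructed
estimates (see `docs/methods.md`), so these B values characterize the bundled
tables, not the published supplementary figures.

Net route costs per pyruvate, with all cofactors converted to formate at
η = 2 ATP/NADH:

```text
$ formayield energetics
route  reaction_count  atp_cost  nadph_cost  nadh_cost  formate_assimilated  co2_fixed  formate_total_per_pyruvate
rglyp               6       2.0         2.0        1.0                  2.0        1.0                         6.0
  cbb               6       7.0         0.0        5.0                  0.0        3.0                         8.5
```

6 vs 8.5 mol formate per mol pyruvate is the stoichiometric root of the yield
advantage: the rGlyP assimilates two of its three carbons directly from
formate instead of burning all formate for energy.

Statistics on measured (or simulated) chemostat samples:

```bash
formayield simulate chemostat --seed 1 -o samples.tsv
formayield chemostat --samples samples.tsv --test pooled
```

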