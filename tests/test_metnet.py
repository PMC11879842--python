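"""Model data structures, balance audits and pathway-variant editing."""

from fractions import Fraction

import pytest

from formayield.errors import ModelEditError, ValidationError
from formayield.metnet import (
    Metabolite,
    Reaction,
    StoichiometricModel,
    apply_variant,
    balance_biomass_atp,
    cbb_variant,
    check_balance,
    formula_to_string,
    parse_formula,
    read_id_map,
    rglyp_variant,
)

F = Fraction


def _hydrolysis_model(with_water: bool = True) -> StoichiometricModel:
    """ATP + H2O -> ADP + Pi + H with standard formulas and charges."""
    mets = [
        Metabolite("atp_c", formula=parse_formula("C10H12N5O13P3"), charge=-4),
        Metabolite("adp_c", formula=parse_formula("C10H12N5O10P2"), charge=-3),
        Metabolite("pi_c", formula=parse_formula("HO4P"), charge=-2),
        Metabolite("h2o_c", formula=parse_formula("H2O"), charge=0),
        Metabolite("h_c", formula=parse_formula("H"), charge=1),
    ]
    stoich = {"atp_c": F(-1), "adp_c": F(1), "pi_c": F(1)}
    if with_water:
        stoich |= {"h2o_c": F(-1), "h_c": F(1)}
    rxn = Reaction("ATPH", stoich, lower_bound=0)
    return StoichiometricModel(metabolites=mets, reactions=[rxn])


class TestParsing:
    @pytest.mark.parametrize(
        "formula, counts",
        [
            ("H2O", {"H": 2, "O": 1}),
            ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
            ("H", {"H": 1}),
            ("", {}),
        ],
    )
    def test_formula_round_trip(self, formula, counts):
        assert parse_formula(formula) == counts
        assert parse_formula(formula_to_string(counts)) == counts

    def test_malformed_formula_rejected(self):
        with pytest.raises(ValidationError):
            parse_formula("h2o")


class TestInvariants:
    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ValidationError):
            Reaction("r", {})

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            Reaction("r", {"a": F(1)}, lower_bound=1, upper_bound=-1)

    def test_exchange_touches_one_metabolite(self):
        with pytest.raises(ValidationError):
            Reaction("EX", {"a": F(-1), "b": F(1)}, is_exchange=True)

    def test_unknown_metabolite_reference_rejected(self):
        model = StoichiometricModel(metabolites=[Metabolite("a")])
        with pytest.raises(ValidationError):
            model.add_reaction(Reaction("r", {"ghost": F(1)}))

    def test_duplicate_ids_rejected(self):
        model = StoichiometricModel(metabolites=[Metabolite("a")])
        with pytest.raises(ValidationError):
            model.add_metabolite(Metabolite("a"))


class TestApplyVariant:
    def test_rglyp_edits(self, core_model, rglyp_spec):
        edited = apply_variant(core_model, rglyp_spec)
        assert "Ftl" in edited.reactions and "Fch" in edited.reactions
        assert edited.reactions["GLYAMT"].lower_bound < 0
        rbpc = edited.reactions["RBPC"]
        assert (rbpc.lower_bound, rbpc.upper_bound) == (0.0, 0.0)
        assert len(edited.reactions) == len(core_model.reactions) + 2

    def test_cbb_edits(self, core_model, cbb_spec):
        edited = apply_variant(core_model, cbb_spec)
        assert edited.reactions["GLYAMT"].lower_bound == 0
        assert len(edited.reactions) == len(core_model.reactions)

    def test_input_model_not_mutated(self, core_model, rglyp_spec):
        before = core_model.reactions["GLYAMT"].lower_bound
        apply_variant(core_model, rglyp_spec)
        assert core_model.reactions["GLYAMT"].lower_bound == before
        assert "Ftl" not in core_model.reactions

    def test_double_application(self, core_model, rglyp_spec, cbb_spec):
        once = apply_variant(core_model, rglyp_spec)
        with pytest.raises(ModelEditError, match="already present"):
            apply_variant(once, rglyp_spec)
        # the CBB recipe adds nothing, so it is idempotent
        twice = apply_variant(apply_variant(core_model, cbb_spec), cbb_spec)
        assert twice.reactions["GLYAMT"].lower_bound == 0

    def test_missing_reaction_reported(self, rglyp_spec):
        tiny = StoichiometricModel(
            metabolites=[Metabolite("a")],
            reactions=[Reaction("r", {"a": F(1)})],
        )
        with pytest.raises(ModelEditError, match="GLYAMT"):
            apply_variant(tiny, cbb_variant())
        with pytest.raises(ModelEditError):
            apply_variant(tiny, rglyp_spec)


class TestCheckBalance:
    def test_atp_hydrolysis_balanced(self):
        report = check_balance(_hydrolysis_model(), "ATPH")
        assert report.balanced and not report.element_imbalance
        assert report.charge_imbalance == 0

    def test_missing_water_deficit(self):
        # ATP -> ADP + Pi without water or proton; hand tally (products minus
        # reactants): H 13-12 = +1, O 14-13 = +1, charge -5-(-4) = -1, i.e.
        # exactly one H2O missing on the left and one H+ on the right
        report = check_balance(_hydrolysis_model(with_water=False), "ATPH")
        assert not report.balanced and not report.indeterminate
        assert report.element_imbalance["O"] == 1
        assert report.element_imbalance["H"] == 1
        assert report.charge_imbalance == -1

    def test_formula_less_metabolites_indeterminate(self):
        model = StoichiometricModel(
            metabolites=[Metabolite("x"), Metabolite("y")],
            reactions=[Reaction("r", {"x": F(-1), "y": F(1)})],
        )
        report = check_balance(model, "r")
        assert report.indeterminate and not report.balanced

    def test_exchange_indeterminate_by_design(self, core_model):
        report = check_balance(core_model, "EX_formate_e")
        assert report.indeterminate
        assert "by design" in report.reason

    def test_unknown_reaction(self, core_model):
        with pytest.raises(KeyError):
            check_balance(core_model, "nope")

    def test_core_model_fully_balanced(self, core_model):
        """Every non-exchange core reaction balances C, H, O, N, P and charge."""
        for rid, rxn in core_model.reactions.items():
            if rxn.is_exchange:
                continue
            report = check_balance(core_model, rid)
            assert report.balanced, (rid, report.element_imbalance,
                                     report.charge_imbalance)


class TestBalanceBiomassAtp:
    def _biomass_model(self, h2o=F(0), h=F(0)):
        mets = [
            Metabolite("atp_c", formula=parse_formula("C10H12N5O13P3"), charge=-4),
            Metabolite("adp_c", formula=parse_formula("C10H12N5O10P2"), charge=-3),
            Metabolite("pi_c", formula=parse_formula("HO4P"), charge=-2),
            Metabolite("h2o_c", formula=parse_formula("H2O"), charge=0),
            Metabolite("h_c", formula=parse_formula("H"), charge=1),
            Metabolite("x_c"),
        ]
        stoich = {"atp_c": F(-50), "adp_c": F(50), "pi_c": F(50), "x_c": F(1)}
        if h2o:
            stoich["h2o_c"] = h2o
        if h:
            stoich["h_c"] = h
        rxn = Reaction("Biomass", stoich, lower_bound=0)
        return StoichiometricModel(metabolites=mets, reactions=[rxn],
                                   biomass_reaction_id="Biomass")

    def test_missing_water_and_proton_added_in_gam_amount(self):
        out = balance_biomass_atp(self._biomass_model())
        biomass = out.reactions["Biomass"]
        assert biomass.stoichiometry["h2o_c"] == F(-50)
        assert biomass.stoichiometry["h_c"] == F(50)
        assert biomass.stoichiometry["atp_c"] == F(-50)  # GAM unchanged

    def test_already_balanced_unchanged(self):
        model = self._biomass_model(h2o=F(-50), h=F(50))
        out = balance_biomass_atp(model)
        assert (out.reactions["Biomass"].stoichiometry
                == model.reactions["Biomass"].stoichiometry)

    def test_hydrolysis_part_balances_after_edit(self):
        out = balance_biomass_atp(self._biomass_model())
        s = out.reactions["Biomass"].stoichiometry
        hydrolysis = Reaction("hyd", {k: s[k] for k in
                                      ("atp_c", "adp_c", "pi_c", "h2o_c", "h_c")})
        probe = StoichiometricModel(
            metabolites=list(out.metabolites.values()), reactions=[hydrolysis]
        )
        assert check_balance(probe, "hyd").balanced

    def test_missing_atp_species(self):
        model = StoichiometricModel(
            metabolites=[Metabolite("x")],
            reactions=[Reaction("Biomass", {"x": F(1)})],
            biomass_reaction_id="Biomass",
        )
        with pytest.raises(ModelEditError):
            balance_biomass_atp(model)


def test_id_map_overrides_defaults(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("# canonical\tmodel-id\nformate\tM_for\nglyamt\tGCSr\n")
    mapping = read_id_map(path)
    assert mapping["formate"] == "M_for"
    assert mapping["glyamt"] == "GCSr"
    assert mapping["atp"] == "atp_c"  # untouched default
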