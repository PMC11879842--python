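"""Exact route accounting against an independent symbolic linear-algebra oracle."""

from fractions import Fraction

import pytest

from formayield.energetics import (
    NadphSource,
    RouteDefinition,
    RouteName,
    carbon_in_net,
    cbb_route,
    compare_routes,
    degree_of_reduction,
    electron_balance,
    net_conversion,
    rglyp_route,
    total_formate_per_pyruvate,
)
from formayield.errors import RouteError
from formayield.metnet import Reaction

F = Fraction


def _sympy_net_conversion(route: RouteDefinition) -> dict[str, Fraction]:
    """Independent oracle: solve the elimination system with sympy, exactly."""
    import sympy

    rxns = route.reactions
    constraints = sorted(route.internal_compounds) + [route.target]
    A = sympy.Matrix([
        [sympy.Rational(r.stoichiometry.get(cid, 0)) for r in rxns]
        for cid in constraints
    ])
    b = sympy.Matrix([0] * len(route.internal_compounds) + [1])
    solution, params = A.gauss_jordan_solve(b)
    solution = solution.subs({p: 0 for p in params})
    return {
        r.id: Fraction(int(sympy.fraction(v)[0]), int(sympy.fraction(v)[1]))
        for r, v in zip(rxns, solution)
    }


class TestNetConversion:
    def test_rglyp_tallies(self):
        """2 formate + CO2 + 2 ATP + 2 NADPH + NADH -> pyruvate, THF/NH3 internal."""
        net = net_conversion(rglyp_route())
        t = net.tallies
        assert t["formate_assimilated"] == 2
        assert t["co2_fixed"] == 1
        assert t["atp_cost"] == 2
        assert t["nadph_cost"] == 2
        assert t["nadh_cost"] == 1
        assert t["reaction_count"] == 6
        assert net.net_stoichiometry["pyr"] == 1
        for internal in ("thf", "10fthf", "methf", "mlthf", "gly", "ser", "nh3"):
            assert internal not in net.net_stoichiometry

    def test_cbb_tallies(self):
        """3 CO2 + 7 ATP + 5 NADH -> pyruvate with NAD-dependent GAPDH."""
        net = net_conversion(cbb_route())
        t = net.tallies
        assert t["co2_fixed"] == 3
        assert t["atp_cost"] == 7
        assert t["nadh_cost"] == 5
        assert t["nadph_cost"] == 0
        assert t["formate_assimilated"] == 0
        assert net.net_stoichiometry["pyr"] == 1

    def test_gapdh_cofactor_switch_moves_cost_not_totals(self):
        nad = net_conversion(cbb_route("nad")).tallies
        nadp = net_conversion(cbb_route("nadp")).tallies
        assert nadp["nadph_cost"] == nad["nadh_cost"] == 5
        assert nadp["nadh_cost"] == nad["nadph_cost"] == 0
        assert (nad["nadh_cost"] + nad["nadph_cost"]
                == nadp["nadh_cost"] + nadp["nadph_cost"])
        assert nad["atp_cost"] == nadp["atp_cost"]

    @pytest.mark.parametrize("route_factory", [rglyp_route, cbb_route])
    def test_matches_sympy_oracle(self, route_factory):
        route = route_factory()
        ours = net_conversion(route).flux_multipliers
        oracle = _sympy_net_conversion(route)
        assert ours == oracle

    @pytest.mark.parametrize("route_factory", [rglyp_route, cbb_route])
    def test_exact_carbon_and_electron_balance(self, route_factory):
        net = net_conversion(route_factory())
        assert carbon_in_net(net) == 3  # exactly three substrate carbons
        consumed, produced = electron_balance(net)
        assert consumed == produced  # exact rational equality
        # substrate electrons equal pyruvate's degree of reduction (10)
        t = net.tallies
        substrate_electrons = (
            2 * t["formate_assimilated"]
            + 2 * (t["nadh_cost"] + t["nadph_cost"])
        )
        assert substrate_electrons == degree_of_reduction("pyr") == 10

    def test_internal_elimination_is_exact_rational_zero(self):
        net = net_conversion(rglyp_route())
        route = rglyp_route()
        for cid in route.internal_compounds:
            total = sum(
                (net.flux_multipliers[r.id] * r.stoichiometry.get(cid, F(0))
                 for r in route.reactions),
                F(0),
            )
            assert total == F(0)

    def test_empty_route_rejected(self):
        with pytest.raises(RouteError):
            net_conversion(RouteDefinition(
                name=RouteName.RGLYP, reactions=[], internal_compounds=set()))

    def test_unbalanceable_intermediate_reported(self):
        # the intermediate is produced but never consumed
        route = RouteDefinition(
            name=RouteName.CBB,
            reactions=[
                Reaction("r1", {"x": F(1), "orphan": F(1)}, lower_bound=0),
            ],
            internal_compounds={"orphan"},
            target="x",
        )
        with pytest.raises(RouteError):
            net_conversion(route)

    def test_random_chain_routes_match_oracle(self, rng):
        """20 random feasible conversion chains agree with the sympy oracle."""
        for _ in range(20):
            n = int(rng.integers(2, 6))
            reactions = []
            for i in range(n):
                stoich = {f"x{i}": F(-int(rng.integers(1, 4))),
                          f"x{i + 1}": F(int(rng.integers(1, 4)))}
                if rng.random() < 0.5:  # random external cofactor
                    stoich["cof"] = F(int(rng.integers(-2, 3)) or 1)
                reactions.append(Reaction(f"r{i}", stoich, lower_bound=0))
            route = RouteDefinition(
                name=RouteName.RGLYP,
                reactions=reactions,
                internal_compounds={f"x{i}" for i in range(1, n)},
                target=f"x{n}",
            )
            net = net_conversion(route)
            assert net.flux_multipliers == _sympy_net_conversion(route)
            assert net.net_stoichiometry[f"x{n}"] == 1


class TestFormateTotals:
    def test_zero_cofactor_costs(self):
        net = net_conversion(rglyp_route())
        bare = net_conversion(rglyp_route())
        for key in ("atp_cost", "nadph_cost", "nadh_cost"):
            bare.tallies[key] = F(0)
        assert total_formate_per_pyruvate(bare) == bare.tallies[
            "formate_assimilated"]
        assert total_formate_per_pyruvate(net) > total_formate_per_pyruvate(bare)

    def test_rglyp_hand_arithmetic(self):
        """2 assimilated + 1 NADH + 2 NADPH + 2 ATP / 2 = 6 formate/pyruvate."""
        net = net_conversion(rglyp_route())
        assert total_formate_per_pyruvate(net, atp_per_nadh=2) == F(6)
        # CBB: 0 + 5 NADH + 7 ATP / 2 = 8.5
        assert total_formate_per_pyruvate(
            net_conversion(cbb_route()), atp_per_nadh=2) == F(17, 2)

    def test_monotone_in_atp_per_nadh(self):
        net = net_conversion(cbb_route())
        totals = [total_formate_per_pyruvate(net, apn)
                  for apn in (0.5, 1, 1.5, 2, 3, 10)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_rglyp_cheaper_for_any_ratio(self):
        """rGlyP needs strictly less formate per pyruvate for all P/O in (0, 10]."""
        rg = net_conversion(rglyp_route())
        cb = net_conversion(cbb_route())
        for apn in (F(1, 100), F(1, 2), F(1), F(3, 2), F(2), F(3), F(10)):
            assert (total_formate_per_pyruvate(rg, apn)
                    < total_formate_per_pyruvate(cb, apn))

    def test_direct_nadph_source_ignores_overhead(self):
        net = net_conversion(rglyp_route())
        trans = total_formate_per_pyruvate(
            net, 2, NadphSource.TRANSHYDROGENASE, transhydrogenase_overhead=F(3, 2))
        direct = total_formate_per_pyruvate(
            net, 2, NadphSource.DIRECT, transhydrogenase_overhead=F(3, 2))
        assert trans > direct == F(6)

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            total_formate_per_pyruvate(net_conversion(rglyp_route()), 0)


class TestCompareRoutes:
    def test_table_ordering(self):
        table = compare_routes().set_index("route")
        assert table.loc["rglyp", "atp_cost"] < table.loc["cbb", "atp_cost"]
        assert (table.loc["rglyp", "formate_total_per_pyruvate"]
                < table.loc["cbb", "formate_total_per_pyruvate"])

    def test_identical_route_twice_is_all_equal(self):
        table = compare_routes(rglyp=rglyp_route(), cbb=rglyp_route())
        numeric = table.drop(columns="route")
        assert (numeric.iloc[0] == numeric.iloc[1]).all()

    def test_ordering_preserved_across_sweep(self):
        for apn in (1, 1.5, 2, 3):
            table = compare_routes(atp_per_nadh=apn).set_index("route")
            assert (table.loc["rglyp", "formate_total_per_pyruvate"]
                    < table.loc["cbb", "formate_total_per_pyruvate"])

    def test_mdf_column_present_when_requested(self):
        table = compare_routes(include_mdf=True)
        assert "mdf_kj_mol" in table.columns
        assert table["mdf_kj_mol"].notna().all()
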