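"""Elemental partitioning, cross-condition correlation, production and
flux-map comparison."""

import copy
import math

import pytest

from diazogem.core_model import (
    DiazogemError,
    MetabolicModel,
    Metabolite,
    ReactionRecord,
    apply_medium,
    parse_formula,
)
from diazogem.fba import FluxDistribution, fba, pfba
from diazogem.partition import (
    add_sink,
    build_element_flux_table,
    compare_conditions,
    compare_flux_maps,
    element_throughput,
    normalize_flux_map,
    partition_fluxes,
    production_rate,
)
from diazogem.synth import toy_medium


def _met(mid, formula, charge=0):
    return Metabolite(id=mid, formula=formula, charge=charge,
                      compartment=mid.rsplit("_", 1)[1])


class TestElementThroughput:
    def test_glycolytic_carbon_count(self):
        mets = {"glc__D_c": _met("glc__D_c", "C6H12O6"),
                "pyr_c": _met("pyr_c", "C3H3O3", -1)}
        rxn = ReactionRecord(id="R", stoichiometry={"glc__D_c": -1, "pyr_c": 2},
                             lower_bound=0, upper_bound=1000)
        assert element_throughput(rxn, 2.0, "C", mets) == pytest.approx(12.0)

    def test_zero_flux_zero_throughput(self, toy):
        for rxn in toy.reactions.values():
            assert element_throughput(rxn, 0.0, "C", toy.metabolites) == 0.0

    def test_dinitrogen_reduction_ammonia_count(self):
        # bare N2 + 3 H2 -> 2 NH3: product-side nitrogen throughput at
        # v = 1 is 2 (hand count)
        mets = {"n2_c": _met("n2_c", "N2"), "h2_c": _met("h2_c", "H2"),
                "nh3_c": _met("nh3_c", "H3N")}
        rxn = ReactionRecord(id="R", stoichiometry={"n2_c": -1, "h2_c": -3,
                                                    "nh3_c": 2},
                             lower_bound=0, upper_bound=1000)
        assert element_throughput(rxn, 1.0, "N", mets) == pytest.approx(2.0)

    def test_toy_nitrogenase_matches_bruteforce_tally(self, toy):
        rxn = toy.reactions["NIT"]
        expected = sum(
            coeff * parse_formula(toy.metabolites[m].formula).get("N", 0)
            for m, coeff in rxn.products().items()
        )
        assert element_throughput(rxn, 1.0, "N", toy.metabolites) == pytest.approx(
            expected)

    def test_balanced_reactions_product_equals_substrate_side(self, toy):
        from diazogem.qc import element_balance

        report = element_balance(toy)
        for rid in report.imbalances:
            if not report.is_balanced(rid):
                continue
            rxn = toy.reactions[rid]
            for element in ("C", "N"):
                prod = sum(
                    c * parse_formula(toy.metabolites[m].formula).get(element, 0)
                    for m, c in rxn.products().items())
                sub = sum(
                    c * parse_formula(toy.metabolites[m].formula).get(element, 0)
                    for m, c in rxn.substrates().items())
                assert prod == pytest.approx(sub, abs=1e-9)


class TestPartitionFluxes:
    def test_subsystem_mean_includes_zeros(self):
        model = MetabolicModel(id="m")
        for mid in ("a_c", "b_c", "x_c"):
            model.add_metabolite(_met(mid, "C2H4O2"))
        model.add_reaction(ReactionRecord(
            id="R1", stoichiometry={"a_c": -1, "b_c": 1}, lower_bound=0,
            upper_bound=1000, subsystem="S"))
        model.add_reaction(ReactionRecord(
            id="R2", stoichiometry={"a_c": -1, "x_c": 1}, lower_bound=0,
            upper_bound=1000, subsystem="S"))
        dist = FluxDistribution(fluxes={"R1": 2.0, "R2": 0.0})
        table = partition_fluxes(model, dist, "C")
        # throughputs {4, 0} -> mean 2
        assert table.averages["S"] == pytest.approx(2.0)

    def test_blocked_subsystem_reports_zero(self, toy):
        medium = toy_medium()
        medium["EX_nh4_e"] = (0.0, 1000.0)
        medium["EX_n2_e"] = (-1000.0, 1000.0)
        dist = pfba(apply_medium(toy, medium))
        table = partition_fluxes(toy, dist, "C")
        assert table.averages["Secondary metabolites biosynthesis"] == pytest.approx(
            0.0, abs=1e-6)

    def test_transport_and_exchange_flagged_excluded(self, toy):
        dist = pfba(apply_medium(toy, toy_medium()))
        table = partition_fluxes(toy, dist, "C")
        assert "Transport" in table.excluded
        assert "Exchange" in table.excluded
        assert "Transport" not in table.headline()

    def test_entries_nonnegative(self, toy):
        dist = pfba(apply_medium(toy, toy_medium()))
        for element in ("C", "N"):
            table = partition_fluxes(toy, dist, element)
            assert all(v >= 0 for v in table.averages.values())


class TestCompareConditions:
    def _two_condition_tables(self, toy):
        dists = {
            src: pfba(apply_medium(toy, toy_medium(f"EX_{src}_e")))
            for src in ("glc__D", "fru", "pyr")
        }
        return build_element_flux_table(toy, dists, "C")

    def test_identical_tables_correlate_perfectly(self, toy):
        table = self._two_condition_tables(toy)
        corr = compare_conditions(table, copy.deepcopy(table))
        for sub, r in corr.r.items():
            if r is not None:
                assert r == pytest.approx(1.0)
        assert corr.global_percent_change == pytest.approx(0.0, abs=1e-9)

    def test_scaled_table_keeps_r_changes_total(self, toy):
        table = self._two_condition_tables(toy)
        scaled = copy.deepcopy(table)
        scaled.data = scaled.data * 0.95
        corr = compare_conditions(scaled, table)
        for r in corr.r.values():
            if r is not None:
                assert r == pytest.approx(1.0)
        assert corr.global_percent_change == pytest.approx(-5.0, abs=1e-9)

    def test_rescaling_both_tables_leaves_r_invariant(self, toy):
        table = self._two_condition_tables(toy)
        a, b = copy.deepcopy(table), copy.deepcopy(table)
        b.data = b.data * 1.7
        base = compare_conditions(a, b)
        a2, b2 = copy.deepcopy(a), copy.deepcopy(b)
        a2.data, b2.data = a2.data * 3.0, b2.data * 3.0
        again = compare_conditions(a2, b2)
        for sub in base.r:
            if base.r[sub] is not None:
                assert again.r[sub] == pytest.approx(base.r[sub])

    def test_nitrogen_subsystem_decorrelates_under_diazotrophy(self, toy):
        sources = ("glc__D", "fru", "pyr")
        diazo = build_element_flux_table(
            toy,
            {s: pfba(apply_medium(toy, toy_medium(f"EX_{s}_e", diazotrophic=True)))
             for s in sources},
            "N",
        )
        nondiazo = build_element_flux_table(
            toy,
            {s: pfba(apply_medium(toy, toy_medium(f"EX_{s}_e", diazotrophic=False)))
             for s in sources},
            "N",
        )
        corr = compare_conditions(diazo, nondiazo)
        # nitrogenase only runs diazotrophically: its subsystem cannot
        # correlate as well as core carbon metabolism
        core = corr.r.get("Carbohydrate metabolism")
        nitro = corr.r.get("Nitrogen metabolism")
        assert core is not None and core > 0.9
        assert nitro is None or nitro < core

    def test_mismatched_tables_rejected(self, toy):
        table = self._two_condition_tables(toy)
        other = copy.deepcopy(table)
        other.data = other.data.iloc[:-1]
        with pytest.raises(DiazogemError):
            compare_conditions(table, other)


class TestSinksAndProduction:
    def test_sink_added_and_harmless(self, toy):
        base = fba(apply_medium(toy, toy_medium())).objective_value
        with_sink = add_sink(toy, "phb_c")
        assert "SK_phb_c" in with_sink.reactions
        after = fba(apply_medium(with_sink, toy_medium())).objective_value
        assert after == pytest.approx(base, rel=1e-9)

    def test_sink_idempotent(self, toy):
        once = add_sink(toy, "phb_c")
        twice = add_sink(once, "phb_c")
        assert len(twice.reactions) == len(once.reactions)

    def test_unknown_metabolite_rejected(self, toy):
        with pytest.raises(DiazogemError):
            add_sink(toy, "ghost_c")

    def test_growth_coupled_alginate_matches_bof_coefficient(self, toy):
        from diazogem.synth import ALGINATE_BOF_COEFFICIENT

        mu, alg_flux = production_rate(
            toy, "ALGE", toy_medium(), growth_fraction=1.0,
            objective_id="BOF_alg")
        assert alg_flux == pytest.approx(ALGINATE_BOF_COEFFICIENT * mu, rel=1e-6)

    def test_zero_growth_fraction_maximizes_yield(self, toy):
        with_sink = add_sink(toy, "phb_c")
        _, coupled = production_rate(with_sink, "SK_phb_c", toy_medium(), 1.0)
        _, free = production_rate(with_sink, "SK_phb_c", toy_medium(), 0.0)
        assert free >= coupled - 1e-9
        assert free > 0

    def test_ammonium_supports_more_production_than_n2(self, toy):
        # growth-coupled alginate secretion at equal carbon uptake: the
        # ATP cost of nitrogen fixation lowers both growth and production
        _, nondiazo = production_rate(
            toy, "ALGE", toy_medium(diazotrophic=False), 1.0,
            objective_id="BOF_alg")
        _, diazo = production_rate(
            toy, "ALGE", toy_medium(diazotrophic=True), 1.0,
            objective_id="BOF_alg")
        assert nondiazo >= diazo - 1e-6
        assert diazo > 0

    def test_reproducible_across_runs(self, toy):
        a = production_rate(toy, "ALGE", toy_medium(), 1.0, objective_id="BOF_alg")
        b = production_rate(toy, "ALGE", toy_medium(), 1.0, objective_id="BOF_alg")
        assert a == b


class TestFluxMaps:
    def test_anchor_maps_to_hundred(self):
        dist = FluxDistribution(fluxes={"EX_glc": -5.0, "R": 2.5})
        normalized = normalize_flux_map(dist, "EX_glc")
        assert normalized["EX_glc"] == pytest.approx(-100.0)
        assert normalized["R"] == pytest.approx(50.0)

    def test_zero_anchor_rejected(self):
        with pytest.raises(DiazogemError):
            normalize_flux_map(FluxDistribution(fluxes={"A": 0.0}), "A")

    def test_normalization_idempotent_and_ratio_preserving(self):
        dist = FluxDistribution(fluxes={"A": -4.0, "B": 3.0, "C": 1.0})
        once = normalize_flux_map(dist, "A")
        twice = normalize_flux_map(FluxDistribution(fluxes=once), "A")
        assert once == pytest.approx(twice)
        assert once["B"] / once["C"] == pytest.approx(3.0)

    def test_percent_error_thresholds(self):
        cmp = compare_flux_maps({"ok": 90.0, "bad": 130.0, "same": 10.0},
                                {"ok": 100.0, "bad": 100.0, "same": 10.0})
        assert cmp.percent_error["ok"] == pytest.approx(10.0)
        assert cmp.agree["ok"] and not cmp.agree["bad"]
        assert cmp.percent_error["same"] == 0.0
        assert cmp.n_disagree == 1

    def test_zero_reference_handling(self):
        cmp = compare_flux_maps({"a": 0.0, "b": 1.0}, {"a": 0.0, "b": 0.0})
        assert cmp.percent_error["a"] == 0.0
        assert math.isinf(cmp.percent_error["b"]) and "b" in cmp.infinite

    def test_identical_maps_full_agreement(self):
        ref = {"a": 1.0, "b": -2.0}
        cmp = compare_flux_maps(ref, dict(ref))
        assert cmp.n_agree == 2 and all(e == 0 for e in cmp.percent_error.values())
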