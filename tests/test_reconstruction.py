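"""Curation and gap-filling: hit filtering, GPR remapping, pruning,
dead-end classification, minimal gap-fill sets."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from diazogem.core_model import (
    GprTree,
    MetabolicModel,
    Metabolite,
    ReactionRecord,
    apply_medium,
)
from diazogem.fba import fba
from diazogem.reconstruction import (
    GROWTH_THRESHOLD,
    HomologyHit,
    best_hit_mapping,
    classify_dead_ends,
    filter_hits,
    gapfill,
    prune_exogenous,
    read_hits,
    remap_gpr,
    write_hits,
)
from diazogem.synth import toy_medium

from conftest import build_toy3


def hit(identity, evalue, coverage, q="t1", s="a1"):
    return HomologyHit(query=q, subject=s, identity=identity, evalue=evalue,
                       coverage=coverage)


class TestFilterHits:
    def test_clear_pass(self):
        assert filter_hits([hit(45.0, 1e-10, 90)]) != []

    def test_exact_boundary_inclusive(self):
        assert filter_hits([hit(40.0, 1e-4, 85.0)]) != []

    @pytest.mark.parametrize(
        "identity,evalue,coverage",
        [(39.9, 1e-10, 99), (60, 1e-2, 99), (60, 1e-10, 84)],
    )
    def test_each_criterion_alone_fails(self, identity, evalue, coverage):
        assert filter_hits([hit(identity, evalue, coverage)]) == []

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100), st.floats(1e-200, 1.0), st.floats(0, 100)
            ),
            max_size=30,
        ),
        st.floats(0, 100),
        st.floats(1e-200, 1e-2),
        st.floats(0, 100),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_each_threshold(self, rows, min_id, max_ev, min_cov):
        hits = [hit(i, e, c, q=f"q{k}") for k, (i, e, c) in enumerate(rows)]
        base = set(
            (h.query, h.subject)
            for h in filter_hits(hits, min_id, max_ev, min_cov)
        )
        relaxed = set(
            (h.query, h.subject)
            for h in filter_hits(hits, min_id / 2, max_ev * 2, min_cov / 2)
        )
        assert base <= relaxed

    def test_tsv_roundtrip(self, tmp_path):
        hits = [hit(45, 1e-10, 90, q="tA", s="gA"), hit(30, 1e-2, 50, q="tB", s="gB")]
        path = tmp_path / "hits.tsv"
        write_hits(hits, path)
        assert read_hits(path) == hits


class TestBestHitMapping:
    def test_lowest_evalue_wins(self):
        hits = [hit(50, 1e-10, 90, s="a1"), hit(90, 1e-5, 90, s="a2")]
        assert best_hit_mapping(hits) == {"t1": "a1"}

    def test_ties_broken_by_identity_then_subject(self):
        hits = [hit(50, 1e-10, 90, s="a2"), hit(80, 1e-10, 90, s="a3"),
                hit(80, 1e-10, 90, s="a1")]
        assert best_hit_mapping(hits) == {"t1": "a1"}


class TestRemapGpr:
    def test_full_complex_mapped(self):
        out = remap_gpr(GprTree.from_string("tA and tB"),
                        {"tA": "gA", "tB": "gB"})
        assert out.gpr.to_string() == "gA and gB"
        assert not out.exogenous_only

    def test_or_drops_unmapped_leaf(self):
        out = remap_gpr(GprTree.from_string("tA or tB"), {"tA": "gA"})
        assert out.gpr.to_string() == "gA"

    def test_strict_never_asserts_partial_complex(self):
        # truth-table check: under strict policy the remapped GPR is active
        # only when the full original complex had all subunits mapped
        tree = GprTree.from_string("(tA and tB) or tC")
        for mapped in itertools.chain.from_iterable(
            itertools.combinations(["tA", "tB", "tC"], k) for k in range(4)
        ):
            mapping = {t: t.replace("t", "g") for t in mapped}
            out = remap_gpr(tree, mapping, policy="strict")
            full_and = {"tA", "tB"} <= set(mapped)
            has_tc = "tC" in mapped
            if not full_and and not has_tc:
                assert out.exogenous_only
            else:
                active_genes = out.gpr.genes()
                if full_and and not has_tc:
                    assert active_genes == {"gA", "gB"}
                if has_tc and not full_and:
                    assert active_genes == {"gC"}

    def test_permissive_keeps_partial_complex(self):
        out = remap_gpr(GprTree.from_string("tA and tB"), {"tA": "gA"},
                        policy="permissive")
        assert out.gpr.to_string() == "gA"


class TestPruneExogenous:
    def _toy_with_exo(self, carries_flux: bool):
        model = build_toy3()
        model.add_metabolite(Metabolite(id="Z_c", compartment="c"))
        stoich = (
            {"A_c": -1, "B_c": 1} if carries_flux else {"A_c": -1, "Z_c": 1}
        )
        model.add_reaction(ReactionRecord(
            id="EXO", stoichiometry=stoich, lower_bound=0, upper_bound=1000,
            provenance="template:iML1515"))
        return model

    def test_dead_branch_removed_optima_unchanged(self):
        model = self._toy_with_exo(carries_flux=False)
        conds = [{"EX_A": (-10.0, 1000.0)}]
        before = fba(apply_medium(model, conds[0])).objective_value
        pruned, removed = prune_exogenous(model, conds, ["EXO"])
        assert removed == ["EXO"]
        after = fba(apply_medium(pruned, conds[0])).objective_value
        assert after == pytest.approx(before, rel=1e-6)

    def test_flux_carrier_kept_under_any_condition(self):
        model = self._toy_with_exo(carries_flux=True)
        conds = [{"EX_A": (0.0, 1000.0)}, {"EX_A": (-10.0, 1000.0)}]
        _, removed = prune_exogenous(model, conds, ["EXO"])
        assert removed == []

    def test_native_orphan_never_pruned(self):
        model = self._toy_with_exo(carries_flux=False)
        # blocked native orphan alongside the exogenous one
        model.add_metabolite(Metabolite(id="W_c", compartment="c"))
        model.add_reaction(ReactionRecord(
            id="ORPH", stoichiometry={"A_c": -1, "W_c": 1},
            lower_bound=0, upper_bound=1000, provenance="orphan"))
        pruned, removed = prune_exogenous(
            model, [{"EX_A": (-10.0, 1000.0)}], ["EXO"])
        assert removed == ["EXO"]
        assert "ORPH" in pruned.reactions


class TestDeadEnds:
    def test_produced_only(self, toy3):
        toy3.add_metabolite(Metabolite(id="X_c", compartment="c"))
        toy3.add_reaction(ReactionRecord(
            id="RX", stoichiometry={"A_c": -1, "X_c": 1},
            lower_bound=0, upper_bound=1000))
        assert classify_dead_ends(toy3).classes["X_c"] == "produced-only"

    def test_consumed_only(self, toy3):
        toy3.add_metabolite(Metabolite(id="X_c", compartment="c"))
        toy3.add_reaction(ReactionRecord(
            id="RX", stoichiometry={"X_c": -1, "B_c": 1},
            lower_bound=0, upper_bound=1000))
        assert classify_dead_ends(toy3).classes["X_c"] == "consumed-only"

    def test_reversible_single_reaction_flagged_not_dead(self, toy3):
        toy3.add_metabolite(Metabolite(id="X_c", compartment="c"))
        toy3.add_reaction(ReactionRecord(
            id="RX", stoichiometry={"A_c": -1, "X_c": 1},
            lower_bound=-1000, upper_bound=1000))
        report = classify_dead_ends(toy3)
        assert "X_c" not in report.classes
        assert "X_c" in report.single_reaction

    def test_disconnected(self, toy3):
        toy3.add_metabolite(Metabolite(id="lonely_c", compartment="c"))
        assert classify_dead_ends(toy3).classes["lonely_c"] == "disconnected"

    def test_agrees_with_bruteforce_incidence_scan(self):
        import numpy as np

        rng = np.random.default_rng(7)
        for _ in range(50):
            n_mets = int(rng.integers(3, 10))
            model = MetabolicModel(id="rand")
            for i in range(n_mets):
                model.add_metabolite(Metabolite(id=f"m{i}_c", compartment="c"))
            n_rxns = int(rng.integers(1, 30))
            for j in range(n_rxns):
                a, b = rng.choice(n_mets, size=2, replace=False)
                rev = bool(rng.random() < 0.4)
                model.add_reaction(ReactionRecord(
                    id=f"r{j}", stoichiometry={f"m{a}_c": -1.0, f"m{b}_c": 1.0},
                    lower_bound=-1000 if rev else 0, upper_bound=1000))
            report = classify_dead_ends(model)
            # brute force: incidence scan over (reaction, direction) pairs
            prod, cons, touch = set(), set(), set()
            for rxn in model.reactions.values():
                directions = []
                if rxn.upper_bound > 0:
                    directions.append(1)
                if rxn.lower_bound < 0:
                    directions.append(-1)
                for met, coeff in rxn.stoichiometry.items():
                    touch.add(met)
                    for d in directions:
                        (prod if coeff * d > 0 else cons).add(met)
            for met in model.metabolites:
                expected = None
                if met not in touch:
                    expected = "disconnected"
                elif met in prod and met not in cons:
                    expected = "produced-only"
                elif met in cons and met not in prod:
                    expected = "consumed-only"
                assert report.classes.get(met) == expected


def _pool_from(reactions, source: MetabolicModel) -> MetabolicModel:
    pool = MetabolicModel(id="pool")
    for rxn in reactions:
        for met_id in rxn.stoichiometry:
            if met_id not in pool.metabolites:
                pool.add_metabolite(source.metabolites[met_id])
        pool.add_reaction(rxn)
    return pool


def bruteforce_gapfill(model, pool, target, medium, threshold=GROWTH_THRESHOLD):
    """Independent oracle: exhaustive smallest-subset search."""
    from diazogem.reconstruction import _growth_with

    ids = sorted(pool.reactions)
    for size in range(0, len(ids) + 1):
        for subset in itertools.combinations(ids, size):
            if _growth_with(model, pool, subset, target, medium) > threshold:
                return list(subset)
    return None


class TestGapfill:
    def test_restores_deleted_reaction(self, toy3):
        broken = toy3.copy()
        r1 = broken.reactions["R1"]
        broken.remove_reaction("R1")
        irrelevant = ReactionRecord(
            id="R_noise", stoichiometry={"A_c": -1, "A_e": 1},
            lower_bound=0, upper_bound=1000)
        pool = _pool_from([r1.copy(), irrelevant], toy3)
        sol = gapfill(broken, pool)
        assert sol.filled and sol.added == ["R1"]
        assert sol.added == bruteforce_gapfill(broken, pool, "BIO", None)

    def test_already_growing_needs_nothing(self, toy3):
        pool = _pool_from(
            [ReactionRecord(id="Rp", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0, upper_bound=1000)],
            toy3,
        )
        sol = gapfill(toy3, pool)
        assert sol.filled and sol.added == []

    def test_lexicographic_tie_break(self, toy3):
        broken = toy3.copy()
        broken.remove_reaction("R1")
        twins = [
            ReactionRecord(id=rid, stoichiometry={"A_c": -1, "B_c": 1},
                           lower_bound=0, upper_bound=1000)
            for rid in ("R1b", "R1a")
        ]
        pool = _pool_from(twins, toy3)
        sol = gapfill(broken, pool)
        assert sol.added == ["R1a"]

    def test_two_gap_case_matches_bruteforce(self, toy3):
        broken = toy3.copy()
        r1, ta = broken.reactions["R1"], broken.reactions["TA"]
        broken.remove_reaction("R1")
        broken.remove_reaction("TA")
        noise = [
            ReactionRecord(id=f"N{i}", stoichiometry={"B_c": -1, "A_c": 1},
                           lower_bound=0, upper_bound=1000)
            for i in range(2)
        ]
        pool = _pool_from([r1.copy(), ta.copy()] + noise, toy3)
        sol = gapfill(broken, pool)
        assert sorted(sol.added) == ["R1", "TA"]
        assert sorted(sol.added) == sorted(
            bruteforce_gapfill(broken, pool, "BIO", None))

    def test_deletion_minimality(self, toy3):
        from diazogem.reconstruction import _growth_with

        broken = toy3.copy()
        r1 = broken.reactions["R1"]
        broken.remove_reaction("R1")
        pool = _pool_from([r1.copy()], toy3)
        sol = gapfill(broken, pool)
        for rid in sol.added:
            rest = [r for r in sol.added if r != rid]
            assert _growth_with(broken, pool, rest, "BIO", None) <= GROWTH_THRESHOLD

    def test_unfillable_reports_dead_ends(self, toy3):
        broken = toy3.copy()
        broken.remove_reaction("R1")
        pool = _pool_from(
            [ReactionRecord(id="Rx", stoichiometry={"B_c": -1, "A_c": 1},
                            lower_bound=0, upper_bound=1000)],
            toy3,
        )
        sol = gapfill(broken, pool)
        assert not sol.filled and sol.added == []
        assert sol.closest_dead_ends  # names the disconnection

    def test_overlapping_pool_rejected(self, toy3):
        from diazogem.core_model import DiazogemError

        pool = _pool_from([toy3.reactions["R1"].copy()], toy3)
        with pytest.raises(DiazogemError):
            gapfill(toy3, pool)

    def test_toy_diazotroph_gapfill_with_medium(self, toy):
        broken = toy.copy()
        gs = broken.reactions["GSGOGAT"]
        broken.remove_reaction("GSGOGAT")
        noise = ReactionRecord(
            id="AAA_noise", stoichiometry={"h2o_c": -1, "h2o_e": 1},
            lower_bound=0, upper_bound=1000)
        pool = _pool_from([gs.copy(), noise], toy)
        sol = gapfill(broken, pool, medium=toy_medium())
        assert sol.added == ["GSGOGAT"]
        assert sol.objective_value > GROWTH_THRESHOLD
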