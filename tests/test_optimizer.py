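import itertools

import pytest

from gramtriple import EngineConfig
from gramtriple.errors import OptimizeError
from gramtriple.gram_index import GramIndex
from gramtriple.optimizer import (
    AccessPlan,
    JoinPlan,
    cost_regscan,
    estimate_candidates,
    optimize,
    plan_access,
    plan_vars,
)
from gramtriple.regex_planner import CandidatePlan, FullScan, IdxAnd, IdxOr, IdxScan
from gramtriple.sparql import parse_sparql

from conftest import make_synthetic_index


def _index_with(pages: dict[str, int], height: int) -> GramIndex:
    idx = GramIndex(part="O", alpha=2, beta=4, sel_threshold=0.1)
    for g, p in pages.items():
        idx.entries[g] = [(1, (0,))]
        idx.num_pages[g] = p
    idx.height = height
    return idx


def _and(*grams: str) -> CandidatePlan:
    if len(grams) == 1:
        return CandidatePlan(IdxScan(grams[0]), "O")
    return CandidatePlan(
        IdxAnd(tuple(IdxScan(g) for g in grams), tuple(("ordered",) for _ in grams[:-1])),
        "O",
    )


class TestCostRegscan:
    # hand-computed: unit * (|G| * height + sum of page counts)
    CASES = [
        # (gram->pages, height, grams in plan, unit, expected)
        ({"aa": 3, "bb": 3, "cc": 2, "dd": 2}, 2, ("aa", "bb", "cc", "dd"), 1.0, 18.0),
        ({"aa": 1}, 1, ("aa",), 1.0, 2.0),
        ({"aa": 1}, 3, ("aa",), 1.0, 4.0),
        ({"aa": 5, "bb": 7}, 2, ("aa", "bb"), 1.0, 16.0),
        ({"aa": 5, "bb": 7}, 2, ("aa", "bb"), 2.0, 32.0),
        ({"aa": 10, "bb": 1, "cc": 1}, 4, ("aa", "bb", "cc"), 1.0, 24.0),
        ({"aa": 2, "bb": 2, "cc": 2}, 1, ("aa", "bb"), 1.0, 6.0),
        ({"aa": 8}, 2, ("aa",), 0.5, 5.0),
        ({"aa": 1, "bb": 1, "cc": 1, "dd": 1, "ee": 1}, 2, ("aa", "bb", "cc", "dd", "ee"), 1.0, 15.0),
        ({"aa": 100}, 5, ("aa",), 1.0, 105.0),
        ({"aa": 3, "bb": 4}, 3, ("aa", "bb"), 1.5, 19.5),
    ]

    @pytest.mark.parametrize("pages,height,grams,unit,expected", CASES)
    def test_printed_formula(self, pages, height, grams, unit, expected):
        idx = _index_with(pages, height)
        est = cost_regscan(_and(*grams), idx, unit_cost=unit)
        assert est.total == pytest.approx(expected)

    def test_total_is_sum_of_breakdown(self):
        idx = _index_with({"aa": 3, "bb": 2}, 2)
        est = cost_regscan(_and("aa", "bb"), idx)
        assert est.total == pytest.approx(sum(v for _, v in est.breakdown))

    def test_empty_plan_costs_nothing(self):
        idx = _index_with({}, 1)
        assert cost_regscan(CandidatePlan(None, "O"), idx).total == 0.0

    def test_duplicate_grams_charged_once(self):
        idx = _index_with({"aa": 3}, 2)
        est = cost_regscan(_and("aa", "aa"), idx)
        assert est.total == pytest.approx(1 * 2 + 3)

    def test_fullscan_costs_table_pages(self):
        idx = _index_with({}, 1)
        est = cost_regscan(
            CandidatePlan(FullScan(), "O"), idx, n_triples=300, entries_per_page=128
        )
        assert est.total == pytest.approx(3.0)

    def test_adding_a_gram_never_decreases_cost(self):
        idx = _index_with({"aa": 3, "bb": 2, "cc": 4}, 2)
        subsets = [("aa",), ("aa", "bb"), ("aa", "bb", "cc")]
        costs = [cost_regscan(_and(*s), idx).total for s in subsets]
        assert costs == sorted(costs)


class TestEstimateCandidates:
    def test_and_takes_min_or_takes_sum(self):
        idx = make_synthetic_index(
            {"aa", "bb"}, postings={"aa": [(i, (0,)) for i in range(1, 6)],
                                    "bb": [(1, (0,)), (2, (0,))]}
        )
        assert estimate_candidates(IdxScan("aa"), idx, 100) == 5
        and_node = IdxAnd((IdxScan("aa"), IdxScan("bb")), (("ordered",),))
        assert estimate_candidates(and_node, idx, 100) == 2
        or_node = IdxOr((IdxScan("aa"), IdxScan("bb")))
        assert estimate_candidates(or_node, idx, 100) == 7


class TestOptimize:
    def test_regscan_chosen_when_postings_are_small(self, go_store, go_indexes):
        spec = parse_sparql(
            'SELECT * WHERE {?s ?p ?o FILTER regex (?o, ".*XQZV.*") .}'
        )
        qep = optimize(spec, go_store, go_indexes, EngineConfig())
        assert isinstance(qep, AccessPlan)
        assert qep.regscan is not None

    def test_unconstrained_pattern_falls_back_to_scan(self, go_store, go_indexes):
        spec = parse_sparql('SELECT * WHERE {?s ?p ?o FILTER regex (?o, ".*") .}')
        qep = optimize(spec, go_store, go_indexes, EngineConfig())
        assert isinstance(qep, AccessPlan)
        assert qep.regscan is None  # full scan + verify is the only option

    def test_determinism(self, go_store, go_indexes):
        q = (
            "SELECT * WHERE {?gp rdf:type ?type ."
            '?gp rdfs:label ?name FILTER regex (?name, "activity") .'
            "?gp rdfs:comment ?comment .}"
        )
        spec = parse_sparql(q)
        a = optimize(spec, go_store, go_indexes, EngineConfig())
        b = optimize(spec, go_store, go_indexes, EngineConfig())
        assert a.serialize() == b.serialize()

    def test_too_many_patterns_rejected(self, go_store, go_indexes):
        pats = " . ".join(f"?s ?p{i} ?o{i}" for i in range(9))
        spec = parse_sparql("SELECT * WHERE {" + pats + " .}")
        with pytest.raises(OptimizeError):
            optimize(spec, go_store, go_indexes, EngineConfig())

    @pytest.mark.parametrize(
        "query",
        [
            'SELECT * WHERE {?gp rdfs:label ?name FILTER regex (?name, "activity") .}',
            "SELECT * WHERE {?gp rdf:type ?t .?gp rdfs:label ?n .}",
            "SELECT * WHERE {?gp rdf:type ?t .?gp rdfs:label ?n "
            'FILTER regex (?n, "cellular") .?gp rdfs:comment ?c .}',
            "SELECT * WHERE {?a go:consider ?b .?a rdfs:label ?la .?b rdfs:label ?lb "
            '.?b rdf:type ?t FILTER regex (?t, "Function") .}',
        ],
    )
    def test_chosen_cost_minimal_over_exhaustive_enumeration(
        self, query, go_store, go_indexes
    ):
        """Independent recursive enumeration of every bushy join order and
        method must not beat the optimizer's plan on estimated cost."""
        config = EngineConfig()
        spec = parse_sparql(query)
        chosen = optimize(spec, go_store, go_indexes, config)

        from gramtriple.optimizer import _assign_filters

        assigned = _assign_filters(spec)
        leaves = [
            plan_access(i, p, assigned[i], go_store, go_indexes, config)
            for i, p in enumerate(spec.patterns)
        ]

        def enumerate_plans(items):
            if len(items) == 1:
                yield items[0]
                return
            indices = range(len(items))
            for r in range(1, len(items)):
                for combo in itertools.combinations(indices, r):
                    left_items = [items[i] for i in combo]
                    right_items = [items[i] for i in indices if i not in combo]
                    for lp in enumerate_plans(left_items):
                        for rp in enumerate_plans(right_items):
                            shared = tuple(sorted(plan_vars(lp) & plan_vars(rp)))
                            if not shared:
                                continue
                            cost = lp.cost + rp.cost + lp.card + rp.card
                            card = min(lp.card, rp.card)
                            yield JoinPlan("HSJN", lp, rp, shared, cost, card, None)
                            if lp.sorted_key == shared and rp.sorted_key == shared:
                                yield JoinPlan("MGJN", lp, rp, shared, cost, card, shared)

        alternatives = list(enumerate_plans(leaves))
        assert alternatives, "query must admit at least one plan"
        best = min(a.cost for a in alternatives)
        assert chosen.cost <= best + 1e-9
        assert all(chosen.cost <= a.cost + 1e-9 for a in alternatives)
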