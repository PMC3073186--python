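import random

import pytest

from gramtriple import EngineConfig, evaluate, parse_sparql
from gramtriple.errors import GramTripleError
from gramtriple.exec_engine import (
    FilterVerifyOp,
    HsjnOp,
    IdxAndOp,
    IdxOrOp,
    IdxScanOp,
    MgjnOp,
    Operator,
    RegScanOp,
    TScanOp,
)
from gramtriple.fixtures import (
    oracle_query,
    oracle_regex_scan,
    random_pattern,
)
from gramtriple.regex_planner import compile_pattern
from gramtriple.sparql import TriplePattern
from gramtriple.triple_store import load_database

from conftest import make_synthetic_index


class _ListOp(Operator):
    def __init__(self, items):
        super().__init__()
        self.items = list(items)

    def _produce(self):
        yield from self.items


class TestGetNextContract:
    def test_exhaustion_is_idempotent(self):
        op = _ListOp([(1, (0,))])
        assert op.get_next() == (1, (0,))
        assert op.get_next() is None
        assert op.get_next() is None

    def test_idxscan_streams_postings_in_tid_order(self):
        index = make_synthetic_index(
            {"MOUSE"}, alpha=5, beta=5, postings={"MOUSE": [(1, (6,)), (2, (6,))]}
        )
        got = list(IdxScanOp("MOUSE", index))
        assert got == [(1, (6,)), (2, (6,))]

    def test_idxscan_on_missing_key_is_empty(self):
        index = make_synthetic_index(set())
        assert list(IdxScanOp("NOPE", index)) == []

    def test_stream_length_matches_postings(self, small_indexes):
        idx = small_indexes["O"]
        for g in idx.keys()[:50]:
            assert len(list(IdxScanOp(g, idx))) == len(idx.lookup(g))


class TestIdxAnd:
    def test_exact_gap_intersection(self):
        left = _ListOp([(1, (6,)), (2, (6,))])
        right = _ListOp([(1, (8,)), (2, (8,))])
        got = list(IdxAndOp([left, right], [("exact", 2)]))
        assert [tid for tid, _ in got] == [1, 2]

    def test_disjoint_tids_empty(self):
        got = list(IdxAndOp([_ListOp([(1, (0,))]), _ListOp([(2, (0,))])], [("ordered",)]))
        assert got == []

    def test_ordered_constraint_violation_drops_tid(self):
        left = _ListOp([(1, (5,))])
        right = _ListOp([(1, (3,))])
        assert list(IdxAndOp([left, right], [("ordered",)])) == []

    def test_unknown_offsets_fall_back_to_tid_intersection(self):
        left = _ListOp([(1, None), (3, None)])
        right = _ListOp([(1, (0,)), (2, (0,))])
        assert [t for t, _ in IdxAndOp([left, right], [("ordered",)])] == [1]


class TestIdxOr:
    def test_union(self):
        got = list(IdxOrOp([_ListOp([(1, (0,))]), _ListOp([(2, (0,))])]))
        assert [t for t, _ in got] == [1, 2]

    def test_union_with_empty_is_identity(self):
        got = list(IdxOrOp([_ListOp([(1, (0,)), (4, (0,))]), _ListOp([])]))
        assert [t for t, _ in got] == [1, 4]

    def test_matches_set_union_oracle(self):
        rng = random.Random(0)
        for _ in range(20):
            sets = [sorted(rng.sample(range(1, 40), rng.randint(0, 12))) for _ in range(3)]
            ops = [_ListOp([(t, (0,)) for t in s]) for s in sets]
            got = [t for t, _ in IdxOrOp(ops)]
            assert got == sorted(set().union(*sets))


class TestRegScanAndFilter:
    def test_candidates_include_true_match(self, fig_store):
        index = make_synthetic_index({"GPR", "CCD", "MOU", "USE"}, postings={
            "GPR": [(1, (0,))],
            "CCD": [(2, (0,))],
            "MOU": [(1, (6,)), (2, (6,))],
            "USE": [(1, (8,)), (2, (8,))],
        })
        plan = compile_pattern("(GPR|CCD).*MOUSE.*", index)
        tids = [tid for tid, _ in RegScanOp(plan, index, fig_store)]
        assert 1 in tids and 2 in tids

    def test_empty_subplan_result_is_empty_stream(self, fig_store):
        index = make_synthetic_index({"ZZZ"}, postings={"ZZZ": []})
        plan = compile_pattern("ZZZ", index)
        assert list(RegScanOp(plan, index, fig_store)) == []

    def test_filter_keeps_true_match_and_drops_others(self, fig_store):
        source = _ListOp(
            [(tid, fig_store.triple(tid)[1:]) for tid in (1, 2)]
        )
        kept = list(
            FilterVerifyOp(source, "(GPR|CCD).*MOUSE.*", "O", fig_store, "anchored")
        )
        assert [t for t, _ in kept] == [1, 2]
        source2 = _ListOp([(1, fig_store.triple(1)[1:])])
        assert list(FilterVerifyOp(source2, "CCD.*", "O", fig_store, "anchored")) == []

    @pytest.mark.parametrize("semantics", ["anchored", "search"])
    def test_verified_equals_full_scan_oracle(self, go_store, go_indexes, semantics):
        for pattern in [".*MOUSE.*", "(GPR|CCD).*", ".*spliceosomal.*", "BP.*"]:
            plan = compile_pattern(pattern, go_indexes["O"])
            verified = {
                tid
                for tid, _ in FilterVerifyOp(
                    RegScanOp(plan, go_indexes["O"], go_store),
                    pattern,
                    "O",
                    go_store,
                    semantics,
                )
            }
            assert verified == oracle_regex_scan(go_store, pattern, "O", semantics)


class TestScansAndJoins:
    def _store(self):
        return load_database(
            [
                ("x1", "mnemonic", "GPR64_MOUSE"),
                ("x2", "mnemonic", "CCD80_MOUSE"),
                ("x1", "type", "Protein"),
            ]
        )

    def test_tscan_binds_and_counts(self):
        store = self._store()
        pat = TriplePattern(("var", "x"), ("const", "mnemonic"), ("var", "m"))
        rows = list(TScanOp(pat, store))
        assert len(rows) == 2
        assert all(set(r) == {"x", "m"} for r in rows)

    def test_tscan_constant_mismatch_empty(self):
        pat = TriplePattern(("var", "x"), ("const", "nope"), ("var", "m"))
        assert list(TScanOp(pat, self._store())) == []

    def test_tscan_all_variables_returns_all_triples(self):
        pat = TriplePattern(("var", "a"), ("var", "b"), ("var", "c"))
        assert len(list(TScanOp(pat, self._store()))) == 3

    def test_tscan_sorted_by_first_variable(self, go_store):
        pat = TriplePattern(("var", "s"), ("var", "p"), ("var", "o"))
        rows = [r["s"] for r in TScanOp(pat, go_store)]
        assert rows == sorted(rows)

    def test_two_pattern_join_finds_the_answer(self):
        store = self._store()
        left = TScanOp(
            TriplePattern(("var", "x"), ("const", "mnemonic"), ("var", "m")), store
        )
        right = TScanOp(
            TriplePattern(("var", "x"), ("const", "type"), ("const", "Protein")), store
        )
        rows = list(MgjnOp(left, right, ("x",)))
        assert len(rows) == 1
        assert store.dictionary.string_of(rows[0]["m"]) == "GPR64_MOUSE"

    def test_disjoint_keys_join_empty(self):
        left = _ListOp([{"x": 1, "a": 1}])
        right = _ListOp([{"x": 2, "b": 1}])
        assert list(HsjnOp(left, right, ("x",))) == []

    def test_mgjn_rejects_unsorted_input(self):
        left = _ListOp([{"x": 2}, {"x": 1}])
        right = _ListOp([{"x": 1}, {"x": 2}])
        with pytest.raises(GramTripleError, match="sorted"):
            list(MgjnOp(left, right, ("x",)))

    def test_joins_agree_with_nested_loop_oracle(self):
        rng = random.Random(1)
        for _ in range(25):
            lrows = [
                {"x": rng.randint(1, 6), "a": rng.randint(1, 4)} for _ in range(rng.randint(0, 10))
            ]
            rrows = [
                {"x": rng.randint(1, 6), "b": rng.randint(1, 4)} for _ in range(rng.randint(0, 10))
            ]
            oracle = sorted(
                tuple(sorted({**l, **r}.items()))
                for l in lrows
                for r in rrows
                if l["x"] == r["x"]
            )
            hs = sorted(
                tuple(sorted(row.items()))
                for row in HsjnOp(_ListOp(lrows), _ListOp(rrows), ("x",))
            )
            key = lambda r: r["x"]
            mg = sorted(
                tuple(sorted(row.items()))
                for row in MgjnOp(
                    _ListOp(sorted(lrows, key=key)),
                    _ListOp(sorted(rrows, key=key)),
                    ("x",),
                )
            )
            assert hs == oracle and mg == oracle


class TestEndToEnd:
    def test_engine_equals_naive_evaluator(self, go_store, go_indexes):
        cfg = EngineConfig(regex_semantics="search")
        q = (
            "SELECT * WHERE {?gp rdf:type ?type ."
            '?gp rdfs:label ?name FILTER regex (?name, "activity") .}'
        )
        spec = parse_sparql(q)
        _, rows, _ = evaluate(spec, go_store, go_indexes, cfg)
        assert rows == oracle_query(spec, go_store, semantics="search")
        assert len(rows) > 0

    def test_filter_output_independent_of_positional_mode(self, go_store, go_indexes):
        q = 'SELECT * WHERE {?s ?p ?o FILTER regex (?o, ".*MOUSE.*") .}'
        spec = parse_sparql(q)
        _, exact_rows, _ = evaluate(
            spec, go_store, go_indexes, EngineConfig(positional="exact")
        )
        _, ordered_rows, _ = evaluate(
            spec, go_store, go_indexes, EngineConfig(positional="ordered")
        )
        assert exact_rows == ordered_rows
        assert len(exact_rows) > 0

    def test_candidates_superset_of_verified(self, go_store, go_indexes):
        rng = random.Random(9)
        strings = go_store.part_strings("O")
        for _ in range(30):
            pattern = random_pattern(rng, strings)
            plan = compile_pattern(pattern, go_indexes["O"])
            cand = {tid for tid, _ in RegScanOp(plan, go_indexes["O"], go_store)}
            truth = oracle_regex_scan(go_store, pattern, "O", "anchored")
            assert cand >= truth
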