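"""Iterator (GetNext) execution of query plans.

Every operator exposes ``get_next()`` returning one result or ``None`` at
exhaustion; further calls after exhaustion keep returning ``None``.  Inside
a REGSCAN sub-plan the stream items are ``(tid, offsets)`` pairs in
ascending tid order (``offsets`` is ``None`` once positional information
has been discarded, e.g. past an IDXOR); at the QEP level the items are
binding rows mapping variable names to string IDs.

REGSCAN produces *candidate* triples only; the FILTER verification step
re-checks the original pattern with Python's ``re`` engine against the full
lexical form, so the final answers are exact whatever the sub-plan pruned.
"""
from __future__ import annotations

import re
from typing import Iterator, Sequence

from .config import EngineConfig
from .errors import GramTripleError
from .gram_index import GramIndex
from .optimizer import QEP, AccessPlan, JoinPlan, optimize
from .regex_planner import CandidatePlan, FullScan, IdxAnd, IdxOr, IdxScan
from .sparql import QuerySpec, TriplePattern, parse_sparql
from .triple_store import TripleStore

BindingRow = dict[str, int]


class Operator:
    """Base GetNext operator: pull-based, one result per call, idempotent
    exhaustion.  ``calls`` counts GetNext invocations for tracing."""

    def __init__(self) -> None:
        self._iter: Iterator | None = None
        self._done = False
        self.calls = 0

    def _produce(self) -> Iterator:
        raise NotImplementedError

    def get_next(self):
        self.calls += 1
        if self._done:
            return None
        if self._iter is None:
            self._iter = self._produce()
        try:
            return next(self._iter)
        except StopIteration:
            self._done = True
            return None

    def __iter__(self):
        while True:
            item = self.get_next()
            if item is None:
                return
            yield item


# ---------------------------------------------------------------------------
# REGSCAN sub-plan operators: streams of (tid, offsets | None)


class IdxScanOp(Operator):
    """Scan the posting list of one gram, in tid order."""

    def __init__(self, gram: str, index: GramIndex) -> None:
        super().__init__()
        self.gram = gram
        self.index = index

    def _produce(self):
        postings = self.index.lookup(self.gram)
        if postings is None:  # planner emits keys only; stay defensive
            return
        for tid, offs in postings:
            yield (tid, offs)


def _exists_chain(offset_lists: Sequence[Sequence[int]], start: int) -> bool:
    """True when strictly increasing offsets can be chosen across the lists,
    beginning with ``start`` from the first list (greedy minimal choice)."""
    cur = start
    for offs in offset_lists[1:]:
        nxt = next((o for o in offs if o > cur), None)
        if nxt is None:
            return False
        cur = nxt
    return True


class IdxAndOp(Operator):
    """Offset-aware n-way intersection of tid-ascending child streams.

    A tid passes only if some choice of child offsets satisfies the
    pairwise constraints; the emitted offsets are the satisfying start
    offsets of the leftmost child (``None`` when the left child carries no
    offsets, in which case the offset constraints are vacuous)."""

    def __init__(self, children: list[Operator], constraints: Sequence[tuple]) -> None:
        super().__init__()
        self.children = children
        self.constraints = tuple(constraints)

    def _produce(self):
        items = [c.get_next() for c in self.children]
        while all(it is not None for it in items):
            tids = [it[0] for it in items]
            hi = max(tids)
            if all(t == hi for t in tids):
                offs = self._combine([it[1] for it in items])
                if offs is not False:
                    yield (hi, offs)
                items = [c.get_next() for c in self.children]
            else:
                for i, c in enumerate(self.children):
                    while items[i] is not None and items[i][0] < hi:
                        items[i] = c.get_next()
                    if items[i] is None:
                        return

    def _combine(self, offset_lists):
        """Check positional constraints; returns surviving left-start
        offsets, None (no offset info), or False (tid rejected)."""
        if any(o is None for o in offset_lists):
            return None
        if all(kind == "exact" for kind, *_ in self.constraints):
            gaps = [0]
            for _, gap in self.constraints:
                gaps.append(gaps[-1] + gap)
            sets = [set(o) for o in offset_lists]
            starts = tuple(
                o
                for o in offset_lists[0]
                if all(o + gaps[i] in sets[i] for i in range(1, len(sets)))
            )
            return starts if starts else False
        starts = tuple(
            o for o in offset_lists[0] if _exists_chain(offset_lists, o)
        )
        return starts if starts else False


class IdxOrOp(Operator):
    """Sorted duplicate-free union of tid-ascending child streams; offset
    information is discarded."""

    def __init__(self, children: list[Operator]) -> None:
        super().__init__()
        self.children = children

    def _produce(self):
        items = [c.get_next() for c in self.children]
        while any(it is not None for it in items):
            lo = min(it[0] for it in items if it is not None)
            yield (lo, None)
            for i, c in enumerate(self.children):
                while items[i] is not None and items[i][0] == lo:
                    items[i] = c.get_next()


class FullScanOp(Operator):
    """Every triple of the store, as (tid, None)."""

    def __init__(self, store: TripleStore) -> None:
        super().__init__()
        self.store = store

    def _produce(self):
        for t in self.store:
            yield (t.tid, None)


def build_subplan_operator(node, index: GramIndex, store: TripleStore) -> Operator:
    if isinstance(node, IdxScan):
        return IdxScanOp(node.gram, index)
    if isinstance(node, IdxAnd):
        return IdxAndOp(
            [build_subplan_operator(c, index, store) for c in node.children],
            node.constraints,
        )
    if isinstance(node, IdxOr):
        return IdxOrOp([build_subplan_operator(c, index, store) for c in node.children])
    if isinstance(node, FullScan):
        return FullScanOp(store)
    raise TypeError(f"unexpected sub-plan node {node!r}")


class RegScanOp(Operator):
    """Resolve candidate tids from the sub-plan into (tid, (s, p, o))
    string-ID triples via the dictionary."""

    def __init__(
        self, plan: CandidatePlan, index: GramIndex, store: TripleStore
    ) -> None:
        super().__init__()
        self.store = store
        if plan.root is None:
            self.sub: Operator | None = None
        else:
            self.sub = build_subplan_operator(plan.root, index, store)

    def _produce(self):
        if self.sub is None:
            return
        for tid, _ in self.sub:
            t = self.store.triple(tid)
            yield (tid, (t.s, t.p, t.o))


def compile_filter(pattern: str, semantics: str) -> "re.Pattern[str]":
    return re.compile(pattern, re.DOTALL)


def matches(compiled: "re.Pattern[str]", text: str, semantics: str) -> bool:
    if semantics == "anchored":
        return compiled.fullmatch(text) is not None
    return compiled.search(text) is not None


class FilterVerifyOp(Operator):
    """Exact regex re-check of REGSCAN candidates on the bound part's full
    lexical form; false positives stop here."""

    def __init__(
        self,
        source: Operator,
        pattern: str,
        part: str,
        store: TripleStore,
        semantics: str = "anchored",
    ) -> None:
        super().__init__()
        self.source = source
        self.part = part
        self.store = store
        self.semantics = semantics
        self.compiled = compile_filter(pattern, semantics)

    def _produce(self):
        part_pos = {"S": 0, "P": 1, "O": 2}[self.part]
        for tid, sids in self.source:
            text = self.store.dictionary.string_of(sids[part_pos])
            if matches(self.compiled, text, self.semantics):
                yield (tid, sids)


# ---------------------------------------------------------------------------
# QEP operators: streams of BindingRow


def _bind(pattern: TriplePattern, sids: tuple[int, int, int], store: TripleStore):
    """Match one triple's string IDs against a pattern; returns the binding
    row or None (constant mismatch / inconsistent repeated variable)."""
    row: BindingRow = {}
    for (kind, value), sid in zip(pattern.terms, sids):
        if kind == "const":
            if store.dictionary.id_of(value) != sid:
                return None
        else:
            if value in row and row[value] != sid:
                return None
            row[value] = sid
    return row


class TScanOp(Operator):
    """Triple-pattern scan: one row per matching triple, sorted by the
    first variable's string ID (so a merge join can consume it)."""

    def __init__(self, pattern: TriplePattern, store: TripleStore) -> None:
        super().__init__()
        self.pattern = pattern
        self.store = store

    def _produce(self):
        rows = []
        for t in self.store:
            row = _bind(self.pattern, (t.s, t.p, t.o), self.store)
            if row is not None:
                rows.append(row)
        pvars = self.pattern.variables()
        if pvars:
            first = pvars[0]
            rows.sort(key=lambda r: r[first])
        yield from rows


class RegexLeafOp(Operator):
    """A regex-filtered triple pattern: candidates (REGSCAN or full scan),
    pattern-constant matching, then FILTER verification of every attached
    regex."""

    def __init__(
        self,
        leaf: AccessPlan,
        store: TripleStore,
        indexes: dict[str, GramIndex],
        semantics: str = "anchored",
    ) -> None:
        super().__init__()
        self.leaf = leaf
        self.store = store
        self.semantics = semantics
        if leaf.regscan is not None:
            self.source: Operator = RegScanOp(
                leaf.regscan, indexes[leaf.regscan.part], store
            )
        else:
            self.source = FullScanOp(store)
        self.checks = [
            (f.var, compile_filter(f.pattern, semantics)) for f in leaf.filters
        ]

    def _produce(self):
        for item in self.source:
            tid = item[0]
            t = self.store.triple(tid)
            row = _bind(self.leaf.pattern, (t.s, t.p, t.o), self.store)
            if row is None:
                continue
            ok = True
            for var, compiled in self.checks:
                text = self.store.dictionary.string_of(row[var])
                if not matches(compiled, text, self.semantics):
                    ok = False
                    break
            if ok:
                yield row


class HsjnOp(Operator):
    """Hash join on the shared variables; no input order required."""

    def __init__(self, left: Operator, right: Operator, join_vars) -> None:
        super().__init__()
        self.left = left
        self.right = right
        self.join_vars = tuple(join_vars)

    def _produce(self):
        table: dict[tuple, list[BindingRow]] = {}
        for row in self.left:
            key = tuple(row[v] for v in self.join_vars)
            table.setdefault(key, []).append(row)
        for row in self.right:
            key = tuple(row[v] for v in self.join_vars)
            for lrow in table.get(key, ()):
                yield {**lrow, **row}


class MgjnOp(Operator):
    """Merge join; both inputs must arrive sorted on the join key, which is
    checked as rows are consumed (a violation is a contract error)."""

    def __init__(self, left: Operator, right: Operator, join_vars) -> None:
        super().__init__()
        self.left = left
        self.right = right
        self.join_vars = tuple(join_vars)

    def _key(self, row: BindingRow) -> tuple:
        return tuple(row[v] for v in self.join_vars)

    def _next_group(self, op: Operator, pending):
        """(key, rows, next_pending) of the next equal-key group."""
        if pending is None:
            return None
        key = self._key(pending)
        group = [pending]
        while True:
            row = op.get_next()
            if row is None:
                return key, group, None
            k = self._key(row)
            if k < key:
                raise GramTripleError("MGJN input is not sorted on the join key")
            if k != key:
                return key, group, row
            group.append(row)

    def _produce(self):
        lpend = self.left.get_next()
        rpend = self.right.get_next()
        lgroup = self._next_group(self.left, lpend)
        rgroup = self._next_group(self.right, rpend)
        while lgroup is not None and rgroup is not None:
            lkey, lrows, lnext = lgroup
            rkey, rrows, rnext = rgroup
            if lkey == rkey:
                for lr in lrows:
                    for rr in rrows:
                        yield {**lr, **rr}
                lgroup = self._next_group(self.left, lnext)
                rgroup = self._next_group(self.right, rnext)
            elif lkey < rkey:
                lgroup = self._next_group(self.left, lnext)
            else:
                rgroup = self._next_group(self.right, rnext)


def build_operator(
    plan: QEP,
    store: TripleStore,
    indexes: dict[str, GramIndex],
    config: EngineConfig,
) -> Operator:
    """Instantiate the operator tree for an optimized QEP."""
    if isinstance(plan, JoinPlan):
        left = build_operator(plan.left, store, indexes, config)
        right = build_operator(plan.right, store, indexes, config)
        cls = MgjnOp if plan.method == "MGJN" else HsjnOp
        return cls(left, right, plan.join_vars)
    if isinstance(plan, AccessPlan):
        if plan.filters or plan.regscan is not None:
            return RegexLeafOp(plan, store, indexes, config.regex_semantics)
        return TScanOp(plan.pattern, store)
    raise TypeError(f"unexpected plan {plan!r}")


# ---------------------------------------------------------------------------
# end-to-end evaluation


def evaluate(
    spec: QuerySpec,
    store: TripleStore,
    indexes: dict[str, GramIndex],
    config: EngineConfig | None = None,
) -> tuple[list[str], list[tuple[str, ...]], QEP]:
    """Optimize and execute a parsed query.

    Returns (projected variable names, result rows as resolved strings
    sorted lexicographically, the chosen QEP).  Rows keep bag semantics
    before sorting; no deduplication is applied.
    """
    config = config or EngineConfig()
    qep = optimize(spec, store, indexes, config)
    root = build_operator(qep, store, indexes, config)
    header = spec.projected()
    d = store.dictionary
    rows = [tuple(d.string_of(r[v]) for v in header) for r in root]
    rows.sort()
    return header, rows, qep


def run_query(
    query_text: str,
    store: TripleStore,
    indexes: dict[str, GramIndex],
    config: EngineConfig | None = None,
) -> tuple[list[str], list[tuple[str, ...]], QEP]:
    """Parse, optimize and execute SPARQL text in one call."""
    return evaluate(parse_sparql(query_text), store, indexes, config or EngineConfig())
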