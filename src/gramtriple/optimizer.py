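"""Cost-based query optimization.

The REGSCAN cost follows the page-access model

    Cost = OnePageAccessCost * (|G| * Height(I) + sum_g NumPages(g))

where G is the set of distinct grams in the candidate plan: every gram costs
one root-to-leaf descent of the part index plus the pages of its posting
list.  A FULLSCAN (or a plain TSCAN) pays the simulated page count of the
triple table instead.  CPU cost is ignored.

Join plans are enumerated exhaustively (all bushy shapes over <= 8 triple
patterns, merge join where input order permits, hash join otherwise) with a
deliberately minimal invented cost model: a join costs its children plus
both input cardinalities, and its output cardinality is estimated as the
smaller input (an independence-flavored heuristic; the reference framework
prices only REGSCAN).  Ties are broken by the lexicographically smallest
plan serialization, so identical inputs always yield the identical plan.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .config import EngineConfig
from .errors import OptimizeError
from .gram_index import GramIndex, simulated_pages
from .regex_planner import (
    CandidatePlan,
    FullScan,
    IdxAnd,
    IdxOr,
    IdxScan,
    choose_index,
    compile_pattern,
)
from .sparql import QuerySpec, RegexFilter, TriplePattern
from .triple_store import TripleStore

MAX_PATTERNS = 8


@dataclass(frozen=True)
class CostEstimate:
    """Total page-access cost and its per-component breakdown."""

    breakdown: tuple[tuple[str, float], ...]

    @property
    def total(self) -> float:
        return sum(v for _, v in self.breakdown)


def cost_regscan(
    plan: CandidatePlan,
    index: GramIndex,
    unit_cost: float = 1.0,
    n_triples: int = 0,
    entries_per_page: int = 128,
) -> CostEstimate:
    """Price a candidate plan against its part index."""
    if plan.root is None:
        return CostEstimate(())
    if isinstance(plan.root, FullScan):
        pages = simulated_pages(n_triples, entries_per_page)
        return CostEstimate((("fullscan", unit_cost * pages),))
    grams = sorted(plan.grams())
    breakdown: list[tuple[str, float]] = [
        ("btree-descents", unit_cost * len(grams) * index.height)
    ]
    for g in grams:
        breakdown.append((f"postings:{g}", unit_cost * index.pages_of(g)))
    return CostEstimate(tuple(breakdown))


def estimate_candidates(root, index: GramIndex, n_triples: int) -> float:
    """Crude cardinality estimate of a candidate plan's output."""
    if root is None:
        return 0.0
    if isinstance(root, FullScan):
        return float(n_triples)
    if isinstance(root, IdxScan):
        postings = index.lookup(root.gram)
        return float(len(postings) if postings is not None else 0)
    if isinstance(root, IdxAnd):
        return min(estimate_candidates(c, index, n_triples) for c in root.children)
    if isinstance(root, IdxOr):
        total = sum(estimate_candidates(c, index, n_triples) for c in root.children)
        return min(total, float(n_triples))
    raise TypeError(f"unexpected plan node {root!r}")


# ---------------------------------------------------------------------------
# QEP plan nodes


@dataclass(frozen=True)
class AccessPlan:
    """Leaf of the QEP: one triple pattern, optionally regex-filtered.

    ``regscan`` is the candidate sub-plan driving a REGSCAN when the
    optimizer picked index access (None means plain TSCAN); all attached
    filters are verified at this leaf regardless of the access path.
    """

    pattern_index: int
    pattern: TriplePattern
    filters: tuple[RegexFilter, ...]
    regscan: CandidatePlan | None
    driver_var: str | None
    cost: float
    card: float
    sorted_key: tuple[str, ...] | None

    def serialize(self) -> str:
        scan = self.regscan.structure() if self.regscan else "TSCAN"
        return f"P{self.pattern_index}[{scan}]"


@dataclass(frozen=True)
class JoinPlan:
    method: str  # "MGJN" | "HSJN"
    left: "QEP"
    right: "QEP"
    join_vars: tuple[str, ...]
    cost: float
    card: float
    sorted_key: tuple[str, ...] | None

    def serialize(self) -> str:
        return f"{self.method}({self.left.serialize()},{self.right.serialize()})"


QEP = Union[AccessPlan, JoinPlan]


def _assign_filters(spec: QuerySpec) -> dict[int, list[RegexFilter]]:
    """Attach each filter to one pattern that binds its variable, preferring
    the pattern it was written against."""
    assigned: dict[int, list[RegexFilter]] = {i: [] for i in range(len(spec.patterns))}
    for f in spec.filters:
        idx = f.pattern_index
        if f.var not in spec.patterns[idx].variables():
            idx = next(
                i for i, p in enumerate(spec.patterns) if f.var in p.variables()
            )
        assigned[idx].append(f)
    return assigned


def _const_selectivity(pattern: TriplePattern, store: TripleStore) -> float:
    sel = 1.0
    for part, (kind, _) in zip(("S", "P", "O"), pattern.terms):
        if kind == "const":
            sel /= max(store.distinct_count(part), 1)
    return sel


def plan_access(
    pattern_index: int,
    pattern: TriplePattern,
    filters: list[RegexFilter],
    store: TripleStore,
    indexes: dict[str, GramIndex],
    config: EngineConfig,
) -> AccessPlan:
    """Pick the cheapest access path for one leaf: TSCAN, or REGSCAN driven
    by one of the attached filters when its gram plan beats the full scan."""
    n = len(store)
    table_pages = simulated_pages(n, config.entries_per_page)
    unit = config.one_page_access_cost
    base_card = n * _const_selectivity(pattern, store)

    best_cost = unit * table_pages
    best_regscan: CandidatePlan | None = None
    best_driver: str | None = None
    best_card = base_card

    for f in filters:
        part = choose_index(pattern.terms, f.var)
        index = indexes[part]
        cand = compile_pattern(f.pattern, index, config.positional)
        est = cost_regscan(
            cand, index, unit, n_triples=n, entries_per_page=config.entries_per_page
        )
        card = min(base_card, estimate_candidates(cand.root, index, n))
        if est.total < best_cost or (
            est.total == best_cost
            and best_regscan is None
            and not isinstance(cand.root, FullScan)
        ):
            best_cost = est.total
            best_regscan = None if isinstance(cand.root, FullScan) else cand
            best_driver = None if best_regscan is None else f.var
            best_card = card
        else:
            best_card = min(best_card, card)

    sorted_key: tuple[str, ...] | None = None
    if best_regscan is None and not filters:
        pvars = pattern.variables()
        if pvars:
            sorted_key = (pvars[0],)
    return AccessPlan(
        pattern_index=pattern_index,
        pattern=pattern,
        filters=tuple(filters),
        regscan=best_regscan,
        driver_var=best_driver,
        cost=best_cost,
        card=max(best_card, 0.0),
        sorted_key=sorted_key,
    )


def plan_vars(plan: QEP) -> set[str]:
    if isinstance(plan, AccessPlan):
        return set(plan.pattern.variables())
    return plan_vars(plan.left) | plan_vars(plan.right)


def _join(left: QEP, right: QEP) -> list[JoinPlan]:
    shared = tuple(sorted(plan_vars(left) & plan_vars(right)))
    if not shared:
        return []
    cost = left.cost + right.cost + left.card + right.card
    card = min(left.card, right.card)
    out = [
        JoinPlan("HSJN", left, right, shared, cost, card, sorted_key=None)
    ]
    if left.sorted_key == shared and right.sorted_key == shared:
        out.append(JoinPlan("MGJN", left, right, shared, cost, card, shared))
    return out


def _better(a: QEP | None, b: QEP) -> QEP:
    if a is None:
        return b
    if b.cost < a.cost:
        return b
    if b.cost == a.cost:
        # prefer merge join, then the smaller serialization, deterministically
        ka = (a.serialize().startswith("HSJN"), a.serialize())
        kb = (b.serialize().startswith("HSJN"), b.serialize())
        if kb < ka:
            return b
    return a


def optimize(
    spec: QuerySpec,
    store: TripleStore,
    indexes: dict[str, GramIndex],
    config: EngineConfig | None = None,
) -> QEP:
    """Exhaustive bottom-up enumeration of bushy QEPs; returns a plan no
    enumerated alternative beats on estimated cost."""
    config = config or EngineConfig()
    n = len(spec.patterns)
    if n > MAX_PATTERNS:
        raise OptimizeError(
            f"{n} triple patterns exceed the exhaustive-enumeration limit "
            f"of {MAX_PATTERNS}"
        )
    assigned = _assign_filters(spec)
    leaves = [
        plan_access(i, spec.patterns[i], assigned[i], store, indexes, config)
        for i in range(n)
    ]
    best: dict[int, QEP] = {1 << i: leaves[i] for i in range(n)}
    full = (1 << n) - 1
    for mask in range(1, full + 1):
        if mask in best and mask.bit_count() == 1:
            continue
        chosen: QEP | None = None
        sub = (mask - 1) & mask
        while sub:
            rest = mask & ~sub
            if sub in best and rest in best and sub < mask:
                for jp in _join(best[sub], best[rest]):
                    chosen = _better(chosen, jp)
            sub = (sub - 1) & mask
        if chosen is not None:
            best[mask] = chosen
    if full not in best:
        raise OptimizeError("could not join all patterns (disconnected query?)")
    return best[full]


def explain(plan: QEP, indexes: dict[str, GramIndex] | None = None, indent: int = 0) -> str:
    """Indented textual rendering of a QEP for the explain command."""
    pad = "  " * indent
    lines: list[str] = []
    if isinstance(plan, JoinPlan):
        lines.append(
            f"{pad}{plan.method} on ({', '.join('?' + v for v in plan.join_vars)}) "
            f"cost={plan.cost:.1f} card~{plan.card:.0f}"
        )
        lines.append(explain(plan.left, indexes, indent + 1))
        lines.append(explain(plan.right, indexes, indent + 1))
        return "\n".join(lines)
    pat = " ".join(
        ("?" + v) if kind == "var" else repr(v) for kind, v in plan.pattern.terms
    )
    if plan.regscan is None:
        head = f"{pad}TSCAN {pat} cost={plan.cost:.1f} card~{plan.card:.0f}"
    else:
        head = (
            f"{pad}REGSCAN[{plan.regscan.part}] {pat} "
            f"cost={plan.cost:.1f} card~{plan.card:.0f}"
        )
    lines.append(head)
    for f in plan.filters:
        lines.append(f"{pad}  FILTER ?{f.var} ~ /{f.pattern}/")
    if plan.regscan is not None:
        lines.append(
            _explain_subplan(plan.regscan.root, indexes, plan.regscan.part, indent + 1)
        )
    return "\n".join(lines)


def _explain_subplan(node, indexes, part, indent: int) -> str:
    pad = "  " * indent
    if isinstance(node, IdxScan):
        extra = ""
        if indexes is not None:
            postings = indexes[part].lookup(node.gram)
            if postings is not None:
                extra = (
                    f" [{len(postings)} postings,"
                    f" {indexes[part].pages_of(node.gram)} pages]"
                )
        return f"{pad}IDXSCAN({node.gram}){extra}"
    if isinstance(node, (IdxAnd, IdxOr)):
        name = "IDXAND" if isinstance(node, IdxAnd) else "IDXOR"
        lines = [f"{pad}{name}"]
        for c in node.children:
            lines.append(_explain_subplan(c, indexes, part, indent + 1))
        return "\n".join(lines)
    if isinstance(node, FullScan):
        return f"{pad}FULLSCAN"
    return f"{pad}EMPTY"
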