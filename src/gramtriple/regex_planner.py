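"""Regex-to-candidate-plan compiler.

Pipeline: ``parse_regex`` -> ``normalize`` -> ``to_parse_tree`` ->
``plan_from_tree``.

A FILTER pattern is first parsed into an AST over literal-gram runs,
alternation, Kleene star and friends; normalization rewrites the sugar
(``x+`` -> ``xx*``, ``x?`` -> ``(x|eps)``, character classes -> alternation
over members) so only GRAM / CONCAT / OR / STAR (plus the symbolic ANYCHAR)
remain.  The parse tree then abstracts matching into *constraints*: STAR
subtrees and bare ANYCHAR impose no indexable constraint and become ALL,
and ALL nodes are merged away (AND drops them; an OR with an ALL child is
itself ALL), leaving an AND/OR tree over literal grams.

Plan emission maps AND/OR/gram to IDXAND/IDXOR/IDXSCAN.  A gram that is not
an index key is replaced by an IDXAND over index-key substrings covering it
(with exact offset gaps), or by ALL when no substring is indexed, after
which the merging rules re-apply upward; a root that collapses to ALL means
the index cannot prune at all and the plan degenerates to a full scan of
the part.  Whatever survives is a *candidate* plan: its result is always a
superset of the true match set, and FILTER verification removes the false
positives.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .errors import PlannerError, RegexSyntaxError, UnsupportedRegexError
from .gram_index import GramIndex

# ---------------------------------------------------------------------------
# AST node types


@dataclass(frozen=True)
class Gram:
    """A literal run of characters; Gram("") is the empty string (epsilon)."""

    text: str


@dataclass(frozen=True)
class AnyChar:
    """'.', kept symbolic: an alternation over every character."""


@dataclass(frozen=True)
class CharClass:
    """A character class like [a-z0-9]; raw AST only."""

    chars: tuple[str, ...]


@dataclass(frozen=True)
class Concat:
    children: tuple["RegexNode", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["RegexNode", ...]


@dataclass(frozen=True)
class Star:
    child: "RegexNode"


@dataclass(frozen=True)
class Plus:
    child: "RegexNode"


@dataclass(frozen=True)
class Opt:
    child: "RegexNode"


RegexNode = Union[Gram, AnyChar, CharClass, Concat, Or, Star, Plus, Opt]

EPSILON = Gram("")

_QUANTIFIERS = {"*": Star, "+": Plus, "?": Opt}
_META = set(".|*+?()[]\\")


class _Scanner:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def peek(self) -> str | None:
        return self.text[self.pos] if self.pos < len(self.text) else None

    def take(self) -> str:
        ch = self.text[self.pos]
        self.pos += 1
        return ch

    def error(self, msg: str, unsupported: bool = False) -> Exception:
        cls = UnsupportedRegexError if unsupported else RegexSyntaxError
        return cls(f"{msg} at position {self.pos} in pattern {self.text!r}")


def parse_regex(pattern: str) -> RegexNode:
    """Parse the supported regex grammar into a raw AST.

    Supported: literals, '.', '|', '*', '+', '?', grouping, character
    classes with ranges, backslash escapes of metacharacters.  Anchors,
    counted repetition, backreferences, lookaround and negated classes
    raise :class:`UnsupportedRegexError`.
    """
    sc = _Scanner(pattern)
    node = _parse_alternation(sc)
    if sc.peek() is not None:
        raise sc.error(f"unexpected {sc.peek()!r}")
    return node


def _parse_alternation(sc: _Scanner) -> RegexNode:
    branches = [_parse_concat(sc)]
    while sc.peek() == "|":
        sc.take()
        branches.append(_parse_concat(sc))
    if len(branches) == 1:
        return branches[0]
    return Or(tuple(branches))


def _parse_concat(sc: _Scanner) -> RegexNode:
    factors: list[RegexNode] = []
    while sc.peek() is not None and sc.peek() not in "|)":
        factors.append(_parse_factor(sc))
    # merge adjacent unquantified literal runs into one gram
    merged: list[RegexNode] = []
    for node in factors:
        if merged and isinstance(node, Gram) and isinstance(merged[-1], Gram):
            merged[-1] = Gram(merged[-1].text + node.text)
        else:
            merged.append(node)
    if not merged:
        return EPSILON
    if len(merged) == 1:
        return merged[0]
    return Concat(tuple(merged))


def _parse_factor(sc: _Scanner) -> RegexNode:
    atom = _parse_atom(sc)
    ch = sc.peek()
    if ch in _QUANTIFIERS:
        sc.take()
        if sc.peek() in _QUANTIFIERS:
            raise sc.error("stacked quantifiers", unsupported=True)
        return _QUANTIFIERS[ch](atom)
    if ch == "{":
        raise sc.error("counted repetition {m,n}", unsupported=True)
    return atom


def _parse_atom(sc: _Scanner) -> RegexNode:
    ch = sc.peek()
    if ch is None:
        raise sc.error("pattern ended unexpectedly")
    if ch in ("^", "$"):
        raise sc.error(f"anchor {ch!r}", unsupported=True)
    if ch == "{":
        raise sc.error("counted repetition {m,n}", unsupported=True)
    if ch == ".":
        sc.take()
        return AnyChar()
    if ch == "(":
        sc.take()
        if sc.peek() == "?":
            raise sc.error("group extension '(?'", unsupported=True)
        inner = _parse_alternation(sc)
        if sc.peek() != ")":
            raise sc.error("unclosed group")
        sc.take()
        return inner
    if ch == "[":
        return _parse_class(sc)
    if ch == "\\":
        sc.take()
        esc = sc.peek()
        if esc is None:
            raise sc.error("dangling backslash")
        if esc.isdigit():
            raise sc.error("backreference", unsupported=True)
        if esc.isalpha():
            raise sc.error(f"escape class \\{esc}", unsupported=True)
        sc.take()
        return Gram(esc)
    if ch in ")*+?]|":
        raise sc.error(f"misplaced {ch!r}")
    sc.take()
    return Gram(ch)


def _parse_class(sc: _Scanner) -> CharClass:
    sc.take()  # '['
    if sc.peek() == "^":
        raise sc.error("negated character class", unsupported=True)
    members: list[str] = []
    while True:
        ch = sc.peek()
        if ch is None:
            raise sc.error("unclosed character class")
        if ch == "]":
            sc.take()
            break
        sc.take()
        if ch == "\\":
            nxt = sc.peek()
            if nxt is None:
                raise sc.error("dangling backslash in class")
            if nxt.isalnum():
                raise sc.error(f"escape class \\{nxt} in class", unsupported=True)
            ch = sc.take()
        if sc.peek() == "-" and sc.text[sc.pos + 1 : sc.pos + 2] not in ("]", ""):
            sc.take()  # '-'
            hi = sc.take()
            if ord(hi) < ord(ch):
                raise sc.error(f"reversed range {ch}-{hi}")
            members.extend(chr(c) for c in range(ord(ch), ord(hi) + 1))
        else:
            members.append(ch)
    if not members:
        raise sc.error("empty character class")
    return CharClass(tuple(dict.fromkeys(members)))


# ---------------------------------------------------------------------------
# normalization


def normalize(node: RegexNode) -> RegexNode:
    """Rewrite to the OR/STAR core: only GRAM, CONCAT, OR, STAR and the
    symbolic ANYCHAR remain, ``x+`` becomes ``xx*``, ``x?`` becomes
    ``(x|eps)``, classes become OR over member characters."""
    if isinstance(node, Gram) or isinstance(node, AnyChar):
        return node
    if isinstance(node, CharClass):
        if len(node.chars) == 1:
            return Gram(node.chars[0])
        return Or(tuple(Gram(c) for c in node.chars))
    if isinstance(node, Plus):
        child = normalize(node.child)
        return _make_concat([child, Star(child)])
    if isinstance(node, Opt):
        return normalize(Or((node.child, EPSILON)))
    if isinstance(node, Star):
        child = normalize(node.child)
        if isinstance(child, Star):
            return child
        if child == EPSILON:
            return EPSILON
        return Star(child)
    if isinstance(node, Concat):
        flat: list[RegexNode] = []
        for c in node.children:
            nc = normalize(c)
            if isinstance(nc, Concat):
                flat.extend(nc.children)
            elif nc == EPSILON:
                continue  # epsilon is the concat identity
            else:
                flat.append(nc)
        return _make_concat(flat)
    if isinstance(node, Or):
        flat: list[RegexNode] = []
        for c in node.children:
            nc = normalize(c)
            if isinstance(nc, Or):
                flat.extend(nc.children)
            else:
                flat.append(nc)
        unique = tuple(dict.fromkeys(flat))
        if len(unique) == 1:
            return unique[0]
        return Or(unique)
    raise TypeError(f"unexpected node {node!r}")


def _make_concat(children: list[RegexNode]) -> RegexNode:
    merged: list[RegexNode] = []
    for node in children:
        if merged and isinstance(node, Gram) and isinstance(merged[-1], Gram):
            merged[-1] = Gram(merged[-1].text + node.text)
        else:
            merged.append(node)
    if not merged:
        return EPSILON
    if len(merged) == 1:
        return merged[0]
    return Concat(tuple(merged))


def to_regex_string(node: RegexNode) -> str:
    """Render an AST back to pattern text accepted by the ``re`` module
    (used to cross-check that normalization preserves the language)."""
    return _render(node, top=True)


def _escape(text: str) -> str:
    return "".join("\\" + c if c in _META else c for c in text)


def _render(node: RegexNode, top: bool = False) -> str:
    if isinstance(node, Gram):
        return _escape(node.text)
    if isinstance(node, AnyChar):
        return "."
    if isinstance(node, CharClass):
        return "(" + "|".join(_escape(c) for c in node.chars) + ")"
    if isinstance(node, Star):
        return _render_atom(node.child) + "*"
    if isinstance(node, Plus):
        return _render_atom(node.child) + "+"
    if isinstance(node, Opt):
        return _render_atom(node.child) + "?"
    if isinstance(node, Concat):
        parts = []
        for c in node.children:
            s = _render(c)
            if isinstance(c, Or):
                s = "(" + s + ")"
            parts.append(s)
        return "".join(parts)
    if isinstance(node, Or):
        s = "|".join(_render(c) for c in node.children)
        return s if top else s
    raise TypeError(f"unexpected node {node!r}")


def _render_atom(node: RegexNode) -> str:
    s = _render(node)
    if isinstance(node, Gram) and len(node.text) == 1 and node.text not in _META:
        return s
    if isinstance(node, AnyChar):
        return s
    return "(" + s + ")"


# ---------------------------------------------------------------------------
# parse tree (AND/OR/ALL over grams)


@dataclass(frozen=True)
class PTGram:
    text: str


@dataclass(frozen=True)
class PTAnd:
    children: tuple["ParseTree", ...]


@dataclass(frozen=True)
class PTOr:
    children: tuple["ParseTree", ...]


@dataclass(frozen=True)
class PTAll:
    """No indexable constraint ('any string')."""


ParseTree = Union[PTGram, PTAnd, PTOr, PTAll]
ALL = PTAll()


def make_and(children: list[ParseTree]) -> ParseTree:
    """AND-merge: ALL children impose nothing and are dropped."""
    kept = [c for c in children if not isinstance(c, PTAll)]
    if not kept:
        return ALL
    if len(kept) == 1:
        return kept[0]
    return PTAnd(tuple(kept))


def make_or(children: list[ParseTree]) -> ParseTree:
    """OR-merge: one unconstrained branch makes the whole OR unconstrained."""
    if any(isinstance(c, PTAll) for c in children):
        return ALL
    if len(children) == 1:
        return children[0]
    return PTOr(tuple(children))


def to_parse_tree(node: RegexNode) -> ParseTree:
    """Abstract a normalized AST into the AND/OR constraint tree: STAR
    subtrees, bare ANYCHAR and epsilon all become ALL, then the merge
    rules run bottom-up."""
    if isinstance(node, Gram):
        return PTGram(node.text) if node.text else ALL
    if isinstance(node, (AnyChar, Star)):
        return ALL
    if isinstance(node, Concat):
        return make_and([to_parse_tree(c) for c in node.children])
    if isinstance(node, Or):
        return make_or([to_parse_tree(c) for c in node.children])
    raise TypeError(f"not a normalized node: {node!r}")


def remerge(tree: ParseTree) -> ParseTree:
    """Re-apply the merge rules bottom-up; merging is a fixpoint, so this is
    the identity on any tree produced by :func:`to_parse_tree`."""
    if isinstance(tree, PTAnd):
        return make_and([remerge(c) for c in tree.children])
    if isinstance(tree, PTOr):
        return make_or([remerge(c) for c in tree.children])
    return tree


# ---------------------------------------------------------------------------
# candidate plan


@dataclass(frozen=True)
class IdxScan:
    gram: str


@dataclass(frozen=True)
class IdxAnd:
    """Offset-aware intersection.  ``constraints[i]`` relates child i to
    child i+1: ("ordered",) means some left occurrence starts strictly
    before some right occurrence; ("exact", gap) pins the right start to
    left start + gap (substring decompositions)."""

    children: tuple["PlanNode", ...]
    constraints: tuple[tuple, ...]


@dataclass(frozen=True)
class IdxOr:
    children: tuple["PlanNode", ...]


@dataclass(frozen=True)
class FullScan:
    """Scan every triple of the part: the index cannot prune this pattern."""


PlanNode = Union[IdxScan, IdxAnd, IdxOr, FullScan]


@dataclass(frozen=True)
class CandidatePlan:
    root: PlanNode | None  # None: empty plan (no constraint source at all)
    part: str

    def structure(self) -> str:
        return plan_structure(self.root)

    def grams(self) -> set[str]:
        return plan_grams(self.root)


def plan_structure(node: PlanNode | None) -> str:
    """Canonical textual shape of a plan, ignoring positional metadata."""
    if node is None:
        return "EMPTY"
    if isinstance(node, IdxScan):
        return f"IDXSCAN({node.gram})"
    if isinstance(node, IdxAnd):
        return "IDXAND(" + ",".join(plan_structure(c) for c in node.children) + ")"
    if isinstance(node, IdxOr):
        return "IDXOR(" + ",".join(plan_structure(c) for c in node.children) + ")"
    if isinstance(node, FullScan):
        return "FULLSCAN"
    raise TypeError(f"unexpected plan node {node!r}")


def plan_grams(node: PlanNode | None) -> set[str]:
    if node is None or isinstance(node, FullScan):
        return set()
    if isinstance(node, IdxScan):
        return {node.gram}
    out: set[str] = set()
    for c in node.children:
        out |= plan_grams(c)
    return out


def choose_index(pattern_terms, filter_var: str) -> str:
    """Which part index serves a filter: the position where the filter
    variable occurs in the triple pattern (must be exactly one)."""
    positions = [
        part
        for part, term in zip(("S", "P", "O"), pattern_terms)
        if term == ("var", filter_var)
    ]
    if not positions:
        raise PlannerError(f"filter variable ?{filter_var} not in the triple pattern")
    if len(positions) > 1:
        raise PlannerError(
            f"filter variable ?{filter_var} occurs in several positions"
        )
    return positions[0]


def _cover_gram(g: str, index: GramIndex) -> list[tuple[int, str]]:
    """Greedy left-to-right cover of g by indexed substrings, longest-extent
    first; overlaps allowed; uncoverable stretches are skipped (any subset
    of substring constraints is sound)."""
    occs: list[tuple[int, str]] = []
    for i in range(len(g)):
        for length in range(index.alpha, index.beta + 1):
            if i + length <= len(g) and index.lookup(g[i : i + length]) is not None:
                occs.append((i, g[i : i + length]))
    if not occs:
        return []
    picks: list[tuple[int, str]] = []
    pos = 0
    while pos < len(g):
        covering = [(s, sub) for s, sub in occs if s <= pos < s + len(sub)]
        if covering:
            s, sub = max(covering, key=lambda it: (it[0] + len(it[1]), -it[0]))
            if not picks or picks[-1] != (s, sub):
                picks.append((s, sub))
            pos = s + len(sub)
        else:
            later = [s for s, _ in occs if s > pos]
            if not later:
                break
            pos = min(later)
    return picks


def _plan_gram(g: str, index: GramIndex, positional: str) -> PlanNode | PTAll:
    # case 1: g itself is an index key
    if index.lookup(g) is not None:
        return IdxScan(g)
    # case 2: cover g with indexed substrings
    picks = _cover_gram(g, index)
    if not picks:
        return ALL  # case 3: nothing indexed inside g
    if len(picks) == 1:
        return IdxScan(picks[0][1])
    children = tuple(IdxScan(sub) for _, sub in picks)
    if positional == "exact":
        constraints = tuple(
            ("exact", picks[i + 1][0] - picks[i][0]) for i in range(len(picks) - 1)
        )
    else:
        constraints = tuple(("ordered",) for _ in range(len(picks) - 1))
    return IdxAnd(children, constraints)


def plan_from_tree(
    tree: ParseTree, index: GramIndex, positional: str = "exact"
) -> CandidatePlan:
    """Emit the REGSCAN sub-plan for a merged parse tree against one part
    index.  Unindexed grams fall back to substring covers or ALL, and the
    merge rules re-apply upward; an ALL root degenerates to FULLSCAN."""
    root = _emit(tree, index, positional)
    if isinstance(root, PTAll):
        root = FullScan()
    return CandidatePlan(root=root, part=index.part)


def _emit(tree: ParseTree, index: GramIndex, positional: str):
    if isinstance(tree, PTAll):
        return ALL
    if isinstance(tree, PTGram):
        return _plan_gram(tree.text, index, positional)
    if isinstance(tree, PTAnd):
        emitted = [_emit(c, index, positional) for c in tree.children]
        kept = [e for e in emitted if not isinstance(e, PTAll)]
        if not kept:
            return ALL
        if len(kept) == 1:
            return kept[0]
        return IdxAnd(tuple(kept), tuple(("ordered",) for _ in kept[:-1]))
    if isinstance(tree, PTOr):
        emitted = [_emit(c, index, positional) for c in tree.children]
        if any(isinstance(e, PTAll) for e in emitted):
            return ALL
        if len(emitted) == 1:
            return emitted[0]
        return IdxOr(tuple(emitted))
    raise TypeError(f"unexpected tree node {tree!r}")


def compile_pattern(
    pattern: str, index: GramIndex, positional: str = "exact"
) -> CandidatePlan:
    """parse -> normalize -> parse tree -> plan, in one call.

    The emitted constraints are containment-based, so the same plan is
    sound under both anchored and search verification semantics."""
    tree = to_parse_tree(normalize(parse_regex(pattern)))
    return plan_from_tree(tree, index, positional)
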