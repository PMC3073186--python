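"""Synthetic GO-like corpora and independent brute-force oracles.

``generate_corpus`` emits deterministic N-Triples text whose strings mimic
a Gene-Ontology dump: ``GO_0005...`` term IRIs, protein mnemonics like
``GPR64_MOUSE`` with a small shared suffix pool, label/comment phrases
built from a
biology word pool (``spliceosomal``, ``activity``, ``molecular`` ... so the
stock query set finds matches), ISBN-like citation strings, and a small
Unicode admixture to exercise code-point offsets.  A configurable fraction
of object strings carries a rare marker gram that falls below any realistic
selectivity threshold.

The oracles at the bottom re-derive, by exhaustive scanning and with no
code shared with the indexed implementations, the answers the engine is
supposed to produce; property tests compare the two routes.
"""
from __future__ import annotations

import random
import re
from dataclasses import dataclass
from itertools import combinations

from .sparql import QuerySpec
from .triple_store import TripleStore

GO = "http://www.geneontology.org/go#"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"

_WORDS = [
    "spliceosomal",
    "complex",
    "assembly",
    "binding",
    "activity",
    "cellular",
    "molecular",
    "transport",
    "membrane",
    "kinase",
    "regulation",
    "process",
    "nuclear",
    "ribosomal",
    "transferase",
    "protein",
    "signaling",
    "metabolic",
]
_RNA_WORDS = ["mRNA", "tRNA", "rRNA"]
_TYPES = ["MolecularFunction", "BiologicalProcess", "CellularComponent"]
_UNICODE_BITS = ["α-helix", "β-barrel", "Δ-domain"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic synthetic corpus."""

    seed: int
    n_triples: int
    mnemonic_suffixes: tuple[str, ...] = ("_MOUSE", "_HUMAN", "_YEAST")
    prefix_alphabet: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    go_id_low: int = 5000
    go_id_high: int = 5999
    rare_gram: str = "XQZV"
    rare_fraction: float = 0.05
    unicode_fraction: float = 0.02
    isbn_fraction: float = 0.15
    consider_fraction: float = 0.1


def _escape_literal(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def _label(rng: random.Random, spec: FixtureSpec) -> str:
    words = rng.sample(_WORDS, k=rng.randint(2, 4))
    if rng.random() < 0.25:
        words.insert(rng.randrange(len(words) + 1), rng.choice(_RNA_WORDS))
    if rng.random() < 0.1:
        words = ["BP"] + words + ["in", "mouse"]
    text = " ".join(words)
    if rng.random() < spec.unicode_fraction:
        text += " " + rng.choice(_UNICODE_BITS)
    if rng.random() < spec.rare_fraction:
        text += " " + spec.rare_gram
    return text


def _mnemonic(rng: random.Random, spec: FixtureSpec) -> str:
    prefix = "".join(rng.choice(spec.prefix_alphabet) for _ in range(rng.randint(3, 5)))
    return f"{prefix}{rng.randint(1, 99)}{rng.choice(spec.mnemonic_suffixes)}"


def generate_corpus(spec: FixtureSpec) -> str:
    """Deterministic N-Triples text with exactly ``spec.n_triples`` statements."""
    rng = random.Random(spec.seed)
    lines: list[str] = []
    subjects: list[str] = []
    entity = 0
    while len(lines) < spec.n_triples:
        entity += 1
        if rng.random() < 0.5:
            go_id = rng.randint(spec.go_id_low, spec.go_id_high)
        else:
            go_id = rng.randint(10000, 99999)
        subj = f"<{GO}GO_{go_id:07d}_{entity}>"
        subjects.append(subj)
        lines.append(f'{subj} <{RDF}type> <{GO}{rng.choice(_TYPES)}> .')
        lines.append(
            f'{subj} <{RDFS}label> "{_escape_literal(_label(rng, spec))}" .'
        )
        comment = (
            f"a {rng.choice(_WORDS)} {rng.choice(_WORDS)} annotation "
            f"of the {rng.choice(_WORDS)} class"
        )
        if rng.random() < spec.isbn_fraction:
            comment += f"; see ISBN 0{rng.randint(10, 99)}19857{rng.randint(0, 9)}"
        lines.append(f'{subj} <{RDFS}comment> "{_escape_literal(comment)}" .')
        lines.append(f'{subj} <{GO}mnemonic> "{_mnemonic(rng, spec)}" .')
        if rng.random() < spec.consider_fraction and entity > 1:
            lines.append(f'{subj} <{GO}consider> {rng.choice(subjects[:-1])} .')
    return "\n".join(lines[: spec.n_triples]) + "\n"


# The stock GO query set: the eight query shapes the engine is exercised
# with end-to-end (labels, alternation, bracketed digit classes, multi-way
# joins, filters on subjects, chained filters).  Typographic quotes are on
# purpose: the parser must accept them.
GO_QUERIES: tuple[str, ...] = (
    'SELECT * WHERE {?gp rdfs:label ?name FILTER regex (?name, ”spliceosomal”) .}',
    'SELECT * WHERE {?gp rdfs:label ?name FILTER regex (?name, ”mRNA|tRNA”) .}',
    'SELECT * WHERE {?gene ?pred ?isbn FILTER regex (?isbn, ”[0-9]19857[0-9]”) .}',
    'SELECT * WHERE {?gp rdf:type ?type .?gp rdfs:label ?name '
    'FILTER regex (?name, ”BP.*mouse”) .}',
    'SELECT * WHERE {?gp rdf:type ?type FILTER regex (?gp, ”0005[0-9][0-9][0-9]”) '
    '.?gp rdfs:label ?name .?gp rdfs:comment ?comment .}',
    'SELECT * WHERE {?gp rdf:type ?type FILTER regex (?gp, ”0005[0-9][0-9][0-9]”) '
    '.?gp rdfs:label ?name FILTER regex (?name, ”activity”) '
    '.?gp rdfs:comment ?comment .}',
    'SELECT * WHERE {?gp rdf:type ?type FILTER regex (?gp, ”0005[0-9][0-9][0-9]”) '
    '.?gp rdfs:label ?name FILTER regex (?name, ”activity”) '
    '.?gp rdfs:comment ?comment FILTER regex (?comment, ”molecular”).}',
    'SELECT * WHERE {?gp1 go:consider ?gp2 . ?gp1 ?p1 ?ns1 '
    'FILTER regex (?ns1, ”cellular”) .?gp2 ?p2 ?ns2 '
    'FILTER regex (?ns2, ”molecular”) .}',
)


# ---------------------------------------------------------------------------
# brute-force oracles (no code shared with the indexed implementations)


def oracle_regex_scan(
    corpus: TripleStore, pattern: str, part: str, semantics: str = "anchored"
) -> set[int]:
    """Exact answer set of a regex filter on one part: full scan + ``re``."""
    compiled = re.compile(pattern, re.DOTALL)
    check = compiled.fullmatch if semantics == "anchored" else compiled.search
    hits: set[int] = set()
    for tid in range(1, len(corpus) + 1):
        if check(corpus.part_string(tid, part)) is not None:
            hits.add(tid)
    return hits


def oracle_selective_grams(
    corpus: TripleStore, part: str, alpha: int, beta: int, c: float
) -> set[str]:
    """Independent re-derivation of the index key set: enumerate every gram,
    threshold on selectivity, keep only minimal infrequent grams."""
    strings = corpus.part_strings(part)
    n = len(strings)
    if n == 0:
        return set()
    counts: dict[str, int] = {}
    for s in strings:
        grams = {
            s[i:j]
            for i in range(len(s))
            for j in range(i + alpha, min(i + beta, len(s)) + 1)
        }
        for g in grams:
            counts[g] = counts.get(g, 0) + 1
    infrequent = {g for g, cnt in counts.items() if cnt / n <= c}
    out = set()
    for g in infrequent:
        has_infrequent_part = any(
            g[i:j] in infrequent
            for i, j in combinations(range(len(g) + 1), 2)
            if (j - i) >= alpha and (j - i) < len(g)
        )
        if not has_infrequent_part:
            out.add(g)
    return out


def oracle_query(
    spec: QuerySpec, corpus: TripleStore, semantics: str = "anchored"
) -> list[tuple[str, ...]]:
    """Naive query evaluation: per-pattern scan, nested-loop natural join,
    regex filters via ``re``, lexicographic projection order (bag
    semantics, like the engine)."""
    d = corpus.dictionary

    def pattern_rows(pat):
        rows = []
        for tid in range(1, len(corpus) + 1):
            s, p, o = corpus.resolve(tid)
            row: dict[str, str] = {}
            ok = True
            for (kind, value), text in zip(pat.terms, (s, p, o)):
                if kind == "const":
                    if value != text:
                        ok = False
                        break
                else:
                    if value in row and row[value] != text:
                        ok = False
                        break
                    row[value] = text
            if ok:
                rows.append(row)
        return rows

    partial: list[dict[str, str]] = [{}]
    for pat in spec.patterns:
        rows = pattern_rows(pat)
        joined = []
        for acc in partial:
            for row in rows:
                if all(acc.get(k, v) == v for k, v in row.items()):
                    joined.append({**acc, **row})
        partial = joined
    checks = [(f.var, re.compile(f.pattern, re.DOTALL)) for f in spec.filters]
    survivors = []
    for acc in partial:
        ok = True
        for var, compiled in checks:
            text = acc[var]
            hit = (
                compiled.fullmatch(text)
                if semantics == "anchored"
                else compiled.search(text)
            )
            if hit is None:
                ok = False
                break
        if ok:
            survivors.append(acc)
    header = spec.projected()
    out = [tuple(acc[v] for v in header) for acc in survivors]
    out.sort()
    return out


# ---------------------------------------------------------------------------
# random supported patterns for property tests


def random_pattern(rng: random.Random, strings: list[str]) -> str:
    """A random pattern within the supported grammar, biased toward pieces
    of actual corpus strings so a useful fraction of patterns match."""

    def piece() -> str:
        s = rng.choice(strings)
        if len(s) < 2:
            return re.escape(s or "x")
        length = rng.randint(2, min(6, len(s)))
        start = rng.randrange(len(s) - length + 1)
        return re.escape(s[start : start + length])

    kind = rng.random()
    if kind < 0.2:
        return piece()
    if kind < 0.35:
        return f"{piece()}|{piece()}"
    if kind < 0.5:
        return f".*{piece()}.*"
    if kind < 0.65:
        return f"({piece()}|{piece()}).*{piece()}.*"
    if kind < 0.75:
        return f".*{piece()}[a-z ]*{piece()}.*"
    if kind < 0.85:
        return f".*{piece()}.?{piece()}.*"
    if kind < 0.95:
        return f".*{piece()}.+{piece()}.*"
    return f"{piece()}.*"
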