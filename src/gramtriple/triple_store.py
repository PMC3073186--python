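"""Dictionary-encoded RDF triple store.

An RDF database here is the set D = {t_1 .. t_n} of triples in file order,
with dense triple IDs 1..n.  Every distinct lexical form (shared across the
subject / predicate / object positions) is interned once in a bidirectional
string dictionary, so a triple is stored as three integer string IDs.

Lexical forms are *bare*: IRIs lose their angle brackets, literals lose their
surrounding quotes (any datatype or language tag is kept verbatim after the
closing quote position), and blank nodes keep their ``_:label`` spelling.
Gram extraction and regex filters therefore operate on the strings a user
actually sees.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence, TextIO

from rdflib import BNode, Literal, URIRef
from rdflib.plugins.parsers import ntriples as _nt

from .errors import NTriplesParseError, StorageError, UnknownTripleError

PARTS = ("S", "P", "O")
_DB_FORMAT = "gramtriple-db"
_DB_VERSION = 1

LexicalTriple = tuple[str, str, str]


class Triple(NamedTuple):
    """A dictionary-encoded triple: (tid, subject-ID, predicate-ID, object-ID)."""

    tid: int
    s: int
    p: int
    o: int


class StringDictionary:
    """Bidirectional string <-> integer-ID map with 1-based dense IDs."""

    def __init__(self) -> None:
        self._forward: dict[str, int] = {}
        self._inverse: list[str] = []

    def __len__(self) -> int:
        return len(self._inverse)

    def __contains__(self, text: str) -> bool:
        return text in self._forward

    def intern(self, text: str) -> int:
        sid = self._forward.get(text)
        if sid is None:
            self._inverse.append(text)
            sid = len(self._inverse)
            self._forward[text] = sid
        return sid

    def id_of(self, text: str) -> int | None:
        return self._forward.get(text)

    def string_of(self, sid: int) -> str:
        if not 1 <= sid <= len(self._inverse):
            raise KeyError(f"unknown string ID {sid}")
        return self._inverse[sid - 1]

    def strings(self) -> Sequence[str]:
        return tuple(self._inverse)


@dataclass
class TripleStore:
    """The triple table plus its string dictionary."""

    dictionary: StringDictionary = field(default_factory=StringDictionary)
    triples: list[Triple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def add(self, lexical: LexicalTriple) -> Triple:
        s, p, o = lexical
        t = Triple(
            len(self.triples) + 1,
            self.dictionary.intern(s),
            self.dictionary.intern(p),
            self.dictionary.intern(o),
        )
        self.triples.append(t)
        return t

    def triple(self, tid: int) -> Triple:
        if not 1 <= tid <= len(self.triples):
            raise UnknownTripleError(f"no triple with ID {tid}")
        return self.triples[tid - 1]

    def resolve(self, tid: int) -> LexicalTriple:
        """Round-trip a triple ID back to its three lexical forms."""
        t = self.triple(tid)
        d = self.dictionary
        return (d.string_of(t.s), d.string_of(t.p), d.string_of(t.o))

    def part_string(self, tid: int, part: str) -> str:
        t = self.triple(tid)
        sid = {"S": t.s, "P": t.p, "O": t.o}[part]
        return self.dictionary.string_of(sid)

    def part_strings(self, part: str) -> list[str]:
        """Part strings of every triple, aligned with tids 1..n."""
        idx = {"S": 1, "P": 2, "O": 3}[part]
        d = self.dictionary
        return [d.string_of(t[idx]) for t in self.triples]

    def distinct_count(self, part: str) -> int:
        idx = {"S": 1, "P": 2, "O": 3}[part]
        return len({t[idx] for t in self.triples})


class _ListSink:
    def __init__(self) -> None:
        self.triples: list = []

    def triple(self, s, p, o) -> None:  # rdflib sink protocol
        self.triples.append((s, p, o))


class _LabelKeepingParser(_nt.W3CNTriplesParser):
    """N-Triples parser that keeps blank-node labels verbatim.

    The stock parser re-maps ``_:b0`` to a document-scoped fresh ID; here a
    bnode is just an opaque string, so the printed label must survive."""

    def nodeid(self, bnode_context=None):
        if self.peek("_"):
            bnode_id = self.eat(_nt.r_nodeid).group(1)
            return BNode(bnode_id)
        return False


# Strict N-Triples wants absolute IRIs, but real-world snippets (and the
# worked examples here) use bare names like <Gpr64>.  Relative IRIs are
# absolutized under a private base before parsing and stripped afterwards,
# so their lexical form survives verbatim.
_REL_BASE = "urn:x-gramtriple-rel:"


def _absolutize(line: str) -> str:
    out: list[str] = []
    i = 0
    in_quote = False
    while i < len(line):
        ch = line[i]
        if in_quote:
            out.append(ch)
            if ch == "\\" and i + 1 < len(line):
                out.append(line[i + 1])
                i += 1
            elif ch == '"':
                in_quote = False
        elif ch == '"':
            out.append(ch)
            in_quote = True
        elif ch == "<":
            end = line.find(">", i)
            if end == -1:
                out.append(ch)
            else:
                body = line[i + 1 : end]
                if ":" not in body:
                    out.append(f"<{_REL_BASE}{body}>")
                else:
                    out.append(line[i : end + 1])
                i = end
        else:
            out.append(ch)
        i += 1
    return "".join(out)


def _lexical(term) -> str:
    if isinstance(term, URIRef):
        text = str(term)
        if text.startswith(_REL_BASE):
            return text[len(_REL_BASE) :]
        return text
    if isinstance(term, BNode):
        return f"_:{term}"
    if isinstance(term, Literal):
        text = str(term)
        if term.language:
            return f"{text}@{term.language}"
        if term.datatype is not None:
            return f"{text}^^<{term.datatype}>"
        return text
    raise NTriplesParseError(f"unexpected term {term!r}")


def parse_ntriples(source: str | Path | TextIO) -> list[LexicalTriple]:
    """Parse N-Triples text into bare lexical-form triples, in file order.

    ``source`` may be a path, an open text stream, or the document text
    itself (anything containing a newline or starting with '<', '_' or '#'
    is treated as text).  Malformed statements raise
    :class:`NTriplesParseError` naming the 1-based line number.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        p = Path(source)
        looks_like_doc = (
            "\n" in source or source.strip() == "" or source.lstrip()[:1] in "<_#"
        )
        if not looks_like_doc and p.is_file():
            text = p.read_text(encoding="utf-8")
        else:
            text = source
    else:
        text = source.read()

    sink = _ListSink()
    parser = _LabelKeepingParser(sink=sink)
    out: list[LexicalTriple] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        before = len(sink.triples)
        try:
            parser.parsestring(_absolutize(line) + "\n")
        except _nt.ParseError as exc:
            raise NTriplesParseError(f"line {lineno}: {exc}") from exc
        if len(sink.triples) != before + 1:
            raise NTriplesParseError(f"line {lineno}: not a single N-Triples statement")
        s, p, o = sink.triples[-1]
        out.append((_lexical(s), _lexical(p), _lexical(o)))
    return out


def load_database(triples: Iterable[LexicalTriple]) -> TripleStore:
    """Build a store from lexical triples; tids follow input order,
    duplicates keep distinct tids, strings are interned once."""
    store = TripleStore()
    for lex in triples:
        store.add(lex)
    return store


def load_ntriples(source: str | Path | TextIO) -> TripleStore:
    return load_database(parse_ntriples(source))


# ---------------------------------------------------------------------------
# persistence: versioned JSON container


def store_to_dict(store: TripleStore) -> dict:
    return {
        "strings": list(store.dictionary.strings()),
        "triples": [[t.s, t.p, t.o] for t in store.triples],
    }


def store_from_dict(data: dict) -> TripleStore:
    store = TripleStore()
    for text in data["strings"]:
        store.dictionary.intern(text)
    for i, (s, p, o) in enumerate(data["triples"], start=1):
        store.triples.append(Triple(i, s, p, o))
    return store


def save_database(path: str | Path, store: TripleStore) -> None:
    payload = {"format": _DB_FORMAT, "version": _DB_VERSION, **store_to_dict(store)}
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_database_file(path: str | Path) -> TripleStore:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise StorageError(f"unreadable database file {path}: {exc}") from exc
    if data.get("format") != _DB_FORMAT or data.get("version") != _DB_VERSION:
        raise StorageError(
            f"{path}: not a {_DB_FORMAT} v{_DB_VERSION} container"
        )
    return store_from_dict(data)
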