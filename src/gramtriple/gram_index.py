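"""Selective-gram inverted indexes over the three triple parts.

One index per part (I_S, I_P, I_O).  The keys are the *selective grams* of
the build corpus: substrings of length alpha..beta whose selectivity
Sel(g) = C(g)/N is at most the threshold c (C(g) counts triples whose part
string contains g, N is the total triple count), minus every gram that
contains a shorter infrequent gram of length >= alpha.  The surviving keys
are the minimal infrequent grams and form an antichain under the substring
relation: indexing a superstring of an already-infrequent gram buys no extra
pruning power, only index size.

Each key maps to a posting list of (tid, offsets) records — every 0-based
character offset at which the gram occurs in that triple's part string —
plus a simulated page count.  Page counts and a simulated B+-tree height
feed the I/O cost model; the in-memory key container is an ordered dict, the
paging is a deterministic formula, not real disk layout.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .config import EngineConfig
from .errors import StorageError
from .triple_store import PARTS, TripleStore

_IDX_FORMAT = "gramtriple-index"
_IDX_VERSION = 1

# posting list: sorted-by-tid records of (tid, strictly increasing offsets)
PostingList = list[tuple[int, tuple[int, ...]]]


def enumerate_grams(s: str, alpha: int, beta: int) -> set[tuple[str, int]]:
    """All (gram, start-offset) pairs of s with alpha <= len(gram) <= beta.

    Offsets are 0-based character (code point) positions.  Strings shorter
    than alpha yield the empty set.
    """
    if not 1 <= alpha <= beta:
        raise ValueError("require 1 <= alpha <= beta")
    out: set[tuple[str, int]] = set()
    n = len(s)
    for length in range(alpha, beta + 1):
        for i in range(n - length + 1):
            out.add((s[i : i + length], i))
    return out


def _containment_counts(strings: Sequence[str], alpha: int, beta: int) -> dict[str, int]:
    """C(g) for every gram of length alpha..beta occurring in ``strings``:
    the number of strings (triples, one string per triple) containing g."""
    counts: dict[str, int] = {}
    for s in strings:
        seen: set[str] = set()
        n = len(s)
        for length in range(alpha, beta + 1):
            for i in range(n - length + 1):
                seen.add(s[i : i + length])
        for g in seen:
            counts[g] = counts.get(g, 0) + 1
    return counts


def selectivity(g: str, corpus: TripleStore, part: str) -> float:
    """Sel(g) = C(g)/N on the given part, counting triples as documents."""
    if len(corpus) == 0:
        raise ValueError("selectivity is undefined on an empty corpus")
    strings = corpus.part_strings(part)
    c = sum(1 for s in strings if g in s)
    return c / len(strings)


def _minimal_infrequent(infrequent: set[str], alpha: int) -> set[str]:
    """Drop every gram containing a shorter infrequent gram of length >= alpha."""
    selected: set[str] = set()
    for g in infrequent:
        redundant = False
        for length in range(alpha, len(g)):
            for i in range(len(g) - length + 1):
                if g[i : i + length] in infrequent:
                    redundant = True
                    break
            if redundant:
                break
        if not redundant:
            selected.add(g)
    return selected


def select_selective_grams(
    corpus: TripleStore, part: str, alpha: int, beta: int, c: float
) -> set[str]:
    """The index key set for one part: minimal infrequent grams in [alpha, beta]."""
    if not 0.0 < c <= 1.0:
        raise ValueError("threshold c must be in (0, 1]")
    strings = corpus.part_strings(part)
    n = len(strings)
    if n == 0:
        return set()
    counts = _containment_counts(strings, alpha, beta)
    infrequent = {g for g, cnt in counts.items() if cnt / n <= c}
    return _minimal_infrequent(infrequent, alpha)


@dataclass
class GramIndex:
    """One part's inverted index of selective grams."""

    part: str
    alpha: int
    beta: int
    sel_threshold: float
    entries: dict[str, PostingList] = field(default_factory=dict)
    num_pages: dict[str, int] = field(default_factory=dict)
    height: int = 1

    def lookup(self, g: str) -> PostingList | None:
        """Posting list of g, or None when g is not a key (absent != empty)."""
        return self.entries.get(g)

    def keys(self) -> list[str]:
        return list(self.entries)

    def pages_of(self, g: str) -> int:
        return self.num_pages[g]

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GramIndex):
            return NotImplemented
        return (
            self.part == other.part
            and self.alpha == other.alpha
            and self.beta == other.beta
            and self.sel_threshold == other.sel_threshold
            and self.entries == other.entries
            and self.num_pages == other.num_pages
            and self.height == other.height
        )


def simulated_pages(n_entries: int, entries_per_page: int) -> int:
    """Pages needed for a posting list of ``n_entries`` records (min 1 page
    once a list exists; 0 entries -> 0 pages)."""
    if n_entries <= 0:
        return 0
    return math.ceil(n_entries / entries_per_page)


def simulated_height(n_keys: int, fanout: int) -> int:
    """Stand-in B+-tree height: 1 + ceil(log_fanout(#keys)), floor 1."""
    if n_keys <= 1:
        return 1
    return 1 + math.ceil(math.log(n_keys, fanout))


def build_index(
    corpus: TripleStore, part: str, config: EngineConfig
) -> GramIndex:
    alpha, beta, c = config.alpha, config.beta, config.sel_threshold
    index = GramIndex(part=part, alpha=alpha, beta=beta, sel_threshold=c)
    if len(corpus) == 0:
        return index
    selected = select_selective_grams(corpus, part, alpha, beta, c)
    postings: dict[str, PostingList] = {g: [] for g in selected}
    strings = corpus.part_strings(part)
    for tid, s in enumerate(strings, start=1):
        hits: dict[str, list[int]] = {}
        n = len(s)
        for length in range(alpha, beta + 1):
            for i in range(n - length + 1):
                g = s[i : i + length]
                if g in postings:
                    hits.setdefault(g, []).append(i)
        for g, offs in hits.items():
            postings[g].append((tid, tuple(sorted(offs))))
    for g in sorted(postings):
        index.entries[g] = postings[g]
        index.num_pages[g] = simulated_pages(len(postings[g]), config.entries_per_page)
    index.height = simulated_height(len(index.entries), config.fanout)
    return index


def build_indexes(
    corpus: TripleStore, config: EngineConfig | None = None
) -> dict[str, GramIndex]:
    """Build {part: GramIndex} for all three parts (IndexBuild)."""
    config = config or EngineConfig()
    return {part: build_index(corpus, part, config) for part in PARTS}


# ---------------------------------------------------------------------------
# persistence


def indexes_to_dict(indexes: dict[str, GramIndex]) -> dict:
    out = {}
    for part, idx in indexes.items():
        out[part] = {
            "alpha": idx.alpha,
            "beta": idx.beta,
            "sel_threshold": idx.sel_threshold,
            "height": idx.height,
            "entries": [
                [g, [[tid, list(offs)] for tid, offs in plist], idx.num_pages[g]]
                for g, plist in idx.entries.items()
            ],
        }
    return out


def indexes_from_dict(data: dict) -> dict[str, GramIndex]:
    out: dict[str, GramIndex] = {}
    for part, rec in data.items():
        idx = GramIndex(
            part=part,
            alpha=rec["alpha"],
            beta=rec["beta"],
            sel_threshold=rec["sel_threshold"],
            height=rec["height"],
        )
        for g, plist, pages in rec["entries"]:
            idx.entries[g] = [(tid, tuple(offs)) for tid, offs in plist]
            idx.num_pages[g] = pages
        out[part] = idx
    return out


def persist_indexes(path: str | Path, indexes: dict[str, GramIndex]) -> None:
    payload = {
        "format": _IDX_FORMAT,
        "version": _IDX_VERSION,
        "parts": indexes_to_dict(indexes),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_indexes(path: str | Path) -> dict[str, GramIndex]:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise StorageError(f"unreadable index file {path}: {exc}") from exc
    if data.get("format") != _IDX_FORMAT or data.get("version") != _IDX_VERSION:
        raise StorageError(f"{path}: not a {_IDX_FORMAT} v{_IDX_VERSION} container")
    return indexes_from_dict(data["parts"])
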