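"""Engine configuration.

All knobs that change index contents, plan shape, or verification semantics
live here so the CLI, the library surface, and the tests share one source of
defaults.  Index-shape parameters follow the reference setup: gram lengths
2..4 and an infrequency threshold of 0.1.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters of the index, cost model, and matcher.

    alpha, beta
        Minimum / maximum indexed gram length (characters).
    sel_threshold
        Selectivity cut-off ``c``: a gram is *infrequent* when the fraction
        of triples whose part string contains it is <= c.
    entries_per_page
        Simulated page capacity of a posting list, in (tid, offsets)
        records; drives NumPages and hence the cost model.
    fanout
        Simulated B+-tree fanout; drives the index height term of the cost
        model.
    one_page_access_cost
        Unit I/O cost of touching one page.  Only ratios matter for plan
        choice, so the default is 1.0.
    regex_semantics
        "anchored": a FILTER pattern must match the whole lexical form;
        "search": substring semantics (the pattern is treated as if wrapped
        in ``.*``...``.*``), matching SPARQL's regex().
    positional
        "exact": substring decompositions of an unindexed gram constrain
        child offsets to exact gaps; "ordered": only left-before-right.
    """

    alpha: int = 2
    beta: int = 4
    sel_threshold: float = 0.1
    entries_per_page: int = 128
    fanout: int = 256
    one_page_access_cost: float = 1.0
    regex_semantics: str = "anchored"
    positional: str = "exact"

    def __post_init__(self) -> None:
        if not (1 <= self.alpha <= self.beta):
            raise ValueError("require 1 <= alpha <= beta")
        if not (0.0 < self.sel_threshold <= 1.0):
            raise ValueError("sel_threshold must be in (0, 1]")
        if self.entries_per_page < 1 or self.fanout < 2:
            raise ValueError("entries_per_page >= 1 and fanout >= 2 required")
        if self.regex_semantics not in ("anchored", "search"):
            raise ValueError("regex_semantics must be 'anchored' or 'search'")
        if self.positional not in ("exact", "ordered"):
            raise ValueError("positional must be 'exact' or 'ordered'")

    def replace(self, **overrides: Any) -> "EngineConfig":
        """Return a copy with non-None overrides applied."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "EngineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
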