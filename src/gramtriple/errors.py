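"""Exception hierarchy for gramtriple."""


class GramTripleError(Exception):
    """Base class for all gramtriple errors."""


class NTriplesParseError(GramTripleError):
    """Malformed N-Triples input; message names the offending line number."""


class UnknownTripleError(GramTripleError):
    """A triple ID that is not present in the store."""


class StorageError(GramTripleError):
    """Persisted container is truncated, corrupt, or of an unsupported version."""


class RegexSyntaxError(GramTripleError):
    """Pattern text does not parse under the supported regex grammar."""


class UnsupportedRegexError(RegexSyntaxError):
    """Pattern uses a construct outside the supported grammar (anchors,
    backreferences, lookaround, counted repetition, negated classes)."""


class PlannerError(GramTripleError):
    """Candidate-plan compilation was asked something it cannot answer,
    e.g. a filter variable absent from its triple pattern."""


class SparqlSyntaxError(GramTripleError):
    """Query text does not parse under the supported SPARQL subset."""


class QueryValidationError(GramTripleError):
    """Query parsed but violates a structural constraint (empty WHERE,
    disconnected pattern graph, filter on an unbound variable)."""


class OptimizeError(GramTripleError):
    """The optimizer cannot enumerate plans for this query shape."""
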