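# Methods

This note documents the model behind `gramtriple`, the choices that were
genuinely open when it was designed, and what its tests do and do not
establish.

## Data model

An RDF database is the ordered triple table `D = {t_1 … t_n}`: triple IDs
are dense, 1-based, and follow file order, and duplicate statements keep
distinct IDs (bag semantics end to end).  All three positions share one
string dictionary, a bijection between lexical forms and integer IDs; a
per-position dictionary would also be defensible, but a shared one is
smaller and makes cross-position joins a pure integer comparison.

Lexical forms are *bare*: IRIs without angle brackets, literals without
their surrounding quotes (datatype/language tags are kept verbatim after
the closing-quote position, e.g. `5^^<…#int>`), blank nodes as their
`_:label` spelling.  Indexing and regex matching both operate on these
bare forms, so a pattern matches exactly what a user sees in the data.
Strings are sequences of Unicode code points; all offsets are code-point
offsets, which keeps posting offsets aligned with Python's regex engine
during verification.  Comparison is case-sensitive throughout (SPARQL's
`regex()` is case-sensitive without the `"i"` flag, which is unsupported).

N-Triples parsing is delegated to rdflib's W3C parser, driven line by line
so that errors carry a line number and statement order survives.  Two
deliberate relaxations: blank-node labels are kept verbatim rather than
re-minted (a bnode here is only an opaque string), and relative IRIs like
`<Gpr64>` are accepted by absolutizing them under a private URN base that
is stripped again on output.

## Selective-gram indexes

One inverted index per part, `I_S`, `I_P`, `I_O`, because a filter applies
to exactly one position of a triple pattern.  Keys are chosen in two steps
on the build corpus:

1. **Infrequency.** `Sel(g) = C(g)/N ≤ c`, where the "document" unit is a
   triple (not a distinct string): `C(g)` counts triples whose part string
   contains `g`, and `N` is the total triple count.  Counting triples
   follows the posting lists, which are keyed by triple ID; a consequence
   is that predicate grams are almost always frequent and `I_P` is nearly
   empty on realistic data, which is accepted (a regex on the predicate
   position then simply falls back to scan-and-verify).
2. **Minimality.** Any infrequent gram containing a shorter infrequent
   gram of length ≥ α prunes no candidate the shorter one does not, so
   only minimal infrequent grams are kept.  Minimality considers only
   substrings of length ≥ α, because shorter grams are never index
   candidates; with α = β this makes every infrequent gram minimal by
   construction.  The resulting key set is an antichain under the
   substring relation, and every infrequent gram in the length window
   either is a key or contains one (completeness), which is what makes
   substring covers of unindexed grams possible at query time.

Defaults α = 2, β = 4, c = 0.1; all three are configuration, and the
defaults follow the reference setup for this index family.  Raising β
lengthens keys (better pruning, bigger index); raising c admits more keys.

Postings are `(tid, sorted offsets)` records in tid order.  Two quantities
are *simulated* rather than measured, since the key container is an
in-memory ordered map, not a paged tree:

* `NumPages(g) = ceil(#posting records / entries_per_page)`, with
  `entries_per_page = 128` by default;
* `Height(I) = 1 + ceil(log_fanout(#keys))` with fanout 256, floor 1.

Both formulas are deterministic so the cost model is exactly testable; the
constants only set the scale of cost comparisons, not their ordering for
plans over the same index.

## Pattern compilation

The supported regex grammar covers literals, `.`, alternation, grouping,
`*` `+` `?`, character classes with ranges, and escapes of
metacharacters.  Anchors, counted repetition `{m,n}`, backreferences,
lookaround, escape classes (`\d` …) and negated classes raise an explicit
"unsupported" error — silently mishandling an anchor would corrupt
results, and negated classes cannot be normalized to a finite alternation.

Normalization rewrites to an OR/STAR core: `x+ → x x*`, `x? → (x | ε)`,
classes to alternations over members, adjacent literals merged into gram
runs.  `.` is kept as a symbolic any-character node instead of
materializing an alternation over an alphabet: wherever it survives to the
constraint stage it is unconstraining anyway, so this is observationally
equivalent and avoids alphabet-size blowup.  Normalization preserves the
matched language (property-tested against Python's `re` on generated
pattern/probe pairs).

The parse tree abstracts the normalized regex into containment
constraints: STAR subtrees, bare `.`, and ε all become ALL ("any string");
an AND drops ALL children; an OR with an ALL child is itself ALL.  Merging
is run bottom-up and is a fixpoint.  An `x?` branch therefore makes its
alternation unconstraining — sound, since ε cannot be indexed.

Plan emission maps AND/OR/gram onto IDXAND/IDXOR/IDXSCAN.  For a gram that
is not an index key, a greedy left-to-right cover by indexed substrings is
used (at each uncovered position, the indexed substring reaching furthest;
overlaps allowed; uncoverable stretches skipped — any subset of substring
constraints is sound).  Covers carry **exact offset gaps** between
consecutive substrings (`USE` must start exactly 2 after `MOU` inside
`MOUSE`), which tightens candidate sets at no soundness risk; the
`positional = ordered` switch falls back to pure left-before-right
ordering, matching the looser published rule, and final answers are
identical in either mode because verification is exact.  Concatenation-
level IDXANDs use ordering-only constraints, and IDXOR discards offsets
(its union has no single anchor position).  A plan whose root merges to
ALL degenerates to FULLSCAN of the part plus verification.

Candidate soundness — plan output ⊇ true matches for every pattern and
corpus — is the central invariant and is swept against a brute-force regex
scan on seeded corpora.

## Execution

All operators implement `get_next()` (one result per call, idempotent
exhaustion).  Sub-plan streams are `(tid, offsets)` in ascending tid
order; IDXAND is an n-way sorted intersection that admits a tid only if
some offset choice satisfies the chain of constraints (checked greedily
for ordering constraints, by set membership for exact gaps), and emits the
satisfying leftmost-child start offsets — the choice of surfaced offsets
is unobservable after FILTER, so leftmost is simply the cheapest.  Once a
child carries no offsets (past an IDXOR), offset constraints become
vacuous and the intersection is by tid only, which is again sound.

REGSCAN resolves candidate tids through the dictionary and hands
`(s, p, o)` string IDs upward; the leaf operator then re-checks pattern
constants and verifies every attached regex filter with Python's `re` on
the *original* (un-normalized) pattern — normalization exists only for
candidate generation, verification must be ground truth.

Two FILTER semantics are provided.  `anchored` (default) requires the
whole lexical form to match, which reflects how patterns in this idiom are
written (explicit `.*` wrappers); `search` gives SPARQL's substring
`regex()` behavior.  Candidate plans are containment-based and therefore
sound under both; only the verification call changes.

TSCAN materializes and sorts its bindings by the first variable's string
ID so a merge join can consume it; MGJN checks sortedness as it consumes
and treats a violation as a contract error; HSJN builds on the left input.
Joins are natural joins on shared variables with bag semantics; SELECT
does not deduplicate, and result rows are sorted lexicographically by
their resolved strings purely for reproducible output.

## Cost model and optimization

REGSCAN cost follows the page-access formula
`Cost = OnePageAccessCost × (|G| × Height(I) + Σ NumPages(g))` with `G`
the set of *distinct* grams in the plan (a gram appearing twice descends
the tree once).  `OnePageAccessCost = 1` since only ratios matter.  CPU
cost is ignored.  TSCAN and FULLSCAN pay the simulated page count of the
triple table under the same `entries_per_page` rule.

The reference cost model prices only REGSCAN, so the join side is this
package's own minimal model: a join costs its children plus both input
cardinalities; leaf cardinalities come from posting sizes (min across an
AND, capped sum across an OR) and uniform constant selectivities
(`n / #distinct strings` per bound position); join output cardinality is
estimated as the smaller input.  This is deliberately crude — it exists to
order alternatives, not to predict runtimes — and it is documented here
precisely because it is invented.

Optimization enumerates all bushy join trees over ≤ 8 triple patterns
(beyond that the exhaustive space is unreasonable and the call errors
out), choosing per leaf between TSCAN-plus-verify and the cheapest
filter-driven REGSCAN, and per join between HSJN and (when both inputs are
ordered on the key) MGJN.  Ties prefer merge join, then the smaller plan
serialization, so the chosen plan is a deterministic function of query and
index.

## Synthetic corpora and what the tests show

The fixture generator emulates the *string shapes* of a Gene-Ontology RDF
dump: GO-style term IRIs (about half carrying a `0005…` identifier
prefix), `rdf:type` / `rdfs:label` / `rdfs:comment` / `mnemonic` /
`consider` predicates, protein mnemonics like `KQW23_MOUSE` over a
three-suffix pool, label and comment phrases drawn from a biology word
pool so that the stock eight-query set finds matches, occasional ISBN-like
citation strings, a small Unicode admixture (≈ 2%) to exercise code-point
offsets, and a rare marker gram in ≈ 5% of labels so that something always
falls below the selectivity threshold.  Identical parameters give
byte-identical output.

It does **not** reproduce the scale (hundreds of thousands of triples),
the vocabulary skew, or the string-length distribution of the real dump,
and no wall-clock or index-size comparison against another RDF store is
meaningful at this scale.  What the passing suite does establish:
exactness (engine ≡ brute-force evaluator) and candidate soundness over
thousands of random pattern/corpus pairs, equivalence of the gram-selection
rule with an independent oracle, the printed-formula cost values, and plan
optimality within the enumerated space.  Property sweeps use corpora of
300–2,000 triples and 200 patterns per corpus — sizes chosen so the whole
suite runs in well under a minute per sweep while still exercising
paging (posting lists longer than one page) and index heights above 1.

## Known limitations

* Rebuild-only indexes; no maintenance under updates or deletes.
* No `OPTIONAL` / `UNION` / `ORDER BY` / `LIMIT` / `DISTINCT`; no named
  graphs; no datatype-aware comparison (typed literals compare as their
  lexical form).
* Regular *path* queries over the graph (regex over edge sequences) are a
  different problem and out of scope.
* The persisted database is a versioned JSON container — portable and
  diffable, but neither compact nor paged; the page counts it stores are
  the simulated ones described above.
* `I_P` is near-empty under triple-counting selectivity (see above), so
  predicate-position filters effectively always scan.
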