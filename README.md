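# gramtriple

Regular-expression FILTER patterns are common in SPARQL queries over
life-science RDF resources (Gene Ontology, UniProt, Bio2RDF): users rarely
know the exact lexical form of a label, mnemonic or identifier, so they ask
for `regex(?m, "(GPR|CCD).*MOUSE.*")` instead of an exact value.  A naive
engine answers such a query by scanning every triple and running the regex
on each string.  `gramtriple` is a small, self-contained query engine that
answers them from an inverted index instead.

## The method

Let `D = {t_1 … t_n}` be the triple table, with each triple dictionary-
encoded into three string IDs.  For each part (subject, predicate, object)
the engine builds an inverted index `I_S`, `I_P`, `I_O` whose keys are the
**selective grams** of that part's strings:

* a gram is any substring of length `α ≤ len ≤ β` (defaults 2–4);
* its selectivity is `Sel(g) = C(g)/N`, where `C(g)` counts triples whose
  part string contains `g` and `N = n`; grams with `Sel(g) ≤ c`
  (default `c = 0.1`) are *infrequent*;
* an infrequent gram that contains a shorter infrequent gram (of length
  ≥ α) is redundant and dropped.  The surviving keys are the minimal
  infrequent grams and form an antichain under the substring relation.

Each key maps to a posting list of `(tid, offsets)` records — every 0-based
character offset at which the gram occurs — plus a simulated page count.

A FILTER pattern is compiled into a candidate plan: the regex is normalized
to an OR/STAR core (`x+ → xx*`, classes → alternations), its parse tree
turns STAR subtrees into unconstraining ALL nodes that merge away, and the
remaining AND/OR tree over literal grams becomes IDXAND / IDXOR / IDXSCAN
operators.  A gram that is not an index key is replaced by an IDXAND over
indexed substrings covering it (with exact offset gaps); if nothing inside
it is indexed the plan degenerates toward a full scan.  The candidate set
is always a **superset** of the true answers, and a FILTER operator
re-checks the original regex on every candidate, so results are exact.

Plans are chosen by an I/O cost model,

    Cost = OnePageAccessCost × (|G| × Height(I) + Σ_{g∈G} NumPages(g)),

and an exhaustive bottom-up optimizer that also enumerates join orders
(merge join / hash join) for multi-pattern queries.  Execution follows the
GetNext iterator model: every operator returns one result per call.

## Worked example

```sh
$ gramtriple make-fixture --seed 11 --n 2000 --out go.nt
wrote 2000 triples to go.nt
$ gramtriple build-index go.nt --db go.db
indexed 2000 triples in 0.35s; keys S=130 P=7 O=1102
$ gramtriple query --db go.db --regex-semantics search \
    --sparql 'SELECT * WHERE {?gp rdfs:label ?name FILTER regex (?name, "spliceosomal") .}' \
    | head -3
?gp	?name
http://www.geneontology.org/go#GO_0005030_21	mRNA spliceosomal complex
http://www.geneontology.org/go#GO_0005041_71	protein spliceosomal kinase regulation
```

The summary line on stderr (`# 93 rows in 0.002s, plan
P0[IDXAND(IDXSCAN(spl),IDXSCAN(ice),IDXSCAN(eos))]`) shows what happened:
the pattern `spliceosomal` was covered by three indexed grams, their
posting lists were intersected with offset constraints, and only those
candidates were regex-verified — no full scan.  `gramtriple explain`
prints the same plan as a tree with posting sizes, page counts and the
cost estimate:

```
REGSCAN[O] ?gp 'http://www.w3.org/2000/01/rdf-schema#label' ?name cost=15.0 card~160
  FILTER ?name ~ /.*spliceosomal.*/
  IDXAND
    IDXSCAN(spl) [160 postings, 2 pages]
    IDXSCAN(ice) [160 postings, 2 pages]
    IDXSCAN(eos) [160 postings, 2 pages]
```

`gramtriple stats --db go.db` summarizes key counts, simulated B+-tree
heights and page totals per part index.

In the library, the same pipeline is three calls:

```python
from gramtriple import EngineConfig, build_indexes, load_ntriples, run_query

store = load_ntriples("go.nt")
indexes = build_indexes(store, EngineConfig())
header, rows, plan = run_query(
    'SELECT * WHERE {?s ?p ?o FILTER regex (?o, ".*MOUSE.*") .}',
    store, indexes, EngineConfig(),
)
```

By default a FILTER pattern must match the whole lexical form (the usual
query idiom therefore wraps patterns in `.*`); pass
`EngineConfig(regex_semantics="search")` or `--regex-semantics search` for
SPARQL's substring-search `regex()` behavior.

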