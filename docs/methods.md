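# Methods

## Problem and model

Genomic-epidemiology pipelines summarise pathogen relatedness as square
pairwise matrices: SNP distances between whole genomes, posterior
probabilities of directed transmission, or IBD fractions between parasite
isolates. tgkit turns such a matrix into a transmission graph by
thresholding, manipulates the graph, and exports it for rendering.

Thresholding conventions:

- **at_most** (distance): pair linked iff `v ≤ t`. The canonical use is
  grouping *M. tuberculosis* genomes at ≤50 SNPs. The threshold is
  inclusive because the convention is written "≤".
- **at_least** (similarity/probability): pair linked iff `v ≥ t`, e.g. an
  IBD fraction cutoff of 0.2 for *P. vivax*. Whether such cutoffs are
  strict or inclusive is rarely stated; tgkit documents them as inclusive,
  mirroring the distance convention. Values exactly at the cutoff are rare
  in continuous data, so the choice is practically inconsequential.

Clusters are the weak connected components of the thresholded graph —
single-linkage clustering by construction. Direction is ignored for
connectivity because directed probability matrices are usually produced
per-cluster after an undirected distance clustering; a cluster should not
fall apart merely because some probabilities are one-directional.

## trjson

The storage dialect is JSON with `nodes` and `edges` arrays. Design
choices where the format was genuinely open:

- Top-level keys are `nodes`, `edges`, `directed` (boolean, default
  false) and `definitions` (optional array). Readers tolerate the absence
  of the last two, so minimal documents remain valid.
- Attribute values are exactly strings, integers or floats. Booleans are
  rejected — writers must stringify them — and so are null and nested
  structures. This keeps every attribute usable by the filter language and
  the palette assignment without case analysis.
- Self-loops are rejected: a transmission link from a sample to itself is
  meaningless, and matrix conversion skips the diagonal, so a loop can
  only arise from malformed input.
- Undirected graphs cap at one edge per unordered pair; directed graphs at
  one per ordered pair (two between a node pair, one per direction).
- Serialization is canonical: nodes and edges in insertion order, object
  keys in fixed order (`id`/`source`/`target` first, then attributes
  sorted lexicographically), 2-space indentation. Identical graphs give
  byte-identical files; diffs are meaningful.
- Ids imported from tables are coerced to strings once, at import. Inside
  trjson they must already be strings; the numeric-looking string `"0042"`
  is never silently turned into `42`.

Validation is implemented directly in Python and reports *every*
violation with a rule id and a JSON-path-style location, rather than
stopping at the first; unparseable text raises a distinct parse error. A
JSON Schema document (`src/tgkit/schema/trjson.schema.json`) describes the
shape for other toolchains; the cross-object rules (id uniqueness,
endpoint resolution, pair caps, definition/value agreement) are beyond
JSON Schema and live in the validator.

## Conversion

- Undirected conversion requires symmetry within a relative tolerance of
  1e-9; larger asymmetry aborts with a hint to use directed mode, since a
  genuinely asymmetric matrix is a directed one.
- Missing cells (empty, `NA`, `NaN`) never yield edges; they are distinct
  from zero. A zero probability fails any positive `at_least` threshold,
  which is precisely how zero-imputed between-cluster entries stay
  edge-free without a special case.
- Converted edge attributes are always floats, even when integral, because
  matrix cells are parsed as floating point; this avoids an attribute's
  kind flapping between files that happen to contain round numbers.
- Metadata merges never change topology. Unmatched rows are reported, not
  fatal (tables routinely cover more samples than a subgraph); attribute
  collisions are errors unless overwrite is requested, because silently
  clobbering a value is how annotation mistakes propagate into figures.
  Merges return a `MergeOutcome` (graph + matched count + unmatched list)
  so the report is a first-class value rather than a log side effect.

## Filter language

Grammar (EBNF):

```
expr        = or_expr ;
or_expr     = and_expr , { "or" , and_expr } ;
and_expr    = not_expr , { "and" , not_expr } ;
not_expr    = "not" , not_expr | atom ;
atom        = "(" , expr , ")" | comparison ;
comparison  = NAME , OP , literal ;
OP          = "==" | "!=" | "<" | "<=" | ">" | ">=" ;
literal     = NUMBER | STRING ;
```

Implemented as a hand-written tokenizer plus recursive-descent parser —
the grammar is small enough that a parser generator would cost more than
it saves, and hand-rolling gives exact character positions in error
messages. Semantics chosen for interactive filtering:

- A comparison on a missing attribute is **false**, not an error:
  filtering heterogeneously annotated graphs must not abort on partially
  annotated nodes. Strict mode (opt-in) raises instead, naming the
  attribute and the offending node/edge.
- Equality unifies integers and floats numerically; a string never equals
  a number; string comparison is case-sensitive exact match (no patterns).
- Ordering operators require numeric literals at parse time; applied to a
  string-valued attribute at run time they yield false, keeping evaluation
  total.
- Keywords are case-insensitive, attribute names case-sensitive.

## Graph operations

All operations are pure — they return new graphs — which lets the
composition laws be tested literally: filtering with `e1` then `e2` equals
filtering with `e1 and e2`, and re-filtering a loosely thresholded graph
at a stricter cutoff equals converting the matrix at the stricter cutoff
directly. Edge filtering never drops isolated nodes implicitly
(`drop_isolated_nodes` is the explicit verb) because silent node loss
corrupts cluster-size statistics. Component indices are assigned by
decreasing size with ties broken by smallest member id, so output ordering
is reproducible across platforms and node orderings.

## Styling, layout, export

- The qualitative palette is a fixed 12-class set of paired hues shipped
  as literal hex values; attribute values get colours in sorted order
  (numbers before strings), so the assignment is independent of node
  order. At most 12 distinct values receive the scheme; beyond that every
  value falls back to one neutral grey with a warning — recycling colours
  would silently conflate categories. Individual entries can be
  overridden.
- Shapes: six (circle, square, triangle, diamond, hexagon, star),
  assigned in sorted value order; more than six distinct values is an
  error. Default shape is circle, default node colour a neutral grey, so
  style resolution is total for every rendered element.
- Layout: seeded Fruchterman–Reingold spring embedding per component
  (default seed 42, documented here), each component normalised to a unit
  box and packed onto a grid by decreasing size with padding, so component
  bounding boxes never overlap and identical (graph, seed) inputs give
  identical coordinates.
- Render export emits the element dialect of the cytoscape web renderer:
  one element per node (with `position` and resolved colour/shape/label in
  `data`) and per edge, plus the directedness flag so the renderer draws
  arrows from the source.
- Image export uses matplotlib: PNG at a requested dpi, or SVG. SVG output
  is byte-deterministic (fixed hash salt, no embedded date) so figures can
  be diffed and cached.

## Synthetic fixtures

The fixture generators emulate the *structure* of real relatedness
matrices, not their biology:

- `simulate_distance_matrix`: symmetric, zero diagonal, within-cluster
  values uniform on [0, `within_max`], between-cluster on
  [`between_min`, 2·`between_min`], with `within_max < between_min`
  enforced. Defaults used across tests (`within_max=20`,
  `between_min=100`) bracket the 50-SNP cutoff convention.
- `simulate_probability_matrix`: asymmetric, independent per-direction
  draws on (0, 1) within clusters, exact zeros between clusters and on the
  diagonal — the shape of per-cluster directed-transmission output with
  zero imputation.
- `simulate_ibd_matrix`: symmetric values in [0, 1], unit diagonal,
  planted clonal pairs on [0.9, 1.0] against a [0, 0.1] background, so the
  0.2 relatedness cutoff separates them with margin. The 54-isolate scale
  used in tests mirrors a typical monoclonal *P. vivax* panel.
- `simulate_metadata`: uniform categorical draws (e.g. region, resistance
  class) per node id.

Separation between related and unrelated ranges is **enforced, not
probabilistic**, so recovery contracts are exact and never flaky. The
flip side: these fixtures contain no boundary-straddling values, no
measurement noise, no missing data and no realistic cluster-size
distributions, so passing recovery tests demonstrates the correctness of
the thresholding/clustering machinery — not robustness of any threshold
choice on real data. All draws come from a single seeded generator per
call.

## Verification battery and problem sizes

`scripts/acceptance.py` measures, with oracles implemented independently
inside the script: the palette bound (sweeping 1–15 values), conversion
agreement with brute-force pair enumeration (100 random matrices, n
5–30, both conventions and directedness modes), planted-cluster recovery
at the 50-unit cutoff and clonal-pair recovery at the 0.2 cutoff (50
fixtures each, n 10–60), the re-thresholding consistency law (50
matrices), query-language agreement with a recursive oracle plus double
negation and De Morgan (500 expression trees of depth ≤ 3), serialization
round-trips (100 random graphs), and element-count preservation through
the full pipeline on a 60-node, 8-cluster directed fixture. These sizes
keep the whole battery under a few seconds while exercising every code
path at non-trivial scale.

## Known limitations

- Desk-scale only: graphs are held in memory, conversion is a dense
  O(n²) scan; no streaming parser for very large matrices.
- No interoperability guarantee with other tools' transmission-graph JSON
  dialects; the `directed`/`definitions` key names are this package's
  canonical choice.
- No centrality metrics, transmission-chain reconstruction, temporal
  inference, arithmetic/regex/set syntax in filters, or interactive
  viewing — batch equivalents (filters, subgraph extraction, exports)
  cover those workflows.
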