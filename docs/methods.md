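# Methods

## The display model

`goenrichview` visualizes GO term enrichment from several pairwise
differential-expression comparisons at once. It deliberately does not
aggregate terms or compute semantic similarity: every displayed data point is
one term in one analysis, and the relationship between terms is conveyed
purely by the order and indentation of their labels along user-selected
root-to-term paths. This trades compactness for comparability — the same
fixed row structure is shared by every analysis column, so a change across a
dose series is a horizontal read.

The enrichment statistics themselves are *inputs*: the package consumes the
summary tables of GOstats' hypergeometric test (per term: p-value, odds
ratio, expected and observed DEG counts, gene-set size) and never re-derives
them. Because the number of differentially expressed genes differs between
analyses, observed/expected counts are not directly comparable across
columns; the displayed quantity is therefore the fold change
`Count / ExpCount`, alongside the odds ratio.

## Ontology model and graph queries

The OBO release is parsed into three flat per-domain collections. Parent
edges are `is_a` by default; `part_of` is opt-in (`relations={"is_a",
"part_of"}`). `is_a`-only guarantees edges never leave a namespace, which
keeps the three domains disjoint DAGs; other relationship types (`regulates`
etc.) and `consider` tags are ignored with a debug log line. Obsolete terms
are kept in the index so old result files still resolve, but are stripped of
edges and excluded from displayable sets. Duplicate stanzas for one id:
last definition wins, with a warning. Acyclicity is checked at load (via
networkx) and a violation reports one concrete cycle.

Path handling follows from GO's scale (tens of thousands of terms, order
10^5–10^6 unique root-to-leaf paths): paths are built on the fly.
`enumerate_paths` is a lazy generator in lexicographic id order (stable
output, golden-file friendly) with a hard cap of 10 000 paths per term —
deep GO terms explode combinatorially, and a batch tool must bound that where
an interactive one can rely on the user. `count_paths_to` uses the exact
recurrence `N(root) = 1`, `N(t) = Σ_parents N(p)`, memoized iteratively so
deep chains cannot exhaust the Python stack.

Depth is the *longest* root-to-term path, matching the GO community's "term
level" usage. The nearest common ancestor of a term set is the set of
deepest common ancestors — a DAG can have several at equal depth, and all
are returned (sorted by id) rather than picking one arbitrarily.

## Enrichment ingestion

Tables are tab- or comma-delimited with a header; the id column is the first
matching `GO[A-Z]*ID` (GOstats names it per domain: GOBPID/GOMFID/GOCCID),
other columns matched case-insensitively. `Inf` odds ratios (a zero cell in
the 2×2 table) are stored faithfully and clamped only at render time. Rows
with unparseable numerics are rejected with row-numbered errors rather than
silently skipped.

Over- and under-representation results are combined into a single record set
per analysis: union of ids, smaller p-value wins where a term appears in
both, ties to over. The written combined-file format adds a `Direction`
column; a `concat` policy that keeps both rows is available at the file
level, and combined files lacking a direction column are read back with
direction inferred as under ⇔ odds ratio < 1. Records citing unknown ids
are collected into an unmatched report (written next to the figure by the
CLI), never dropped silently.

Significance is strict `p < α`, default α = 0.05 on raw p-values — GOstats
reports raw hypergeometric p-values and no particular correction is assumed;
Benjamini–Hochberg (statsmodels' step-up over all records of one analysis,
both directions pooled) is available as `adjust="benjamini_hochberg"`.
Fold change for under-represented terms is displayed as observed/expected
(< 1), not its reciprocal, keeping one monotone axis.

## Row assembly and node states

Every term of every selected path becomes one row; indentation is the
position within its path. Shared leading prefixes of *consecutive* paths are
emitted once; beyond that, a term on several selected paths is repeated on
purpose — which route to a term is informative is a user decision, and the
duplication preserves it. "Hide parent data" suppresses only the glyphs of
non-terminal rows; their labels remain, because the indentation structure
must stay readable. (Whether row collapsing would be preferable is left as
a documented alternative; only glyph suppression is implemented.)

Node states — has own data / only descendants have data / no data — are
computed in one reverse-topological sweep and drive tree-style summaries
(`validate` prints their counts).

Selections persist as versioned plain text (`#gotermpaths v1`, one
`>`-joined path per line), ids only and ontology-release-agnostic; loading
validates every edge against the current ontology, reports *all* stale edges
and still returns the valid subset, so a figure can be partially recreated
against a newer GO release (CLI exit code 3).

## Rendering

SVG output is a pure function of (rows, labels, axis, style): coordinates
are formatted to two decimals, there are no timestamps or generated ids, and
repeated calls are byte-identical — figure regressions are caught by
golden-file comparison. The odds-ratio axis defaults to 0–25; the
fold-change axis auto-fits to the smallest integer ≥ the largest displayed
fold. Out-of-range values clamp to the axis end and gain a small chevron
marker. Default colours (green `#2ca02c`, pink `#f7b6d2`, red `#d62728`,
grey `#9e9e9e`), glyph geometry and panel widths are package choices held in
one `StyleOptions` structure, all overridable. PNG export delegates to an
SVG rasterizer if one is importable and otherwise raises a capability error
advising SVG; raster output is checked by dimensions only, since bytes are
rasterizer-dependent.

## Synthetic data

The fixture generator emulates the two real inputs at desk scale:

* **Ontology**: `n_terms` per namespace (default 12; the demo preset uses
  15), each new term drawing 1..`max_parents` (default 2) parents uniformly
  among earlier terms of its namespace — acyclic by construction. One
  `alt_id` and one obsolete term are injected per namespace from 5 terms up.
  The generated edge list is returned alongside the OBO text as the parser
  oracle, and the OBO output is cross-checked against obonet, an independent
  reader.
* **Enrichment**: one over- and one under-table per analysis, columns and
  header exactly as GOstats' summary. Planted signal terms get
  p ~ U(10⁻⁶, 0.01) and a specified fold (observed = round(fold × expected),
  expected ~ U(1, 10)); all other terms get p ~ U(0.1, 1) and fold near 1.
  The two p ranges straddle no conventional threshold, so at α = 0.05 the
  recoverable ground truth is exact. The demo preset mirrors a two-genotype
  × two-dose design: four analyses, one planted over-represented term
  (fold 4.0) and one under-represented (fold 0.25).

p-values are *assigned*, not drawn from a hypergeometric model: the package
displays enrichment output, so the fixtures need format and range fidelity,
not statistical realism. Consequently, passing the recovery tests shows the
pipeline is faithful to its inputs — it says nothing about the power or
calibration of the upstream enrichment test, about correlated p-values on
nested GO terms, or about batch effects in real RNA-seq series.

## Verification sizes and numerical choices

The oracle suite runs 200 seeded random DAGs of 5–40 terms, comparing the
path-count recurrence and lazy enumeration against exhaustive upward DFS for
every term, and the NCA against a brute-force common-ancestor scan (50
random pairs/triples per DAG) whose depths are derived from enumerated paths
rather than the recurrence. The scale check uses a ~1500-term synthetic
domain (≈10⁵–10⁶ root-to-leaf paths depending on seed), where the memoized
recurrence answers instantly while enumeration would not. Fold × expected =
observed is exact to 1e-12; SVG coordinate placement is affine in the data
value to within the 0.01 px introduced by two-decimal formatting.

## Known limitations

* No OWL or GAF parsing, and no downloading of GO releases; the user supplies
  an OBO file.
* No semantic-similarity scores, term clustering, or term-reduction step —
  term selection is manual (or scripted via `paths`/`nca`/`search`).
* Cross-namespace relationships are dropped, so queries never span domains.
* The hard 10 000-path cap makes `paths` unusable for a handful of extremely
  deep GO terms; raise or disable it explicitly if needed.
* The per-analysis glyph panels share one axis for both odds ratio and fold
  change; with very different ranges the unlabelled quantity can compress
  (switch `--axis` to relabel/rescale).
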