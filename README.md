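# goenrichview

Compare Gene Ontology (GO) term enrichment across a *series* of differential
gene expression analyses — a time course, a dose–response design, multiple
treatment arms — in one figure.

Most GO visualization tools summarise a single enrichment analysis, often by
clustering semantically similar terms, which makes results from related
experiments hard to line up. `goenrichview` instead keeps individual terms
and their DAG relationships explicit: the figure lists the selected GO terms
on the left, indentation encoding parent→child steps along user-chosen
root-to-term paths, and draws one small glyph panel per analysis on the
right, so a physiological change can be read across columns.

It is a library first (Python API, see `examples/`) with a thin `goenrichview`
CLI on top, aimed at people who already have per-comparison enrichment
results from GOstats' `hyperGTest` (or anything emitting the same table
layout) and want to compose them into a publication figure.

## What it computes and draws

* **Ontology model.** An OBO release is parsed into three per-domain term
  collections (biological process, molecular function, cellular component)
  forming a DAG under `is_a` (and optionally `part_of`) edges. Obsolete
  terms stay resolvable but edgeless; `alt_id`s resolve to canonical terms.
* **Path queries.** Because a term may have several parents, it lies on
  several root-to-term paths. Paths are enumerated lazily in lexicographic
  order, and counted with the memoized recurrence `N(t) = 1` for roots,
  otherwise `N(t) = Σ_p N(p)` over parents — the full GO has hundreds of
  thousands of root-to-leaf paths, so they are never materialised up front.
  Nearest common ancestor of a term set = the deepest term(s) ancestral to
  all of them (depth = longest root path; all ties returned).
* **Enrichment records.** Per analysis, GOstats over- and under-
  representation tables (`GO*ID, Pvalue, OddsRatio, ExpCount, Count, Size,
  Term`) are combined into one record per term (smaller p wins; ties go to
  over). Fold change is `Count / ExpCount`; significance is strict
  `p < α` (default α = 0.05 on raw p, Benjamini–Hochberg opt-in).
* **Glyphs.** Per term and analysis: a triangle at the odds ratio (points up
  for over-representation, down for under; green when significant, pink when
  not) and a vertical bar at the fold change (red significant, grey not).
  The panel axis shows either the fold-change scale (auto-fit) or the odds
  ratio scale (0–25 by default); values beyond the axis clamp to the end
  with a small overflow chevron.
* **Deterministic SVG.** Rendering is a pure function of its inputs —
  identical calls give byte-identical files.

## Worked example

`python examples/02_compare_enrichment.py` generates the seeded synthetic
demo — a 45-term toy ontology and four pairwise analyses in a two-genotype ×
two-dose layout, with one planted over-represented term (fold 4.0) and one
planted under-represented term (fold 0.25) — then runs the full pipeline and
prints:

```
ontology: 45 terms
unmatched ids: 0
wildtype_low_dose: significant terms ['GO:0000004', 'GO:0000006']
disease_low_dose: significant terms ['GO:0000004', 'GO:0000006']
wildtype_high_dose: significant terms ['GO:0000004', 'GO:0000006']
disease_high_dose: significant terms ['GO:0000004', 'GO:0000006']
terms with own data: 14
figure: 3 rows x 4 panels -> .../comparison.svg
```

Exactly the two planted terms come out significant in every analysis (the
pipeline recovered the ground truth), 14 of the 15 biological-process terms
carry records (the obsolete one cannot), and the figure shows the 3-term
path to the over-represented term against all four analyses.

The same flow from the shell:

```
goenrichview fixtures --seed 7 --outdir demo
goenrichview paths --obo demo/ontology.obo GO:0000004   # pipes into a selection file
goenrichview render --obo demo/ontology.obo \
    --analysis wt_low=demo/wildtype_low_dose_over.tsv,demo/wildtype_low_dose_under.tsv \
    --analysis disease_low=demo/disease_low_dose_over.tsv,demo/disease_low_dose_under.tsv \
    --selection sel.txt --out figure.svg
```

`search`, `nca` and `validate` complete the command set; exit codes are
0 success, 1 data error, 2 usage error, 3 partial success (stale selection
paths are reported while the valid ones are still rendered).

## Selection files

A figure is recreated from a versioned plain-text list of paths:

```
#gotermpaths v1
#show_parent_data: false
GO:0000001>GO:0000002>GO:0000004
```

Loading validates every edge against the current ontology and reports all
stale edges while returning the valid subset.

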