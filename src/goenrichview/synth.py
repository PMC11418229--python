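"""Seeded generators for toy ontologies and matched enrichment tables.

These emulate the two inputs of a real run — a GO release in OBO format and
per-analysis GOstats hyperGTest summaries (one over- and one under-
representation table each) — at desk scale and with known ground truth, so
the whole pipeline is testable without a GO download or a sequencing
experiment.  Graphs are acyclic by construction (parents are drawn only from
earlier-created terms); p-values are assigned from disjoint significant /
non-significant ranges rather than computed from a hypergeometric model,
because the package visualizes enrichment output rather than re-deriving it.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .ontology import NAMESPACES, Ontology, parse_obo


@dataclass(frozen=True)
class SignalTerm:
    """A term planted as significantly enriched/depleted in every analysis."""

    go_id: str
    direction: str  # "over" | "under"
    fold: float  # observed/expected ratio to plant


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``n_terms`` terms are created per namespace; term *i* (beyond the root)
    draws 1..``max_parents`` parents uniformly among earlier terms of the
    same namespace, so the graph is acyclic by construction.  When
    ``n_terms >= 5`` one alt_id and one obsolete term are injected per
    namespace.  Enrichment tables cover the ``enrichment_namespace`` domain.
    """

    n_terms: int = 12
    max_parents: int = 2
    n_analyses: int = 4
    signal_terms: list[SignalTerm] = field(default_factory=list)
    seed: int = 0
    enrichment_namespace: str = "biological_process"
    labels: list[str] | None = None

    def analysis_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        return [f"analysis_{k + 1}" for k in range(self.n_analyses)]


def _term_id(counter: int) -> str:
    return f"GO:{counter:07d}"


def make_ontology(spec: FixtureSpec) -> tuple[str, list[tuple[str, str, str]]]:
    """Build OBO text plus the ground-truth (child, relation, parent) edges.

    Returned edges are the oracle for parser tests: parsing the text must
    recover exactly this edge set.  Obsolete terms contribute no edges; the
    alt_id is attached to the second term of each namespace.
    """
    if spec.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = random.Random(spec.seed)
    stanzas: list[str] = ["format-version: 1.2", ""]
    edges: list[tuple[str, str, str]] = []
    counter = 0
    alt_counter = 9_000_000
    for ns in NAMESPACES:
        ns_ids: list[str] = []
        inject_extras = spec.n_terms >= 5
        for i in range(spec.n_terms):
            counter += 1
            tid = _term_id(counter)
            obsolete = inject_extras and i == spec.n_terms - 1
            lines = [
                "[Term]",
                f"id: {tid}",
                f"name: term {tid.split(':')[1]}",
                f"namespace: {ns}",
            ]
            if inject_extras and i == 1:
                alt_counter += 1
                lines.append(f"alt_id: {_term_id(alt_counter)}")
            if obsolete:
                lines.append("is_obsolete: true")
            elif i > 0:
                n_parents = rng.randint(1, min(spec.max_parents, len(ns_ids)))
                for parent in rng.sample(ns_ids, n_parents):
                    lines.append(f"is_a: {parent}")
                    edges.append((tid, "is_a", parent))
            stanzas.extend(lines)
            stanzas.append("")
            if not obsolete:
                ns_ids.append(tid)
    return "\n".join(stanzas) + "\n", edges


GOSTATS_ID_COLUMN = {
    "biological_process": "GOBPID",
    "molecular_function": "GOMFID",
    "cellular_component": "GOCCID",
}


@dataclass
class EnrichmentGroundTruth:
    """What the generator planted, for comparison after a pipeline run."""

    signal: dict[str, SignalTerm]
    expected_counts: dict[tuple[str, str], float]  # (label, go_id) → ExpCount
    observed_counts: dict[tuple[str, str], int]


def make_enrichment(
    spec: FixtureSpec, ontology: Ontology
) -> tuple[dict[str, tuple[str, str]], EnrichmentGroundTruth]:
    """Generate per-analysis (over table, under table) GOstats-format text.

    Signal terms get p ~ U(1e-6, 0.01) and the planted fold (observed =
    round(fold × expected) with expected ~ U(1, 10)); every other displayable
    term of the namespace gets p ~ U(0.1, 1) and fold near 1, so at the
    conventional alpha = 0.05 exactly the planted terms come out significant.
    """
    rng = random.Random(spec.seed + 1)
    ns = spec.enrichment_namespace
    signal = {s.go_id: s for s in spec.signal_terms}
    for gid in signal:
        try:
            ontology.resolve(gid)
        except Exception as exc:
            raise ValueError(f"signal term {gid} not in ontology") from exc

    id_col = GOSTATS_ID_COLUMN[ns]
    header = "\t".join(
        [id_col, "Pvalue", "OddsRatio", "ExpCount", "Count", "Size", "Term"]
    )
    terms = sorted(ontology.displayable(ns), key=lambda t: t.id)
    tables: dict[str, tuple[str, str]] = {}
    truth = EnrichmentGroundTruth(signal=signal, expected_counts={},
                                  observed_counts={})
    for label in spec.analysis_labels():
        over_rows, under_rows = [], []
        for term in terms:
            sig = signal.get(term.id)
            if sig is not None:
                p = rng.uniform(1e-6, 0.01)
                expected = rng.uniform(1.0, 10.0)
                observed = round(sig.fold * expected)
                if sig.direction == "over":
                    odds = rng.uniform(2.0, 20.0)
                    bucket = over_rows
                else:
                    odds = rng.uniform(0.05, 0.5)
                    bucket = under_rows
            else:
                p = rng.uniform(0.1, 1.0)
                expected = rng.uniform(1.0, 10.0)
                observed = round(expected * rng.uniform(0.9, 1.1))
                odds = rng.uniform(0.8, 1.25)
                bucket = over_rows if odds >= 1 else under_rows
            size = observed + rng.randint(5, 50)
            bucket.append(
                "\t".join(
                    [
                        term.id,
                        f"{p:.6g}",
                        f"{odds:.4g}",
                        f"{expected:.4g}",
                        str(observed),
                        str(size),
                        term.name,
                    ]
                )
            )
            truth.expected_counts[(label, term.id)] = float(f"{expected:.4g}")
            truth.observed_counts[(label, term.id)] = observed
        tables[label] = (
            header + "\n" + "\n".join(over_rows) + "\n",
            header + "\n" + "\n".join(under_rows) + "\n",
        )
    return tables, truth


def demo_spec(seed: int = 7) -> FixtureSpec:
    """A 4-analysis preset mirroring a two-genotype × two-dose design."""
    return FixtureSpec(
        n_terms=15,
        max_parents=2,
        n_analyses=4,
        seed=seed,
        labels=[
            "wildtype_low_dose",
            "disease_low_dose",
            "wildtype_high_dose",
            "disease_high_dose",
        ],
    )


def with_default_signal(spec: FixtureSpec, ontology: Ontology) -> FixtureSpec:
    """Plant one over- and one under-represented signal term if none set."""
    if spec.signal_terms:
        return spec
    terms = sorted(
        t.id for t in ontology.displayable(spec.enrichment_namespace)
    )
    spec.signal_terms = [
        SignalTerm(terms[min(3, len(terms) - 1)], "over", 4.0),
        SignalTerm(terms[min(5, len(terms) - 1)], "under", 0.25),
    ]
    return spec


def write_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Materialise a full fixture set (OBO + tables + ground truth) on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obo_text, edges = make_ontology(spec)
    (outdir / "ontology.obo").write_text(obo_text)
    ont = parse_obo(outdir / "ontology.obo")
    with_default_signal(spec, ont)
    tables, truth = make_enrichment(spec, ont)
    for label, (over_text, under_text) in tables.items():
        (outdir / f"{label}_over.tsv").write_text(over_text)
        (outdir / f"{label}_under.tsv").write_text(under_text)
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "edges": edges,
                "signal_terms": [
                    {"go_id": s.go_id, "direction": s.direction, "fold": s.fold}
                    for s in spec.signal_terms
                ],
                "labels": spec.analysis_labels(),
            },
            indent=2,
        )
        + "\n"
    )
    return outdir
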