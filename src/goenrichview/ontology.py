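"""In-memory model of the Gene Ontology DAG.

The ontology is held as three flat per-domain collections (biological_process,
molecular_function, cellular_component) of :class:`Term` nodes carrying their
parent edges; child links are derived by inversion.  Paths through the DAG are
never materialised here — they are constructed on demand by :mod:`.dag`.

Only ``is_a`` edges are admitted as parent edges by default; ``part_of`` can be
opted in.  This guarantees parent edges never leave a namespace.  Obsolete
terms are retained (so old result files still resolve) but stripped of edges
and excluded from the displayable sets.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import networkx as nx

from .errors import OboParseError, StructuralError, UnknownTermError

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
DEFAULT_RELATIONS = frozenset({"is_a"})
SUPPORTED_RELATIONS = frozenset({"is_a", "part_of"})

GO_ID_RE = re.compile(r"GO:\d{7}$")


@dataclass
class Term:
    """One GO term node.

    ``parent_edges`` holds ``(parent_id, relation)`` pairs; ``child_ids`` is the
    derived inverse maintained by :func:`link_children`.
    """

    id: str
    name: str = ""
    namespace: str = ""
    parent_edges: set[tuple[str, str]] = field(default_factory=set)
    child_ids: set[str] = field(default_factory=set)
    alt_ids: set[str] = field(default_factory=set)
    is_obsolete: bool = False

    @property
    def parent_ids(self) -> set[str]:
        return {p for p, _ in self.parent_edges}


@dataclass
class Ontology:
    """Three per-domain term collections with id/alt-id lookup."""

    domains: dict[str, dict[str, Term]] = field(
        default_factory=lambda: {ns: {} for ns in NAMESPACES}
    )
    alt_index: dict[str, str] = field(default_factory=dict)
    edge_relations: frozenset[str] = DEFAULT_RELATIONS

    # -- lookup ---------------------------------------------------------
    def __contains__(self, go_id: str) -> bool:
        try:
            self.resolve(go_id)
        except UnknownTermError:
            return False
        return True

    def __len__(self) -> int:
        return sum(len(d) for d in self.domains.values())

    def terms(self, namespace: str | None = None) -> Iterator[Term]:
        """Iterate terms, optionally restricted to one namespace."""
        spaces = (namespace,) if namespace else NAMESPACES
        for ns in spaces:
            yield from self.domains[ns].values()

    def get(self, go_id: str) -> Term | None:
        for d in self.domains.values():
            t = d.get(go_id)
            if t is not None:
                return t
        return None

    def resolve(self, go_id: str) -> Term:
        """Return the canonical term for a primary or alternative id.

        Raises :class:`UnknownTermError` when the id resolves nowhere.
        """
        t = self.get(go_id)
        if t is None and go_id in self.alt_index:
            t = self.get(self.alt_index[go_id])
        if t is None:
            raise UnknownTermError(go_id)
        return t

    @property
    def roots(self) -> dict[str, set[str]]:
        """Non-obsolete ids with no parent edges, per namespace."""
        return {
            ns: {
                t.id
                for t in d.values()
                if not t.parent_edges and not t.is_obsolete
            }
            for ns, d in self.domains.items()
        }

    def displayable(self, namespace: str | None = None) -> Iterator[Term]:
        """Non-obsolete terms (obsolete ones are index-only)."""
        return (t for t in self.terms(namespace) if not t.is_obsolete)

    # -- serialization --------------------------------------------------
    def to_obo(self) -> str:
        """Serialize back to OBO flat text (round-trip aid for testing)."""
        out = ["format-version: 1.2", ""]
        for ns in NAMESPACES:
            for tid in sorted(self.domains[ns]):
                t = self.domains[ns][tid]
                out.append("[Term]")
                out.append(f"id: {t.id}")
                out.append(f"name: {t.name}")
                out.append(f"namespace: {t.namespace}")
                for alt in sorted(t.alt_ids):
                    out.append(f"alt_id: {alt}")
                for parent, rel in sorted(t.parent_edges):
                    if rel == "is_a":
                        out.append(f"is_a: {parent}")
                    else:
                        out.append(f"relationship: {rel} {parent}")
                if t.is_obsolete:
                    out.append("is_obsolete: true")
                out.append("")
        return "\n".join(out) + "\n"


def _open_stream(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def parse_obo(
    source: str | Path | IO[str],
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Parameters
    ----------
    source:
        Path (``.gz`` accepted) or open text stream.
    relations:
        Relationship tags admitted as parent edges, a subset of
        ``{"is_a", "part_of"}``.  ``is_a`` always creates an edge;
        ``relationship: part_of`` only when opted in.

    Raises
    ------
    OboParseError
        Missing id/namespace, bad id syntax, or unknown namespace —
        the message names the offending line.
    StructuralError
        A cycle among parent edges; the message lists one cycle.
    """
    relations = frozenset(relations)
    if not relations <= SUPPORTED_RELATIONS:
        raise ValueError(
            f"unsupported relations: {sorted(relations - SUPPORTED_RELATIONS)}"
        )

    stream = _open_stream(source)
    ont = Ontology(edge_relations=relations)

    stanza: dict | None = None
    stanza_line = 0
    in_term = False

    def flush(end_line: int) -> None:
        nonlocal stanza
        if stanza is None:
            return
        _ingest_stanza(ont, stanza, stanza_line)
        stanza = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("!", 1)[0].strip() if not raw.startswith("!") else ""
        if raw.strip().startswith("["):
            flush(lineno)
            header = raw.strip()
            in_term = header == "[Term]"
            if in_term:
                stanza = {
                    "id": None,
                    "name": "",
                    "namespace": None,
                    "parents": [],
                    "alt_ids": [],
                    "obsolete": False,
                }
                stanza_line = lineno
            continue
        if not in_term or stanza is None or not line:
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            if not GO_ID_RE.match(value):
                raise OboParseError(f"malformed term id {value!r}", lineno)
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "namespace":
            if value not in NAMESPACES:
                raise OboParseError(f"unknown namespace {value!r}", lineno)
            stanza["namespace"] = value
        elif tag == "is_a":
            stanza["parents"].append((value, "is_a", lineno))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) >= 2:
                rel, target = parts[0], parts[1]
                if rel in relations:
                    stanza["parents"].append((target, rel, lineno))
                else:
                    logger.debug(
                        "line %d: ignoring relationship %r (not admitted)",
                        lineno,
                        rel,
                    )
        elif tag == "alt_id":
            stanza["alt_ids"].append(value)
        elif tag == "is_obsolete":
            stanza["obsolete"] = value.lower() == "true"
        elif tag == "consider":
            logger.debug("line %d: ignoring consider tag", lineno)
        # all other tags (def, synonym, xref, ...) are not retained

    flush(-1)
    _finalize(ont)
    return ont


def _ingest_stanza(ont: Ontology, stanza: dict, line: int) -> None:
    if stanza["id"] is None:
        raise OboParseError("[Term] stanza missing id", line)
    if stanza["namespace"] is None:
        raise OboParseError(
            f"[Term] stanza for {stanza['id']} missing namespace", line
        )
    tid = stanza["id"]
    ns = stanza["namespace"]
    term = Term(id=tid, name=stanza["name"], namespace=ns)
    term.alt_ids = set(stanza["alt_ids"])
    term.is_obsolete = stanza["obsolete"]
    if term.is_obsolete:
        if stanza["parents"]:
            logger.warning(
                "obsolete term %s: dropping %d parent edge(s)",
                tid,
                len(stanza["parents"]),
            )
    else:
        term.parent_edges = {(p, rel) for p, rel, _ in stanza["parents"]}

    # duplicate stanza for one id: last wins, with a warning
    existing = ont.get(tid)
    if existing is not None:
        logger.warning("duplicate stanza for %s: last definition wins", tid)
        del ont.domains[existing.namespace][tid]
    ont.domains[ns][tid] = term
    for alt in term.alt_ids:
        ont.alt_index[alt] = tid


def _finalize(ont: Ontology) -> None:
    """Prune dangling/cross-namespace edges, derive children, check acyclicity."""
    for ns in NAMESPACES:
        col = ont.domains[ns]
        for term in col.values():
            kept = set()
            for parent, rel in term.parent_edges:
                ptarget = col.get(parent)
                if ptarget is None or ptarget.is_obsolete:
                    where = ont.get(parent)
                    if where is not None and where.namespace != ns:
                        logger.debug(
                            "dropping cross-namespace edge %s -%s-> %s",
                            term.id,
                            rel,
                            parent,
                        )
                    else:
                        logger.warning(
                            "dropping edge %s -%s-> %s: parent not loadable",
                            term.id,
                            rel,
                            parent,
                        )
                    continue
                kept.add((parent, rel))
            term.parent_edges = kept
    link_children(ont)
    check_acyclic(ont)


def link_children(ont: Ontology) -> Ontology:
    """(Re)derive ``child_ids`` as the exact inverse of ``parent_edges``.

    Pure and idempotent; safe to call repeatedly.
    """
    for term in ont.terms():
        term.child_ids = set()
    for term in ont.terms():
        for parent, _ in term.parent_edges:
            ont.get(parent).child_ids.add(term.id)
    return ont


def check_acyclic(ont: Ontology) -> None:
    """Raise :class:`StructuralError` listing one cycle if the DAG is cyclic."""
    g = to_networkx(ont)
    if nx.is_directed_acyclic_graph(g):
        return
    cycle = nx.find_cycle(g)
    path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
    raise StructuralError(f"cycle among parent edges: {path}")


def to_networkx(ont: Ontology, namespace: str | None = None) -> "nx.DiGraph":
    """Parent→child digraph of the non-obsolete terms (graph-library bridge)."""
    g = nx.DiGraph()
    for term in ont.displayable(namespace):
        g.add_node(term.id)
        for parent, _ in term.parent_edges:
            g.add_edge(parent, term.id)
    return g


def resolve(ont: Ontology, go_id: str) -> Term:
    """Module-level alias for :meth:`Ontology.resolve`."""
    return ont.resolve(go_id)
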