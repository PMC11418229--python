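"""From path selection + attached enrichment data to ordered display rows.

The figure is an indented list: each selected root→term path contributes one
row per term, indent growing by one per step; shared leading prefixes of
consecutive paths are emitted once.  A term sitting on several selected paths
is deliberately shown once per path — in a DAG the same term occurs in many
places, and which path is shown is the user's scientific choice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .dag import TermPath
from .enrichment import AnnotationIndex, EnrichmentRecord, fold_change
from .errors import (
    SelectionVersionError,
    StaleSelectionError,
    UndefinedFoldError,
)
from .ontology import Ontology

SELECTION_HEADER = "#gotermpaths v1"


class NodeState(enum.Enum):
    """Tree-node annotation state (green disc / green circle / pink disc)."""

    HAS_DATA = "has_data"
    DESCENDANT_HAS_DATA = "descendant_has_data"
    NO_DATA = "no_data"


@dataclass
class Selection:
    """An ordered list of root→term paths plus display toggles."""

    paths: list[TermPath] = field(default_factory=list)
    show_parent_data: bool = True


@dataclass
class DisplayRow:
    """One term at one indentation depth, with its per-analysis glyph inputs.

    ``per_analysis`` entries are ``(record | None, significant, fold | None)``
    in analysis label order; an empty list means glyphs are suppressed for
    this row (parent data hidden).
    """

    go_id: str
    label: str
    indent: int
    per_analysis: list[tuple[EnrichmentRecord | None, bool, float | None]] = field(
        default_factory=list
    )
    is_terminal: bool = False


def node_states(ont: Ontology, index: AnnotationIndex) -> dict[str, NodeState]:
    """Classify every non-obsolete term in one reverse-topological sweep.

    HAS_DATA dominates; DESCENDANT_HAS_DATA marks data-free terms with at
    least one annotated descendant; the rest are NO_DATA (hidden by default
    in a tree browser, shown pink if displayed).
    """
    has_own = {
        gid for gid, slots in index.records.items() if any(s is not None for s in slots)
    }
    states: dict[str, NodeState] = {}
    terms = [t for t in ont.displayable()]
    # Kahn order over child edges, processed in reverse (children first)
    order: list[str] = []
    remaining = {t.id: len(t.parent_ids) for t in terms}
    queue = sorted(tid for tid, n in remaining.items() if n == 0)
    ids = set(remaining)
    while queue:
        tid = queue.pop()
        order.append(tid)
        for child in ont.resolve(tid).child_ids & ids:
            remaining[child] -= 1
            if remaining[child] == 0:
                queue.append(child)
    desc_has: dict[str, bool] = {}
    for tid in reversed(order):
        term = ont.resolve(tid)
        desc_has[tid] = any(
            c in has_own or desc_has.get(c, False)
            for c in term.child_ids & ids
        )
        if tid in has_own:
            states[tid] = NodeState.HAS_DATA
        elif desc_has[tid]:
            states[tid] = NodeState.DESCENDANT_HAS_DATA
        else:
            states[tid] = NodeState.NO_DATA
    return states


def _validate_path(ont: Ontology, path: TermPath) -> list[str]:
    """Return the broken steps of a path as "PARENT>CHILD" strings."""
    bad: list[str] = []
    for a, b in zip(path, path[1:]):
        try:
            child = ont.resolve(b)
            ont.resolve(a)
        except Exception:
            bad.append(f"{a}>{b}")
            continue
        if a not in child.parent_ids:
            bad.append(f"{a}>{b}")
    if not bad and path:
        try:
            first = ont.resolve(path[0])
            if first.parent_ids:
                bad.append(f"(root)>{path[0]}")
        except Exception:
            bad.append(f"(root)>{path[0]}")
    return bad


def assemble_rows(
    selection: Selection,
    ont: Ontology,
    index: AnnotationIndex,
) -> list[DisplayRow]:
    """Expand the selected paths into the ordered, indented row list.

    Consecutive paths sharing a leading prefix emit the shared terms once.
    With ``show_parent_data`` off, non-terminal rows keep their labels but
    carry no glyph data.
    """
    aset = index.analysis_set
    sig_maps = (
        {label: aset.significance(label) for label in aset.labels}
        if aset is not None
        else {label: {} for label in index.labels}
    )

    rows: list[DisplayRow] = []
    prev: TermPath = ()
    for path in selection.paths:
        bad = _validate_path(ont, path)
        if bad:
            raise StaleSelectionError(bad)
        shared = 0
        while (
            shared < len(prev)
            and shared < len(path) - 1  # the terminal term is always emitted
            and prev[shared] == path[shared]
        ):
            shared += 1
        for i in range(shared, len(path)):
            gid = path[i]
            term = ont.resolve(gid)
            terminal = i == len(path) - 1
            if selection.show_parent_data or terminal:
                per = _per_analysis(gid, index, sig_maps)
            else:
                per = []
            rows.append(
                DisplayRow(
                    go_id=gid,
                    label=term.name or gid,
                    indent=i,
                    per_analysis=per,
                    is_terminal=terminal,
                )
            )
        prev = path
    return rows


def _per_analysis(gid, index: AnnotationIndex, sig_maps):
    out = []
    for label, rec in zip(index.labels, index.per_analysis(gid)):
        if rec is None:
            out.append((None, False, None))
            continue
        sig = sig_maps.get(label, {}).get(rec.go_id, False)
        try:
            fc = fold_change(rec)
        except UndefinedFoldError:
            fc = None
        out.append((rec, sig, fc))
    return out


def save_selection(selection: Selection, dest: str | Path | IO[str]) -> None:
    """Write the versioned plain-text path file (ids joined by ``>``)."""
    lines = [SELECTION_HEADER]
    if not selection.show_parent_data:
        lines.append("#show_parent_data: false")
    for path in selection.paths:
        lines.append(">".join(path))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def load_selection(source: str | Path | IO[str], ont: Ontology) -> Selection:
    """Read and validate a saved selection against the current ontology.

    Every edge of every path is checked; if any path is stale a
    :class:`StaleSelectionError` is raised carrying ALL failures plus the
    still-valid subset (``exc.selection``) so callers can proceed partially.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != SELECTION_HEADER:
        raise SelectionVersionError(
            f"expected header {SELECTION_HEADER!r}, got "
            f"{lines[0].strip() if lines else '<empty file>'!r}"
        )
    show_parent = True
    paths: list[TermPath] = []
    failures: list[str] = []
    for line in lines[1:]:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#show_parent_data:"):
            show_parent = line.split(":", 1)[1].strip().lower() == "true"
            continue
        if line.startswith("#"):
            continue
        path = tuple(p.strip() for p in line.split(">") if p.strip())
        bad = _validate_path(ont, path)
        if bad:
            failures.extend(bad)
        else:
            paths.append(path)
    selection = Selection(paths=paths, show_parent_data=show_parent)
    if failures:
        raise StaleSelectionError(failures, selection=selection)
    return selection
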