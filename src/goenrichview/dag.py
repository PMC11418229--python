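"""Graph queries over the ontology DAG.

Root-to-term paths are constructed on the fly: the full GO has hundreds of
thousands of unique root-to-leaf paths, so enumeration is lazy (a generator in
lexicographic id order) with a hard cap, while counting uses the memoized
recurrence N(t) = 1 for roots, else sum of N(parent) over parents.
"""

from __future__ import annotations

from typing import Iterator, Sequence

from .errors import DomainMixingError, PathExplosionError
from .ontology import Ontology, Term

DEFAULT_MAX_PATHS = 10_000

TermPath = tuple[str, ...]
"""Ordered root→target id sequence along parent→child edges."""


def _canonical(ont: Ontology, go_id: str) -> Term:
    return ont.resolve(go_id)


def ancestors(ont: Ontology, go_id: str) -> set[str]:
    """All ids reachable by following parent edges; excludes the term itself."""
    start = _canonical(ont, go_id)
    seen: set[str] = set()
    stack = [p for p in start.parent_ids]
    while stack:
        pid = stack.pop()
        if pid in seen:
            continue
        seen.add(pid)
        stack.extend(ont.resolve(pid).parent_ids)
    return seen


def descendants(ont: Ontology, go_id: str) -> set[str]:
    """Transitive closure of child_ids; excludes the term itself."""
    start = _canonical(ont, go_id)
    seen: set[str] = set()
    stack = list(start.child_ids)
    while stack:
        cid = stack.pop()
        if cid in seen:
            continue
        seen.add(cid)
        stack.extend(ont.resolve(cid).child_ids)
    return seen


def depth(ont: Ontology, go_id: str) -> int:
    """Length in edges of the LONGEST root→term path (GO "term level")."""
    target = _canonical(ont, go_id)
    memo: dict[str, int] = {}
    # iterative post-order so deep synthetic chains cannot blow the stack
    stack: list[tuple[str, bool]] = [(target.id, False)]
    while stack:
        tid, ready = stack.pop()
        if tid in memo:
            continue
        parents = ont.resolve(tid).parent_ids
        if ready or not parents:
            memo[tid] = max((memo[p] for p in parents), default=-1) + 1
        else:
            stack.append((tid, True))
            stack.extend((p, False) for p in parents if p not in memo)
    return memo[target.id]


def enumerate_paths(
    ont: Ontology,
    target: str,
    max_paths: int | None = DEFAULT_MAX_PATHS,
) -> Iterator[TermPath]:
    """Yield every distinct root→target path exactly once.

    Paths are produced in lexicographic order over their id sequences; the
    generator is lazy, so callers may take the first *k* without materialising
    the rest.  Raises :class:`PathExplosionError` beyond ``max_paths``
    (``None`` disables the cap).
    """
    t = _canonical(ont, target)
    allowed = ancestors(ont, t.id)
    allowed.add(t.id)

    ns = t.namespace
    start_roots = sorted(ont.roots[ns] & allowed)

    emitted = 0

    def walk(tid: str, prefix: list[str]) -> Iterator[TermPath]:
        nonlocal emitted
        prefix.append(tid)
        if tid == t.id:
            emitted += 1
            if max_paths is not None and emitted > max_paths:
                raise PathExplosionError(
                    f"more than {max_paths} root-to-term paths for {t.id}"
                )
            yield tuple(prefix)
        else:
            for child in sorted(ont.resolve(tid).child_ids & allowed):
                yield from walk(child, prefix)
        prefix.pop()

    for root in start_roots:
        yield from walk(root, [])


def count_paths_to(ont: Ontology, target: str) -> int:
    """Number of distinct root→target paths, by the memoized parent recurrence."""
    t = _canonical(ont, target)
    memo: dict[str, int] = {}
    stack: list[tuple[str, bool]] = [(t.id, False)]
    while stack:
        tid, ready = stack.pop()
        if tid in memo:
            continue
        parents = ont.resolve(tid).parent_ids
        if not parents:
            memo[tid] = 1
        elif ready:
            memo[tid] = sum(memo[p] for p in parents)
        else:
            stack.append((tid, True))
            stack.extend((p, False) for p in parents if p not in memo)
    return memo[t.id]


def count_leaf_paths(ont: Ontology, namespace: str) -> int:
    """Total root→leaf paths in one domain (leaf = childless, non-obsolete)."""
    total = 0
    for term in ont.displayable(namespace):
        if not term.child_ids:
            total += count_paths_to(ont, term.id)
    return total


def nearest_common_ancestor(ont: Ontology, ids: Sequence[str]) -> list[str]:
    """All deepest common ancestors of ``ids``, sorted by id.

    A DAG can have several equally-deep common ancestors; all are returned.
    A singleton query returns the term itself.
    """
    if not ids:
        raise ValueError("nearest_common_ancestor requires at least one id")
    terms = [_canonical(ont, i) for i in ids]
    spaces = {t.namespace for t in terms}
    if len(spaces) > 1:
        raise DomainMixingError(
            f"ids span namespaces: {sorted(spaces)}"
        )
    candidates: set[str] | None = None
    for t in terms:
        own = ancestors(ont, t.id) | {t.id}
        candidates = own if candidates is None else candidates & own
    assert candidates is not None
    if not candidates:
        return []
    best = max(depth(ont, c) for c in candidates)
    return sorted(c for c in candidates if depth(ont, c) == best)


def search_terms(ont: Ontology, query: str) -> list[str]:
    """Find term ids by exact id (incl. alt ids) or name substring.

    An id hit returns just the canonical id; otherwise a case-insensitive
    substring match on names, sorted by (name length, id).  Empty result is
    a valid answer.
    """
    try:
        return [ont.resolve(query).id]
    except Exception:
        pass
    q = query.lower()
    hits = [
        t
        for t in ont.displayable()
        if q in t.name.lower()
    ]
    hits.sort(key=lambda t: (len(t.name), t.id))
    return [t.id for t in hits]
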