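"""Brute-force oracles, deliberately independent of the library's algorithms.

Paths are enumerated by walking UP parent edges from the target (the library
walks down from the roots); depth and NCA are derived from those enumerated
paths rather than from memoized recurrences.
"""

from __future__ import annotations


def brute_paths(ont, target: str) -> set[tuple[str, ...]]:
    """All root→target paths by exhaustive upward DFS."""
    out: set[tuple[str, ...]] = set()

    def up(tid, suffix):
        term = ont.resolve(tid)
        parents = term.parent_ids
        if not parents:
            out.add((tid, *suffix))
            return
        for p in parents:
            up(p, (tid, *suffix))

    up(ont.resolve(target).id, ())
    return out


def brute_depth(ont, tid: str) -> int:
    return max(len(p) - 1 for p in brute_paths(ont, tid))


def brute_common_ancestors(ont, ids) -> set[str]:
    common = None
    for gid in ids:
        anc = {p for path in brute_paths(ont, gid) for p in path}
        common = anc if common is None else common & anc
    return common or set()


def brute_nca(ont, ids) -> list[str]:
    common = brute_common_ancestors(ont, ids)
    if not common:
        return []
    best = max(brute_depth(ont, c) for c in common)
    return sorted(c for c in common if brute_depth(ont, c) == best)
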