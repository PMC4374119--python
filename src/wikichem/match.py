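"""Subgraph-isomorphism confirmation for the two-step substructure search.

Backtracking search in the VF2 spirit: query atoms are ordered so that the
rarest elements (relative to the target) are placed first and subsequent
atoms stay connected to the partial mapping, which prunes hard on typical
chemical graphs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .molgraph import Bond, MolecularGraph

__all__ = ["MatchOptions", "is_substructure", "count_matches"]


@dataclass(frozen=True)
class MatchOptions:
    """aromatic_strict: an aromatic query bond only matches an aromatic
    target bond (and kekule only kekule); charge_strict: formal charges must
    be equal."""

    aromatic_strict: bool = True
    charge_strict: bool = True


DEFAULT_OPTIONS = MatchOptions()


def _atom_compatible(q, t, q_graph, t_graph, qi, ti, opts: MatchOptions) -> bool:
    if q.element != t.element:
        return False
    if opts.aromatic_strict and q.aromatic != t.aromatic:
        return False
    if opts.charge_strict and q.charge != t.charge:
        return False
    # bracket-origin query atoms impose a minimum-H constraint
    if q.explicit_h is not None and t_graph.hydrogens(ti) < q.explicit_h:
        return False
    if q_graph.degree(qi) > t_graph.degree(ti):
        return False
    return True


def _bond_compatible(qb: Bond, tb: Bond, opts: MatchOptions) -> bool:
    if opts.aromatic_strict:
        if qb.aromatic != tb.aromatic:
            return False
        return True if qb.aromatic else qb.order == tb.order
    if qb.aromatic or tb.aromatic:
        # relaxed: aromatic matches aromatic or a kekule single/double
        return qb.order in (1, 2) and tb.order in (1, 2)
    return qb.order == tb.order


def _query_order(query: MolecularGraph, target: MolecularGraph) -> list[int]:
    """Connected ordering of query atoms, rarest element (in the target)
    first."""
    target_counts = Counter(a.element for a in target.atoms)
    rarity = {i: target_counts.get(a.element, 0) for i, a in enumerate(query.atoms)}
    n = len(query.atoms)
    order: list[int] = []
    placed: set[int] = set()
    while len(order) < n:
        frontier = {
            nb for i in placed for nb in query.neighbors(i) if nb not in placed
        }
        pool = frontier if frontier else set(range(n)) - placed
        nxt = min(pool, key=lambda i: (rarity[i], -query.degree(i), i))
        order.append(nxt)
        placed.add(nxt)
    return order


def _match_iter(query: MolecularGraph, target: MolecularGraph, opts: MatchOptions):
    """Yield complete injective mappings query-atom-index -> target-atom-index."""
    nq, nt = len(query.atoms), len(target.atoms)
    if nq > nt or len(query.bonds) > len(target.bonds):
        return
    order = _query_order(query, target)
    mapping: dict[int, int] = {}
    used: set[int] = set()

    def candidates(qi: int):
        mapped_nbs = [nb for nb in query.neighbors(qi) if nb in mapping]
        if mapped_nbs:
            anchor = mapped_nbs[0]
            return target.neighbors(mapping[anchor])
        return range(nt)

    def rec(depth: int):
        if depth == len(order):
            yield dict(mapping)
            return
        qi = order[depth]
        q_atom = query.atoms[qi]
        for ti in candidates(qi):
            if ti in used:
                continue
            if not _atom_compatible(q_atom, target.atoms[ti], query, target, qi, ti, opts):
                continue
            ok = True
            for nb in query.neighbors(qi):
                if nb in mapping:
                    qb = query.bond_between(qi, nb)
                    tb = target.bond_between(ti, mapping[nb])
                    if tb is None or not _bond_compatible(qb, tb, opts):
                        ok = False
                        break
            if not ok:
                continue
            mapping[qi] = ti
            used.add(ti)
            yield from rec(depth + 1)
            del mapping[qi]
            used.remove(ti)

    yield from rec(0)


def is_substructure(
    query: MolecularGraph,
    target: MolecularGraph,
    opts: MatchOptions = DEFAULT_OPTIONS,
) -> bool:
    """True iff the query graph embeds injectively into the target preserving
    elements, aromatic flags, charges (per options) and bond compatibility."""
    for _ in _match_iter(query, target, opts):
        return True
    return False


def count_matches(
    query: MolecularGraph,
    target: MolecularGraph,
    opts: MatchOptions = DEFAULT_OPTIONS,
    *,
    limit: int | None = None,
) -> int:
    """Number of distinct target atom subsets onto which the query maps.

    ``limit`` allows early exit once that many distinct images were seen
    (used by threshold fingerprint bits); the returned count is then
    ``min(true count, limit)``.
    """
    images: set[frozenset[int]] = set()
    for mapping in _match_iter(query, target, opts):
        images.add(frozenset(mapping.values()))
        if limit is not None and len(images) >= limit:
            break
    return len(images)
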