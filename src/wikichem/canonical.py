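"""Canonical atom ranking and canonical SMILES generation.

Ranks come from Morgan-style iterative refinement of a per-atom invariant,
with deterministic tie-breaking; the canonical string is then produced by a
rank-driven depth-first write.  Canonical strings are the identity used by
the exact-match search mode and by duplicate detection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .molgraph import MolecularGraph, parse_smiles, write_smiles

__all__ = ["CanonicalForm", "canonical_ranks", "canonical_smiles", "same_structure"]


@dataclass(frozen=True)
class CanonicalForm:
    canonical_smiles: str
    stereo_stripped_smiles: str
    has_stereo: bool


def _smallest_ring_size(graph: MolecularGraph, atom: int) -> int:
    """Size of the smallest ring through *atom*; 0 when acyclic."""
    best = 0
    for bi in graph.adjacency()[atom]:
        bond = graph.bonds[bi]
        other = bond.other(atom)
        # shortest path atom -> other avoiding this bond
        dist = {atom: 0}
        dq = deque([atom])
        found = -1
        while dq:
            cur = dq.popleft()
            if cur == other:
                found = dist[cur]
                break
            for bj in graph.adjacency()[cur]:
                if bj == bi:
                    continue
                nb = graph.bonds[bj].other(cur)
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    dq.append(nb)
        if found >= 0:
            size = found + 1
            if best == 0 or size < best:
                best = size
    return best


def _initial_invariants(graph: MolecularGraph) -> list[tuple]:
    return [
        (
            atom.element,
            atom.charge,
            atom.isotope or 0,
            graph.degree(i),
            graph.hydrogens(i),
            atom.aromatic,
            _smallest_ring_size(graph, i),
        )
        for i, atom in enumerate(graph.atoms)
    ]


def _refine(graph: MolecularGraph, ranks: list[int]) -> list[int]:
    n = len(graph.atoms)
    while True:
        keys = [
            (ranks[i], tuple(sorted(ranks[nb] for nb in graph.neighbors(i))))
            for i in range(n)
        ]
        new_ranks = _dense_ranks(keys)
        if new_ranks == ranks:
            return ranks
        ranks = new_ranks


def _dense_ranks(keys: list) -> list[int]:
    order = sorted(set(keys))
    lookup = {k: r for r, k in enumerate(order)}
    return [lookup[k] for k in keys]


def canonical_ranks(graph: MolecularGraph) -> list[int]:
    """A permutation of 0..n-1, invariant under atom relabeling.

    Iterative refinement from the initial invariant; remaining ties are broken
    by doubling all ranks and promoting the lowest-index member of the first
    tied class, then refining again, until all ranks are distinct.
    """
    n = len(graph.atoms)
    ranks = _dense_ranks(_initial_invariants(graph))
    ranks = _refine(graph, ranks)
    while len(set(ranks)) < n:
        counts: dict[int, list[int]] = {}
        for i, r in enumerate(ranks):
            counts.setdefault(r, []).append(i)
        tied_rank = min(r for r, members in counts.items() if len(members) > 1)
        chosen = min(counts[tied_rank])
        ranks = [r * 2 for r in ranks]
        ranks[chosen] -= 1
        ranks = _refine(graph, _dense_ranks(ranks))
    return _dense_ranks(ranks)


def canonical_smiles(graph: MolecularGraph) -> CanonicalForm:
    """Canonical SMILES (stereo-aware) plus the stereo-stripped variant."""
    ranks = canonical_ranks(graph)
    full = write_smiles(graph, priority=ranks, include_stereo=True)
    has_stereo = full != write_smiles(graph, priority=ranks, include_stereo=False)
    stripped = full
    if has_stereo:
        # strip by re-parsing the stereo-free write so ranks are recomputed
        # on the achiral graph (stereo feeds nothing into ranking, but the
        # round-trip keeps the two surfaces guaranteed-consistent)
        bare = write_smiles(graph, priority=ranks, include_stereo=False)
        g2 = parse_smiles(bare)
        assert isinstance(g2, MolecularGraph), bare
        stripped = write_smiles(g2, priority=canonical_ranks(g2), include_stereo=False)
    return CanonicalForm(full, stripped, has_stereo)


def same_structure(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Stereo-aware identity: equal canonical SMILES strings."""
    return canonical_smiles(a).canonical_smiles == canonical_smiles(b).canonical_smiles
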