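"""Murcko-style scaffolds (ring systems + linkers, exocyclic multiply-bonded
atoms retained) and scaffold frequency reporting over a structure index."""

from __future__ import annotations

from dataclasses import dataclass

from .canonical import canonical_smiles
from .elements import ALLOWED_VALENCES
from .molgraph import Atom, Bond, MolecularGraph, default_valence, parse_smiles
from .search import StructureIndex

__all__ = ["ScaffoldReport", "murcko_scaffold", "scaffold_smiles", "top_scaffolds"]


def _subgraph(graph: MolecularGraph, keep: set[int]) -> MolecularGraph:
    """Induced subgraph with hydrogens refilled to valence; stereo descriptors
    are dropped (they may reference removed atoms)."""
    remap = {old: new for new, old in enumerate(sorted(keep))}
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    for old in sorted(keep):
        src = graph.atoms[old]
        atoms.append(
            Atom(
                element=src.element,
                isotope=src.isotope,
                charge=src.charge,
                explicit_h=src.explicit_h,
                aromatic=src.aromatic,
            )
        )
    for bond in graph.bonds:
        if bond.a in keep and bond.b in keep:
            bonds.append(
                Bond(remap[bond.a], remap[bond.b], order=bond.order, aromatic=bond.aromatic)
            )
    sub = MolecularGraph(atoms=atoms, bonds=bonds)
    implicit: list[int] = []
    for new, old in enumerate(sorted(keep)):
        atom = sub.atoms[new]
        bond_sum = sum(sub.bonds[bi].order for bi in sub.adjacency()[new])
        if atom.explicit_h is None and atom.element in ALLOWED_VALENCES:
            v = default_valence(atom.element, bond_sum)
            implicit.append(max(0, (v or bond_sum) - bond_sum))
        elif atom.explicit_h is not None:
            # bracket atom: grow the H count by whatever bond order was cut
            old_sum = sum(graph.bonds[bi].order for bi in graph.adjacency()[old])
            implicit.append(atom.explicit_h + (old_sum - bond_sum))
            atom.explicit_h = implicit[-1]
        else:
            implicit.append(0)
    sub.implicit_h = implicit
    return sub


def murcko_scaffold(mol: MolecularGraph) -> MolecularGraph | None:
    """Ring systems plus the linkers connecting them; atoms double- or
    triple-bonded to a kept atom are retained.  None for acyclic input."""
    ring_atoms = mol.ring_atoms()
    if not ring_atoms:
        return None
    keep = set(range(len(mol.atoms)))
    # phase 1: strip side chains down to rings + linkers
    changed = True
    while changed:
        changed = False
        for i in sorted(keep):
            if i in ring_atoms:
                continue
            degree = sum(1 for nb in mol.neighbors(i) if nb in keep)
            if degree <= 1:
                keep.discard(i)
                changed = True
    # phase 2: re-attach atoms directly multiply-bonded to the framework
    # (single pass: chained cumulene-like extensions stay side chains)
    core = set(keep)
    for bond in mol.bonds:
        if bond.order >= 2 and not bond.aromatic:
            for x, y in ((bond.a, bond.b), (bond.b, bond.a)):
                if x in core and y not in core:
                    keep.add(y)
    return _subgraph(mol, keep)


def scaffold_smiles(mol: MolecularGraph) -> str | None:
    scaffold = murcko_scaffold(mol)
    if scaffold is None:
        return None
    return canonical_smiles(scaffold).canonical_smiles


@dataclass
class ScaffoldReport:
    rows: list[tuple[str, int]]  # (canonical scaffold SMILES, count), desc
    covered: int  # molecules whose scaffold made the list


def top_scaffolds(index: StructureIndex, n: int) -> ScaffoldReport:
    """Count records per canonical scaffold (acyclic records contribute to
    none) and keep the n most common; ties break on the scaffold string."""
    counts: dict[str, int] = {}
    for rec in index.records:
        graph = parse_smiles(rec.structure)
        assert isinstance(graph, MolecularGraph), rec.structure
        smiles = scaffold_smiles(graph)
        if smiles is not None:
            counts[smiles] = counts.get(smiles, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[: max(n, 0)]
    return ScaffoldReport(rows=rows, covered=sum(c for _, c in rows))
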