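"""Deterministic synthetic fixtures: random valence-respecting molecules,
randomized SMILES rewrites, random connected subgraph queries, and a
synthetic wiki-page corpus that exhibits every behavior the extraction
pipeline must handle (multi-SMILES pages, stereo pairs, missing SMILES, each
error class, cross-page duplicates) together with a ground-truth manifest.

One integer seed drives a single ``random.Random`` stream, so every fixture
is regenerable byte-identically.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .canonical import canonical_smiles
from .molgraph import (
    Atom,
    Bond,
    ErrorClass,
    MolecularGraph,
    ParseIssue,
    kekulize,
    parse_smiles,
    write_smiles,
)
from .wikiparse import WikiPage

__all__ = [
    "GenConfig",
    "random_molecule",
    "permuted_smiles",
    "random_connected_subgraph",
    "induced_subgraph",
    "synth_wiki_corpus",
    "CorpusManifest",
]

_GROW_ELEMENTS = [
    ("C", 4), ("C", 4), ("C", 4), ("C", 4), ("C", 4),
    ("N", 3), ("N", 3), ("O", 2), ("O", 2), ("S", 2),
    ("F", 1), ("Cl", 1), ("Br", 1), ("I", 1),
]

# aromatic ring templates: (SMILES-free description) element, aromatic,
# explicit H for bracket atoms; bonds close the cycle
_AROMATIC_TEMPLATES = [
    # benzene
    [("C", None)] * 6,
    # pyridine
    [("N", None)] + [("C", None)] * 5,
    # pyrrole
    [("N", 1)] + [("C", None)] * 4,
    # furan
    [("O", None)] + [("C", None)] * 4,
    # thiophene
    [("S", None)] + [("C", None)] * 4,
]


@dataclass
class GenConfig:
    seed: int = 0
    n_molecules: int = 100
    atom_budget: tuple[int, int] = (1, 12)
    ring_probability: float = 0.3
    error_mix: dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    # corpus extras (defaults documented; all drawn from the same stream)
    missing_rate: float = 0.1
    multi_same_rate: float = 0.08
    stereo_pair_rate: float = 0.06
    n_pages: int = 100

    def __post_init__(self):
        if sum(self.error_mix.values()) > 1.0 + 1e-9:
            raise ValueError("error_mix proportions must sum to <= 1")


def _finalize(graph: MolecularGraph) -> MolecularGraph:
    kk = kekulize(graph)
    assert isinstance(kk, MolecularGraph)
    implicit = []
    from .elements import default_valence

    for i, atom in enumerate(graph.atoms):
        if atom.explicit_h is not None:
            implicit.append(atom.explicit_h)
        else:
            bond_sum = sum(graph.bonds[bi].order for bi in graph.adjacency()[i])
            v = default_valence(atom.element, bond_sum)
            assert v is not None, (atom.element, bond_sum)
            implicit.append(v - bond_sum)
    graph.implicit_h = implicit
    return graph


def _free_valence(graph: MolecularGraph, caps: list[int], i: int) -> int:
    bond_sum = sum(graph.bonds[bi].order for bi in graph.adjacency()[i])
    reserved = graph.atoms[i].explicit_h or 0
    return caps[i] - bond_sum - reserved


def random_molecule(config: GenConfig, rng: random.Random) -> str:
    """A random valid SMILES: a valence-respecting random tree over common
    elements, optionally carrying an aromatic ring template and/or an extra
    aliphatic ring closure.  Output always parses cleanly."""
    lo, hi = config.atom_budget
    budget = rng.randint(lo, hi)
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    caps: list[int] = []

    def add_atom(element, cap, aromatic=False, explicit_h=None) -> int:
        atoms.append(Atom(element=element, aromatic=aromatic, explicit_h=explicit_h))
        caps.append(cap)
        return len(atoms) - 1

    graph = MolecularGraph(atoms=atoms, bonds=bonds)

    def add_bond(a, b, order=1, aromatic=False):
        bonds.append(Bond(a, b, order=order, aromatic=aromatic))
        graph._adj = None

    use_ring = budget >= 5 and rng.random() < config.ring_probability
    if use_ring:
        template = rng.choice(_AROMATIC_TEMPLATES)
        n = len(template)
        for el, h in template:
            # growth caps count aromatic ring bonds at order 1, so atoms that
            # will receive a kekule double bond reserve one valence unit
            if el == "C":
                cap = 3
            elif el == "N":
                cap = 3 if h else 2  # [nH] donates its lone pair; bare n gets a double bond
            else:
                cap = 2  # O / S donors, fully used by the two ring bonds
            add_atom(el, cap, aromatic=True, explicit_h=h)
        for k in range(n):
            add_bond(k, (k + 1) % n, aromatic=True)
    else:
        el, cap = rng.choice(_GROW_ELEMENTS)
        add_atom(el, cap)

    while len(atoms) < budget:
        sites = [i for i in range(len(atoms)) if _free_valence(graph, caps, i) >= 1]
        if not sites:
            break
        parent = rng.choice(sites)
        el, cap = rng.choice(_GROW_ELEMENTS)
        child = add_atom(el, cap)
        order = 1
        if (
            cap >= 2
            and not atoms[parent].aromatic
            and _free_valence(graph, caps, parent) >= 2
            and rng.random() < 0.15
        ):
            order = 2
        add_bond(parent, child, order=order)

    # aromatic atoms need their kekule double bond: reserve by construction
    # (ring bonds handled by kekulize; substituents above use single bonds)
    if not use_ring and len(atoms) >= 4 and rng.random() < config.ring_probability:
        # try one aliphatic ring closure between distant atoms with free valence
        cands = [i for i in range(len(atoms)) if _free_valence(graph, caps, i) >= 1]
        rng.shuffle(cands)
        done = False
        for a in cands:
            if done:
                break
            for b in cands:
                if b <= a or graph.bond_between(a, b) is not None:
                    continue
                add_bond(a, b)
                done = True
                break

    smiles = write_smiles(_finalize(graph))
    check = parse_smiles(smiles)
    assert isinstance(check, MolecularGraph), (smiles, check)
    return smiles


def permuted_smiles(mol: MolecularGraph, rng: random.Random) -> str:
    """The same graph rewritten from a random root with shuffled neighbor
    order; parses back to an isomorphic graph."""
    n = len(mol.atoms)
    prio = list(range(n))
    rng.shuffle(prio)
    out = write_smiles(mol, priority=prio)
    check = parse_smiles(out)
    assert isinstance(check, MolecularGraph), out
    return out


def induced_subgraph(graph: MolecularGraph, atom_subset) -> MolecularGraph:
    """Induced subgraph usable as a substructure query: every atom pins its
    hydrogen count to the parent's, so the identity embedding always
    satisfies the matcher's bracket-atom minimum-H rule."""
    keep = sorted(set(atom_subset))
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        src = graph.atoms[old]
        atoms.append(
            Atom(
                element=src.element,
                isotope=src.isotope,
                charge=src.charge,
                explicit_h=graph.hydrogens(old),
                aromatic=src.aromatic,
            )
        )
    bonds = [
        Bond(remap[b.a], remap[b.b], order=b.order, aromatic=b.aromatic)
        for b in graph.bonds
        if b.a in remap and b.b in remap
    ]
    sub = MolecularGraph(atoms=atoms, bonds=bonds)
    sub.implicit_h = [a.explicit_h for a in atoms]
    return sub


def random_connected_subgraph(
    graph: MolecularGraph, rng: random.Random, min_atoms: int = 1
) -> MolecularGraph:
    """Random connected induced subgraph (random-walk expansion)."""
    comp = rng.choice(graph.components())
    size = rng.randint(min(min_atoms, len(comp)), len(comp))
    start = rng.choice(comp)
    chosen = {start}
    frontier = set(graph.neighbors(start))
    while len(chosen) < size and frontier:
        nxt = rng.choice(sorted(frontier))
        chosen.add(nxt)
        frontier |= set(graph.neighbors(nxt))
        frontier -= chosen
    return induced_subgraph(graph, chosen)


# ---------------------------------------------------------------------------
# synthetic wiki corpus
# ---------------------------------------------------------------------------


@dataclass
class CorpusManifest:
    """Ground truth for the end-to-end conservation check."""

    n_pages: int = 0
    pages_missing_smiles: int = 0
    entries_total: int = 0  # SMILES parameters planted
    kept: int = 0
    within_page_drops: int = 0
    errors_by_class: dict[str, int] = field(default_factory=dict)
    duplicate_groups: int = 0  # cross-page stereo-aware duplicate groups

    @property
    def errors_total(self) -> int:
        return sum(self.errors_by_class.values())


_STEREO_PAIRS = [
    ("N[C@@H](C)C(=O)O", "N[C@H](C)C(=O)O"),
    ("C[C@H](O)CC", "C[C@@H](O)CC"),
    ("F/C=C/F", "F/C=C\\F"),
    ("C/C=C/C(=O)O", "C/C=C\\C(=O)O"),
    ("N[C@@H](CC)C(=O)O", "N[C@H](CC)C(=O)O"),
]


def _chembox(title: str, smiles_fields: list[tuple[str, str]]) -> str:
    lines = ["{{Chembox", f"| Name = {title}", "{{Chembox Identifiers"]
    for name, value in smiles_fields:
        lines.append(f"| {name} = {value}")
    lines += ["}}", "}}"]
    return "\n".join(lines)


def _drugbox(title: str, smiles_fields: list[tuple[str, str]]) -> str:
    lines = ["{{Infobox drug", f"| drug_name = {title}"]
    for name, value in smiles_fields:
        lines.append(f"| {name} = {value}")
    lines.append("}}")
    return "\n".join(lines)


def _broken_smiles(error_class: str, base: str, rng: random.Random) -> str:
    if error_class == ErrorClass.UNCLOSED_RING.value:
        return base + "9"
    if error_class == ErrorClass.UNCLOSED_PARENTHESIS.value:
        return "C(" + base
    if error_class == ErrorClass.BARE_ATOM_NEEDS_BRACKETS.value:
        # first letter must not itself be an organic-subset symbol
        return rng.choice(["Hg", "Au", "Zn", "Ag"]) + base
    if error_class == ErrorClass.BAD_TOKEN.value:
        return base + rng.choice(["!", "?", "~", "*"])
    if error_class == ErrorClass.VALENCE_ERROR.value:
        return "CC(C)(C)(C)C"
    if error_class == ErrorClass.KEKULIZATION_FAILURE.value:
        return "c1cccc1"  # odd aromatic carbocycle; no n to repair
    if error_class == ErrorClass.PYRROLE_NITROGEN.value:
        # a pyrrole-bearing molecule with its [nH] stripped to bare n
        pyrrole = "c1cc[nH]c1"
        return pyrrole.replace("[nH]", "n")
    raise ValueError(f"unknown error class {error_class}")


def synth_wiki_corpus(config: GenConfig) -> tuple[list[WikiPage], CorpusManifest]:
    rng = random.Random(config.seed)
    manifest = CorpusManifest(n_pages=config.n_pages)
    pages: list[WikiPage] = []
    kept_structures: list[tuple[str, str]] = []  # (canonical, page)

    error_classes = list(config.error_mix.items())
    err_total = sum(p for _, p in error_classes)
    special = config.missing_rate + config.multi_same_rate + config.stereo_pair_rate
    dup_pool: list[str] = []
    stereo_pool = list(_STEREO_PAIRS)

    def canon(s: str) -> str:
        g = parse_smiles(s)
        assert isinstance(g, MolecularGraph), (s, g)
        return canonical_smiles(g).canonical_smiles

    used_canonicals: set[str] = set()

    def _note_kept(item: tuple[str, str]) -> None:
        kept_structures.append(item)
        used_canonicals.add(item[0])

    def fresh_molecule() -> str:
        # retry a few times so accidental cross-page collisions do not
        # masquerade as planted duplicates
        s = random_molecule(config, rng)
        for _ in range(25):
            if canon(s) not in used_canonicals:
                break
            s = random_molecule(config, rng)
        return s

    for k in range(config.n_pages):
        title = f"Synthpage {k:04d}"
        box = _chembox if rng.random() < 0.5 else _drugbox
        roll = rng.random()
        fields: list[tuple[str, str]] = []

        if roll < err_total:
            # an error page: one broken SMILES parameter
            acc = 0.0
            chosen = error_classes[-1][0]
            for cls, p in error_classes:
                acc += p
                if roll < acc:
                    chosen = cls
                    break
            base = random_molecule(config, rng)
            bad = _broken_smiles(chosen, base, rng)
            issue = parse_smiles(bad)
            assert isinstance(issue, ParseIssue) and issue.error_class.value == chosen, (
                bad,
                issue,
            )
            if chosen == ErrorClass.PYRROLE_NITROGEN.value:
                assert issue.suggested_fix is not None
            fields.append(("SMILES", bad))
            manifest.entries_total += 1
            manifest.errors_by_class[chosen] = manifest.errors_by_class.get(chosen, 0) + 1
        elif roll < err_total + config.missing_rate:
            manifest.pages_missing_smiles += 1
        elif roll < err_total + config.missing_rate + config.multi_same_rate:
            # same structure twice (different writings): first one kept
            s = fresh_molecule()
            g = parse_smiles(s)
            assert isinstance(g, MolecularGraph)
            fields.append(("SMILES", s))
            fields.append(("SMILES1", permuted_smiles(g, rng)))
            manifest.entries_total += 2
            manifest.kept += 1
            manifest.within_page_drops += 1
            _note_kept((canon(s), title))
        elif roll < err_total + config.missing_rate + config.multi_same_rate + config.stereo_pair_rate:
            if stereo_pool:
                # drawn without replacement so duplicate_rate=0 really means
                # no cross-page duplicates
                a, b = stereo_pool.pop(rng.randrange(len(stereo_pool)))
                fields.append(("SMILES", a))
                fields.append(("SMILES1", b))
                manifest.entries_total += 2
                manifest.kept += 2
                _note_kept((canon(a), title))
                _note_kept((canon(b), title))
            else:  # pool exhausted: fall back to a plain valid page
                s = fresh_molecule()
                dup_pool.append(s)
                fields.append(("SMILES", s))
                manifest.entries_total += 1
                manifest.kept += 1
                _note_kept((canon(s), title))
        else:
            if dup_pool and rng.random() < config.duplicate_rate:
                s = rng.choice(dup_pool)
            else:
                s = fresh_molecule()
                dup_pool.append(s)
            fields.append(("SMILES", s))
            manifest.entries_total += 1
            manifest.kept += 1
            _note_kept((canon(s), title))

        pages.append(WikiPage(title=title, wikitext=box(title, fields)))

    _ = special
    groups: dict[str, set[str]] = {}
    for structure, page in kept_structures:
        groups.setdefault(structure, set()).add(page)
    manifest.duplicate_groups = sum(
        1
        for structure, page_set in groups.items()
        if len(page_set) >= 2
        and sum(1 for s, _ in kept_structures if s == structure) >= 2
    )
    return pages, manifest
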