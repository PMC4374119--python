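"""Molecular graphs from SMILES: tokenizer, parser, kekulization, hydrogen
model, error classification with repair suggestion, formula and weight.

The accepted dialect is the SMILES organic subset (B C N O P S F Cl Br I,
aromatic b c n o p s) plus bracket atoms carrying isotope / charge / H-count /
@ / @@, ring closures (digits and %nn), bond symbols ``- = # : / \\`` and
dot-disconnection.  Aromatic input is kekulized by solving a perfect matching
over the atoms that require a double bond; failure to kekulize is itself a
classified error, and the common bare-``n`` pyrrole mistake gets a repair
suggestion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .elements import (
    ALLOWED_VALENCES,
    AROMATIC_ELEMENTS,
    AROMATIC_TOKENS,
    ATOMIC_WEIGHTS,
    ELEMENT_SYMBOLS,
    ORGANIC_SUBSET,
    default_valence,
)

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "ErrorClass",
    "ParseIssue",
    "parse_smiles",
    "kekulize",
    "suggest_pyrrole_fix",
    "molecular_formula",
    "molecular_weight",
    "write_smiles",
]


class ErrorClass(str, Enum):
    PYRROLE_NITROGEN = "PYRROLE_NITROGEN"
    UNCLOSED_RING = "UNCLOSED_RING"
    UNCLOSED_PARENTHESIS = "UNCLOSED_PARENTHESIS"
    BARE_ATOM_NEEDS_BRACKETS = "BARE_ATOM_NEEDS_BRACKETS"
    KEKULIZATION_FAILURE = "KEKULIZATION_FAILURE"
    BAD_TOKEN = "BAD_TOKEN"
    VALENCE_ERROR = "VALENCE_ERROR"


@dataclass
class ParseIssue:
    """A classified SMILES malformation; at most one is reported per input."""

    error_class: ErrorClass
    position: int
    message: str
    suggested_fix: str | None = None

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        fix = f" (try: {self.suggested_fix})" if self.suggested_fix else ""
        return f"{self.error_class.value}@{self.position}: {self.message}{fix}"


@dataclass
class Atom:
    element: str
    isotope: int | None = None
    charge: int = 0
    explicit_h: int | None = None  # set iff the atom came from a bracket
    aromatic: bool = False
    tetrahedral_parity: str | None = None  # '@' or '@@'
    # Parse-time neighbor order for stereo re-expression; -1 marks the
    # in-bracket implicit hydrogen.
    neighbor_order: list[int] = field(default_factory=list)


@dataclass
class Bond:
    a: int
    b: int
    order: int = 1  # 1, 2, 3; aromatic bonds get 1 or 2 after kekulization
    aromatic: bool = False
    cis_trans_mark: str | None = None  # '/' or '\\' in the written a->b sense

    def other(self, idx: int) -> int:
        return self.b if idx == self.a else self.a

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class MolecularGraph:
    atoms: list[Atom]
    bonds: list[Bond]
    implicit_h: list[int] = field(default_factory=list)
    multi_fragment: bool = False
    # double-bond stereo: bond index -> (ref neighbor of bond.a,
    # ref neighbor of bond.b, 'cis' | 'trans')
    db_stereo: dict[int, tuple[int, int, str]] = field(default_factory=dict)
    _adj: dict[int, list[int]] | None = None  # atom -> incident bond indices

    def __len__(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> dict[int, list[int]]:
        if self._adj is None:
            adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
            for bi, b in enumerate(self.bonds):
                adj[b.a].append(bi)
                adj[b.b].append(bi)
            self._adj = adj
        return self._adj

    def neighbors(self, idx: int) -> list[int]:
        return [self.bonds[bi].other(idx) for bi in self.adjacency()[idx]]

    def bond_between(self, a: int, b: int) -> Bond | None:
        for bi in self.adjacency()[a]:
            if self.bonds[bi].other(a) == b:
                return self.bonds[bi]
        return None

    def degree(self, idx: int) -> int:
        return len(self.adjacency()[idx])

    def hydrogens(self, idx: int) -> int:
        return self.implicit_h[idx]

    def total_h(self, idx: int) -> int:
        return self.implicit_h[idx]

    def components(self) -> list[list[int]]:
        seen: set[int] = set()
        comps = []
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                a = stack.pop()
                comp.append(a)
                for nb in self.neighbors(a):
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            comps.append(sorted(comp))
        return comps

    def ring_bond_indices(self) -> set[int]:
        """Bond indices that lie on at least one cycle (non-bridges)."""
        bridges = _bridges(self)
        return {bi for bi in range(len(self.bonds)) if bi not in bridges}

    def ring_atoms(self) -> set[int]:
        out: set[int] = set()
        for bi in self.ring_bond_indices():
            out.add(self.bonds[bi].a)
            out.add(self.bonds[bi].b)
        return out


def _bridges(graph: MolecularGraph) -> set[int]:
    """Bond indices that are bridges (iterative Tarjan lowpoint)."""
    n = len(graph.atoms)
    adj = graph.adjacency()
    disc = [-1] * n
    low = [0] * n
    out: set[int] = set()
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        stack: list[tuple[int, int, int]] = [(root, -1, 0)]  # (node, via bond, child ptr)
        while stack:
            node, via, ptr = stack.pop()
            if ptr == 0:
                disc[node] = low[node] = timer
                timer += 1
            if ptr < len(adj[node]):
                stack.append((node, via, ptr + 1))
                bi = adj[node][ptr]
                if bi == via:
                    continue
                nb = graph.bonds[bi].other(node)
                if disc[nb] == -1:
                    stack.append((nb, bi, 0))
                else:
                    low[node] = min(low[node], disc[nb])
            else:
                if via != -1:
                    parent = graph.bonds[via].other(node)
                    low[parent] = min(low[parent], low[node])
                    if low[node] > disc[parent]:
                        out.add(via)
    return out


class _ParseError(Exception):
    def __init__(self, issue: ParseIssue):
        self.issue = issue


_BRACKET_RE = re.compile(
    r"\[(?P<iso>\d+)?"
    r"(?P<sym>se|as|[A-Z][a-z]?|[bcnops])"
    r"(?P<chiral>@@?)?"
    r"(?P<hcount>H\d*)?"
    r"(?P<charge>\+\+|--|\+\d*|-\d*)?"
    r"\]"
)

_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, ":": 1, "/": 1, "\\": 1}


def _bare_atom_token(s: str, i: int) -> tuple[str, bool, int] | None:
    """Try to read an organic-subset atom at position i.

    Returns (element, aromatic, length) or None.
    """
    two = s[i : i + 2]
    if two in ("Cl", "Br"):
        return two, False, 2
    ch = s[i]
    if ch in "BCNOPSFI":
        return ch, False, 1
    if ch in "bcnops":
        return AROMATIC_TOKENS[ch], True, 1
    return None


def _tokenize_and_build(smiles: str) -> tuple[MolecularGraph, list[int]]:
    """First pass: syntax.  Returns the raw (un-kekulized) graph plus the
    source character offset of every atom.  Raises _ParseError for any of the
    syntax-level malformations."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    atom_pos: list[int] = []
    prev: int | None = None
    pending: tuple[str, int] | None = None  # (bond char, pos)
    branch_stack: list[tuple[int | None, int]] = []  # (prev atom, '(' pos)
    ring_open: dict[str, tuple[int, str | None, int]] = {}  # digit -> (atom, bond char, pos)
    multi_fragment = False

    def bad(pos: int, msg: str) -> _ParseError:
        return _ParseError(ParseIssue(ErrorClass.BAD_TOKEN, pos, msg))

    def add_atom(atom: Atom, pos: int) -> None:
        nonlocal prev, pending
        atoms.append(atom)
        atom_pos.append(pos)
        idx = len(atoms) - 1
        if prev is not None:
            _make_bond(prev, idx, pending, pos)
        elif pending is not None:
            raise bad(pending[1], "bond symbol with no preceding atom")
        prev = idx
        pending = None

    def _make_bond(a: int, b: int, bond: tuple[str, int] | None, pos: int) -> None:
        if a == b:
            raise bad(pos, "atom bonded to itself")
        for bd in bonds:
            if {bd.a, bd.b} == {a, b}:
                raise bad(pos, "duplicate bond between the same atoms")
        mark = None
        if bond is None:
            order = 1
            aromatic = atoms[a].aromatic and atoms[b].aromatic
        else:
            ch = bond[0]
            order = _BOND_ORDERS[ch]
            aromatic = ch == ":"
            if aromatic and not (atoms[a].aromatic and atoms[b].aromatic):
                raise bad(bond[1], "aromatic bond between non-aromatic atoms")
            if ch in "/\\":
                mark = ch
        bonds.append(Bond(a, b, order=order, aromatic=aromatic, cis_trans_mark=mark))
        atoms[a].neighbor_order.append(b)
        atoms[b].neighbor_order.append(a)

    def ring_closure(digit: str, pos: int) -> None:
        nonlocal pending
        if prev is None:
            raise bad(pos, "ring closure digit with no preceding atom")
        if digit in ring_open:
            o_atom, o_bond, o_pos = ring_open.pop(digit)
            if o_atom == prev:
                raise bad(pos, "ring closure to the same atom")
            here = pending[0] if pending else None
            there = o_bond
            if here and there and here != there and {here, there} != {"/", "\\"}:
                raise bad(pos, "conflicting ring-closure bond symbols")
            bond_char = here or there
            bond = (bond_char, pos) if bond_char else None
            # stereo neighbor order: the opening atom recorded a placeholder
            _make_bond(o_atom, prev, bond, pos)
            # fix placeholder ordering for the opening atom
            oa = atoms[o_atom].neighbor_order
            if ("ring", digit) in oa:
                oa[oa.index(("ring", digit))] = prev  # type: ignore[list-item]
                oa.pop()  # drop the duplicate appended by _make_bond
        else:
            ring_open[digit] = (prev, pending[0] if pending else None, pos)
            atoms[prev].neighbor_order.append(("ring", digit))  # type: ignore[arg-type]
        pending = None

    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch.isspace():
            if smiles[i:].strip():
                raise bad(i, "whitespace inside SMILES")
            break
        if ch == "(":
            if prev is None:
                raise bad(i, "branch opened before any atom")
            branch_stack.append((prev, i))
            i += 1
            continue
        if ch == ")":
            if not branch_stack:
                raise _ParseError(
                    ParseIssue(
                        ErrorClass.UNCLOSED_PARENTHESIS, i, "unmatched closing parenthesis"
                    )
                )
            prev, _ = branch_stack.pop()
            i += 1
            continue
        if ch in _BOND_ORDERS:
            if pending is not None:
                raise bad(i, "two consecutive bond symbols")
            pending = (ch, i)
            i += 1
            continue
        if ch == ".":
            if pending is not None:
                raise bad(i, "bond symbol before dot")
            if branch_stack:
                raise bad(i, "dot inside a branch")
            prev = None
            multi_fragment = True
            i += 1
            continue
        if ch.isdigit():
            ring_closure(ch, i)
            i += 1
            continue
        if ch == "%":
            m = re.match(r"%(\d\d)", smiles[i:])
            if not m:
                raise bad(i, "'%' must be followed by two digits")
            ring_closure(m.group(1), i)
            i += 3
            continue
        if ch == "[":
            m = _BRACKET_RE.match(smiles, i)
            if not m:
                raise bad(i, "malformed bracket atom")
            iso = int(m.group("iso")) if m.group("iso") else None
            sym = m.group("sym")
            aromatic = sym in AROMATIC_TOKENS
            element = AROMATIC_TOKENS.get(sym, sym)
            if element not in ELEMENT_SYMBOLS:
                raise bad(i, f"unknown element symbol '{sym}'")
            if aromatic and element not in AROMATIC_ELEMENTS:
                raise bad(i, f"element '{element}' cannot be aromatic")
            hc = m.group("hcount")
            hcount = 0
            if hc:
                hcount = int(hc[1:]) if len(hc) > 1 else 1
            cg = m.group("charge")
            charge = 0
            if cg:
                if cg == "++":
                    charge = 2
                elif cg == "--":
                    charge = -2
                elif len(cg) == 1:
                    charge = 1 if cg == "+" else -1
                else:
                    charge = int(cg[1:]) * (1 if cg[0] == "+" else -1)
            add_atom(
                Atom(
                    element=element,
                    isotope=iso,
                    charge=charge,
                    explicit_h=hcount,
                    aromatic=aromatic,
                    tetrahedral_parity=m.group("chiral"),
                ),
                i,
            )
            if m.group("chiral") and hcount >= 1:
                # in-bracket H sits right after the preceding atom in the
                # stereo neighbor order
                order = atoms[-1].neighbor_order
                order.insert(1 if order else 0, -1)
            i = m.end()
            continue
        tok = _bare_atom_token(smiles, i)
        if tok is not None:
            element, aromatic, length = tok
            add_atom(Atom(element=element, aromatic=aromatic), i)
            i += length
            continue
        # not part of the dialect: distinguish "known element outside
        # brackets" from arbitrary junk
        two = smiles[i : i + 2]
        if ch.isupper():
            if two in ELEMENT_SYMBOLS:
                raise _ParseError(
                    ParseIssue(
                        ErrorClass.BARE_ATOM_NEEDS_BRACKETS,
                        i,
                        f"atom '{two}' must be written in square brackets",
                    )
                )
            if ch in ELEMENT_SYMBOLS:
                raise _ParseError(
                    ParseIssue(
                        ErrorClass.BARE_ATOM_NEEDS_BRACKETS,
                        i,
                        f"atom '{ch}' must be written in square brackets",
                    )
                )
        raise bad(i, f"unexpected character {ch!r}")

    if not atoms:
        raise bad(0, "no atoms found")
    if ring_open:
        digit, (_, _, pos) = min(ring_open.items(), key=lambda kv: kv[1][2])
        raise _ParseError(
            ParseIssue(ErrorClass.UNCLOSED_RING, pos, f"ring bond {digit} never closed")
        )
    if branch_stack:
        _, pos = branch_stack[0]
        raise _ParseError(
            ParseIssue(ErrorClass.UNCLOSED_PARENTHESIS, pos, "parenthesis never closed")
        )
    if pending is not None:
        raise bad(pending[1], "dangling bond symbol")

    graph = MolecularGraph(atoms=atoms, bonds=bonds, multi_fragment=multi_fragment)
    # drop unresolved ring placeholders cannot happen (checked above); scrub
    # stereo neighbor orders that contain tuples defensively
    for atom in atoms:
        atom.neighbor_order = [x for x in atom.neighbor_order if not isinstance(x, tuple)] if any(
            isinstance(x, tuple) for x in atom.neighbor_order
        ) else atom.neighbor_order
    return graph, atom_pos


def _needs_double_bond(graph: MolecularGraph, idx: int) -> bool:
    """Whether an aromatic atom must receive exactly one double bond during
    kekulization (i.e. it is not a lone-pair donor and is not already
    saturated by an explicit non-aromatic multiple bond)."""
    atom = graph.atoms[idx]
    for bi in graph.adjacency()[idx]:
        bond = graph.bonds[bi]
        if not bond.aromatic and bond.order >= 2:
            return False  # exocyclic double bond already present
    sigma = graph.degree(idx) + (atom.explicit_h or 0)
    el, q = atom.element, atom.charge
    if el == "C":
        return q == 0
    if el in ("N", "P", "As"):
        if q > 0:
            return True
        if q < 0:
            return False
        return sigma == 2
    if el in ("O", "S", "Se"):
        return q > 0
    if el == "B":
        return False
    return False


def _lex_smallest_matching(
    needy: list[int], edges: dict[int, list[int]]
) -> dict[int, int] | None:
    """Perfect matching over *needy* using only *edges*; greedy with
    backtracking on ascending indices yields the matching whose sorted edge
    list is lexicographically smallest."""
    matched: dict[int, int] = {}

    def rec() -> bool:
        free = [a for a in needy if a not in matched]
        if not free:
            return True
        a = free[0]
        for b in sorted(edges.get(a, ())):
            if b in matched or b == a:
                continue
            matched[a] = b
            matched[b] = a
            if rec():
                return True
            del matched[a]
            del matched[b]
        return False

    return matched if rec() else None


def kekulize(graph: MolecularGraph) -> MolecularGraph | ParseIssue:
    """Resolve aromatic bond orders in place.  Every aromatic atom that
    requires a double bond gets exactly one, found as a perfect matching over
    the aromatic subgraph; the deterministic tie-break picks the matching with
    the lexicographically smallest sorted endpoint-pair list."""
    needy = [i for i in range(len(graph.atoms)) if graph.atoms[i].aromatic and _needs_double_bond(graph, i)]
    needy_set = set(needy)
    edges: dict[int, list[int]] = {}
    for bond in graph.bonds:
        if bond.aromatic and bond.a in needy_set and bond.b in needy_set:
            edges.setdefault(bond.a, []).append(bond.b)
            edges.setdefault(bond.b, []).append(bond.a)
    matching = _lex_smallest_matching(needy, edges)
    if matching is None:
        pos_atom = needy[0] if needy else 0
        return ParseIssue(
            ErrorClass.KEKULIZATION_FAILURE,
            0,
            f"aromatic system cannot be kekulized (atom index {pos_atom})",
        )
    pairs = {frozenset((a, b)) for a, b in matching.items()}
    for bond in graph.bonds:
        if bond.aromatic:
            bond.order = 2 if frozenset((bond.a, bond.b)) in pairs else 1
    return graph


def _assign_hydrogens(graph: MolecularGraph, atom_pos: list[int]) -> ParseIssue | None:
    implicit: list[int] = []
    for i, atom in enumerate(graph.atoms):
        if atom.explicit_h is not None:
            implicit.append(atom.explicit_h)
            continue
        bond_sum = sum(graph.bonds[bi].order for bi in graph.adjacency()[i])
        v = default_valence(atom.element, bond_sum)
        if v is None:
            return ParseIssue(
                ErrorClass.VALENCE_ERROR,
                atom_pos[i],
                f"{atom.element} with bond order sum {bond_sum} exceeds allowed valences "
                f"{ALLOWED_VALENCES.get(atom.element)}",
            )
        implicit.append(v - bond_sum)
    graph.implicit_h = implicit
    return None


def _simple_cycles_of_size(graph: MolecularGraph, sizes: tuple[int, ...]) -> list[list[int]]:
    adj = graph.adjacency()
    top = max(sizes)
    rings: list[list[int]] = []
    for start in range(len(graph.atoms)):
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            if len(path) in sizes and len(path) >= 3:
                if any(graph.bonds[bi].other(node) == start for bi in adj[node]):
                    if path[1] < path[-1]:  # one direction only
                        rings.append(path)
            if len(path) == top:
                continue
            for bi in adj[node]:
                nb = graph.bonds[bi].other(node)
                if nb <= start or nb in path:
                    continue
                stack.append((nb, path + [nb]))
    return rings


def _perceive_aromatic_rings(graph: MolecularGraph) -> None:
    """Flip kekule-written aromatic rings to the aromatic form (flags only;
    kekule bond orders are kept).

    A 5- or 6-membered ring of aromatizable elements counts pi electrons the
    usual way — 1 for an atom whose double bond lies on a ring bond, 2 for a
    saturated lone-pair donor (pyrrole N, furan O, ...) — and is aromatized
    when every atom participates and the total is 4n+2.  Fused systems work
    per ring because the shared double bond is itself a ring bond.
    """
    ring_bonds = graph.ring_bond_indices()
    adj = graph.adjacency()

    def contribution(a: int) -> int | None:
        atom = graph.atoms[a]
        if atom.element not in AROMATIC_ELEMENTS:
            return None
        doubles = [bi for bi in adj[a] if graph.bonds[bi].order >= 2]
        if doubles:
            if any(graph.bonds[bi].order > 2 for bi in doubles):
                return None
            if all(bi in ring_bonds for bi in doubles):
                return 1
            return None  # exocyclic double bond (quinone-like): stay kekule
        sigma = graph.degree(a) + graph.hydrogens(a)
        el, q = atom.element, atom.charge
        if el in ("N", "P", "As") and q <= 0 and sigma == 3:
            return 2
        if el in ("O", "S", "Se") and q == 0 and sigma == 2:
            return 2
        if el == "C" and q < 0:
            return 2
        if el == "C" and q > 0:
            return 0
        return None

    aromatic_atoms: set[int] = set()
    aromatic_bonds: set[int] = set()
    for ring in _simple_cycles_of_size(graph, (5, 6)):
        if any(graph.atoms[a].aromatic for a in ring):
            continue
        contribs = [contribution(a) for a in ring]
        if any(c is None for c in contribs):
            continue
        if sum(contribs) % 4 != 2:  # Hueckel 4n+2
            continue
        aromatic_atoms.update(ring)
        for k in range(len(ring)):
            a, b = ring[k], ring[(k + 1) % len(ring)]
            for bi in adj[a]:
                if graph.bonds[bi].other(a) == b:
                    aromatic_bonds.add(bi)
    for a in aromatic_atoms:
        graph.atoms[a].aromatic = True
    for bi in aromatic_bonds:
        graph.bonds[bi].aromatic = True


def _resolve_db_stereo(graph: MolecularGraph) -> None:
    """Convert the parsed '/' and '\\' marks into per-double-bond relative
    configurations (reference neighbor on each side + cis/trans)."""

    def u(p: int, x: int) -> int | None:
        bond = graph.bond_between(p, x)
        if bond is None or bond.cis_trans_mark is None:
            return None
        val = 1 if bond.cis_trans_mark == "/" else -1
        return val if (bond.a, bond.b) == (p, x) else -val

    for bi, bond in enumerate(graph.bonds):
        if bond.order != 2 or bond.aromatic:
            continue
        x, y = bond.a, bond.b
        px = [p for p in graph.neighbors(x) if p != y and u(p, x) is not None]
        qy = [q for q in graph.neighbors(y) if q != x and u(q, y) is not None]
        if not px or not qy:
            continue
        p, q = min(px), min(qy)
        rel = "cis" if u(p, x) == u(q, y) else "trans"
        graph.db_stereo[bi] = (p, q, rel)


def parse_smiles(smiles: str, *, _classify_pyrrole: bool = True) -> MolecularGraph | ParseIssue:
    """Parse a SMILES string into a kekulized, valence-checked molecular
    graph, or return the single most specific :class:`ParseIssue`.

    Error precedence: syntax errors > kekulization errors > valence errors.
    A kekulization failure repairable by rewriting bare aromatic ``n`` as
    ``[nH]`` is reported as ``PYRROLE_NITROGEN`` with the repaired string
    attached.
    """
    if not smiles or not smiles.strip():
        return ParseIssue(ErrorClass.BAD_TOKEN, 0, "empty SMILES")
    try:
        graph, atom_pos = _tokenize_and_build(smiles.strip())
    except _ParseError as exc:
        return exc.issue

    kk = kekulize(graph)
    if isinstance(kk, ParseIssue):
        if _classify_pyrrole:
            fix = suggest_pyrrole_fix(smiles.strip())
            if fix is not None:
                first_n = _bare_aromatic_n_offsets(smiles.strip())
                return ParseIssue(
                    ErrorClass.PYRROLE_NITROGEN,
                    first_n[0] if first_n else 0,
                    "aromatic nitrogen with a hydrogen must be written [nH]",
                    suggested_fix=fix,
                )
        return kk

    issue = _assign_hydrogens(graph, atom_pos)
    if issue is not None:
        return issue
    _perceive_aromatic_rings(graph)
    _resolve_db_stereo(graph)
    return graph


def _bare_aromatic_n_offsets(smiles: str) -> list[int]:
    """Character offsets of every bare (unbracketed) aromatic ``n`` token."""
    out = []
    depth = 0
    for i, ch in enumerate(smiles):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif ch == "n" and depth == 0:
            out.append(i)
    return out


def suggest_pyrrole_fix(smiles: str) -> str | None:
    """For a SMILES that fails kekulization, try promoting bare aromatic
    ``n`` tokens to ``[nH]`` — minimal subsets first, leftmost-first within a
    subset size — and return the first candidate that parses cleanly."""
    base = parse_smiles(smiles, _classify_pyrrole=False)
    if not (isinstance(base, ParseIssue) and base.error_class == ErrorClass.KEKULIZATION_FAILURE):
        return None
    offsets = _bare_aromatic_n_offsets(smiles)
    if not offsets:
        return None
    from itertools import combinations

    for size in range(1, len(offsets) + 1):
        for subset in combinations(offsets, size):
            chars = list(smiles)
            for off in sorted(subset, reverse=True):
                chars[off : off + 1] = list("[nH]")
            candidate = "".join(chars)
            if isinstance(parse_smiles(candidate, _classify_pyrrole=False), MolecularGraph):
                return candidate
    return None


def molecular_formula(graph: MolecularGraph) -> str:
    """Hill-order molecular formula (C, H, then alphabetical; fully
    alphabetical when no carbon), counting implicit and explicit hydrogens."""
    counts: dict[str, int] = {}
    h_total = 0
    for i, atom in enumerate(graph.atoms):
        if atom.element == "H":
            h_total += 1
        else:
            counts[atom.element] = counts.get(atom.element, 0) + 1
        h_total += graph.hydrogens(i)
    if h_total:
        counts["H"] = counts.get("H", 0) + h_total

    def fmt(el: str) -> str:
        c = counts[el]
        return el if c == 1 else f"{el}{c}"

    parts: list[str] = []
    if "C" in counts:
        parts.append(fmt("C"))
        if "H" in counts:
            parts.append(fmt("H"))
        parts.extend(fmt(el) for el in sorted(counts) if el not in ("C", "H"))
    else:
        parts.extend(fmt(el) for el in sorted(counts))
    return "".join(parts)


def molecular_weight(graph: MolecularGraph) -> float:
    """Molecular weight in Daltons, rounded to 2 decimals.  Isotope mass
    numbers substitute the standard atomic weight when specified."""
    total = 0.0
    for i, atom in enumerate(graph.atoms):
        total += float(atom.isotope) if atom.isotope is not None else ATOMIC_WEIGHTS[atom.element]
        total += graph.hydrogens(i) * ATOMIC_WEIGHTS["H"]
    return round(total, 2)


# ---------------------------------------------------------------------------
# SMILES writer
# ---------------------------------------------------------------------------


def _implied_bare_h(graph: MolecularGraph, idx: int) -> int | None:
    """H count a bare (unbracketed) atom would get on re-parse, or None if
    the atom cannot be written bare."""
    atom = graph.atoms[idx]
    if atom.element not in ORGANIC_SUBSET or atom.isotope or atom.charge:
        return None
    if atom.aromatic and atom.element not in ("B", "C", "N", "O", "P", "S"):
        return None
    bond_sum = sum(graph.bonds[bi].order for bi in graph.adjacency()[idx])
    if atom.aromatic:
        # a bare aromatic atom re-parses with sigma == degree; its
        # needs-a-double-bond status must agree with the double bond it
        # actually carries, else the bare form changes meaning (pyrrole [nH])
        probe = Atom(element=atom.element, aromatic=True)
        saved = graph.atoms[idx]
        graph.atoms[idx] = probe
        try:
            would_need = _needs_double_bond(graph, idx)
        finally:
            graph.atoms[idx] = saved
        has_double = any(
            graph.bonds[bi].order == 2 for bi in graph.adjacency()[idx]
        )
        if would_need != has_double:
            return None
    v = default_valence(atom.element, bond_sum)
    return None if v is None else v - bond_sum


def _permutation_parity(a: list[int], b: list[int]) -> int:
    """0 for even, 1 for odd permutation taking list a to list b."""
    perm = [b.index(x) for x in a]
    parity = 0
    seen = [False] * len(perm)
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, clen = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            clen += 1
        parity ^= (clen - 1) & 1
    return parity


def write_smiles(
    graph: MolecularGraph,
    *,
    priority: list[int] | None = None,
    start: int | None = None,
    include_stereo: bool = True,
) -> str:
    """Serialize the graph back to SMILES.

    ``priority`` (one value per atom, lower = earlier) controls both the DFS
    root within each fragment and the neighbor visiting order, which makes
    this one writer serve canonical output, round-trip tests and randomized
    rewrites alike.
    """
    n = len(graph.atoms)
    prio = priority if priority is not None else list(range(n))
    adj = graph.adjacency()

    parts = []
    visited: set[int] = set()
    comps = graph.components()
    comps.sort(key=lambda comp: min((prio[a], a) for a in comp))
    for comp in comps:
        if start is not None and start in comp and start not in visited:
            root = start
        else:
            root = min(comp, key=lambda a: (prio[a], a))
        parts.append(_write_fragment(graph, root, prio, visited, adj, include_stereo))
    return ".".join(parts)


def _write_fragment(graph, root, prio, visited, adj, include_stereo) -> str:
    # DFS to discover tree structure and ring-closure (back) edges
    parent: dict[int, int | None] = {root: None}
    children: dict[int, list[int]] = {}
    closure_bonds: list[tuple[int, int]] = []  # (a, b) discovery order
    order: list[int] = []
    seen_edges: set[tuple[int, int]] = set()

    stack = [root]
    local_seen = {root}
    while stack:
        a = stack.pop()
        order.append(a)
        visited.add(a)
        nbs = sorted(
            (b for b in graph.neighbors(a)), key=lambda b: (prio[b], b)
        )
        kids = []
        for b in nbs:
            ek = (min(a, b), max(a, b))
            if ek in seen_edges:
                continue
            if b in local_seen:
                seen_edges.add(ek)
                closure_bonds.append((a, b))
                continue
            seen_edges.add(ek)
            parent[b] = a
            kids.append(b)
            local_seen.add(b)
        children[a] = kids
        for b in reversed(kids):
            stack.append(b)

    # assign ring-closure digits in order of first encounter during writing
    emit_order = _emit_order(root, children)
    pos_of = {a: i for i, a in enumerate(emit_order)}
    ring_digits: dict[tuple[int, int], str] = {}
    open_at: dict[int, list[tuple[int, str]]] = {}
    close_at: dict[int, list[tuple[int, str]]] = {}
    next_digit = 1
    pending_digits: list[str] = []
    events = []
    for a, b in closure_bonds:
        first, second = (a, b) if pos_of[a] < pos_of[b] else (b, a)
        events.append((pos_of[first], first, second))
    events.sort()
    free: list[str] = []
    active: dict[tuple[int, int], str] = {}
    closes_by_pos: dict[int, list[tuple[int, int]]] = {}
    for _, first, second in events:
        closes_by_pos.setdefault(pos_of[second], []).append((first, second))
    pos_iter = 0
    for pos in range(len(emit_order)):
        atom = emit_order[pos]
        for first, second in [e[1:] for e in events if e[0] == pos]:
            if free:
                d = free.pop(0)
            else:
                d = str(next_digit) if next_digit < 10 else f"%{next_digit:02d}"
                next_digit += 1
            active[(first, second)] = d
            open_at.setdefault(first, []).append((second, d))
        for first, second in closes_by_pos.get(pos, []):
            d = active.pop((first, second))
            close_at.setdefault(second, []).append((first, d))
            free.append(d)
            free.sort()
    _ = pending_digits, pos_iter

    cis_trans = _plan_cis_trans(graph, emit_order, parent, include_stereo)

    def bond_symbol(a: int, b: int) -> str:
        bond = graph.bond_between(a, b)
        assert bond is not None
        if (a, b) in cis_trans:
            return cis_trans[(a, b)]
        if bond.aromatic:
            return ""
        if bond.order == 2:
            return "="
        if bond.order == 3:
            return "#"
        if graph.atoms[a].aromatic and graph.atoms[b].aromatic:
            return "-"  # single bond between two aromatic atoms must be explicit
        return ""

    def atom_token(a: int) -> str:
        atom = graph.atoms[a]
        h = graph.hydrogens(a)
        stereo = atom.tetrahedral_parity if include_stereo else None
        if stereo and len(atom.neighbor_order) == 4:
            written = _written_neighbor_order(a, parent, open_at, close_at, children, h)
            if written is not None and sorted(written) == sorted(atom.neighbor_order):
                if _permutation_parity(atom.neighbor_order, written):
                    stereo = "@@" if atom.tetrahedral_parity == "@" else "@"
            else:
                stereo = None
        elif stereo:
            stereo = None
        sym = atom.element.lower() if atom.aromatic else atom.element
        needs_bracket = (
            atom.isotope is not None
            or atom.charge != 0
            or stereo is not None
            or atom.element not in ORGANIC_SUBSET
            or (atom.aromatic and atom.element not in ("B", "C", "N", "O", "P", "S"))
            or _implied_bare_h(graph, a) != h
        )
        if not needs_bracket:
            return sym
        out = "["
        if atom.isotope is not None:
            out += str(atom.isotope)
        out += sym
        if stereo:
            out += stereo
        if h == 1:
            out += "H"
        elif h > 1:
            out += f"H{h}"
        if atom.charge:
            q = atom.charge
            out += ("+" if q > 0 else "-") + (str(abs(q)) if abs(q) > 1 else "")
        return out + "]"

    def rec(a: int) -> str:
        s = atom_token(a)
        for second, d in open_at.get(a, []):
            sym = cis_trans.get((a, second), "")
            s += sym + d
        for first, d in close_at.get(a, []):
            sym = cis_trans.get((first, a), "")
            bond = graph.bond_between(first, a)
            extra = ""
            if bond is not None and not bond.aromatic and bond.order == 2:
                extra = "="
            elif bond is not None and not bond.aromatic and bond.order == 3:
                extra = "#"
            s += (sym or extra) + d
        kids = children.get(a, [])
        for k, b in enumerate(kids):
            seg = bond_symbol(a, b) + rec(b)
            if k < len(kids) - 1:
                s += f"({seg})"
            else:
                s += seg
        return s

    return rec(root)


def _emit_order(root: int, children: dict[int, list[int]]) -> list[int]:
    out: list[int] = []

    def rec(a: int) -> None:
        out.append(a)
        for b in children.get(a, []):
            rec(b)

    rec(root)
    return out


def _written_neighbor_order(a, parent, open_at, close_at, children, h) -> list[int] | None:
    """Neighbor order as it will appear in the output string: preceding atom,
    in-bracket H, ring-closure partners (digit order), then branch atoms."""
    written: list[int] = []
    if parent.get(a) is not None:
        written.append(parent[a])
    if h >= 1:
        if h > 1:
            return None
        written.append(-1)
    for second, _d in open_at.get(a, []):
        written.append(second)
    for first, _d in close_at.get(a, []):
        written.append(first)
    written.extend(children.get(a, []))
    return written if len(written) == 4 else None


def _plan_cis_trans(graph, emit_order, parent, include_stereo) -> dict[tuple[int, int], str]:
    """Assign '/' and '\\' marks to single bonds so that every recorded
    double-bond configuration is reproduced.  Keys are (from, to) pairs in
    the direction the writer emits the bond."""
    if not include_stereo or not graph.db_stereo:
        return {}
    pos_of = {a: i for i, a in enumerate(emit_order)}

    # u-value per single bond in canonical (low, high) orientation
    u_val: dict[tuple[int, int], int] = {}

    def get_u(p: int, x: int) -> int | None:
        k = (min(p, x), max(p, x))
        if k not in u_val:
            return None
        return u_val[k] if (p, x) == k else -u_val[k]

    def set_u(p: int, x: int, v: int) -> bool:
        k = (min(p, x), max(p, x))
        vv = v if (p, x) == k else -v
        if k in u_val:
            return u_val[k] == vv
        u_val[k] = vv
        return True

    order_key = lambda bi: min(
        pos_of.get(graph.bonds[bi].a, 1 << 30), pos_of.get(graph.bonds[bi].b, 1 << 30)
    )
    for bi in sorted(graph.db_stereo, key=order_key):
        p, q, rel = graph.db_stereo[bi]
        bond = graph.bonds[bi]
        x, y = bond.a, bond.b
        if p not in pos_of or q not in pos_of:
            continue
        upx = get_u(p, x)
        if upx is None:
            set_u(p, x, 1)
            upx = 1
        uqy = upx if rel == "cis" else -upx
        set_u(q, y, uqy)  # on conflict the earlier assignment wins

    marks: dict[tuple[int, int], str] = {}
    for (lo, hi), v in u_val.items():
        # emit direction: the atom written earlier comes first
        if parent.get(hi) == lo or (pos_of.get(lo, 0) < pos_of.get(hi, 0)):
            frm, to, vv = lo, hi, v
        else:
            frm, to, vv = hi, lo, -v
        marks[(frm, to)] = "/" if vv > 0 else "\\"
    return marks
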