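"""Fragment-dictionary binary fingerprint: 512 bits packed into 16 unsigned
32-bit words, with Tanimoto similarity and the subset screen used by the
two-step substructure search.

Bit *i* is set when dictionary fragment *i* occurs in the molecule at least
``min_count`` times.  Because every bit is a substructure predicate, bit-set
containment is implied by graph containment, which is exactly the soundness
property the screening step relies on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

from .match import MatchOptions, count_matches
from .molgraph import MolecularGraph, parse_smiles

__all__ = [
    "FragmentDictionary",
    "Descriptor",
    "EvaluationCounter",
    "compute_descriptor",
    "tanimoto",
    "screen_pass",
    "load_default_dictionary",
    "load_dictionary",
    "N_BITS",
    "N_WORDS",
]

N_BITS = 512
N_WORDS = 16
_WORD_MASK = 0xFFFFFFFF

# fragment matching ignores aromatic/kekule strictness subtleties as little
# as possible: strict matching keeps every bit a sound substructure predicate
_FRAGMENT_OPTS = MatchOptions(aromatic_strict=True, charge_strict=True)


@dataclass(frozen=True)
class _Fragment:
    smiles: str
    graph: MolecularGraph
    min_count: int
    elements: tuple[tuple[str, int], ...]  # element -> required count
    n_bonds: int


class FragmentDictionary:
    """Ordered set of exactly 512 query fragments; bit i <-> fragment i."""

    def __init__(self, entries: list[tuple[str, int]], version: str):
        if len(entries) != N_BITS:
            raise ValueError(f"fragment dictionary must have {N_BITS} entries, got {len(entries)}")
        self.version = version
        self.fragments: list[_Fragment] = []
        for smiles, min_count in entries:
            if min_count < 1:
                raise ValueError(f"min_count must be >= 1 for {smiles!r}")
            graph = parse_smiles(smiles)
            if not isinstance(graph, MolecularGraph):
                raise ValueError(f"fragment {smiles!r} does not parse: {graph}")
            counts = Counter(a.element for a in graph.atoms)
            self.fragments.append(
                _Fragment(
                    smiles=smiles,
                    graph=graph,
                    min_count=min_count,
                    elements=tuple(sorted(counts.items())),
                    n_bonds=len(graph.bonds),
                )
            )

    def __len__(self) -> int:
        return N_BITS


@dataclass(frozen=True)
class Descriptor:
    """512-bit fingerprint as 16 unsigned 32-bit words; global bit 32*w + j
    is bit j (little-endian) of word w."""

    words: tuple[int, ...]
    version: str

    def __post_init__(self):
        if len(self.words) != N_WORDS:
            raise ValueError(f"descriptor needs {N_WORDS} words")
        if any(w < 0 or w > _WORD_MASK for w in self.words):
            raise ValueError("words must be unsigned 32-bit integers")

    @property
    def bits(self) -> list[bool]:
        return [bool((self.words[i // 32] >> (i % 32)) & 1) for i in range(N_BITS)]

    @classmethod
    def from_bits(cls, bits, version: str) -> "Descriptor":
        bits = list(bits)
        if len(bits) != N_BITS:
            raise ValueError(f"need {N_BITS} bits")
        words = [0] * N_WORDS
        for i, b in enumerate(bits):
            if b:
                words[i // 32] |= 1 << (i % 32)
        return cls(tuple(words), version)

    def popcount(self) -> int:
        return sum(w.bit_count() for w in self.words)


class EvaluationCounter:
    """Counts fragment-vs-molecule substructure evaluations (one per
    dictionary fragment, element-count fast paths included)."""

    def __init__(self) -> None:
        self.evaluations = 0


def compute_descriptor(
    mol: MolecularGraph,
    dictionary: FragmentDictionary,
    counter: EvaluationCounter | None = None,
) -> Descriptor:
    """One substructure evaluation per dictionary fragment (exactly 512).

    A fragment whose element requirements the molecule cannot meet is
    resolved by the (provably sound) element-count pre-check; everything else
    runs the graph matcher with early exit at ``min_count`` occurrences.
    """
    mol_counts = Counter(a.element for a in mol.atoms)
    n_bonds = len(mol.bonds)
    words = [0] * N_WORDS
    for i, frag in enumerate(dictionary.fragments):
        if counter is not None:
            counter.evaluations += 1
        if frag.n_bonds > n_bonds:
            continue
        if any(mol_counts.get(el, 0) < need for el, need in frag.elements):
            continue
        if count_matches(frag.graph, mol, _FRAGMENT_OPTS, limit=frag.min_count) >= frag.min_count:
            words[i // 32] |= 1 << (i % 32)
    return Descriptor(tuple(words), dictionary.version)


def tanimoto(a: Descriptor, b: Descriptor) -> float:
    """|a AND b| / |a OR b|; 1.0 when both fingerprints are empty."""
    if a.version != b.version:
        raise ValueError(f"dictionary version mismatch: {a.version!r} vs {b.version!r}")
    inter = sum((x & y).bit_count() for x, y in zip(a.words, b.words))
    union = sum((x | y).bit_count() for x, y in zip(a.words, b.words))
    return 1.0 if union == 0 else inter / union


def screen_pass(query_desc: Descriptor, target_desc: Descriptor) -> bool:
    """True iff every query bit is present in the target (word-wise subset)."""
    if query_desc.version != target_desc.version:
        raise ValueError("dictionary version mismatch")
    return all((q & ~t) & _WORD_MASK == 0 for q, t in zip(query_desc.words, target_desc.words))


# ---------------------------------------------------------------------------
# dictionary serialization
# ---------------------------------------------------------------------------


def load_dictionary(path, version: str | None = None) -> FragmentDictionary:
    """Plain-text format: one ``SMILES<TAB>min_count`` per line, line order =
    bit order; ``#`` lines are comments, a ``#version:`` comment names the
    dictionary."""
    entries: list[tuple[str, int]] = []
    file_version = version
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#version:"):
                file_version = file_version or line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            smiles, _, count = line.partition("\t")
            entries.append((smiles.strip(), int(count) if count.strip() else 1))
    return FragmentDictionary(entries, file_version or "unversioned")


_default_cache: FragmentDictionary | None = None


def load_default_dictionary() -> FragmentDictionary:
    global _default_cache
    if _default_cache is None:
        ref = resources.files("wikichem").joinpath("data/fragments_v1.txt")
        with resources.as_file(ref) as path:
            _default_cache = load_dictionary(path)
    return _default_cache
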