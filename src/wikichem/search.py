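"""Structure index construction, JSON (de)serialization and the three search
modes: exact, substructure (fingerprint screen + graph-match confirm) and
Tanimoto similarity, with the ranking rules that keep an exact match on top.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

from .canonical import canonical_smiles
from .fingerprint import (
    Descriptor,
    FragmentDictionary,
    compute_descriptor,
    screen_pass,
    tanimoto,
)
from .match import DEFAULT_OPTIONS, MatchOptions, is_substructure
from .molgraph import (
    MolecularGraph,
    ParseIssue,
    molecular_formula,
    molecular_weight,
    parse_smiles,
)

__all__ = [
    "IndexRecord",
    "StructureIndex",
    "IndexError_",
    "SearchHit",
    "SearchResult",
    "build_index",
    "load_index",
    "save_index",
    "search_substructure",
    "search_similarity",
    "search_exact",
]


@dataclass(frozen=True)
class IndexRecord:
    structure: str  # canonical SMILES
    words: tuple[int, ...]  # 16 x uint32 descriptor
    mf: str  # Hill formula
    mw: float  # Daltons, 2 decimals
    page: str  # source page title
    stereo_stripped: str = ""  # canonical skeleton for near-duplicate reports

    def descriptor(self, version: str) -> Descriptor:
        return Descriptor(self.words, version)


@dataclass(frozen=True)
class IndexError_:
    """An input entry that could not be indexed, with its classified cause."""

    page: str
    smiles_raw: str
    issue: ParseIssue


@dataclass
class StructureIndex:
    dictionary_version: str
    built_at: str
    records: list[IndexRecord] = field(default_factory=list)
    errors: list[IndexError_] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SearchHit:
    record: IndexRecord
    score: float | None  # Tanimoto, similarity mode only
    mw_delta: float


@dataclass
class SearchResult:
    mode: str
    hits: list[SearchHit]

    def filter_pages(self, text: str) -> "SearchResult":
        """Case-insensitive substring filter on the page title, applied after
        ranking."""
        needle = text.lower()
        return SearchResult(
            self.mode, [h for h in self.hits if needle in h.record.page.lower()]
        )

    def top(self, n: int) -> "SearchResult":
        return SearchResult(self.mode, self.hits[:n])


def build_index(
    entries,
    dictionary: FragmentDictionary,
    *,
    built_at: str | None = None,
) -> StructureIndex:
    """entries: iterable of (smiles, page).  Unparseable entries are routed
    to the error list, never dropped silently; duplicate (page, canonical)
    pairs collapse to one record."""
    index = StructureIndex(
        dictionary_version=dictionary.version,
        built_at=built_at or time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )
    seen: set[tuple[str, str]] = set()
    for smiles, page in entries:
        if "\t" in page or "\n" in page:
            raise ValueError(f"page title contains forbidden whitespace: {page!r}")
        graph = parse_smiles(smiles)
        if isinstance(graph, ParseIssue):
            index.errors.append(IndexError_(page=page, smiles_raw=smiles, issue=graph))
            continue
        form = canonical_smiles(graph)
        key = (page, form.canonical_smiles)
        if key in seen:
            continue
        seen.add(key)
        desc = compute_descriptor(graph, dictionary)
        index.records.append(
            IndexRecord(
                structure=form.canonical_smiles,
                words=desc.words,
                mf=molecular_formula(graph),
                mw=molecular_weight(graph),
                page=page,
                stereo_stripped=form.stereo_stripped_smiles,
            )
        )
    return index


def save_index(index: StructureIndex, path) -> None:
    payload = {
        "header": {
            "dictionary_version": index.dictionary_version,
            "built_at": index.built_at,
            "count": index.count,
        },
        "records": [
            {
                "structure": r.structure,
                "words": list(r.words),
                "mf": r.mf,
                "mw": r.mw,
                "page": r.page,
                "stereo_stripped": r.stereo_stripped,
            }
            for r in index.records
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_index(path) -> StructureIndex:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    header = payload["header"]
    index = StructureIndex(
        dictionary_version=header["dictionary_version"], built_at=header["built_at"]
    )
    for r in payload["records"]:
        index.records.append(
            IndexRecord(
                structure=r["structure"],
                words=tuple(r["words"]),
                mf=r["mf"],
                mw=r["mw"],
                page=r["page"],
                stereo_stripped=r.get("stereo_stripped", r["structure"]),
            )
        )
    if len(index.records) != header["count"]:
        raise ValueError("index record count does not match header")
    return index


def _query_forms(query: MolecularGraph):
    form = canonical_smiles(query)
    return form, molecular_weight(query)


def search_substructure(
    query: MolecularGraph,
    index: StructureIndex,
    dictionary: FragmentDictionary,
    opts: MatchOptions = DEFAULT_OPTIONS,
) -> SearchResult:
    """Two-step search: fingerprint subset screen, then graph-match
    confirmation.  Hits sort by ascending |MW delta|, exact structural match
    first among ties, then page title."""
    if dictionary.version != index.dictionary_version:
        raise ValueError("index was built with a different fragment dictionary")
    q_desc = compute_descriptor(query, dictionary)
    form, q_mw = _query_forms(query)
    parsed_cache: dict[str, MolecularGraph] = {}
    hits: list[SearchHit] = []
    for rec in index.records:
        if not screen_pass(q_desc, rec.descriptor(dictionary.version)):
            continue
        target = parsed_cache.get(rec.structure)
        if target is None:
            target = parse_smiles(rec.structure)
            assert isinstance(target, MolecularGraph), rec.structure
            parsed_cache[rec.structure] = target
        if is_substructure(query, target, opts):
            hits.append(SearchHit(rec, None, round(abs(rec.mw - q_mw), 2)))
    hits.sort(
        key=lambda h: (
            h.mw_delta,
            h.record.structure != form.canonical_smiles,
            h.record.page,
        )
    )
    return SearchResult("sub", hits)


def search_similarity(
    query: MolecularGraph,
    index: StructureIndex,
    dictionary: FragmentDictionary,
) -> SearchResult:
    """Every record scored by Tanimoto; descending score, ties by ascending
    |MW delta| then page title; any record with the query's exact (stereo-
    aware canonical) structure is forced to the top."""
    if dictionary.version != index.dictionary_version:
        raise ValueError("index was built with a different fragment dictionary")
    q_desc = compute_descriptor(query, dictionary)
    form, q_mw = _query_forms(query)
    hits = [
        SearchHit(
            rec,
            tanimoto(q_desc, rec.descriptor(dictionary.version)),
            round(abs(rec.mw - q_mw), 2),
        )
        for rec in index.records
    ]
    hits.sort(
        key=lambda h: (
            h.record.structure != form.canonical_smiles,
            -(h.score or 0.0),
            h.mw_delta,
            h.record.page,
        )
    )
    return SearchResult("sim", hits)


def search_exact(query: MolecularGraph, index: StructureIndex) -> SearchResult:
    """Canonical-string equality; structures shared by several pages all
    come back, sorted by page title."""
    form, q_mw = _query_forms(query)
    hits = [
        SearchHit(rec, None, round(abs(rec.mw - q_mw), 2))
        for rec in index.records
        if rec.structure == form.canonical_smiles
    ]
    hits.sort(key=lambda h: h.record.page)
    return SearchResult("exact", hits)
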