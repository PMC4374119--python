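"""Chembox / Drugbox harvesting from raw wiki markup, the multi-SMILES
consolidation policy, duplicate detection across pages, cross-reference
comparison and the SMILES list export.

The template scanner is deliberately small: it brace-matches ``{{...}}``
regions (nested sections included), splits parameters at top level and keeps
every parameter named ``SMILES`` with an optional numeric suffix.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .canonical import canonical_smiles
from .molgraph import MolecularGraph, ParseIssue, molecular_formula, parse_smiles
from .search import IndexRecord, StructureIndex

__all__ = [
    "WikiPage",
    "ChemEntry",
    "ConsolidationReport",
    "DuplicateGroup",
    "DuplicateReport",
    "Verdict",
    "CrossRefVerdict",
    "extract_entries",
    "extract_entries_report",
    "consolidate",
    "find_duplicates",
    "classify_crossref",
    "export_smiles_list",
    "read_pages_jsonl",
    "read_pages_dir",
    "write_pages_jsonl",
]


@dataclass(frozen=True)
class WikiPage:
    title: str
    wikitext: str

    def __post_init__(self):
        if not self.title:
            raise ValueError("page title must be non-empty")


@dataclass(frozen=True)
class ChemEntry:
    page: str
    smiles_raw: str
    smiles_field: str  # e.g. SMILES, SMILES1, SMILES2
    template: str  # 'chembox' | 'drugbox'


_SMILES_PARAM = re.compile(r"^smiles[0-9]*$", re.IGNORECASE)
_NOWIKI = re.compile(r"</?nowiki\s*/?>", re.IGNORECASE)
_COMMENT = re.compile(r"<!--.*?-->", re.DOTALL)


def _find_templates(text: str) -> tuple[list[tuple[int, int]], bool]:
    """Spans of top-level ``{{...}}`` regions; the flag reports unbalanced
    braces."""
    spans = []
    malformed = False
    i = 0
    while True:
        start = text.find("{{", i)
        if start < 0:
            break
        depth = 0
        j = start
        end = -1
        while j < len(text) - 1:
            two = text[j : j + 2]
            if two == "{{":
                depth += 1
                j += 2
            elif two == "}}":
                depth -= 1
                j += 2
                if depth == 0:
                    end = j
                    break
            else:
                j += 1
        if end < 0:
            malformed = True
            break
        spans.append((start, end))
        i = end
    return spans, malformed


def _split_params(body: str) -> list[str]:
    """Split a template body on '|' at nesting depth zero (both {{ }} and
    [[ ]] nesting suppressed)."""
    parts: list[str] = []
    depth = 0
    buf: list[str] = []
    i = 0
    while i < len(body):
        two = body[i : i + 2]
        if two in ("{{", "[["):
            depth += 1
            buf.append(two)
            i += 2
        elif two in ("}}", "]]"):
            depth -= 1
            buf.append(two)
            i += 2
        elif body[i] == "|" and depth == 0:
            parts.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(body[i])
            i += 1
    parts.append("".join(buf))
    return parts


def _clean_value(value: str) -> str:
    value = _COMMENT.sub("", value)
    value = _NOWIKI.sub("", value)
    value = value.replace("{{!}}", "|")
    return value.strip()


def _collect_smiles_params(template_text: str, out: list[tuple[str, str]]) -> None:
    """Recursively collect (field name, value) pairs for SMILES-like
    parameters from a ``{{...}}`` chunk and its nested section templates."""
    body = template_text[2:-2]
    parts = _split_params(body)
    for part in parts[1:]:
        name, eq, value = part.partition("=")
        if eq:
            pname = name.strip()
            if _SMILES_PARAM.match(pname):
                cleaned = _clean_value(value)
                if cleaned:
                    out.append((pname, cleaned))
        # recurse into nested templates in the raw part (section sub-boxes)
        for s, e in _find_templates(part)[0]:
            _collect_smiles_params(part[s:e], out)


def extract_entries_report(page: WikiPage) -> tuple[list[ChemEntry], list[str]]:
    """Entries plus page-level warnings (e.g. unbalanced template braces)."""
    warnings: list[str] = []
    spans, malformed = _find_templates(page.wikitext)
    if malformed:
        warnings.append("unbalanced template braces")
    entries: list[ChemEntry] = []
    for s, e in spans:
        chunk = page.wikitext[s:e]
        head = _split_params(chunk[2:-2])[0].strip().lower()
        if head.startswith("chembox"):
            template = "chembox"
        elif head.startswith("infobox drug") or head.startswith("drugbox"):
            template = "drugbox"
        else:
            continue
        found: list[tuple[str, str]] = []
        _collect_smiles_params(chunk, found)
        for field_name, value in found:
            entries.append(
                ChemEntry(
                    page=page.title,
                    smiles_raw=value,
                    smiles_field=field_name,
                    template=template,
                )
            )
    return entries, warnings


def extract_entries(page: WikiPage) -> list[ChemEntry]:
    """Every SMILES-bearing parameter of every chemical infobox on the page,
    in document order.  Pages without any SMILES yield an empty list."""
    return extract_entries_report(page)[0]


@dataclass
class ConsolidationReport:
    """Per-page outcome of the multi-SMILES policy: within a page, entries
    encoding exactly the same (stereo-aware) structure keep only the first;
    distinct structures each stay; unparseable entries go to the error rows."""

    kept: list[ChemEntry] = field(default_factory=list)
    kept_structures: list[str] = field(default_factory=list)  # canonical, 1:1 with kept
    errors: list[tuple[ChemEntry, ParseIssue]] = field(default_factory=list)
    dropped_duplicates: list[ChemEntry] = field(default_factory=list)


def consolidate(entries: list[ChemEntry]) -> ConsolidationReport:
    report = ConsolidationReport()
    seen: set[str] = set()
    for entry in entries:
        graph = parse_smiles(entry.smiles_raw)
        if isinstance(graph, ParseIssue):
            report.errors.append((entry, graph))
            continue
        canon = canonical_smiles(graph).canonical_smiles
        if canon in seen:
            report.dropped_duplicates.append(entry)
            continue
        seen.add(canon)
        report.kept.append(entry)
        report.kept_structures.append(canon)
    return report


@dataclass(frozen=True)
class DuplicateGroup:
    structure: str
    records: tuple[IndexRecord, ...]
    stereo_stripped: bool  # True when the group only merges after stripping


@dataclass
class DuplicateReport:
    exact: list[DuplicateGroup] = field(default_factory=list)
    stripped: list[DuplicateGroup] = field(default_factory=list)


def find_duplicates(index: StructureIndex) -> DuplicateReport:
    """Cross-page duplicates: groups of records sharing one stereo-aware
    canonical structure, and a second listing on stereo-stripped skeletons
    flagging groups that only merge once stereo is ignored."""
    report = DuplicateReport()
    by_structure: dict[str, list[IndexRecord]] = {}
    for rec in index.records:
        by_structure.setdefault(rec.structure, []).append(rec)
    exact_keys = set()
    for structure in sorted(by_structure):
        recs = by_structure[structure]
        if len(recs) >= 2 and len({r.page for r in recs}) >= 2:
            exact_keys.add(structure)
            report.exact.append(
                DuplicateGroup(structure, tuple(sorted(recs, key=lambda r: r.page)), False)
            )
    by_skeleton: dict[str, list[IndexRecord]] = {}
    for rec in index.records:
        by_skeleton.setdefault(rec.stereo_stripped or rec.structure, []).append(rec)
    for skeleton in sorted(by_skeleton):
        recs = by_skeleton[skeleton]
        if len(recs) >= 2 and len({r.page for r in recs}) >= 2:
            merged_only = len({r.structure for r in recs}) > 1
            report.stripped.append(
                DuplicateGroup(
                    skeleton, tuple(sorted(recs, key=lambda r: r.page)), merged_only
                )
            )
    return report


class Verdict(str, Enum):
    MATCH = "MATCH"
    SAME_FORMULA_DIFFERENT_STRUCTURE = "SAME_FORMULA_DIFFERENT_STRUCTURE"
    FORMULA_MISMATCH = "FORMULA_MISMATCH"
    SKIPPED = "SKIPPED"  # reference did not parse


@dataclass(frozen=True)
class CrossRefVerdict:
    verdict: Verdict
    note: str


def classify_crossref(wiki_smiles: str, reference_smiles: str) -> CrossRefVerdict:
    """Compare a harvested structure with an external reference: identical
    canonical forms are a MATCH; same Hill formula but different structure
    flags a tautomer / positional-isomer candidate; else the formulas simply
    disagree."""
    wiki = parse_smiles(wiki_smiles)
    if isinstance(wiki, ParseIssue):
        raise ValueError(f"wiki SMILES does not parse: {wiki}")
    ref = parse_smiles(reference_smiles)
    if isinstance(ref, ParseIssue):
        return CrossRefVerdict(Verdict.SKIPPED, f"reference does not parse: {ref}")
    if canonical_smiles(wiki).canonical_smiles == canonical_smiles(ref).canonical_smiles:
        return CrossRefVerdict(Verdict.MATCH, "identical canonical structures")
    wf, rf = molecular_formula(wiki), molecular_formula(ref)
    if wf == rf:
        return CrossRefVerdict(
            Verdict.SAME_FORMULA_DIFFERENT_STRUCTURE,
            f"both {wf}: tautomer or positional isomer candidate",
        )
    return CrossRefVerdict(Verdict.FORMULA_MISMATCH, f"{wf} vs {rf}")


def export_smiles_list(index: StructureIndex, path) -> None:
    """One ``canonical SMILES<TAB>page title`` line per record, ordered by
    page title (records of one page keep index order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in sorted(index.records, key=lambda r: r.page):
            fh.write(f"{rec.structure}\t{rec.page}\n")


# ---------------------------------------------------------------------------
# page input formats
# ---------------------------------------------------------------------------


def read_pages_jsonl(path) -> list[WikiPage]:
    pages = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            pages.append(WikiPage(title=obj["title"], wikitext=obj["wikitext"]))
    return pages


def read_pages_dir(path) -> list[WikiPage]:
    pages = []
    for fp in sorted(Path(path).glob("*.wiki")):
        pages.append(WikiPage(title=fp.stem, wikitext=fp.read_text(encoding="utf-8")))
    return pages


def write_pages_jsonl(pages: list[WikiPage], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for page in pages:
            fh.write(json.dumps({"title": page.title, "wikitext": page.wikitext}) + "\n")
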