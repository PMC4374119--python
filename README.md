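# wikichem

A library + CLI that harvests SMILES strings from wiki chemistry infoboxes
(Chembox / Infobox drug markup), validates and canonicalizes them, builds a
fingerprint-indexed JSON structure database, and answers exact, substructure
and similarity queries — plus the curation analyses that go with maintaining
such a collection (SMILES error browser with repair suggestions, cross-page
duplicate detection, external cross-reference comparison, scaffold frequency
tables).

Everything is self-contained pure Python: its own SMILES parser and
kekulizer, Morgan-style canonicalizer, VF2-style subgraph matcher and a
512-bit fragment-dictionary fingerprint (16 × uint32 words) used both for
Tanimoto similarity and as the sound pre-screen of the two-step substructure
search. RDKit appears only as an independent oracle in the test suite.

## Library tour

| module                 | what it does |
|------------------------|--------------|
| `wikichem.molgraph`    | SMILES tokenizer/parser, kekulization (perfect matching over double-bond-requiring aromatic atoms), hydrogen/valence model, error taxonomy (`PYRROLE_NITROGEN`, `UNCLOSED_RING`, ...) with pyrrole `n` → `[nH]` repair, Hill formula, molecular weight |
| `wikichem.canonical`   | canonical atom ranks, canonical (stereo-aware) SMILES, stereo-stripped variant, structural identity |
| `wikichem.match`       | subgraph isomorphism (`is_substructure`, `count_matches`) with aromatic/charge strictness options |
| `wikichem.fingerprint` | 512-fragment dictionary (`data/fragments_v1.txt`, one `SMILES<TAB>min_count` per line, line order = bit order), descriptor computation, Tanimoto, subset screen |
| `wikichem.search`      | JSON index build/load/save; exact / substructure / similarity search with the exact-match-first ranking rules |
| `wikichem.wikiparse`   | infobox template scanning, multi-SMILES consolidation, duplicate groups, cross-reference verdicts, SMILES list export |
| `wikichem.scaffold`    | Murcko-style scaffolds and top-N frequency reports |
| `wikichem.synthgen`    | seeded random molecules, SMILES rewrites, connected subgraph queries, synthetic wiki corpora with ground-truth manifests |

## CLI

```bash
wikichem --version

# generate a synthetic corpus + manifest, then run the pipeline on it
wikichem synth --seed 42 --pages 200 -o corpus.jsonl --manifest manifest.json
wikichem extract corpus.jsonl -o index.json --errors errors.tsv

# search (modes: exact | sub | sim)
wikichem search --mode sub  --query 'c1ccccc1' --index index.json
wikichem search --mode sim  --query 'CCO' --index index.json --top 10 --format json
wikichem search --mode exact --query 'OCC' --index index.json --filter ethanol

# curation reports
wikichem dedupe index.json
wikichem scaffolds index.json --top 250
wikichem export-smiles index.json -o smiles.txt
wikichem validate smiles.txt          # exit 2 when any line fails
```

Exit codes: 0 success, 1 usage error, 2 data errors found (`validate`),
3 I/O failure. Inputs for `extract` are line-delimited JSON records of
`{"title": ..., "wikitext": ...}` or a directory of `.wiki` text files.

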