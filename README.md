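# refaudit

Audit reference-sequence availability per organism per DNA-barcode locus
across pluggable record sources — live NCBI Nucleotide, live BOLD, local
CRUX-style reference databases, and offline file-backed snapshots.

Given a CSV of organism names and barcode loci, `refaudit` builds:

- a **Coverage Matrix** (organisms × barcode groups, one sequence count per
  cell; zeros expose reference gaps, failed searches render as `NA`, never 0);
- a **Results Summary** (per-barcode sequence counts, percentage share,
  organisms covered / missing);
- **deduplicated per-barcode FASTA bundles** (BOLD records whose GenBank
  cross-reference is already in NCBI can be removed before download);
- **exportable search statements** that can be pasted into the NCBI web
  interface to replay and validate every query.

When a species has zero records, the search falls back up the taxonomy
backbone (genus → family → order). A species that is missing from the
backbone is reported as an all-zero row with an `UNREGISTERED` flag and is
*not* searched at broader ranks. Name corrections are appended to the
user's organism list, never replacing the original input.

## Test

```sh
python -m pytest -q tests/
```

The suite is fully offline: live NCBI/BOLD access is exercised through
injected transports, and everything else runs against deterministic
synthetic snapshots with planted coverage structure (`refaudit.synth`).

## CLI

```sh
# generate a deterministic demo snapshot (plus paired NCBI/BOLD snapshots)
refaudit synth --out demo_snap --seed 1 --pair

# write a query CSV (header: organism,barcode; columns independently ragged)
printf 'organism,barcode\nXenopus laevis,CO1\nAquarana catesbeiana,16S\n' > query.csv

# audit: coverage matrix + summary + search statements + run log
refaudit audit --db snapshot --snapshot demo_snap --query query.csv --out out/

# fetch: per-barcode FASTA zip, with filters and NCBI-duplicate removal
refaudit fetch --db snapshot --snapshot demo_snap/bold --query query.csv \
    --out out/ --min-len 100 --max-len 2000 \
    --dedupe-against-ncbi demo_snap/ncbi

# standalone dedupe of a BOLD-like snapshot against an NCBI-like one
refaudit dedupe --bold-snapshot demo_snap/bold --ncbi-snapshot demo_snap/ncbi --out deduped/
```

`--db crux` audits a local CRUX directory (`<barcode>.fasta` +
`<barcode>_taxonomy.txt` per locus) and always reports every subdatabase
present, zeros included. `--db ncbi` requires `--email` (E-utilities
policy); requests are rate-limited, retried with exponential backoff, and
cached on disk. Exit codes: 0 success, 1 fatal, 2 partial (some cells
failed, rendered `NA`), 3 empty fetch result.

Barcode groups (CO1, 16S, 18S, 12S, FITS, PITS, trnL plus synonym marker
spellings) ship in `src/refaudit/data/barcode_groups.csv`; matching is
case-insensitive exact match, never substring.

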