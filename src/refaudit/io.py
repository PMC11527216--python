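"""Readers/writers for the query CSV template and every result artifact.

All writers are deterministic: fixed field order, LF endings, and no
timestamps inside the content (the zip manifest carries the timestamp so
the archive itself stays byte-reproducible).
"""

from __future__ import annotations

import csv
import io as _io
import warnings as _warnings
import zipfile
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .coverage import (
    CoverageMatrix,
    FallbackRow,
    SummaryRow,
    SummaryTable,
)
from .errors import EmptyInputError, MalformedCSVError
from .model import SequenceRecord

__all__ = [
    "read_query_csv",
    "write_query_csv_template",
    "write_fasta_zip",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_summary_csv",
    "read_summary_csv",
    "write_tally_csv",
    "read_tally_csv",
]

QUERY_HEADER = ["organism", "barcode"]
FASTA_WRAP = 80
# Fixed zip entry timestamp keeps archives byte-identical across runs.
_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


# ---------------------------------------------------------------------------
# Query CSV


def read_query_csv(path) -> tuple[list[str], list[str]]:
    """Parse the ``organism,barcode`` template.

    The two columns are independently ragged — blank cells are skipped, so
    11 organisms can sit beside 2 barcodes. Order is preserved; duplicates
    are removed with a warning. An empty barcode column means "use all
    default groups" (a CRUX audit always covers all its subdatabases
    regardless). At least one organism is required.
    """
    p = Path(path)
    if not p.is_file():
        raise MalformedCSVError(f"query CSV not found: {p}")
    organisms: list[str] = []
    barcodes: list[str] = []
    seen_org: set[str] = set()
    seen_bc: set[str] = set()
    with open(p, newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedCSVError("query CSV is empty (missing header row)")
        header = [h.strip().lower() for h in header]
        if header[: len(QUERY_HEADER)] != QUERY_HEADER:
            raise MalformedCSVError(
                f"row 1: header must start with {','.join(QUERY_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for rownum, row in enumerate(reader, start=2):
            org = row[0].strip() if len(row) > 0 else ""
            bc = row[1].strip() if len(row) > 1 else ""
            if org:
                key = org.casefold()
                if key in seen_org:
                    _warnings.warn(
                        f"row {rownum}: duplicate organism {org!r} ignored",
                        stacklevel=2,
                    )
                else:
                    seen_org.add(key)
                    organisms.append(org)
            if bc:
                key = bc.casefold()
                if key in seen_bc:
                    _warnings.warn(
                        f"row {rownum}: duplicate barcode {bc!r} ignored",
                        stacklevel=2,
                    )
                else:
                    seen_bc.add(key)
                    barcodes.append(bc)
    if not organisms:
        raise MalformedCSVError("query CSV contains zero organisms")
    return organisms, barcodes


def write_query_csv_template(path, organisms: Iterable[str] = (), barcodes: Iterable[str] = ()):
    orgs = list(organisms)
    bcs = list(barcodes)
    lines = [",".join(QUERY_HEADER)]
    for i in range(max(len(orgs), len(bcs), 1)):
        o = orgs[i] if i < len(orgs) else ""
        b = bcs[i] if i < len(bcs) else ""
        lines.append(f"{o},{b}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA zip bundle


def _wrap(seq: str, width: int = FASTA_WRAP) -> list[str]:
    return [seq[i : i + width] for i in range(0, len(seq), width)]


def _fasta_text(records: list[SequenceRecord]) -> str:
    blocks = []
    for rec in sorted(records, key=lambda r: r.accession):
        if rec.sequence is None:
            raise ValueError(f"record {rec.accession} carries no sequence text")
        lines = [f">{rec.accession} {rec.organism} {rec.marker} {rec.source_db.value}"]
        lines.extend(_wrap(rec.sequence))
        blocks.append("\n".join(lines))
    # one blank line between records keeps files valid for common aligners
    return "\n\n".join(blocks) + "\n"


def write_fasta_zip(
    records_by_barcode: Mapping[str, list[SequenceRecord]], path
) -> dict:
    """Write one ``<barcode>.fasta`` per non-empty barcode into a zip.

    Record headers are ``><accession> <organism> <marker> <source_db>``,
    sequences wrapped at 80 columns, records accession-sorted, one blank
    line between records. Returns a manifest of (barcode, n_records,
    file_size) entries; raises EMPTY_INPUT (no zip written) when there are
    no records at all.
    """
    non_empty = {b: recs for b, recs in records_by_barcode.items() if recs}
    if not non_empty:
        raise EmptyInputError("no records to bundle; zip not written")
    entries = []
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for barcode in sorted(non_empty):
            text = _fasta_text(non_empty[barcode])
            info = zipfile.ZipInfo(f"{barcode}.fasta", date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            payload = text.encode("utf-8")
            zf.writestr(info, payload)
            entries.append(
                {
                    "barcode": barcode,
                    "n_records": len(non_empty[barcode]),
                    "file_size": len(payload),
                }
            )
    return {"files": entries, "n_total": sum(e["n_records"] for e in entries)}


# ---------------------------------------------------------------------------
# Coverage matrix CSV


def _flags_cell(flags: set[str]) -> str:
    return ";".join(sorted(flags))


def write_matrix_csv(cm: CoverageMatrix, path) -> None:
    """First column organism (fallback rows as ``<rank>: <taxon>`` beneath
    their organism), one column per barcode, flags column last. Absent
    cells render as NA, never 0."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["organism"] + list(cm.barcodes) + ["flags"])
    fallbacks_by_org: dict[str, list[FallbackRow]] = {}
    for fb in cm.fallback_rows:
        fallbacks_by_org.setdefault(fb.organism, []).append(fb)
    for org in cm.organisms:
        row = [org]
        for b in cm.barcodes:
            v = cm.cells[(org, b)]
            row.append("NA" if v is None else str(v))
        row.append(_flags_cell(cm.flags.get(org, set())))
        writer.writerow(row)
        for fb in fallbacks_by_org.get(org, []):
            frow = [f"{fb.rank}: {fb.taxon}"]
            for b in cm.barcodes:
                frow.append("" if b not in fb.counts else str(fb.counts[b]))
            frow.append("")
            writer.writerow(frow)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_matrix_csv(path) -> CoverageMatrix:
    """Inverse of :func:`write_matrix_csv` (for round-trip verification)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        barcodes = header[1:-1]
        organisms: list[str] = []
        cells: dict[tuple[str, str], Optional[int]] = {}
        fallback_rows: list[FallbackRow] = []
        flags: dict[str, set[str]] = {}
        current_org: Optional[str] = None
        for row in reader:
            label = row[0]
            if ": " in label and label.split(": ")[0] in (
                "genus",
                "family",
                "order",
                "class",
            ):
                rank, taxon = label.split(": ", 1)
                counts = {
                    b: int(v) for b, v in zip(barcodes, row[1:-1]) if v not in ("", "NA")
                }
                fallback_rows.append(
                    FallbackRow(current_org or "", rank, taxon, counts)
                )
                continue
            current_org = label
            organisms.append(label)
            for b, v in zip(barcodes, row[1:-1]):
                cells[(label, b)] = None if v == "NA" else int(v)
            flags[label] = set(row[-1].split(";")) if row[-1] else set()
    return CoverageMatrix(
        organisms=organisms,
        barcodes=barcodes,
        cells=cells,
        fallback_rows=fallback_rows,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Summary CSV


SUMMARY_HEADER = [
    "barcode",
    "n_sequences",
    "pct_of_total",
    "n_organisms_covered",
    "n_organisms_missing",
]


def write_summary_csv(st: SummaryTable, path) -> None:
    """Four data columns in display order plus a totals footer row."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(SUMMARY_HEADER)
    for row in st.rows:
        writer.writerow(
            [
                row.barcode,
                row.n_sequences,
                f"{row.pct_of_total:.1f}",
                row.n_organisms_covered,
                row.n_organisms_missing,
            ]
        )
    writer.writerow(
        ["TOTAL", st.total_sequences, "", st.total_organisms_detected, st.n_organisms]
    )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_summary_csv(path) -> SummaryTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != SUMMARY_HEADER:
            raise MalformedCSVError(f"unexpected summary header: {header}")
        rows: list[SummaryRow] = []
        totals: Optional[tuple[int, int, int]] = None
        for row in reader:
            if row[0] == "TOTAL":
                totals = (int(row[1]), int(row[3]), int(row[4]))
                continue
            rows.append(
                SummaryRow(
                    barcode=row[0],
                    n_sequences=int(row[1]),
                    pct_of_total=float(row[2]),
                    n_organisms_covered=int(row[3]),
                    n_organisms_missing=int(row[4]),
                )
            )
    if totals is None:
        raise MalformedCSVError("summary CSV lacks a TOTAL footer row")
    return SummaryTable(
        rows=rows,
        total_sequences=totals[0],
        total_organisms_detected=totals[1],
        n_organisms=totals[2],
    )


# ---------------------------------------------------------------------------
# Country tally CSV


TALLY_HEADER = ["country", "n_records", "n_organisms"]


def write_tally_csv(tally: list[tuple[str, int, int]], path) -> None:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(TALLY_HEADER)
    for country, n_records, n_organisms in tally:
        writer.writerow([country, n_records, n_organisms])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_tally_csv(path) -> list[tuple[str, int, int]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != TALLY_HEADER:
            raise MalformedCSVError(f"unexpected tally header: {header}")
        return [(row[0], int(row[1]), int(row[2])) for row in reader]
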