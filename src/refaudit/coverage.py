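"""Coverage Matrix and Results Summary construction, record-level filters,
cross-database deduplication and country tallies.

The Coverage Matrix is the central artifact: one row per input organism,
one column per barcode group, each cell the number of sequences found for
that pair. Zeros expose reference gaps; a failed search is an *absent*
cell (rendered NA), never a zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

from .errors import SourceUnavailableError
from .model import (
    BarcodeGroup,
    FilterSpec,
    OrganismQuery,
    SequenceRecord,
    normalize_name,
)
from .sources.base import RecordSource, UNSPECIFIED_COUNTRY
from .taxonomy import Backbone, fallback_search

__all__ = [
    "FallbackRow",
    "CoverageMatrix",
    "SummaryRow",
    "SummaryTable",
    "build_coverage_matrix",
    "summarize",
    "apply_length_filter",
    "apply_country_filter",
    "dedupe_cross_db",
    "country_tally",
    "strip_version",
]

FLAG_UNREGISTERED = "UNREGISTERED"
FLAG_CORRECTED = "CORRECTED"
FLAG_SOURCE_ERROR = "SOURCE_ERROR"


@dataclass
class FallbackRow:
    """Ancestor-rank counts displayed beneath an all-zero species row."""

    organism: str  # the input organism this row belongs to
    rank: str
    taxon: str
    counts: dict[str, int] = field(default_factory=dict)  # barcode -> count


@dataclass
class CoverageMatrix:
    organisms: list[str]  # input order
    barcodes: list[str]  # canonical names, input order
    cells: dict[tuple[str, str], Optional[int]]  # None = source error (NA)
    fallback_rows: list[FallbackRow] = field(default_factory=list)
    flags: dict[str, set[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    query_log: list[str] = field(default_factory=list)

    def cell(self, organism: str, barcode: str) -> Optional[int]:
        return self.cells[(organism, barcode)]


@dataclass
class SummaryRow:
    barcode: str
    n_sequences: int
    pct_of_total: float  # half-up, 1 decimal, computed from raw counts
    n_organisms_covered: int
    n_organisms_missing: int


@dataclass
class SummaryTable:
    rows: list[SummaryRow]
    total_sequences: int
    total_organisms_detected: int
    n_organisms: int


def _round_half_up_1dp(value: float) -> float:
    return float(Decimal(str(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def build_coverage_matrix(
    src: RecordSource,
    queries: list[OrganismQuery],
    groups: list[BarcodeGroup],
    filters: Optional[FilterSpec] = None,
    enable_fallback: bool = False,
    backbone: Optional[Backbone] = None,
) -> CoverageMatrix:
    """Count every organism × barcode pair; optionally fall back by rank.

    Cell counts pool the original name with its appended corrections. A
    SOURCE_UNAVAILABLE on any cell flags the organism SOURCE_ERROR and
    leaves the cell absent (NA) rather than zero. With fallback enabled, a
    zero cell triggers an ancestor-rank search whose results land in
    ``fallback_rows``; an organism missing from the backbone gets the
    UNREGISTERED flag and an all-zero row with no ancestor queries.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    if not groups:
        raise ValueError("groups must be non-empty")
    organisms = [q.input_name for q in queries]
    barcodes = [g.canonical for g in groups]
    cells: dict[tuple[str, str], Optional[int]] = {}
    flags: dict[str, set[str]] = {o: set() for o in organisms}
    fallback_rows: list[FallbackRow] = []
    warnings: list[str] = []
    query_log: list[str] = []

    for oq in queries:
        if oq.corrected:
            flags[oq.input_name].add(FLAG_CORRECTED)
        row_fallbacks: dict[tuple[str, str], FallbackRow] = {}
        for group in groups:
            key = (oq.input_name, group.canonical)
            if enable_fallback and backbone is not None:
                try:
                    result = fallback_search(src, oq, group, backbone, filters)
                except SourceUnavailableError as exc:
                    cells[key] = None
                    flags[oq.input_name].add(FLAG_SOURCE_ERROR)
                    warnings.append(f"{oq.input_name} × {group.canonical}: {exc}")
                    continue
                cells[key] = result.species_count
                query_log.extend(result.query_log)
                warnings.extend(result.warnings)
                if result.unregistered:
                    flags[oq.input_name].add(FLAG_UNREGISTERED)
                for rank, taxon, n in result.entries[1:]:
                    fb = row_fallbacks.setdefault(
                        (rank, taxon), FallbackRow(oq.input_name, rank, taxon)
                    )
                    fb.counts[group.canonical] = n
            else:
                try:
                    total = 0
                    for name in oq.resolved_names:
                        n = src.count_matches(name, group, filters)
                        query_log.append(
                            f"species {name!r} [{group.canonical}] -> {n}"
                        )
                        total += n
                    cells[key] = total
                except SourceUnavailableError as exc:
                    cells[key] = None
                    flags[oq.input_name].add(FLAG_SOURCE_ERROR)
                    warnings.append(f"{oq.input_name} × {group.canonical}: {exc}")
        fallback_rows.extend(row_fallbacks.values())

    return CoverageMatrix(
        organisms=organisms,
        barcodes=barcodes,
        cells=cells,
        fallback_rows=fallback_rows,
        flags=flags,
        warnings=warnings,
        query_log=query_log,
    )


def summarize(cm: CoverageMatrix) -> SummaryTable:
    """Per-barcode totals over species-rank cells only.

    Fallback rows are deliberately excluded: mixing ranks would double-count
    a record under both its species and its genus. Percentages are half-up
    rounded to one decimal but computed from the raw counts; an all-zero
    matrix reports 0.0 everywhere. Absent (NA) cells contribute nothing and
    do not count as coverage.
    """
    if not cm.barcodes:
        raise ValueError("coverage matrix has no barcodes")
    per_barcode: dict[str, int] = {}
    covered: dict[str, int] = {}
    for b in cm.barcodes:
        values = [cm.cells[(o, b)] for o in cm.organisms]
        per_barcode[b] = sum(v for v in values if v is not None)
        covered[b] = sum(1 for v in values if v is not None and v > 0)
    total = sum(per_barcode.values())
    rows = []
    for b in cm.barcodes:
        pct = _round_half_up_1dp(100.0 * per_barcode[b] / total) if total > 0 else 0.0
        rows.append(
            SummaryRow(
                barcode=b,
                n_sequences=per_barcode[b],
                pct_of_total=pct,
                n_organisms_covered=covered[b],
                n_organisms_missing=len(cm.organisms) - covered[b],
            )
        )
    detected = sum(
        1
        for o in cm.organisms
        if any(
            cm.cells[(o, b)] is not None and cm.cells[(o, b)] > 0 for b in cm.barcodes
        )
    )
    return SummaryTable(
        rows=rows,
        total_sequences=total,
        total_organisms_detected=detected,
        n_organisms=len(cm.organisms),
    )


def apply_length_filter(
    recs: Iterable[SequenceRecord],
    min_length: Optional[int] = None,
    max_length: Optional[int] = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Keep records with min ≤ seq_length ≤ max (inclusive bounds).

    Returns (kept, dropped). With no bounds this is the identity. Records
    with absent seq_length are dropped (and reported via ``dropped``) only
    when a bound is active — incomplete metadata must not silently vanish
    otherwise.
    """
    if min_length is not None and max_length is not None and min_length > max_length:
        raise ValueError("min_length > max_length")
    if min_length is None and max_length is None:
        return list(recs), []
    kept: list[SequenceRecord] = []
    dropped: list[SequenceRecord] = []
    for rec in recs:
        if rec.seq_length is None:
            dropped.append(rec)
        elif min_length is not None and rec.seq_length < min_length:
            dropped.append(rec)
        elif max_length is not None and rec.seq_length > max_length:
            dropped.append(rec)
        else:
            kept.append(rec)
    return kept, dropped


def apply_country_filter(
    recs: Iterable[SequenceRecord], countries: Iterable[str]
) -> list[SequenceRecord]:
    """Keep records whose country (trimmed, case-insensitive) is wanted.

    Records with absent country metadata match only the reserved name
    "Unspecified". An empty country set keeps nothing.
    """
    wanted = {normalize_name(c) for c in countries}
    out = []
    for rec in recs:
        country = rec.country.strip() if rec.country else UNSPECIFIED_COUNTRY
        if normalize_name(country) in wanted:
            out.append(rec)
    return out


def strip_version(accession: str) -> str:
    """Drop a trailing .N version suffix (BOLD xrefs and NCBI ids disagree)."""
    head, dot, tail = accession.rpartition(".")
    if dot and tail.isdigit():
        return head
    return accession


def dedupe_cross_db(
    bold_recs: Iterable[SequenceRecord], ncbi_accession_set: set[str]
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split BOLD records into (kept, removed) against an NCBI accession set.

    A record is removed iff its GenBank cross-reference — version-stripped —
    is present in the (already version-stripped) NCBI set. Records without
    a cross-reference are always kept. Input order is preserved on both
    sides and the two lists partition the input.
    """
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    for rec in bold_recs:
        if rec.genbank_xref is not None and strip_version(rec.genbank_xref) in ncbi_accession_set:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def country_tally(
    recs: Iterable[SequenceRecord],
) -> list[tuple[str, int, int]]:
    """(country, n_records, n_organisms) rows, n_records descending then name.

    Absent countries pool under "Unspecified". Σ n_records equals the input
    size.
    """
    counts: dict[str, int] = {}
    organisms: dict[str, set[str]] = {}
    for rec in recs:
        country = rec.country.strip() if rec.country else UNSPECIFIED_COUNTRY
        counts[country] = counts.get(country, 0) + 1
        organisms.setdefault(country, set()).add(normalize_name(rec.organism))
    return sorted(
        ((c, n, len(organisms[c])) for c, n in counts.items()),
        key=lambda row: (-row[1], row[0]),
    )
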