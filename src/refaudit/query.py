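"""Deterministic construction of database query statements.

Every builder is a pure function: equal inputs yield byte-identical
statement text, so exported statements can be replayed against the
database's own web interface to validate results.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional

from .errors import InvalidNameError
from .model import BarcodeGroup, FilterSpec, SearchStatement, SourceDB

__all__ = [
    "QueryMode",
    "build_entrez_term",
    "build_bold_taxon_query",
    "export_search_statements",
    "term_is_balanced",
    "SLEN_MIN_SENTINEL",
    "SLEN_MAX_SENTINEL",
]

# NCBI has no one-sided [SLEN] range; a missing bound is filled with these.
SLEN_MIN_SENTINEL = 1
SLEN_MAX_SENTINEL = 99999999


class QueryMode(enum.Enum):
    """FIELDED targets [ORGN]/[GENE] metadata fields; ALL_FIELDS is the
    looser fallback for entries with incomplete metadata."""

    FIELDED = "fielded"
    ALL_FIELDS = "all_fields"


def _check_name(name: str) -> None:
    if not name or not name.strip():
        raise InvalidNameError("organism/taxon name must be non-empty")
    # NCBI term syntax has no portable quote escape: fail loudly instead of
    # emitting a silently corrupted query.
    if '"' in name:
        raise InvalidNameError(f"name contains a double quote: {name!r}")


def build_entrez_term(
    organism: str,
    group: BarcodeGroup,
    mode: QueryMode = QueryMode.FIELDED,
    filters: Optional[FilterSpec] = None,
) -> SearchStatement:
    """Build the Entrez term for one organism × barcode group.

    FIELDED mode serializes as
    ``("<organism>"[ORGN]) AND ("<syn1>"[GENE] OR ...)``; ALL_FIELDS swaps
    every field tag for ``[All Fields]``. Synonyms are OR-ed inside one
    statement (one round-trip per pair; counts match union semantics).
    Length bounds append NCBI's range syntax ``("min"[SLEN] : "max"[SLEN])``.
    """
    _check_name(organism)
    if mode is QueryMode.FIELDED:
        org_tag, gene_tag = "[ORGN]", "[GENE]"
    else:
        org_tag = gene_tag = "[All Fields]"
    gene_clause = " OR ".join(f'"{s}"{gene_tag}' for s in group.synonyms)
    text = f'("{organism}"{org_tag}) AND ({gene_clause})'
    if filters is not None and filters.has_length_filter:
        lo = filters.min_length if filters.min_length is not None else SLEN_MIN_SENTINEL
        hi = filters.max_length if filters.max_length is not None else SLEN_MAX_SENTINEL
        text += f' AND ("{lo}"[SLEN] : "{hi}"[SLEN])'
    return SearchStatement(
        target_db=SourceDB.NCBI, text=text, organism=organism, barcode=group.canonical
    )


def build_bold_taxon_query(taxon: str) -> SearchStatement:
    """Statement for BOLD's combined specimen+sequence retrieval.

    BOLD resolves the taxon server-side with subtree semantics: querying a
    genus returns records for every species beneath it.
    """
    _check_name(taxon)
    return SearchStatement(
        target_db=SourceDB.BOLD,
        text=f"taxon={taxon}&format=tsv",
        organism=taxon,
        barcode="*",
    )


def export_search_statements(stmts: Iterable[SearchStatement]) -> str:
    """Render statements as a replayable text document.

    Each statement becomes two lines: ``# <db> <organism> <barcode>`` then
    the literal query text, in input order. Empty input yields an empty
    document. Output is byte-reproducible (LF endings, no timestamps).
    """
    lines: list[str] = []
    for s in stmts:
        lines.append(f"# {s.target_db.value} {s.organism} {s.barcode}")
        lines.append(s.text)
    if not lines:
        return ""
    return "\n".join(lines) + "\n"


def term_is_balanced(text: str) -> bool:
    """Check bracket/quote balance of a query term (round-trip guard).

    Characters inside double-quoted strings are opaque — an organism named
    with a parenthesis must not unbalance the term.
    """
    if text.count('"') % 2 != 0:
        return False
    depth = 0
    brackets = 0
    in_quotes = False
    for ch in text:
        if ch == '"':
            in_quotes = not in_quotes
        elif in_quotes:
            continue
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
        elif ch == "[":
            brackets += 1
        elif ch == "]":
            brackets -= 1
            if brackets < 0:
                return False
    return depth == 0 and brackets == 0 and not in_quotes
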