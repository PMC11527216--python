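"""Domain types shared by every module, plus marker-name normalization.

The central objects are :class:`SequenceRecord` (one database entry, metadata
carried verbatim — never silently corrected), :class:`BarcodeGroup` (a
canonical barcode locus plus its synonym marker spellings) and the small
value types used to describe queries and filters.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

__all__ = [
    "SourceDB",
    "RANK_ORDER",
    "Lineage",
    "SequenceRecord",
    "BarcodeGroup",
    "OrganismQuery",
    "FilterSpec",
    "SearchStatement",
    "UNMATCHED",
    "normalize_marker",
    "validate_record",
    "default_barcode_groups",
    "load_barcode_groups",
    "normalize_name",
]


class SourceDB(str, enum.Enum):
    """Which database a record came from."""

    NCBI = "NCBI"
    BOLD = "BOLD"
    CRUX = "CRUX"
    SNAPSHOT = "SNAPSHOT"


#: Fixed ordered rank vocabulary, broadest first.
RANK_ORDER: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANK_ORDER)}

#: Nucleotide alphabet accepted in record sequences (IUPAC + gaps).
_SEQ_CHARS = frozenset("ACGTUNRYSWKMBDHV-")

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Collapse whitespace and casefold, for organism-name comparison."""
    return _WS.sub(" ", name.strip()).casefold()


class _Sentinel:
    def __init__(self, label: str):
        self._label = label

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._label

    def __bool__(self) -> bool:
        return False


#: Returned by :func:`normalize_marker` when no group claims the label.
UNMATCHED = _Sentinel("UNMATCHED")


@dataclass(frozen=True)
class Lineage:
    """An ordered rank → name mapping drawn from :data:`RANK_ORDER`.

    ``incomplete`` flags lineages that break the "species implies genus"
    rule instead of rejecting them: real databases hold such entries.
    """

    ranks: Mapping[str, str]
    incomplete: bool = False

    def __post_init__(self):
        unknown = set(self.ranks) - set(RANK_ORDER)
        if unknown:
            raise ValueError(f"unknown ranks: {sorted(unknown)}")
        ordered = {r: self.ranks[r] for r in RANK_ORDER if r in self.ranks}
        object.__setattr__(self, "ranks", ordered)
        if "species" in ordered and "genus" not in ordered and not self.incomplete:
            object.__setattr__(self, "incomplete", True)

    def get(self, rank: str) -> Optional[str]:
        return self.ranks.get(rank)

    def names(self) -> tuple[str, ...]:
        return tuple(self.ranks.values())

    def contains(self, taxon: str) -> bool:
        """True if ``taxon`` appears at any rank (case-insensitive)."""
        t = normalize_name(taxon)
        return any(normalize_name(v) == t for v in self.ranks.values())

    def truncated(self, rank: str) -> "Lineage":
        """Lineage cut off at ``rank`` (inclusive), e.g. a genus entry."""
        cut = _RANK_INDEX[rank]
        return Lineage({r: n for r, n in self.ranks.items() if _RANK_INDEX[r] <= cut})

    def to_string(self) -> str:
        """Seven-field semicolon string, blank for missing ranks."""
        return ";".join(self.ranks.get(r, "") for r in RANK_ORDER)

    @classmethod
    def from_string(cls, s: str) -> "Lineage":
        parts = s.split(";")
        if len(parts) != len(RANK_ORDER):
            raise ValueError(
                f"lineage string has {len(parts)} fields, expected {len(RANK_ORDER)}"
            )
        ranks = {r: p.strip() for r, p in zip(RANK_ORDER, parts) if p.strip()}
        return cls(ranks)


@dataclass(frozen=True)
class SequenceRecord:
    """One database entry; metadata is carried verbatim, never corrected."""

    source_db: SourceDB
    accession: str
    organism: str
    marker: str
    seq_length: Optional[int] = None
    lineage: Optional[Lineage] = None
    country: Optional[str] = None
    genbank_xref: Optional[str] = None
    sequence: Optional[str] = None


def _ungapped_length(sequence: str) -> int:
    return len(sequence) - sequence.count("-")


def validate_record(rec: SequenceRecord) -> list[str]:
    """Return a human-readable violation per broken invariant; [] if clean."""
    violations: list[str] = []
    if not rec.accession:
        violations.append("accession: must be non-empty")
    if rec.seq_length is not None and rec.seq_length < 1:
        violations.append("seq_length: must be >= 1 when present")
    if rec.sequence is not None:
        bad = set(rec.sequence.upper()) - _SEQ_CHARS
        if bad:
            violations.append(f"sequence: illegal characters {sorted(bad)}")
        if rec.seq_length is not None and rec.seq_length != _ungapped_length(
            rec.sequence
        ):
            violations.append(
                "seq_length: does not equal ungapped sequence length "
                f"({rec.seq_length} != {_ungapped_length(rec.sequence)})"
            )
    if rec.genbank_xref is not None and rec.source_db is not SourceDB.BOLD:
        violations.append("genbank_xref: only meaningful on BOLD records")
    return violations


@dataclass(frozen=True)
class BarcodeGroup:
    """A canonical barcode locus plus synonym marker spellings.

    ``synonyms`` is an ordered tuple — query builders emit synonyms in the
    declared order so statements are reproducible.
    """

    canonical: str
    synonyms: tuple[str, ...]

    def __post_init__(self):
        norm = {normalize_name(s) for s in self.synonyms}
        if normalize_name(self.canonical) not in norm:
            raise ValueError(
                f"canonical {self.canonical!r} missing from its synonym set"
            )
        if len(norm) != len(self.synonyms):
            raise ValueError(f"duplicate synonyms in group {self.canonical!r}")

    def matches(self, raw: str) -> bool:
        r = normalize_name(raw)
        return any(normalize_name(s) == r for s in self.synonyms)

    @classmethod
    def singleton(cls, name: str) -> "BarcodeGroup":
        return cls(canonical=name, synonyms=(name,))


def _check_disjoint(groups: Iterable[BarcodeGroup]) -> None:
    seen: dict[str, str] = {}
    for g in groups:
        for s in g.synonyms:
            key = normalize_name(s)
            if key in seen and seen[key] != g.canonical:
                raise ValueError(
                    f"synonym {s!r} claimed by both {seen[key]!r} and {g.canonical!r}"
                )
            seen[key] = g.canonical


def load_barcode_groups(path) -> list[BarcodeGroup]:
    """Load a canonical,synonym CSV (one row per synonym) into groups."""
    order: list[str] = []
    syns: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"canonical", "synonym"} - set(
            reader.fieldnames
        ):
            raise ValueError("barcode-group CSV needs 'canonical,synonym' header")
        for row in reader:
            canon = row["canonical"].strip()
            syn = row["synonym"].strip()
            if not canon or not syn:
                continue
            if canon not in syns:
                order.append(canon)
                syns[canon] = []
            syns[canon].append(syn)
    groups = [BarcodeGroup(c, tuple(syns[c])) for c in order]
    _check_disjoint(groups)
    return groups


def default_barcode_groups() -> list[BarcodeGroup]:
    """The shipped groups: CO1, 16S, 18S, 12S, FITS, PITS, trnL."""
    ref = resources.files("refaudit.data").joinpath("barcode_groups.csv")
    with resources.as_file(ref) as path:
        return load_barcode_groups(path)


def normalize_marker(raw: str, groups: Iterable[BarcodeGroup]):
    """Map a raw marker label onto its group's canonical name.

    Matching is case-insensitive exact match after whitespace normalization
    — deliberately not substring match, which would mis-group e.g. "CO1"
    inside "CO12". Returns :data:`UNMATCHED` when no group claims the label.
    """
    for g in groups:
        if g.matches(raw):
            return g.canonical
    return UNMATCHED


@dataclass
class OrganismQuery:
    """A user-supplied organism name plus appended (never replacing) corrections."""

    input_name: str
    resolved_names: list[str] = field(default_factory=list)
    resolution_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.resolved_names:
            self.resolved_names = [self.input_name]
        if self.resolved_names[0] != self.input_name:
            raise ValueError("resolved_names must start with the original input")
        if len(set(self.resolved_names)) != len(self.resolved_names):
            raise ValueError("resolved_names must not contain duplicates")

    @property
    def corrected(self) -> bool:
        return len(self.resolved_names) > 1


@dataclass(frozen=True)
class FilterSpec:
    """Record-level filters: length bounds, country whitelist, BOLD dedupe."""

    min_length: Optional[int] = None
    max_length: Optional[int] = None
    countries: Optional[frozenset[str]] = None
    exclude_ncbi_duplicates: bool = False

    def __post_init__(self):
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError("min_length > max_length")
        if self.countries is not None and not isinstance(self.countries, frozenset):
            object.__setattr__(self, "countries", frozenset(self.countries))

    @property
    def has_length_filter(self) -> bool:
        return self.min_length is not None or self.max_length is not None


@dataclass(frozen=True)
class SearchStatement:
    """The literal query text submitted to a database, for export/audit."""

    target_db: SourceDB
    text: str
    organism: str
    barcode: str

    def __post_init__(self):
        if not self.text:
            raise ValueError("statement text must be non-empty")
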