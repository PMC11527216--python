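"""Name resolution and rank-fallback search up the taxonomic backbone.

Two behaviors anchor this module:

* corrections are *appended* to the user's organism list, never replacing
  the original input;
* when a species has zero records, the search walks up the backbone to
  genus, family and order — but a species absent from the backbone is
  reported as an all-zero row with an UNREGISTERED flag and is *not*
  searched at broader ranks, because there is no lineage to walk.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol, Union

from .errors import SourceUnavailableError
from .model import BarcodeGroup, FilterSpec, Lineage, OrganismQuery, normalize_name
from .sources.base import Capability, RecordSource

logger = logging.getLogger(__name__)

__all__ = [
    "UNREGISTERED",
    "Backbone",
    "backbone_from_lineages",
    "NameResolver",
    "IdentityResolver",
    "TableResolver",
    "resolve_names",
    "lineage_of",
    "FallbackResult",
    "fallback_search",
    "FALLBACK_RANKS",
]

#: Ancestor ranks walked when the species-level count is zero, in order.
FALLBACK_RANKS: tuple[str, ...] = ("genus", "family", "order")


class _Unregistered:
    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNREGISTERED"

    def __bool__(self) -> bool:
        return False


#: Value returned when a name is absent from the taxonomy backbone.
UNREGISTERED = _Unregistered()


class Backbone:
    """Case-insensitive name → :class:`Lineage` lookup table."""

    def __init__(self, table: dict[str, Lineage]):
        self._table = {normalize_name(k): v for k, v in table.items()}

    def lookup(self, name: str) -> Optional[Lineage]:
        return self._table.get(normalize_name(name))

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._table

    def __len__(self) -> int:
        return len(self._table)

    @classmethod
    def from_tsv(cls, path) -> "Backbone":
        """Load ``name<TAB>lineage-string`` rows (CRUX lineage format)."""
        table: dict[str, Lineage] = {}
        with open(path, encoding="utf-8") as fh:
            first = True
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if first and parts[:2] == ["name", "lineage"]:
                    first = False
                    continue
                first = False
                if len(parts) != 2:
                    raise ValueError(f"backbone line needs 2 fields: {line!r}")
                table[parts[0]] = Lineage.from_string(parts[1])
        return cls(table)

    @classmethod
    def from_snapshot(cls, snapshot) -> "Backbone":
        return cls(dict(snapshot.backbone))


def backbone_from_lineages(lineages: Iterable[Lineage]) -> dict[str, Lineage]:
    """Derive a name→lineage table (species + all ancestor entries)."""
    table: dict[str, Lineage] = {}
    for lin in lineages:
        for rank, name in lin.ranks.items():
            table.setdefault(name, lin.truncated(rank))
    return table


def lineage_of(name: str, backbone: Backbone) -> Union[Lineage, _Unregistered]:
    """Full available lineage for ``name``, or :data:`UNREGISTERED`."""
    lin = backbone.lookup(name)
    return lin if lin is not None else UNREGISTERED


# ---------------------------------------------------------------------------
# Name resolution


class NameResolver(Protocol):
    """Pluggable correction interface: name → corrected names (may be empty)."""

    def corrections(self, name: str) -> list[tuple[str, str]]:
        """Return (corrected_name, note) pairs for ``name``."""
        ...


class IdentityResolver:
    """No corrections; the offline default when no table is supplied."""

    def corrections(self, name: str) -> list[tuple[str, str]]:
        return []


class TableResolver:
    """Offline table-driven resolver from a wrong_name,correct_name CSV."""

    def __init__(self, mapping: dict[str, str], note: str = "correction table"):
        self._mapping = {normalize_name(k): v for k, v in mapping.items()}
        self._note = note

    @classmethod
    def from_csv(cls, path) -> "TableResolver":
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {"wrong_name", "correct_name"} - set(
                reader.fieldnames
            ):
                raise ValueError(
                    "correction CSV needs 'wrong_name,correct_name' header"
                )
            for row in reader:
                wrong = (row["wrong_name"] or "").strip()
                right = (row["correct_name"] or "").strip()
                if wrong and right:
                    mapping[wrong] = right
        return cls(mapping, note=f"correction table {path}")

    def corrections(self, name: str) -> list[tuple[str, str]]:
        hit = self._mapping.get(normalize_name(name))
        return [(hit, self._note)] if hit else []


def resolve_names(
    names: Iterable[str], resolver: Optional[NameResolver] = None
) -> list[OrganismQuery]:
    """One :class:`OrganismQuery` per input, corrections appended after the
    original (never replacing it), every correction logged with its source.
    Resolver failure degrades to identity resolution with a warning."""
    resolver = resolver or IdentityResolver()
    out: list[OrganismQuery] = []
    for name in names:
        resolved = [name]
        log: list[tuple[str, str, str]] = []
        try:
            corrections = resolver.corrections(name)
        except Exception as exc:  # degrade, never fail the whole query
            logger.warning("name resolver failed for %r: %s", name, exc)
            corrections = []
        for corrected, note in corrections:
            if normalize_name(corrected) in {normalize_name(r) for r in resolved}:
                continue
            resolved.append(corrected)
            log.append((name, corrected, note))
        out.append(
            OrganismQuery(input_name=name, resolved_names=resolved, resolution_log=log)
        )
    return out


# ---------------------------------------------------------------------------
# Rank-fallback search


@dataclass
class FallbackResult:
    """Outcome of a species search with optional ancestor-rank fallback."""

    entries: list[tuple[str, str, int]]  # (rank, taxon_name, count)
    unregistered: bool = False
    query_log: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def species_count(self) -> int:
        return self.entries[0][2]


def _pooled_species_count(
    src: RecordSource,
    oq: OrganismQuery,
    group: BarcodeGroup,
    filters: Optional[FilterSpec],
    log: list[str],
) -> int:
    """Species-level count pooled over the original + appended names."""
    total = 0
    for name in oq.resolved_names:
        n = src.count_matches(name, group, filters)
        log.append(f"species {name!r} [{group.canonical}] -> {n}")
        total += n
    return total


def _ancestor_count(
    src: RecordSource,
    taxon: str,
    group: BarcodeGroup,
    filters: Optional[FilterSpec],
) -> int:
    # Sources with native subtree semantics count through the lineage; on
    # others the ancestor name is issued as an ordinary organism term
    # (Entrez expands the subtree server-side).
    if src.supports(Capability.SUBTREE_QUERY):
        return src.count_subtree(taxon, group, filters)
    return src.count_matches(taxon, group, filters)


def fallback_search(
    src: RecordSource,
    oq: OrganismQuery,
    group: BarcodeGroup,
    backbone: Backbone,
    filters: Optional[FilterSpec] = None,
) -> FallbackResult:
    """Species count first; on zero, walk genus → family → order.

    Returns only the species entry when it is positive (no ancestor query
    is ever issued — assert the ``query_log``). A species missing from the
    backbone returns a zero species entry flagged unregistered, with no
    broader search. When the backbone's genus disagrees with the binomial's
    first word (a moved species), the backbone wins and the divergence is
    recorded as a warning.
    """
    log: list[str] = []
    warnings: list[str] = []
    try:
        species_n = _pooled_species_count(src, oq, group, filters, log)
    except SourceUnavailableError:
        raise
    entries: list[tuple[str, str, int]] = [("species", oq.input_name, species_n)]
    if species_n > 0:
        return FallbackResult(entries=entries, query_log=log, warnings=warnings)

    lineage: Union[Lineage, _Unregistered] = UNREGISTERED
    for name in oq.resolved_names:
        lineage = lineage_of(name, backbone)
        if lineage is not UNREGISTERED:
            break
    if lineage is UNREGISTERED:
        warnings.append(
            f"{oq.input_name!r} is not registered in the taxonomy backbone; "
            "not searched at broader ranks"
        )
        return FallbackResult(
            entries=entries, unregistered=True, query_log=log, warnings=warnings
        )

    binomial_genus = oq.input_name.split()[0] if oq.input_name.split() else ""
    for rank in FALLBACK_RANKS:
        taxon = lineage.get(rank)
        if not taxon:
            continue
        if rank == "genus" and normalize_name(taxon) != normalize_name(binomial_genus):
            warnings.append(
                f"backbone genus {taxon!r} differs from the binomial's first word "
                f"{binomial_genus!r}; walking the backbone's genus"
            )
        n = _ancestor_count(src, taxon, group, filters)
        log.append(f"{rank} {taxon!r} [{group.canonical}] -> {n}")
        entries.append((rank, taxon, n))
    return FallbackResult(entries=entries, query_log=log, warnings=warnings)
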