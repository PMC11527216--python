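"""Record-source contract and the shared matching predicates.

Matching is exact on the scientific name (case-insensitive,
whitespace-normalized) — name correction lives in :mod:`refaudit.taxonomy`,
not here, so source semantics stay auditable.
"""

from __future__ import annotations

import abc
import enum
from typing import Optional

from ..errors import CapabilityError
from ..model import (
    BarcodeGroup,
    FilterSpec,
    SequenceRecord,
    normalize_marker,
    normalize_name,
)

#: Reserved country name matching records with absent country metadata.
UNSPECIFIED_COUNTRY = "Unspecified"


class Capability(enum.Flag):
    COUNT = enum.auto()
    FETCH = enum.auto()
    SUBTREE_QUERY = enum.auto()
    COUNTRY_METADATA = enum.auto()


def passes_filters(rec: SequenceRecord, filters: Optional[FilterSpec]) -> bool:
    if filters is None:
        return True
    if filters.has_length_filter:
        if rec.seq_length is None:
            return False  # length-less metadata is excluded only by an active filter
        if filters.min_length is not None and rec.seq_length < filters.min_length:
            return False
        if filters.max_length is not None and rec.seq_length > filters.max_length:
            return False
    if filters.countries is not None:
        wanted = {normalize_name(c) for c in filters.countries}
        country = rec.country.strip() if rec.country else UNSPECIFIED_COUNTRY
        if normalize_name(country) not in wanted:
            return False
    return True


def record_matches(
    rec: SequenceRecord,
    organism: str,
    group: BarcodeGroup,
    filters: Optional[FilterSpec] = None,
) -> bool:
    """The audited predicate: exact organism, marker in group, filters pass."""
    if normalize_name(rec.organism) != normalize_name(organism):
        return False
    if normalize_marker(rec.marker, [group]) != group.canonical:
        return False
    return passes_filters(rec, filters)


def record_in_subtree(
    rec: SequenceRecord,
    taxon: str,
    group: BarcodeGroup,
    filters: Optional[FilterSpec] = None,
) -> bool:
    """Subtree predicate: the record's organism or any lineage rank hits taxon."""
    hit = normalize_name(rec.organism) == normalize_name(taxon) or (
        rec.lineage is not None and rec.lineage.contains(taxon)
    )
    if not hit:
        return False
    if normalize_marker(rec.marker, [group]) != group.canonical:
        return False
    return passes_filters(rec, filters)


class RecordSource(abc.ABC):
    """Contract all four backends implement.

    COUNT implies count_matches(q) equals len(fetch_records(q)) under
    identical inputs and source state.
    """

    name: str = "source"
    capabilities: Capability = Capability(0)

    def supports(self, cap: Capability) -> bool:
        return bool(self.capabilities & cap)

    def require(self, cap: Capability) -> None:
        if not self.supports(cap):
            raise CapabilityError(f"{self.name} does not support {cap}")

    @abc.abstractmethod
    def count_matches(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        """Number of records matching the predicate. COUNT capability."""

    @abc.abstractmethod
    def fetch_records(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
        want_sequence: bool = False,
    ) -> list[SequenceRecord]:
        """Records matching the predicate, deterministically ordered."""

    def count_subtree(
        self,
        taxon: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        """Count records anywhere under ``taxon``. SUBTREE_QUERY capability."""
        raise CapabilityError(f"{self.name} does not support subtree queries")


# Module-level forms mirroring the operation signatures.
def count_matches(src: RecordSource, organism, group, filters=None) -> int:
    return src.count_matches(organism, group, filters)


def fetch_records(src: RecordSource, organism, group, filters=None, want_sequence=False):
    return src.fetch_records(organism, group, filters, want_sequence)
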