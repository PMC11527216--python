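"""Live BOLD source via the public combined specimen+sequence API.

One request per taxon; BOLD resolves subtree semantics server-side, so a
genus query returns every species beneath it. The TSV response's marker,
country and GenBank-accession columns are mapped into
:class:`SequenceRecord` fields; the GenBank cross-reference is what makes
NCBI deduplication possible downstream.
"""

from __future__ import annotations

import csv
import io as _io
import time
import urllib.error
import urllib.parse
import urllib.request
from typing import Callable, Optional

from ..errors import SourceUnavailableError
from ..model import BarcodeGroup, FilterSpec, SequenceRecord, SourceDB
from ..query import build_bold_taxon_query
from .base import Capability, RecordSource, passes_filters, record_matches
from .cache import DiskCache

BOLD_BASE = "https://v4.boldsystems.org/index.php/API_Public"
MAX_ATTEMPTS = 5

Transport = Callable[[str], bytes]

# combined-API column → SequenceRecord field
_COLMAP = {
    "processid": "accession",
    "species_name": "organism",
    "markercode": "marker",
    "country": "country",
    "genbank_accession": "genbank_xref",
    "nucleotides": "sequence",
}


def _urllib_transport(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


class BoldSource(RecordSource):
    capabilities = (
        Capability.COUNT
        | Capability.FETCH
        | Capability.SUBTREE_QUERY
        | Capability.COUNTRY_METADATA
    )

    def __init__(
        self,
        base_url: str = BOLD_BASE,
        transport: Optional[Transport] = None,
        cache: Optional[DiskCache] = None,
        sleeper: Callable[[float], None] = time.sleep,
    ):
        self.name = "bold"
        self.base_url = base_url.rstrip("/")
        self.transport = transport or _urllib_transport
        self.cache = cache
        self._sleep = sleeper

    def _request(self, url: str, cache_key: str) -> bytes:
        if self.cache is not None:
            hit = self.cache.get(cache_key)
            if hit is not None:
                return hit
        delay = 1.0
        last_exc: Exception | None = None
        for attempt in range(MAX_ATTEMPTS):
            try:
                payload = self.transport(url)
                if self.cache is not None:
                    self.cache.put(cache_key, payload)
                return payload
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                last_exc = exc
                if attempt < MAX_ATTEMPTS - 1:
                    self._sleep(delay)
                    delay *= 2.0
        raise SourceUnavailableError(
            f"BOLD request failed after {MAX_ATTEMPTS} attempts: {last_exc}"
        )

    def fetch_taxon(self, taxon: str) -> list[SequenceRecord]:
        """All records under ``taxon`` (subtree semantics are BOLD's own)."""
        stmt = build_bold_taxon_query(taxon)
        url = f"{self.base_url}/combined?" + urllib.parse.urlencode(
            dict(urllib.parse.parse_qsl(stmt.text))
        )
        payload = self._request(url, DiskCache.key("bold", stmt.text, "combined"))
        text = payload.decode("utf-8", errors="replace")
        records: list[SequenceRecord] = []
        reader = csv.DictReader(_io.StringIO(text), delimiter="\t")
        for row in reader:
            fields = {out: (row.get(col) or "").strip() for col, out in _COLMAP.items()}
            if not fields["accession"]:
                continue
            seq = fields["sequence"].upper() or None
            records.append(
                SequenceRecord(
                    source_db=SourceDB.BOLD,
                    accession=fields["accession"],
                    organism=fields["organism"],
                    marker=fields["marker"],
                    seq_length=(len(seq) - seq.count("-")) if seq else None,
                    country=fields["country"] or None,
                    genbank_xref=fields["genbank_xref"] or None,
                    sequence=seq,
                )
            )
        return records

    def count_matches(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        return len(self.fetch_records(organism, group, filters))

    def fetch_records(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
        want_sequence: bool = False,
    ) -> list[SequenceRecord]:
        hits = [
            rec
            for rec in self.fetch_taxon(organism)
            if record_matches(rec, organism, group, filters)
        ]
        return sorted(hits, key=lambda r: r.accession)

    def count_subtree(
        self,
        taxon: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        from ..model import normalize_marker

        n = 0
        for rec in self.fetch_taxon(taxon):
            if normalize_marker(rec.marker, [group]) == group.canonical and passes_filters(
                rec, filters
            ):
                n += 1
        return n
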