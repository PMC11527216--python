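"""Local CRUX-style reference database loader.

A CRUX directory holds one subdatabase per barcode: ``<barcode>.fasta``
plus ``<barcode>_taxonomy.txt``. The taxonomy file is a TSV of
``accession<TAB>superkingdom;phylum;class;order;family;genus;species``.
Malformed entries are reported individually and skipped; the load always
continues, and audits against the source cover every subdatabase found
(zeros included).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from ..model import (
    BarcodeGroup,
    FilterSpec,
    Lineage,
    SequenceRecord,
    SourceDB,
)
from .base import Capability, RecordSource, record_in_subtree, record_matches

TAXONOMY_SUFFIX = "_taxonomy.txt"


@dataclass(frozen=True)
class MalformedEntry:
    """One skipped entry and why."""

    barcode: str
    accession: str
    reason: str


class CruxSource(RecordSource):
    """RecordSource over the union of all per-barcode subdatabases."""

    capabilities = Capability.COUNT | Capability.FETCH | Capability.SUBTREE_QUERY

    def __init__(
        self,
        records: list[SequenceRecord],
        barcodes: tuple[str, ...],
        malformed: list[MalformedEntry],
        name: str = "crux",
    ):
        self.records = records
        self.barcodes = barcodes
        self.malformed = malformed
        self.name = name

    def count_matches(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        return sum(
            1 for rec in self.records if record_matches(rec, organism, group, filters)
        )

    def fetch_records(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
        want_sequence: bool = False,
    ) -> list[SequenceRecord]:
        hits = [
            rec for rec in self.records if record_matches(rec, organism, group, filters)
        ]
        return sorted(hits, key=lambda r: r.accession)

    def count_subtree(
        self,
        taxon: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        return sum(
            1 for rec in self.records if record_in_subtree(rec, taxon, group, filters)
        )

    def backbone(self) -> dict[str, Lineage]:
        """Name → lineage table derived from the taxonomy files, including
        ancestor entries, usable for rank-fallback search."""
        from ..taxonomy import backbone_from_lineages

        return backbone_from_lineages(
            rec.lineage for rec in self.records if rec.lineage is not None
        )


def _read_taxonomy(path: Path, barcode: str, malformed: list[MalformedEntry]):
    table: dict[str, Lineage] = {}
    bad: set[str] = set()  # accessions already reported, to avoid double-counting
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                malformed.append(
                    MalformedEntry(barcode, parts[0] if parts else "?",
                                   "taxonomy line is not accession<TAB>lineage")
                )
                if parts:
                    bad.add(parts[0])
                continue
            accession, lineage_str = parts
            try:
                table[accession] = Lineage.from_string(lineage_str)
            except ValueError as exc:
                malformed.append(MalformedEntry(barcode, accession, str(exc)))
                bad.add(accession)
    return table, bad


def load_crux_database(dir_path) -> CruxSource:
    """Load every ``<barcode>.fasta`` + ``<barcode>_taxonomy.txt`` pair.

    Each record's marker is its subdatabase's barcode and its organism is
    the species field of the taxonomy lineage. Entries whose taxonomy line
    lacks the 7 rank fields, or whose FASTA id is missing from the taxonomy
    file, are recorded in ``source.malformed`` and skipped.
    """
    root = Path(dir_path)
    if not root.is_dir():
        raise FileNotFoundError(f"not a directory: {root}")
    records: list[SequenceRecord] = []
    barcodes: list[str] = []
    malformed: list[MalformedEntry] = []
    for tax_path in sorted(root.glob(f"*{TAXONOMY_SUFFIX}")):
        barcode = tax_path.name[: -len(TAXONOMY_SUFFIX)]
        fasta_path = root / f"{barcode}.fasta"
        if not fasta_path.is_file():
            continue
        barcodes.append(barcode)
        taxonomy, bad = _read_taxonomy(tax_path, barcode, malformed)
        for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
            accession = seq_rec.id
            lineage = taxonomy.get(accession)
            if lineage is None:
                if accession not in bad:  # already reported once
                    malformed.append(
                        MalformedEntry(barcode, accession, "FASTA id missing from taxonomy file")
                    )
                continue
            species = lineage.get("species")
            if not species:
                malformed.append(
                    MalformedEntry(barcode, accession, "taxonomy lineage lacks a species field")
                )
                continue
            seq = str(seq_rec.seq).upper()
            records.append(
                SequenceRecord(
                    source_db=SourceDB.CRUX,
                    accession=accession,
                    organism=species,
                    lineage=lineage,
                    marker=barcode,
                    seq_length=len(seq) - seq.count("-"),
                    sequence=seq,
                )
            )
    if not barcodes:
        raise FileNotFoundError(
            f"no <barcode>.fasta + <barcode>{TAXONOMY_SUFFIX} pairs under {root}"
        )
    return CruxSource(
        records=records,
        barcodes=tuple(barcodes),
        malformed=malformed,
        name=f"crux:{root}",
    )
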