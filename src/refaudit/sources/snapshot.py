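"""Offline, file-backed record source.

A snapshot is a directory holding ``records.tsv`` (one record per line,
fixed column order, header required) and ``backbone.tsv`` (name → lineage
string). Save→load is a lossless round-trip, which makes snapshots the
drop-in source for every offline test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ..errors import MalformedSnapshotError
from ..model import (
    BarcodeGroup,
    FilterSpec,
    Lineage,
    SequenceRecord,
    SourceDB,
    normalize_name,
)
from .base import Capability, RecordSource, record_in_subtree, record_matches

RECORDS_FILE = "records.tsv"
BACKBONE_FILE = "backbone.tsv"

_COLUMNS = (
    "source_db",
    "accession",
    "organism",
    "lineage",
    "marker",
    "seq_length",
    "country",
    "genbank_xref",
    "sequence",
)


@dataclass
class Snapshot:
    """Records plus the taxonomy backbone they were collected under."""

    records: list[SequenceRecord] = field(default_factory=list)
    backbone: dict[str, Lineage] = field(default_factory=dict)
    created_with_seed: Optional[int] = None

    def __post_init__(self):
        seen: set[tuple[SourceDB, str]] = set()
        for rec in self.records:
            key = (rec.source_db, rec.accession)
            if key in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(key)


def _cell(value) -> str:
    return "" if value is None else str(value)


def save_snapshot(snapshot: Snapshot, path) -> None:
    """Write ``records.tsv`` + ``backbone.tsv`` under directory ``path``."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(_COLUMNS)]
    for rec in snapshot.records:
        lines.append(
            "\t".join(
                (
                    rec.source_db.value,
                    rec.accession,
                    rec.organism,
                    rec.lineage.to_string() if rec.lineage else "",
                    rec.marker,
                    _cell(rec.seq_length),
                    _cell(rec.country),
                    _cell(rec.genbank_xref),
                    _cell(rec.sequence),
                )
            )
        )
    (p / RECORDS_FILE).write_text("\n".join(lines) + "\n", encoding="utf-8")
    blines = ["name\tlineage"]
    for name in sorted(snapshot.backbone):
        blines.append(f"{name}\t{snapshot.backbone[name].to_string()}")
    if snapshot.created_with_seed is not None:
        blines.append(f"#seed\t{snapshot.created_with_seed}")
    (p / BACKBONE_FILE).write_text("\n".join(blines) + "\n", encoding="utf-8")


def load_snapshot(path) -> Snapshot:
    """Inverse of :func:`save_snapshot`; raises MalformedSnapshotError
    with a line number on any structural problem."""
    p = Path(path)
    rec_path = p / RECORDS_FILE
    if not rec_path.is_file():
        raise MalformedSnapshotError(f"missing {RECORDS_FILE} under {p}")
    records: list[SequenceRecord] = []
    with open(rec_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != list(_COLUMNS):
            raise MalformedSnapshotError("bad or missing header", line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise MalformedSnapshotError(
                    f"expected {len(_COLUMNS)} fields, got {len(parts)}", line=lineno
                )
            row = dict(zip(_COLUMNS, parts))
            try:
                records.append(
                    SequenceRecord(
                        source_db=SourceDB(row["source_db"]),
                        accession=row["accession"],
                        organism=row["organism"],
                        lineage=(
                            Lineage.from_string(row["lineage"])
                            if row["lineage"]
                            else None
                        ),
                        marker=row["marker"],
                        seq_length=int(row["seq_length"]) if row["seq_length"] else None,
                        country=row["country"] or None,
                        genbank_xref=row["genbank_xref"] or None,
                        sequence=row["sequence"] or None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise MalformedSnapshotError(str(exc), line=lineno) from exc
    backbone: dict[str, Lineage] = {}
    seed: Optional[int] = None
    bb_path = p / BACKBONE_FILE
    if bb_path.is_file():
        with open(bb_path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n")
            if header.split("\t") != ["name", "lineage"]:
                raise MalformedSnapshotError("bad backbone header", line=1)
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#seed\t"):
                    seed = int(line.split("\t", 1)[1])
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise MalformedSnapshotError(
                        "backbone line needs name<TAB>lineage", line=lineno
                    )
                try:
                    backbone[parts[0]] = Lineage.from_string(parts[1])
                except ValueError as exc:
                    raise MalformedSnapshotError(str(exc), line=lineno) from exc
    try:
        return Snapshot(records=records, backbone=backbone, created_with_seed=seed)
    except ValueError as exc:
        raise MalformedSnapshotError(str(exc)) from exc


class SnapshotSource(RecordSource):
    """RecordSource over an in-memory :class:`Snapshot`."""

    capabilities = (
        Capability.COUNT
        | Capability.FETCH
        | Capability.SUBTREE_QUERY
        | Capability.COUNTRY_METADATA
    )

    def __init__(self, snapshot: Snapshot, name: str = "snapshot"):
        self.snapshot = snapshot
        self.name = name

    @classmethod
    def from_path(cls, path) -> "SnapshotSource":
        return cls(load_snapshot(path), name=f"snapshot:{os.fspath(path)}")

    def count_matches(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        return sum(
            1
            for rec in self.snapshot.records
            if record_matches(rec, organism, group, filters)
        )

    def fetch_records(
        self,
        organism: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
        want_sequence: bool = False,
    ) -> list[SequenceRecord]:
        hits = [
            rec
            for rec in self.snapshot.records
            if record_matches(rec, organism, group, filters)
        ]
        return sorted(hits, key=lambda r: r.accession)

    def count_subtree(
        self,
        taxon: str,
        group: BarcodeGroup,
        filters: Optional[FilterSpec] = None,
    ) -> int:
        return sum(
            1
            for rec in self.snapshot.records
            if record_in_subtree(rec, taxon, group, filters)
        )

    def organisms(self) -> set[str]:
        return {normalize_name(r.organism) for r in self.snapshot.records}
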