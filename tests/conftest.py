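import pytest

from refaudit.model import (
    BarcodeGroup,
    Lineage,
    SequenceRecord,
    SourceDB,
    default_barcode_groups,
)
from refaudit.sources import Snapshot, SnapshotSource


@pytest.fixture(scope="session")
def default_groups():
    return default_barcode_groups()


@pytest.fixture(scope="session")
def co1_group(default_groups):
    return next(g for g in default_groups if g.canonical == "CO1")


@pytest.fixture(scope="session")
def s16_group(default_groups):
    return next(g for g in default_groups if g.canonical == "16S")


def make_record(
    accession,
    organism="Xenopus laevis",
    marker="CO1",
    seq_length=None,
    sequence=None,
    country=None,
    genbank_xref=None,
    source_db=SourceDB.SNAPSHOT,
    lineage=None,
):
    if sequence is not None and seq_length is None:
        seq_length = len(sequence) - sequence.count("-")
    return SequenceRecord(
        source_db=source_db,
        accession=accession,
        organism=organism,
        marker=marker,
        seq_length=seq_length,
        sequence=sequence,
        country=country,
        genbank_xref=genbank_xref,
        lineage=lineage,
    )


XENOPUS_LINEAGE = Lineage(
    {
        "order": "Anura",
        "family": "Pipidae",
        "genus": "Xenopus",
        "species": "Xenopus laevis",
    }
)


@pytest.fixture
def xenopus_snapshot():
    """Three CO1 records and one 16S record for Xenopus laevis, plus a
    congener and an unrelated species."""
    records = [
        make_record("ACC001", marker="CO1", sequence="ACGT" * 100, lineage=XENOPUS_LINEAGE),
        make_record("ACC002", marker="COI", sequence="ACGT" * 120, lineage=XENOPUS_LINEAGE),
        make_record("ACC003", marker="COX1", sequence="ACGT" * 90, lineage=XENOPUS_LINEAGE),
        make_record("ACC004", marker="16S", sequence="ACGT" * 50, lineage=XENOPUS_LINEAGE),
        make_record(
            "ACC005",
            organism="Xenopus tropicalis",
            marker="CO1",
            sequence="ACGT" * 80,
            lineage=Lineage(
                {
                    "order": "Anura",
                    "family": "Pipidae",
                    "genus": "Xenopus",
                    "species": "Xenopus tropicalis",
                }
            ),
        ),
        make_record(
            "ACC006",
            organism="Dreissena polymorpha",
            marker="CO1",
            sequence="ACGT" * 70,
            lineage=Lineage(
                {
                    "order": "Myida",
                    "family": "Dreissenidae",
                    "genus": "Dreissena",
                    "species": "Dreissena polymorpha",
                }
            ),
        ),
    ]
    backbone = {}
    for rec in records:
        for rank, name in rec.lineage.ranks.items():
            backbone.setdefault(name, rec.lineage.truncated(rank))
    return Snapshot(records=records, backbone=backbone)


@pytest.fixture
def xenopus_source(xenopus_snapshot):
    return SnapshotSource(xenopus_snapshot)
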