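"""Synthetic snapshot generator with planted, known coverage structure.

A :class:`CoveragePlan` fixes exactly how many records each organism ×
barcode pair gets; the generated snapshot is then its own oracle — every
downstream module (coverage counts, fallback, dedupe, filters) can be
checked against the plan instead of live databases. Identical seeds yield
byte-identical snapshots.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .errors import InvalidPlanError
from .model import BarcodeGroup, Lineage, SequenceRecord, SourceDB
from .sources.snapshot import Snapshot

__all__ = [
    "OrganismSpec",
    "CoveragePlan",
    "generate_snapshot",
    "generate_pair",
    "demo_plan",
    "load_plan",
    "save_plan",
]


@dataclass(frozen=True)
class OrganismSpec:
    binomial: str
    genus: str
    family: str
    order: str
    registered: bool = True

    def lineage(self) -> Lineage:
        return Lineage(
            {
                "order": self.order,
                "family": self.family,
                "genus": self.genus,
                "species": self.binomial,
            }
        )


@dataclass
class CoveragePlan:
    organisms: list[OrganismSpec]
    barcodes: list[str]  # canonical names
    planted_counts: dict[tuple[str, str], int]  # (binomial, barcode) -> n
    overlap_k: int = 0  # BOLD records mirrored in NCBI (generate_pair)
    country_pool: list[tuple[Optional[str], int]] = field(
        default_factory=lambda: [("Iceland", 3), ("Chile", 2), ("United States", 2), (None, 1)]
    )
    length_range: tuple[int, int] = (150, 800)
    seed: int = 0
    barcode_groups: Optional[list[BarcodeGroup]] = None  # synonym cycling source

    def validate(self) -> None:
        names = [o.binomial for o in self.organisms]
        if len(set(names)) != len(names):
            raise InvalidPlanError("duplicate organism binomials in plan")
        for o in names:
            for b in self.barcodes:
                if (o, b) not in self.planted_counts:
                    raise InvalidPlanError(f"plan lacks a count for ({o!r}, {b!r})")
        for key, n in self.planted_counts.items():
            if n < 0:
                raise InvalidPlanError(f"negative count for {key}")
        if self.overlap_k < 0:
            raise InvalidPlanError("overlap_k must be >= 0")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise InvalidPlanError("bad length_range")
        if not any(w > 0 for _, w in self.country_pool):
            raise InvalidPlanError("country_pool has no positive weights")

    def total_records(self) -> int:
        return sum(self.planted_counts.values())


def _synonyms_for(plan: CoveragePlan, barcode: str) -> Sequence[str]:
    if plan.barcode_groups:
        for g in plan.barcode_groups:
            if g.canonical == barcode:
                return g.synonyms
    return (barcode,)


_ACCESSION_PREFIX = {
    SourceDB.SNAPSHOT: "SYN",
    SourceDB.NCBI: "SNC",
    SourceDB.BOLD: "SBO",
    SourceDB.CRUX: "SCX",
}


def generate_snapshot(
    plan: CoveragePlan, source_db: SourceDB = SourceDB.SNAPSHOT
) -> Snapshot:
    """Materialize exactly ``planted_counts[o, b]`` records per pair.

    Sequences are uniform random over {A,C,G,T} (the audited predicate
    never reads sequence content), lengths uniform in ``length_range``,
    countries drawn from the weighted pool (None → absent metadata), and
    marker labels cycle through each barcode's synonym spellings so
    normalization is exercised. Unregistered organisms are omitted from
    the backbone. Identical seed → identical snapshot.
    """
    plan.validate()
    rng = random.Random((plan.seed, source_db.value).__repr__())
    prefix = _ACCESSION_PREFIX[source_db]
    pool_names = [c for c, _ in plan.country_pool]
    pool_weights = [w for _, w in plan.country_pool]
    records: list[SequenceRecord] = []
    counter = 0
    for org in plan.organisms:
        for barcode in plan.barcodes:
            synonyms = _synonyms_for(plan, barcode)
            for i in range(plan.planted_counts[(org.binomial, barcode)]):
                counter += 1
                length = rng.randint(*plan.length_range)
                sequence = "".join(rng.choice("ACGT") for _ in range(length))
                country = rng.choices(pool_names, weights=pool_weights, k=1)[0]
                records.append(
                    SequenceRecord(
                        source_db=source_db,
                        accession=f"{prefix}{counter:06d}",
                        organism=org.binomial,
                        lineage=org.lineage(),
                        marker=synonyms[i % len(synonyms)],
                        seq_length=length,
                        country=country,
                        sequence=sequence,
                    )
                )
    backbone: dict[str, Lineage] = {}
    for org in plan.organisms:
        if not org.registered:
            continue
        lin = org.lineage()
        backbone[org.binomial] = lin
        backbone.setdefault(org.genus, lin.truncated("genus"))
        backbone.setdefault(org.family, lin.truncated("family"))
        backbone.setdefault(org.order, lin.truncated("order"))
    return Snapshot(records=records, backbone=backbone, created_with_seed=plan.seed)


def generate_pair(plan: CoveragePlan) -> tuple[Snapshot, Snapshot]:
    """An NCBI-like and a BOLD-like snapshot with a planted overlap.

    Exactly ``plan.overlap_k`` BOLD records carry a genbank_xref equal to
    an accession present in the NCBI-like snapshot (half get a ``.1``
    version suffix to exercise version-stripping); every other xref is
    absent. The plan is the dedupe oracle.
    """
    plan.validate()
    ncbi = generate_snapshot(plan, SourceDB.NCBI)
    bold = generate_snapshot(plan, SourceDB.BOLD)
    if plan.overlap_k > len(bold.records):
        raise InvalidPlanError(
            f"overlap_k={plan.overlap_k} exceeds {len(bold.records)} BOLD records"
        )
    if plan.overlap_k > len(ncbi.records):
        raise InvalidPlanError(
            f"overlap_k={plan.overlap_k} exceeds {len(ncbi.records)} NCBI records"
        )
    rng = random.Random((plan.seed, "overlap").__repr__())
    bold_idx = rng.sample(range(len(bold.records)), plan.overlap_k)
    ncbi_accessions = rng.sample([r.accession for r in ncbi.records], plan.overlap_k)
    for j, (i, acc) in enumerate(zip(bold_idx, ncbi_accessions)):
        xref = f"{acc}.1" if j % 2 else acc
        rec = bold.records[i]
        bold.records[i] = SequenceRecord(
            source_db=rec.source_db,
            accession=rec.accession,
            organism=rec.organism,
            lineage=rec.lineage,
            marker=rec.marker,
            seq_length=rec.seq_length,
            country=rec.country,
            genbank_xref=xref,
            sequence=rec.sequence,
        )
    return ncbi, bold


# ---------------------------------------------------------------------------
# Plan (de)serialization: counts CSV + key=value config


def save_plan(plan: CoveragePlan, counts_path, config_path) -> None:
    with open(counts_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["organism", "genus", "family", "order", "registered", "barcode", "count"]
        )
        for org in plan.organisms:
            for barcode in plan.barcodes:
                writer.writerow(
                    [
                        org.binomial,
                        org.genus,
                        org.family,
                        org.order,
                        "yes" if org.registered else "no",
                        barcode,
                        plan.planted_counts[(org.binomial, barcode)],
                    ]
                )
    lines = [
        f"seed={plan.seed}",
        f"overlap_k={plan.overlap_k}",
        f"min_length={plan.length_range[0]}",
        f"max_length={plan.length_range[1]}",
        "countries=" + ",".join(
            f"{c or ''}:{w}" for c, w in plan.country_pool
        ),
    ]
    Path(config_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_plan(counts_path, config_path=None) -> CoveragePlan:
    organisms: list[OrganismSpec] = []
    seen: dict[str, OrganismSpec] = {}
    barcodes: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    with open(counts_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"organism", "genus", "family", "order", "registered", "barcode", "count"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise InvalidPlanError(f"plan CSV needs columns {sorted(required)}")
        for row in reader:
            name = row["organism"].strip()
            if name not in seen:
                spec = OrganismSpec(
                    binomial=name,
                    genus=row["genus"].strip(),
                    family=row["family"].strip(),
                    order=row["order"].strip(),
                    registered=row["registered"].strip().lower() not in ("no", "false", "0"),
                )
                seen[name] = spec
                organisms.append(spec)
            barcode = row["barcode"].strip()
            if barcode not in barcodes:
                barcodes.append(barcode)
            counts[(name, barcode)] = int(row["count"])
    plan = CoveragePlan(organisms=organisms, barcodes=barcodes, planted_counts=counts)
    if config_path is not None:
        kv: dict[str, str] = {}
        for line in Path(config_path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        if "seed" in kv:
            plan.seed = int(kv["seed"])
        if "overlap_k" in kv:
            plan.overlap_k = int(kv["overlap_k"])
        if "min_length" in kv and "max_length" in kv:
            plan.length_range = (int(kv["min_length"]), int(kv["max_length"]))
        if "countries" in kv and kv["countries"]:
            pool: list[tuple[Optional[str], int]] = []
            for item in kv["countries"].split(","):
                name, _, weight = item.rpartition(":")
                pool.append((name or None, int(weight)))
            plan.country_pool = pool
    plan.validate()
    return plan


def demo_plan(seed: int = 0) -> CoveragePlan:
    """A small plan with deliberate gaps: a congener-only species (genus
    fallback fires) and an unregistered species (all-zero row, no walk)."""
    organisms = [
        OrganismSpec("Aquarana catesbeiana", "Aquarana", "Ranidae", "Anura"),
        OrganismSpec("Aquarana clamitans", "Aquarana", "Ranidae", "Anura"),
        OrganismSpec("Xenopus laevis", "Xenopus", "Pipidae", "Anura"),
        OrganismSpec("Dreissena polymorpha", "Dreissena", "Dreissenidae", "Myida"),
        OrganismSpec(
            "Euwallacea whitfordiodendrus",
            "Euwallacea",
            "Curculionidae",
            "Coleoptera",
            registered=False,
        ),
    ]
    barcodes = ["CO1", "16S", "18S", "12S"]
    counts: dict[tuple[str, str], int] = {}
    planted = {
        ("Aquarana catesbeiana", "CO1"): 0,  # falls back to genus via congener
        ("Aquarana catesbeiana", "16S"): 0,
        ("Aquarana clamitans", "CO1"): 4,
        ("Aquarana clamitans", "16S"): 2,
        ("Xenopus laevis", "CO1"): 7,
        ("Xenopus laevis", "16S"): 3,
        ("Xenopus laevis", "12S"): 2,
        ("Dreissena polymorpha", "16S"): 1,
    }
    for org in organisms:
        for b in barcodes:
            counts[(org.binomial, b)] = planted.get((org.binomial, b), 0)
    return CoveragePlan(
        organisms=organisms,
        barcodes=barcodes,
        planted_counts=counts,
        overlap_k=3,
        seed=seed,
    )
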