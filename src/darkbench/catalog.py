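"""Genome catalogs and curation rules for known vs. uncharacterized genomes.

A benchmark community mixes three genome classes: ``ncbi_available``
(species present in the reference taxonomy before the profiler databases
were built), ``new_ncbi`` (species added to the taxonomy afterwards, hence
invisible to the databases), and ``new_sgb`` (species-level genome bins with
no species-level placement at all).  The curation rules here cap the number
of SGBs per genus by assembly quality, optionally swap reference genomes for
high-quality environmental SGBs of the same species, and rank known species
by their average abundance in real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .taxonomy import CANONICAL_RANKS, Lineage

STATUSES = ("ncbi_available", "new_ncbi", "new_sgb")


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    length_bp: int
    status: str
    lineage: Lineage
    completeness: float = 100.0
    contamination: float = 0.0
    rank_order: int | None = None
    fasta_path: str | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        if self.length_bp <= 0:
            raise ValidationError("length_bp must be positive")
        if self.status == "ncbi_available" and "species" not in self.lineage.assignments:
            raise ValidationError(
                f"{self.genome_id}: ncbi_available genomes need a species assignment"
            )


def quality_score(record_or_completeness, contamination: float | None = None) -> float:
    """Assembly quality: completeness minus five times contamination."""
    if contamination is None:
        completeness = record_or_completeness.completeness
        contamination = record_or_completeness.contamination
    else:
        completeness = record_or_completeness
    if not (0 <= completeness <= 100) or not (0 <= contamination <= 100):
        raise ValidationError("completeness/contamination must be in [0, 100]")
    return completeness - 5.0 * contamination


@dataclass
class GenomeCatalog:
    records: dict[str, GenomeRecord] = field(default_factory=dict)
    environment: str = "unspecified"

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self.records[genome_id]

    def __iter__(self):
        return iter(self.records.values())

    def by_status(self, status: str) -> list[GenomeRecord]:
        if status not in STATUSES:
            raise ValidationError(f"unknown status {status!r}")
        return [r for r in self.records.values() if r.status == status]

    def known_species_ranked(self) -> list[GenomeRecord]:
        """ncbi_available records in ascending rank_order (1 = most abundant).

        Records without a rank_order sort after ranked ones, by genome_id.
        """
        recs = self.by_status("ncbi_available")
        return sorted(
            recs,
            key=lambda r: (r.rank_order is None, r.rank_order or 0, r.genome_id),
        )

    def uncharacterized(self) -> list[GenomeRecord]:
        return sorted(
            (r for r in self.records.values() if r.status != "ncbi_available"),
            key=lambda r: r.genome_id,
        )

    # -- persistence ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for record in sorted(self.records.values(), key=lambda r: r.genome_id):
            row = {
                "genome_id": record.genome_id,
                "length_bp": record.length_bp,
                "status": record.status,
                "completeness": record.completeness,
                "contamination": record.contamination,
                "rank_order": record.rank_order,
                "fasta_path": record.fasta_path,
            }
            for rank in CANONICAL_RANKS:
                taxon = record.lineage.assignments.get(rank)
                row[rank] = taxon if taxon is not None else pd.NA
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, stream: IO[str]) -> None:
        self.to_frame().to_csv(stream, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, stream: IO[str], environment: str = "unspecified") -> "GenomeCatalog":
        frame = pd.read_csv(stream, sep="\t")
        records: dict[str, GenomeRecord] = {}
        for _, row in frame.iterrows():
            assignments = {
                rank: int(row[rank])
                for rank in CANONICAL_RANKS
                if rank in frame.columns and pd.notna(row[rank])
            }
            rank_order = (
                int(row["rank_order"]) if pd.notna(row.get("rank_order")) else None
            )
            fasta = row.get("fasta_path")
            record = GenomeRecord(
                genome_id=str(row["genome_id"]),
                length_bp=int(row["length_bp"]),
                status=str(row["status"]),
                lineage=Lineage(assignments),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                rank_order=rank_order,
                fasta_path=None if pd.isna(fasta) else str(fasta),
            )
            records[record.genome_id] = record
        return cls(records=records, environment=environment)


def select_sgbs_per_genus(
    catalog: GenomeCatalog, max_per_genus: int = 10
) -> list[str]:
    """Cap new SGBs per genus by quality score.

    Within each genus (records with an unknown genus form their own group),
    keep the top *max_per_genus* ``new_sgb`` records ranked by
    :func:`quality_score` descending; quality ties break toward the
    lexicographically smaller genome_id.
    """
    groups: dict[object, list[GenomeRecord]] = {}
    for record in catalog.by_status("new_sgb"):
        genus = record.lineage.assignments.get("genus")
        groups.setdefault(genus, []).append(record)
    selected: list[str] = []
    for genus in sorted(groups, key=lambda g: (g is None, g)):
        members = sorted(
            groups[genus], key=lambda r: (-quality_score(r), r.genome_id)
        )
        selected.extend(r.genome_id for r in members[:max_per_genus])
    return selected


def swap_reference_with_sgb(catalog: GenomeCatalog) -> GenomeCatalog:
    """Replace reference genomes with same-species high-quality SGBs.

    An SGB replaces the reference genome's sequence/length when (1) it has a
    recognized species assignment, (2) that species is already present among
    the ``ncbi_available`` records, and (3) it is more than 90% complete with
    less than 5% contamination.  The reference keeps its status and species
    identity; the SGB record is absorbed.  The count of ``ncbi_available``
    species never changes.
    """
    species_to_ref = {
        r.lineage.assignments["species"]: r.genome_id
        for r in catalog.by_status("ncbi_available")
    }
    records = dict(catalog.records)
    for sgb in sorted(catalog.by_status("new_sgb"), key=lambda r: r.genome_id):
        species = sgb.lineage.assignments.get("species")
        if (
            species is not None
            and species in species_to_ref
            and sgb.completeness > 90
            and sgb.contamination < 5
        ):
            ref_id = species_to_ref[species]
            records[ref_id] = replace(
                records[ref_id],
                length_bp=sgb.length_bp,
                fasta_path=sgb.fasta_path,
            )
            del records[sgb.genome_id]
    return GenomeCatalog(records=records, environment=catalog.environment)


def rank_known_species(mean_abundances: Mapping[str, float]) -> list[str]:
    """Order species by descending mean abundance across profiling methods.

    Ties break by species id ascending; the returned order defines
    rank_order 1..n.
    """
    for species, abundance in mean_abundances.items():
        if abundance < 0 or math.isnan(abundance):
            raise ValidationError(f"invalid abundance for {species!r}: {abundance}")
    return sorted(mean_abundances, key=lambda s: (-mean_abundances[s], s))
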