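"""Synthetic taxonomies, catalogs, sequences and error-bearing profiles.

Everything the benchmark consumes — taxonomy dumps, genome catalogs,
nucleotide sequences, method database name lists, and assigned profiles
carrying realistic profiler error modes (drops, false positives, abundance
noise, rank truncation, extra unknown mass) — can be generated here from a
seed, so the whole pipeline is testable without downloads.  Sequences are
i.i.d. uniform nucleotides: adequate for sketching and mutation mechanics,
not for read-simulator realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .catalog import GenomeCatalog, GenomeRecord
from .errors import ValidationError
from .postprocess import AssignedProfile, RankProfile
from .simdesign import derive_seed
from .taxonomy import Lineage, TaxonomyTable, parse_taxonomy_dump


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic taxonomy/catalog pair."""

    n_phyla: int = 3
    families_per_phylum: int = 3
    genera_per_family: int = 3
    species_per_genus: int = 4
    status_mix: tuple[float, float, float] = (0.5, 0.2, 0.3)
    genome_size_median: int = 40_000
    genome_size_spread: float = 0.25
    synonym_rate: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.status_mix) - 1.0) > 1e-9:
            raise ValidationError("status_mix must sum to 1")
        for count in (
            self.n_phyla,
            self.families_per_phylum,
            self.genera_per_family,
            self.species_per_genus,
        ):
            if count < 1:
                raise ValidationError("all fixture counts must be >= 1")

    @property
    def n_species(self) -> int:
        return (
            self.n_phyla
            * self.families_per_phylum
            * self.genera_per_family
            * self.species_per_genus
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """Profiler error modes injected into an assigned profile."""

    drop_rate: float = 0.0
    false_positive_rate: float = 0.0
    abundance_noise_cv: float = 0.0
    rank_truncation_prob: float = 0.0
    extra_unknown_mass: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "drop_rate",
            "false_positive_rate",
            "rank_truncation_prob",
            "extra_unknown_mass",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.abundance_noise_cv < 0:
            raise ValidationError("abundance_noise_cv must be >= 0")


def make_taxonomy(spec: FixtureSpec) -> tuple[str, str]:
    """Render deterministic (names.dmp, nodes.dmp) text for the spec.

    The tree has a full canonical ladder: root, one superkingdom, one
    kingdom, then the configured phyla each with one class and one order,
    under which families, genera and species fan out.  Species acquire a
    synonym line with probability ``synonym_rate``.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "taxonomy"))
    names_lines: list[str] = []
    nodes_lines: list[str] = []
    next_id = 1

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        taxon_id = next_id
        next_id += 1
        nodes_lines.append(f"{taxon_id}\t|\t{parent}\t|\t{rank}\t|")
        names_lines.append(f"{taxon_id}\t|\t{name}\t|\t\t|\tscientific name\t|")
        return taxon_id

    root = add(1, "no rank", "root")
    superkingdom = add(root, "superkingdom", "Bacteria")
    kingdom = add(superkingdom, "kingdom", "Eubacteria")
    for p in range(1, spec.n_phyla + 1):
        phylum = add(kingdom, "phylum", f"Phylum{p}")
        klass = add(phylum, "class", f"Class{p}")
        order = add(klass, "order", f"Order{p}")
        for f in range(1, spec.families_per_phylum + 1):
            family = add(order, "family", f"Family{p}.{f}")
            for g in range(1, spec.genera_per_family + 1):
                genus = add(family, "genus", f"Genus{p}.{f}.{g}")
                for s in range(1, spec.species_per_genus + 1):
                    name = f"Species{p}.{f}.{g}.{s}"
                    species = add(genus, "species", name)
                    if rng.random() < spec.synonym_rate:
                        names_lines.append(
                            f"{species}\t|\tSynonym{p}.{f}.{g}.{s}\t|\t\t|\tsynonym\t|"
                        )
    return "\n".join(names_lines) + "\n", "\n".join(nodes_lines) + "\n"


def fixture_taxonomy(spec: FixtureSpec) -> TaxonomyTable:
    names, nodes = make_taxonomy(spec)
    return parse_taxonomy_dump(names, nodes)


_SGB_TRUNCATION_RANKS = ("genus", "family", "order")


def make_catalog_and_sequences(
    taxonomy: TaxonomyTable,
    spec: FixtureSpec,
    with_sequences: bool = False,
) -> tuple[GenomeCatalog, dict[str, str]]:
    """One genome per species, with sizes, statuses and quality stats.

    Statuses follow ``status_mix``; ``new_ncbi`` genomes keep their lineage
    only to genus (their species postdates the reference cutoff) and
    ``new_sgb`` genomes truncate at a random rank among genus/family/order.
    Sequences (uniform random nucleotides of exactly the catalog lengths)
    are generated only on request.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "catalog"))
    species_nodes = sorted(
        (n for n in taxonomy.nodes.values() if n.rank == "species"),
        key=lambda n: n.taxon_id,
    )
    statuses = rng.choice(
        ["ncbi_available", "new_ncbi", "new_sgb"],
        size=len(species_nodes),
        p=list(spec.status_mix),
    )
    log_sizes = rng.normal(
        np.log(spec.genome_size_median), spec.genome_size_spread, len(species_nodes)
    )
    known_order = rng.permutation(len(species_nodes))
    records: dict[str, GenomeRecord] = {}
    sequences: dict[str, str] = {}
    next_rank = 1
    for idx in known_order:
        node = species_nodes[idx]
        status = str(statuses[idx])
        lineage = taxonomy.lineage(node.taxon_id)
        if status == "new_ncbi":
            lineage = lineage.truncated("genus")
        elif status == "new_sgb":
            cut = _SGB_TRUNCATION_RANKS[rng.integers(0, len(_SGB_TRUNCATION_RANKS))]
            lineage = lineage.truncated(cut)
        if status == "ncbi_available":
            completeness = float(rng.uniform(95, 100))
            contamination = float(rng.uniform(0, 1))
            rank_order = next_rank
            next_rank += 1
        else:
            completeness = float(rng.uniform(55, 100))
            contamination = float(rng.uniform(0, 12))
            rank_order = None
        genome_id = f"G{node.taxon_id:05d}"
        records[genome_id] = GenomeRecord(
            genome_id=genome_id,
            length_bp=int(round(np.exp(log_sizes[idx]))),
            status=status,
            lineage=lineage,
            completeness=completeness,
            contamination=contamination,
            rank_order=rank_order,
        )
    catalog = GenomeCatalog(records=records, environment="fixture")
    if with_sequences:
        seq_rng = np.random.default_rng(derive_seed(spec.seed, "sequences"))
        for genome_id in sorted(records):
            length = records[genome_id].length_bp
            bases = seq_rng.integers(0, 4, size=length)
            sequences[genome_id] = (
                np.frombuffer(b"ACGT", dtype=np.uint8)[bases].tobytes().decode()
            )
    return catalog, sequences


def make_method_namemap(
    taxonomy: TaxonomyTable, spec: FixtureSpec
) -> list[str]:
    """Simulated method database taxa list with misses and synonyms.

    Each taxon is present with probability ``1 − missing_rate``; present
    taxa that have a synonym are reported by it with probability
    ``synonym_rate``.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "namemap"))
    reported: list[str] = []
    for taxon_id in sorted(taxonomy.nodes):
        node = taxonomy.nodes[taxon_id]
        if rng.random() < spec.missing_rate:
            continue
        synonyms = sorted(node.synonyms)
        if synonyms and rng.random() < spec.synonym_rate:
            reported.append(synonyms[0])
        else:
            reported.append(node.scientific_name)
    return reported


def perturb_profile(
    truth: RankProfile,
    spec: PerturbationSpec,
    taxonomy: TaxonomyTable,
) -> AssignedProfile:
    """Inject profiler-like errors into a true rank profile.

    True taxa drop out at ``drop_rate``; survivors get multiplicative
    log-normal noise with the given coefficient of variation; false
    positives are drawn from same-rank off-profile taxa at an expected
    count of ``false_positive_rate × |truth|``; each survivor is replaced
    by its parent taxon with probability ``rank_truncation_prob``; and
    ``extra_unknown_mass`` is declared as unknown.  The output totals 1.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "perturb"))
    sigma = float(np.sqrt(np.log1p(spec.abundance_noise_cv**2)))
    entries: dict = {}
    for taxon in sorted(truth.entries):
        if rng.random() < spec.drop_rate:
            continue
        weight = truth.entries[taxon]
        if sigma > 0:
            weight *= float(np.exp(rng.normal(-(sigma**2) / 2, sigma)))
        key = taxon
        if spec.rank_truncation_prob > 0 and rng.random() < spec.rank_truncation_prob:
            key = taxonomy.nodes[taxon].parent_id
        entries[key] = entries.get(key, 0.0) + weight

    if spec.false_positive_rate > 0:
        pool = sorted(
            n.taxon_id
            for n in taxonomy.nodes.values()
            if n.rank == truth.rank and n.taxon_id not in truth.entries
        )
        n_fp = min(rng.poisson(spec.false_positive_rate * len(truth.entries)), len(pool))
        if n_fp and entries:
            typical = float(np.median(list(truth.entries.values())))
            for taxon in rng.choice(pool, size=n_fp, replace=False):
                entries[int(taxon)] = entries.get(int(taxon), 0.0) + typical * float(
                    rng.uniform(0.2, 1.0)
                )

    total = sum(entries.values())
    if total == 0:
        return AssignedProfile(
            rank=truth.rank, entries={}, declared_unknown_mass=1.0
        )
    keep = 1.0 - spec.extra_unknown_mass
    entries = {k: v / total * keep for k, v in entries.items()}
    return AssignedProfile(
        rank=truth.rank,
        entries=entries,
        declared_unknown_mass=spec.extra_unknown_mass,
    )
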