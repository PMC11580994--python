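"""Thresholding, unknown-mass handling, rank aggregation, and the
NCBI-available restriction.

Assigned profiles pass through a fixed pipeline before comparison: a 0.05%
abundance threshold (limits false positives from k-mer classifiers), then
removal of declared unknown mass, unknown-labelled names, and unmappable
entries, then renormalization.  The truth side is restricted at each rank
to the genomes whose taxonomy is recognized at that rank, so methods are
not penalized for marking genuinely uncharacterized abundance as unknown
but are penalized for assigning it to recognized taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .catalog import GenomeCatalog
from .errors import DegenerateProfileError, ValidationError
from .simdesign import TrueProfile
from .taxonomy import (
    UNKNOWN,
    UNMAPPABLE,
    TaxonomyTable,
    is_unknown_label,
    rank_depth,
)

#: Ranks at which profiles are evaluated.
EVALUATION_RANKS = ("phylum", "family", "genus", "species")

#: Default relative-abundance threshold (0.05%).
DEFAULT_THRESHOLD = 0.0005


@dataclass
class AssignedProfile:
    """One method's profile at one rank, before or after harmonization.

    Keys may be taxon IDs, raw names, or the :data:`UNMAPPABLE` sentinel;
    ``declared_unknown_mass`` is abundance the method itself marked unknown.
    Entries plus declared unknown mass are expected to total 1 for a
    normalized profile.
    """

    rank: str
    entries: dict = field(default_factory=dict)
    declared_unknown_mass: float = 0.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.entries.values()):
            raise ValidationError("abundances must be nonnegative")
        if self.declared_unknown_mass < 0:
            raise ValidationError("declared_unknown_mass must be nonnegative")

    @property
    def total(self) -> float:
        return sum(self.entries.values()) + self.declared_unknown_mass


@dataclass
class RankProfile:
    """Taxon-ID-keyed relative abundances at one rank."""

    rank: str
    entries: dict[int, float] = field(default_factory=dict)
    provenance: str = "assigned"

    def normalized(self) -> "RankProfile":
        total = sum(self.entries.values())
        if total <= 0:
            raise DegenerateProfileError(f"empty {self.rank} profile")
        return RankProfile(
            rank=self.rank,
            entries={t: a / total for t, a in self.entries.items()},
            provenance=self.provenance,
        )


def apply_threshold(
    profile: AssignedProfile, theta: float = DEFAULT_THRESHOLD
) -> AssignedProfile:
    """Drop entries below *theta* of current total mass and renormalize.

    The declared unknown mass is carried through the renormalization
    unchanged in proportion.  Raises if every entry falls below threshold.
    """
    if theta == 0:
        return profile
    total = profile.total
    if total <= 0:
        raise DegenerateProfileError("profile has no mass")
    survivors = {
        k: a for k, a in profile.entries.items() if a / total >= theta
    }
    if not survivors and profile.declared_unknown_mass == 0:
        raise DegenerateProfileError("all entries fell below the threshold")
    remaining = sum(survivors.values()) + profile.declared_unknown_mass
    scale = 1.0 / remaining if remaining > 0 else 0.0
    return AssignedProfile(
        rank=profile.rank,
        entries={k: a * scale * total for k, a in survivors.items()},
        declared_unknown_mass=profile.declared_unknown_mass * scale * total,
    )


def strip_unknown_and_unmappable(profile: AssignedProfile) -> RankProfile:
    """Remove unknown/unmappable mass and renormalize to a RankProfile.

    Removed: the declared unknown mass, entries keyed by the
    :data:`UNMAPPABLE` sentinel, and entries keyed by strings that
    :func:`~darkbench.taxonomy.is_unknown_label` flags.
    """
    survivors: dict[int, float] = {}
    for key, abundance in profile.entries.items():
        if key is UNMAPPABLE:
            continue
        if isinstance(key, str):
            if is_unknown_label(key):
                continue
            raise ValidationError(
                f"unharmonized name {key!r}: harmonize before stripping"
            )
        survivors[key] = survivors.get(key, 0.0) + abundance
    total = sum(survivors.values())
    if total <= 0:
        raise DegenerateProfileError(
            f"no mappable known mass survives at rank {profile.rank}"
        )
    return RankProfile(
        rank=profile.rank,
        entries={t: a / total for t, a in survivors.items()},
        provenance="assigned",
    )


def aggregate_to_rank(
    profile: AssignedProfile | RankProfile,
    target_rank: str,
    taxonomy: TaxonomyTable,
) -> AssignedProfile:
    """Sum abundances into ancestor taxa at *target_rank*.

    Mass whose taxon has no ancestor at the target rank joins the declared
    unknown mass; string-keyed (unknown-labelled) entries are carried
    unchanged for downstream stripping.
    """
    if rank_depth(target_rank) > rank_depth(profile.rank):
        raise ValidationError(
            f"cannot aggregate {profile.rank} down to {target_rank}"
        )
    entries: dict = {}
    unknown_mass = getattr(profile, "declared_unknown_mass", 0.0)
    for key, abundance in profile.entries.items():
        if key is UNMAPPABLE or isinstance(key, str):
            entries[key] = entries.get(key, 0.0) + abundance
            continue
        ancestor = taxonomy.lineage_query(key, target_rank)
        if ancestor is UNKNOWN:
            unknown_mass += abundance
        else:
            entries[ancestor] = entries.get(ancestor, 0.0) + abundance
    return AssignedProfile(
        rank=target_rank, entries=entries, declared_unknown_mass=unknown_mass
    )


def restrict_truth_to_available(
    true_profile: TrueProfile,
    rank: str,
    catalog: GenomeCatalog,
) -> RankProfile:
    """The reference-available portion of the truth at one rank.

    A genome contributes iff its lineage carries a recognized taxon at
    *rank* (i.e. the rank is at or above its lowest known rank); the
    contributions are aggregated by taxon ID and renormalized to 1.
    """
    rank_depth(rank)
    entries: dict[int, float] = {}
    for genome_id, abundance in true_profile.abundances.items():
        taxon = catalog[genome_id].lineage.at(rank)
        if taxon is UNKNOWN:
            continue
        entries[taxon] = entries.get(taxon, 0.0) + abundance
    total = sum(entries.values())
    if total <= 0:
        raise DegenerateProfileError(f"no genome is available at rank {rank}")
    return RankProfile(
        rank=rank,
        entries={t: a / total for t, a in entries.items()},
        provenance="truth",
    )


def assembly_unknown_fraction(
    unaligned_read_prop: float,
    low_quality_mag_mass: float,
    unplaced_mag_mass: float,
) -> float:
    """Unknown abundance of an assembly run: unaligned reads plus
    low-quality MAG mass plus taxonomically unplaced MAG mass."""
    parts = (unaligned_read_prop, low_quality_mag_mass, unplaced_mag_mass)
    if any(p < 0 or p > 1 for p in parts):
        raise ValidationError("all components must be in [0, 1]")
    total = sum(parts)
    if total > 1 + 1e-12:
        raise ValidationError(f"components sum to {total} > 1")
    return min(total, 1.0)


def truth_as_assigned(
    true_profile: TrueProfile, catalog: GenomeCatalog, rank: str = "species"
) -> AssignedProfile:
    """Re-key the truth as an assigned profile at one rank.

    Genomes without a recognized taxon at *rank* become declared unknown
    mass — this is what a perfectly calibrated profiler would report.
    """
    entries: dict[int, float] = {}
    unknown_mass = 0.0
    for genome_id, abundance in true_profile.abundances.items():
        taxon = catalog[genome_id].lineage.at(rank)
        if taxon is UNKNOWN:
            unknown_mass += abundance
        else:
            entries[taxon] = entries.get(taxon, 0.0) + abundance
    return AssignedProfile(
        rank=rank, entries=entries, declared_unknown_mass=unknown_mass
    )


def postprocess_assigned(
    profile: AssignedProfile,
    target_rank: str,
    taxonomy: TaxonomyTable,
    theta: float = DEFAULT_THRESHOLD,
) -> RankProfile:
    """Full assigned-side pipeline: aggregate, threshold, strip, normalize."""
    aggregated = aggregate_to_rank(profile, target_rank, taxonomy)
    thresholded = apply_threshold(aggregated, theta)
    return strip_unknown_and_unmappable(thresholded)


def postprocess_truth(
    true_profile: TrueProfile,
    target_rank: str,
    catalog: GenomeCatalog,
    theta: float = 0.0,
) -> RankProfile:
    """Truth-side pipeline: availability restriction, optional threshold."""
    restricted = restrict_truth_to_available(true_profile, target_rank, catalog)
    if theta > 0:
        thresholded = apply_threshold(
            AssignedProfile(rank=target_rank, entries=dict(restricted.entries)),
            theta,
        )
        restricted = RankProfile(
            rank=target_rank,
            entries=dict(thresholded.entries),
            provenance="truth",
        ).normalized()
    return restricted
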