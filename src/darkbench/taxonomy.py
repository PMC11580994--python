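"""NCBI-style taxonomy tables and harmonization of profiler taxon names.

Different taxonomic profilers report the same organism under different
names (synonyms, underscored variants, case differences).  Comparing their
output profiles therefore requires mapping every reported name onto a stable
numeric taxon ID drawn from a single taxonomy.  This module parses the
``names.dmp``/``nodes.dmp`` dump dialect, builds a synonym-aware name index,
and converts name-keyed abundance profiles into ID-keyed ones, keeping
explicit track of the abundance mass that cannot be mapped.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .errors import ParseError, StructureError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical rank ladder, highest to lowest.  Nodes of any other rank are
#: traversed transparently during lineage queries.
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_DEPTH = {r: i for i, r in enumerate(CANONICAL_RANKS)}


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._name


#: Returned when a lineage has no taxon at the requested rank.
UNKNOWN = _Sentinel("UNKNOWN")
#: Returned when a reported name has no match in the taxonomy.
UNMAPPABLE = _Sentinel("UNMAPPABLE")


def normalize_name(name: str) -> str:
    """Normalize a taxon name for index lookup.

    Underscores become spaces, internal whitespace collapses to single
    spaces, surrounding whitespace is trimmed, and the result is case-folded.
    """
    return " ".join(name.replace("_", " ").split()).casefold()


def is_unknown_label(name: str) -> bool:
    """True if a reported taxon name denotes unclassified abundance.

    Blank names and names containing ``noname`` or ``incertae``
    (case-insensitive) are treated as unknown mass rather than real taxa.
    """
    if not name or not name.strip():
        return True
    low = name.casefold()
    return "noname" in low or "incertae" in low


def rank_depth(rank: str) -> int:
    """Position of *rank* in the canonical ladder (0 = superkingdom)."""
    try:
        return _RANK_DEPTH[rank]
    except KeyError:
        raise ValidationError(f"not a canonical rank: {rank!r}") from None


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: int
    parent_id: int
    rank: str
    scientific_name: str
    synonyms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Lineage:
    """Per-rank taxon assignment for one genome or MAG.

    ``assignments`` holds taxon IDs for the canonical ranks at which the
    entity has a recognized taxon; absent ranks are unknown.  If a rank is
    assigned, every rank above it must be assigned too.
    """

    assignments: Mapping[str, int]

    def __post_init__(self) -> None:
        seen = False
        for rank in reversed(CANONICAL_RANKS):
            if rank in self.assignments:
                seen = True
            elif seen and rank != CANONICAL_RANKS[0]:
                # gaps above an assigned rank are allowed only for ranks the
                # source taxonomy genuinely lacks; enforce contiguity from the
                # deepest assigned rank upward.
                raise ValidationError(
                    f"lineage gap: rank {rank!r} unassigned below an assigned rank"
                )

    def at(self, rank: str):
        """Taxon ID at *rank*, or :data:`UNKNOWN`."""
        rank_depth(rank)
        return self.assignments.get(rank, UNKNOWN)

    @property
    def lowest_known_rank(self) -> str | None:
        for rank in reversed(CANONICAL_RANKS):
            if rank in self.assignments:
                return rank
        return None

    def truncated(self, lowest_rank: str) -> "Lineage":
        """Copy of this lineage with all ranks below *lowest_rank* dropped."""
        depth = rank_depth(lowest_rank)
        return Lineage(
            {r: t for r, t in self.assignments.items() if rank_depth(r) <= depth}
        )


def taxonomy_contained(inner: Lineage, outer: Lineage) -> bool:
    """True iff every rank assigned in *inner* agrees with *outer*.

    Used to test whether a MAG's (possibly shallower) NCBI-mappable taxonomy
    is contained within a source genome's taxonomy.  An empty *inner*
    lineage is vacuously contained.
    """
    for rank, taxon in inner.assignments.items():
        if outer.assignments.get(rank) != taxon:
            return False
    return True


class TaxonomyTable:
    """Rank-annotated taxon tree with synonym-aware name resolution.

    Parameters
    ----------
    nodes
        Mapping of taxon_id to :class:`TaxonNode`.  The root must be its own
        parent; every other parent_id must exist in the mapping.
    """

    def __init__(self, nodes: Mapping[int, TaxonNode]) -> None:
        self.nodes: dict[int, TaxonNode] = dict(nodes)
        roots = [n for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root node, found {len(roots)}")
        self.root_id = roots[0].taxon_id
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise StructureError(
                    f"node {node.taxon_id} has orphan parent_id {node.parent_id}"
                )
        self.name_index: dict[str, int] = {}
        for taxon_id in sorted(self.nodes):
            node = self.nodes[taxon_id]
            for name in (node.scientific_name, *sorted(node.synonyms)):
                key = normalize_name(name)
                if key in self.name_index and self.name_index[key] != taxon_id:
                    # ambiguous name: keep the lexicographically smallest id
                    logger.warning(
                        "ambiguous taxon name %r: keeping id %d, ignoring %d",
                        name,
                        min(self.name_index[key], taxon_id),
                        max(self.name_index[key], taxon_id),
                    )
                    self.name_index[key] = min(self.name_index[key], taxon_id)
                else:
                    self.name_index[key] = taxon_id

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def resolve(self, name: str):
        """Taxon ID for *name* (synonyms included), or :data:`UNMAPPABLE`."""
        return self.name_index.get(normalize_name(name), UNMAPPABLE)

    def lineage_query(self, taxon_id: int, rank: str):
        """Walk the parent chain of *taxon_id* to its ancestor at *rank*.

        Returns :data:`UNKNOWN` when the chain has no node of that rank
        (e.g. a phylum queried at species rank).
        """
        rank_depth(rank)
        if taxon_id not in self.nodes:
            raise KeyError(f"taxon_id {taxon_id} not in table")
        current = taxon_id
        while True:
            node = self.nodes[current]
            if node.rank == rank:
                return node.taxon_id
            if current == self.root_id:
                return UNKNOWN
            current = node.parent_id

    def lineage(self, taxon_id: int) -> Lineage:
        """Full canonical-rank lineage of *taxon_id* from the tree."""
        if taxon_id not in self.nodes:
            raise KeyError(f"taxon_id {taxon_id} not in table")
        assignments: dict[str, int] = {}
        current = taxon_id
        while True:
            node = self.nodes[current]
            if node.rank in _RANK_DEPTH:
                assignments[node.rank] = node.taxon_id
            if current == self.root_id:
                break
            current = node.parent_id
        return Lineage(assignments)

    # -- dump dialect -----------------------------------------------------

    def to_dump(self) -> tuple[str, str]:
        """Render the table back to (names.dmp, nodes.dmp) text."""
        names = io.StringIO()
        nodes = io.StringIO()
        for taxon_id in sorted(self.nodes):
            node = self.nodes[taxon_id]
            nodes.write(f"{taxon_id}\t|\t{node.parent_id}\t|\t{node.rank}\t|\n")
            names.write(
                f"{taxon_id}\t|\t{node.scientific_name}\t|\t\t|\tscientific name\t|\n"
            )
            for syn in sorted(node.synonyms):
                names.write(f"{taxon_id}\t|\t{syn}\t|\t\t|\tsynonym\t|\n")
        return names.getvalue(), nodes.getvalue()


def _split_dmp_line(line: str, lineno: int, path: str) -> list[str]:
    stripped = line.rstrip("\n")
    if not stripped.endswith("\t|"):
        raise ParseError(f"{path}: line {lineno}: missing '\\t|' terminator")
    return stripped[:-2].split("\t|\t")


def parse_taxonomy_dump(
    names_stream: IO[str] | str, nodes_stream: IO[str] | str
) -> TaxonomyTable:
    """Parse NCBI-dialect ``names.dmp``/``nodes.dmp`` into a table.

    Lines use ``\\t|\\t`` field separators and a ``\\t|`` terminator.  The
    ``scientific name`` class sets each node's primary name; all other name
    classes attach as synonyms so that any recognized variant resolves to
    the same numeric ID.
    """
    if isinstance(names_stream, str):
        names_stream = io.StringIO(names_stream)
    if isinstance(nodes_stream, str):
        nodes_stream = io.StringIO(nodes_stream)

    parents: dict[int, int] = {}
    ranks: dict[int, str] = {}
    for lineno, line in enumerate(nodes_stream, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, "nodes.dmp")
        if len(fields) < 3:
            raise ParseError(f"nodes.dmp: line {lineno}: expected >= 3 fields")
        try:
            taxon_id, parent_id = int(fields[0]), int(fields[1])
        except ValueError:
            raise ParseError(
                f"nodes.dmp: line {lineno}: non-integer taxon or parent id"
            ) from None
        parents[taxon_id] = parent_id
        ranks[taxon_id] = fields[2].strip()

    sci_names: dict[int, str] = {}
    synonyms: dict[int, set[str]] = {}
    for lineno, line in enumerate(names_stream, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, "names.dmp")
        if len(fields) < 4:
            raise ParseError(f"names.dmp: line {lineno}: expected >= 4 fields")
        try:
            taxon_id = int(fields[0])
        except ValueError:
            raise ParseError(f"names.dmp: line {lineno}: non-integer taxon id") from None
        if taxon_id not in parents:
            raise StructureError(
                f"names.dmp: line {lineno}: taxon {taxon_id} absent from nodes.dmp"
            )
        name, name_class = fields[1], fields[3].strip()
        if name_class == "scientific name":
            sci_names[taxon_id] = name
        else:
            synonyms.setdefault(taxon_id, set()).add(name)

    nodes: dict[int, TaxonNode] = {}
    for taxon_id, parent_id in parents.items():
        if taxon_id not in sci_names:
            raise StructureError(f"taxon {taxon_id} has no scientific name")
        nodes[taxon_id] = TaxonNode(
            taxon_id=taxon_id,
            parent_id=parent_id,
            rank=ranks[taxon_id],
            scientific_name=sci_names[taxon_id],
            synonyms=frozenset(synonyms.get(taxon_id, ())),
        )
    return TaxonomyTable(nodes)


@dataclass
class NameMap:
    """Deterministic map from method-reported names to taxon IDs.

    Misses are data, not errors: absent names map to :data:`UNMAPPABLE` and
    are persisted as ``NA``.
    """

    entries: dict[str, int | _Sentinel] = field(default_factory=dict)

    def __getitem__(self, name: str):
        return self.entries.get(name, UNMAPPABLE)

    def mapped_fraction(self) -> float:
        if not self.entries:
            return 0.0
        hits = sum(1 for v in self.entries.values() if v is not UNMAPPABLE)
        return hits / len(self.entries)

    def to_tsv(self, stream: IO[str]) -> None:
        for name in sorted(self.entries):
            value = self.entries[name]
            out = "NA" if value is UNMAPPABLE else str(value)
            stream.write(f"{name}\t{out}\n")

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "NameMap":
        entries: dict[str, int | _Sentinel] = {}
        for lineno, line in enumerate(stream, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"name map line {lineno}: expected 2 columns")
            entries[parts[0]] = UNMAPPABLE if parts[1] == "NA" else int(parts[1])
        return cls(entries)


def build_name_map(
    database_taxa: Iterable[str], taxonomy: TaxonomyTable
) -> NameMap:
    """Resolve each database taxon name to a numeric ID where possible."""
    return NameMap({name: taxonomy.resolve(name) for name in database_taxa})


def harmonize_profile(
    raw: Mapping[str, float], name_map: NameMap
) -> tuple[dict[int, float], float]:
    """Re-key a name-keyed abundance profile by taxon ID.

    Abundances are preserved (no renormalization); names resolving to the
    same ID are summed; the summed abundance of unmappable names is returned
    separately so total mass is conserved.
    """
    mapped: dict[int, float] = {}
    unmappable_mass = 0.0
    for name, abundance in raw.items():
        if abundance < 0:
            raise ValidationError(f"negative abundance for {name!r}: {abundance}")
        target = name_map[name]
        if target is UNMAPPABLE:
            unmappable_mass += abundance
        else:
            mapped[target] = mapped.get(target, 0.0) + abundance
    return mapped, unmappable_mass
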