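"""MAG recovery assessment with MinHash genome sketches.

An uncharacterized genome counts as successfully recovered when an
assembly run produced a MAG that (1) is at least 50% complete with less
than 10% contamination, (2) is strictly closer (in Mash distance) to that
genome than to any other input genome, and (3) carries an NCBI-mappable
taxonomy contained within the genome's own taxonomy.  The recovered
abundance of a sample is the summed true abundance of its recovered
genomes.  Bottom-s MinHash sketches over canonical k-mers give the
distance without external tooling; a precomputed distance table can be
supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GenomeCatalog
from .errors import ValidationError
from .simdesign import TrueProfile
from .taxonomy import Lineage, taxonomy_contained

_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte codes


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit mixing function (splitmix64 finalizer)."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return x ^ (x >> np.uint64(31))


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mer set."""

    kmer_size: int
    sketch_size: int
    hashes: tuple[int, ...]  # sorted ascending, <= sketch_size values

    def __post_init__(self) -> None:
        if len(self.hashes) > self.sketch_size:
            raise ValidationError("sketch holds more hashes than sketch_size")


def canonical_kmer_hashes(sequence: str, kmer_size: int) -> np.ndarray:
    """Distinct hashes of all canonical k-mers of *sequence*.

    A k-mer is canonicalized to the lexicographic minimum of itself and its
    reverse complement; k-mers containing non-ACGT characters are skipped.
    """
    if kmer_size < 1 or kmer_size > 31:
        raise ValidationError("kmer_size must be in [1, 31]")
    if len(sequence) < kmer_size:
        raise ValidationError("sequence shorter than kmer_size")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for i, base in enumerate(b"ACGT"):
        code[arr == base] = i
    valid = code >= 0
    n = len(arr) - kmer_size + 1
    if n <= 0:
        raise ValidationError("sequence shorter than kmer_size")
    # rolling 2-bit encodings of forward and reverse-complement k-mers
    window_valid = np.ones(n, dtype=bool)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    code_u = code.astype(np.uint64, copy=False)
    comp_u = (3 - code).astype(np.uint64, copy=False)
    for offset in range(kmer_size):
        chunk = code_u[offset : offset + n]
        window_valid &= valid[offset : offset + n]
        fwd = (fwd << np.uint64(2)) | chunk
        rev |= comp_u[offset : offset + n] << np.uint64(2 * offset)
    canonical = np.minimum(fwd[window_valid], rev[window_valid])
    if canonical.size == 0:
        raise ValidationError("no valid ACGT k-mers in sequence")
    return np.unique(_splitmix64(np.unique(canonical)))


def sketch_genome(
    sequence: str, kmer_size: int = 21, sketch_size: int = 1000
) -> Sketch:
    """Bottom-*sketch_size* MinHash sketch of a genome sequence."""
    hashes = canonical_kmer_hashes(sequence, kmer_size)
    bottom = np.sort(hashes)[:sketch_size]
    return Sketch(
        kmer_size=kmer_size,
        sketch_size=sketch_size,
        hashes=tuple(int(h) for h in bottom),
    )


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance between two sketches.

    The Jaccard index is estimated on the merged bottom sketch and mapped
    through d = −ln(2j / (1 + j)) / k, with d = 1 for disjoint sketches and
    d = 0 for identical ones.
    """
    if a.kmer_size != b.kmer_size:
        raise ValidationError("sketches have different kmer_size")
    s = min(a.sketch_size, b.sketch_size, len(a.hashes) + len(b.hashes))
    union = np.union1d(np.array(a.hashes, dtype=np.uint64), np.array(b.hashes, dtype=np.uint64))
    merged = np.sort(union)[:s]
    set_a, set_b = set(a.hashes), set(b.hashes)
    shared = sum(1 for h in merged if int(h) in set_a and int(h) in set_b)
    if len(merged) == 0:
        raise ValidationError("empty sketches")
    j = shared / len(merged)
    if j <= 0:
        return 1.0
    if j >= 1:
        return 0.0
    d = -math.log(2 * j / (1 + j)) / a.kmer_size
    return min(d, 1.0)


@dataclass(frozen=True)
class MagRecord:
    mag_id: str
    completeness: float
    contamination: float
    assigned_lineage: Lineage
    sketch: Sketch | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100) or not (0 <= self.contamination <= 100):
            raise ValidationError("completeness/contamination must be in [0, 100]")


def is_quality_mag(mag: MagRecord) -> bool:
    """Medium-or-better quality: >= 50% complete and < 10% contaminated."""
    return mag.completeness >= 50 and mag.contamination < 10


@dataclass
class GenomeRecoveryStatus:
    genome_id: str
    recovered: bool
    failing_criterion: str | None
    nearest_distance: float | None
    best_mag: str | None


@dataclass
class RecoveryResult:
    per_genome: dict[str, GenomeRecoveryStatus] = field(default_factory=dict)
    recovered_abundance_percent: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genome_id": s.genome_id,
                "recovered": s.recovered,
                "failing_criterion": s.failing_criterion,
                "nearest_distance": s.nearest_distance,
                "best_mag": s.best_mag,
            }
            for s in sorted(self.per_genome.values(), key=lambda s: s.genome_id)
        ]
        return pd.DataFrame(rows)


def _distance_table(
    mags: Sequence[MagRecord],
    genome_sketches: Mapping[str, Sketch],
) -> pd.DataFrame:
    data = {
        mag.mag_id: {
            genome_id: mash_distance(mag.sketch, sketch)
            for genome_id, sketch in genome_sketches.items()
        }
        for mag in mags
    }
    return pd.DataFrame(data).T  # rows: mags, columns: genomes


def assess_recovery(
    mags: Sequence[MagRecord],
    catalog: GenomeCatalog,
    true_profile: TrueProfile,
    genome_sketches: Mapping[str, Sketch] | None = None,
    distances: pd.DataFrame | None = None,
) -> RecoveryResult:
    """Evaluate the three recovery criteria for every uncharacterized genome.

    Distances may come from precomputed ``distances`` (rows = mag_id,
    columns = genome_id over *all* input genomes) or be derived from
    sketches.  Distance ties between genomes are conservative: the MAG does
    not recover either genome.
    """
    input_genomes = [r.genome_id for r in catalog if r.genome_id in true_profile.abundances]
    if not input_genomes:
        raise ValidationError("no input genomes overlap the true profile")
    if distances is None:
        if genome_sketches is None:
            raise ValidationError("need genome_sketches or a distance table")
        missing = [g for g in input_genomes if g not in genome_sketches]
        if missing:
            raise ValidationError(f"missing sketches for genomes: {missing[:3]}")
        if any(m.sketch is None for m in mags):
            raise ValidationError("every MAG needs a sketch when no table is given")
        distances = _distance_table(
            mags, {g: genome_sketches[g] for g in input_genomes}
        )

    targets = [
        catalog[g] for g in input_genomes if catalog[g].status != "ncbi_available"
    ]
    result = RecoveryResult()
    recovered_mass = 0.0
    mags_by_id = {m.mag_id: m for m in mags}
    for genome in sorted(targets, key=lambda r: r.genome_id):
        status = GenomeRecoveryStatus(
            genome_id=genome.genome_id,
            recovered=False,
            failing_criterion="no_mag" if not mags else None,
            nearest_distance=None,
            best_mag=None,
        )
        failure = "no_mag" if not mags else None
        for mag_id in sorted(mags_by_id):
            mag = mags_by_id[mag_id]
            d_self = float(distances.loc[mag_id, genome.genome_id])
            others = [
                float(distances.loc[mag_id, g])
                for g in input_genomes
                if g != genome.genome_id
            ]
            if status.nearest_distance is None or d_self < status.nearest_distance:
                status.nearest_distance = d_self
                status.best_mag = mag_id
            if others and d_self >= min(others):
                failure = _prefer(failure, "not_nearest")
                continue
            if not is_quality_mag(mag):
                failure = _prefer(failure, "quality")
                continue
            if not taxonomy_contained(mag.assigned_lineage, genome.lineage):
                failure = _prefer(failure, "taxonomy")
                continue
            status.recovered = True
            status.failing_criterion = None
            status.best_mag = mag_id
            status.nearest_distance = d_self
            break
        if not status.recovered:
            status.failing_criterion = failure or "not_nearest"
        else:
            recovered_mass += true_profile.abundances[genome.genome_id]
        result.per_genome[genome.genome_id] = status
    result.recovered_abundance_percent = 100.0 * recovered_mass
    return result


_FAILURE_ORDER = {"no_mag": 0, "not_nearest": 1, "quality": 2, "taxonomy": 3}


def _prefer(current: str | None, new: str) -> str:
    """Report the failure of the MAG that got furthest through the criteria."""
    if current is None:
        return new
    return current if _FAILURE_ORDER[current] >= _FAILURE_ORDER[new] else new


def optimal_coverage_threshold(
    coverages: Sequence[float], recovered: Sequence[bool]
) -> float:
    """Coverage cut best separating recovered from non-recovered genomes.

    Minimizes misclassifications of the rule ``coverage >= t => recovered``;
    among minimizing cuts, returns the midpoint of the widest gap between
    adjacent observed coverages.
    """
    cov = np.asarray(coverages, dtype=float)
    lab = np.asarray(recovered, dtype=bool)
    if cov.shape != lab.shape or cov.size == 0:
        raise ValidationError("need equal-length nonempty vectors")
    if lab.all() or (~lab).all():
        raise ValidationError("need at least one recovered and one non-recovered")
    values = np.unique(cov)
    # candidate cuts: below the minimum, between adjacent values, above max
    candidates: list[tuple[float, float]] = [(values[0] - 1.0, 0.0)]
    for lo, hi in zip(values[:-1], values[1:]):
        candidates.append(((lo + hi) / 2.0, hi - lo))
    candidates.append((values[-1] + 1.0, 0.0))
    best_t, best_err, best_gap = None, None, -1.0
    for t, gap in candidates:
        errors = int(np.sum((cov >= t) != lab))
        if best_err is None or errors < best_err or (
            errors == best_err and gap > best_gap
        ):
            best_t, best_err, best_gap = t, errors, gap
    return float(best_t)
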