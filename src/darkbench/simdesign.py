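"""Construction of true community profiles and read-simulator inputs.

A synthetic sample is parameterized by species count, sequencing depth,
proportion of uncharacterized species, point-mutation rate, genome-size skew
and the spread of the log-normal species-abundance distribution.  Known
(reference-available) species enter in rank order of their real-data
abundance; their ranked list is randomly split into two order-preserving
halves, interleaved, and assigned descending sorted log-normal draws, so
that dominant species in real data tend to dominate the simulation while
order and abundances still vary between replicates.  Uncharacterized
genomes are chosen by greedily matching genome sizes to a geometric target
sequence, then assigned unsorted log-normal draws.  The known and unknown
blocks are normalized to the known and unknown proportions respectively.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import GenomeCatalog, GenomeRecord
from .errors import ConfigError, ValidationError

# Grid values for the single-parameter sweeps, with the core value of each
# parameter as used for the default ("core") samples.
SPECIES_COUNT_VALUES = (75, 150, 300, 600)
DEPTH_GBP_VALUES = (0.05, 0.5, 1.5, 7.5, 30.0)
UNKNOWN_PROP_VALUES = (0.0, 0.25, 0.5, 0.75, 1.0)
MUTATION_RATE_VALUES = (0.0, 0.01, 0.02, 0.05)
SIZE_SKEW_K_VALUES = (40, 100, 250)
SIGMA_VALUES = (0.5, 1.0, 2.0, 4.0)

GRID_VALUES: dict[str, tuple] = {
    "n_species": SPECIES_COUNT_VALUES,
    "depth_gbp": DEPTH_GBP_VALUES,
    "unknown_prop": UNKNOWN_PROP_VALUES,
    "mutation_rate": MUTATION_RATE_VALUES,
    "size_skew_k": SIZE_SKEW_K_VALUES,
    "sigma": SIGMA_VALUES,
}

#: Core unknown proportion by environment: soil and ocean communities are
#: mostly uncharacterized; animal gut communities are moderately so.
CORE_UNKNOWN_PROP = {"soil": 0.75, "ocean": 0.75, "animal_gut": 0.5}


@dataclass(frozen=True)
class SampleDesign:
    """Parameters of one synthetic sample."""

    n_species: int = 300
    depth_gbp: float = 7.5
    unknown_prop: float = 0.75
    mutation_rate: float = 0.0
    size_skew_k: int = 100
    sigma: float = 1.0
    mu: float = -3.0
    read_length: int = 150
    paired: bool = True
    seed: int = 0
    environment: str = "soil"

    def __post_init__(self) -> None:
        if not 0 <= self.unknown_prop <= 1:
            raise ValidationError("unknown_prop must be in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValidationError("mutation_rate must be in [0, 1]")
        if self.size_skew_k <= 1:
            raise ValidationError("size_skew_k must be > 1")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")

    @property
    def n_unknown(self) -> int:
        return round(self.n_species * self.unknown_prop)

    @property
    def n_known(self) -> int:
        return self.n_species - self.n_unknown

    @property
    def depth_bp(self) -> float:
        return self.depth_gbp * 1e9


def core_design(environment: str, seed: int = 0) -> SampleDesign:
    """The core (default) sample design for an environment."""
    if environment not in CORE_UNKNOWN_PROP:
        raise ConfigError(f"unknown environment {environment!r}")
    return SampleDesign(
        unknown_prop=CORE_UNKNOWN_PROP[environment],
        environment=environment,
        seed=seed,
    )


def reads_for_depth(depth_gbp: float, read_length: int = 150) -> float:
    """Number of reads implied by a sequencing depth in giga-base pairs."""
    if read_length <= 0:
        raise ValidationError("read_length must be positive")
    return depth_gbp * 1e9 / read_length


def min_abundance_for_coverage(
    coverage: float, genome_bp: float, n_reads: float, read_length: int = 150
) -> float:
    """Minimum relative abundance giving *coverage*-fold depth of a genome.

    Under sequence-abundance semantics, a genome of ``genome_bp`` bases
    receives ``a × n_reads × read_length`` sequenced bases, so ``a`` must be
    at least ``coverage × genome_bp / (n_reads × read_length)``.
    """
    total_bp = n_reads * read_length
    if total_bp <= 0 or genome_bp <= 0:
        raise ValidationError("sizes must be positive")
    return coverage * genome_bp / total_bp


@dataclass(frozen=True)
class TrueProfile:
    """Genome-keyed relative abundances with a known/unknown partition."""

    abundances: Mapping[str, float]
    known_mass: float
    unknown_mass: float
    statuses: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if self.abundances and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"abundances sum to {total}, expected 1")
        if any(a <= 0 for a in self.abundances.values()):
            raise ValidationError("all abundances must be > 0")

    def to_tsv(self, stream) -> None:
        stream.write("genome_id\tabundance\tstatus\n")
        for genome_id in sorted(self.abundances):
            status = self.statuses.get(genome_id, "ncbi_available")
            stream.write(f"{genome_id}\t{self.abundances[genome_id]:.12g}\t{status}\n")

    @classmethod
    def from_tsv(cls, stream) -> "TrueProfile":
        abundances: dict[str, float] = {}
        statuses: dict[str, str] = {}
        header = stream.readline()
        if not header.startswith("genome_id"):
            raise ValidationError("true-profile TSV must start with a header row")
        for line in stream:
            if not line.strip():
                continue
            genome_id, abundance, status = line.rstrip("\n").split("\t")
            abundances[genome_id] = float(abundance)
            statuses[genome_id] = status
        known = sum(
            a for g, a in abundances.items() if statuses[g] == "ncbi_available"
        )
        return cls(
            abundances=abundances,
            known_mass=known,
            unknown_mass=sum(abundances.values()) - known,
            statuses=statuses,
        )


@dataclass(frozen=True)
class ParameterGrid:
    """Single-parameter sweep: one field varied, all others at core values."""

    parameter: str
    values: tuple
    replicates: int = 5


def derive_seed(root_seed: int, *labels) -> int:
    """Deterministic sub-seed from a root seed and a label path (< 2^31)."""
    text = ":".join([str(root_seed), *map(repr, labels)])
    digest = hashlib.blake2b(text.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def expand_grid(core: SampleDesign, grid: ParameterGrid) -> list[SampleDesign]:
    """All designs of a sweep, each differing from *core* in one field."""
    if grid.parameter not in {f.name for f in fields(SampleDesign)}:
        raise ConfigError(f"unknown design parameter {grid.parameter!r}")
    designs = []
    for value in grid.values:
        for rep in range(grid.replicates):
            seed = derive_seed(core.seed, grid.parameter, value, rep)
            designs.append(replace(core, **{grid.parameter: value, "seed": seed}))
    return designs


def default_grids(core: SampleDesign, replicates: int = 5) -> list[ParameterGrid]:
    """The six standard single-parameter sweeps around *core*."""
    return [
        ParameterGrid(parameter=name, values=values, replicates=replicates)
        for name, values in GRID_VALUES.items()
    ]


# -- abundance blocks ------------------------------------------------------


def build_known_block(
    ranked_species: Sequence[str],
    n_known: int,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Assign log-normal weights to the top *n_known* ranked species.

    The truncated rank list is randomly split into two order-preserving
    groups (the first gets the extra member when n is odd), the groups are
    interleaved, and the sorted-descending log-normal draws are assigned
    positionally, so top-ranked species tend to receive the largest weights.
    """
    if n_known > len(ranked_species):
        raise ValidationError(
            f"n_known={n_known} exceeds ranked list of {len(ranked_species)}"
        )
    return _known_block_with_split_rng(
        list(ranked_species[:n_known]), mu, sigma, rng, rng
    )


def build_unknown_block(
    selected: Sequence[str], mu: float, sigma: float, rng: np.random.Generator
) -> dict[str, float]:
    """One unsorted log-normal weight per selected uncharacterized genome."""
    draws = np.exp(rng.normal(mu, sigma, size=len(selected)))
    return {genome: float(w) for genome, w in zip(selected, draws)}


def assemble_profile(
    known_block: Mapping[str, float],
    unknown_block: Mapping[str, float],
    unknown_prop: float,
    statuses: Mapping[str, str] | None = None,
) -> TrueProfile:
    """Normalize the two blocks to the known/unknown proportions."""
    if not known_block and not unknown_block:
        raise ValidationError("both abundance blocks are empty")
    if unknown_prop > 0 and not unknown_block:
        raise ValidationError("unknown_prop > 0 but the unknown block is empty")
    if unknown_prop < 1 and not known_block:
        raise ValidationError("known proportion > 0 but the known block is empty")
    overlap = set(known_block) & set(unknown_block)
    if overlap:
        raise ValidationError(f"blocks share genome ids: {sorted(overlap)[:3]}")
    abundances: dict[str, float] = {}
    if known_block:
        total = sum(known_block.values())
        for genome, weight in known_block.items():
            abundances[genome] = weight / total * (1.0 - unknown_prop)
    if unknown_block:
        total = sum(unknown_block.values())
        for genome, weight in unknown_block.items():
            abundances[genome] = weight / total * unknown_prop
    if statuses is None:
        statuses = {g: "ncbi_available" for g in known_block}
        statuses.update({g: "new_sgb" for g in unknown_block})
    return TrueProfile(
        abundances=abundances,
        known_mass=1.0 - unknown_prop if known_block else 0.0,
        unknown_mass=unknown_prop if unknown_block else 0.0,
        statuses=dict(statuses),
    )


# -- genome size targeting -------------------------------------------------


def target_size_sequence(n: int, k: int, median_size: float) -> np.ndarray:
    """Geometric genome-size target sequence centered on the median size.

    ``s_j = median × r^(j − (n−1)/2)`` with ``r = (k−1)/k``: strictly
    decreasing, log-symmetric around the median, with spread controlled by
    *k* (smaller k = wider spread).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if k < 2:
        raise ValidationError("k must be >= 2")
    r = (k - 1) / k
    j = np.arange(n, dtype=float)
    return median_size * r ** (j - (n - 1) / 2)


def greedy_size_match(
    known_genomes: Sequence[GenomeRecord],
    unknown_pool: Sequence[GenomeRecord],
    targets: Sequence[float],
    n_unknown: int,
) -> list[str]:
    """Fill the size-target sequence: knowns first, then unknowns greedily.

    Known genomes (processed in descending length, ties by genome_id) each
    claim the unfilled target slot minimizing the absolute size difference.
    Remaining slots are then visited in sequence order and each takes the
    unused pool genome closest in length (ties toward the smaller
    genome_id).  Returns the selected unknown genome_ids in slot order.
    """
    targets = list(targets)
    if len(targets) != len(known_genomes) + n_unknown:
        raise ValidationError("targets length must equal n_known + n_unknown")
    if len(unknown_pool) < n_unknown:
        raise ValidationError(
            f"unknown pool of {len(unknown_pool)} cannot fill {n_unknown} slots"
        )
    target_arr = np.asarray(targets, dtype=float)
    filled = np.zeros(len(targets), dtype=bool)
    for genome in sorted(known_genomes, key=lambda g: (-g.length_bp, g.genome_id)):
        gaps = np.abs(target_arr - genome.length_bp)
        gaps[filled] = np.inf
        filled[int(np.argmin(gaps))] = True  # ties -> lowest slot index

    pool = sorted(unknown_pool, key=lambda g: (g.length_bp, g.genome_id))
    lengths = np.array([g.length_bp for g in pool], dtype=float)
    used = np.zeros(len(pool), dtype=bool)
    selected: list[str] = []
    for slot in range(len(targets)):
        if filled[slot]:
            continue
        gaps = np.abs(lengths - target_arr[slot])
        gaps[used] = np.inf
        best = int(np.argmin(gaps))  # ties -> shorter length, then lower id
        used[best] = True
        selected.append(pool[best].genome_id)
    return selected


# -- full sample construction ----------------------------------------------


def simulate_profile(design: SampleDesign, catalog: GenomeCatalog) -> TrueProfile:
    """Build the true relative-abundance profile for one sample design.

    Randomness is split into labeled substreams derived from the design
    seed, so the known-block split, the two sets of log-normal draws, and
    downstream mutation are independently reproducible.
    """
    known_records = catalog.known_species_ranked()
    unknown_pool = catalog.uncharacterized()
    n_known, n_unknown = design.n_known, design.n_unknown
    if n_known > len(known_records):
        raise ValidationError(
            f"design needs {n_known} known genomes, catalog has {len(known_records)}"
        )
    if n_unknown > len(unknown_pool):
        raise ValidationError(
            f"design needs {n_unknown} uncharacterized genomes, "
            f"catalog has {len(unknown_pool)}"
        )

    rng_split = np.random.default_rng(derive_seed(design.seed, "split"))
    rng_known = np.random.default_rng(derive_seed(design.seed, "known-draws"))
    rng_unknown = np.random.default_rng(derive_seed(design.seed, "unknown-draws"))

    chosen_known = known_records[:n_known]
    all_lengths = [r.length_bp for r in catalog]
    median_size = float(np.median(all_lengths))
    targets = target_size_sequence(design.n_species, design.size_skew_k, median_size)
    selected_unknown = greedy_size_match(chosen_known, unknown_pool, targets, n_unknown)

    # the split/interleave rng must see the same stream regardless of draws
    known_ids = [r.genome_id for r in chosen_known]
    known_weights = _known_block_with_split_rng(
        known_ids, design.mu, design.sigma, rng_split, rng_known
    )
    unknown_weights = build_unknown_block(
        selected_unknown, design.mu, design.sigma, rng_unknown
    )
    statuses = {r.genome_id: r.status for r in chosen_known}
    statuses.update({g: catalog[g].status for g in selected_unknown})
    return assemble_profile(
        known_weights, unknown_weights, design.unknown_prop, statuses
    )


def _known_block_with_split_rng(
    ranked_ids: Sequence[str],
    mu: float,
    sigma: float,
    rng_split: np.random.Generator,
    rng_draws: np.random.Generator,
) -> dict[str, float]:
    n = len(ranked_ids)
    if n == 0:
        return {}
    size1 = math.ceil(n / 2)
    group1_idx = np.sort(rng_split.choice(n, size=size1, replace=False))
    in_group1 = np.zeros(n, dtype=bool)
    in_group1[group1_idx] = True
    group1 = [ranked_ids[i] for i in range(n) if in_group1[i]]
    group2 = [ranked_ids[i] for i in range(n) if not in_group1[i]]
    interleaved: list[str] = []
    for i in range(size1):
        interleaved.append(group1[i])
        if i < len(group2):
            interleaved.append(group2[i])
    draws = np.sort(np.exp(rng_draws.normal(mu, sigma, size=n)))[::-1]
    return {g: float(w) for g, w in zip(interleaved, draws)}


# -- genome mutation -------------------------------------------------------

_ACGT = b"ACGT"
_IUPAC = set(b"ACGTURYSWKMBDHVN" + b"acgturyswkmbdhvn" + b"-.")


def mutate_genome(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Apply independent substitution point mutations at the given rate.

    Each A/C/G/T position is substituted with probability *rate*, uniformly
    to one of the other three bases; ambiguous IUPAC codes are untouched and
    length is preserved.
    """
    if not 0 <= rate <= 1:
        raise ValidationError("rate must be in [0, 1]")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(bytes(sorted(_IUPAC)), dtype=np.uint8))
    if bad.any():
        offender = chr(arr[np.argmax(bad)])
        raise ValidationError(f"non-IUPAC character in sequence: {offender!r}")
    if rate == 0:
        return sequence
    upper = np.where((arr >= ord("a")) & (arr <= ord("z")), arr - 32, arr)
    base_idx = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(_ACGT):
        base_idx[upper == b] = i
    mutable = base_idx >= 0
    hit = mutable & (rng.random(arr.shape) < rate)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        new_idx = (base_idx[hit].astype(np.int64) + shift) % 4
        lut = np.frombuffer(_ACGT, dtype=np.uint8)
        arr[hit] = lut[new_idx]
    return arr.tobytes().decode("ascii")


# -- coverage and CAMISIM emission -----------------------------------------


def expected_coverage(
    profile: TrueProfile,
    design: SampleDesign,
    catalog: GenomeCatalog,
    semantics: str = "cell",
) -> dict[str, float]:
    """Expected fold coverage of every genome in the profile.

    Under cell-abundance semantics (the CAMISIM input contract), a genome's
    read share is proportional to abundance × genome length, so
    ``coverage_i = a_i × depth_bp / Σ_j a_j g_j``.  Under sequence-abundance
    semantics the abundance is already the base share:
    ``coverage_i = a_i × depth_bp / g_i``.
    """
    if semantics not in ("cell", "sequence"):
        raise ValidationError(f"unknown semantics {semantics!r}")
    lengths = {}
    for genome_id in profile.abundances:
        length = catalog[genome_id].length_bp
        if length <= 0:
            raise ValidationError(f"zero-length genome {genome_id}")
        lengths[genome_id] = length
    depth_bp = design.depth_bp
    if semantics == "cell":
        denom = sum(a * lengths[g] for g, a in profile.abundances.items())
        return {g: a * depth_bp / denom for g, a in profile.abundances.items()}
    return {g: a * depth_bp / lengths[g] for g, a in profile.abundances.items()}


def emit_camisim_config(
    profile: TrueProfile,
    design: SampleDesign,
    genome_paths: Mapping[str, str | Path],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the CAMISIM INI config and its companion TSV inputs.

    Emits ``config.ini`` (art_illumina error model, 150-bp paired reads,
    ``size`` in giga-base pairs from the design), ``genome_to_id.tsv``,
    ``metadata.tsv`` and ``abundance.tsv`` (column sums to 1).  Output is
    byte-deterministic for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes = sorted(profile.abundances)
    missing = [g for g in genomes if g not in genome_paths]
    if missing:
        raise ValidationError(f"missing FASTA paths for: {missing[:3]}")

    abundance_path = out_dir / "abundance.tsv"
    with abundance_path.open("w") as handle:
        for genome_id in genomes:
            handle.write(f"{genome_id}\t{profile.abundances[genome_id]:.12g}\n")

    id_path = out_dir / "genome_to_id.tsv"
    with id_path.open("w") as handle:
        for genome_id in genomes:
            handle.write(f"{genome_id}\t{genome_paths[genome_id]}\n")

    metadata_path = out_dir / "metadata.tsv"
    with metadata_path.open("w") as handle:
        handle.write("genome_ID\tOTU\tNCBI_ID\tnovelty_category\n")
        for otu, genome_id in enumerate(genomes, start=1):
            status = profile.statuses.get(genome_id, "ncbi_available")
            novelty = "known_strain" if status == "ncbi_available" else "new_species"
            handle.write(f"{genome_id}\t{otu}\t\t{novelty}\n")

    config = configparser.ConfigParser()
    config["Main"] = {
        "seed": str(design.seed),
        "phase": "0",
        "max_processors": "1",
        "dataset_id": f"{design.environment}_s{design.seed}",
        "output_directory": str(out_dir / "out"),
        "temp_directory": str(out_dir / "tmp"),
        "gsa": "False",
        "pooled_gsa": "False",
        "anonymous": "False",
        "compress": "1",
    }
    config["ReadSimulator"] = {
        "readsim": "art_illumina",
        "error_profiles": "mbarc",
        "samples": "1",
        "size": repr(design.depth_gbp),
        "type": "art",
        "fragments_size_mean": "270",
        "fragment_size_standard_deviation": "27",
        "profile": "mbarc",
        "read_length": str(design.read_length),
        "paired": str(design.paired),
    }
    config["community0"] = {
        "metadata": str(metadata_path),
        "id_to_genome_file": str(id_path),
        "path_to_abundance_file": str(abundance_path),
        "genomes_total": str(len(genomes)),
        "num_real_genomes": str(len(genomes)),
        "mutation_rate": repr(design.mutation_rate),
    }
    config_path = out_dir / "config.ini"
    with io.StringIO() as buffer:
        config.write(buffer)
        config_path.write_text(buffer.getvalue())
    return {
        "config": config_path,
        "genome_to_id": id_path,
        "metadata": metadata_path,
        "abundance": abundance_path,
    }
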