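"""True-profile construction, size matching, mutation, CAMISIM emission."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from darkbench import simdesign as sd
from darkbench.catalog import GenomeCatalog, GenomeRecord
from darkbench.errors import ConfigError, ValidationError
from darkbench.taxonomy import Lineage

SPECIES_LINEAGE = Lineage(
    {
        "superkingdom": 1,
        "kingdom": 2,
        "phylum": 3,
        "class": 4,
        "order": 5,
        "family": 6,
        "genus": 7,
        "species": 8,
    }
)


def _genome(gid, length, status="new_sgb"):
    lineage = SPECIES_LINEAGE if status == "ncbi_available" else Lineage(
        {k: v for k, v in SPECIES_LINEAGE.assignments.items() if k != "species"}
    )
    return GenomeRecord(genome_id=gid, length_bp=length, status=status, lineage=lineage)


class TestExpandGrid:
    def test_product_count(self):
        core = sd.core_design("soil", seed=5)
        grid = sd.ParameterGrid("sigma", (0.5, 1.0, 2.0, 4.0, 8.0), replicates=5)
        assert len(sd.expand_grid(core, grid)) == 25

    def test_identity_replicate(self):
        core = sd.core_design("soil", seed=5)
        grid = sd.ParameterGrid("sigma", (core.sigma,), replicates=1)
        (design,) = sd.expand_grid(core, grid)
        assert dataclasses.replace(design, seed=core.seed) == core

    def test_seed_determinism(self):
        core = sd.core_design("ocean", seed=9)
        grid = sd.ParameterGrid("depth_gbp", sd.DEPTH_GBP_VALUES, replicates=3)
        seeds_a = [d.seed for d in sd.expand_grid(core, grid)]
        seeds_b = [d.seed for d in sd.expand_grid(core, grid)]
        assert seeds_a == seeds_b
        assert len(set(seeds_a)) == len(seeds_a)
        assert all(0 <= s < 2**31 for s in seeds_a)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError):
            sd.expand_grid(
                sd.core_design("soil"), sd.ParameterGrid("bogus", (1,), 1)
            )


class TestKnownBlock:
    def test_empty_and_single(self, rng):
        assert sd.build_known_block([], 0, -3, 1, rng) == {}
        block = sd.build_known_block(["only"], 1, -3, 1, rng)
        assert set(block) == {"only"} and block["only"] > 0

    def test_weights_are_permuted_draws(self, rng):
        species = [f"s{i}" for i in range(31)]
        seed_rng = np.random.default_rng(77)
        block = sd.build_known_block(species, 31, -3, 1.5, seed_rng)
        replay = np.random.default_rng(77)
        replay.choice(31, size=16, replace=False)
        draws = np.exp(replay.normal(-3, 1.5, size=31))
        assert sorted(block.values()) == pytest.approx(sorted(draws))

    def test_top_ranked_species_receive_larger_weights(self):
        """Interleaving sorted halves with sorted draws preserves, on
        average, the real-data abundance ranking."""
        n = 20
        totals = np.zeros(n)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            block = sd.build_known_block([f"s{i:02d}" for i in range(n)], n, -3, 1, rng)
            totals += [block[f"s{i:02d}"] for i in range(n)]
        rho = stats.spearmanr(np.arange(1, n + 1), totals / 200).statistic
        assert rho < -0.9

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValidationError):
            sd.build_known_block(["a"], 2, -3, 1, rng)


class TestUnknownBlock:
    def test_empty_selection(self, rng):
        assert sd.build_unknown_block([], -3, 1, rng) == {}

    def test_all_weights_positive(self, rng):
        block = sd.build_unknown_block([f"u{i}" for i in range(50)], -3, 2, rng)
        assert all(w > 0 for w in block.values())

    def test_log_weight_spread_matches_sigma(self, rng):
        block = sd.build_unknown_block([f"u{i}" for i in range(10_000)], -3, 1, rng)
        sd_log = np.std(np.log(list(block.values())), ddof=1)
        assert abs(sd_log - 1.0) < 0.05


class TestAssembleProfile:
    def test_known_only(self):
        profile = sd.assemble_profile({"a": 2.0, "b": 6.0}, {}, 0.0)
        assert profile.abundances == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}
        assert profile.unknown_mass == 0

    def test_unknown_only(self):
        profile = sd.assemble_profile({}, {"u": 3.0, "v": 1.0}, 1.0)
        assert profile.abundances["u"] == pytest.approx(0.75)
        assert profile.known_mass == 0

    def test_partition_masses(self):
        profile = sd.assemble_profile({"a": 1.0}, {"u": 1.0, "v": 3.0}, 0.75)
        assert profile.abundances["a"] == pytest.approx(0.25)
        assert sum(profile.abundances.values()) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            sd.assemble_profile({}, {}, 0.5)
        with pytest.raises(ValidationError):
            sd.assemble_profile({"a": 1.0}, {}, 1.0)
        with pytest.raises(ValidationError):
            sd.assemble_profile({"a": 1.0}, {"a": 1.0}, 0.5)

    def test_design_species_split(self, big_catalog):
        design = sd.SampleDesign(n_species=300, unknown_prop=0.75, seed=4)
        profile = sd.simulate_profile(design, big_catalog)
        statuses = [profile.statuses[g] for g in profile.abundances]
        assert statuses.count("ncbi_available") == 75
        assert len(statuses) - statuses.count("ncbi_available") == 225


class TestTargetSizeSequence:
    def test_huge_k_collapses_to_median(self):
        seq = sd.target_size_sequence(7, 10**9, 4_000_000)
        assert np.ptp(seq) / 4_000_000 < 1e-6

    def test_odd_n_centers_on_median(self):
        seq = sd.target_size_sequence(5, 40, 1_000_000)
        assert seq[2] == pytest.approx(1_000_000)

    def test_direct_evaluation(self):
        seq = sd.target_size_sequence(3, 40, 4_000_000)
        assert seq == pytest.approx([4_102_564.1025641, 4_000_000.0, 3_900_000.0])

    def test_strictly_decreasing_with_known_log_range(self):
        n, k = 11, 100
        seq = sd.target_size_sequence(n, k, 5_000_000)
        assert np.all(np.diff(seq) < 0)
        log_range = math.log(seq[0]) - math.log(seq[-1])
        assert log_range == pytest.approx((n - 1) * abs(math.log((k - 1) / k)))


def brute_force_greedy(known, pool, targets, n_unknown):
    """Independent re-implementation: explicit nested scans."""
    slots = {i: None for i in range(len(targets))}
    for genome in sorted(known, key=lambda g: (-g.length_bp, g.genome_id)):
        best, best_gap = None, None
        for i in slots:
            if slots[i] is not None:
                continue
            gap = abs(genome.length_bp - targets[i])
            if best_gap is None or gap < best_gap:
                best, best_gap = i, gap
        slots[best] = genome.genome_id
    remaining = sorted(pool, key=lambda g: (g.length_bp, g.genome_id))
    chosen = []
    for i in sorted(slots):
        if slots[i] is not None:
            continue
        best, best_gap = None, None
        for j, genome in enumerate(remaining):
            gap = abs(genome.length_bp - targets[i])
            if best_gap is None or gap < best_gap:
                best, best_gap = j, gap
        chosen.append(remaining.pop(best).genome_id)
    return chosen


class TestGreedySizeMatch:
    def test_perfect_matching_reproduces_targets(self):
        targets = [5000.0, 4000.0, 3000.0]
        pool = [_genome(f"u{i}", int(t)) for i, t in enumerate(targets)]
        selected = sd.greedy_size_match([], pool, targets, 3)
        assert [int(p) for p in targets] == [
            next(g.length_bp for g in pool if g.genome_id == s) for s in selected
        ]

    def test_no_unknowns(self):
        known = [_genome("k", 4000, "ncbi_available")]
        assert sd.greedy_size_match(known, [], [4000.0], 0) == []

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValidationError):
            sd.greedy_size_match([], [_genome("u", 100)], [1.0, 2.0], 2)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_known, n_unknown = int(rng.integers(0, 4)), int(rng.integers(1, 6))
        known = [
            _genome(f"k{i}", int(rng.integers(1000, 9000)), "ncbi_available")
            for i in range(n_known)
        ]
        pool = [
            _genome(f"u{i}", int(rng.integers(1000, 9000)))
            for i in range(n_unknown + 5)
        ]
        targets = list(
            sd.target_size_sequence(n_known + n_unknown, 40, rng.integers(2000, 8000))
        )
        assert sd.greedy_size_match(known, pool, targets, n_unknown) == (
            brute_force_greedy(known, pool, targets, n_unknown)
        )


class TestMutateGenome:
    def test_zero_rate_identity(self, rng):
        seq = "ACGTNRYacgt"
        assert sd.mutate_genome(seq, 0.0, rng) == seq

    def test_full_rate_changes_every_base(self, rng):
        seq = "ACGT" * 100
        mutated = sd.mutate_genome(seq, 1.0, rng)
        assert len(mutated) == len(seq)
        assert all(a != b for a, b in zip(seq, mutated))

    def test_ambiguity_codes_untouched(self, rng):
        mutated = sd.mutate_genome("NNNN-RYSW", 1.0, rng)
        assert mutated == "NNNN-RYSW"

    def test_rate_recovered_within_binomial_interval(self, rng):
        n = 1_000_000
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=n))
        mutated = sd.mutate_genome(seq, 0.02, rng)
        hamming = sum(a != b for a, b in zip(seq, mutated))
        lo, hi = stats.binom.interval(0.99, n, 0.02)
        assert lo <= hamming <= hi

    def test_non_iupac_rejected(self, rng):
        with pytest.raises(ValidationError):
            sd.mutate_genome("ACGTZ", 0.1, rng)


class TestExpectedCoverage:
    def _catalog(self, lengths):
        return GenomeCatalog(
            records={
                gid: _genome(gid, length, "new_sgb") for gid, length in lengths.items()
            }
        )

    def test_single_genome_identity(self):
        catalog = self._catalog({"g": 4_000_000})
        profile = sd.TrueProfile(
            abundances={"g": 1.0}, known_mass=0, unknown_mass=1.0,
            statuses={"g": "new_sgb"},
        )
        design = sd.SampleDesign(n_species=1, depth_gbp=0.04, unknown_prop=1.0)
        for semantics in ("cell", "sequence"):
            cov = sd.expected_coverage(profile, design, catalog, semantics)
            assert cov["g"] == pytest.approx(10.0)

    def test_equal_lengths_equal_coverage(self):
        catalog = self._catalog({"a": 2_000_000, "b": 2_000_000})
        profile = sd.TrueProfile(
            abundances={"a": 0.5, "b": 0.5}, known_mass=0, unknown_mass=1.0,
            statuses={"a": "new_sgb", "b": "new_sgb"},
        )
        design = sd.SampleDesign(n_species=2, depth_gbp=1.0, unknown_prop=1.0)
        cov = sd.expected_coverage(profile, design, catalog)
        assert cov["a"] == pytest.approx(cov["b"])

    def test_cell_semantics_direct_evaluation(self):
        catalog = self._catalog({"a": 4_000_000, "b": 2_000_000})
        profile = sd.TrueProfile(
            abundances={"a": 0.75, "b": 0.25}, known_mass=0, unknown_mass=1.0,
            statuses={"a": "new_sgb", "b": "new_sgb"},
        )
        design = sd.SampleDesign(n_species=2, depth_gbp=7.0, unknown_prop=1.0)
        cov = sd.expected_coverage(profile, design, catalog, "cell")
        assert cov["a"] == pytest.approx(1500.0)
        assert cov["b"] == pytest.approx(500.0)


class TestCamisimEmission:
    def _emit(self, tmp_path, sub="one"):
        profile = sd.TrueProfile(
            abundances={"a": 0.6, "b": 0.4}, known_mass=1.0, unknown_mass=0.0,
            statuses={"a": "ncbi_available", "b": "ncbi_available"},
        )
        design = sd.SampleDesign(n_species=2, unknown_prop=0.0, seed=2)
        paths = {"a": "a.fasta", "b": "b.fasta"}
        return sd.emit_camisim_config(profile, design, paths, tmp_path / sub)

    def test_abundance_column_sums_to_one(self, tmp_path):
        files = self._emit(tmp_path)
        total = sum(
            float(line.split("\t")[1])
            for line in files["abundance"].read_text().splitlines()
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_config_size_is_depth(self, tmp_path):
        files = self._emit(tmp_path)
        text = files["config"].read_text()
        assert "size = 7.5" in text
        assert "read_length = 150" in text

    def test_re_emission_is_byte_identical(self, tmp_path):
        first = self._emit(tmp_path, "one")
        snapshot = {key: path.read_bytes() for key, path in first.items()}
        second = self._emit(tmp_path, "one")
        assert {key: path.read_bytes() for key, path in second.items()} == snapshot

    def test_missing_fasta_rejected(self, tmp_path):
        profile = sd.TrueProfile(
            abundances={"a": 1.0}, known_mass=1.0, unknown_mass=0.0,
            statuses={"a": "ncbi_available"},
        )
        with pytest.raises(ValidationError):
            sd.emit_camisim_config(
                profile, sd.SampleDesign(n_species=1, unknown_prop=0.0), {}, tmp_path
            )


def test_full_pipeline_determinism(big_catalog):
    design = sd.SampleDesign(n_species=120, unknown_prop=0.5, seed=99)
    one = sd.simulate_profile(design, big_catalog)
    two = sd.simulate_profile(design, big_catalog)
    assert one.abundances == two.abundances
    assert one.statuses == two.statuses


def test_reads_for_depth_identity():
    assert sd.reads_for_depth(7.5, 150) == pytest.approx(50e6)
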