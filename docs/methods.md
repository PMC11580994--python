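# Methods

## The simulation model

A synthetic sample is a relative-abundance vector over a curated genome
catalog, split into a *known* block (genomes whose species were in the
reference taxonomy before the profiler databases were built,
`ncbi_available`) and an *unknown* block (`new_ncbi`: species added to the
taxonomy after the database cutoff; `new_sgb`: species-level genome bins
with no species placement at all, characterized only to genus, family or
order).

Construction of one sample, given a design
(n_species, depth, unknown proportion p, mutation rate, size-skew k,
log-normal μ, σ, seed):

1. **Known block.** Known species are ordered by their average abundance in
   real data (`rank_order`; ties by id). The list is truncated to
   n_known = n_species − round(n_species · p), randomly split into two
   order-preserving groups (the first gets the extra member when n is odd),
   the groups are interleaved, and n_known log-normal(μ, σ²) draws, sorted
   descending, are assigned positionally. Dominant real-data species
   therefore *tend* to dominate the simulation while order and abundances
   vary between replicates; the multiset of assigned weights is exactly the
   multiset of draws.
2. **Genome-size targeting.** A strictly decreasing geometric sequence
   s_j = m · r^(j − (n−1)/2), r = (k−1)/k, with m the median catalog genome
   size, fixes the genome-size profile of the sample (smaller k = wider
   spread). The phrase "normalized to the median" is ambiguous between
   anchoring s_0 at the median and centering the sequence there; we center
   the exponent at (n−1)/2 so the sequence's geometric mean (and, for odd
   n, its middle element) equals the median genome size. Known genomes are
   slotted first, in descending length, each taking the unfilled slot
   minimizing |length − target|; remaining slots are filled in sequence
   order by the unused uncharacterized genome closest in length (ties to
   the smaller genome, then the smaller id — determinism over optimality,
   as in any greedy matching).
3. **Unknown block.** The selected uncharacterized genomes receive one
   unsorted log-normal(μ, σ²) draw each. Draws are deliberately *not*
   sorted: sorting is a property of the known block's construction only.
4. **Normalization.** The known block is scaled to sum to 1 − p and the
   unknown block to p, so both the species count and the abundance split
   match the nominal design exactly (to ~1e-15; the test/acceptance
   tolerance is 1e-9). n_unknown = round(n_species · p): several grid
   combinations (e.g. 75 species at p = 0.25) do not give integer products,
   so rounding is applied and n_known + n_unknown = n_species always holds.
5. **Mutation.** With a nonzero rate, every A/C/G/T position is
   independently substituted (uniformly to one of the other three bases)
   with that probability; ambiguity codes are untouched. This models
   divergence from the reference, not realistic mutation spectra
   (conserved regions are ignored).
6. **Emission.** A CAMISIM-style INI (art_illumina profile, 150-bp paired
   reads, `size` = depth in Gbp), genome/id map, metadata and abundance
   TSVs are written byte-deterministically. The abundance column is
   interpreted as *cell* abundance (CAMISIM's input contract), so expected
   coverage defaults to coverage_i = a_i · depth_bp / Σ_j a_j·g_j; a
   `semantics="sequence"` flag gives a_i · depth_bp / g_i instead.

Randomness is split into labeled substreams (split, known draws, unknown
draws, mutation) derived from the design seed by hashing, so components
are independently reproducible and sub-seeds stay below 2³¹.

### Core designs and sweeps

The core design is 300 species, 7.5 Gbp (= 50 million 150-bp reads),
μ = −3, σ = 1, k = 100, mutation 0, unknown proportion 0.75 (soil, ocean)
or 0.5 (animal gut). Sweeps vary exactly one parameter at a time over
n ∈ {75, 150, 300, 600}, depth ∈ {0.05, 0.5, 1.5, 7.5, 30} Gbp,
p ∈ {0, 0.25, 0.5, 0.75, 1}, mutation ∈ {0, 0.01, 0.02, 0.05},
k ∈ {40, 100, 250}, σ ∈ {0.5, 1, 2, 4}, with 5 replicates per setting by
default.

## The evaluation protocol

Assigned profiles are processed per rank: aggregate to the target rank
(mass without an ancestor at that rank joins the unknown mass), apply the
0.05% abundance threshold (removed taxa's mass is redistributed
proportionally), remove declared-unknown mass, unknown-labelled names
(blank, or containing "noname"/"incertae"), and unmappable entries, then
renormalize. The threshold is applied once; the pipeline is idempotent.

The truth is restricted per rank to *available* taxa: a genome contributes
at rank r iff its lineage has a recognized taxon at r (r at or above its
lowest known rank), and contributions are aggregated and renormalized.
This makes "unknown" a correct answer for uncharacterized abundance at
ranks below a genome's characterization, while the genome's known
higher-rank taxa must still be assigned correctly. A genome characterized
only to family is therefore excluded from the species- and genus-rank
truth but required at family and above.

Set metrics use taxon identity only; Bray-Curtis is ½·Σ|x−y| over the
union of taxa (absent = 0). The Mantel test correlates upper triangles
(Pearson) with the one-sided p-value (1 + #{permuted r ≥ observed}) /
(1 + n_perm), n_perm = 999 by default — the convention of the standard
vegan/scikit-bio implementations. Alpha-diversity agreement is the
Spearman correlation of inverse Simpson indices across samples. The
unknown-calibration slope is the OLS slope of estimated on true unknown
fractions.

Threshold placement is the one genuinely open design point: the published
protocol thresholds assigned profiles only, which breaks the exact
truth-as-assignment identity when true taxa fall below 0.05%. The
evaluation function therefore takes `threshold_truth` (default False =
published behaviour); identity checks pass True so both sides are
processed identically.

## MAG recovery

Sketches are bottom-s MinHash over canonical k-mers (lexicographic min of
k-mer and reverse complement, 2-bit packed, hashed with the splitmix64
finalizer — a fixed, seedless 64-bit mix; k-mers containing non-ACGT
characters are skipped, as in Mash). k = 21, s = 1000 follow the published
Mash defaults; the distance is d = −ln(2j/(1+j))/k with j estimated on the
merged bottom sketch, d = 1 for disjoint and 0 for identical sketches.

An uncharacterized genome is recovered iff some MAG (1) is ≥ 50% complete
and < 10% contaminated, (2) is *strictly* closer to it than to every other
input genome (ties are conservatively non-recoveries), and (3) has its
NCBI-mappable taxonomy contained within the genome's taxonomy (a MAG
placed only to the correct family still qualifies; an empty mappable
lineage is vacuously contained). Recovered abundance is the summed *true*
abundance of recovered genomes. The optimal coverage threshold minimizes
misclassifications of the rule coverage ≥ t ⇒ recovered, breaking ties
toward the midpoint of the widest separating gap. A precomputed distance
table can replace sketching (e.g. to use externally computed Mash
distances).

## The fixture generator, and what passing tests do not show

Fixtures emulate the *structure* of the real inputs: a full-ladder
taxonomy with synonyms, a catalog with log-normal genome sizes and a
status mix, per-method database name lists with misses and synonym
reporting, and assigned profiles with five profiler error modes (drops,
log-normal abundance noise with mean-1 multipliers, same-rank false
positives at a Poisson-distributed count, parent-rank truncation, extra
declared unknown mass). Defaults (e.g. 40 kb median genome size, uniform
i.i.d. sequences) are chosen for test tractability: sketching and mutation
mechanics are exact on such sequences, but nothing here models real genome
composition, conserved regions, read error profiles, or any specific
profiler's biases — passing tests validate the bookkeeping and the
mathematics of the protocol, not profiler performance on real data.
The test suite and acceptance script use catalogs of ≤ 1500 genomes,
genomes of ≤ ~1 Mb and ≤ 6 samples per dataset — sizes chosen so the full
grid (75 designs) and all Monte-Carlo checks complete in seconds while
leaving every code path identical to full-scale use.

## Numerical choices and degenerate inputs

- All ties (quality scores, abundance ranks, greedy slots, ambiguous
  names) break lexicographically/toward the smaller id, with a logged
  warning for ambiguous taxon names.
- Mass conservation is enforced at 1e-9 (profile invariants) and verified
  at ~1e-15 in practice; Bray-Curtis inputs must be normalized to 1e-6.
- Profiles that lose every entry to thresholding or stripping raise a
  degenerate-profile signal; the orchestration layer records NaN rows for
  such samples instead of aborting the dataset.
- Constant vectors make Spearman and the calibration slope undefined;
  these raise rather than return NaN.
- Log-normals are parameterized on the natural-log scale:
  weight = exp(N(μ, σ²)).

## Known limitations

- Read generation itself is delegated: the package emits CAMISIM inputs
  but does not run CAMISIM/ART, and no gold-standard assemblies are
  produced.
- Profiler-native output formats (Kraken reports, mOTUs tables) are out of
  scope; ingestion is via generic long-format TSV after each method's own
  extraction.
- The SGB-per-genus cap and reference swaps assume quality statistics are
  supplied (e.g. from CheckM2); the package does not score genomes.
- Whether MAG-to-genome distances should use mutated or unmutated input
  genomes for nonzero mutation rates is unresolved in the protocol; the
  package accepts either via the distance-table input.
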