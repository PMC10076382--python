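# Methods

`rohscape` studies how population history, local recombination rate and
natural selection shape the landscape of runs of homozygosity (ROH) in a
bottlenecked wild population, by re-running the analysis chain — forward
population simulation, scanning-window ROH calling, hotspot statistics and
windowed haplotype diversity — on synthetic data with known ground truth.
This note documents the models, the parameter choices, the numerical
decisions, and what the desk-scale experiments do and do not demonstrate.

## The ROH caller

The caller reproduces the scanning-window ROH search of PLINK 1.9's
`--homozyg` family. For one individual on one chromosome:

1. Every window of `window_snps` consecutive markers (default 35) is
   *accepted* if it contains at most `window_max_het` heterozygous calls
   (default 1) and at most `window_max_missing` missing calls (default 4).
2. Each marker's *hit fraction* is the fraction of windows covering it that
   are accepted (the denominator shrinks near chromosome ends). Markers with
   hit fraction ≥ `window_hit_threshold` (default 0.05) are ROH-eligible.
3. Maximal runs of eligible markers are candidate segments, split wherever
   adjacent markers are more than `max_gap_kb` (default 1000 kb) apart.
4. Candidates are trimmed to homozygous endpoints. Scanning left to right, a
   candidate is curtailed just before the (`segment_max_het`+1)-th
   heterozygote and restarts after it (default `segment_max_het` 0: every
   interior heterozygote splits the segment). Missing calls inside a segment
   are allowed.
5. Surviving segments must hold ≥ `min_snps` markers (default 40), span
   ≥ `min_length_kb` (default 2500 kb) and satisfy the density bound
   length / n_snps ≤ `max_kb_per_snp` (default 70).

Boundary conventions: window acceptance uses ≤, eligibility uses ≥, and
segment length is `end_pos − start_pos` with no +1 (PLINK's KB column).
Chromosomes shorter than the window yield no calls.

The defaults are the parameter set used for 50K-array red deer data
(≈ 15 SNPs/Mb), where simulations show they recover the true ROH present.

**Coordinates.** Calls run on either the physical map (bp) or the genetic
linkage map (cM). Genetic calling builds a pseudo-physical map with
position = cM × 10³ "kb", so every kb-denominated threshold applies
unchanged; this uses the empirical equivalence 1 Mb ≈ 1 cM for red deer
(genome-wide mean 1.038 cM/Mb). With `cm = bp × 10⁻⁶` the two coordinate
systems produce bit-identical calls — a degenerate case used as a test.

**Heterozygote semantics.** Splitting a candidate at every heterozygote
(`segment_max_het 0`) is a strict reading of the het cap. Tools differ in
whether the cap splits segments, drops them, or is applied only at the
window level, and the choice matters most for marginal tracts: an
identity-by-descent tract of ~2.5 Mb from a common ancestor ~20 generations
back carries on average ~1 heterozygote from post-coalescence mutation
(2tμℓ ≈ 0.95 at μ = 1e-8), so a zero-het rule suppresses the count of
marginal tracts by ~e⁻¹. The strict rule is the package default; the cap is
a parameter, so the lenient variant is one argument away.

**Correctness.** `fixtures.oracle_call_roh` re-derives the same contract by
exhaustively enumerating windows and candidate intervals with plain loops.
The acceptance suite checks set-identity of the fast vectorised caller
against this oracle on 200 randomized fixtures with parameters drawn around
the production set.

## The forward simulator

An individual-based Wright–Fisher model of one chromosome (default 100 Mb).
Each diploid's haplotypes are sorted arrays of mutation tokens
(`position << 21 | counter`), so recombination is a slice-merge and
genotype emission is a counting pass.

* **Reproduction.** Each offspring draws two parents with probability
  proportional to fitness; each transmitted gamete recombines with
  Poisson(map length in Morgans) crossovers (no interference) placed in
  proportion to the local rate, and receives Poisson(μL) new mutations at
  uniform positions. Mutation rate μ = 1e-8 per bp per generation.
* **Fitness** is multiplicative over sites with per-genotype factors
  (1, 1+hs, 1+s); any non-positive factor floors the individual's fitness
  at 0. A population whose total fitness reaches 0 raises
  `SimulationError`.
* **DFE.** Neutral, beneficial and deleterious mutations occur in the ratio
  3:1:10; |s| is gamma-distributed with shape 0.2 and mean 0.001 (h = 0.5)
  for beneficial and 0.01 (h = 0.1, partially recessive) for deleterious
  mutations. The strong-selection model multiplies all selection
  coefficients by five.
* **Recombination.** Model 1 uses a constant 1.038 cM/Mb (the genome-wide
  mean of the red deer linkage map); models 2–4 use a 10-region map
  (1.75, 1.23, 0.89, 0.81, 0.74, 0.80, 0.87, 1.05, 1.20, 0.67 cM/Mb)
  reflecting elevated peri-centromeric recombination on acrocentric
  chromosomes.
* **Demographies.** All scenarios burn in at Ne 7500 for 75,000 generations
  (10 Ne) and end at generation 75,030. `no_bottleneck` stays at 7500;
  `rum` drops to Ne 100 at generation 75,000; `severe_bottleneck` drops to
  Ne 10 at 75,000 and recovers to 100 at 75,005. Output is a sample of the
  final generation (100 diploids; the full population for no-bottleneck),
  emitted as the segregating sites of the sample with bp positions and cM
  positions accumulated from the (nominal) recombination map. Phase is
  retained, so the haplotype-diversity module consumes simulator output
  directly.
* **Fixed mutations** are pruned every 100 generations (configurable) and
  counted; they are invisible to genotype output, as in standard forward
  simulators.

**Rescaling.** A factor Q divides the burn-in population size and duration
by Q and multiplies μ, r and s by Q, preserving the compound parameters
4Neμ, 4Ner and 2Nes. The bottleneck epochs are already small (Ne ≤ 100,
~30 generations) and always run unrescaled at nominal μ, r, s — rescaling
them would shrink ROH tract lengths by Q. Rescaling is exact only while
Q|s| ≪ 1; with the strong-selection model at Q = 25 some deleterious draws
exceed |s| = 1 (recessive lethals) and strong beneficial draws saturate, so
scaled selection runs are qualitative caricatures (see "Desk-scale
experiments").

**Burn-in strategies.** `burn_in="forward"` runs the full rescaled burn-in
with the forward engine. `burn_in="coalescent"` (default) draws the burn-in
endpoint directly from the stationary distribution via the coalescent
(msprime, Hudson model, binary mutations): under neutrality this is the
distribution a 10 Ne forward burn-in converges to, at a small fraction of
the cost, which is what makes 100 Mb chromosomes tractable on a laptop.
When selection should act before the demographic endgame, a forward "tail"
of `burn_in_tail_generations` at burn-in parameters follows the coalescent
draw, giving the DFE a window to generate sweeps and load. The forward
engine itself is validated at small scale where the full forward burn-in is
affordable: equilibrium diversity π within 15% of 4Neμ, π agreement between
Q = 5 and Q = 10, a binomial transition-distribution check of single-site
drift against the Wright–Fisher oracle, and the 1/k shape of the neutral
site-frequency spectrum.

## ROH statistics

* **F_ROH** = (sum of Mb in ROH across autosomes) / 2591.86 Mb, the total
  autosome length of the red deer assembly; genetic-map calls use the same
  denominator via the 1 Mb ≈ 1 cM equivalence.
* **ROH density** per marker = 100 × (individuals with a ROH covering the
  marker) / (individuals genotyped).
* **SNP-density filter.** Scanning-window callers under-call ROH where
  markers are sparse, which biases density maps. Windows of 1500 kb
  sliding by 100 kb tile each chromosome (anchored at the first marker;
  the last window is the first to reach the final marker, so no degenerate
  sliver windows are evaluated past the data); all markers in any window
  holding fewer than 23 markers are discarded.
* **End trimming** removes the first and last 40 markers of each chromosome
  (a ROH cannot extend past a chromosome end, deflating density there).
* **Hotspots.** The threshold is the 99th percentile (linear interpolation
  between order statistics — recorded so alternates can be compared) of
  density over retained markers; retained markers at/above it are hotspot
  SNPs, merged into regions when adjacent in retained-marker order
  (`merge_gap_markers`, default 1) and labelled (a), (b)… per chromosome.
  A short-ROH variant repeats the analysis using only segments of
  2.5–5 Mb (bounds inclusive), the length class enriched for older
  inbreeding.
* **Per-iteration summaries** reduce each simulation to the hotspot
  threshold and the maximum ROH density, the two scalars compared across
  scenarios and models.

## Haplotype diversity

Phased haplotypes are split into 20-SNP windows advancing by 10 SNPs.
Haplotype rows with any missing call in a window are removed from that
window (the stricter whole-window removal is available via
`drop_whole_window=True`; with array-scale missingness the row-wise rule
retains far more data). Within a window, rows are grouped by exact allele
string and diversity is

    D = 1 − Σ nᵢ(nᵢ−1) / (N(N−1)),

the probability that two haplotypes drawn without replacement differ.
Windows with fewer than two usable rows are omitted. Tracks can be
overlaid with hotspot regions, reporting each region's minimum D against
the background median so "diversity drops at a hotspot" is a number, and
`low_diversity_fraction` (windows with D < 0.05) summarises sweep
footprints. Window size matters — narrow dips shallow out as windows
grow — so window/step are exposed everywhere.

## Synthetic fixtures

`generate_planted` builds genotype matrices with homozygous tracts of known
coordinates on a regular marker grid (optionally with low-density gaps and
missing calls sprinkled in), against a background of 30% heterozygosity —
typical for SNP-array data and enough to make tract boundaries sharp.
Setting the background het rate to 0 merges whole chromosomes into one run,
a degenerate case kept as a test to document why the background matters.
`generate_phased` draws haplotype rows block-wise from a template pool with
fixed frequencies, so windowed D has the closed-form expectation
E[D] = 1 − Σp². All generators are pure functions of (spec, seed).

## Desk-scale experiments and what they show

The experiment drivers run at reduced problem sizes chosen so the full
grid completes on one core in minutes:

* **Scenario comparison** (acceptance script; `analysis/01`): 23 iterations,
  Q = 25, 50 Mb chromosome. All scenarios share the same pre-bottleneck
  history, so each iteration draws one coalescent equilibrium (Ne 300,
  i.e. 7500/25) and seeds all three demographic endgames from it;
  per-individual quantities are doubled to the 100 Mb scale. Halving the
  chromosome truncates tracts at the ends (a ~5–15% downward bias on
  counts, worst for the severe scenario's long tracts); the doubling is a
  linearity assumption, valid because expected ROH content per Mb is
  position-stationary.
* **Selection contrasts** (acceptance tests; `analysis/03`): 12 Mb
  chromosome, Q = 25, a 30-generation selection window after the coalescent
  draw, then the scenario endgame. Because s is rescaled ×25, the strongest
  draws saturate (|s| ≥ 1), which exaggerates how quickly selection
  converts into diversity troughs immediately before a bottleneck; the
  no-bottleneck vs severe-bottleneck comparison of the selection effect is
  therefore made on the baseline-normalised (fold) effect, which is the
  scale-invariant form of the claim that selection shapes ROH only where
  drift does not dominate.

What passing these experiments shows: the caller implements its contract
exactly; the simulator's drift, recombination, mutation and rescaling
behave as population-genetic theory predicts; ROH burden reproduces the
drift ordering (no bottleneck ≪ island history < severe bottleneck) with
magnitudes close to the reference values for the bottleneck scenarios; and
the qualitative selection signatures (elevated maximum ROH density where
Ne is large, low-D windows under strong selection) emerge. What it does
not show: SNP-array artefacts (genotyping error, ascertainment bias of
array markers, per-marker missingness structure) are not emulated — the
generator plants clean calls — so thresholds tuned here may need
re-examination on real array data; and scaled selection runs are not
quantitative predictions of sweep dynamics.

Known quantitative caveat: under the strict zero-heterozygote rule the
no-bottleneck scenario's mean ROH per individual is ~0.03 rather than the
~0.06 a heterozygote-tolerant caller reports — marginal 2.5 Mb tracts carry
~1 post-coalescence heterozygote on average, and the strict rule splits
them below the length threshold. The bottleneck scenarios, whose tracts
come from very recent coalescence, are insensitive to this choice.

## Numerical and engineering choices

* Genotype codes: 0/2 homozygous, 1 heterozygous, −1 missing (int8);
  allele polarity is arbitrary for ROH and calls are invariant under
  swapping the homozygous codes (tested).
* bp positions are 1-based as in PLINK map files; duplicate-bp sites from
  coincident mutations are collapsed (first kept) so maps stay strictly
  increasing — at θ = 3e-4 this loses ~0.1% of sites.
* Per-iteration seeds are derived from the base seed and the iteration
  index, never from scheduling, so results are independent of execution
  order; every experiment writes a manifest (config, seeds, version) and
  resumes per iteration from its output directory.
* The caller processes individuals in blocks of 64 to bound the memory of
  the cumulative-sum window machinery (~a few hundred MB at 300 × 200k).
* PLINK text and binary (2-bit SNP-major) dialects are both supported and
  round-trip exactly; ROH tables round-trip through `float_precision=
  "round_trip"` parsing.

## Known limitations

Single chromosome per run; no crossover interference; no tree-sequence
recording (token arrays keep the engine simple but make deep forward runs
at full size expensive — hence the coalescent burn-in); coalescent burn-in
is neutral-only, so selection-at-equilibrium questions need the forward
burn-in at reduced scale; hotspot region merging is marker-index based
(`merge_gap_markers`), not distance-based; empirical phasing is out of
scope — the diversity module consumes phased input from any source.
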