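# Methods

## The model

Filamentous ascomycetes police duplicated DNA with repeat-induced point
mutation (RIP): during the sexual cycle, cytosines inside duplicated
sequences are converted to thymines with a strong dinucleotide preference.
Over generations this drives duplications AT-rich, producing a genome that
is a mosaic of GC-rich gene territory (~56.5% GC in the reference species)
and AT-rich blocks (centromeres, subtelomeres and thousands of interspersed
relics). `ripscape` implements the full analytical chain over this model:

1. **Landscape** — GC fraction in non-overlapping windows (default 500 bp)
   tiled from position 0; trailing partial windows are dropped. GC is
   computed over non-N bases; an all-N window is undefined (NaN) and is
   excluded from histograms and never qualifies as AT-rich. For N-free
   windows AT = 1 − GC exactly, so one track serves both views.
2. **Block calling** — a window qualifies when its GC is at least
   `genome_delta` (default 6) percentage points below the genome-wide mean
   of window GC, and, when a gene-level GC mean is supplied, also at least
   `gene_delta` (default 12) points below it (the effective cutoff is the
   minimum of the two). A block is a maximal run of qualifying windows;
   runs separated by at most `max_gap_windows` (default 0) sub-threshold
   windows merge. Blocks are therefore quantized to the window grid.
3. **Classification** — blocks starting within `subtelomere_margin`
   (default 1 kb) of a chromosome 5′ end or ending within it of the 3′ end
   are subtelomeres; the longest remaining block per chromosome is the
   operational centromere (ties: leftmost); the rest are interspersed.
   "Long" blocks are L ≥ 3 kb (inclusive, matching the 3 ≤ L < 5 bin).
4. **Architecture grouping** — Group III when mean window AT ≥ 58%;
   otherwise Group I when the genome holds ≥ 50 long blocks; otherwise
   Group II. The two thresholds are the widest margins separating the
   twelve published reference genomes shipped in `ripscape.datasets`, and
   both are parameters of `classify_genome_group`.
5. **RIP indices** — TpA/ApT and (CpA+TpG)/(ApC+GpT) from overlapping
   single-strand dinucleotide counts (N-containing pairs skipped). A ratio
   with a zero denominator is *undefined*, a value, not an error. Both
   index sets are complement-closed, so single-strand counting equals
   double-strand counting exactly; this is enforced by a property test.
   The windowed RIP scan flags windows with TpA/ApT ≥ 0.89 and composite
   ≤ 1.03 — the classical cutoffs for RIP'd sequence — merged into regions.
6. **RIP calling** — progeny alleles are globally aligned to the parent
   (match +1, mismatch −2, gap open −8, gap extend −2; first optimal
   traceback, which prefers the diagonal). A parent C aligned to progeny T
   is a call on the plus strand; parent G to progeny A is the mirrored
   call on the minus strand. The context is the C plus its 3′ neighbor
   *in the parent* (for minus-strand calls, the complement of the parent's
   5′ neighbor). Columns adjacent to gap columns yield no RIP call; all
   other substitutions (including T→C) are reported separately as non-RIP
   changes. Calls whose context neighbor is itself substituted are flagged
   but kept with the parent context.
7. **Context ranking** — rates are calls / availability, where
   availability counts every parental C by its 3′ neighbor on both
   strands. Contexts sort by rate; adjacent pairs are related by a
   two-proportion z-test: `≈` when not significant (α = 0.05), `>` when
   significant, `≫` when significant *and* the lower 95% confidence bound
   of the rate ratio (Katz log-interval) is ≥ 3. The confidence-bound form
   (rather than the point ratio) keeps a modest 4-fold difference measured
   from dozens of events at `>`, while a 5-fold difference supported by
   hundreds of events earns `≫`; like any significance-based notation the
   symbols sharpen as sample size grows. Ties under `≈` are unordered:
   CpA≈CpG and CpG≈CpA are the same statement.
8. **Compartmentation** — a block of any class lying entirely between two
   consecutive cluster genes splits the cluster; genes overlapping a block
   are assigned to their 5′-side compartment and flagged (no minimum block
   length is imposed). Telomere boundaries are recognized at cluster edges
   within 1 kb of a chromosome end. With no overlaps, compartments =
   internal separating blocks + 1 (oracle-tested on random layouts).
9. **Expression** — RPK = read count / transcript length; TPM =
   RPK / ΣRPK × 10⁶ with rRNA/tRNA genes removed before normalization, so
   included TPMs sum to one million. Induction classes between two
   conditions use fold = (TPM_b + 0.1)/(TPM_a + 0.1): ≥ 20× highly
   induced, 5–20× significantly upregulated, ≤ 1/5× repressed, otherwise
   unchanged. The 0.1-TPM pseudo-count (settable) keeps zero-expression
   genes finite and unchanged.

## The synthetic-data generator

`ripscape.simulate` builds genomes with the structure the analysis
assumes, with machine-readable truth for every planted feature. Defaults
are the study conditions used by the tests and the acceptance script:

- two chromosomes (300 kb and 260 kb) — a deliberately scaled-down genome
  that preserves every structural element at full local realism;
- gene segments (1.5 kb, 56.5% GC) alternating with intergenic background
  (1 kb, 51% GC); every 25th gene is a tRNA, and nine rRNA genes annotate
  the rDNA array, exercising the TPM exclusion rule;
- terminal telomeric tracts, 14 × TTAGGG at 3′ ends and 14 × CCCTAA at 5′
  ends;
- one 2.5 kb duplicated element just inside each terminus (subtelomere),
  interspersed 2.5 kb duplicated elements at gaps drawn uniformly from
  9–17 kb (mean 13 kb, the reference arm spacing), and a central tandem
  array of 10 × 2 kb units (the centromere-scale block). All copies of a
  family are exact pre-RIP duplicates;
- an rDNA-like head-to-tail array (9 × 1 kb, gene-like GC) on the last
  chromosome, *not* registered as RIP-exposed — tandem rDNA escapes RIP in
  vivo, and here it verifies that un-RIP'd repeats do not become AT-rich
  blocks;
- forward RIP: 20 synchronous cycles in which every C (both strands)
  inside a duplicated region mutates independently with the per-context
  probabilities CpA = CpG = 0.10, CpT = 0.02, CpC = 0.005 per cycle,
  contexts read from the start-of-cycle sequence. The organism's true
  per-cycle rate is unknown; these illustrative defaults drive duplicated
  regions from ~51% to ~23% GC, far past the calling threshold, so the
  causal chain duplication → RIP → AT-rich block is present in the data
  rather than painted on;
- Poisson read counts (base mean 200) for two conditions, with sparse
  planted effects: 1% of genes at 40×, 2% at 10×, 2% at 0.1×. Effects are
  sparse because TPM renormalization dilutes fold changes when induced
  genes carry a large share of the library; at these settings a planted
  40× multiplier realizes ~25-fold in TPM, safely above the 20-fold class
  boundary.

Background sequence is a first-order Markov chain, not i.i.d.: TpA
transitions are depleted (×0.5) and CpA/TpG enriched (×1.3), with the
complementary ApC/GpT factors (×0.85) keeping the statistics strand
symmetric. This mirrors the universal TpA suppression of real DNA. It
matters: on i.i.d. sequence both RIP indices are ≈1, so the classical
cutoffs would flag *everything*; on the biased background un-mutated DNA
scores ~0.5 / ~1.45 and heavily RIP'd DNA ~1.4 / ~0.38, giving the scan a
sub-1% false-positive rate with near-complete sensitivity inside RIP'd
regions.

What the generator does **not** emulate: transposon-derived repeat
families, sequence divergence between duplication copies before RIP,
meiotic recombination and aneuploidy, Ns and assembly gaps (supported by
the analysis code but not planted), read-level error, and overdispersed
(negative-binomial) counts. Passing tests therefore demonstrate
correctness of the *operations* under the assumed structure, not
robustness to every property of real sequencing data.

## Numerical choices and degenerate inputs

- All internal coordinates are 0-based half-open; GFF3 and RepeatMasker
  input is converted on ingest, BED emitted natively.
- Threshold comparisons are inclusive (≥/≤) throughout: repeat filtering
  (length ≥ 140, score ≥ 450), block qualification, long-block boundary,
  induction classes.
- Window SD in genome summaries is the population SD (ddof = 0) over all
  defined windows of all sequences.
- `count_tandem_units` seeds on the best edlib match of the unit anywhere
  in the sequence, then extends head-to-tail in exact unit-length,
  substitution-only steps at ≥ 90% identity; it underestimates copy number
  when copies differ by indels (out of scope).
- Undefined ratios (zero denominators), all-N windows, arms with < 2
  interspersed blocks, chromosomes without a centromere candidate, and
  zero-call tallies are all representable results, not errors; hard errors
  are reserved for malformed input (illegal residues, inverted
  coordinates, empty clusters, all-zero count tables, < 50%-identity
  "homologs").
- Determinism: the simulator is byte-identical under a fixed seed; the
  RIP and count stages draw from child seeds of the study seed so the
  stages are independently reproducible.

## Known limitations

- The merge rule behind the reference genome's printed block totals is
  not derivable from first principles; `max_gap_windows` and the choice of
  calling rule are exposed so real-genome totals can be calibrated.
- The `≈`/`>`/`≫` ranking is a statistical operationalization of an
  informal notation; its symbols depend on sample size by construction.
- The RIP scan thresholds (0.89 / 1.03) are classical defaults, prominent
  as parameters; they are not re-derived from data.
- Pairwise alignment is O(nm); RIP calling is intended for allele-scale
  (kb) sequences, not whole chromosomes.
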