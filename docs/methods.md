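# Methods

This note documents the models and procedures `dccmotif` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
procedure left room.

## Oligonucleotide profiling

For a word w of length k read at a position of the target sequence, the
specificity ratio is

    r(w) = c1(w) / max(c2(w), 0.5) × (L2 / L1)

where c1, c2 are the word's counts in source 1 (the chromosome whose
specificity is being measured, typically the target itself) and
source 2 (the comparison autosome arm), and L1, L2 are the sources'
*effective lengths* — the number of counted windows, i.e.
len − k + 1 minus windows skipped for ambiguous bases. The fixed
pseudocount 0.5 handles words absent from source 2; the L2/L1 factor is
the size correction (counts scale with the number of windows, so the
window-count ratio is the natural size measure). Words are counted on
the given strand only; a `both_strands` flag adds the reverse
complement's windows for sensitivity analyses.

Ratios of R adjacent words are averaged into locus values. A locus
spans k + R − 1 nt; consecutive loci overlap by k + R − 2 nt (defaults
k = 13, R = 5: 17 nt loci, 16 nt overlap). Loci with average ratio at
or above the threshold (default 6.8) whose spans overlap or abut merge
into specific regions; merging at gap 0 is what lets multi-locus
regions grow beyond the 17 nt minimum. Windows containing non-ACGT
characters produce neither counts nor loci.

A caveat found during testing: the *number* of called regions is not
monotone in the threshold. Lowering the threshold adds qualifying loci,
which can bridge two regions into one; only the covered base pairs are
monotone. Cutoff-sweep consumers should read both columns.

## Binding-region calling and consensus

A binding region is a maximal run of probes with signal ≥ `min_signal`
(default 2, in the track's signal units) whose consecutive positions
are ≤ `max_gap` apart (default 1000 bp, chosen for arrays with probes
every 50–100 nt and repeat-masked gaps). Regions span probe positions
half-open, so a lone qualifying probe yields a 1 bp region; probe
footprints are unknown to the track format and not modeled. Consensus
regions pool several datasets' calls, merge any two separated by
*strictly less than* `merge_gap` (1000 bp), and keep only merged
regions *strictly longer than* `min_length` (1000 bp). The asymmetry
(≤ for per-dataset gaps, < for consensus) follows the two rules'
definitions literally.

## Matrix scanning

The positional frequency matrix holds raw base counts per column; the
score of a window is the sum of its bases' counts and the maximum score
is the sum of per-column maxima. No log-odds transform or background
model is applied — the statistic is deliberately the plain count sum.
Windows on both strands scoring at least `cutoff_fraction` (default
0.90) of the maximum are hits; a minus-strand hit is scored against the
reverse-complement matrix and reported in plus-strand coordinates.
Overlapping or abutting hits merge into sites (site score = best window
inside; strand `merged` when both strands contributed), which is why an
internally repetitive motif yields sites longer than the matrix width.
Windows containing ambiguous bases are skipped entirely.

`pattern_to_matrix` turns a degenerate pattern over {A,C,G,T,S,N}
(S = C/G) into a matrix by splitting each column's weight (common
denominator 4) equally over the allowed bases, so exact pattern matches
score the maximum. The built-in default is the [G(CG)N]₄ consensus
(width 12, max score 28). At the 90% cutoff this matrix tolerates any
substitution at N positions and one S→A/T violation, but no violation
of the fixed G positions.

## Density, spacing and positional statistics

Site density is sites per Mb of an interval set; a site belongs to an
interval when its *midpoint* falls inside (boundary handling is not
specified by the procedure; the midpoint rule is symmetric and
splitting-invariant). The standard error comes from partitioning the
interval set's concatenated base pairs into fixed-length fragments
(default 2 Mb for chromosome-scale input; scaled-down runs use smaller
fragments) and taking the SE of per-fragment densities; the final
partial fragment keeps its actual length.

Spacing is the end-to-start distance between consecutive merged sites
per chromosome (site bodies excluded, never across chromosomes).

Sliding profiles place a `window` bp window (default 500) at signed
offsets up to `max_offset` from anchor points — region centers
(floor((start+end)/2)) or seeded random positions — and average site
density per offset over anchors. An anchor's orientation flips the
offset sign so negative offsets always point toward the telomere;
windows extending past a chromosome end are dropped from that offset's
mean. Downstream windows at displacement d cover [pos+d, pos+d+w),
upstream windows [pos−d−w, pos−d): the two windows coincide at d = 0 by
construction.

Gene-relative site positions are (site midpoint − 5′ gene end)/gene
length for genes longer than 2000 bp that contain at least one site
(optionally also carrying a mean-binding score above a floor, read from
the GFF attributes since per-gene signals come from external data);
for minus-strand genes the 5′ nucleotide is the highest coordinate, so
mirrored placements on opposite strands give identical values.
Uniformity is tested with a one-sample KS test on the interval
[trim, 1 − trim] (default trim 0.05, excluding the depleted gene
extremes), with the kept values rescaled to [0, 1].

## Conservation

Each aligned pair covers one motif site ± `flank` nt (default 100).
Columns are assigned to site or flank by query coordinate; a column is
a difference when its characters differ. Gap treatment is a design
choice the source procedure does not fix: a gap against a base counts
as a difference, gap–gap columns are excluded from the total, and a
column where the *query* has a gap belongs to the site only when the
insertion falls strictly inside it. The synthetic generator is
substitution-only, so these conventions never affect the shipped tests.

With aggregate counts (N aligned columns, K in sites, n differences, k
in sites), site identity is (K−k)/K and flank identity
((N−K)−(n−k))/(N−K). The shared-rate null is tested with the
lower-tail cumulative hypergeometric probability P(X ≤ k),
X ~ Hypergeom(N, K, n), evaluated in log space (scipy `hypergeom.logcdf`)
for numerical safety at genome-scale counts; the lower tail is the
conservation direction (fewer differences in sites than expected).
Under equal per-column substitution rates, k conditional on n is
exactly hypergeometric, so the test is exactly calibrated on the
generator's output — the 200-seed calibration test exercises the
implementation, not an approximation.

Upstream homology search (the step that produces the alignments) is
out of scope; its conventional thresholds (E ≤ 10⁻³, ≥ 40 nt homology)
are carried as provenance metadata into reports only.

## Codon classes

Read in its three frames, [GSN]ₙ yields the codon patterns GSN, SNG,
NGS; its reverse complement [NSC]ₙ yields NSC, SCN, CNS. Each expands
to exactly 8 codons (4 N-choices × 2 S-choices); the classes differ in
distinct amino acids encoded under the standard nuclear genetic code —
(CG)NG: 8; N(CG)C: 7; NG(CG) and CN(CG): 5; G(CG)N and (CG)CN: 2 —
which is the quantity contrasted between partitions. None contains a
stop codon (classes that would are flagged, not rejected).

Sites map to codons through the annotated gene models only (no
three-frame scan): for each site×CDS overlap, codons whose three bases
all lie inside the site are emitted in the gene's reading frame
(minus-strand genes on the reverse complement); partial codons at the
edges are discarded. A codon string may match more than one class
(e.g. GCC matches both G(CG)N and N(CG)C); the procedure's tie-break is
not specified, so the primary class is the first match in a fixed
frequency-ordered priority ((CG)NG, CN(CG), N(CG)C, NG(CG), G(CG)N,
(CG)CN) and all matches are kept on the assignment. Sites overlapping
several genes contribute to each, flagged ambiguous.

Class shares between partitions (inside/outside binding regions, by
≥ 1 bp site overlap) are compared with Pearson's χ² on the 2×2 table,
df = 1, no continuity correction (counts at the relevant scales make it
immaterial). Codon-usage ratios are relative codon frequencies between
two CDS sets; a helper compounds a single-codon ratio over a run of n
identical codons (ratio^n).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- a target chromosome (default 400 kb — a scaled-down stand-in chosen
  so the full pipeline and the 20-seed recovery experiments run in
  seconds; all rates are per-Mb and scale-free) with
  `planted_region_count` = 10 regions of 4 kb, motif instances planted
  at Poisson-distributed positions at 1500 sites/Mb inside the regions
  and 600 sites/Mb outside (the binding-region/background contrast),
  instances sampled uniformly from the degenerate pattern's expansion
  and never overlapping;
- a background chromosome carrying the outside density only;
- probe tracks with spacing uniform in [50, 100] nt and signal
  Normal(3, 0.3) inside regions vs Normal(0, 0.3) outside;
- non-overlapping single-CDS gene models (length uniform in
  [900, 4500] rounded to a codon multiple, random strand);
- ortholog alignments: gapless site ± flank windows against copies
  mutated per column at `site_sub_rate` = 0.12 inside sites and
  `flank_sub_rate` = 0.15 in flanks (substitutions to a uniformly
  chosen different base), truncated flanks recorded.

Two deliberate departures from a naive design, both required for the
planted truth to be well-defined:

- **Base composition.** The default composition is i.i.d. with GC
  fraction 0.30 rather than uniform. The [G(CG)N]₄ matrix is GC-rich,
  and at GC 0.5 its chance-match rate at the 90% cutoff is
  (gc/2)⁴ · P(Bin(4, gc) ≥ 3) per strand ≈ 1900 sites/Mb — three times
  the planted outside density, which would make the planted densities
  unrecoverable in principle. At GC 0.30 the chance rate is ≈ 70
  sites/Mb, an order of magnitude below the planted rates, and remains
  analytically checkable. The composition is configurable (including
  uniform).
- **Region separation.** Planted regions keep ≥ 2000 bp between them
  (`min_region_separation`): regions closer than the caller's 1 kb gap
  rule would legitimately merge into one called region, making
  boundary recovery ill-posed rather than wrong.

Every generator is a pure function of (config, seed); independent RNG
streams per product mean, e.g., the probe track does not change when
the gene count does.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: chromatin structure and repeat content;
the word-repetition structure of real X-specific sequence (instances
drawn uniformly from 4096 pattern expansions rarely repeat an identical
13-mer, so the profiling stage at the stringent 6.8 default typically
calls no regions on synthetic bundles — profiling correctness is
established by oracle tests, and threshold-level behaviour on real
chromosomes by the optional data-gated test); indels in ortholog
evolution; heterogeneous probe response; correlated mutation processes.

## Degenerate inputs and numeric conventions

Coordinates are 0-based half-open everywhere in memory and in BED;
probe TSV and GFF3 are 1-based on disk, converted in the I/O layer.
Sequences shorter than a window produce empty results, not errors;
empty region sets make densities undefined (error); fewer than five
values make the KS test undefined (error). Fragment SEs with a single
fragment are reported as 0. Ties in scores are kept (≥ comparisons
throughout). Seeds derive per-product streams from
`numpy.random.default_rng([seed, stream])`.

## Scaling of shipped experiments

The test suite and acceptance script run everything at scaled-down
problem sizes chosen as the package's own defaults: 400 kb genomes for
the 20-seed recovery experiments; ~113 000 aligned columns (1018 pairs
of a 12 nt site ± 50 nt flanks, matching the original analysis' aggregate column
count and its ~11% site-column share) for the conservation power
experiment; 100 pairs × 200 seeds for calibration. Chromosome-scale
results (tens of Mb) require the Release 4.3 chromosome
FASTA files and author-provided ChIP tracks; the two genome-only
quantities are covered by an optional test that runs when the
chromosome files are placed under `tests/data/release43/`.
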