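# Methods

## Inverted-repeat model and detection

A perfect inverted repeat (IR) is `left_arm + spacer + right_arm` with
`reverse_complement(left_arm) == right_arm` exactly; the spacer is
unconstrained. Hairpin/cruciform formation favours long arms and short loops,
so the defaults are a minimum arm of **10 bp** and a maximum spacer of
**8 bp**; a spacer of 0 is a perfect palindrome. `N` is treated as unable to
base-pair (it breaks arm extension but may sit in a spacer), and any other
IUPAC ambiguity code is mapped to `N` on ingest with a logged count.

Every IR is indexed by its *center*: the position where the left arm ends
and the spacer length. Per center the detector reports the unique **maximal**
arm — the arms can be extended neither outward by one more complementary
pair, nor (for spacer ≥ 2) inward by converting the two innermost spacer
bases into one extra pair. The inward rule means a reported IR's spacer never
has complementary end bases; the IR that *would* result from that extension is
reported at the same center sum with spacer − 2 instead, so each repeat
appears exactly once. Overlapping IRs at different centers are all reported;
double counting is resolved only at the footprint level (interval union),
because density is defined on base-pair coverage. Output is sorted by
(start, spacer) and fully deterministic.

The production scan is, per spacer length, a vectorized innermost-pair seed
scan followed by per-character outward extension — O(genome × (max_spacer+1))
expected on random sequence. An independent reference enumerator
(`brute_force_inverted_repeats`) recomputes the same set by binary search on
the arm at every center using slice extraction and Biopython reverse
complement; arm validity at a fixed center is downward-closed, which makes the
search correct. The two implementations share no code and are checked for
exact set identity on hundreds of random sequences.

Two conventions were genuinely open and are exposed as switches with these
defaults:

- **"IR bp" for densities counts the full span** (arms + spacer), as the
  union of spans; `use="arms"` restricts to arm bases.
- **Circular replicons are scanned as linear**; the topology flag is
  recorded but origin-spanning IRs are not searched.

Density is `1000 · footprint_bp / region_bp` (IR bp per kB). Species-level
density is the mean over a species' assemblies; rank-level density F(R) is
the mean over member species.

## Dinucleotide-preserving shuffled controls

Expected IR content under the null of "local composition only" comes from
shuffled genomes that preserve the exact multiset of overlapping
dinucleotides in every **1,000-bp chunk**, shuffled independently (the final
partial chunk is its own segment; doublets straddling chunk boundaries are
not preserved, by construction). The shuffle is the Altschul–Erickson
Euler-walk construction: one uniformly drawn "last exit" edge per vertex,
accepted when those edges form an arborescence into the final residue
(rejection sampling), remaining out-edges permuted uniformly, and the Euler
path read off. This guarantees exact doublet preservation — including
N-containing doublets, since `N` participates as a fifth symbol — and fixed
first/last residues per chunk. One seeded stream drives all chunks of a
genome; a fixed seed reproduces the control byte-for-byte.

## Enrichment and effect sizes

For observed O and expected E (densities or bp counts, both ≥ 0):
`FE = (O − E)/(O + E)`, defined as 0 when O = E (covering O = E = 0);
FE ∈ [−1, 1], antisymmetric, and scale-invariant. Across the paired
(real, control) densities of a rank's species:

- Hedges' g on paired differences d_i = X_i − Y_i:
  `g = J(N−1) · mean(d)/sd(d)` with `J(n) = 1 − 3/(4n−1)`. The sample
  (n−1) standard deviation is the default (`sd_mode="population"`
  available); zero-variance differences make g undefined and are flagged.
- Paired Cliff's δ: `2·P(X>Y) + P(X=Y) − 1` with empirical plug-in
  proportions; ties enter exactly through the `P(X=Y)` term. The unpaired
  form is `(#{x>y} − #{x<y})/(N·M)` over all cross pairs.
- Significance: two-sided Wilcoxon signed-rank per rank (scipy), BH
  adjustment across ranks (statsmodels). Degenerate groups (all differences
  zero) are flagged and excluded from the BH set.

## Topography

Functional compartments are merged, mutually disjoint interval sets derived
from gene annotations: genic, its complement intergenic, exonic, intronic
(genic − exonic), CDS, and strand-aware UTRs (5′ UTR = exonic bases 5′ of the
CDS start; 3′ UTR = exonic bases 3′ of the CDS end). Prokaryote-style genes
without explicit exons get a single gene-spanning exon on ingest. Compartment
density intersects the IR footprint with each compartment, so an IR
straddling a boundary contributes to each side proportionally.

Positional profiles count IR footprint bp at each offset of a symmetric
window around an anchor — **±500 bp (1001 positions)** for TSS/TES, **±100 bp**
for points of termination supplied as BED. TSS/TES are the strand-aware
first/last base of the gene feature (translation bounds for prokaryotes and
viruses, transcription bounds for eukaryotes). Minus-strand windows are
reversed so negative offsets are always upstream of the gene. Genes whose
window overruns a contig end are dropped with a logged count — zero-padding
would bias the window mean. Each profile is normalized by its own window mean
(so mean enrichment is exactly 1 and genome size cancels); a window with no
IR bp has undefined enrichment and is flagged. Overlapping genes each
contribute their own window. Aggregation across species is the per-offset
arithmetic mean of enrichment vectors; confidence bands are per-offset
2.5/97.5 percentiles over **1,000** two-stage bootstrap replicates (families
resampled with replacement, then species within drawn families). With a
single family the outer layer is degenerate and resampling falls back to
species only, with a warning. A standard-error band is available as an
alternative to the percentile band.

## Intraspecific SNV burden

Variants pass the quality filter **MQ ≥ 50 and QUAL ≥ 60** (both inclusive);
only single-nucleotide biallelic alleles count, multi-allelic records are
split per alt, and records lacking an MQ annotation are excluded (the
conservative reading of a quality filter) — all drops are counted in the log.
Each genomic position is a binary indicator: duplicate alleles at a position
count once and allele frequency is ignored. The genome-wide site density is
r = distinct SNV positions / genome length.

Two nulls for the SNV count in a segment (arm or spacer footprint):

- length-based: `E(L, r) = L·r`, L the merged non-overlapping segment bp;
- trinucleotide-adjusted: classify every position with a full N-free
  trinucleotide context by the canonical class of its centered triplet
  (canonical = lexicographic minimum of the triplet and its reverse
  complement; 32 classes), estimate `p_j` = genome-wide SNV sites in class j
  / genome positions in class j, and take `E[X] = Σ_j c_j·p_j` with c_j the
  segment's class counts. Contig-end and N-adjacent positions are excluded
  from both numerator and denominator (symmetric exclusion keeps p_j
  unbiased). With uniform class rates the two nulls coincide on N-free
  genomes.

Arm and spacer footprints are merged separately; a base claimed by an arm of
one IR and the spacer of another goes to **arms** by default (pairing
constrains the base; the precedence is switchable). Fisher's exact test
(two-tailed) compares observed vs trinucleotide-expected SNVs inside the IR
footprint against the rest of the genome, with the expected count rounded
half away from zero to form the 2×2 table; zero-margin tables are flagged.

IRs are **near** a terminator when any base of their span lies within
**50 bp (inclusive)** of a terminator interval; per segment × near/far
stratum (optionally per spacer length) the SNV density is observed sites per
segment bp, and near-vs-far contrasts across species use the unpaired
Cliff's δ. The regression-deviation ratio fits through-origin least-squares
slopes of observed on expected burden across species (the 45° comparison
presumes no intercept) and reports
`R = |arctan(slope) − π/4|` of the numerator segment over the denominator
segment. The default orientation is **spacer over arm**, so R > 1 reads
"spacers deviate more from the identity line than arms"; the opposite
orientation is available because the symbol-to-segment assignment is
interpretation-sensitive. A denominator slope of exactly 1 leaves R
undefined (flagged).

## Synthetic data: what it emulates and what it does not

The generator produces the conditions the statistics assume: i.i.d. or
first-order-Markov background (default GC 0.5; optional CpG depletion makes
shuffle tests non-trivial), planted perfect IRs with chosen arm/spacer
lengths and arm GC, prokaryote-style gene grids with configurable UTRs,
terminator intervals a fixed offset downstream of gene ends, and Bernoulli
SNV sites with per-class rates (defaults in the 10⁻³–10⁻² range typical of
intraspecific bacterial variation; base rate 5·10⁻³) and footprint
multipliers. Two multiplier sets exist: plain spacer/arm multipliers
(defaults 1), and near-terminator multipliers (defaults ×3 spacer, ×0.5 arm)
emulating elevated spacer polymorphism and arm conservation at intrinsic
terminators — the qualitative pattern the terminator-partition statistics
are designed to resolve, encoded in the generator so that sign checks test
the analysis rather than a coin flip.

Planted IRs are guard-flanked (the base before and after the span is chosen
not to pair) and their spacer end-bases are screened against pairing, so the
planted arm is exactly the maximal arm and truth is exact. Anchored
placements center the IR span at a chosen window offset from each gene's
TSS/TES (strand-aware, with a ±1 offset asymmetry for even spans) and are
planted before uniform placements sample the remaining space; infeasible
packing raises with the required extra length. The truth table is the
brute-force enumerator's scan of the *final* genome, so accidental
background IRs are truth, not false positives, and recall is measured
against complete truth.

What the generator does **not** emulate: repeat-driven genome architecture
(tandem repeats, transposable elements), phylogenetic correlation between
species, recombination, indels, or assembly error. Passing recovery tests
therefore demonstrates correctness of the measurement chain under the
declared statistical model, not robustness to every property of real
genomes.

## Problem sizes and numerical choices

The test suite and analysis scripts run at desk scale by design: detector ↔
enumerator identity on 200 random 2-kb sequences; planted-IR recovery with
50 IRs spanning arms 10–10,000 bp in a 75-kb genome; 1,000 shuffled 1-kb
chunks; burden-multiplier recovery (m ∈ {1, 2, 4}) pooled over 10 replicate
25-kb genomes with 80 planted IRs each, judged within 3 binomial standard
errors of the pooled ratio; TSS-profile recovery over 20 genomes with
10 genes each and 1,000 bootstrap replicates; and a 12-assembly cohort for
the narrative scripts. Tolerances: exact equality for set-valued and
closed-form results, 1e-12 for effect-size formula agreement, 1e-9 for the
trinucleotide expectation against per-position summation, 3·SE bands for
stochastic recovery. Seeds are fixed everywhere; every stochastic routine
takes an explicit seed or Generator.

Known limitations: detection cost degrades toward O(n²) on pathologically
self-complementary sequences (e.g. long `(ACGT)ₙ` tracts); origin-spanning
IRs on circular replicons are not reported; the pipeline's per-assembly
shuffle seeds derive deterministically from the run seed, so adding an
assembly changes other assemblies' controls only if it changes their sort
order; and rank-level inference at cohort sizes of a few species has limited
power (the Wilcoxon p-value floor for n pairs is 2⁻ⁿ⁺¹·2).
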