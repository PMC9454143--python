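# Methods

This note documents the models, parameter choices and numerical details
behind phasikit, and what the synthetic benchmarks do and do not show.

## Preprocessing

Reads are collapsed to unique sequences with per-library counts (order is
lexicographic for determinism). Cleaning retains reads of 16–30 nt — the
enrichment window of typical sRNA libraries — and removes polyA artifacts,
flagged when ≥ 80% of bases are A or a run of ≥ 8 A occurs. No published
rule pins the polyA definition; both knobs are configurable. Structural
ncRNA removal (rRNA, tRNA, snRNA, snoRNA, scRNA) is exact-substring
matching on either strand against a class-labelled reference, with class
attribution in the fixed order rRNA → tRNA → snRNA → snoRNA → scRNA. All
filters conserve read mass (`raw = retained + Σ removed`, asserted on
every run) and are idempotent.

FASTQ qualities are parsed but ignored: cleaning is composition-based
only, and the simulator emits post-trimming reads, so no adapter or
Phred logic exists anywhere in the package.

## Mapping

Mapping is zero-mismatch by construction ("perfect match" semantics): a
12-mer seed index over the plus strand, candidate verification by full
substring comparison, minus-strand hits via the reverse-complemented
query. The mapper is property-tested against a naive all-positions scan.
Multi-mapped reads are retained for phased-locus detection with mass
split equally across placements (repeat-resident 24-nt loci would
otherwise be undetectable) but are excluded from novel-miRNA candidacy —
with one deliberate exception: a read with exactly two placements within
one 300-nt span is the mature of a near-palindromic hairpin matching both
arms, and counts as uniquely placed.

The degradation filter (drop reads overlapping annotated genes or
repeats) applies only on the miRNA-identification branch, and only to
reads whose *every* placement is annotation-covered: miRNAs legitimately
match their own target transcripts, and discarding them for that reason
would destroy trigger identification.

## RNA thermodynamics

Hairpin evaluation needs pair geometry, not accurate folding free
energies, so the default folder is a weighted Nussinov maximizer
(GC = 3, AU = 2, GU = 1; minimum loop 3; traceback prefers 5′-most
pairs; O(n²) numpy inner loops over diagonals). Any conforming folder can
be registered in `FOLD_BACKENDS` — the downstream criteria consume only
the pair list.

Duplex scoring uses a bundled nearest-neighbor stack table
(`data/duplex_stacks.tsv`, version 1): the ten standard Watson–Crick
dinucleotide stacks, with stacks containing G:U wobbles assigned class
averages (−1.3 kcal/mol for one wobble, −0.5 for two). Each mismatch adds
+1.0 kcal/mol and breaks stacking. The target-acceptance criterion is the
*ratio* of duplex energy to the perfect-complement energy (threshold
0.74), which is insensitive to affine rescaling of the table; the exact
published energy model behind that threshold is not recoverable, so the
table is versioned and the mismatch penalty configurable. G:U counts as a
pair for energy but as a mismatch for the sequence rules
(`gu_is_mismatch`, default true — pattern matching is sequence-literal).

## Novel-miRNA criteria

The annotation thresholds follow community practice for plant MIRNA loci:
precursor windows of mature ± 150 nt (two variants, mature near either
end), mature fully on one stem arm, ≤ 5 unpaired mature positions and
≤ 3-nt asymmetric bulges in the duplex region, a star with 2-nt 3′
overhangs, mature + star ≥ 75% of the window's read mass (this mass rule
is what separates hairpins from phased loci, whose reads spread over many
registers), mature 20–22 nt. Candidates require ≥ 20 reads.

Two numerical details matter. First, a pair-maximizing fold occasionally
attaches one or two terminal mature bases to distant partners; along a
clean antiparallel helix `i + partner(i)` is constant, so pairs whose
diagonal deviates from the within-mature median by more than the bulge
tolerance (3 nt) are discarded as off-helix before the duplex criteria
are applied. Second, the star interval is derived from the overhang
geometry — star 5′ end = partner of the 3rd-from-last mature base, star
3′ end = partner of the mature 5′ base + 3 — extrapolated along the helix
diagonal when those exact bases sit in a terminal bulge.

Novel families are single-linkage clusters at ≤ 2 mismatches between
equal-length matures, numbered miRN1, miRN2, … by descending total
abundance with deterministic tie-breaks.

## Expression

TPM = count / library mapped total × 10⁶ (columns sum to 10⁶ over the
full counted set). Differential expression between embryo and endosperm
within each cross uses fold change on group means with a pseudocount of
1 TPM and a two-sided Welch t-test on log2(TPM+1); significance is
|FC| ≥ 2 and raw P < 0.05. With three replicates per group no
distributional model is estimable, and the screening criterion uses raw
P-values; the Welch test is the simplest defensible choice and the test
function is swappable. On Poisson-null features the realized type-I rate
is ≤ 0.07 at α = 0.05 (asserted in the suite). Expression groups come
from average-linkage hierarchical clustering of row-z-scored log2
profiles, cut at k = 5 for known families and k = 3 for novel families
by default.

## Phased-locus detection

Registers live in strand-adjusted coordinate space: plus-strand reads at
their 5′ start, minus-strand reads at interval end + 2, which maps both
members of a phasiRNA duplex (2-nt 3′ overhangs) to the same class. Only
reads whose length equals the period contribute phased occupancy and
mass `P`; all other read mass in the window is `U`.

Windows span 9 cycles and conceptually slide by 1 nt; only starts that
put some occupied slot in register are materialized (all other windows
have n = 0 and cannot score), which makes the scan exact and fast. The
score is `(n − 2)·ln(1 + 10P/(1+U))` with an occupancy floor of n ≥ 3;
the P-value is `hypergeom.sf(n − 1, N=2·span, m=2·cycles, q)`, verified
against exhaustive enumeration for all N ≤ 12. Thresholds: score ≥ 10
(21-nt), ≥ 5 (24-nt), P < 0.001. Passing windows are merged when
overlapping and trimmed to the outermost in-register occupied position;
IDs are `PHAS{period}-i` in (chromosome, start) order. A
`register_tolerance` knob (default 0) admits ± 1-nt wobble.

Because trimming extends to any in-register occupied slot inside a
passing window, deep background can stretch locus boundaries by a few
cycles beyond the true precursor; benchmarks therefore score recall by
interval overlap, and the boundary-exactness check runs on noise-free
constructions.

## Trigger identification

Candidate sites are scanned on both strands of the locus ± 200 nt. The
cleavage-implied register is `site_start + L − 10` for a plus-strand
target; for a minus-strand target the cut base is `site_start + 9` and
the duplex-overhang adjustment adds 3 to place it in the shared register
space. A site is a trigger when its implied register is within ± 1 nt
(mod period) of the locus register. Two-hit detection requires a second
same-family site (positions 10–11 exempt, all other rules enforced)
separated from the cleavable in-register site by ≥ 3 phased cycles; the
two-hit call supersedes one-hit reporting for that family. Flank and
tolerance are config keys; no published values exist for either.

## Locus annotation

Genic means ≥ 1 shared base with an annotated gene, strand-agnostic;
otherwise the literal token "Intergenic". Putative function is the
overlapping gene's product string, "ncRNA" for configured ncRNA
intervals, "uncharacterized mRNA" for product-less genes, else "NULL".
Repeat overlap is reported per locus as covered fraction (overlapping
repeat pieces merged), with a summary share of loci majority-covered.
Genic + intergenic partition the locus set exactly (asserted).

## Synthetic data: what it emulates, and what it does not

The generator plants features in a random-background genome (default
2 × 100 kb, GC 0.40): hairpins (mature arm, ≥ 15-nt loop,
reverse-complement star arm; the star *read* is offset +2 so the duplex
carries 2-nt 3′ overhangs), phased loci whose 5′ trigger site's cleavage
point coincides with the first register, a TAS3-like two-hit construction
(cleavable 3′ site in register, 5′ anchor mutated at miRNA positions
10–11), an rRNA-like contaminant, and an mRNA-degradation gene. Reads are
drawn per library from a multinomial over features (Dirichlet-distributed
cycle usage, concentration 3, so loci are unevenly covered), genomic
background, polyA artifacts and sub-16-nt fragments.

Defaults are chosen to mirror the structure of real embryo/endosperm
libraries at desk scale: 12 libraries (2 crosses × 2 tissues × 3
replicates) of 20,000 reads, 75% background with a length profile peaking
at 24 nt (23 and 22 nt next) — the heterochromatic-siRNA-dominated
majority of such libraries — a 1:10 star:mature ratio (invertible to
exercise star-abundance reporting), and 4-fold tissue multipliers on
selected features to power the differential-expression checks. Tissue
multipliers act on per-library category weights, i.e. relative to the
other features in the same library, exactly as library-size-normalized
abundances behave.

What passing the benchmarks does **not** show: the simulator has no
sequencing errors, no adapters, no isomiR/processing heterogeneity, no
genome-scale repeat families (multi-mapping arises only from planted
palindromes), and feature density far above a real genome's. Recall 1.0
on these constructions demonstrates correctness of the callers' logic
under their own assumptions, not field performance on real libraries.

## Benchmark problem sizes

The recovery benchmark runs the full pipeline on the default layout
(200 kb, 12 × 20,000 reads); null false-positive runs use a register-free
20-kb genome at matched per-bp read density (12 × 2,000 reads). These
sizes keep a five-seed recovery plus a 100-seed null sweep within a few
minutes while leaving every per-feature read count far above the
detection floors.

## Known limitations

* The Nussinov folder ignores stacking energetics; criteria were made
  robust to its tie-breaking artifacts (helix-diagonal filter), but a
  thermodynamic backend is the better choice when available.
* Hypergeometric occupancy counts positions, not reads, and treats
  positions as exchangeable; clustered background inflates q and is
  conservative for the P-value.
* Trigger search is restricted to loci called by the detector; a trigger
  of an undetected locus is invisible by construction.
* Differential expression with n = 3 has limited power and the raw-P
  screening criterion does not control FDR across features.
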