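# Methods

## The problem

Plant plastid transcripts are post-transcriptionally edited: specific
cytidines in coding sequences are deaminated to uridine (C-to-U), usually
restoring an evolutionarily conserved amino acid, and the wobble adenosine
of tRNA-Arg(ACG) is deaminated to inosine (A-to-I), which sequencers and
the translation machinery read as G. Public small-RNA libraries — sequenced
for nuclear miRNA work, with no plastid enrichment — contain large numbers
of plastid transcript fragments, and those fragments carry the editing
signal: an edited read differs from the chloroplast genome by a C→T (or
A→G) substitution. `cpedit` turns that observation into a detection and
quantification pipeline, testable end to end on synthetic data.

## Read triage (the hierarchical partition)

Reads of 18–24 nt (the small-RNA window; an mRNA mode disables the filter)
are mapped strand-specifically — forward strand only, no reverse
complement — and without gaps, in four stages:

1. exact match (0 mismatches) against the chloroplast targets — genome,
   extracted CDS and tRNA sense sequences → class `cp_m0` (unedited
   plastid evidence);
2. survivors, exact match against the nuclear genome, then the
   mitochondrial genome → discarded;
3. survivors, ≤2 mismatches against the chloroplast targets → class
   `cp_m2` (the editing-informative reads);
4. the rest are unaligned.

The order matters. Plastid DNA insertions in nuclear genomes (NUPTs) are
exact copies of chloroplast sequence; filtering against the nuclear genome
*first* would absorb unedited plastid reads into the nuclear bin and bias
every editing percentage upward. Stage 1 therefore precedes the
subtraction. Within stage 2, nuclear precedes mitochondrial so that a read
matching both is deterministically counted as nuclear. Mapping against the
extracted sense CDS/tRNA sequences in addition to the genome serves two
purposes: reads from minus-strand genes are sense-strand transcript
fragments and only match the extracted copy (forward-strand genome mapping
cannot see them), and splice-junction-spanning reads only match the spliced
copy. tRNAs are included among the stage-3 targets as well, since the A→G
tRNA evidence lives in mismatched reads.

The aligner reports **all** equal-best placements (the minimal-mismatch
stratum), never sampling ties: genes duplicated in the plastid inverted
repeat legitimately multi-map, and dropping or sampling multireads would
zero or randomize their coverage. Each alignment carries `n_best_loci`;
pileup construction counts each placement once by default, with a
`fractional` policy (weight 1/n_best_loci) available. The search uses
pigeonhole seeding — a read split into `max_mm + 1` near-equal segments
must contain one exact-matching segment in any alignment with ≤ `max_mm`
substitutions — with full Hamming verification of candidate loci, so it is
exactly equivalent to a brute-force scan of every window (property-tested
against one). Substitution-only alignment is deliberate: the editing model
is a substitution model, and gaps would blur it.

## Pileup and calling

Retained alignments are tallied into per-feature columns in spliced
transcript coordinates (1-based, sense strand). Genome placements are
projected into overlapping features strand-awarely (observed bases are
complemented for minus-strand features); when a read has both a direct
feature placement and the co-located genome placement, it contributes
once.

**Terminal-edit filter.** Mismatch observations within `terminal_window`
(default 1) bases of either read end are alignment-artifact-prone and are
removed from the column entirely (tallied per column in
`terminal_excluded`); matching bases at terminal read positions still
count toward depth. Two consequences are documented rather than hidden:
(a) the reported percent is computed *after* filtering; (b) because edited
observations at read ends are removed while unedited terminal observations
remain, the estimator has a small downward bias of order
`rate·(1−t)/(1−rate·t)` where `t ≈ 2/length` is the terminal fraction —
about 5% relative at 18–24 nt reads with w=1. This stays comfortably
inside the exact binomial 99% interval at the coverages the recovery tests
use. The window width is exposed as a flag since no canonical value
exists.

**Variant test.** A column with reference base C on a CDS (A on a tRNA)
and `edited` T (G) observations out of `total` is scored with the
one-sided binomial tail

    p = P[X ≥ edited],  X ~ Binomial(total, err_rate)

against a flat per-base error rate (default 1e-3, ≈ Q30). The tail is
evaluated entirely in log10 domain via `gammaln` + `logsumexp`: deep,
fully edited columns produce tails far below the double-precision
underflow limit (log10 p < −300) and must stay finite. The unit tests
check the implementation against an exact rational summation
(`fractions.Fraction` with big-integer logarithms) to ≤1e-6 relative log
error up to n = 1000. Proprietary "approximate" SNP p-values from GUI
tools are not reproducible and are not a target; the thresholds that
matter are the standard discovery threshold p ≤ 1e-2 and the stringent
threshold p ≤ 1e-10 for novel-site discovery.

**Call requirements** (standard mode): matching reference base, total
coverage ≥ 5, at least one edited observation surviving the terminal
filter, p ≤ max_p. Percent editing is 100·edited/total, reported rounded
half-up to one decimal (5/12 → 41.7) with full precision kept internally.
Calling is monotone: adding an edited observation never removes a call;
raising `min_coverage` or lowering `max_p` never adds one.

## Confirmation of predicted sites

Externally predicted C-to-U sites (a PREP-style table: gene, CDS position,
codon change, score in [0,1]) are filtered by a score cutoff (0.5 lenient
/ 0.8 stringent), deduplicated by (gene, cds_pos) — inverted-repeat gene
copies collapse to one record — and classified into four mutually
exclusive statuses: `confirmed` (*), `covered_not_edited` (−),
`no_coverage` (0), `genomic_T` (T). `genomic_T` — the species already
encodes T at the predicted position, so no editing is possible — depends
only on the reference sequence, never on reads. Confirmation is two-track:
`lenient` mode confirms on ≥1 edited read surviving the terminal filter
(manual-inspection style; real per-site tables include confirmed rows with
1–2 edited reads, which no p-threshold would pass), while `strict` mode
requires a passing call from the caller. Default is lenient for
confirmation and strict (stringent p) for novel-site discovery.
Predictions naming genes absent from the annotation are reported
separately and excluded from denominators, never silently dropped.

tRNA scanning reports A→G calls with 1-based positions from the annotated
tRNA 5′ end (not Sprinzl numbering); calls at position 34 or 35 are
flagged as potential anticodon-wobble sites without asserting which
convention applies.

## qPCR quantification

Allele-specific primer pairs give Ct values for the edited (T) and
unedited (C) template variants; with d = meanCt(T) − meanCt(C) the editing
percentage is 100·2^d/(2^d+1), amplification efficiency fixed at 2. The
formula is implemented verbatim in this orientation. Note the tension
with standard qPCR logic — lower Ct means more template, so one might
expect −d in the exponent — but the source equation cannot be re-derived
from published Ct values; a `flip_sign` option serves users who want the
other orientation. The output is strictly increasing in d, satisfies
rate(d)+rate(−d)=100, and stays in (0,100) for finite d. Tissue summaries
report median/min/max over biological replicates (boxplot-whisker
semantics).

## The synthetic-data generator

`simdata` emulates the statistical structure the pipeline is built for,
not any particular genome:

* a chloroplast genome (default 20 kb — scaled from the 120–160 kb of real
  plastomes to desk scale) carrying CDS (default 8 × 450 nt, start/stop
  codons, no internal stops) and tRNAs (3 × 74 nt with A at positions
  34–35) on alternating strands, separated by random intergenic spacers;
* a nuclear genome (50 kb) with exact plastid insertions (default 2 × 120
  bp ≥ the 50 bp NUPT floor) — the decoys that make the stage order
  testable;
* a mitochondrial genome (10 kb) scrubbed of chloroplast 18-mers by
  brute-force k-mer scan;
* reads drawn per class — defaults 45% nuclear / 0.1% mitochondrial / 23%
  chloroplast (80% of those from feature transcripts) / rest unmappable,
  after the distribution of a whole-plant Arabidopsis library; the
  per-genome proportions are a convenience default, not a biological
  claim;
* per-read Bernoulli editing at planted sites (no haplotype structure —
  matching the caller's binomial model), i.i.d. substitution errors at
  `error_rate`, uniform read start within the feature, lengths uniform on
  18–24 nt (50–150 in mRNA mode).

The truth table records, per site, overlapping and edited read counts
(the Bernoulli outcomes, recorded before sequencing errors), and per
read, origin, coordinates, edited positions and error count. When
`error_rate == 0` it also records the partition class the hierarchy must
assign: the generator verifies each read with its own independent
seed-and-verify scan (a separate implementation from the mapper module)
and resamples background reads that collide with a reference by chance —
a random 18-mer lands within 2 mismatches of a 20 kb genome about 4 times
in 10⁴ draws, enough to break exact count equality at library scale if
ignored. The mapper's correctness oracle in the test suite is a third,
fully brute-force all-windows scan, so the generator's verifier never
vouches for the mapper.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: position-dependent error profiles and
quality-score structure (errors are flat), RNA degradation biases and the
real, highly non-uniform sRNA coverage landscape, antisense plastid reads
(available as a knob, default 0), indels, inverted-repeat duplication
(multiread handling is exercised by unit tests instead), and genome-origin
reads crossing feature boundaries (intergenic reads are drawn strictly
between features so that per-site truth counts match feature pileup depth
exactly).

## Numerical and design choices

* Coordinates: 1-based inclusive at every external interface, 0-based
  half-open internally. Minus-strand feature segments are stored in
  transcript (5′→3′) order.
* U→T normalization on FASTA input; N allowed in references, reads with N
  are dropped before mapping and tallied.
* Percent rounding: decimal half-up (not banker's), one decimal.
* Binomial tail: `gammaln`-based log-space summation over the integer
  support; fractional multiread weights are rounded down to the nearest
  achievable count before the tail is taken (conservative).
* Determinism everywhere: all simulation randomness flows from
  `SimConfig.seed` through named `numpy` generator streams; the mapper
  reports full tie strata instead of sampling; pipeline reruns are
  byte-identical (the run log records parameters, versions and input
  checksums, no timestamps).
* Problem sizes in the test suite and the acceptance script (20 kb
  plastome, 80k–100k reads, ≥50× coverage at planted sites) are the
  package's desk-scale defaults: large enough that binomial intervals are
  meaningful, small enough to iterate on quickly.

## Known limitations

* The pure-Python aligner is built for desk-scale references (tens of kb);
  real 150 kb plastomes with tens of millions of reads would want an
  indexed aligner front-end emitting the same alignment records.
* Only C→T (CDS) and A→G (tRNA) change types are modelled; U-to-C and
  other rarer editing types are out of scope.
* The editing-percent estimator is mildly biased downward by the terminal
  filter (quantified above); an unbiased variant would exclude terminal
  read positions from depth as well, at the cost of diverging from the
  documented depth semantics.
* Sense strand is taken from the annotation; no strand-flip inference.
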