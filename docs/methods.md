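# Methods

## The measurement model

TAPS chemistry converts a modified cytosine (5mC or 5hmC; TAPS reports their
sum) into a base sequenced as T and leaves unmodified cytosines intact. For
a reference cytosine the data are therefore counts of converted (T) and
unconverted (C) read bases, and the modification level is

    level = n_converted / (n_converted + n_unconverted).

This inversion of the bisulfite convention is applied exactly once, in
`methcall.modification_level`; every column name in the package says
converted/unconverted rather than methylated/unmethylated, so no other code
path ever needs to know which chemistry it is serving. Bases that are
neither C nor T over the site (sequencing errors, deletions, low-quality
bases) are tallied as `n_other` and never enter the denominator.

Strand discipline follows from the library design. The Y-shaped adapter has
two distinguishable arms, so after amplification every sequenced molecule
begins with one of two 5' adapters. Classification by that adapter (the
"forward"/"reverse" groups) together with the alignment orientation
identifies the biological strand of origin:

    forward group, reverse-mapped  -> OT     reverse group, forward-mapped -> OT
    forward group, forward-mapped  -> OB     reverse group, reverse-mapped -> OB

After normalization the SAM reverse bit encodes OT (0) / OB (16) directly.
Plus-strand cytosines are then counted only from OT reads and minus-strand
cytosines (G in the plus reference) only from OB reads, read off the
complementary base (A = converted, G = unconverted). This is what makes the
calls strand-specific; the package's tests verify that permuting OB reads
never changes a plus-strand call.

## Simulator

The simulator exists so that every stage is testable against complete
ground truth. One master seed drives a single `numpy` generator; identical
seeds give byte-identical outputs, and each output file header records the
seed.

**Genome.** I.i.d. bases at a configurable GC fraction (default 0.42,
mammalian-like), with extra CpG dinucleotides planted at a configurable
per-bp rate (default 0.01) on top of the background — at rate 0 the CpG
frequency is exactly the i.i.d. expectation, which the tests check against
a binomial oracle. Diploid mode plants phased heterozygous SNVs at a given
density (default in tests 1–2 per kb, typical of crosses between divergent
strains), avoiding the C/G of CpG dyads so truth CpGs survive on both
haplotypes; each haplotype is the reference plus its own alt alleles.

**Methylome.** Each CpG dyad draws a modification probability from a
two-component Beta mixture — Beta(8,2) "high" bulk and Beta(1,20) "low"
island-like component, weights 0.8/0.2 — with the component drawn once per
2-kb block rather than per CpG. The block structure gives the methylome
regional (CpG-island-like) variation; without it, binned levels are nearly
constant across the genome and replicate-correlation measurements are
meaningless. Both strands of a dyad share one probability (symmetric CpG
methylation); non-CpG cytosines are unmethylated. Per molecule, each
cytosine's modification state is realized by an independent Bernoulli draw
from its probability, and that realized state is recorded in the truth
table.

**Spike-in.** A separate 4-kb random contig emulating an HpaII-
methyltransferase-treated control: probability exactly 1.0 at the internal
C of every CCGG on both strands (CCGG is its own reverse complement), 0.0
elsewhere. Completeness of the enzymatic methylation is not known for the
real control; 1.0 is assumed and exposed as the methylome itself, so a
partially methylated control is one `set_cpg_levels` call away. An
in-silico HpaII digest helper confirms the methylated control is uncut.

**Reads.** Fragment lengths are lognormal with median 5,000 bp (sigma 0.35)
truncated below 3,000 bp, emulating 5-kb shearing followed by >3-kb size
selection; the spike-in is drawn with molar fraction 0.005 by default. Each
molecule picks a haplotype and a biological strand fairly, realizes its
methylation, converts (modified C→T with probability `conversion_rate`,
default 0.9623; unmodified C→T with `false_conversion_cpg` 0.0036 or
`false_conversion_cph` 0.0012 — the control-measured operating point of the
chemistry), and receives adapter arms. The forward-group construct carries
the reverse complement of the converted strand between the forward 5'/3'
adapters; the reverse-group construct is its reverse complement. This is
the unique arrangement consistent with the flag-normalization table above
given that SAM stores sequences in reference orientation. Sequencing noise
is substitution-only at 0.1% (HiFi-like); indels are not modeled — a known
limitation, so CIGAR-indel handling in the caller is exercised by dedicated
randomized tests rather than by the simulator. Optional PCR duplicates are
extra copies of a molecule with independent sequencing errors.

What the simulator does **not** emulate: alignment error and soft-clipping
(the truth SAM has exact coordinates and pure-match CIGARs), PCR
amplification bias, polymerase kinetics, CCS pass structure, real genome
repeat content, and non-CpG methylation. Passing tests therefore
demonstrate correctness of the counting, strand, phasing and QC logic under
known chemistry — not robustness to alignment artifacts.

## Numerical and procedural choices

* **Adapter matching** — semi-global (infix) edit-distance alignment via
  edlib within a 5'/3' window, error budget 10% of adapter length. If both
  5' adapters match, the smaller distance wins and an exact tie is left
  unclassified; this symmetric rule replaces the order-dependent behavior
  of sequential trimming passes and is deliberate. A read whose 3' adapter
  is absent is still classified by its 5' arm.
* **Normalization idempotency** — a read whose biological strand is already
  set passes through unchanged, so pipelines can re-run the stage safely;
  the original flag is preserved in the `XF` tag and the strand in `XB`.
* **Duplicate marking** — reads sharing contig and biological strand whose
  5' and 3' coordinates both fall within `pos_tolerance` (default 20 bp) of
  a group's first member are one group; the highest-MAPQ (then longest,
  then lexicographically first) member is kept. The spike-in contig is a
  special case: the control is a single PCR product, so distinct control
  molecules share exact coordinates, and the spike-in QC stage therefore
  ignores duplicate flags on that contig.
* **Base quality** — bases below Q13 are excluded from counts (configurable;
  the threshold is a conventional low-quality floor, not a measured value).
* **Coordinates** — 0-based half-open everywhere internally and in
  bedGraph/BED; 1-based only at VCF boundaries.
* **CpG merging** — the minus-strand member of a dyad (position p+1) is
  summed into the plus-strand C at p, and the level recomputed from summed
  counts. Dataset comparisons default to merged dyads, with per-strand
  output available, since per-dyad units are the natural comparison grain.
* **Spike-in QC** — rates are pooled over read bases (total converted /
  total observed), not averaged per site, matching the per-base ratio
  definition of the level; a category with zero coverage reports a missing
  rate rather than 0. Off-target exclusion matches the CpG's 4-mer with the
  C at the position homologous to the internal C of CCGG, using the
  reverse-complement context for minus-strand sites; edge cytosines whose
  4-mer is truncated cannot match a motif and stay in the unmodified set.
* **Haplotagging** — majority vote over phased variants with margin ≥ 1 and
  conflict fraction ≤ 0.2; ties are never assigned, which keeps label-swap
  symmetry exact. Variants whose alleles are C/T are skipped on OT reads
  and G/A on OB reads because TAPS conversion is indistinguishable from
  those substitutions on the informative strand. Simple deletions vote via
  the read's deletion track; other indels are out of scope.
* **ASM statistic** — two-sided Fisher exact test on the per-allele 2×2
  converted/unconverted table at CpGs with ≥ 5 (configurable) bases per
  allele, Benjamini–Hochberg across tested CpGs. The exact test is
  conservative at finite depth: on simulated null loci (equal allele
  methylation, ~30–40× per allele) the pooled p<0.05 rate is ≈ 0.04, below
  the nominal 0.05. The acceptance test asserts type-I control (rate not
  exceeding 0.05 by more than 3 binomial SDs) rather than two-sided
  agreement with 0.05, which a discrete exact test cannot promise.
* **SV overlap** — intervals are extended by a 5-bp flank (configurable) on
  both sides, clipped at zero; two SVs match when extended intervals
  intersect and types agree. A zero-length insertion is treated as a 1-bp
  breakpoint interval so half-open intersection is well defined. Matched
  counts are reported per set since the mapping need not be one-to-one.

## Problem sizes

The test suite and the acceptance script run on desk-scale instances chosen
to make each property measurable with comfortable statistical margins:
200-kb genomes with 2,000 reads (~50× coverage) for round-trip and strand
checks, a 4-kb control with ~600 full-length reads (~10⁵–10⁶ cytosine
observations) for rate recovery within 3 binomial SEs, 30-kb diploid loci
with ~500 reads for phasing, and 20 replicate simulations for the null ASM
rate. Everything runs in a few minutes on one CPU.

## Known limitations

Substitution-only error model; no alignment simulation (consume a real
aligner's BAM for real data); unphased VCFs are rejected rather than
phased; insertion alleles do not participate in haplotagging; conversion
cannot distinguish 5mC from 5hmC (inherent to the chemistry).
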