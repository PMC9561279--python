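# lrtaps

Strand-aware, base-resolution DNA methylation calling for **TAPS-converted
long reads**, plus a chemistry simulator with complete ground truth.

TAPS (TET-assisted pyridine borane sequencing) oxidizes 5mC/5hmC to 5caC and
reduces it to dihydrouracil, which amplifies and sequences as **T** — so a
modified cytosine reads as T while unmodified cytosines stay C, the inverse
of bisulfite. Combined with multi-kilobase HiFi-style reads, this gives
direct methylomes over repetitive regions, structural variants and whole
haplotypes that short reads cannot resolve. The catch is bookkeeping:
Y-shaped adapters encode which biological strand (original top, OT, or
original bottom, OB) each read came from, and every downstream count must
respect that strand.

`lrtaps` implements the full analysis:

* **taps_sim** (`lrtaps.simulate`) — random (optionally diploid) genomes with
  a bimodal, domain-structured CpG methylome; a fully C^mCGG-methylated 4-kb
  spike-in control; lognormal fragments, Y-adapter ligation, TAPS conversion
  with configurable true/false conversion rates, substitution noise; outputs
  FASTQ, truth SAM, truth tables.
* **strand_io** (`lrtaps.strand`) — adapter-based read classification
  (semi-global edit-distance matching), flag normalization so the SAM
  reverse bit encodes OT/OB, coordinate-tolerant duplicate marking, MAPQ
  filtering.
* **methcall** (`lrtaps.methcall`) — CIGAR-aware per-cytosine pileup with the
  TAPS-inverted counting rule

      level = n_converted / (n_converted + n_unconverted)

  where OT reads cover plus-strand cytosines (T = converted) and OB reads
  cover minus-strand cytosines (A over the reference G = converted); CpG
  strand merging; bedGraph/bedMethyl output.
* **spikein_qc** (`lrtaps.spikein`) — conversion rate at HpaII-methylated
  CCGG sites and false-positive rates at unmodified CpG/CpH, excluding
  TCGG/CCGT/ACGG contexts as likely methyltransferase off-targets.
* **asm_phasing** (`lrtaps.phasing`) — haplotagging at phased heterozygous
  variants (C/T variants are skipped on OT reads and G/A on OB reads, since
  conversion mimics them), per-allele methylomes, and a Fisher-exact +
  Benjamini–Hochberg test for allele-specific methylation.
* **summarize** (`lrtaps.summarize`) — read N50, CpG coverage overlap between
  call sets, binned Pearson correlation, and SV call-set overlap after 5-bp
  flank extension.

Alignment itself is delegated to any long-read aligner (e.g. minimap2) — or
skipped entirely by using the simulator's truth SAM.

## Worked example

Simulate a 200-kb library (2,000 reads, 2% spike-in molar fraction) and run
the whole pipeline on the truth alignments:

```sh
lrtaps simulate --out-dir sim --genome-size 200000 --n-reads 2000 \
    --spikein-fraction 0.02 --seed 7
lrtaps run --reference sim/reference.fasta --reads sim/reads.fastq \
    --alignments sim/truth.sam --spikein-name spikein --out-dir out --seed 7
```

The spike-in QC report (`out/spikein_qc.tsv`):

```
category        n_converted  n_total  rate
methylated_cpg  620          642      0.965732
unmodified_cpg  32           8079     0.003961
cph             51           32274    0.001580
excluded        3            1958     0.001532
```

Reading: 96.6% of read bases over the control's HpaII-methylated CCGG
cytosines were converted to T (the simulator's true conversion rate is
96.23%), while only 0.40% of bases over unmodified CpGs and 0.16% over CpHs
converted falsely (simulated at 0.36% and 0.12%, plus ~0.03% from the 0.1%
substitution error model). The 1,958 bases at TCGG/CCGT/ACGG CpGs were
excluded from the false-positive rate.

The called methylome (`out/methylome_cpg.bedGraph`, one CpG dyad per row;
level in percent, then converted and unconverted counts):

```
track type="bedGraph" description="lrtaps 0.1.0 converted/(converted+unconverted) version=0.1.0 seed=7"
contig1	92	93	100	4	0
contig1	100	101	100	4	0
contig1	102	103	100	4	0
```

With `--vcf` pointing at phased heterozygous variants, the pipeline also
writes per-haplotype methylomes and an allele-specific-methylation table
(`asm.tsv` with level differences, p- and q-values).

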