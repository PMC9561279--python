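"""Ground-truth simulator for TAPS-converted long-read libraries.

The simulator produces everything the downstream pipeline consumes —
reference FASTA, adapter-carrying FASTQ, a truth SAM with correct
coordinates, and a per-molecule truth table — from a single seeded RNG, so
that every stage (strand classification, flag normalization, duplicate
marking, pileup, spike-in QC, phasing) can be verified against known truth.

Chemistry model: TAPS converts modified cytosines (5mC/5hmC) to a base read
as T, the inverse of bisulfite. Each molecule is a genomic fragment; its
biological strand of origin (OT = original top = plus, OB = original bottom
= minus) is drawn fairly; per-cytosine modification is realized by a
Bernoulli draw from the methylome; conversion then turns each modified C
into T with probability ``conversion_rate`` and each unmodified C into T
with a small context-dependent false-conversion probability. Y-adapter
arms are attached so that adapter identity plus alignment orientation
recovers the strand of origin, and the molecule is emitted in a uniformly
chosen sequencing orientation. Sequencing noise is substitution-only.

A fully CCGG-methylated spike-in contig (emulating an HpaII-
methyltransferase-treated control) is included at a configurable molar
fraction for conversion-rate QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import __version__
from .adapters import DEFAULT_ADAPTERS, AdapterConfig
from .dna import (
    CTX_CPG,
    CTX_NONE,
    CONTEXT_NAMES,
    array_to_seq,
    cytosine_context_arrays,
    revcomp,
    revcomp_array,
    seq_to_array,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C = ord("C")
_G = ord("G")
_T = ord("T")
_A = ord("A")


class HetVariant(NamedTuple):
    """A phased heterozygous variant; ``hap`` is the haplotype carrying alt."""

    contig: str
    pos: int
    ref: str
    alt: str
    hap: int


@dataclass
class SimGenome:
    """A simulated (optionally diploid) genome.

    contigs map contig name to an uppercase A/C/G/T string carrying the ref
    allele of every variant. het_variants are phased SNVs/indels; the alt
    allele lives on haplotype ``hap``, so each haplotype's sequence is the
    reference with its own alt alleles applied. ``spikein_name`` names the
    control contig, if present.
    """

    contigs: dict[str, str]
    ploidy: int = 1
    het_variants: list[HetVariant] = field(default_factory=list)
    spikein_name: str | None = None

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")
        for v in self.het_variants:
            seq = self.contigs[v.contig]
            if not 0 <= v.pos < len(seq):
                raise ValueError(f"variant position {v.pos} outside {v.contig}")
            if seq[v.pos : v.pos + len(v.ref)] != v.ref:
                raise ValueError(f"variant ref mismatch at {v.contig}:{v.pos}")
        if self.spikein_name is not None:
            if "CCGG" not in self.contigs[self.spikein_name]:
                raise ValueError("spike-in contig contains no CCGG site")

    def main_contigs(self) -> list[str]:
        return [c for c in self.contigs if c != self.spikein_name]

    def haplotype_sequence(self, contig: str, hap: int) -> str:
        """Contig sequence of one haplotype (SNVs only; indels unsupported here)."""
        seq = self.contigs[contig]
        if hap == 0 or self.ploidy == 1:
            return seq
        arr = bytearray(seq, "ascii")
        for v in self.het_variants:
            if v.contig == contig and v.hap == hap and len(v.ref) == 1 == len(v.alt):
                arr[v.pos] = ord(v.alt)
        return arr.decode("ascii")

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_vcf(self, path: str) -> None:
        """Write het variants as a minimal phased VCF (GT 0|1 or 1|0)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=lrtaps {__version__}\n")
            for name, seq in self.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
            for v in sorted(self.het_variants, key=lambda v: (v.contig, v.pos)):
                gt = "0|1" if v.hap == 2 else "1|0"
                fh.write(
                    f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n"
                )


class Methylome:
    """Per-cytosine modification probabilities on both strands.

    Stored as per-contig float arrays (NaN where the strand base is not C)
    plus int8 context-code arrays. Plus-strand CpG cytosines at position p
    pair with minus-strand cytosines at p+1; the generator assigns the same
    probability to both members of a pair (symmetric CpG methylation).
    """

    def __init__(self) -> None:
        self.prob: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.ctx: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def add_contig(self, name: str, seq: str) -> None:
        plus_ctx, minus_ctx = cytosine_context_arrays(seq)
        n = len(seq)
        plus = np.full(n, np.nan)
        minus = np.full(n, np.nan)
        plus[plus_ctx != CTX_NONE] = 0.0
        minus[minus_ctx != CTX_NONE] = 0.0
        self.prob[name] = (plus, minus)
        self.ctx[name] = (plus_ctx, minus_ctx)

    def probability(self, contig: str, pos: int, strand: str) -> float:
        arr = self.prob[contig][0 if strand == "+" else 1]
        return float(arr[pos])

    def context(self, contig: str, pos: int, strand: str) -> str | None:
        code = self.ctx[contig][0 if strand == "+" else 1][pos]
        return None if code == CTX_NONE else CONTEXT_NAMES[int(code)]

    def contigs(self) -> list[str]:
        return list(self.prob)

    def to_bed(self, path: str, header: str | None = None) -> None:
        """Write the truth methylome as BED: contig, start, end, level, strand, context."""
        with open(path, "w") as fh:
            if header:
                fh.write(f"#{header}\n")
            for name in self.prob:
                for si, strand in ((0, "+"), (1, "-")):
                    probs = self.prob[name][si]
                    ctxs = self.ctx[name][si]
                    for p in np.flatnonzero(~np.isnan(probs)):
                        fh.write(
                            f"{name}\t{p}\t{p + 1}\t{probs[p]:.4f}\t{strand}\t"
                            f"{CONTEXT_NAMES[int(ctxs[p])]}\n"
                        )


@dataclass
class SimParams:
    """Library and chemistry parameters for read simulation.

    Defaults are the study conditions of the protocol being emulated:
    5-kb lognormal fragments size-selected above 3 kb, a 0.5% molar
    spike-in, conversion/false-conversion rates matching the published
    spike-in calibration (96.23% at modified CpG, 0.36%/0.12% false at
    unmodified CpG/CpH), and a HiFi-like 0.1% substitution error rate.
    """

    n_reads: int = 2000
    fragment_median: float = 5000.0
    fragment_sigma: float = 0.35
    fragment_min: int = 3000
    conversion_rate: float = 0.9623
    false_conversion_cpg: float = 0.0036
    false_conversion_cph: float = 0.0012
    error_rate: float = 0.001
    spikein_fraction: float = 0.005
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "conversion_rate",
            "false_conversion_cpg",
            "false_conversion_cph",
            "error_rate",
            "spikein_fraction",
            "duplicate_rate",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


class ConversionResult(NamedTuple):
    sequence: str
    n_modified: int
    n_modified_converted: int
    n_unmodified: int
    n_unmodified_converted: int


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def make_spikein(
    length: int = 4000,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    name: str = "spikein",
    min_ccgg: int = 5,
    max_retries: int = 50,
) -> tuple[str, Methylome]:
    """Random control sequence fully methylated at the internal C of CCGG.

    Emulates an HpaII-methyltransferase-treated control: probability 1.0 at
    the inner cytosine of every CCGG on both strands (CCGG is palindromic),
    0.0 at every other cytosine. Resamples until at least ``min_ccgg``
    CCGG sites are present; after ``max_retries`` the remaining sites are
    planted at random positions.
    """
    if length < 100:
        raise ValueError("spike-in length must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = ""
    for _ in range(max_retries):
        arr = _random_sequence(rng, length, 0.5)
        seq = array_to_seq(arr)
        if seq.count("CCGG") >= min_ccgg:
            break
    else:
        arr = seq_to_array(seq)
        while array_to_seq(arr).count("CCGG") < min_ccgg:
            pos = int(rng.integers(0, length - 4))
            arr[pos : pos + 4] = seq_to_array("CCGG")
        seq = array_to_seq(arr)

    meth = Methylome()
    meth.add_contig(name, seq)
    plus, minus = meth.prob[name]
    start = 0
    while True:
        i = seq.find("CCGG", start)
        if i < 0:
            break
        plus[i + 1] = 1.0  # internal C, plus strand
        minus[i + 2] = 1.0  # internal C of the palindromic minus-strand CCGG
        start = i + 1
    return seq, meth


def hpaii_cut_sites(seq: str, methylome: Methylome, contig: str) -> list[int]:
    """In-silico HpaII digest: cut positions at CCGG whose internal C is unmodified.

    HpaII is blocked by methylation of the internal cytosine; a fully
    C^mCGG-methylated control therefore yields no cuts.
    """
    plus, _ = methylome.prob[contig]
    cuts = []
    start = 0
    while True:
        i = seq.find("CCGG", start)
        if i < 0:
            break
        if plus[i + 1] < 1.0:
            cuts.append(i + 1)
        start = i + 1
    return cuts


def simulate_genome(
    genome_size: int = 200_000,
    n_contigs: int = 1,
    gc: float = 0.42,
    cpg_enrichment: float = 0.01,
    mixture_weights: tuple[float, float] = (0.8, 0.2),
    high_beta: tuple[float, float] = (8.0, 2.0),
    low_beta: tuple[float, float] = (1.0, 20.0),
    domain_size: int = 2000,
    het_snp_density: float = 0.0,
    ploidy: int = 1,
    avoid_cpg_snps: bool = True,
    include_spikein: bool = True,
    spikein_length: int = 4000,
    spikein_name: str = "spikein",
    seed: int = 0,
) -> tuple[SimGenome, Methylome]:
    """Generate a random genome and a bimodal CpG methylome with full truth.

    The methylome draws each CpG unit's modification probability from a
    two-component Beta mixture (a high-methylation bulk component and a
    low-methylation island-like component) and assigns it symmetrically to
    both strands of the pair; non-CpG cytosines are unmethylated. The
    mixture component is drawn once per ``domain_size`` block, not per CpG,
    so low-methylation stretches form contiguous island-like domains and
    the methylome has regional structure as mammalian methylomes do.
    ``cpg_enrichment`` plants extra CpG dinucleotides at that per-bp rate on
    top of the i.i.d. base background (0 leaves the background untouched).
    In diploid mode, het SNPs are planted at ``het_snp_density`` per bp,
    by default avoiding the C/G of CpG pairs so truth CpGs survive on both
    haplotypes.
    """
    if abs(sum(mixture_weights) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if genome_size // n_contigs < 1000:
        raise ValueError("contigs must be at least 1 kb")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    rng = np.random.default_rng(seed)

    contigs: dict[str, str] = {}
    per = genome_size // n_contigs
    for ci in range(n_contigs):
        arr = _random_sequence(rng, per, gc)
        if cpg_enrichment > 0:
            n_extra = rng.poisson(cpg_enrichment * per)
            pos = rng.integers(0, per - 1, size=n_extra)
            arr[pos] = _C
            arr[pos + 1] = _G
        contigs[f"contig{ci + 1}"] = array_to_seq(arr)

    spikein = None
    if include_spikein:
        spikein_seq, spike_meth = make_spikein(
            spikein_length, rng=rng, name=spikein_name
        )
        contigs[spikein_name] = spikein_seq
        spikein = spikein_name

    meth = Methylome()
    for name, seq in contigs.items():
        if name == spikein:
            continue
        meth.add_contig(name, seq)
        plus, minus = meth.prob[name]
        plus_ctx, _ = meth.ctx[name]
        cpg_pos = np.flatnonzero(plus_ctx == CTX_CPG)
        # drop a CpG whose G is the last base only if position+1 leaves the contig
        cpg_pos = cpg_pos[cpg_pos + 1 < len(seq)]
        n_blocks = len(seq) // domain_size + 1
        block_high = rng.random(n_blocks) < mixture_weights[0]
        comp = block_high[cpg_pos // domain_size]
        levels = np.where(
            comp,
            rng.beta(*high_beta, size=cpg_pos.size),
            rng.beta(*low_beta, size=cpg_pos.size),
        )
        plus[cpg_pos] = levels
        minus[cpg_pos + 1] = levels
    if include_spikein:
        meth.prob[spikein_name] = spike_meth.prob[spikein_name]
        meth.ctx[spikein_name] = spike_meth.ctx[spikein_name]

    variants: list[HetVariant] = []
    if ploidy == 2 and het_snp_density > 0:
        for name, seq in contigs.items():
            if name == spikein:
                continue
            arr = seq_to_array(seq)
            mask = rng.random(arr.size) < het_snp_density
            if avoid_cpg_snps:
                plus_ctx, minus_ctx = meth.ctx[name]
                mask &= ~((plus_ctx == CTX_CPG) | (minus_ctx == CTX_CPG))
            for p in np.flatnonzero(mask):
                ref = chr(arr[p])
                alt = chr(rng.choice([b for b in _BASES if b != arr[p]]))
                variants.append(HetVariant(name, int(p), ref, alt, int(rng.integers(1, 3))))

    genome = SimGenome(
        contigs=contigs, ploidy=ploidy, het_variants=variants, spikein_name=spikein
    )
    return genome, meth


def set_cpg_levels(
    methylome: Methylome, contig: str, start: int, end: int, level: float
) -> int:
    """Set every CpG modification probability in [start, end) to ``level``
    on both strands; returns the number of CpG units changed.

    Useful for planting imprinted or differentially methylated loci, e.g.
    on one haplotype's methylome only.
    """
    plus, minus = methylome.prob[contig]
    plus_ctx, minus_ctx = methylome.ctx[contig]
    sel_plus = np.flatnonzero(plus_ctx[start:end] == CTX_CPG) + start
    sel_minus = np.flatnonzero(minus_ctx[start:end] == CTX_CPG) + start
    plus[sel_plus] = level
    minus[sel_minus] = level
    return int(sel_plus.size)


def copy_methylome(methylome: Methylome) -> Methylome:
    out = Methylome()
    for name in methylome.prob:
        out.prob[name] = tuple(a.copy() for a in methylome.prob[name])
        out.ctx[name] = tuple(a.copy() for a in methylome.ctx[name])
    return out


def taps_convert(
    strand_sequence: str,
    realized_states: dict[int, bool],
    contexts: dict[int, str],
    params: SimParams,
    rng: np.random.Generator,
) -> ConversionResult:
    """Apply TAPS chemistry to one strand: modified C reads as T.

    Each position in ``realized_states`` must be a C of ``strand_sequence``
    (coordinates local to the strand, 5'->3'). Modified cytosines convert
    to T with probability ``conversion_rate``; unmodified cytosines convert
    with ``false_conversion_cpg`` or ``false_conversion_cph`` according to
    their context. Non-C bases are never touched.
    """
    arr = seq_to_array(strand_sequence)
    pos = np.fromiter(realized_states.keys(), dtype=np.int64, count=len(realized_states))
    if pos.size and not np.all(arr[pos] == _C):
        bad = pos[arr[pos] != _C][0]
        raise ValueError(f"realized state at non-C position {bad}")
    modified = np.fromiter(
        (realized_states[int(p)] for p in pos), dtype=bool, count=pos.size
    )
    is_cpg = np.fromiter(
        (contexts.get(int(p), "CHH") == "CpG" for p in pos), dtype=bool, count=pos.size
    )
    return _convert(arr, pos, modified, is_cpg, params, rng)


def _convert(
    arr: np.ndarray,
    pos: np.ndarray,
    modified: np.ndarray,
    is_cpg: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> ConversionResult:
    u = rng.random(pos.size)
    p_convert = np.where(
        modified,
        params.conversion_rate,
        np.where(is_cpg, params.false_conversion_cpg, params.false_conversion_cph),
    )
    convert = u < p_convert
    arr = arr.copy()
    arr[pos[convert]] = _T
    n_mod = int(modified.sum())
    return ConversionResult(
        sequence=array_to_seq(arr),
        n_modified=n_mod,
        n_modified_converted=int((convert & modified).sum()),
        n_unmodified=int(pos.size - n_mod),
        n_unmodified_converted=int((convert & ~modified).sum()),
    )


def _add_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size == 0:
        return arr
    arr = arr.copy()
    # substitute with one of the three other bases, uniformly
    for h in hits:
        choices = _BASES[_BASES != arr[h]]
        arr[h] = choices[rng.integers(0, choices.size)]
    return arr


@dataclass
class SimulatedReads:
    """Simulation output: FASTQ records, truth alignments, truth table."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: pd.DataFrame
    sam_records: list[dict]
    genome: SimGenome
    params: SimParams
    adapters: AdapterConfig

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def write_truth_sam(self, path: str) -> None:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in self.genome.contigs.items()
            ],
            "PG": [
                {
                    "ID": "lrtaps-sim",
                    "PN": "lrtaps",
                    "VN": __version__,
                    "CL": f"seed={self.params.seed}",
                }
            ],
        }
        names = list(self.genome.contigs)
        recs = sorted(
            self.sam_records, key=lambda r: (names.index(r["contig"]), r["start"])
        )
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            for r in recs:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r["read_id"]
                a.flag = r["flag"]
                a.reference_name = r["contig"]
                a.reference_start = r["start"]
                a.mapping_quality = 60
                a.cigarstring = f"{len(r['seq'])}M"
                a.query_sequence = r["seq"]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
                # XG is the adapter group consumed by flag normalization;
                # Y* tags are simulation truth, opaque to the pipeline
                a.set_tag("XG", r["group"])
                a.set_tag("YB", r["strand"])
                a.set_tag("YH", r["haplotype"])
                a.set_tag("YS", int(r["is_spikein"]))
                if r["duplicate_of"]:
                    a.set_tag("YD", r["duplicate_of"])
                out.write(a)

    def write_truth_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#lrtaps {__version__} seed={self.params.seed}\n")
            self.truth.to_csv(fh, sep="\t", index=False)

    def aligned_reads(self) -> list:
        """Truth alignments as AlignedRead records (aligner-style raw flags,
        strand group attached), ready for normalize_strand."""
        from .strand import AlignedRead

        return [
            AlignedRead(
                read_id=r["read_id"],
                contig=r["contig"],
                start=r["start"],
                flag=r["flag"],
                mapq=60,
                cigar=f"{len(r['seq'])}M",
                seq=r["seq"],
                strand_group=r["group"],
            )
            for r in self.sam_records
        ]

    def realized_cpg_fractions(self) -> pd.DataFrame:
        """Aggregate per-read realized CpG states into per-site truth fractions.

        Returns one row per (contig, pos, strand) with the count of modified
        and unmodified read-level states — the exact quantity the caller
        should recover in the noiseless limit. Duplicate reads are excluded
        (they are re-reads of the same molecule).
        """
        rows: dict[tuple[str, int, str], list[int]] = {}
        for _, rec in self.truth.iterrows():
            if rec.duplicate_of:
                continue
            if not rec.cpg_states:
                continue
            strand = "+" if rec.strand == "OT" else "-"
            for item in rec.cpg_states.split(";"):
                p, m = item.split(":")
                key = (rec.contig, int(p), strand)
                cnt = rows.setdefault(key, [0, 0])
                cnt[0 if m == "1" else 1] += 1
        out = pd.DataFrame(
            [
                {"contig": c, "pos": p, "strand": s, "n_mod": v[0], "n_unmod": v[1]}
                for (c, p, s), v in rows.items()
            ]
        )
        if len(out):
            out["truth_level"] = out.n_mod / (out.n_mod + out.n_unmod)
        return out


def simulate_reads(
    genome: SimGenome,
    methylome: Methylome,
    params: SimParams,
    adapters: AdapterConfig = DEFAULT_ADAPTERS,
    seed: int | None = None,
    methylome_hap2: Methylome | None = None,
) -> SimulatedReads:
    """Simulate a TAPS long-read library with complete ground truth.

    Per molecule: a contig is chosen length-weighted (or the spike-in with
    probability ``spikein_fraction``), a lognormal fragment is drawn, a
    haplotype (diploid mode) and a biological strand (OT/OB, p=0.5) are
    drawn, per-cytosine modification is realized from the methylome,
    TAPS conversion is applied to the biological strand, Y-adapter arms are
    attached, and the molecule is emitted in a uniformly chosen sequencing
    orientation with substitution errors. The truth SAM stores each read the
    way an aligner would (SEQ in reference orientation, reverse bit set when
    the trimmed insert maps to the minus strand), MAPQ 60, full-match CIGAR.

    ``methylome_hap2``, when given, replaces the methylome for haplotype-2
    molecules — this is how allele-specific methylation (e.g. an imprinted
    locus) is simulated.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    main = genome.main_contigs()
    lengths = np.array([len(genome.contigs[c]) for c in main], dtype=float)
    weights = lengths / lengths.sum()

    # per (contig, hap): sequence array and per-strand context arrays
    hap_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def hap_arrays(contig: str, hap: int):
        key = (contig, hap)
        if key not in hap_cache:
            seq = genome.haplotype_sequence(contig, hap)
            arr = seq_to_array(seq)
            pc, mc = cytosine_context_arrays(arr)
            hap_cache[key] = (arr, pc, mc)
        return hap_cache[key]

    mu = np.log(params.fragment_median)
    reads: list[tuple[str, str, str]] = []
    sam_records: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(params.n_reads):
        is_spike = bool(
            genome.spikein_name is not None and rng.random() < params.spikein_fraction
        )
        if is_spike:
            contig = genome.spikein_name
        else:
            contig = main[int(rng.choice(len(main), p=weights))]
        clen = len(genome.contigs[contig])
        frag = int(np.exp(rng.normal(mu, params.fragment_sigma)))
        frag = max(frag, params.fragment_min)
        frag = min(frag, clen)
        start = int(rng.integers(0, clen - frag + 1))
        end = start + frag

        hap = int(rng.integers(1, 3)) if genome.ploidy == 2 and not is_spike else 0
        arr, plus_ctx, minus_ctx = hap_arrays(contig, hap)
        meth = methylome_hap2 if (hap == 2 and methylome_hap2 is not None) else methylome
        ref_plus_prob, ref_minus_prob = meth.prob[contig]
        ref_plus_ctx, ref_minus_ctx = meth.ctx[contig]

        strand = "OT" if rng.random() < 0.5 else "OB"
        frag_arr = arr[start:end]

        if strand == "OT":
            c_abs = start + np.flatnonzero(frag_arr == _C)
            prob = ref_plus_prob[c_abs]
            ctx = plus_ctx[c_abs]  # haplotype-local context for chemistry
            truth_ctx = ref_plus_ctx[c_abs]
            local = c_abs - start
            bio = frag_arr.copy()
        else:
            g_abs = start + np.flatnonzero(frag_arr == _G)
            prob = ref_minus_prob[g_abs]
            ctx = minus_ctx[g_abs]
            truth_ctx = ref_minus_ctx[g_abs]
            c_abs = g_abs
            local = (end - 1) - g_abs
            bio = revcomp_array(frag_arr)

        prob = np.where(np.isnan(prob), 0.0, prob)
        modified = rng.random(prob.size) < prob
        conv = _convert(bio, local, modified, ctx == CTX_CPG, params, rng)
        conv_arr = seq_to_array(conv.sequence)

        # truth: realized states at reference-CpG cytosines of this strand
        cpg_mask = truth_ctx == CTX_CPG
        cpg_states = ";".join(
            f"{int(p)}:{1 if m else 0}"
            for p, m in zip(c_abs[cpg_mask], modified[cpg_mask])
        )

        group = "forward" if rng.random() < 0.5 else "reverse"
        rid = f"mol{i:06d}"
        n_copies = 2 if rng.random() < params.duplicate_rate else 1
        for copy in range(n_copies):
            read_id = rid if copy == 0 else f"{rid}.dup{copy}"
            if group == "forward":
                insert = revcomp_array(conv_arr)
                construct = np.concatenate(
                    [seq_to_array(adapters.forward_5p), insert, seq_to_array(adapters.forward_3p)]
                )
            else:
                insert = conv_arr
                construct = np.concatenate(
                    [seq_to_array(adapters.reverse_5p), insert, seq_to_array(adapters.reverse_3p)]
                )
            construct = _add_errors(construct, params.error_rate, rng)
            a5 = len(adapters.forward_5p if group == "forward" else adapters.reverse_5p)
            insert_err = construct[a5 : a5 + frag]
            flag16 = (strand == "OT") == (group == "forward")
            if flag16:
                seq_ref = array_to_seq(revcomp_array(insert_err))
                flag = 16
            else:
                seq_ref = array_to_seq(insert_err)
                flag = 0
            read_seq = array_to_seq(construct)
            reads.append((read_id, read_seq, "I" * len(read_seq)))
            sam_records.append(
                {
                    "read_id": read_id,
                    "contig": contig,
                    "start": start,
                    "flag": flag,
                    "seq": seq_ref,
                    "group": group,
                    "strand": strand,
                    "haplotype": hap,
                    "is_spikein": is_spike,
                    "duplicate_of": rid if copy > 0 else "",
                }
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "group": group,
                    "flag": flag,
                    "haplotype": hap,
                    "is_spikein": is_spike,
                    "duplicate_of": rid if copy > 0 else "",
                    "n_cpg": int(cpg_mask.sum()),
                    "cpg_states": cpg_states,
                    "n_modified": conv.n_modified,
                    "n_modified_converted": conv.n_modified_converted,
                    "n_unmodified": conv.n_unmodified,
                    "n_unmodified_converted": conv.n_unmodified_converted,
                }
            )

    truth = pd.DataFrame(truth_rows)
    return SimulatedReads(
        reads=reads,
        truth=truth,
        sam_records=sam_records,
        genome=genome,
        params=params,
        adapters=adapters,
    )
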