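"""End-to-end pipeline: classify -> (align) -> normalize -> duplicates ->
MAPQ filter -> pileup -> outputs.

Alignment is delegated: the pipeline consumes an existing SAM/BAM (an
external long-read aligner's output, or the simulator's truth SAM whose
coordinates are exact). All other stages run natively. Every text output
carries a header with the package version, seed and key parameters.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from . import __version__
from .adapters import AdapterConfig
from .methcall import merge_cpg_strands, pileup_cytosines, write_methylome
from .phasing import allele_methylomes, haplotag_reads, read_phased_vcf, test_asm
from .spikein import partition_spikein_sites, spikein_report
from .strand import (
    classify_strand,
    filter_alignments,
    mark_duplicates,
    normalize_strand,
    read_sam,
    write_sam,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    reference: str  # FASTA
    reads: str | None = None  # FASTQ with adapters (classification input)
    alignments: str | None = None  # SAM/BAM of trimmed reads
    vcf: str | None = None  # phased het variants for ASM
    spikein_name: str | None = None
    out_dir: str = "lrtaps_out"
    min_mapq: int = 10
    min_depth: int = 5
    flank: int = 5
    adapter_error: float = 0.1
    dup_tolerance: int = 20
    min_baseq: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_mapq", "min_depth", "flank", "dup_tolerance", "min_baseq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def read_fasta(path: str) -> dict[str, str]:
    contigs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        contigs[name] = "".join(chunks)
    return contigs


def read_fastq(path: str) -> list[tuple[str, str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            reads.append((header[1:].split()[0], seq, qual))
    return reads


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the full analysis; returns a map of output name -> path.

    Stages follow library order: adapter classification (when raw reads are
    given), flag normalization, duplicate marking, MAPQ filtering, cytosine
    pileup, CpG strand merging, and optional spike-in QC and ASM phasing.
    On failure, partially written outputs are removed and the stage-named
    error propagates.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    note = f"version={__version__} seed={config.seed}"

    def path(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        return p

    try:
        reference = read_fasta(config.reference)
        adapters = AdapterConfig(max_error_rate=config.adapter_error)

        groups: dict[str, str] = {}
        if config.reads:
            logger.info("stage classify: %s", config.reads)
            calls = [
                classify_strand(rid, seq, qual, adapters)
                for rid, seq, qual in read_fastq(config.reads)
            ]
            for grp in ("forward", "reverse", "unclassified"):
                fq = path(f"classified_{grp}.fastq")
                with open(fq, "w") as fh:
                    for c in calls:
                        if c.group == grp:
                            fh.write(f"@{c.read_id}\n{c.sequence}\n+\n{c.qualities}\n")
                outputs[f"fastq_{grp}"] = fq
            rep = path("classification.tsv")
            with open(rep, "w") as fh:
                fh.write(f"#lrtaps classification {note}\n")
                fh.write("read_id\tgroup\tdist_5p\tdist_3p\ttrimmed_length\n")
                for c in calls:
                    fh.write(
                        f"{c.read_id}\t{c.group}\t{c.dist_5p}\t{c.dist_3p}\t"
                        f"{len(c.sequence)}\n"
                    )
            outputs["classification"] = rep
            groups = {c.read_id: c.group for c in calls}

        if not config.alignments:
            raise FileNotFoundError(
                "stage align: no alignments provided (run an external long-read "
                "aligner on the classified FASTQs, or use the simulator truth SAM)"
            )
        logger.info("stage normalize: %s", config.alignments)
        raw = read_sam(config.alignments)
        normalized = []
        for r in raw:
            grp = groups.get(r.read_id, r.strand_group)
            if grp in ("forward", "reverse"):
                normalized.append(normalize_strand(r, grp))
        logger.info("normalized %d/%d reads", len(normalized), len(raw))

        logger.info("stage duplicates")
        normalized.sort(key=lambda r: (r.contig, r.start))
        marked = mark_duplicates(normalized, config.dup_tolerance)
        sam_out = path("normalized.sam")
        write_sam(
            marked,
            sam_out,
            {n: len(s) for n, s in reference.items()},
            program_line=f"lrtaps run {note}",
        )
        outputs["normalized_sam"] = sam_out

        logger.info("stage filter: MAPQ >= %d", config.min_mapq)
        kept = filter_alignments(marked, config.min_mapq)

        logger.info("stage pileup: %d reads", len(kept))
        calls_df = pileup_cytosines(kept, reference, min_baseq=config.min_baseq)
        merged = merge_cpg_strands(calls_df)
        bed = path("methylome_cpg.bedGraph")
        write_methylome(merged, bed, min_depth=1, header_note=note)
        outputs["methylome"] = bed
        per_strand = path("methylome_per_strand.bedGraph")
        write_methylome(
            calls_df[calls_df.context == "CpG"], per_strand, min_depth=1,
            header_note=note + " per-strand",
        )
        outputs["methylome_per_strand"] = per_strand

        if config.spikein_name and config.spikein_name in reference:
            logger.info("stage qc-spikein: %s", config.spikein_name)
            part = partition_spikein_sites(reference[config.spikein_name])
            # duplicate flags are ignored on the control: the spike-in is a
            # single PCR product, so distinct molecules share exact
            # coordinates and would otherwise be discarded as duplicates
            spike_reads = [
                r for r in marked
                if r.contig == config.spikein_name and r.mapq >= config.min_mapq
            ]
            spike_calls = pileup_cytosines(
                spike_reads,
                {config.spikein_name: reference[config.spikein_name]},
                min_baseq=config.min_baseq,
            )
            report = spikein_report(spike_calls, part)
            qc = path("spikein_qc.tsv")
            report.to_tsv(qc, header_note=note)
            outputs["spikein_qc"] = qc

        if config.vcf:
            logger.info("stage phase: %s", config.vcf)
            variants = read_phased_vcf(config.vcf)
            tags = haplotag_reads(kept, variants)
            tag_path = path("haplotags.tsv")
            tags.to_tsv(tag_path, header_note=note)
            outputs["haplotags"] = tag_path
            h1, h2 = allele_methylomes(tags, kept, reference,
                                       min_baseq=config.min_baseq)
            for hap, calls in ((1, h1), (2, h2)):
                p = path(f"methylome_hap{hap}.bedGraph")
                write_methylome(
                    merge_cpg_strands(calls), p, min_depth=1,
                    header_note=f"{note} haplotype={hap}",
                )
                outputs[f"methylome_hap{hap}"] = p
            asm = test_asm(
                merge_cpg_strands(h1).assign(context="CpG"),
                merge_cpg_strands(h2).assign(context="CpG"),
                min_depth_per_allele=config.min_depth,
                merged=True,
            )
            asm_path = path("asm.tsv")
            with open(asm_path, "w") as fh:
                fh.write(f"#lrtaps ASM {note}\n")
                asm.to_csv(fh, sep="\t", index=False)
            outputs["asm"] = asm_path

        return outputs
    except Exception:
        for p in outputs.values():
            if os.path.exists(p):
                os.remove(p)
        raise
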