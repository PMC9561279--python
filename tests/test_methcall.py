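"""Pileup caller: counting rule, strand discipline, CIGAR handling, merging,
and agreement with a naive per-column oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from lrtaps.methcall import (
    merge_cpg_strands,
    modification_level,
    pileup_cytosines,
    read_bedgraph,
    write_methylome,
)
from lrtaps.strand import OB, OT, AlignedRead
from conftest import normalized


def _aligned(seq, start=0, contig="c", strand=OT, cigar=None, rid="r", quals=None):
    return AlignedRead(
        read_id=rid, contig=contig, start=start, flag=0 if strand == OT else 16,
        mapq=60, cigar=cigar or f"{len(seq)}M", seq=seq,
        quals=None if quals is None else np.asarray(quals, dtype=np.int16),
        biological_strand=strand,
    )


def brute_force_pileup(reads, reference, min_baseq=0):
    """Independent per-column recount: expand each CIGAR base by base and
    tally T/C (OT over plus-strand Cs) or A/G (OB over minus-strand Cs)."""
    counts = {}

    def bump(contig, pos, strand, cls):
        key = (contig, pos, strand)
        c = counts.setdefault(key, [0, 0, 0])
        c[cls] += 1

    for read in reads:
        ref = reference[read.contig]
        strand = "-" if read.biological_strand == OB else "+"
        site, conv, unconv = ("G", "A", "G") if strand == "-" else ("C", "T", "C")
        rpos, gpos = 0, read.start
        for op, ln in read.cigar_ops():
            for _ in range(ln):
                if op in "M=X":
                    if ref[gpos] == site:
                        base = read.seq[rpos]
                        q_ok = read.quals is None or read.quals[rpos] >= min_baseq
                        if not q_ok:
                            bump(read.contig, gpos, strand, 2)
                        elif base == conv:
                            bump(read.contig, gpos, strand, 0)
                        elif base == unconv:
                            bump(read.contig, gpos, strand, 1)
                        else:
                            bump(read.contig, gpos, strand, 2)
                    rpos += 1
                    gpos += 1
                elif op in "IS":
                    rpos += 1
                elif op in "DN":
                    if ref[gpos] == site:
                        bump(read.contig, gpos, strand, 2)
                    gpos += 1
    return counts


def random_instance(rng, ref_len=300, n_reads=10):
    ref = "".join(rng.choice(list("ACGT"), ref_len))
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, ref_len - 50))
        ops = []
        remaining = int(rng.integers(30, min(120, ref_len - start)))
        seq_len = 0
        gspan = 0
        while remaining > 0:
            kind = rng.choice(["M", "M", "M", "I", "D"])
            ln = int(rng.integers(1, min(15, remaining) + 1))
            if kind == "M":
                ops.append(("M", ln)); seq_len += ln; gspan += ln; remaining -= ln
            elif kind == "I":
                ops.append(("I", ln)); seq_len += ln
            else:
                ops.append(("D", ln)); gspan += ln; remaining -= ln
        # merge adjacent same ops to keep the CIGAR valid
        merged = []
        for op, ln in ops:
            if merged and merged[-1][0] == op:
                merged[-1][1] += ln
            else:
                merged.append([op, ln])
        if merged[0][0] != "M":
            merged.insert(0, ["M", 1]); seq_len += 1; gspan += 1
        if merged[-1][0] != "M":
            merged.append(["M", 1]); seq_len += 1; gspan += 1
        if start + gspan > ref_len:
            continue
        cigar = "".join(f"{ln}{op}" for op, ln in merged)
        seq = "".join(rng.choice(list("ACGT"), seq_len))
        quals = rng.integers(0, 40, seq_len)
        strand = OT if rng.random() < 0.5 else OB
        reads.append(_aligned(seq, start=start, strand=strand, cigar=cigar,
                              rid=f"r{i}", quals=quals))
    return {"c": ref}, reads


class TestModificationLevel:
    @pytest.mark.parametrize("nc,nu,expected", [(8, 2, 0.8), (0, 5, 0.0), (5, 0, 1.0)])
    def test_ratio(self, nc, nu, expected):
        assert modification_level(nc, nu) == pytest.approx(expected)

    def test_zero_depth_is_missing(self):
        assert math.isnan(modification_level(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            modification_level(-1, 0)


class TestPileup:
    REF = {"c": "AACGTT"}  # CpG at positions 2 (plus C) / 3 (minus C)

    def test_single_ot_read_with_t_is_converted(self):
        calls = pileup_cytosines([_aligned("AATGTT")], self.REF)
        site = calls[(calls.pos == 2) & (calls.strand == "+")].iloc[0]
        assert (site.n_converted, site.n_unconverted, site.level) == (1, 0, 1.0)
        assert site.context == "CpG"

    def test_ob_read_does_not_contribute_to_plus_strand(self):
        calls = pileup_cytosines([_aligned("AATGTT", strand=OB)], self.REF)
        assert calls[(calls.pos == 2) & (calls.strand == "+")].empty
        # the same read covers the minus-strand C at position 3 (G on plus)
        site = calls[(calls.pos == 3) & (calls.strand == "-")].iloc[0]
        assert site.n_unconverted == 1

    def test_ob_converted_base_is_a(self):
        calls = pileup_cytosines([_aligned("AACATT", strand=OB)], self.REF)
        site = calls[(calls.pos == 3) & (calls.strand == "-")].iloc[0]
        assert (site.n_converted, site.level) == (1, 1.0)

    def test_deletion_counts_as_other(self):
        read = _aligned("AAT", cigar="2M2D1M")  # deletes the CpG columns 2-3
        calls = pileup_cytosines([read], self.REF)
        site = calls[(calls.pos == 2) & (calls.strand == "+")].iloc[0]
        assert (site.n_converted, site.n_unconverted, site.n_other) == (0, 0, 1)
        assert math.isnan(site.level)

    def test_low_quality_base_excluded(self):
        read = _aligned("AATGTT", quals=[40, 40, 5, 40, 40, 40])
        calls = pileup_cytosines([read], self.REF, min_baseq=13)
        site = calls[(calls.pos == 2) & (calls.strand == "+")].iloc[0]
        assert (site.n_converted, site.n_other) == (0, 1)

    def test_overhanging_read_rejected(self):
        with pytest.raises(ValueError, match="overhangs"):
            pileup_cytosines([_aligned("ACGTACGT", start=3)], self.REF)

    def test_missing_contig_rejected(self):
        with pytest.raises(KeyError):
            pileup_cytosines([_aligned("ACG", contig="chrX")], self.REF)

    def test_counts_sum_to_depth(self, noiseless_sim):
        genome, *_, sim = noiseless_sim
        calls = pileup_cytosines(normalized(sim)[:300], genome.contigs)
        assert (calls.n_converted + calls.n_unconverted + calls.n_other
                == calls.depth).all()

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            ref, reads = random_instance(rng)
            fast = pileup_cytosines(reads, ref, min_baseq=13)
            slow = brute_force_pileup(reads, ref, min_baseq=13)
            got = {
                (r.contig, r.pos, r.strand): [r.n_converted, r.n_unconverted, r.n_other]
                for r in fast.itertuples()
            }
            assert got == slow

    def test_strand_isolation(self, noiseless_sim):
        # removing all OB reads leaves every plus-strand call unchanged
        genome, *_, sim = noiseless_sim
        reads = normalized(sim)[:200]
        full = pileup_cytosines(reads, genome.contigs)
        ot_only = pileup_cytosines([r for r in reads if r.biological_strand == OT],
                                   genome.contigs)
        pd.testing.assert_frame_equal(
            full[full.strand == "+"].reset_index(drop=True),
            ot_only[ot_only.strand == "+"].reset_index(drop=True),
        )

    def test_parameter_recovery_at_deep_uniform_locus(self):
        # conversion 0.95 over a fully methylated locus, >=200x: mean level
        # within 3 binomial SEs of 0.95
        from lrtaps.simulate import (SimParams, copy_methylome, set_cpg_levels,
                                     simulate_genome, simulate_reads)

        genome, meth = simulate_genome(genome_size=10_000, include_spikein=False,
                                       seed=77)
        m = copy_methylome(meth)
        set_cpg_levels(m, "contig1", 0, 10_000, 1.0)
        params = SimParams(n_reads=1500, conversion_rate=0.95,
                           false_conversion_cpg=0.0, false_conversion_cph=0.0,
                           error_rate=0.0, spikein_fraction=0.0, seed=77)
        sim = simulate_reads(genome, m, params)
        calls = pileup_cytosines(normalized(sim), genome.contigs)
        cpg = calls[(calls.context == "CpG") & (calls.depth >= 200)]
        assert len(cpg) > 50
        n_bases = (cpg.n_converted + cpg.n_unconverted).sum()
        pooled = cpg.n_converted.sum() / n_bases
        assert abs(pooled - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n_bases)


class TestMergeCpg:
    def test_strand_additivity(self):
        calls = pd.DataFrame(
            {
                "contig": ["c", "c"],
                "pos": [2, 3],
                "strand": ["+", "-"],
                "context": ["CpG", "CpG"],
                "n_converted": [3, 1],
                "n_unconverted": [1, 1],
                "n_other": [0, 0],
                "depth": [4, 2],
                "level": [0.75, 0.5],
            }
        )
        merged = merge_cpg_strands(calls)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row.pos, row.n_converted, row.n_unconverted) == (2, 4, 2)
        assert row.level == pytest.approx(2 / 3)

    def test_single_strand_passthrough(self):
        calls = pd.DataFrame(
            {
                "contig": ["c"], "pos": [3], "strand": ["-"], "context": ["CpG"],
                "n_converted": [2], "n_unconverted": [0], "n_other": [0],
                "depth": [2], "level": [1.0],
            }
        )
        merged = merge_cpg_strands(calls)
        assert (merged.iloc[0].pos, merged.iloc[0].n_converted) == (2, 2)

    def test_merged_depth_equals_strand_sum(self, noiseless_sim):
        genome, *_, sim = noiseless_sim
        calls = pileup_cytosines(normalized(sim)[:300], genome.contigs)
        merged = merge_cpg_strands(calls)
        assert merged.depth.sum() == calls[calls.context == "CpG"].depth.sum()


class TestWriteMethylome:
    def _calls(self):
        return pd.DataFrame(
            {
                "contig": ["c"] * 3, "pos": [2, 10, 20],
                "n_converted": [3, 2, 0], "n_unconverted": [1, 2, 6],
                "n_other": [0, 0, 0], "depth": [4, 4, 6],
                "level": [0.75, 0.5, 0.0],
            }
        )

    def test_min_depth_drops_shallow_site(self, tmp_path):
        p = tmp_path / "m.bedGraph"
        n = write_methylome(self._calls(), str(p), min_depth=5)
        assert n == 1  # only the depth-6 site survives

    def test_empty_calls_header_only(self, tmp_path):
        p = tmp_path / "m.bedGraph"
        write_methylome(self._calls().iloc[:0], str(p))
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_record_count_matches_filter(self, tmp_path, noiseless_sim):
        genome, *_, sim = noiseless_sim
        calls = merge_cpg_strands(
            pileup_cytosines(normalized(sim)[:300], genome.contigs)
        )
        p = tmp_path / "m.bedGraph"
        n = write_methylome(calls, str(p), min_depth=5)
        expected = ((calls.n_converted + calls.n_unconverted) >= 5).sum()
        assert n == expected

    def test_bedgraph_roundtrip(self, tmp_path):
        p = tmp_path / "m.bedGraph"
        write_methylome(self._calls(), str(p))
        back = read_bedgraph(str(p))
        assert list(back.n_converted) == [3, 2, 0]
        assert np.allclose(back.level, [0.75, 0.5, 0.0])
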