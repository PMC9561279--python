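"""Dataset-level summaries: N50, CpG coverage overlap, binned correlation,
and structural-variant overlap with flank extension."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


def read_n50(lengths: Sequence[int]) -> int:
    """N50 of a read-length set: the smallest length L such that reads of
    length >= L hold at least half of all bases."""
    if len(lengths) == 0:
        raise ValueError("read_n50 requires at least one length")
    arr = np.sort(np.asarray(lengths))[::-1]
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(arr[idx])


def coverage_overlap(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, min_depth: int = 5
) -> tuple[int, int, int]:
    """Venn counts of CpG units covered at >= min_depth in each call set.

    Call sets are keyed by (contig, pos); pass strand-merged CpG calls so a
    unit means one CpG dyad. Returns (only_a, both, only_b).
    """

    def sites(df: pd.DataFrame) -> set[tuple[str, int]]:
        dep = df.n_converted + df.n_unconverted
        sub = df[dep >= min_depth]
        return set(zip(sub.contig, sub.pos))

    a, b = sites(calls_a), sites(calls_b)
    return len(a - b), len(a & b), len(b - a)


def binned_correlation(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    bin_size: int,
    min_depth: int = 5,
) -> float:
    """Pearson r between mean methylation levels in fixed-width genomic bins.

    Within each call set, sites with depth >= min_depth are averaged per
    (contig, pos // bin_size) bin; the correlation runs over bins present in
    both sets. Raises if fewer than two shared bins exist.
    """

    def binned(df: pd.DataFrame) -> pd.Series:
        dep = df.n_converted + df.n_unconverted
        sub = df[dep >= min_depth].copy()
        sub["bin"] = sub.pos // bin_size
        return sub.groupby(["contig", "bin"])["level"].mean()

    a, b = binned(calls_a), binned(calls_b)
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    if len(joined) < 2:
        raise ValueError("need at least 2 bins with data in both call sets")
    return float(pearsonr(joined["a"], joined["b"])[0])


@dataclass(frozen=True)
class SvInterval:
    """A structural variant as a half-open interval; INS may be zero-length."""

    contig: str
    start: int
    end: int
    type: str = "other"  # INS | DEL | other

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("SV interval start > end")

    @property
    def length(self) -> int:
        return self.end - self.start


def sv_overlap(
    svs_a: Sequence[SvInterval], svs_b: Sequence[SvInterval], flank: int = 5
) -> tuple[int, int, int]:
    """SV call-set comparison after extending every interval by ``flank`` bp.

    Two SVs match when their extended intervals intersect on the same contig
    and their types are equal. A zero-length insertion is treated as a 1-bp
    breakpoint interval so half-open intersection is well defined. Returns
    (only_a, both, only_b) where ``both`` counts matched A intervals
    (matched counts can differ between sets when the mapping is not
    one-to-one; ``only_b`` uses B's own matched status).
    """

    def ext(sv: SvInterval) -> tuple[int, int]:
        return max(0, sv.start - flank), max(sv.end, sv.start + 1) + flank

    matched_a = 0
    matched_b = [False] * len(svs_b)
    for a in svs_a:
        sa, ea = ext(a)
        hit = False
        for j, b in enumerate(svs_b):
            if a.contig != b.contig or a.type != b.type:
                continue
            sb, eb = ext(b)
            if sa < eb and sb < ea:
                hit = True
                matched_b[j] = True
        if hit:
            matched_a += 1
    return len(svs_a) - matched_a, matched_a, len(matched_b) - sum(matched_b)


def read_sv_bed(path: str) -> list[SvInterval]:
    """Read SVs from BED: contig, start, end, type."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            svtype = fields[3] if len(fields) > 3 else "other"
            out.append(SvInterval(fields[0], int(fields[1]), int(fields[2]), svtype))
    return out


def read_sv_vcf(path: str) -> list[SvInterval]:
    """Minimal SV VCF reader using INFO SVTYPE/SVLEN/END."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE", "other")
            if svtype == "INS":
                end = rec.start
            else:
                end = rec.stop
            out.append(SvInterval(rec.chrom, rec.start, end, svtype))
    return out


def annotation_overlap_fraction(
    calls: pd.DataFrame, regions: Sequence[tuple[str, int, int]]
) -> float:
    """Fraction of call sites falling inside any annotation interval
    (e.g. repeat regions from a BED track)."""
    if calls.empty:
        raise ValueError("empty call set")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in regions:
        by_contig.setdefault(contig, []).append((start, end))
    inside = 0
    for row in calls.itertuples(index=False):
        for start, end in by_contig.get(row.contig, []):
            if start <= row.pos < end:
                inside += 1
                break
    return inside / len(calls)
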