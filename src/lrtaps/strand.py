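"""Adapter-based strand classification and alignment-flag normalization.

Each Y-adapter-tagged read starts with one of two 5' adapters. Reads
carrying the forward 5' adapter form the "forward" group, the rest are
tried against the reverse 5' adapter; neither match leaves the read
unclassified. After alignment, adapter group plus the SAM reverse bit
recover the biological strand of origin:

    forward group, flag 16  -> OT, flag rewritten to 0
    reverse group, flag 0   -> OT, flag rewritten to 0
    reverse group, flag 16  -> OB, flag stays 16
    forward group, flag 0   -> OB, flag rewritten to 16

so after normalization the reverse bit encodes the biological strand (0 =
original top, 16 = original bottom) regardless of sequencing orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib
import numpy as np

from .adapters import DEFAULT_ADAPTERS, AdapterConfig

FORWARD = "forward"
REVERSE = "reverse"
UNCLASSIFIED = "unclassified"
OT = "OT"
OB = "OB"


@dataclass
class StrandCall:
    """Classification of one raw read."""

    read_id: str
    group: str  # forward | reverse | unclassified
    sequence: str
    qualities: str
    dist_5p: int = -1  # edit distance of the matched 5' adapter (-1: none)
    dist_3p: int = -1


@dataclass
class AlignedRead:
    """One aligned read with normalized strand information.

    ``seq`` and ``quals`` are stored in reference orientation as in SAM;
    ``flag`` carries the (possibly rewritten) reverse bit. ``orig_flag``
    preserves the aligner's flag across normalization.
    """

    read_id: str
    contig: str
    start: int  # 0-based leftmost reference position
    flag: int
    mapq: int
    cigar: str
    seq: str
    quals: np.ndarray | None = None
    strand_group: str = UNCLASSIFIED
    biological_strand: str | None = None  # OT | OB after normalization
    is_duplicate: bool = False
    orig_flag: int | None = None

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 16)

    def cigar_ops(self) -> list[tuple[str, int]]:
        ops = []
        n = ""
        for ch in self.cigar:
            if ch.isdigit():
                n += ch
            else:
                ops.append((ch, int(n)))
                n = ""
        return ops

    @property
    def end(self) -> int:
        """0-based exclusive reference end from the CIGAR."""
        span = sum(ln for op, ln in self.cigar_ops() if op in "MDN=X")
        return self.start + span

    @classmethod
    def from_pysam(cls, aln) -> "AlignedRead":
        quals = None
        if aln.query_qualities is not None:
            quals = np.asarray(aln.query_qualities, dtype=np.int16)
        return cls(
            read_id=aln.query_name,
            contig=aln.reference_name,
            start=aln.reference_start,
            flag=aln.flag,
            mapq=aln.mapping_quality,
            cigar=aln.cigarstring or f"{aln.query_length}M",
            seq=aln.query_sequence,
            quals=quals,
            strand_group=aln.get_tag("XG") if aln.has_tag("XG") else UNCLASSIFIED,
            biological_strand=aln.get_tag("XB") if aln.has_tag("XB") else None,
            is_duplicate=bool(aln.flag & 1024),
            orig_flag=aln.get_tag("XF") if aln.has_tag("XF") else None,
        )


def _match_5p(adapter: str, seq: str, max_err: int, window_pad: int = 50):
    """Semi-global match of an adapter near the read 5' end.

    Returns (edit_distance, end_of_match) or None. The adapter is aligned as
    an infix of a window at the start of the read, anchoring classification
    to the ligated 5' arm.
    """
    window = seq[: len(adapter) + window_pad]
    res = edlib.align(adapter, window, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_err:
        return None
    end = res["locations"][0][1] + 1
    return res["editDistance"], end


def _match_3p(adapter: str, seq: str, max_err: int, window_pad: int = 50):
    """Match an adapter near the read 3' end; returns (dist, start_of_match)."""
    off = max(0, len(seq) - len(adapter) - window_pad)
    window = seq[off:]
    res = edlib.align(adapter, window, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_err:
        return None
    return res["editDistance"], off + res["locations"][0][0]


def classify_strand(
    read_id: str,
    sequence: str,
    qualities: str | None = None,
    config: AdapterConfig = DEFAULT_ADAPTERS,
) -> StrandCall:
    """Assign a read to the forward or reverse adapter group and trim.

    Both 5' adapters are aligned semi-globally; the smaller edit distance
    wins (an exact tie is left unclassified). The matching 3' adapter is
    trimmed when present; a read-through that never reaches the 3' adapter
    is still classified by its 5' arm alone.
    """
    if qualities is None:
        qualities = "I" * len(sequence)
    if not sequence:
        return StrandCall(read_id, UNCLASSIFIED, sequence, qualities)

    max_err_f = int(config.max_error_rate * len(config.forward_5p))
    max_err_r = int(config.max_error_rate * len(config.reverse_5p))
    fwd = _match_5p(config.forward_5p, sequence, max_err_f)
    rev = _match_5p(config.reverse_5p, sequence, max_err_r)

    if fwd is None and rev is None:
        return StrandCall(read_id, UNCLASSIFIED, sequence, qualities)
    if fwd is not None and rev is not None:
        if fwd[0] == rev[0]:
            return StrandCall(read_id, UNCLASSIFIED, sequence, qualities)
        group = FORWARD if fwd[0] < rev[0] else REVERSE
    else:
        group = FORWARD if fwd is not None else REVERSE

    dist5, cut5 = fwd if group == FORWARD else rev
    a3 = config.forward_3p if group == FORWARD else config.reverse_3p
    max_err_3 = int(config.max_error_rate * len(a3))
    m3 = _match_3p(a3, sequence[cut5:], max_err_3)
    if m3 is not None:
        dist3, cut3 = m3
        trimmed = sequence[cut5 : cut5 + cut3]
        quals = qualities[cut5 : cut5 + cut3]
    else:
        dist3 = -1
        trimmed = sequence[cut5:]
        quals = qualities[cut5:]
    return StrandCall(read_id, group, trimmed, quals, dist5, dist3)


def classify_reads(
    reads: Iterable[tuple[str, str, str]], config: AdapterConfig = DEFAULT_ADAPTERS
) -> list[StrandCall]:
    return [classify_strand(rid, seq, qual, config) for rid, seq, qual in reads]


def normalize_strand(read: AlignedRead, group: str | None = None) -> AlignedRead:
    """Rewrite the flag so the reverse bit encodes the biological strand.

    Idempotent: a read whose biological strand is already set is returned
    unchanged. Unclassified reads are rejected.
    """
    if read.biological_strand is not None:
        return read
    if group is None:
        group = read.strand_group
    if group not in (FORWARD, REVERSE):
        raise ValueError(f"cannot normalize read {read.read_id}: group {group!r}")
    is_ot = (group == FORWARD) == bool(read.flag & 16)
    new_flag = (read.flag & ~16) | (0 if is_ot else 16)
    return replace(
        read,
        flag=new_flag,
        orig_flag=read.flag,
        strand_group=group,
        biological_strand=OT if is_ot else OB,
    )


def mark_duplicates(
    reads: Sequence[AlignedRead], pos_tolerance: int = 20
) -> list[AlignedRead]:
    """Flag PCR duplicates among coordinate-sorted normalized reads.

    Reads sharing contig and biological strand whose 5' and 3' reference
    coordinates both lie within ``pos_tolerance`` of a duplicate group's
    first member form one group; the best member (highest MAPQ, then
    longest, then lexicographically smallest id) stays unflagged.
    """
    last: dict[str, int] = {}
    for r in reads:
        if r.contig in last and r.start < last[r.contig]:
            raise ValueError("mark_duplicates requires coordinate-sorted input")
        last[r.contig] = r.start

    out = [replace(r, is_duplicate=False) for r in reads]
    clusters: dict[tuple[str, str], list[list[int]]] = {}
    for i, r in enumerate(out):
        key = (r.contig, r.biological_strand or "?")
        placed = False
        for cluster in clusters.setdefault(key, []):
            rep = out[cluster[0]]
            if abs(r.start - rep.start) <= pos_tolerance and abs(r.end - rep.end) <= pos_tolerance:
                cluster.append(i)
                placed = True
                break
        if not placed:
            clusters[key].append([i])

    for groups in clusters.values():
        for cluster in groups:
            if len(cluster) < 2:
                continue
            best = min(
                cluster,
                key=lambda i: (-out[i].mapq, -(out[i].end - out[i].start), out[i].read_id),
            )
            for i in cluster:
                if i != best:
                    out[i].is_duplicate = True
    return out


def filter_alignments(
    reads: Iterable[AlignedRead], min_mapq: int = 10
) -> list[AlignedRead]:
    """Keep reads with MAPQ >= min_mapq and the duplicate flag unset."""
    return [r for r in reads if r.mapq >= min_mapq and not r.is_duplicate]


def ensure_normalized(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Normalize any read that still carries a raw aligner flag.

    Reads whose biological strand is already set pass through untouched
    (normalize_strand is idempotent); reads without a known adapter group
    are dropped — they cannot be strand-assigned.
    """
    out = []
    for r in reads:
        if r.biological_strand is not None:
            out.append(r)
        elif r.strand_group in (FORWARD, REVERSE):
            out.append(normalize_strand(r))
    return out


def read_sam(path: str) -> list[AlignedRead]:
    """Load mapped reads from SAM/BAM into AlignedRead records."""
    import pysam

    out = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            out.append(AlignedRead.from_pysam(aln))
    return out


def write_sam(reads: Sequence[AlignedRead], path: str, contig_lengths: dict[str, int],
              program_line: str = "") -> None:
    """Write normalized reads as headered SAM, original flag in the XF tag."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contig_lengths.items()],
        "PG": [{"ID": "lrtaps", "PN": "lrtaps", "CL": program_line or "lrtaps"}],
    }
    names = list(contig_lengths)
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in sorted(reads, key=lambda r: (names.index(r.contig), r.start)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = r.flag | (1024 if r.is_duplicate else 0)
            a.reference_name = r.contig
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar
            a.query_sequence = r.seq
            if r.quals is not None:
                a.query_qualities = list(map(int, r.quals))
            if r.orig_flag is not None:
                a.set_tag("XF", r.orig_flag)
            a.set_tag("XG", r.strand_group)
            if r.biological_strand:
                a.set_tag("XB", r.biological_strand)
            out.write(a)
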