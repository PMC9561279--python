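"""Per-cytosine modification calling with the TAPS-inverted counting rule.

TAPS reads a modified cytosine as T, so the modification level of a site is

    level = n_converted / (n_converted + n_unconverted)

where n_converted counts reads showing T over a reference C and
n_unconverted counts reads showing C — the inverse of the bisulfite
convention. That inversion happens here, once, and nowhere else in the
package; all column names speak of converted/unconverted bases.

Strand discipline: a plus-strand reference C is covered only by OT reads
(read base T = converted, C = unconverted); a minus-strand C — a G in the
plus-strand reference — only by OB reads, read off the complementary base
(A = converted, G = unconverted). Bases below the quality floor, non-C/T
observations and deletions are tallied as ``n_other`` and never enter the
level denominator.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .dna import CONTEXT_NAMES, cytosine_context_arrays, seq_to_array
from .strand import OB, OT, AlignedRead

_C, _G, _T, _A = (ord(b) for b in "CGTA")

CALL_COLUMNS = [
    "contig",
    "pos",
    "strand",
    "context",
    "n_converted",
    "n_unconverted",
    "n_other",
    "depth",
    "level",
]


def modification_level(n_converted: int, n_unconverted: int) -> float:
    """TAPS modification level; NaN when the site has no C/T evidence."""
    if n_converted < 0 or n_unconverted < 0:
        raise ValueError("counts must be non-negative")
    denom = n_converted + n_unconverted
    return n_converted / denom if denom else float("nan")


def _reference_arrays(reference: Mapping[str, str]):
    """Per-contig cytosine masks and context codes for both strands."""
    out = {}
    for name, seq in reference.items():
        arr = seq_to_array(seq)
        plus_ctx, minus_ctx = cytosine_context_arrays(arr)
        out[name] = (arr, plus_ctx, minus_ctx)
    return out


def pileup_cytosines(
    alignments: Iterable[AlignedRead],
    reference: Mapping[str, str],
    contexts: set[str] = frozenset({"CpG", "CHG", "CHH"}),
    min_baseq: int = 13,
) -> pd.DataFrame:
    """Count converted/unconverted bases at every covered reference cytosine.

    ``alignments`` must already be normalized (flag bit 16 = OB), MAPQ- and
    duplicate-filtered. Returns a DataFrame with one row per covered
    cytosine (columns: contig, pos, strand, context, n_converted,
    n_unconverted, n_other, depth, level), sorted by coordinate. CIGAR-aware:
    insertions and soft clips consume read bases only, deletions over a
    cytosine count as n_other.
    """
    refs = _reference_arrays(reference)
    counts: dict[str, np.ndarray] = {}  # contig -> (2 strands, 3 classes, L)
    for name, (arr, _, _) in refs.items():
        counts[name] = np.zeros((2, 3, arr.size), dtype=np.int64)

    for read in alignments:
        if read.contig not in refs:
            raise KeyError(f"contig {read.contig} absent from reference")
        ref_arr, _, _ = refs[read.contig]
        if read.biological_strand is not None:
            is_ob = read.biological_strand == OB
        else:
            is_ob = bool(read.flag & 16)
        si = 1 if is_ob else 0
        site_base = _G if is_ob else _C
        conv_base = _A if is_ob else _T
        cnt = counts[read.contig]

        seq = seq_to_array(read.seq)
        quals = read.quals
        rpos = 0
        gpos = read.start
        for op, ln in read.cigar_ops():
            if op in "M=X":
                if gpos + ln > ref_arr.size:
                    raise ValueError(
                        f"read {read.read_id} overhangs contig {read.contig}"
                    )
                ref_slice = ref_arr[gpos : gpos + ln]
                mask = ref_slice == site_base
                if mask.any():
                    idx = np.flatnonzero(mask)
                    bases = seq[rpos + idx]
                    if quals is not None and min_baseq > 0:
                        ok = quals[rpos + idx] >= min_baseq
                    else:
                        ok = np.ones(idx.size, dtype=bool)
                    g = gpos + idx
                    conv = ok & (bases == conv_base)
                    unconv = ok & (bases == site_base)
                    other = ~(conv | unconv)
                    np.add.at(cnt[si, 0], g[conv], 1)
                    np.add.at(cnt[si, 1], g[unconv], 1)
                    np.add.at(cnt[si, 2], g[other], 1)
                rpos += ln
                gpos += ln
            elif op in "IS":
                rpos += ln
            elif op in "DN":
                ref_slice = ref_arr[gpos : gpos + ln]
                del_sites = gpos + np.flatnonzero(ref_slice == site_base)
                np.add.at(cnt[si, 2], del_sites, 1)
                gpos += ln
            elif op == "H":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    rows = []
    wanted = {k for k, v in CONTEXT_NAMES.items() if v in contexts}
    for name, (arr, plus_ctx, minus_ctx) in refs.items():
        cnt = counts[name]
        for si, strand, ctx_arr in ((0, "+", plus_ctx), (1, "-", minus_ctx)):
            depth = cnt[si].sum(axis=0)
            covered = np.flatnonzero((depth > 0) & np.isin(ctx_arr, list(wanted)))
            for p in covered:
                nc, nu, no = (int(cnt[si, k, p]) for k in range(3))
                rows.append(
                    (
                        name,
                        int(p),
                        strand,
                        CONTEXT_NAMES[int(ctx_arr[p])],
                        nc,
                        nu,
                        no,
                        nc + nu + no,
                        modification_level(nc, nu),
                    )
                )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.sort_values(["contig", "pos", "strand"], ignore_index=True)


def merge_cpg_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Combine the two strands of each CpG into one record keyed at the C
    of the plus strand.

    The minus-strand cytosine of a CpG sits one base to the right of the
    plus-strand C; its counts are added to position p and the level is
    recomputed from the summed counts. Non-CpG rows are dropped.
    """
    cpg = calls[calls.context == "CpG"].copy()
    if cpg.empty:
        return pd.DataFrame(columns=["contig", "pos", "n_converted", "n_unconverted",
                                     "n_other", "depth", "level"])
    cpg["unit"] = np.where(cpg.strand == "-", cpg.pos - 1, cpg.pos)
    merged = (
        cpg.groupby(["contig", "unit"], as_index=False)[
            ["n_converted", "n_unconverted", "n_other"]
        ]
        .sum()
        .rename(columns={"unit": "pos"})
    )
    merged["depth"] = merged.n_converted + merged.n_unconverted + merged.n_other
    merged["level"] = [
        modification_level(c, u)
        for c, u in zip(merged.n_converted, merged.n_unconverted)
    ]
    return merged.sort_values(["contig", "pos"], ignore_index=True)


def write_methylome(
    calls: pd.DataFrame,
    path: str,
    min_depth: int = 1,
    fmt: str = "bedGraph",
    header_note: str = "",
) -> int:
    """Write calls as bedGraph (level%, n_converted, n_unconverted) or
    minimal bedMethyl; returns the number of records written.

    Sites with n_converted + n_unconverted < min_depth are dropped. The
    bedGraph column order matches the common methylation-caller layout:
    contig, start, end, level in percent, converted count, unconverted
    count.
    """
    kept = calls[(calls.n_converted + calls.n_unconverted) >= min_depth]
    strand_col = kept["strand"] if "strand" in kept.columns else None
    with open(path, "w") as fh:
        if fmt == "bedGraph":
            fh.write(
                f'track type="bedGraph" description="lrtaps {__version__} '
                f'converted/(converted+unconverted) {header_note}"\n'
            )
            for row in kept.itertuples(index=False):
                lvl = 100.0 * row.level
                fh.write(
                    f"{row.contig}\t{row.pos}\t{row.pos + 1}\t{lvl:.6g}\t"
                    f"{row.n_converted}\t{row.n_unconverted}\n"
                )
        elif fmt == "bedmethyl":
            fh.write(f"#lrtaps {__version__} {header_note}\n")
            for i, row in enumerate(kept.itertuples(index=False)):
                strand = getattr(row, "strand", ".")
                depth = row.n_converted + row.n_unconverted
                lvl = 100.0 * row.level
                fh.write(
                    f"{row.contig}\t{row.pos}\t{row.pos + 1}\tCpG\t"
                    f"{min(depth, 1000)}\t{strand}\t{row.pos}\t{row.pos + 1}\t"
                    f"0,0,0\t{depth}\t{lvl:.4g}\n"
                )
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return len(kept)


def read_bedgraph(path: str) -> pd.DataFrame:
    """Read a bedGraph written by write_methylome back into a call table."""
    import io

    with open(path) as fh:
        body = "".join(
            ln for ln in fh if not ln.startswith(("track", "#")) and ln.strip()
        )
    df = pd.read_csv(
        io.StringIO(body),
        sep="\t",
        names=["contig", "pos", "end", "level_pct", "n_converted", "n_unconverted"],
        dtype={"contig": str},
    )
    df["pos"] = df.pos.astype(int)
    df["n_converted"] = df.n_converted.astype(int)
    df["n_unconverted"] = df.n_unconverted.astype(int)
    df["depth"] = df.n_converted + df.n_unconverted
    df["level"] = df.level_pct / 100.0
    return df.drop(columns=["end", "level_pct"])
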