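"""Low-level DNA sequence helpers shared across the toolkit.

Coordinates are 0-based half-open throughout. Cytosine context codes follow
the usual trinucleotide convention: CpG (C followed by G), CHG (C-H-G with
H in {A,C,T}) and CHH (everything else). Contexts are assigned per strand:
a minus-strand cytosine appears as G in the plus-strand reference and its
context is read off the reverse complement.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# context codes used in numpy arrays
CTX_NONE = -1  # position is not a cytosine on this strand
CTX_CPG = 0
CTX_CHG = 1
CTX_CHH = 2

CONTEXT_NAMES = {CTX_CPG: "CpG", CTX_CHG: "CHG", CTX_CHH: "CHH"}

_A, _C, _G, _T = (ord(b) for b in "ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    comp = np.full(256, ord("N"), dtype=np.uint8)
    for a, b in zip(b"ACGTacgt", b"TGCAtgca"):
        comp[a] = b
    return comp[out]


def cytosine_context_arrays(seq: str | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position cytosine context codes for both strands.

    Returns ``(plus_ctx, minus_ctx)`` int8 arrays of the sequence length.
    ``plus_ctx[i]`` is the context of a plus-strand C at i (CTX_NONE if the
    base is not C); ``minus_ctx[i]`` is the context of a minus-strand C,
    i.e. a G in the plus-strand sequence. Cytosines too close to the contig
    edge for a full trinucleotide default to CHH.
    """
    arr = seq_to_array(seq) if isinstance(seq, str) else seq
    n = arr.size
    is_c = arr == _C
    is_g = arr == _G

    nxt = np.zeros(n, dtype=np.uint8)
    nxt2 = np.zeros(n, dtype=np.uint8)
    if n > 1:
        nxt[:-1] = arr[1:]
    if n > 2:
        nxt2[:-2] = arr[2:]
    prv = np.zeros(n, dtype=np.uint8)
    prv2 = np.zeros(n, dtype=np.uint8)
    if n > 1:
        prv[1:] = arr[:-1]
    if n > 2:
        prv2[2:] = arr[:-2]

    plus = np.full(n, CTX_NONE, dtype=np.int8)
    plus[is_c] = CTX_CHH
    plus[is_c & (nxt != _G) & (nxt2 == _G)] = CTX_CHG
    plus[is_c & (nxt == _G)] = CTX_CPG

    minus = np.full(n, CTX_NONE, dtype=np.int8)
    minus[is_g] = CTX_CHH
    minus[is_g & (prv != _C) & (prv2 == _C)] = CTX_CHG
    minus[is_g & (prv == _C)] = CTX_CPG
    return plus, minus


def cpg_plus_positions(seq: str | np.ndarray) -> np.ndarray:
    """Positions i with seq[i:i+2] == 'CG' (the plus-strand C of each CpG)."""
    plus, _ = cytosine_context_arrays(seq)
    return np.flatnonzero(plus == CTX_CPG)
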