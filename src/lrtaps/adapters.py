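"""Y-shaped adapter sequences and configuration.

A Y-shaped (forked) adapter has two non-complementary arms, so the two
strands of each genomic duplex receive distinguishable adapter ends. After
amplification every sequenced molecule therefore starts with one of two 5'
adapters, and the identity of that adapter together with the alignment
orientation recovers the biological strand of origin (OT = original top,
OB = original bottom).

The defaults are the adapter arms used for long-read TAPS libraries; the
forward 3' adapter is the reverse complement of the reverse 5' adapter and
vice versa, which is enforced as an invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dna import revcomp

FORWARD_5P = "CCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"
FORWARD_3P = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACCGATGTATCTCGTA"
REVERSE_5P = "TACGAGATACATCGGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
REVERSE_3P = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGG"


@dataclass(frozen=True)
class AdapterConfig:
    """Adapter pair plus matching tolerances for read classification.

    max_error_rate is the edit-distance budget as a fraction of the adapter
    length; min_overlap is the shortest adapter suffix/prefix accepted at a
    read end.
    """

    forward_5p: str = FORWARD_5P
    forward_3p: str = FORWARD_3P
    reverse_5p: str = REVERSE_5P
    reverse_3p: str = REVERSE_3P
    max_error_rate: float = 0.1
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_error_rate < 1.0:
            raise ValueError("max_error_rate must be in [0, 1)")
        if revcomp(self.forward_3p) != self.reverse_5p or revcomp(
            self.reverse_3p
        ) != self.forward_5p:
            raise ValueError(
                "forward/reverse adapters must be reverse complements of "
                "each other's opposite ends"
            )


DEFAULT_ADAPTERS = AdapterConfig()
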