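"""Conversion-rate QC from the fully CCGG-methylated spike-in control.

The control is treated with HpaII methyltransferase, which methylates the
internal cytosine of every CCGG. Reads mapped to the control therefore
measure:

  * conversion rate — converted fraction at the internal C of CCGG sites
    (truly modified);
  * CpG false-positive rate — converted fraction at all other CpG
    cytosines, excluding CpGs whose 4-mer context is TCGG, CCGT or ACGG
    (one mismatch away from the CCGG recognition site, hence likely
    enzymatic off-targets rather than chemistry failures);
  * CpH false-positive rate — converted fraction at non-CpG cytosines.

Rates are pooled over read bases (total converted / total observed), not
averaged per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .dna import revcomp

logger = logging.getLogger(__name__)

OFF_TARGET_MOTIFS = frozenset({"TCGG", "CCGT", "ACGG"})


@dataclass
class SpikeinPartition:
    """Cytosine sites of the spike-in, keyed (position, strand).

    The four sets partition every cytosine on both strands: HpaII-methylated
    CCGG internal Cs, unmodified CpGs, off-target-excluded CpGs, and CpHs.
    """

    methylated_cpg: set[tuple[int, str]]
    unmodified_cpg: set[tuple[int, str]]
    cph: set[tuple[int, str]]
    excluded: set[tuple[int, str]]


@dataclass
class SpikeinReport:
    conversion_rate: float | None
    fpr_cpg: float | None
    fpr_cph: float | None
    counts: dict[str, tuple[int, int]]  # category -> (n_converted, n_total)
    n_excluded_sites: int

    def to_tsv(self, path: str, header_note: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(f"#lrtaps spike-in QC {header_note}\n")
            fh.write("category\tn_converted\tn_total\trate\n")
            for cat, (nc, nt) in self.counts.items():
                rate = f"{nc / nt:.6f}" if nt else "NA"
                fh.write(f"{cat}\t{nc}\t{nt}\t{rate}\n")

    def __str__(self) -> str:
        def pct(x):
            return f"{100 * x:.2f}%" if x is not None else "NA (no coverage)"

        return (
            f"spike-in conversion rate (methylated CpG): {pct(self.conversion_rate)}\n"
            f"false-positive rate (unmodified CpG):      {pct(self.fpr_cpg)}\n"
            f"false-positive rate (unmodified CpH):      {pct(self.fpr_cph)}\n"
            f"off-target CpG sites excluded:             {self.n_excluded_sites}"
        )


def partition_spikein_sites(spikein_sequence: str) -> SpikeinPartition:
    """Partition every cytosine of both spike-in strands into QC categories.

    A CpG's 4-mer context places its C at the position homologous to the
    internal C of CCGG (one base of left flank, two of right); minus-strand
    sites use the reverse-complement context. CpGs whose 4-mer cannot be
    read because the site touches the sequence edge cannot match an
    off-target motif and stay in the unmodified set.
    """
    seq = spikein_sequence
    n = len(seq)
    meth: set[tuple[int, str]] = set()
    unmod: set[tuple[int, str]] = set()
    cph: set[tuple[int, str]] = set()
    excl: set[tuple[int, str]] = set()

    for i, base in enumerate(seq):
        if base == "C":
            if i + 1 < n and seq[i + 1] == "G":
                fourmer = seq[i - 1 : i + 3] if i >= 1 and i + 3 <= n else ""
                if fourmer == "CCGG":
                    meth.add((i, "+"))
                elif fourmer in OFF_TARGET_MOTIFS:
                    excl.add((i, "+"))
                else:
                    unmod.add((i, "+"))
            else:
                cph.add((i, "+"))
        if base == "G":
            # minus-strand cytosine at plus coordinate i
            if i >= 1 and seq[i - 1] == "C":
                fourmer = revcomp(seq[i - 2 : i + 2]) if i >= 2 and i + 2 <= n else ""
                if fourmer == "CCGG":
                    meth.add((i, "-"))
                elif fourmer in OFF_TARGET_MOTIFS:
                    excl.add((i, "-"))
                else:
                    unmod.add((i, "-"))
            else:
                cph.add((i, "-"))
    return SpikeinPartition(meth, unmod, cph, excl)


def spikein_report(
    site_calls: pd.DataFrame, partition: SpikeinPartition
) -> SpikeinReport:
    """Pool per-site counts into conversion and false-positive rates.

    ``site_calls`` must be per-strand calls restricted to the spike-in
    contig. A category with zero covered bases reports a missing rate (not
    0) and logs a warning.
    """
    cats = {
        "methylated_cpg": partition.methylated_cpg,
        "unmodified_cpg": partition.unmodified_cpg,
        "cph": partition.cph,
        "excluded": partition.excluded,
    }
    counts: dict[str, tuple[int, int]] = {}
    for name, sites in cats.items():
        if len(site_calls):
            mask = pd.Series(
                [(p, s) in sites for p, s in zip(site_calls.pos, site_calls.strand)],
                index=site_calls.index,
            )
            sub = site_calls[mask]
            nc = int(sub.n_converted.sum())
            nt = nc + int(sub.n_unconverted.sum())
        else:
            nc = nt = 0
        counts[name] = (nc, nt)

    def rate(cat: str) -> float | None:
        nc, nt = counts[cat]
        if nt == 0:
            logger.warning("spike-in category %s has no covered bases", cat)
            return None
        return nc / nt

    return SpikeinReport(
        conversion_rate=rate("methylated_cpg"),
        fpr_cpg=rate("unmodified_cpg"),
        fpr_cph=rate("cph"),
        counts=counts,
        n_excluded_sites=len(partition.excluded),
    )
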