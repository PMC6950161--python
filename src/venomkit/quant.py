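"""Transcript and peptide abundance: RPM and relative peak area.

Transcript abundance uses Reads Per Million rather than TPM: venom-peptide
ORFs often sit on overextended contigs, so length normalization would
systematically understate short peptide transcripts.  RPM for a peptide is
the sum, over the contigs encoding it, of aligned reads divided by total
aligned reads in millions.  Peptide-level abundance is the relative LC-MS
peak area: each peptide's integrated area as a percentage of the summed
areas of all quantified peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = ["QuantRecord", "rpm", "relative_abundance"]


@dataclass(frozen=True)
class QuantRecord:
    """Per-peptide abundance: transcript RPM and relative peak area (%).

    ``relative_abundance`` is None for trace-level peptides that were
    detected but not integrated (excluded from the 100% normalization).
    """

    peptide: str
    rpm: Optional[float] = None
    relative_abundance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rpm is not None and self.rpm < 0:
            raise ValueError("RPM must be non-negative")
        if self.relative_abundance is not None and self.relative_abundance < 0:
            raise ValueError("relative abundance must be non-negative")


def rpm(
    contig_counts: Mapping[str, int],
    total_aligned_reads: int,
    peptide_to_contigs: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Reads-per-million per peptide, summed over its encoding contigs.

    RPM(peptide) = sum_contigs count / (total_aligned_reads / 1e6).  No
    length normalization (this is deliberately not TPM).
    """
    if total_aligned_reads <= 0:
        raise ValueError("total aligned reads must be positive")
    for counts in (contig_counts,):
        for c, n in counts.items():
            if n < 0:
                raise ValueError(f"negative read count for contig {c!r}")
    out: dict[str, float] = {}
    per_million = total_aligned_reads / 1e6
    for peptide, contigs in peptide_to_contigs.items():
        total = 0
        for contig in contigs:
            if contig not in contig_counts:
                raise KeyError(
                    f"peptide {peptide!r} maps to unknown contig {contig!r}")
            total += contig_counts[contig]
        out[peptide] = total / per_million
    return out


def relative_abundance(
    peak_areas: Mapping[str, float],
    trace: Sequence[str] = (),
) -> dict[str, Optional[float]]:
    """Percent contribution of each peptide's peak area to the summed areas.

    Peptides listed in ``trace`` were seen only at trace levels: they are
    reported with None and excluded from the 100% normalization.
    """
    trace_set = set(trace)
    quantified = {p: a for p, a in peak_areas.items() if p not in trace_set}
    if any(a < 0 for a in quantified.values()):
        raise ValueError("peak areas must be non-negative")
    total = sum(quantified.values())
    if total <= 0:
        raise ValueError("at least one quantified peak area must be positive")
    out: dict[str, Optional[float]] = {
        p: 100.0 * a / total for p, a in quantified.items()}
    for p in peak_areas:
        if p in trace_set:
            out[p] = None
    return out
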