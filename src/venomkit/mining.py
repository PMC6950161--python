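"""Transcript mining: translation, ORFs, tag matching, precursor segmentation.

Venom-gland contigs are translated in six frames; maximal stop-free
stretches are treated as candidate ORFs (no start-codon anchoring, since
assembled contigs are frequently overextended and precursors can lie
mid-contig).  De novo MS/MS sequence tags, filtered on their Average Local
Confidence score, are matched into the translated frames — with I and L
interchangeable by default, as they are isobaric and indistinguishable by
mass — to locate the precursors that carry the observed mature peptides.
Precursors are then segmented into signal / prepro / mature regions and
conserved prepro blocks summarized as a majority consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence, Union

from Bio.Seq import Seq

__all__ = [
    "Contig",
    "SequenceTag",
    "ORF",
    "TagMatch",
    "PrecursorModel",
    "six_frame_translate",
    "extract_orfs",
    "match_tags",
    "segment_precursor",
    "consensus_sequence",
]

STOP = "*"
_NUC = frozenset("ACGTN")

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Contig:
    identifier: str
    sequence: str
    aligned_read_count: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("contig sequence must be non-empty")
        seq = self.sequence.upper()
        bad = next((i for i, b in enumerate(seq) if b not in _NUC), None)
        if bad is not None:
            raise ValueError(
                f"non-IUPAC nucleotide {seq[bad]!r} at position {bad} "
                f"in contig {self.identifier}")
        object.__setattr__(self, "sequence", seq)
        if self.aligned_read_count < 0:
            raise ValueError("aligned read count must be non-negative")


@dataclass(frozen=True)
class SequenceTag:
    """A de novo MS/MS sequence tag with its ALC confidence score (0-100%)."""

    sequence: str
    alc_score: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("tag sequence must be non-empty")
        if not 0 <= self.alc_score <= 100:
            raise ValueError("ALC score must lie in [0, 100]")


@dataclass(frozen=True)
class ORF:
    """A stop-free translated stretch with its frame and residue coordinates.

    ``start``/``end`` are 0-based half-open positions within the frame's
    amino-acid string.
    """

    sequence: str
    frame: int
    start: int
    end: int
    contig_id: str = ""


@dataclass(frozen=True)
class TagMatch:
    tag: SequenceTag
    orf: ORF
    offset: int
    mismatches: int = 0


def six_frame_translate(contig: Contig) -> dict[int, str]:
    """Translate a contig in all six frames under the standard genetic code.

    Frames +1..+3 read the given strand, -1..-3 the reverse complement;
    stops are rendered ``*``, codons containing N translate to ``X``, and
    trailing partial codons are dropped.
    """
    fwd = Seq(contig.sequence)
    rev = fwd.reverse_complement()
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        for strand, seq in ((f, fwd), (-f, rev)):
            sub = seq[f - 1:]
            sub = sub[:len(sub) - len(sub) % 3]
            out[strand] = str(sub.translate(table=1))
    return out


def extract_orfs(
    frames: dict[int, str],
    min_length: int = 1,
    contig_id: str = "",
) -> list[ORF]:
    """Maximal stop-free stretches of every frame, at least ``min_length`` aa.

    Stop-to-stop extraction: no start codon is required, so partial coding
    regions at contig edges are retained.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    orfs: list[ORF] = []
    for frame in sorted(frames, key=lambda f: FRAMES.index(f)):
        aa = frames[frame]
        pos = 0
        for segment in aa.split(STOP):
            if len(segment) >= min_length:
                orfs.append(ORF(sequence=segment, frame=frame, start=pos,
                                end=pos + len(segment), contig_id=contig_id))
            pos += len(segment) + 1
    return orfs


def _canon(seq: str, il_equivalent: bool) -> str:
    return seq.replace("L", "I") if il_equivalent else seq


def match_tags(
    tags: Sequence[SequenceTag],
    orfs: Sequence[ORF],
    alc_threshold: float = 60.0,
    il_equivalent: bool = True,
    max_mismatches: int = 0,
) -> list[TagMatch]:
    """Locate confidence-filtered tags inside translated ORFs.

    Tags with ALC below ``alc_threshold`` are discarded.  A tag matches at
    an offset when every position agrees, with I/L treated as one residue
    when ``il_equivalent`` (they are isobaric).  ``max_mismatches`` allows a
    scored-mismatch mode (at most that many disagreeing positions).
    """
    if not 0 <= alc_threshold <= 100:
        raise ValueError("ALC threshold must lie in [0, 100]")
    kept = [t for t in tags if t.alc_score >= alc_threshold]
    matches: list[TagMatch] = []
    for tag in kept:
        t = _canon(tag.sequence, il_equivalent)
        for orf in orfs:
            s = _canon(orf.sequence, il_equivalent)
            for off in range(len(s) - len(t) + 1):
                mm = sum(a != b for a, b in zip(t, s[off:off + len(t)]))
                if mm <= max_mismatches:
                    matches.append(TagMatch(tag=tag, orf=orf, offset=off,
                                            mismatches=mm))
    return matches


@dataclass(frozen=True)
class PrecursorModel:
    """Signal + prepro + mature segmentation of a translated precursor ORF.

    Spans are 0-based half-open over ``sequence`` and must tile it in order
    signal, prepro, mature; the mature span is never empty.  The
    ``amidation_donor`` flag records whether the residue immediately after
    the mature span is a glycine — the standard C-terminal amidation donor
    — a heuristic for flagging amidated mature peptides.
    """

    sequence: str
    signal: tuple[int, int]
    prepro: tuple[int, int]
    mature: tuple[int, int]
    source_contigs: tuple[str, ...] = ()
    amidation_donor: bool = False

    def __post_init__(self) -> None:
        s, p, m = self.signal, self.prepro, self.mature
        if not (0 == s[0] <= s[1] == p[0] <= p[1] == m[0] < m[1] <= len(self.sequence)):
            raise ValueError(
                f"spans must tile the ORF in order signal {s}, prepro {p}, "
                f"mature {m} over length {len(self.sequence)}")
        if p[1] == 0:
            raise ValueError("prepro region must be non-empty")

    @property
    def signal_sequence(self) -> str:
        return self.sequence[self.signal[0]:self.signal[1]]

    @property
    def prepro_sequence(self) -> str:
        return self.sequence[self.prepro[0]:self.prepro[1]]

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature[0]:self.mature[1]]


CleavageRule = Union[int, str, re.Pattern]


def segment_precursor(
    orf_sequence: str,
    cleavage_rule: CleavageRule,
    signal_end: int = 0,
    source_contigs: Sequence[str] = (),
) -> PrecursorModel:
    """Split a precursor ORF at a declared prepro/mature cleavage site.

    ``cleavage_rule`` is one of: an explicit cut position (int, 0-based,
    cut before that index); a mature-sequence anchor (str — the mature span
    becomes the anchor's first occurrence); or a compiled motif pattern (cut
    immediately after the first match).  Residues after the mature span are
    not part of any region but a trailing glycine sets ``amidation_donor``.
    """
    n = len(orf_sequence)
    mature_end = n
    if isinstance(cleavage_rule, int):
        cut = cleavage_rule
    elif isinstance(cleavage_rule, re.Pattern):
        m = cleavage_rule.search(orf_sequence)
        if m is None:
            raise ValueError(f"cleavage motif {cleavage_rule.pattern!r} not "
                             f"found in ORF")
        cut = m.end()
    else:
        idx = orf_sequence.find(cleavage_rule)
        if idx < 0:
            raise ValueError("mature anchor not found in ORF")
        cut = idx
        mature_end = idx + len(cleavage_rule)
    if not 0 < cut < n:
        raise ValueError(f"cleavage position {cut} leaves an empty prepro or "
                         f"mature region (ORF length {n})")
    if not 0 <= signal_end <= cut:
        raise ValueError("signal region must end at or before the cleavage site")
    donor = mature_end < n and orf_sequence[mature_end] == "G"
    return PrecursorModel(
        sequence=orf_sequence,
        signal=(0, signal_end),
        prepro=(signal_end, cut),
        mature=(cut, mature_end),
        source_contigs=tuple(source_contigs),
        amidation_donor=donor,
    )


def consensus_sequence(
    aligned_block: Sequence[str],
    majority_threshold: float = 0.6,
    gap: str = "-",
    wildcard: str = "X",
) -> str:
    """Column-majority consensus of an equal-length alignment block.

    Per column, the residue held by more than ``majority_threshold`` of the
    non-gap rows is emitted, otherwise the wildcard; columns where gaps are
    the majority are dropped.
    """
    if not aligned_block:
        raise ValueError("alignment block must be non-empty")
    width = len(aligned_block[0])
    if any(len(r) != width for r in aligned_block):
        raise ValueError("all alignment rows must have equal length")
    if not 0.5 < majority_threshold <= 1.0:
        raise ValueError("majority threshold must lie in (0.5, 1]")
    out = []
    for col in range(width):
        column = [r[col] for r in aligned_block]
        residues = [c for c in column if c != gap]
        if len(residues) * 2 <= len(column):
            continue  # gap-majority column dropped
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        best, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        out.append(best if n > majority_threshold * len(residues) else wildcard)
    return "".join(out)
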