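"""File formats and configuration.

FASTA dialect: peptide records are uppercase, wrapped at 60 columns;
a ``*`` token in the description line marks C-terminal amidation (never in
the sequence itself).  Observations travel as CSV with columns
``mass, retention_time, peak_area, condition, label``; read counts as a
two-column TSV ``contig_id<TAB>count``; de novo tags as CSV
``sequence, alc``.  Match reports serialize to JSON and TSV.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import PeptideChain
from .dimers import MassObservation, MatchReport
from .mining import Contig, SequenceTag

__all__ = [
    "read_peptides_fasta", "write_peptides_fasta",
    "read_contigs_fasta", "write_contigs_fasta",
    "read_counts_tsv", "write_counts_tsv",
    "read_tags_csv", "write_tags_csv",
    "read_observations_csv", "write_observations_csv",
    "write_match_report_json", "write_match_report_tsv",
    "PipelineConfig", "load_config",
]

PathLike = Union[str, Path]
AMIDATION_TOKEN = "*"


def read_peptides_fasta(path: PathLike) -> list[PeptideChain]:
    """Peptide chains from FASTA; '*' in the description flags amidation."""
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc_tokens = rec.description.split()
        amidated = AMIDATION_TOKEN in desc_tokens
        chains.append(PeptideChain(sequence=str(rec.seq).upper(),
                                   c_terminal_amidated=amidated,
                                   name=rec.id))
    if not chains:
        raise ValueError(f"no FASTA records in {path}")
    return chains


def write_peptides_fasta(chains: Sequence[PeptideChain], path: PathLike) -> None:
    records = []
    for c in chains:
        desc = AMIDATION_TOKEN if c.c_terminal_amidated else ""
        records.append(SeqRecord(Seq(c.sequence), id=c.name or "peptide",
                                 description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_contigs_fasta(path: PathLike,
                       counts: Optional[dict[str, int]] = None) -> list[Contig]:
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        n = counts.get(rec.id, 0) if counts else 0
        contigs.append(Contig(identifier=rec.id, sequence=str(rec.seq).upper(),
                              aligned_read_count=n))
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_contigs_fasta(contigs: Sequence[Contig], path: PathLike) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.identifier, description="")
               for c in contigs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_counts_tsv(path: PathLike) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated "
                                 f"columns, got {len(parts)}")
            try:
                counts[parts[0]] = int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: count {parts[1]!r} is not "
                                 f"an integer") from None
    return counts


def write_counts_tsv(contigs: Sequence[Contig], path: PathLike) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f"{c.identifier}\t{c.aligned_read_count}\n")


def read_tags_csv(path: PathLike) -> list[SequenceTag]:
    tags = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), 2):
            try:
                tags.append(SequenceTag(sequence=row["sequence"].strip(),
                                        alc_score=float(row["alc"])))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad tag row: {exc}") from None
    return tags


def write_tags_csv(tags: Sequence[SequenceTag], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sequence", "alc"])
        for t in tags:
            w.writerow([t.sequence, t.alc_score])


_OBS_COLUMNS = ["mass", "retention_time", "peak_area", "condition", "label"]


def read_observations_csv(path: PathLike) -> list[MassObservation]:
    obs = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), 2):
            try:
                obs.append(MassObservation(
                    mass=float(row["mass"]),
                    condition=row["condition"].strip(),
                    retention_time=(float(row["retention_time"])
                                    if row.get("retention_time") else None),
                    peak_area=(float(row["peak_area"])
                               if row.get("peak_area") else None),
                    label=row.get("label", "") or "",
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad observation row: {exc}") from None
    return obs


def write_observations_csv(observations: Sequence[MassObservation],
                           path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_OBS_COLUMNS)
        for o in observations:
            w.writerow([f"{o.mass:.4f}",
                        "" if o.retention_time is None else f"{o.retention_time:.2f}",
                        "" if o.peak_area is None else f"{o.peak_area:.1f}",
                        o.condition, o.label])


def write_match_report_json(report: MatchReport, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_records(), fh, indent=2)


def write_match_report_tsv(report: MatchReport, path: PathLike) -> None:
    pd.DataFrame.from_records(report.to_records()).to_csv(
        path, sep="\t", index=False, float_format="%.4f")


@dataclasses.dataclass
class PipelineConfig:
    """Validated knobs for the pipeline, loadable from YAML."""

    tolerance_calculated: float = 0.05   # calculated-vs-calculated checks, Da
    tolerance_orbitrap: float = 0.02     # high-resolution observations, Da
    tolerance_ion_trap: float = 3.5      # low-resolution observations, Da
    mass_type: str = "monoisotopic"
    dimer_convention: str = "chemical"
    alc_threshold: float = 60.0
    il_equivalent: bool = True
    hydrophobic_set: str = "ACFILMVWY"
    pka_set: str = "bjellqvist"          # used for pI
    charge_pka_set: str = "lehninger"    # used for net charge
    majority_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tolerance_calculated", "tolerance_orbitrap",
                     "tolerance_ion_trap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mass_type not in ("monoisotopic", "average"):
            raise ValueError(f"unknown mass type {self.mass_type!r}")
        if self.dimer_convention not in ("chemical", "additive"):
            raise ValueError(f"unknown convention {self.dimer_convention!r}")
        if not 0 <= self.alc_threshold <= 100:
            raise ValueError("ALC threshold must lie in [0, 100]")
        if not 0.5 < self.majority_threshold <= 1.0:
            raise ValueError("majority threshold must lie in (0.5, 1]")


def load_config(path: Optional[PathLike] = None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    unknown = set(raw) - {f.name for f in dataclasses.fields(PipelineConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
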