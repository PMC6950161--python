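"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the structure of a venom-gland study: toxin
precursors share a conserved signal+prepro template (with point mutations)
and carry highly variable, cationic-biased mature peptides, some
C-terminally amidated via a glycine donor; precursors are embedded in
contigs with random UTRs (occasionally split over two contigs, to exercise
RPM summation) and aligned-read counts are drawn multinomially from true
frequencies.  Mass lists for native, DTT-reduced and alkylated aliquots are
derived from the planted chains and assemblies with Gaussian mass noise and
uniform decoy masses, with a Dirichlet abundance profile dominated by one
species — mirroring the skewed composition defensive venoms show.

Everything is reproducible from the seed, and every planted observable is
derivable from the manifest by the core modules.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chem import Assembly, PeptideChain, assembly_mass, chain_mass, alkylated_mass
from .dimers import MassObservation
from .mining import Contig, SequenceTag

__all__ = [
    "SyntheticManifest",
    "PlantedPrecursor",
    "PlantedAssembly",
    "generate_transcriptome",
    "generate_mass_lists",
    "generate_tags",
]

# Conserved signal+prepro template (54 aa, matching the typical length of
# ant-toxin prepro regions); mutated per precursor to emulate family drift.
PREPRO_TEMPLATE = (
    "MKLSYLLLVLAVCFALAIVFAPSEEAEADAVSVGMADAEPDALAESLANALADAEP"
)

_CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "TTA"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "AGA"],
    "S": ["TCT", "AGC"], "T": ["ACT", "ACC"], "V": ["GTT", "GTC"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

# cationic-biased mature composition (K/R-rich, mirroring polycationic
# defensive venom peptides)
_MATURE_AA = list("ACDEFGHIKLMNPQRSTVWY")
_MATURE_W = np.array([
    6, 1, 2, 3, 3, 5, 1, 4, 12, 9, 2, 2, 2, 2, 8, 3, 3, 5, 2, 2,
], dtype=float)
_MATURE_W /= _MATURE_W.sum()

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedPrecursor:
    identifier: str
    full_sequence: str
    signal_end: int
    cleavage_position: int
    mature: str
    amidated: bool
    contig_ids: tuple[str, ...]

    def mature_chain(self) -> PeptideChain:
        return PeptideChain(sequence=self.mature,
                            c_terminal_amidated=self.amidated,
                            name=self.identifier)


@dataclass(frozen=True)
class PlantedAssembly:
    chain_ids: tuple[str, ...]
    interchain_bonds: int
    intrachain_bonds: int


@dataclass
class SyntheticManifest:
    """Ground truth for one synthetic dataset."""

    seed: int
    precursors: list[PlantedPrecursor] = field(default_factory=list)
    assemblies: list[PlantedAssembly] = field(default_factory=list)
    true_rpm: dict[str, float] = field(default_factory=dict)
    true_abundance: dict[str, float] = field(default_factory=dict)
    total_aligned_reads: int = 0
    mass_sigma: float = 0.0

    def chains(self) -> dict[str, PeptideChain]:
        return {p.identifier: p.mature_chain() for p in self.precursors}

    def planted_assembly_objects(self) -> list[Assembly]:
        chains = self.chains()
        out = []
        for pa in self.assemblies:
            out.append(Assembly(
                chains=tuple(chains[i] for i in pa.chain_ids),
                interchain_bonds=pa.interchain_bonds,
                intrachain_bonds=pa.intrachain_bonds,
                convention="chemical",
                name="+".join(pa.chain_ids)))
        return out

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticManifest":
        raw = json.loads(text)
        raw["precursors"] = [PlantedPrecursor(**{**p, "contig_ids": tuple(p["contig_ids"])})
                             for p in raw["precursors"]]
        raw["assemblies"] = [PlantedAssembly(**{**a, "chain_ids": tuple(a["chain_ids"])})
                             for a in raw["assemblies"]]
        return cls(**raw)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(template: str, n_mutations: int, rng: np.random.Generator) -> str:
    seq = list(template)
    # never mutate the initiator Met
    sites = rng.choice(np.arange(1, len(seq)), size=n_mutations, replace=False)
    for s in sites:
        choices = [a for a in _AA20 if a != seq[s]]
        seq[s] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _random_mature(rng: np.random.Generator, n_cys: int,
                   length: Optional[int] = None) -> str:
    n = int(length if length is not None else rng.integers(22, 34))
    aa = rng.choice(_MATURE_AA, size=n, p=_MATURE_W)
    seq = [a for a in aa if a != "C"][:n]
    while len(seq) < n:
        seq.append(_MATURE_AA[rng.integers(len(_MATURE_AA))])
    seq = [a if a != "C" else "A" for a in seq]
    if n_cys:
        sites = rng.choice(np.arange(2, n - 2), size=n_cys, replace=False)
        for s in sites:
            seq[s] = "C"
    if seq[0] == "M":  # avoid spurious in-frame starts upstream of signal
        seq[0] = "D"
    return "".join(seq)


def generate_transcriptome(
    n_precursors: int = 6,
    read_depth: int = 1_000_000,
    seed: int = 0,
    n_dimer_chains: Optional[int] = None,
    prepro_mutations: int = 4,
    n_background_contigs: int = 8,
) -> tuple[list[Contig], SyntheticManifest]:
    """Plant precursors in contigs and draw aligned-read counts.

    ``n_dimer_chains`` of the precursors carry an odd cysteine count (one
    or three) and are paired into planted assemblies; the rest are
    cysteine-free linear peptides.  Roughly every third peptide is split
    across two contigs so RPM summation is exercised.
    """
    if n_precursors < 1 or read_depth < 1:
        raise ValueError("need at least one precursor and one read")
    if n_dimer_chains is None:
        n_dimer_chains = min(3, n_precursors)
    if n_dimer_chains > n_precursors:
        raise ValueError("cannot have more dimer chains than precursors")
    rng = np.random.default_rng(seed)
    manifest = SyntheticManifest(seed=seed)
    contigs: list[Contig] = []
    contig_freq: list[float] = []

    # resample matures until all chain/assembly masses are well separated,
    # so mass matching on synthetic data is unambiguous at tolerance <= 0.5
    while True:
        matures, amid, ncys_list = [], [], []
        for i in range(n_precursors):
            n_cys = (1 if i < max(0, n_dimer_chains - 1)
                     else 3 if i < n_dimer_chains else 0)
            matures.append(_random_mature(rng, n_cys))
            amid.append(bool(rng.integers(2)))
            ncys_list.append(n_cys)
        chains = [PeptideChain(m, c_terminal_amidated=a)
                  for m, a in zip(matures, amid)]
        masses = [chain_mass(c) for c in chains]
        # candidate dimer masses too
        cand = [c for c in chains if c.cysteine_count % 2 == 1]
        for a, b in itertools.combinations_with_replacement(cand, 2):
            bonds = (a.cysteine_count + b.cysteine_count) // 2
            masses.append(chain_mass(a) + chain_mass(b)
                          - 2 * 1.0078250319 * bonds)
        masses = sorted(masses)
        if all(b - a > 1.5 for a, b in zip(masses, masses[1:])):
            break

    # expression profile: Dirichlet with one dominant species
    alpha = np.full(n_precursors + n_background_contigs, 1.0)
    alpha[rng.integers(n_precursors)] = 40.0
    freq = rng.dirichlet(alpha)

    for i in range(n_precursors):
        ident = f"SYNTX-{i + 1:02d}"
        prepro = _mutate(PREPRO_TEMPLATE, prepro_mutations, rng)
        full = prepro + matures[i] + ("G" if amid[i] else "")
        cds = _reverse_translate(full, rng) + "TAA"
        split = i % 3 == 1 and n_precursors > 1
        n_copies = 2 if split else 1
        ids = []
        for k in range(n_copies):
            cid = f"contig_{len(contigs) + 1:03d}"
            ids.append(cid)
            utr5 = _random_nt(int(rng.integers(15, 60)), rng)
            utr3 = _random_nt(int(rng.integers(15, 60)), rng)
            contigs.append(Contig(identifier=cid, sequence=utr5 + cds + utr3))
            contig_freq.append(freq[i] / n_copies)
        manifest.precursors.append(PlantedPrecursor(
            identifier=ident,
            full_sequence=full,
            signal_end=23,
            cleavage_position=len(prepro),
            mature=matures[i],
            amidated=amid[i],
            contig_ids=tuple(ids),
        ))

    for j in range(n_background_contigs):
        cid = f"contig_{len(contigs) + 1:03d}"
        contigs.append(Contig(identifier=cid,
                              sequence=_random_nt(int(rng.integers(200, 600)), rng)))
        contig_freq.append(freq[n_precursors + j])

    # planted assemblies over the odd-cysteine chains: one heterodimer of the
    # first two 1-Cys chains (if available) and one homodimer of the 3-Cys chain
    odd = [p for p, n in zip(manifest.precursors, ncys_list) if n % 2 == 1]
    one_cys = [p for p, n in zip(manifest.precursors, ncys_list) if n == 1]
    three_cys = [p for p, n in zip(manifest.precursors, ncys_list) if n == 3]
    if len(one_cys) >= 2:
        manifest.assemblies.append(PlantedAssembly(
            chain_ids=(one_cys[0].identifier, one_cys[1].identifier),
            interchain_bonds=1, intrachain_bonds=0))
    elif len(one_cys) == 1:
        manifest.assemblies.append(PlantedAssembly(
            chain_ids=(one_cys[0].identifier, one_cys[0].identifier),
            interchain_bonds=1, intrachain_bonds=0))
    for p in three_cys:
        manifest.assemblies.append(PlantedAssembly(
            chain_ids=(p.identifier, p.identifier),
            interchain_bonds=1, intrachain_bonds=2))

    probs = np.array(contig_freq)
    probs /= probs.sum()
    counts = rng.multinomial(read_depth, probs)
    contigs = [dataclasses.replace(c, aligned_read_count=int(n))
               for c, n in zip(contigs, counts)]
    manifest.total_aligned_reads = read_depth
    per_million = read_depth / 1e6
    cmap = {c.identifier: c.aligned_read_count for c in contigs}
    for p in manifest.precursors:
        manifest.true_rpm[p.identifier] = (
            sum(cmap[cid] for cid in p.contig_ids) / per_million)
    return contigs, manifest


def generate_mass_lists(
    manifest: SyntheticManifest,
    sigma: float = 0.02,
    seed: int = 0,
    n_decoys: int = 5,
) -> tuple[list[MassObservation], list[MassObservation], list[MassObservation]]:
    """Native / reduced / alkylated mass lists from the planted truth.

    Native: monomer masses of free peptides plus assembly masses, with
    Gaussian noise (sd ``sigma``) and uniform decoys kept at least 1 Da from
    every true mass.  Reduced: chain masses, with dimer native masses gone.
    Alkylated: chain masses + 57.02146 per cysteine.  Peak areas follow a
    Dirichlet profile with one dominant species.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    chains = manifest.chains()
    assemblies = manifest.planted_assembly_objects()
    dimer_chain_ids = {cid for pa in manifest.assemblies for cid in pa.chain_ids}

    native_true: list[tuple[str, float]] = []
    for ident, chain in chains.items():
        if ident not in dimer_chain_ids:
            native_true.append((ident, chain_mass(chain)))
    for asm in assemblies:
        native_true.append((asm.name, assembly_mass(asm)))

    abund = rng.dirichlet(np.r_[40.0, np.ones(len(native_true) - 1)])
    rng.shuffle(abund)
    manifest.mass_sigma = sigma
    manifest.true_abundance = {
        name: 100.0 * a for (name, _), a in zip(native_true, abund)}

    def noisy(m: float) -> float:
        return float(m + rng.normal(0.0, sigma)) if sigma else m

    native = [MassObservation(mass=noisy(m), condition="native",
                              retention_time=float(rng.uniform(10, 55)),
                              peak_area=float(1e6 * a), label=name)
              for (name, m), a in zip(native_true, abund)]

    all_true = ([m for _, m in native_true]
                + [chain_mass(c) for c in chains.values()]
                + [alkylated_mass(c) for c in chains.values()])
    lo, hi = min(all_true) - 200, max(all_true) + 200
    made = 0
    while made < n_decoys:
        m = float(rng.uniform(lo, hi))
        if all(abs(m - t) > 1.0 for t in all_true):
            native.append(MassObservation(mass=m, condition="native",
                                          retention_time=float(rng.uniform(10, 55)),
                                          peak_area=float(rng.uniform(1e3, 1e5)),
                                          label=f"decoy_{made + 1}"))
            made += 1

    reduced = [MassObservation(mass=noisy(chain_mass(c)), condition="reduced",
                               label=ident)
               for ident, c in chains.items()]
    alkylated = [MassObservation(mass=noisy(alkylated_mass(c)),
                                 condition="alkylated", label=ident)
                 for ident, c in chains.items()]
    return native, reduced, alkylated


def generate_tags(
    manifest: SyntheticManifest,
    seed: int = 0,
    n_per_peptide: int = 3,
    tag_length: int = 9,
    n_low_confidence: int = 4,
) -> list[SequenceTag]:
    """De novo sequence tags drawn from the planted mature peptides.

    Emits ``n_per_peptide`` high-confidence substrings (ALC 70-99) per
    mature sequence plus some sub-threshold shuffled tags (ALC 30-59) that a
    correct pipeline must discard.
    """
    rng = np.random.default_rng(seed)
    tags: list[SequenceTag] = []
    for p in manifest.precursors:
        m = p.mature
        length = min(tag_length, len(m))
        for _ in range(n_per_peptide):
            off = int(rng.integers(0, len(m) - length + 1))
            tags.append(SequenceTag(sequence=m[off:off + length],
                                    alc_score=float(rng.uniform(70, 99))))
    for _ in range(n_low_confidence):
        letters = list(rng.choice(list(_AA20), size=tag_length))
        tags.append(SequenceTag(sequence="".join(letters),
                                alc_score=float(rng.uniform(30, 59))))
    return tags
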