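"""Exact peptide and assembly mass arithmetic.

Masses of mature venom peptides are computed by residue summation: the mass
of a chain is the sum of its residue masses plus one water (the termini),
adjusted for terminal and site-localized modifications.  Disulfide-linked
dimers lose two hydrogens per cystine bridge; chemical reduction restores
them and iodoacetamide alkylation caps each free thiol with a
carbamidomethyl group (+57.02146 Da), which is what makes dimer hypotheses
testable from mass lists alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

__all__ = [
    "AminoAcidTable",
    "ModificationRegistry",
    "PeptideChain",
    "Assembly",
    "STANDARD_TABLE",
    "STANDARD_MODIFICATIONS",
    "chain_mass",
    "assembly_mass",
    "reduced_chain_masses",
    "alkylated_mass",
]

MassType = Literal["monoisotopic", "average"]

# Standard residue masses, Da (residue = amino acid minus water).
_MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONOISOTOPIC = 18.010565
WATER_AVERAGE = 18.01528
HYDROGEN_MONOISOTOPIC = 1.0078250319
PROTON = 1.00727646688


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue mass lookup for the 20 standard amino acids."""

    residue_monoisotopic_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(_MONOISOTOPIC))
    residue_average_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(_AVERAGE))
    water_mass: float = WATER_MONOISOTOPIC
    water_mass_average: float = WATER_AVERAGE
    hydrogen_mass: float = HYDROGEN_MONOISOTOPIC
    proton_mass: float = PROTON

    def __post_init__(self) -> None:
        codes = set("ACDEFGHIKLMNPQRSTVWY")
        for table in (self.residue_monoisotopic_mass, self.residue_average_mass):
            if set(table) != codes:
                missing = codes - set(table)
                extra = set(table) - codes
                raise ValueError(
                    f"residue table must cover the 20 standard codes exactly "
                    f"(missing={sorted(missing)}, extra={sorted(extra)})")
            if any(m <= 0 for m in table.values()):
                raise ValueError("all residue masses must be positive")

    def residue_mass(self, code: str, mass_type: MassType = "monoisotopic") -> float:
        table = (self.residue_monoisotopic_mass if mass_type == "monoisotopic"
                 else self.residue_average_mass)
        return table[code]

    def water(self, mass_type: MassType = "monoisotopic") -> float:
        return self.water_mass if mass_type == "monoisotopic" else self.water_mass_average


STANDARD_TABLE = AminoAcidTable()


@dataclass(frozen=True)
class ModificationRegistry:
    """Named mass deltas (Da) for the modifications this pipeline handles.

    ``carbamidomethyl_per_cys`` is the iodoacetamide cap on a free thiol,
    the "+57 Da per cysteine" shift used to count cysteines from spectra.
    ``disulfide_per_bond`` is the loss of two hydrogens when a cystine
    bridge forms.
    """

    c_terminal_amidation: float = -0.98402
    carbamidomethyl_per_cys: float = +57.02146
    met_oxidation: float = +15.99491
    pyroglutamate_from_glu: float = -18.010565
    disulfide_per_bond: float = -2 * HYDROGEN_MONOISOTOPIC

    def delta(self, name: str) -> float:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown modification {name!r}") from None

    @property
    def site_modification_names(self) -> tuple[str, ...]:
        return ("met_oxidation", "pyroglutamate_from_glu", "carbamidomethyl_per_cys")


STANDARD_MODIFICATIONS = ModificationRegistry()

_VALID_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideChain:
    """A single peptide chain: sequence, terminal state, site modifications.

    ``site_modifications`` holds ``(position, modification_name)`` pairs with
    0-based positions; names must exist in the modification registry.
    """

    sequence: str
    c_terminal_amidated: bool = False
    site_modifications: tuple[tuple[int, str], ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in _VALID_CODES:
                raise ValueError(
                    f"unknown residue code {aa!r} at position {i} in sequence")
        object.__setattr__(self, "site_modifications",
                           tuple(self.site_modifications))
        for pos, mod in self.site_modifications:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside sequence of length "
                    f"{len(self.sequence)}")
            STANDARD_MODIFICATIONS.delta(mod)  # raises KeyError if unknown

    @property
    def cysteine_count(self) -> int:
        return self.sequence.count("C")

    def __len__(self) -> int:
        return len(self.sequence)


Convention = Literal["chemical", "additive"]


@dataclass(frozen=True)
class Assembly:
    """One or two chains with a disulfide-bond count and a mass convention.

    The *chemical* convention subtracts two hydrogens per disulfide bond
    (what the mass spectrometer measures); the *additive* convention is the
    plain sum of chain masses and is retained for compatibility with
    published values computed that way.
    """

    chains: tuple[PeptideChain, ...]
    interchain_bonds: int = 0
    intrachain_bonds: int = 0
    convention: Convention = "chemical"
    name: str = ""

    def __post_init__(self) -> None:
        chains = tuple(self.chains)
        object.__setattr__(self, "chains", chains)
        if len(chains) not in (1, 2):
            raise ValueError("an assembly has one or two chains")
        if self.interchain_bonds < 0 or self.intrachain_bonds < 0:
            raise ValueError("bond counts must be non-negative")
        if len(chains) == 1 and self.interchain_bonds != 0:
            raise ValueError("a one-chain assembly cannot have interchain bonds")
        if 2 * self.total_bonds > self.cysteine_count:
            raise ValueError(
                f"{self.total_bonds} disulfide bonds need "
                f"{2 * self.total_bonds} cysteines but only "
                f"{self.cysteine_count} are present")
        if self.convention not in ("chemical", "additive"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def total_bonds(self) -> int:
        return self.interchain_bonds + self.intrachain_bonds

    @property
    def cysteine_count(self) -> int:
        return sum(c.cysteine_count for c in self.chains)

    @property
    def is_dimer(self) -> bool:
        return len(self.chains) == 2

    @property
    def free_cysteines(self) -> int:
        return self.cysteine_count - 2 * self.total_bonds


def chain_mass(
    chain: PeptideChain,
    mass_type: MassType = "monoisotopic",
    table: AminoAcidTable = STANDARD_TABLE,
    mods: ModificationRegistry = STANDARD_MODIFICATIONS,
) -> float:
    """Neutral mass of a single chain with free (reduced) cysteines.

    Sum of residue masses + water, plus the amidation delta when flagged and
    any site-modification deltas.  Cysteines count as free thiols at this
    level; disulfide arithmetic lives in :func:`assembly_mass`.
    """
    mass = table.water(mass_type)
    for aa in chain.sequence:
        mass += table.residue_mass(aa, mass_type)
    if chain.c_terminal_amidated:
        mass += mods.c_terminal_amidation
    for _pos, mod in chain.site_modifications:
        mass += mods.delta(mod)
    return mass


def assembly_mass(
    assembly: Assembly,
    mass_type: MassType = "monoisotopic",
    table: AminoAcidTable = STANDARD_TABLE,
    mods: ModificationRegistry = STANDARD_MODIFICATIONS,
) -> float:
    """Neutral mass of an assembly under its convention.

    chemical: sum of chain masses − 2 H per disulfide bond;
    additive: plain sum of chain masses (bond counts ignored).
    """
    total = sum(chain_mass(c, mass_type, table, mods) for c in assembly.chains)
    if assembly.convention == "chemical":
        total += mods.disulfide_per_bond * assembly.total_bonds
    return total


def reduced_chain_masses(
    assembly: Assembly,
    mass_type: MassType = "monoisotopic",
    table: AminoAcidTable = STANDARD_TABLE,
    mods: ModificationRegistry = STANDARD_MODIFICATIONS,
) -> list[float]:
    """Masses of the fully reduced (free-thiol) constituent chains.

    This is what a DTT-reduced aliquot shows for a disulfide-linked dimer:
    the dimer mass disappears and the chain masses appear.
    """
    return [chain_mass(c, mass_type, table, mods) for c in assembly.chains]


def alkylated_mass(
    chain: PeptideChain,
    mass_type: MassType = "monoisotopic",
    table: AminoAcidTable = STANDARD_TABLE,
    mods: ModificationRegistry = STANDARD_MODIFICATIONS,
) -> float:
    """Mass of a reduced chain after iodoacetamide capping of every cysteine."""
    return (chain_mass(chain, mass_type, table, mods)
            + mods.carbamidomethyl_per_cys * chain.cysteine_count)
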