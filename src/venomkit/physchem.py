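"""Physicochemical annotation: hydrophobicity, charge, pI, sequence identity.

Net charge is a Henderson-Hasselbalch sum over the termini and the
ionizable side chains (D, E, C, Y, H, K, R); the isoelectric point is found
by bisection on that monotonically decreasing function.  Three pKa tables
are shipped: a Bjellqvist-style table with residue-specific terminal pKa
values (the table behind the common web pI calculators), a classic
textbook (Lehninger-style) table, and an EMBOSS-style table.

Conventions follow the tools venom studies typically report with, which
differ between the two quantities: net charge defaults to the textbook
table (whose high N-terminal pKa keeps the amino terminus protonated at
pH 7) and honours C-terminal amidation; the pI defaults to the Bjellqvist
table and mirrors the ubiquitous web calculators, which score the bare
sequence — free termini, free cysteines, and a dimer as the concatenation
of its chains with a single pair of termini.  A strict ``as_modified`` pI
mode is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence, Union

from Bio import Align

from .chem import Assembly, PeptideChain

__all__ = [
    "PKaSet",
    "PKA_SETS",
    "HYDROPHOBIC_DEFAULT",
    "PhyschemProfile",
    "hydrophobic_fraction",
    "net_charge",
    "isoelectric_point",
    "percent_identity",
    "average_identity",
]

HYDROPHOBIC_DEFAULT = frozenset("ACFILMVWY")


@dataclass(frozen=True)
class PKaSet:
    """pKa values for the ionizable groups of a peptide.

    ``nterm``/``cterm`` hold a ``"default"`` entry plus optional overrides
    keyed by the terminal residue (the Bjellqvist tables make terminal pKa
    depend on which residue carries the terminus).
    """

    name: str
    positive: Mapping[str, float]   # side chains protonated below their pKa
    negative: Mapping[str, float]   # side chains deprotonated above their pKa
    nterm: Mapping[str, float]
    cterm: Mapping[str, float]

    def nterm_pka(self, residue: str) -> float:
        return self.nterm.get(residue, self.nterm["default"])

    def cterm_pka(self, residue: str) -> float:
        return self.cterm.get(residue, self.cterm["default"])


# Bjellqvist-style table (residue-specific terminal pKa), as used by the
# common web pI calculators.
_BJELLQVIST = PKaSet(
    name="bjellqvist",
    positive={"K": 10.0, "R": 12.0, "H": 5.98},
    negative={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    nterm={"default": 7.5, "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
           "T": 6.82, "V": 7.44, "E": 7.7},
    cterm={"default": 3.55, "D": 4.55, "E": 4.75},
)

# EMBOSS-style table: single terminal constants.
_EMBOSS = PKaSet(
    name="emboss",
    positive={"K": 10.8, "R": 12.5, "H": 6.5},
    negative={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    nterm={"default": 8.6},
    cterm={"default": 3.6},
)

# Classic textbook constants (free-amino-acid pKa values), the table behind
# simple peptide-property web calculators; its high N-terminal pKa leaves
# the amino terminus fully protonated at pH 7.
_LEHNINGER = PKaSet(
    name="lehninger",
    positive={"K": 10.53, "R": 12.48, "H": 6.0},
    negative={"D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07},
    nterm={"default": 9.69},
    cterm={"default": 2.34},
)

PKA_SETS: dict[str, PKaSet] = {"bjellqvist": _BJELLQVIST, "emboss": _EMBOSS,
                               "lehninger": _LEHNINGER}


def _resolve_pka(pka_set: Union[str, PKaSet]) -> PKaSet:
    if isinstance(pka_set, PKaSet):
        return pka_set
    try:
        return PKA_SETS[pka_set]
    except KeyError:
        raise KeyError(f"unknown pKa set {pka_set!r}; available: "
                       f"{sorted(PKA_SETS)}") from None


def hydrophobic_fraction(
    chain: Union[PeptideChain, str],
    hydrophobic_set: frozenset = HYDROPHOBIC_DEFAULT,
) -> float:
    """Percentage of residues belonging to the hydrophobic set."""
    seq = chain.sequence if isinstance(chain, PeptideChain) else chain
    return 100.0 * sum(aa in hydrophobic_set for aa in seq) / len(seq)


def _chain_charge(
    sequence: str,
    pH: float,
    pka: PKaSet,
    *,
    n_terminus: bool = True,
    c_terminus: bool = True,
    ionizable_cys: Union[bool, int] = True,
) -> float:
    """Henderson-Hasselbalch net charge of one chain's groups.

    ``ionizable_cys`` may be a count to score only that many free thiols
    (disulfide-bonded cysteines do not ionize).
    """
    positive = 0.0
    negative = 0.0
    if n_terminus:
        positive += 1.0 / (1.0 + 10 ** (pH - pka.nterm_pka(sequence[0])))
    if c_terminus:
        negative += 1.0 / (1.0 + 10 ** (pka.cterm_pka(sequence[-1]) - pH))
    n_cys = sequence.count("C")
    free_cys = (n_cys if ionizable_cys is True
                else 0 if ionizable_cys is False else int(ionizable_cys))
    for aa, pk in pka.positive.items():
        positive += sequence.count(aa) / (1.0 + 10 ** (pH - pk))
    for aa, pk in pka.negative.items():
        count = free_cys if aa == "C" else sequence.count(aa)
        negative += count / (1.0 + 10 ** (pk - pH))
    return positive - negative


def net_charge(
    molecule: Union[PeptideChain, Assembly, str],
    pH: float = 7.0,
    pka_set: Union[str, PKaSet] = "lehninger",
    exclude_bonded_cys: bool = False,
) -> float:
    """Net charge at the given pH.

    A chain's C-terminus is suppressed when amidated.  An assembly's charge
    is the exact sum of its chains' charges, so a homodimer carries exactly
    twice its monomer's charge.  By default every cysteine is scored as a
    free thiol (what the common property calculators do, and a <0.05 e
    effect at pH 7 for typical pKa tables); ``exclude_bonded_cys`` removes
    disulfide-bonded cysteines from the ionizable set instead.
    """
    if not 0 < pH < 14:
        raise ValueError("pH must lie in (0, 14)")
    pka = _resolve_pka(pka_set)
    if isinstance(molecule, str):
        molecule = PeptideChain(sequence=molecule)
    if isinstance(molecule, PeptideChain):
        return _chain_charge(molecule.sequence, pH, pka,
                             c_terminus=not molecule.c_terminal_amidated)
    free_left = (molecule.free_cysteines if exclude_bonded_cys
                 else molecule.cysteine_count)
    total = 0.0
    for chain in molecule.chains:
        take = min(free_left, chain.cysteine_count)
        free_left -= take
        total += _chain_charge(chain.sequence, pH, pka,
                               c_terminus=not chain.c_terminal_amidated,
                               ionizable_cys=take)
    return total


PIConvention = Literal["sequence", "as_modified"]


def isoelectric_point(
    molecule: Union[PeptideChain, Assembly, str],
    pka_set: Union[str, PKaSet] = "bjellqvist",
    convention: PIConvention = "sequence",
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    ``convention="sequence"`` (default) scores the bare sequence the way
    the common web calculators do: free termini, free cysteines, and an
    assembly as the concatenation of its chains with one N- and one
    C-terminus.  ``"as_modified"`` uses :func:`net_charge` directly, i.e.
    honours amidation and disulfide bonding.
    """
    pka = _resolve_pka(pka_set)
    if isinstance(molecule, str):
        molecule = PeptideChain(sequence=molecule)
    if convention == "sequence":
        seq = (molecule.sequence if isinstance(molecule, PeptideChain)
               else "".join(c.sequence for c in molecule.chains))
        f = lambda pH: _chain_charge(seq, pH, pka)
    elif convention == "as_modified":
        f = lambda pH: net_charge(molecule, pH, pka)
    else:
        raise ValueError(f"unknown pI convention {convention!r}")
    lo, hi = 1e-6, 14.0 - 1e-6
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("net charge has no zero crossing in (0, 14)")
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        c = f(mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def percent_identity(a: str, b: str) -> float:
    """Pairwise identity in percent.

    Equal-length sequences are scored positionally (matches / length).
    Unequal lengths are globally aligned (match +1, mismatch 0, gap
    penalized) and identity is matches / alignment length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) == len(b):
        return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return 100.0 * matches / len(sa)


def average_identity(block: Sequence[str]) -> float:
    """Mean pairwise identity over all sequence pairs in the block."""
    if len(block) < 2:
        raise ValueError("need at least two sequences")
    pairs = list(itertools.combinations(block, 2))
    return sum(percent_identity(a, b) for a, b in pairs) / len(pairs)


@dataclass(frozen=True)
class PhyschemProfile:
    """Descriptive physicochemical summary of a peptide or assembly."""

    hydrophobic_fraction: float
    net_charge_at_pH7: float
    isoelectric_point: float
    hydrophobic_set: frozenset = HYDROPHOBIC_DEFAULT

    @classmethod
    def of(cls, molecule: Union[PeptideChain, Assembly],
           charge_pka: Union[str, PKaSet] = "lehninger",
           pi_pka: Union[str, PKaSet] = "bjellqvist",
           hydrophobic_set: frozenset = HYDROPHOBIC_DEFAULT,
           ) -> "PhyschemProfile":
        if isinstance(molecule, Assembly):
            seq = "".join(c.sequence for c in molecule.chains)
        else:
            seq = molecule.sequence
        return cls(
            hydrophobic_fraction=hydrophobic_fraction(seq, hydrophobic_set),
            net_charge_at_pH7=net_charge(molecule, 7.0, charge_pka),
            isoelectric_point=isoelectric_point(molecule, pi_pka),
            hydrophobic_set=hydrophobic_set,
        )
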