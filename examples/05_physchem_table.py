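"""Physicochemical annotation of mature venom peptides.

Hydrophobic residue percentage (set {A,C,F,I,L,M,V,W,Y}), net charge at
pH 7 (Henderson-Hasselbalch; amidation removes the C-terminal carboxyl),
isoelectric point (bisection; web-calculator convention scores the bare
sequence, a dimer as the concatenated chains), and pairwise identity.
"""

from venomkit import (Assembly, PeptideChain, average_identity,
                      hydrophobic_fraction, isoelectric_point, net_charge)

peptides = {
    "U1": PeptideChain("TLTNMSLREILEKLGIKIPPGLNI"),
    "U2a": PeptideChain("DWKNTAKEWGKKVGEALLDCAKQKM", c_terminal_amidated=True),
    "U4": PeptideChain("GILGVIARWIWKLIQILAPTAAVEVATRLGLPQ"),
    "U5": PeptideChain("FWGLILQGIWAVVKWAGPIIVDIAADYVIEYV",
                       c_terminal_amidated=True),
}
print(f"{'name':5s} {'hydrophobic %':>13s} {'charge pH7':>11s} {'pI':>6s}")
for name, chain in peptides.items():
    print(f"{name:5s} {hydrophobic_fraction(chain):13.2f} "
          f"{net_charge(chain):11.1f} {isoelectric_point(chain):6.2f}")

homodimer = Assembly(chains=(peptides["U2a"], peptides["U2a"]),
                     interchain_bonds=1)
print(f"U2a homodimer charge: {net_charge(homodimer):.1f} "
      "(exactly twice the monomer)")

dimer_chains = ["DWKNTAKEWGKKVGEALLDCAKQKM", "DWKGGAKDCAKKGAQCVLECVQQKM",
                "DWTDTAKEWGRKVGGALLDCAKQKM"]
print(f"mean pairwise identity of the dimer chains: "
      f"{average_identity(dimer_chains):.0f} %")
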