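"""Peptide and disulfide-linked dimer mass arithmetic.

Computes monoisotopic masses for two mature ant-venom peptides and their
covalent assemblies.  A C-terminal amidation subtracts 0.98402 Da; each
disulfide bond removes two hydrogens (the "chemical" convention), while the
"additive" convention is the plain sum of chain masses.
"""

from venomkit import Assembly, PeptideChain, assembly_mass, chain_mass, \
    reduced_chain_masses, alkylated_mass

a = PeptideChain("DWKNTAKEWGKKVGEALLDCAKQKM", c_terminal_amidated=True,
                 name="chain-A")
c = PeptideChain("DWTDTAKEWGRKVGGALLDCAKQKM", c_terminal_amidated=True,
                 name="chain-C")

print(f"{a.name}: {chain_mass(a):.2f} Da (amidated, 1 Cys)")
print(f"{c.name}: {chain_mass(c):.2f} Da (amidated, 1 Cys)")

hetero = Assembly(chains=(c, a), interchain_bonds=1)
print(f"heterodimer, 1 S-S, chemical: {assembly_mass(hetero):.2f} Da")
additive = Assembly(chains=(c, a), interchain_bonds=1, convention="additive")
print(f"heterodimer, additive:        {assembly_mass(additive):.2f} Da "
      "(plain chain sum; 2.02 Da above the chemical value)")

print("reduced chains:", [f"{m:.2f}" for m in reduced_chain_masses(hetero)],
      "- what a DTT-treated aliquot shows instead of the dimer mass")
print(f"alkylated chain-A: {alkylated_mass(a):.2f} Da "
      "(+57.02 per cysteine caps each freed thiol)")
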