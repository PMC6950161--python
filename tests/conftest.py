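"""Shared fixtures: the published T. aethiops venom peptide table."""

import pytest
from hypothesis import HealthCheck, settings

from venomkit import Assembly, PeptideChain

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

# Mature venom peptide sequences of Tetraponera aethiops with their printed
# monoisotopic masses, net charges, hydrophobic percentages and pI values.
U1 = "TLTNMSLREILEKLGIKIPPGLNI"
U2A = "DWKNTAKEWGKKVGEALLDCAKQKM"
U2B = "DWKGGAKDCAKKGAQCVLECVQQKM"
U2C = "DWTDTAKEWGRKVGGALLDCAKQKM"
U3 = "KKKRKWVTKAIKEVGKTIGEALVEEAVSAALSAATEGGEKEE"
U4 = "GILGVIARWIWKLIQILAPTAAVEVATRLGLPQ"
U5 = "FWGLILQGIWAVVKWAGPIIVDIAADYVIEYV"


@pytest.fixture(scope="session")
def toxin_chains():
    return {
        "U1": PeptideChain(U1, name="U1-PSDTX-Ta1a"),
        "U2a": PeptideChain(U2A, c_terminal_amidated=True, name="U2-PSDTX-Ta1a"),
        "U2b": PeptideChain(U2B, c_terminal_amidated=True, name="U2-PSDTX-Ta1b"),
        "U2c": PeptideChain(U2C, c_terminal_amidated=True, name="U2-PSDTX-Ta1c"),
        "U3": PeptideChain(U3, name="U3-PSDTX-Ta1a"),
        "U4": PeptideChain(U4, name="U4-PSDTX-Ta1a"),
        "U5": PeptideChain(U5, c_terminal_amidated=True, name="U5-PSDTX-Ta1a"),
    }


@pytest.fixture(scope="session")
def toxin_assemblies(toxin_chains):
    c = toxin_chains
    return {
        "Ta1a_homo": Assembly(chains=(c["U2a"], c["U2a"]), interchain_bonds=1,
                              name="Ta1a homodimer"),
        "Ta1b_homo": Assembly(chains=(c["U2b"], c["U2b"]), interchain_bonds=1,
                              intrachain_bonds=2, name="Ta1b homodimer"),
        "Ta1c_homo": Assembly(chains=(c["U2c"], c["U2c"]), interchain_bonds=1,
                              name="Ta1c homodimer"),
        "hetero": Assembly(chains=(c["U2c"], c["U2a"]), interchain_bonds=1,
                           name="Ta1c/Ta1a heterodimer"),
    }
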