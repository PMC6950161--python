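"""Dimer inference: candidate selection, enumeration, matching, verification."""

import itertools

import pytest
from hypothesis import given, strategies as st
from pyteomics import mass as ptmass

from venomkit.chem import Assembly, PeptideChain, chain_mass
from venomkit.dimers import (
    MassObservation,
    dimer_scan,
    enumerate_assemblies,
    match_masses,
    select_dimer_candidates,
    verify_by_alkylation,
    verify_by_reduction,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def obs(mass, condition="native", **kw):
    return MassObservation(mass=mass, condition=condition, **kw)


class TestCandidateSelection:
    def test_odd_cysteine_chains_retained_in_order(self, toxin_chains):
        chains = [toxin_chains["U2a"], toxin_chains["U2b"], toxin_chains["U2c"]]
        assert select_dimer_candidates(chains) == chains

    @pytest.mark.parametrize("seq,kept", [
        ("AKGA", False),      # 0 Cys: nothing to pair
        ("ACKGCA", False),    # 2 Cys: can self-pair
        ("ACKGA", True),      # 1 Cys
        ("ACCKGCA", True),    # 3 Cys
    ])
    def test_parity_rule(self, seq, kept):
        got = select_dimer_candidates([PeptideChain(seq)])
        assert bool(got) is kept


class TestEnumeration:
    def test_counts_n_homodimers_plus_pairs(self, toxin_chains):
        cands = [toxin_chains["U2a"], toxin_chains["U2b"], toxin_chains["U2c"]]
        hyps = enumerate_assemblies(cands)
        assert len(hyps) == 6  # 3 homodimers + 3 heterodimers

    def test_single_candidate_yields_one_homodimer(self):
        hyps = enumerate_assemblies([PeptideChain("ACKGA")])
        assert len(hyps) == 1
        assert hyps[0].assembly.is_dimer

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_assemblies([])

    def test_published_homodimer_masses_appear(self, toxin_chains):
        hyps = enumerate_assemblies(
            [toxin_chains["U2a"], toxin_chains["U2b"], toxin_chains["U2c"]])
        masses = sorted(h.theoretical_mass for h in hyps)
        assert any(abs(m - 5438.60) <= 0.05 for m in masses)  # Ta1b homodimer
        assert any(abs(m - 5608.78) <= 0.05 for m in masses)  # Ta1c homodimer

    def test_three_plus_three_cysteines_pair_fully_and_flag_topology(self):
        chain = PeptideChain("ACCKGCA")  # 3 Cys
        (hyp,) = enumerate_assemblies([chain])
        assert hyp.assembly.total_bonds == 3
        assert hyp.assembly.interchain_bonds >= 1
        assert hyp.topology_ambiguous  # 3 interchain or 1 inter + 2 intra

    def test_one_plus_one_cysteine_single_interchain_bond(self):
        chain = PeptideChain("ACKGA")
        (hyp,) = enumerate_assemblies([chain])
        assert (hyp.assembly.interchain_bonds, hyp.assembly.intrachain_bonds) \
            == (1, 0)
        assert not hyp.topology_ambiguous


class TestMatching:
    def test_low_resolution_match_with_signed_error(self, toxin_chains):
        hyps = enumerate_assemblies([toxin_chains["U2b"]])
        report = match_masses(hyps, [obs(5441.80)], tolerance=3.5)
        assert len(report.matches) == 1
        (hyp, err), = report.matches[0]["hypotheses"]
        assert err == pytest.approx(3.21, abs=0.01)

    def test_tight_tolerance_rejects_same_pair(self, toxin_chains):
        hyps = enumerate_assemblies([toxin_chains["U2b"]])
        report = match_masses(hyps, [obs(5441.80)], tolerance=0.5)
        assert not report.matches
        assert len(report.unexplained) == 1

    def test_exact_match_has_zero_error(self):
        hyps = enumerate_assemblies([PeptideChain("ACKGA")])
        report = match_masses(hyps, [obs(hyps[0].theoretical_mass)], 0.1)
        (_, err), = report.matches[0]["hypotheses"]
        assert err == 0.0

    def test_non_native_observation_rejected(self):
        hyps = enumerate_assemblies([PeptideChain("ACKGA")])
        with pytest.raises(ValueError, match="native"):
            match_masses(hyps, [obs(1000.0, condition="reduced")], 0.5)

    def test_every_observation_matched_or_unexplained(self, toxin_chains):
        hyps = enumerate_assemblies(
            [toxin_chains["U2a"], toxin_chains["U2b"], toxin_chains["U2c"]])
        observations = [obs(5438.59), obs(5680.89), obs(4242.0)]
        report = match_masses(hyps, observations, tolerance=0.5)
        accounted = ([m["observation"] for m in report.matches]
                     + report.unexplained)
        assert sorted(o.mass for o in accounted) \
            == sorted(o.mass for o in observations)

    @given(tol1=st.floats(0.01, 2.0), tol2=st.floats(0.01, 2.0))
    def test_match_monotonic_in_tolerance(self, tol1, tol2, toxin_chains):
        lo, hi = sorted([tol1, tol2])
        hyps = [enumerate_assemblies(
            [toxin_chains["U2a"], toxin_chains["U2c"]])
            for _ in range(2)]  # fresh hypotheses per run (stateful matching)
        observations = [obs(5680.5), obs(5750.9), obs(3000.0)]
        small = match_masses(hyps[0], observations, lo)
        large = match_masses(hyps[1], observations, hi)
        matched_small = {m["observation"].mass for m in small.matches}
        matched_large = {m["observation"].mass for m in large.matches}
        assert matched_small <= matched_large

    def test_tie_broken_by_error_then_mass(self):
        a = PeptideChain("ACKGA")
        b = PeptideChain("ACKGAR")
        hyps = enumerate_assemblies([a, b])
        mid = sum(h.theoretical_mass for h in hyps) / len(hyps)
        report = match_masses(hyps, [obs(mid)], tolerance=1000.0)
        ranked = report.matches[0]["hypotheses"]
        errors = [abs(e) for _, e in ranked]
        assert errors == sorted(errors)


class TestVerification:
    def _matched_heterodimer(self, toxin_chains, native_mass=5678.87):
        asm_hyps = enumerate_assemblies(
            [toxin_chains["U2a"], toxin_chains["U2c"]])
        report = match_masses(asm_hyps, [obs(native_mass)], tolerance=0.5)
        (hyp, _), = report.matches[0]["hypotheses"]
        return hyp

    def test_heterodimer_reduction_consistent(self, toxin_chains):
        """Reduction makes both chain masses appear and the dimer vanish."""
        hyp = self._matched_heterodimer(toxin_chains)
        reduced = [obs(2875.47, "reduced"), obs(2805.39, "reduced")]
        assert verify_by_reduction(hyp, reduced, 0.5) == "reduction_consistent"

    def test_persisting_native_mass_contradicts(self, toxin_chains):
        hyp = self._matched_heterodimer(toxin_chains)
        reduced = [obs(2875.47, "reduced"), obs(2805.39, "reduced"),
                   obs(5678.87, "reduced")]
        assert verify_by_reduction(hyp, reduced, 0.5) == "contradicted"

    def test_empty_reduced_list_leaves_unverified(self, toxin_chains):
        hyp = self._matched_heterodimer(toxin_chains)
        assert verify_by_reduction(hyp, [], 0.5) == "unverified"

    def test_monomer_must_persist_under_reduction(self):
        chain = PeptideChain("AKGWAKE")
        asm = Assembly(chains=(chain,))
        from venomkit.dimers import DimerHypothesis
        hyp = DimerHypothesis(assembly=asm, theoretical_mass=chain_mass(chain))
        match_masses([hyp], [obs(chain_mass(chain))], 0.1)
        persists = [obs(chain_mass(chain), "reduced")]
        assert verify_by_reduction(hyp, persists, 0.1) == "reduction_consistent"
        hyp2 = DimerHypothesis(assembly=asm, theoretical_mass=chain_mass(chain))
        match_masses([hyp2], [obs(chain_mass(chain))], 0.1)
        assert verify_by_reduction(hyp2, [obs(999.0, "reduced")], 0.1) \
            == "contradicted"

    def test_alkylation_one_cysteine_fully_verifies(self, toxin_chains):
        hyp = self._matched_heterodimer(toxin_chains)
        verify_by_reduction(hyp, [obs(2875.47, "reduced"),
                                  obs(2805.39, "reduced")], 0.5)
        alk = [obs(2875.48 + 57.02, "alkylated"), obs(2805.41 + 57.02, "alkylated")]
        assert verify_by_alkylation(hyp, alk, 0.5) == "fully_verified"

    def test_alkylation_shift_not_multiple_of_57_contradicts(self, toxin_chains):
        hyp = self._matched_heterodimer(toxin_chains)
        verify_by_reduction(hyp, [obs(2875.47, "reduced"),
                                  obs(2805.39, "reduced")], 0.5)
        alk = [obs(2875.48 + 85.0, "alkylated")]
        assert verify_by_alkylation(hyp, alk, 0.5) == "contradicted"

    def test_status_never_moves_backwards(self, toxin_chains):
        hyp = self._matched_heterodimer(toxin_chains)
        verify_by_reduction(hyp, [obs(2875.47, "reduced"),
                                  obs(2805.39, "reduced")], 0.5)
        with pytest.raises(ValueError, match="cannot move"):
            hyp.advance("unverified")


class TestBruteForceOracle:
    def test_enumeration_and_matching_agree_with_pairwise_loop(self):
        """Independent pyteomics-based pairwise loop reproduces the scan."""
        seqs = ["ACKGAWK", "AKCWECK", "GCKKAWA", "AWKECKAK", "ACKWGCCKA"]
        chains = [PeptideChain(s, name=f"c{i}") for i, s in enumerate(seqs)]
        cands = [c for c in chains if c.sequence.count("C") % 2 == 1]
        hyps = enumerate_assemblies(cands)

        H2 = 2 * 1.0078250319
        oracle = {}
        for a, b in itertools.combinations_with_replacement(cands, 2):
            bonds = (a.sequence.count("C") + b.sequence.count("C")) // 2
            m = (ptmass.calculate_mass(sequence=a.sequence)
                 + ptmass.calculate_mass(sequence=b.sequence) - H2 * bonds)
            oracle[frozenset([a.name, b.name])] = m
        ours = {frozenset(c.name for c in h.assembly.chains):
                h.theoretical_mass for h in hyps}
        assert set(ours) == set(oracle)
        for key in oracle:
            assert ours[key] == pytest.approx(oracle[key], abs=1e-4)

        observations = [obs(round(m, 1)) for m in list(oracle.values())[:3]]
        report = match_masses(hyps, observations, tolerance=0.2)
        matched = {m["observation"].mass for m in report.matches}
        oracle_matched = {o.mass for o in observations
                          if any(abs(o.mass - m) <= 0.2
                                 for m in oracle.values())}
        assert matched == oracle_matched


def test_full_scan_on_published_mass_list(toxin_chains):
    """The ion-trap native list resolves to the published assignments."""
    chains = [toxin_chains[k] for k in ("U2a", "U2b", "U2c")]
    native = [obs(5441.80, label="Ta-5438"), obs(5753.64, label="Ta-5750"),
              obs(5683.60, label="Ta-5680"), obs(5610.63, label="Ta-5608"),
              obs(2877.72, label="Ta-2875"), obs(5773.80, label="Ta-5773")]
    hyps, report = dimer_scan(chains, native, tolerance=3.5,
                              conventions=("chemical",))
    matched_labels = {m["observation"].label for m in report.matches}
    assert {"Ta-5438", "Ta-5608", "Ta-2875"} <= matched_labels
    assert any(o.label == "Ta-5773" for o in report.unexplained)
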