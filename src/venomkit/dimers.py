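"""Dimer hypothesis enumeration, mass matching and chemical verification.

Venom transcripts encoding chains with an odd number of cysteines cannot
close all their thiols intramolecularly and are therefore candidates for
covalent dimers.  This module enumerates homodimer/heterodimer hypotheses
over such chains, matches their theoretical masses to the native LC-MS mass
list, and then tests each matched hypothesis against reduced and
reduced/alkylated mass lists: on reduction a genuine dimer's native mass
disappears and its chain masses appear; on alkylation each chain shifts by
+57.02146 Da per cysteine, which independently counts the cysteines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .chem import (
    Assembly,
    Convention,
    PeptideChain,
    alkylated_mass,
    assembly_mass,
    reduced_chain_masses,
)

__all__ = [
    "MassObservation",
    "DimerHypothesis",
    "MatchReport",
    "select_dimer_candidates",
    "enumerate_assemblies",
    "match_masses",
    "verify_by_reduction",
    "verify_by_alkylation",
    "dimer_scan",
]

Condition = Literal["native", "reduced", "alkylated"]
Status = Literal["unverified", "reduction_consistent", "fully_verified", "contradicted"]

# forward-only ordering of verification states
_STATUS_RANK = {"unverified": 0, "reduction_consistent": 1,
                "fully_verified": 2, "contradicted": 2}

CARBAMIDOMETHYL = 57.02146


@dataclass(frozen=True)
class MassObservation:
    """One deconvoluted neutral mass from an LC-MS run."""

    mass: float
    condition: Condition
    retention_time: Optional[float] = None
    peak_area: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("observed mass must be positive")
        if self.condition not in ("native", "reduced", "alkylated"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.peak_area is not None and self.peak_area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass
class DimerHypothesis:
    """A candidate assembly with its theoretical mass and verification state.

    ``topology_ambiguous`` flags assemblies whose total bond count admits
    more than one interchain/intrachain split (e.g. two 3-Cys chains can be
    joined by three interchain bonds or one interchain plus two intrachain
    bonds — same mass either way).
    """

    assembly: Assembly
    theoretical_mass: float
    matched_observation: Optional[MassObservation] = None
    mass_error: Optional[float] = None
    verification_status: Status = "unverified"
    topology_ambiguous: bool = False

    def advance(self, status: Status) -> None:
        """Move the verification state forward; never backwards."""
        if _STATUS_RANK[status] < _STATUS_RANK[self.verification_status]:
            raise ValueError(
                f"cannot move from {self.verification_status} back to {status}")
        self.verification_status = status


def select_dimer_candidates(chains: Sequence[PeptideChain]) -> list[PeptideChain]:
    """Chains with an odd cysteine count, in input order.

    An odd number of thiols cannot be fully paired within one chain, so at
    least one cysteine must bond intermolecularly (or stay free) — the
    transcriptomic signature that first suggests dimers.
    """
    return [c for c in chains if c.cysteine_count % 2 == 1]


def _pairing(ca: int, cb: int) -> tuple[int, int, bool]:
    """Max-pairing bond counts for a two-chain assembly.

    Returns (interchain, intrachain, ambiguous): total bonds pair as many
    cysteines as possible with at least one interchain bond; ambiguous when
    several interchain/intrachain splits achieve that total.
    """
    total = (ca + cb) // 2
    # interchain count must leave an even number of cysteines on each chain
    feasible = [i for i in range(1, min(ca, cb) + 1)
                if (ca - i) % 2 == 0 and (cb - i) % 2 == 0
                and (ca - i) // 2 + (cb - i) // 2 + i == total]
    if not feasible:
        raise ValueError(
            f"chains with {ca} and {cb} cysteines admit no interchain pairing")
    inter = min(feasible)
    intra = total - inter
    return inter, intra, len(feasible) > 1


def enumerate_assemblies(
    candidates: Sequence[PeptideChain],
    conventions: Iterable[Convention] = ("chemical",),
    include_monomers: bool = False,
) -> list[DimerHypothesis]:
    """All homodimer and heterodimer hypotheses over the candidate chains.

    For n candidates this yields n homodimers and n(n-1)/2 heterodimers per
    convention; with ``include_monomers`` each chain is additionally emitted
    as a free monomer (species can occur both free and dimerized).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate chain")
    hypotheses: list[DimerHypothesis] = []
    for convention in conventions:
        if include_monomers:
            for c in candidates:
                asm = Assembly(chains=(c,), convention=convention,
                               name=c.name or c.sequence[:8])
                hypotheses.append(DimerHypothesis(
                    assembly=asm, theoretical_mass=assembly_mass(asm)))
        for a, b in itertools.combinations_with_replacement(candidates, 2):
            inter, intra, ambiguous = _pairing(a.cysteine_count, b.cysteine_count)
            kind = "homodimer" if a is b else "heterodimer"
            asm = Assembly(
                chains=(a, b), interchain_bonds=inter, intrachain_bonds=intra,
                convention=convention,
                name=f"{a.name or a.sequence[:8]}/{b.name or b.sequence[:8]} {kind}")
            hypotheses.append(DimerHypothesis(
                assembly=asm, theoretical_mass=assembly_mass(asm),
                topology_ambiguous=ambiguous))
    return hypotheses


@dataclass
class MatchReport:
    """Outcome of matching hypotheses against a native mass list.

    Every native observation appears exactly once: either under ``matches``
    (with its best hypothesis first) or under ``unexplained``.
    """

    matches: list[dict] = field(default_factory=list)
    unexplained: list[MassObservation] = field(default_factory=list)
    unmatched_hypotheses: list[DimerHypothesis] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        rows = []
        for m in self.matches:
            for rank, (hyp, err) in enumerate(m["hypotheses"]):
                rows.append({
                    "observed_mass": m["observation"].mass,
                    "observation_label": m["observation"].label,
                    "hypothesis": hyp.assembly.name,
                    "theoretical_mass": hyp.theoretical_mass,
                    "error_da": err,
                    "error_ppm": 1e6 * err / hyp.theoretical_mass,
                    "rank": rank,
                    "status": hyp.verification_status,
                })
        for obs in self.unexplained:
            rows.append({
                "observed_mass": obs.mass, "observation_label": obs.label,
                "hypothesis": None, "theoretical_mass": None,
                "error_da": None, "error_ppm": None, "rank": None,
                "status": "unexplained",
            })
        return rows


def match_masses(
    hypotheses: Sequence[DimerHypothesis],
    observations: Sequence[MassObservation],
    tolerance: float,
) -> MatchReport:
    """Match theoretical masses to native observations within ``tolerance`` Da.

    All hypotheses within tolerance of an observation are recorded, ordered
    by absolute error then theoretical mass (deterministic ties); the best
    one is stored on the hypothesis as its matched observation.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    for obs in observations:
        if obs.condition != "native":
            raise ValueError(
                f"match_masses expects native observations, got "
                f"{obs.condition!r} ({obs.label or obs.mass})")
    report = MatchReport()
    matched_ids: set[int] = set()
    for obs in observations:
        within = []
        for hyp in hypotheses:
            err = obs.mass - hyp.theoretical_mass
            if abs(err) <= tolerance:
                within.append((hyp, err))
        within.sort(key=lambda he: (abs(he[1]), he[0].theoretical_mass))
        if within:
            report.matches.append({"observation": obs, "hypotheses": within})
            for hyp, err in within:
                matched_ids.add(id(hyp))
                # keep the best (smallest |error|) observation per hypothesis
                if hyp.mass_error is None or abs(err) < abs(hyp.mass_error):
                    hyp.matched_observation = obs
                    hyp.mass_error = err
        else:
            report.unexplained.append(obs)
    report.unmatched_hypotheses = [h for h in hypotheses
                                   if id(h) not in matched_ids]
    return report


def _present(mass: float, observations: Sequence[MassObservation],
             tolerance: float) -> bool:
    return any(abs(o.mass - mass) <= tolerance for o in observations)


def verify_by_reduction(
    hypothesis: DimerHypothesis,
    reduced_observations: Sequence[MassObservation],
    tolerance: float,
) -> Status:
    """Check a matched hypothesis against the DTT-reduced mass list.

    A dimer is reduction-consistent when every constituent chain mass is
    observed in the reduced list and the native mass has disappeared; a
    persisting native mass contradicts the dimer.  A monomer without
    intrachain bonds must persist unchanged.  An empty reduced list leaves
    the hypothesis unverified.
    """
    if hypothesis.matched_observation is None:
        raise ValueError("hypothesis must be matched to a native observation first")
    if not reduced_observations:
        return hypothesis.verification_status
    native_mass = hypothesis.matched_observation.mass
    if not hypothesis.assembly.is_dimer and hypothesis.assembly.total_bonds == 0:
        status: Status = ("reduction_consistent"
                          if _present(native_mass, reduced_observations, tolerance)
                          else "contradicted")
        hypothesis.advance(status)
        return status
    chain_masses = reduced_chain_masses(hypothesis.assembly)
    chains_seen = all(_present(m, reduced_observations, tolerance)
                      for m in chain_masses)
    native_gone = not _present(native_mass, reduced_observations, tolerance)
    if not native_gone:
        hypothesis.advance("contradicted")
    elif chains_seen:
        hypothesis.advance("reduction_consistent")
    return hypothesis.verification_status


def verify_by_alkylation(
    hypothesis: DimerHypothesis,
    alkylated_observations: Sequence[MassObservation],
    tolerance: float,
) -> Status:
    """Check a reduction-consistent hypothesis against the alkylated list.

    Each reduced chain must appear shifted by +57.02146 Da per cysteine;
    the implied cysteine count (shift / 57.02146, rounded) must equal the
    sequence's count.  A shift not within 0.25 Da of an integer multiple of
    the carbamidomethyl delta contradicts the hypothesis.
    """
    if hypothesis.verification_status != "reduction_consistent":
        raise ValueError("hypothesis must be reduction_consistent before "
                         "alkylation verification")
    all_chains_ok = True
    for chain in hypothesis.assembly.chains:
        from .chem import chain_mass  # local to avoid cycle at import time
        reduced = chain_mass(chain)
        expected = alkylated_mass(chain)
        n_cys = chain.cysteine_count
        # search window: shifts up to one extra cap beyond the cysteine count
        window = CARBAMIDOMETHYL * (n_cys + 1) + 2.0
        in_window = [o for o in alkylated_observations
                     if -tolerance <= o.mass - reduced <= window]
        if not in_window:
            all_chains_ok = False
            continue
        best = min(in_window, key=lambda o: abs(o.mass - expected))
        shift = best.mass - reduced
        k = round(shift / CARBAMIDOMETHYL)
        if abs(shift - k * CARBAMIDOMETHYL) > 0.25:
            hypothesis.advance("contradicted")
            return hypothesis.verification_status
        if abs(best.mass - expected) <= tolerance and k == n_cys:
            continue
        if k != n_cys:
            hypothesis.advance("contradicted")
            return hypothesis.verification_status
        all_chains_ok = False
    if all_chains_ok:
        hypothesis.advance("fully_verified")
    return hypothesis.verification_status


def dimer_scan(
    chains: Sequence[PeptideChain],
    native: Sequence[MassObservation],
    reduced: Sequence[MassObservation] = (),
    alkylated: Sequence[MassObservation] = (),
    tolerance: float = 0.5,
    conventions: Iterable[Convention] = ("chemical",),
    include_monomers: bool = True,
) -> tuple[list[DimerHypothesis], MatchReport]:
    """Full candidate → enumerate → match → verify pipeline over mass lists."""
    candidates = select_dimer_candidates(chains)
    monomer_only = [c for c in chains if c not in candidates]
    hypotheses = (enumerate_assemblies(candidates, conventions,
                                       include_monomers=include_monomers)
                  if candidates else [])
    if include_monomers:
        for c in monomer_only:
            asm = Assembly(chains=(c,), convention="chemical",
                           name=c.name or c.sequence[:8])
            hypotheses.append(DimerHypothesis(
                assembly=asm, theoretical_mass=assembly_mass(asm)))
    report = match_masses(hypotheses, native, tolerance)
    for hyp in hypotheses:
        if hyp.matched_observation is None:
            continue
        verify_by_reduction(hyp, reduced, tolerance)
        if hyp.verification_status == "reduction_consistent" and alkylated:
            verify_by_alkylation(hyp, alkylated, tolerance)
    return hypotheses, report
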