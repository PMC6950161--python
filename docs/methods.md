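# Methods

## Mass model

A peptide chain's neutral monoisotopic (or average) mass is the sum of its
residue masses plus one water, with modification deltas applied on top:
C-terminal amidation −0.98402 Da, methionine oxidation +15.99491 Da,
pyroglutamate −18.01056 Da, and carbamidomethylation +57.02146 Da per
cysteine. Residue masses are the standard monoisotopic and average tables;
isoleucine and leucine share a mass but remain distinct codes — no
mass-based merging happens at this layer. Masses are kept unrounded
internally and rounded (2 dp) only at presentation.

An assembly is one or two chains plus a disulfide-bond count. Under the
default **chemical** convention each cystine bridge removes two hydrogens
(2 × 1.0078250 Da); the **additive** convention ignores bonds and returns
the plain chain sum. Both are exposed because published dimer masses for
this system mix the conventions: the 3-bond and the single-bond Ta1c
homodimers follow the chemical arithmetic while the Ta1a homodimer and the
heterodimer values are plain doublings/sums. The package does not decide
which was intended; the convention is a parameter and the 2.016 Da/bond gap
between the two is surfaced rather than absorbed.

## Dimer inference

Chains with an odd cysteine count (one, three, …) cannot close all thiols
intramolecularly; these are the dimer candidates. For *n* candidates the
scan enumerates *n* homodimers and *n(n−1)/2* heterodimers (monomer
hypotheses are also emitted by default, since a chain can occur both free
and dimerized). Bond counts pair the maximum number of cysteines with at
least one interchain bond; when several interchain/intrachain splits
achieve the same total (two 3-Cys chains: 3 interchain, or 1 + 2
intrachain) the hypothesis is flagged topology-ambiguous — the masses are
identical and MS1 data cannot resolve the split.

Matching accepts a hypothesis–observation pair when |Δm| ≤ tolerance; ties
are ordered by |Δm| then theoretical mass so reports are reproducible.
Default tolerances: 0.05 Da for calculated-vs-calculated comparisons,
0.02 Da for Orbitrap-grade observations, 3.5 Da for ion-trap-grade
observations (published low-resolution masses deviate from the calculated
values by up to ~3.2 Da). Verification is a forward-only state machine
(unverified → reduction_consistent → fully_verified, or → contradicted):

- **Reduction:** a dimer is consistent when every constituent chain mass is
  present in the reduced list and the native mass is absent; a persisting
  native mass contradicts it. A monomer without intrachain bonds must
  persist. An empty reduced list leaves the state unchanged.
- **Alkylation:** each chain must reappear shifted by +57.02146 Da per
  cysteine. The observed shift divided by 57.02146, rounded, must equal the
  sequence's cysteine count; a shift more than 0.25 Da away from any
  integer multiple contradicts the hypothesis. Observations are searched
  within one extra carbamidomethyl unit beyond the expected shift, so an
  unrelated distant peak is not misread as a contradiction.

## Transcript mining

Contigs are translated in six frames under the standard genetic code
(stops rendered `*`, N-containing codons `X`, trailing partial codons
dropped). ORF extraction is stop-to-stop with no start-codon requirement:
assemblies of venom-gland transcriptomes are frequently overextended and
precursors can sit mid-contig, so anchoring on ATG would lose real
precursors. De novo tags are filtered on their ALC score (tags at or above
the threshold are kept; default 60%) and located by exact substring search
with I and L interchangeable by default; a scored-mismatch mode (≤ *k*
mismatches) exists behind a flag. Gapped alignment is deliberately not
used: tags are short and high-confidence, and exact/I-L-tolerant matching
is sufficient and much easier to reason about.

Precursor segmentation requires a declared cleavage rule — an explicit cut
position, a mature-sequence anchor, or a motif — rather than a signal
peptide predictor; there is no testable description of the prediction step
to reimplement, and a declared rule keeps the segmentation auditable. A
glycine immediately following the mature span is flagged as the standard
C-terminal amidation donor (a heuristic, overridable). Consensus over an
aligned block emits the residue exceeding the majority threshold
(default 0.6 of non-gap rows) per column, else `X`; columns where gaps are
the majority are dropped.

## Quantification

RPM(peptide) = Σ over encoding contigs of aligned reads ÷ (total aligned
reads / 10⁶). No length normalization (this is not TPM): peptide ORFs on
overextended contigs would be systematically understated. Read counts are
used as provided — whether the upstream aligner counted reads or pairs is
the caller's bookkeeping, not re-interpreted here. Relative abundance is
100 × area ÷ Σ areas over the quantified peptides; peptides declared
trace-level carry a null abundance and are excluded from the 100%
normalization.

## Physicochemical annotation

Net charge is the Henderson–Hasselbalch sum over the N-terminus, the
C-terminus (suppressed when amidated) and the D, E, C, Y, H, K, R side
chains. Three pKa tables ship: `lehninger` (classic textbook constants,
N-term 9.69 — the behaviour of the simple peptide-property calculators),
`bjellqvist` (residue-specific terminal pKa values, the table behind the
common pI servers) and `emboss`. The two quantities default to different
tables because the reference values they are checked against come from
different tools: net charge defaults to `lehninger`, pI to `bjellqvist`.

Assembly charge is the exact sum of its chains' charges, so a homodimer is
exactly twice its monomer. Cysteines are scored as free thiols by default —
at pH 7 a thiol contributes under 0.05 e, and the tables this reproduces
were computed that way; `exclude_bonded_cys=True` removes bridged
cysteines from the ionizable set for the chemically strict reading.

The pI is found by bisection on the charge function (strictly decreasing
in pH, so the zero is unique), to |charge| < 1e−4. The default convention
scores the bare sequence — free termini, free cysteines, and an assembly
as the concatenation of its chains with a single pair of termini — because
that is how the ubiquitous web calculators behave and how the reference
pI values were produced; `convention="as_modified"` honours amidation and
bond state instead (for an amidated acidic peptide the two can differ by
~0.5 pH).

Percent identity scores equal-length pairs positionally; unequal lengths
are globally aligned (match +1, mismatch 0, gap open −1, extend −0.5) and
identity is matches over alignment length. The hydrophobic set is
{A, C, F, I, L, M, V, W, Y}; it reproduces all six distinct published
hydrophobic percentages for this system simultaneously.

## Synthetic data

The generator emulates the structure of a venom-gland study without any
external data. Precursors share a conserved 56-residue signal+prepro
template carrying a handful of point mutations each (family drift);
mature regions are random 22–33-mers with a cationic bias (venom peptides
of this kind are polycationic), about half amidated via a trailing glycine
donor. Three of the default six precursors carry an odd cysteine count
(1, 1, 3) and are paired into one heterodimer and one 3-bond homodimer.
Coding sequences are reverse-translated with random codons, embedded in
contigs with random UTRs, and roughly every third peptide is split across
two contigs to exercise RPM summation. Read counts are multinomial over a
Dirichlet expression profile with one dominant species, mirroring the
strongly skewed composition of defensive venoms.

Mass lists: native = free-monomer plus assembly masses with Gaussian noise
(default σ 0.02 Da, Orbitrap-like; 1.5 Da emulates ion-trap data) plus
uniform decoy masses kept ≥ 1 Da from every true mass; reduced = chain
masses with dimer natives absent; alkylated = chain masses + 57.02146 per
cysteine. Peak areas follow a dominant-species Dirichlet. Mature sequences
are resampled until all chain and hypothesis masses are ≥ 1.5 Da apart, so
matching at ≤ 0.5 Da tolerance is unambiguous by construction — the
generator models a resolvable peptidome, not co-eluting isobars.

What the synthetic data does *not* model: isotope envelopes, charge-state
deconvolution errors, chromatographic co-elution, sequence errors in de
novo tags, or assembly chimerism. Passing the round-trip therefore shows
the pipeline's logic is sound under clean-but-noisy inputs, not that it is
robust to every artefact of real instruments.

The end-to-end recovery pipeline chooses the prepro/mature cleavage by
mass verification: candidate matures (ending at the ORF end or before a
terminal glycine, starting at or before the first tag hit, at most 60
residues) are accepted when the reduced chain mass *and* the alkylated
mass both match observations; the candidate with the smallest combined
error wins. Requiring both lists agrees with how cysteine counts are
established experimentally and makes a coincidental single-mass collision
insufficient.

## Problem sizes and determinism

Default simulations use 6 precursors, ~10–14 contigs and 10⁶ aligned
reads; the full simulate-and-recover round trip runs in well under a
second, and the 20-seed recovery experiment in the test suite completes in
a few seconds. Every random draw flows from a single integer seed through
one generator, so identical seeds give byte-identical FASTA/CSV output.

## Known limitations

- Disulfide connectivity (which cysteine pairs with which) is not
  resolved; only bond counts and topology ambiguity are reported.
- Observed masses are assumed already deconvoluted to neutral monoisotopic
  (or average) values; no raw-spectrum processing.
- The amidation-donor glycine rule is a heuristic; non-canonical
  processing would need an explicit cleavage rule.
- Published low-resolution values force a wide (3.5 Da) matching tolerance
  under which nearby hypotheses can tie; ties are reported, not hidden.
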