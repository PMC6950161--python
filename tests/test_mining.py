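"""Transcript mining: translation, ORFs, tags, segmentation, consensus."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from venomkit.mining import (
    Contig,
    SequenceTag,
    consensus_sequence,
    extract_orfs,
    match_tags,
    segment_precursor,
    six_frame_translate,
)

nucleotides = st.text(alphabet="ACGT", min_size=6, max_size=120)


class TestTranslation:
    def test_standard_code_frame_one(self):
        frames = six_frame_translate(Contig("c", "ATGGCT"))
        assert frames[1] == "MA"

    def test_stops_rendered_as_sentinel(self):
        frames = six_frame_translate(Contig("c", "ATGTAAGCT"))
        assert frames[1] == "M*A"

    def test_n_codon_translates_to_unknown(self):
        frames = six_frame_translate(Contig("c", "ATGANT"))
        assert frames[1] == "MX"

    def test_trailing_partial_codon_dropped(self):
        frames = six_frame_translate(Contig("c", "ATGGCTA"))
        assert frames[1] == "MA"

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            Contig("c", "ATGZCT")

    @given(seq=nucleotides)
    def test_reverse_frames_equal_forward_frames_of_revcomp(self, seq):
        from Bio.Seq import Seq
        rc = str(Seq(seq).reverse_complement())
        fwd_of_rc = six_frame_translate(Contig("a", rc))
        rev = six_frame_translate(Contig("b", seq))
        for f in (1, 2, 3):
            assert rev[-f] == fwd_of_rc[f]


class TestOrfExtraction:
    def test_stop_free_frame_is_one_orf(self):
        orfs = extract_orfs({1: "MAGLCPEPTLDE"})
        assert len(orfs) == 1
        assert orfs[0].sequence == "MAGLCPEPTLDE"

    def test_minimum_length_boundary(self):
        frames = {1: "A" * 99 + "*" + "A" * 100}
        orfs = extract_orfs(frames, min_length=100)
        assert [len(o.sequence) for o in orfs] == [100]

    def test_min_length_one_counts_segments(self):
        orfs = extract_orfs({1: "AA*G*CCC"}, min_length=1)
        assert len(orfs) == 3

    def test_coordinates_are_half_open_within_frame(self):
        (o1, o2) = extract_orfs({1: "AAA*GG"}, min_length=1)
        assert (o1.start, o1.end) == (0, 3)
        assert (o2.start, o2.end) == (4, 6)

    def test_planted_precursor_found_in_exactly_one_frame(self):
        from venomkit.synthetic import generate_transcriptome
        contigs, manifest = generate_transcriptome(n_precursors=2, seed=11,
                                                   read_depth=1000)
        p = manifest.precursors[0]
        contig = next(c for c in contigs if c.identifier == p.contig_ids[0])
        frames = six_frame_translate(contig)
        hits = [f for f, aa in frames.items() if p.full_sequence in aa]
        assert len(hits) == 1


class TestTagMatching:
    ORF_SEQ = "TLTNMSLREILEKLGIKIPPGLNI"

    def _orfs(self):
        return extract_orfs({1: self.ORF_SEQ})

    def test_tag_substring_matches(self):
        tags = [SequenceTag("GIKIPPGLN", 90.0)]
        matches = match_tags(tags, self._orfs())
        assert len(matches) == 1
        assert matches[0].offset == self.ORF_SEQ.index("GIKIPPGLN")

    def test_isoleucine_leucine_equivalence_toggle(self):
        tags = [SequenceTag("GLKLPPGLN", 90.0)]
        assert match_tags(tags, self._orfs(), il_equivalent=True)
        assert not match_tags(tags, self._orfs(), il_equivalent=False)

    def test_low_confidence_tag_discarded(self):
        tags = [SequenceTag("GIKIPPGLN", 59.0)]
        assert not match_tags(tags, self._orfs(), alc_threshold=60.0)

    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=12,
                       max_size=40))
    def test_strict_matches_subset_of_il_tolerant(self, seq):
        orfs = extract_orfs({1: seq})
        tags = [SequenceTag(seq[i:i + 6], 80.0)
                for i in range(0, len(seq) - 6, 3)]
        strict = {(m.tag.sequence, m.offset)
                  for m in match_tags(tags, orfs, il_equivalent=False)}
        tolerant = {(m.tag.sequence, m.offset)
                    for m in match_tags(tags, orfs, il_equivalent=True)}
        assert strict <= tolerant

    def test_single_mismatch_mode(self):
        tags = [SequenceTag("GIKIPPGAN", 90.0)]  # one mismatch vs ORF
        assert not match_tags(tags, self._orfs())
        assert match_tags(tags, self._orfs(), max_mismatches=1)


class TestSegmentation:
    PREPRO = "MKLSYLLLVLAVSFALAIVFA"
    MATURE = "DWKNTAKEWGKKVGEALLDAKQKM"

    def test_anchor_defines_mature_span_and_donor(self):
        orf = self.PREPRO + self.MATURE + "G"
        model = segment_precursor(orf, self.MATURE, signal_end=10)
        assert model.mature_sequence == self.MATURE
        assert model.prepro_sequence == self.PREPRO[10:]
        assert model.amidation_donor

    def test_no_trailing_glycine_no_donor(self):
        orf = self.PREPRO + self.MATURE
        model = segment_precursor(orf, self.MATURE)
        assert not model.amidation_donor

    def test_cut_position_zero_rejected(self):
        with pytest.raises(ValueError, match="empty prepro"):
            segment_precursor(self.PREPRO + self.MATURE, 0)

    def test_absent_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            segment_precursor(self.PREPRO, "WWWWW")

    def test_motif_rule_cuts_after_match(self):
        orf = self.PREPRO + self.MATURE
        model = segment_precursor(orf, re.compile("IVFA"))
        assert model.mature_sequence == self.MATURE

    def test_explicit_position_rule(self):
        orf = self.PREPRO + self.MATURE
        model = segment_precursor(orf, len(self.PREPRO))
        assert model.mature_sequence == self.MATURE


class TestConsensus:
    def test_identical_rows_returned_verbatim(self):
        assert consensus_sequence(["MADAEP"] * 4) == "MADAEP"

    def test_majority_threshold_fraction(self):
        block = ["A", "A", "G"]
        assert consensus_sequence(block, majority_threshold=0.6) == "A"
        assert consensus_sequence(block, majority_threshold=0.7) == "X"

    def test_gap_majority_column_dropped(self):
        block = ["A-K", "A-K", "AGK"]
        assert consensus_sequence(block) == "AK"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            consensus_sequence(["AAA", "AA"])

    def test_mutated_columns_become_wildcards(self):
        """Columns mutated across rows (no majority) read X, others verbatim."""
        rng = np.random.default_rng(3)
        template = "MSVGMADAEPDALAESLANALADAEP"
        mutated_cols = {4, 11, 19}
        rows = []
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for r in range(4):
            row = list(template)
            for cidx in mutated_cols:
                # every row gets a different residue at the mutated column
                row[cidx] = residues[(residues.index(template[cidx]) + 1 + r)
                                     % len(residues)]
            rows.append("".join(row))
        cons = consensus_sequence(rows, majority_threshold=0.6)
        for i, aa in enumerate(cons):
            assert aa == ("X" if i in mutated_cols else template[i])


def test_planted_mature_recovered_by_tags_and_segmentation():
    """Tags locate the precursor ORF; anchor segmentation yields the mature."""
    from venomkit.synthetic import generate_tags, generate_transcriptome

    for seed in range(20):
        contigs, manifest = generate_transcriptome(n_precursors=3, seed=seed,
                                                   read_depth=1000)
        tags = generate_tags(manifest, seed=seed)
        for p in manifest.precursors:
            contig = next(c for c in contigs if c.identifier == p.contig_ids[0])
            orfs = extract_orfs(six_frame_translate(contig), min_length=20,
                                contig_id=contig.identifier)
            hits = match_tags(tags, orfs, alc_threshold=60.0)
            assert any(p.full_sequence in m.orf.sequence for m in hits)
            orf = next(m.orf for m in hits if p.full_sequence in m.orf.sequence)
            model = segment_precursor(orf.sequence, p.mature)
            assert model.mature_sequence == p.mature
            assert model.amidation_donor == p.amidated
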