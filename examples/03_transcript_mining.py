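"""Transcript mining: six-frame translation, tags, segmentation, consensus.

Builds a small synthetic venom-gland transcriptome, translates a contig in
six frames, locates the precursor via a de novo sequence tag, cleaves it at
the declared prepro/mature boundary, and summarizes mutated prepro regions
as a majority consensus (ambiguous columns read X).
"""

from venomkit import (SequenceTag, consensus_sequence, extract_orfs,
                      match_tags, segment_precursor, six_frame_translate)
from venomkit.synthetic import generate_tags, generate_transcriptome

contigs, manifest = generate_transcriptome(n_precursors=3, seed=42,
                                           read_depth=100_000)
p = manifest.precursors[0]
contig = next(c for c in contigs if c.identifier == p.contig_ids[0])

frames = six_frame_translate(contig)
orfs = extract_orfs(frames, min_length=20, contig_id=contig.identifier)
print(f"{contig.identifier}: {len(orfs)} ORFs >= 20 aa across 6 frames")

tags = generate_tags(manifest, seed=42)
hits = match_tags(tags, orfs, alc_threshold=60.0, il_equivalent=True)
orf = next(m.orf for m in hits if p.full_sequence in m.orf.sequence)
print(f"tag hits locate the precursor in frame {orf.frame:+d}")

model = segment_precursor(orf.sequence, p.mature, signal_end=p.signal_end)
print("mature peptide:", model.mature_sequence)
print("amidation donor glycine follows the mature end:",
      model.amidation_donor)

prepros = [q.full_sequence[:q.cleavage_position] for q in manifest.precursors]
print("prepro consensus:", consensus_sequence(prepros,
                                              majority_threshold=0.6))
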