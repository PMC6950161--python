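"""Transcript RPM and peptide relative peak-area abundance.

RPM divides a contig's aligned reads by the total aligned reads in
millions and sums over the contigs encoding a peptide — deliberately not
TPM, since overextended contigs would understate short peptide
transcripts.  Relative abundance is each peptide's integrated LC-MS peak
area as a percent of all integrated areas; trace-level peptides are
reported but excluded from the normalization.
"""

from venomkit import relative_abundance, rpm

counts = {"contig_001": 300_000, "contig_002": 200_000, "contig_003": 90_000}
mapping = {"toxin-A": ["contig_001", "contig_002"],  # split over 2 contigs
           "toxin-B": ["contig_003"]}
rpms = rpm(counts, total_aligned_reads=4_000_000, peptide_to_contigs=mapping)
for peptide, value in rpms.items():
    print(f"{peptide}: {value:,.0f} RPM")

areas = {"toxin-A": 8.2e6, "toxin-B": 3.1e6, "toxin-C": 1.1e6,
         "toxin-D": 2.0e5}
rel = relative_abundance(areas, trace=["toxin-D"])
for peptide, pct in rel.items():
    shown = "trace" if pct is None else f"{pct:.2f} %"
    print(f"{peptide}: {shown}")
print("(the percentages of the quantified peptides sum to 100)")
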