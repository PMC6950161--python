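"""Dimer inference from candidate chains and an ion-trap mass list.

The three odd-cysteine chains of the T. aethiops venom are enumerated into
homo/heterodimer hypotheses and matched to the low-resolution native LC-MS
mass list at 3.5 Da tolerance; reduction and alkylation lists then verify
the matched hypotheses.  Masses the transcripts cannot explain are listed
as unexplained.
"""

from venomkit import MassObservation, PeptideChain, dimer_scan

chains = [
    PeptideChain("DWKNTAKEWGKKVGEALLDCAKQKM", c_terminal_amidated=True,
                 name="Ta1a"),
    PeptideChain("DWKGGAKDCAKKGAQCVLECVQQKM", c_terminal_amidated=True,
                 name="Ta1b"),
    PeptideChain("DWTDTAKEWGRKVGGALLDCAKQKM", c_terminal_amidated=True,
                 name="Ta1c"),
]

native = [MassObservation(m, "native", label=lbl) for m, lbl in [
    (2877.72, "Ta-2875"), (5441.80, "Ta-5438"), (5610.63, "Ta-5608"),
    (5773.80, "Ta-5773")]]
reduced = [MassObservation(m, "reduced") for m in (2875.47, 2805.39, 2722.32)]
alkylated = [MassObservation(m, "alkylated")
             for m in (2932.50, 2862.43, 2893.38)]

hypotheses, report = dimer_scan(chains, native, reduced, alkylated,
                                tolerance=3.5)
for h in hypotheses:
    obs = "-" if h.matched_observation is None else h.matched_observation.label
    print(f"{h.assembly.name:28s} {h.theoretical_mass:9.2f} Da  "
          f"matched={obs:8s} status={h.verification_status}")
print("unexplained:", [o.label for o in report.unexplained],
      "- observed masses no transcript-derived hypothesis accounts for")
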