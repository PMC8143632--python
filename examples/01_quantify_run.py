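"""Distributed spectral counts and dNSAF for one AP-MS run.

Two proteins share a peptide; its 4 spectra are split 3:1 according to the
proteins' unique counts, and dNSAF then corrects for protein length.
"""

from apmskit.io import PeptideEvidence, ProteinDatabase, ProteinRecord
from apmskit.quant import quantify_run

proteins = ProteinDatabase([
    ProteinRecord("SCAF", "MKVLAEGHTSWQ" * 25),   # 300 residues
    ProteinRecord("PARTNER", "MAGKLEVHTSWQ" * 8 + "MKVR"),  # 100 residues
])

evidence = [
    PeptideEvidence("run1", "LVEYK", 6, frozenset({"SCAF"})),
    PeptideEvidence("run1", "AGHTR", 2, frozenset({"PARTNER"})),
    PeptideEvidence("run1", "SHAREDK", 4, frozenset({"SCAF", "PARTNER"})),
]

run = quantify_run(evidence, proteins)
print(run.table.round(4))
print()
print("The shared peptide's 4 counts split 3:1 by unique evidence, giving")
print("distributed totals 9 and 3; equal dNSAF values (0.5 each) show the")
print("length normalization: 9 counts over 300 residues equal 3 over 100.")
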