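"""Consensus-filter novel allele candidates across detection tools.

Classifies two datasets by isotype composition, applies the class-specific
multi-tool voting rule, and classifies each retained candidate's SNP as
replacement or silent by antibody region.
"""

import igsim
from igsim.consensus import ToolCallSet, rs_classify

igm = igsim.IsotypeProfile(
    counts={"IgM": 70, "IgD": 10, "IgG": 20}, total_clones=100, assigned_clones=95
)
igg = igsim.IsotypeProfile(
    counts={"IgM": 20, "IgG": 60, "IgA": 20}, total_clones=100, assigned_clones=90
)
print(f"dataset 1 class: {igsim.classify_dataset(igm).value}")
print(f"dataset 2 class: {igsim.classify_dataset(igg).value}")

db = igsim.generate_toy_germline(seed=1)
allele = db["IGHV1-S*01"]
nac = allele.sequence[:30]

calls = [
    ToolCallSet.from_sequences("TIgGER", [nac]),
    ToolCallSet.from_sequences("IMPre", [nac, "ACGTACGTACGT"]),
    ToolCallSet.from_sequences("Partis", ["ACGTACGTACGT"]),
]
retained_igm = igsim.filter_nacs(calls, igsim.classify_dataset(igm))
retained_igg = igsim.filter_nacs(calls, igsim.classify_dataset(igg))
print(f"retained under IgM rule: {len(retained_igm)} "
      "(TIgGER+IMPre suffices when TIgGER votes)")
print(f"retained under IgG rule: {len(retained_igg)} "
      "(IMPre votes ignored; no pair within TIgGER/IgDiscover/Partis)")

snp = igsim.SNPSpec(locus=90, ref=allele.sequence[89], alt="A" if allele.sequence[89] != "A" else "G")
cls, region = rs_classify(snp, allele)
print(f"SNP {igsim.snp_notation(snp)}: {cls} ({region})")
# R = the substitution changes the encoded amino acid; S = silent.  FR/CDR
# comes from the allele's framework/CDR interval annotations.
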