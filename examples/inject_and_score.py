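"""Inject artificial novel alleles and score detection calls against them.

Creates three novel-allele truths (3 SNPs each), then scores a synthetic
call set containing one perfect full-length call, one partial call that
covers all SNPs, one call with a stray mismatch, and one unrelated
sequence — at both the allele and SNP level.
"""

import igsim
from igsim.benchmark import AlleleCall, SNPCall, score

db = igsim.generate_toy_germline(seed=1)
targets = ["IGHV1-S*01", "IGHV2-S*01", "IGHV3-S*01"]
customized, truths = igsim.inject_artificial_snps(db, targets, n_snps=3, seed=5)
customized, removed = igsim.prune_confusable(customized, truths)
print(f"injected 3 SNPs into {len(truths)} alleles; pruned {len(removed)} confusable refs")

t0 = truths[0]
stray = list(t0.novel_sequence)
stray[150] = "A" if stray[150] != "A" else "C"
calls = [
    AlleleCall(t0.novel_sequence, tool="demo"),          # perfect: TP
    AlleleCall(truths[1].novel_sequence[:290], tool="demo"),  # partial: TP
    AlleleCall("".join(stray), tool="demo"),             # stray mismatch: FP
    AlleleCall("ACGT" * 70, tool="demo"),                # unrelated: FP
]
res = score(calls, truths, "allele")
print(f"allele level: sensitivity={res.sensitivity:.2f} specificity={res.specificity:.2f}")

snp_calls = [
    SNPCall(t.source_allele, s.locus, s.alt) for t in truths[:2] for s in t.snps
]
snp_calls.append(SNPCall(t0.source_allele, 279, "A"))  # wrong locus: FP
res_snp = score(snp_calls, truths, "SNP")
print(f"SNP level: sensitivity={res_snp.sensitivity:.2f} specificity={res_snp.specificity:.2f}")
# Sensitivity is the fraction of planted truths recovered; "specificity"
# (precision) is the fraction of reported calls that are genuine.
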