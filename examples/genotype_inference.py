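"""Infer a personal germline V genotype from annotated contigs.

Emulates a single-cell contig table for one heterozygous gene: a major
allele, a minor allele at ~30% of its support, truncated copies of the
major that must be merged, and rare junk that must be filtered.
"""

import numpy as np

import igsim

rng = np.random.default_rng(4)
major = "".join(rng.choice(list("ACGT"), 296))
minor = list(major)
minor[100] = "A" if major[100] != "A" else "G"
minor = "".join(minor)

contigs = (
    [igsim.AnnotatedContig(f"c{i}", "IGHV9-E*01", major) for i in range(136)]
    + [igsim.AnnotatedContig(f"m{i}", "IGHV9-E*01", minor) for i in range(44)]
    + [igsim.AnnotatedContig(f"t{i}", "IGHV9-E*01", major[6:]) for i in range(12)]
    + [igsim.AnnotatedContig("junk", "IGHV9-E*01", "".join(rng.choice(list("ACGT"), 296)))]
)

genotype = igsim.infer_genotype(contigs)
call = genotype["IGHV9-E"]
print(f"gene IGHV9-E: primary count {call.primary.count} "
      f"(136 full-length + 12 merged truncations)")
print(f"secondary count {call.secondary.count}, allele ratio {call.ratio:.2f}")
print(f"minor allele differs from major at locus 101: "
      f"{call.secondary.sequence[100]} vs {call.primary.sequence[100]}")
# The secondary allele is retained because 44 >= 148/10; the ratio is the
# minor/major supportive-contig quotient rounded half-up to 2 decimals.
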