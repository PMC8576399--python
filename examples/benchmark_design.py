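"""Expand benchmark designs into per-repertoire simulation configs.

Each design varies one property of the planted novel alleles across four
groups of five replicates (two groups for the SHM design): expression
tier, minor-allele ratio (with compensating read budgets), SNP count, or
SHM load.
"""

import igsim
from igsim.designs import SimulationConfig

base = SimulationConfig(seed=123, n_reads=100_000)

for name in ("DEXPR", "DALLELE", "DSNP", "DSHM"):
    configs = igsim.build_design(name, base)
    print(f"{name}: {len(configs)} repertoire configs")

dallele = igsim.build_design("DALLELE", base)
budgets = sorted({(c.minor_ratio, c.n_reads) for c in dallele})
for ratio, n_reads in budgets:
    print(f"  minor ratio {ratio:.2f} -> {n_reads} reads")
# Lower minor-allele ratios get proportionally more reads so every group's
# novel allele is supported by the same expected number of reads:
print("exact budget for the 30% group (millions, from a 0.1 M base):",
      f"{igsim.compute_read_budget(0.1, 0.50, 0.30):.4f}")
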