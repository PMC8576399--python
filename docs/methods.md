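# Methods

This note records the models implemented in `igsim`, the defaults and why
they were chosen, what the synthetic fixtures do and do not emulate, and
the numerical conventions a user should know before trusting a result.

## Rearrangement model

A rearrangement is fully determined by an allele triple and a junction
plan over ten entities (V3D, V3P, N1, D5D, D5P, D3D, D3P, N2, J5D, J5P).
Conventions:

- **P nucleotides** are modelled as the reverse complement of the
  terminal k bases of the adjacent segment end and can only occur where
  the paired deletion length is zero; a sampled plan with both a deletion
  and a P length at the same end is resolved by forcing the P length to
  zero. This follows standard immunogenetics usage of "palindromic"
  insertions at untrimmed coding ends.
- **N nucleotides** are uniform over A/C/G/T. Real N regions are
  TdT-biased toward G/C; the composition is a single sampling line and
  can be replaced, but uniformity is the default because none of the
  package's measured quantities depend on N composition.
- **Productivity** is defined as in-frame from V codon 1 with no stop
  codon over the whole sequence (AIRR convention). Exact productive
  counts (⌊n·f⌋) come from rejection sampling rather than per-record
  Bernoulli draws, so small simulations are exactly reproducible and the
  realized fraction never wobbles. Draws whose deletions would consume a
  short segment are redrawn; deletion lengths are therefore truncated
  only by rejection, never clamped.
- Usage draws are independent per segment. For a ratio-controlled gene
  the gene is drawn by its summed allele weight, then the allele by the
  configured ratio; only two alleles per controlled gene are supported.

## Maturation model

Lineages grow per root: each of `iterations` rounds selects
⌈`select_fraction`·pool⌉ members without replacement, mutates each
position independently with probability p(i)·`mut_ability_fold`, and adds
the mutants to the pool. Duplicate sequences are collapsed (earliest
parent kept), so pools are nonredundant; substitutions only, so length is
invariant and the parent distance equals the mutation count.

Defaults: `iterations=5`, `select_fraction=0.3`, power law `alpha=2`,
`max_size=50`. The bundled mutability profile emulates an end-repertoire
positional mutation-frequency estimate: baseline 3.2% per position with
smooth log-normal noise and threefold elevation inside CDR intervals
(profile mean ≈ 4.3%). Because such estimates aggregate several mutation
rounds, iterating them directly would hyper-mutate; the damping factor
`mut_ability_fold = 0.85` was calibrated once so that the default
pipeline yields a mean V-region mismatch rate of ≈ 6%, the SHM load
typical of class-switched (IgG) repertoires. The calibration constant
lives in `fixtures` (configuration), not in the algorithm.

Clone sizes are drawn from P(s) ∝ s^(−α) truncated to [1, `max_size`].
When `max_sequences` caps the output, whole members are dropped by random
permutation prefix (their sizes set to 0) rather than truncating sizes,
preserving the power-law shape of what remains.

`compute_shm_rate` compares each member against the *true source V
allele* over the root's templated V span (positions 1..v_end), so the
reported rate is a germline-mismatch fraction, not a parent-chain count.

## Read simulation

Reads sample source molecules proportional to clone-size weights. Mate 1
covers the 5′ end, mate 2 the reverse complement of the 3′ end; amplicons
shorter than the read length yield truncated mates (no padding policy).
The default per-cycle error profile rises linearly from 0.001 to 0.01 —
an explicit stand-in for MiSeq quality decay, fully overridable via TSV.
Qualities are deterministic per cycle (Q = −10·log₁₀ e, rounded,
Phred+33); only substitution errors are simulated, matching the
substitution-only scope of the whole pipeline (no INDELs anywhere).

## Novel-allele injection and scoring

Injection samples SNP loci uniformly *without* replacement within one
allele from [1, 280] — the 5′ window junctional trimming cannot reach —
and the new base uniformly from the three alternatives. The altered copy
keeps the public allele name; the untouched real sequence is the
rediscovery target. Truth SNPs are recorded detector-oriented: ref = base
in the customized reference, alt = base in the novel sequence, so the
notation (e.g. `G92A`) reads as "reference G, novel A". The same locus
may recur across different target alleles (independent draws).

`prune_confusable` removes any *other* reference allele strictly closer
(global unit-cost edit distance, via edlib) to a truth's novel sequence
than the altered source allele itself; ties are kept, and altered targets
are never removed. Without this step reads from the novel allele would
annotate to the competitor and the injection would be undetectable by
construction.

Allele-level scoring slides the called sequence ungapped along each
truth's novel sequence (edlib infix alignment for ranking; exact
substring search for the zero-mismatch decision). The best truth is the
one at minimal edit distance, ties broken by truth name. A call longer
than every candidate cannot be a mismatch-free infix and is scored FP
with a warning. Sensitivity counts distinct truths (a truth hit twice
counts once); each call is labelled on its own merits, so two calls
matching one truth are two TPs. "Specificity" follows the field's
benchmarking usage and is mathematically precision (TP / all calls); it
is reported as unavailable (None) when a tool makes no calls, never as
0/0.

## Genotype inference

Unique V-segment sequences are tallied per gene; shorter segments merge
into longer ones containing them with the same allele annotation
(longest-first, counts added, forward strand only); entries shorter than
290 bp or with fewer than 10 supporting contigs are discarded (strict
`<`); the top-count sequence per gene is the primary allele and the
runner-up is retained only at ≥ 1/10 of the primary's support. At most
two alleles are ever called per gene; count ties break lexicographically
by sequence. Ratios are rounded half-up to two decimals (`decimal`, not
banker's rounding) so printed ratios are stable.

## Consensus filtration

Datasets classify as SHM-sparse when IgM+IgD clones strictly outnumber
IgG+IgA+IgE clones, otherwise SHM-rich; classification requires a
constant-gene assignment for strictly more than half the clones. The
equal-counts tie falls to SHM-rich — a deliberate reading of the
"otherwise" rule, recorded here as this package's choice. Voting
identity across tools is exact normalized sequence equality (degenerate
IUPAC codes resolved first); tools reporting different-length fragments
of the same allele should be reconciled through the allele-level matcher
before voting. Cross-validation is exact full-sequence identity after
normalization; substrings do not count. Degenerate codes resolve to the
alphabetically first base they denote (R→A, Y→C, N→A, …) — the mapping
is arbitrary but deterministic, which is what cross-validation needs.

R/S classification translates the codon containing the SNP before and
after substitution (frame anchored at V position 1); the FR/CDR label
comes from the allele's region annotations. No IMGT-numbering engine is
implemented: fixtures carry plausible FR/CDR intervals, and real interval
maps can be supplied per allele.

## Synthetic fixtures: what they are and are not

The toy germline set packs V alleles two per gene (the second a
2-substitution variant of the first) so heterozygous-gene experiments
have realistic targets; V alleles are stop-free in frame 1 and 296 bp by
default (typical of full-length IGHV), D segments 12–16 bp, J segments
48 bp. The fixtures do **not** emulate: IMGT gaps and numbering, real
gene-usage skew, hotspot-motif (WRC/GYW) targeting, selection pressure,
INDEL novel alleles, light chains, or primer/adaptor artifacts. Tests
passing on fixtures therefore demonstrate the *mechanics* (bookkeeping,
distributional control, scoring definitions), not that simulated
repertoires are indistinguishable from real Ig-seq data.

## Problem sizes and numerical choices

Distribution-recovery checks run at 10⁵ draws (3 binomial σ bands),
SHM calibration checks at 2,000–10,000 roots, and the read-count
contract at 10⁴ plus one full 10⁶-pair run; these sizes give the
acceptance checks sub-minute runtimes while keeping Monte-Carlo error
well inside the asserted bands. Categorical sampling uses cumulative
arrays with `searchsorted` (exact, fast); all randomness flows from
`numpy.random.default_rng` seeds, with stage and replicate seeds derived
from a master seed via `SeedSequence.spawn` reduced to 31-bit words —
the same master seed reproduces every output byte-for-byte.

## Known limitations

- Junction-length distributions, mutability profile and substitution
  matrix default to synthetic stand-ins; quantitative realism requires
  supplying empirically estimated tables (TSV hooks exist for all four).
- The productive-fraction control conditions on productivity jointly, so
  per-gene usage among *productive-only* outputs can shift slightly if
  some alleles carry frame-hostile ends (not the case for the bundled
  fixtures).
- `merge_nested_segments` matches forward-strand containment only.
- Reported "specificity" is precision; users comparing against
  sensitivity/specificity in the ROC sense should rename accordingly.
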