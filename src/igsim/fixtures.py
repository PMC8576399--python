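"""Synthetic toy germline references and default parameter models.

Everything the simulator needs can be generated reproducibly from a seed:
a toy germline set (V alleles with open reading frames and FR/CDR region
annotations, short D segments, J segments), a junctional-modification
model, a positional mutability profile with elevated CDR rates, and a
uniform substitution matrix.  These fixtures stand in for licensed public
germline databases, which cannot be redistributed; real references can be
supplied as FASTA/TSV wherever a fixture is used.
"""

from __future__ import annotations

import numpy as np

from .germline import GermlineAllele, GermlineDatabase
from .maturation import MutabilityModel, SubstitutionModel
from .rearrange import JunctionModel

__all__ = [
    "generate_toy_germline",
    "default_junction_model",
    "default_mutability_model",
    "default_substitution_model",
    "TOY_V_REGIONS",
    "DEFAULT_MUT_ABILITY_FOLD",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

#: FR/CDR intervals (1-based, closed) used for all toy V alleles of the
#: default 296 bp length; loosely modelled on IMGT variable-domain layout.
TOY_V_REGIONS = {
    "FR1": (1, 78),
    "CDR1": (79, 114),
    "FR2": (115, 165),
    "CDR2": (166, 195),
    "FR3": (196, 296),
}

#: Default damping factor applied to the positional mutability profile so
#: that iterated maturation with the default settings (5 iterations, 0.3
#: selection fraction) lands near a 6% mean V-region mutation frequency.
#: Stored here as configuration, not inside the maturation algorithm.
DEFAULT_MUT_ABILITY_FOLD = 0.85


def _scale_regions(v_length: int) -> dict[str, tuple[int, int]]:
    if v_length == 296:
        return dict(TOY_V_REGIONS)
    regions = {}
    prev_end = 0
    labels = list(TOY_V_REGIONS)
    for i, label in enumerate(labels):
        start, end = TOY_V_REGIONS[label]
        new_end = v_length if i == len(labels) - 1 else round(end * v_length / 296)
        regions[label] = (prev_end + 1, max(prev_end + 1, new_end))
        prev_end = regions[label][1]
    return regions


def _random_orf(length: int, rng: np.random.Generator) -> str:
    """Random sequence of ``length`` bp with no stop codon in frame 1."""
    n_codons = -(-length // 3)
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_codons)
    return "".join(_SAFE_CODONS[i] for i in idx)[:length]


def _variant_without_stops(seq: str, n_diffs: int, rng: np.random.Generator) -> str:
    """A copy of ``seq`` differing at ``n_diffs`` positions, still stop-free."""
    for _ in range(200):
        out = list(seq)
        loci = rng.choice(len(seq), size=n_diffs, replace=False)
        for pos in loci:
            out[pos] = _BASES[(("ACGT".index(seq[pos])) + rng.integers(1, 4)) % 4]
        cand = "".join(out)
        codons = {cand[i: i + 3] for i in range(0, len(cand) - 2, 3)}
        if not (codons & _STOPS):
            return cand
    raise RuntimeError("could not build a stop-free allele variant")


def generate_toy_germline(
    n_v: int = 48,
    n_d: int = 5,
    n_j: int = 6,
    v_length: int = 296,
    seed: int = 0,
    pair_distance: int = 2,
) -> GermlineDatabase:
    """Generate a reproducible toy heavy-chain germline database.

    V alleles are packed two per gene (``IGHVk-S*01`` / ``IGHVk-S*02``,
    the second a ``pair_distance``-substitution variant of the first) so
    two-allele ratio experiments have heterozygous genes to work with.  V
    alleles translate without stop codons in frame 1 and carry FR/CDR
    region annotations; D segments are 12-16 bp, J segments 48 bp.
    """
    if min(n_v, n_d, n_j) < 1:
        raise ValueError("allele counts must be >= 1")
    if v_length < 290:
        raise ValueError("v_length must be >= 290")
    rng = np.random.default_rng(seed)
    regions = _scale_regions(v_length)
    db = GermlineDatabase()

    made = 0
    gene_idx = 0
    while made < n_v:
        gene_idx += 1
        base = _random_orf(v_length, rng)
        db.add(
            GermlineAllele(
                name=f"IGHV{gene_idx}-S*01",
                sequence=base,
                segment="V",
                regions=regions,
            )
        )
        made += 1
        if made < n_v:
            db.add(
                GermlineAllele(
                    name=f"IGHV{gene_idx}-S*02",
                    sequence=_variant_without_stops(base, pair_distance, rng),
                    segment="V",
                    regions=regions,
                )
            )
            made += 1

    for i in range(n_d):
        length = int(rng.integers(12, 17))
        seq = "".join(_BASES[k] for k in rng.integers(0, 4, size=length))
        db.add(GermlineAllele(name=f"IGHD{i + 1}-S*01", sequence=seq, segment="D"))

    for i in range(n_j):
        seq = _random_orf(48, rng)
        db.add(GermlineAllele(name=f"IGHJ{i + 1}-S*01", sequence=seq, segment="J"))
    return db


def default_junction_model() -> JunctionModel:
    """Junctional length pmfs with short geometric-tailed supports.

    Deletions decay geometrically from 0; N insertions peak at a few
    nucleotides; P insertions are short and rare, as in real junctions.
    """

    def geometric(max_len: int, p: float) -> dict[int, float]:
        probs = {k: (1 - p) ** k * p for k in range(max_len + 1)}
        total = sum(probs.values())
        return {k: v / total for k, v in probs.items()}

    pal = {0: 0.70, 1: 0.15, 2: 0.10, 3: 0.05}
    n_ins = {k: v for k, v in enumerate([0.10, 0.14, 0.17, 0.17, 0.14, 0.10, 0.08, 0.05, 0.03, 0.02])}
    return JunctionModel(
        {
            "V3D": geometric(6, 0.45),
            "V3P": dict(pal),
            "N1": dict(n_ins),
            "D5D": geometric(4, 0.5),
            "D5P": dict(pal),
            "D3D": geometric(4, 0.5),
            "D3P": dict(pal),
            "N2": dict(n_ins),
            "J5D": geometric(8, 0.4),
            "J5P": dict(pal),
        }
    )


def default_mutability_model(
    length: int = 360,
    mut_ability_fold: float = DEFAULT_MUT_ABILITY_FOLD,
    seed: int = 7,
    regions: dict[str, tuple[int, int]] | None = None,
) -> MutabilityModel:
    """Smooth positional mutability profile with CDR-elevated rates.

    The profile emulates a positional mutation-frequency estimate from an
    end repertoire (sequences that have already completed maturation):
    baseline ~3.2% per position with smooth multiplicative noise, CDR
    intervals raised threefold since hypermutation concentrates in the
    antigen-binding loops.  Because such estimates aggregate several
    mutation rounds, the per-round probability is damped by
    ``mut_ability_fold``.
    """
    rng = np.random.default_rng(seed)
    base = 0.032
    noise = rng.normal(0, 1, size=length)
    kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(noise, kernel, mode="same")
    profile = base * np.exp(0.35 * smooth)
    for label, (start, end) in (regions or TOY_V_REGIONS).items():
        if label.upper().startswith("CDR"):
            hi = min(end, length)
            profile[start - 1: hi] *= 3.0
    return MutabilityModel(np.clip(profile, 0, 0.25), mut_ability_fold)


def default_substitution_model() -> SubstitutionModel:
    """Transition-biased substitution matrix (transitions twice as likely)."""
    m = np.zeros((4, 4))
    order = "ACGT"
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i == j:
                continue
            m[i, j] = 2.0 if (a, b) in transitions else 1.0
        m[i] /= m[i].sum()
    return SubstitutionModel(m)
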