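"""Independent V(D)J rearrangement simulation.

Rearrangements are assembled from one V, one D and one J germline segment
joined through two junctions.  Each junction is described by ten entities:
exonuclease deletion lengths (V3D, D5D, D3D, J5D), palindromic P-nucleotide
lengths on untrimmed ends (V3P, D5P, D3P, J5P) and nontemplated N-nucleotide
insertions (N1 between V and D, N2 between D and J).  Gene usage, a
two-allele ratio per heterozygous gene, junctional length distributions and
the productive fraction are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineAllele, GermlineDatabase

__all__ = [
    "UsageModel",
    "JunctionModel",
    "JunctionPlan",
    "Rearrangement",
    "sample_genes",
    "sample_junction",
    "assemble_rearrangement",
    "is_productive",
    "simulate_rearrangements",
    "JUNCTION_ENTITIES",
]

JUNCTION_ENTITIES = (
    "V3D", "V3P", "N1", "D5D", "D5P", "D3D", "D3P", "N2", "J5D", "J5P",
)

# Deletion entity paired with the P-nucleotide entity it suppresses:
# P nucleotides arise only on untrimmed coding ends.
_DELETION_SUPPRESSES = {"V3D": "V3P", "D5D": "D5P", "D3D": "D3P", "J5D": "J5P"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UsageModel:
    """Per-segment gene/allele usage with optional two-allele ratios.

    ``usage`` maps segment ("V"/"D"/"J") to {allele name: weight}; weights
    are normalized per segment.  ``allele_ratios`` maps a gene name to
    ``(allele1, allele2, ratio)`` where ``ratio`` is the fraction of that
    gene's rearrangements assigned ``allele2`` (the minor allele when
    ratio < 0.5).  Only two alleles per ratio-controlled gene are
    supported.
    """

    def __init__(
        self,
        usage: dict[str, dict[str, float]],
        allele_ratios: dict[str, tuple[str, str, float]] | None = None,
    ):
        self.allele_ratios = dict(allele_ratios or {})
        for gene, (a1, a2, ratio) in self.allele_ratios.items():
            if not (0 < ratio < 1):
                raise ValueError(f"allele ratio for {gene} must be in (0,1)")
            if a1.split("*")[0] != gene or a2.split("*")[0] != gene:
                raise ValueError(f"ratio alleles of {gene} must belong to it")
        self._items: dict[str, tuple[list[str], np.ndarray]] = {}
        self.usage = {}
        for segment, table in usage.items():
            if not table:
                raise ValueError(f"empty usage table for segment {segment}")
            if any(w < 0 for w in table.values()):
                raise ValueError("usage weights must be >= 0")
            total = float(sum(table.values()))
            if total <= 0:
                raise ValueError(f"usage weights for {segment} sum to zero")
            self.usage[segment] = {k: v / total for k, v in table.items()}
            # Collapse ratio-controlled allele pairs into one gene-level
            # item; the allele is then resolved by the ratio.
            items: dict[str, float] = {}
            for name, w in self.usage[segment].items():
                gene = name.split("*")[0]
                key = gene if gene in self.allele_ratios else name
                items[key] = items.get(key, 0.0) + w
            names = list(items)
            weights = np.array([items[n] for n in names])
            self._items[segment] = (names, np.cumsum(weights))

    def sample(self, segment: str, rng: np.random.Generator) -> str:
        names, cum = self._items[segment]
        pick = names[min(int(np.searchsorted(cum, rng.random(), side="right")), len(names) - 1)]
        if pick in self.allele_ratios:
            a1, a2, ratio = self.allele_ratios[pick]
            return a2 if rng.random() < ratio else a1
        return pick

    @classmethod
    def uniform(cls, db: GermlineDatabase) -> "UsageModel":
        """Equal usage over every allele in the database."""
        usage = {
            seg: {a.name: 1.0 for a in db.by_segment(seg)} for seg in "VDJ"
        }
        return cls(usage)

    @classmethod
    def from_tsv(cls, path, allele_ratios=None) -> "UsageModel":
        """Read a usage table with columns segment, allele, weight."""
        df = pd.read_csv(path, sep="\t")
        usage: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            usage.setdefault(row["segment"], {})[row["allele"]] = float(row["weight"])
        return cls(usage, allele_ratios)

    def to_tsv(self, path) -> None:
        rows = [
            {"segment": seg, "allele": a, "weight": w}
            for seg, table in self.usage.items()
            for a, w in table.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sample_genes(
    model: UsageModel, rng: np.random.Generator
) -> tuple[str, str, str]:
    """Draw a (V, D, J) allele triple, independent per segment."""
    return model.sample("V", rng), model.sample("D", rng), model.sample("J", rng)


class JunctionModel:
    """Ten pmfs over non-negative lengths, one per junction entity."""

    def __init__(self, pmfs: dict[str, dict[int, float]]):
        missing = set(JUNCTION_ENTITIES) - set(pmfs)
        if missing:
            raise ValueError(f"missing junction entities: {sorted(missing)}")
        self._support: dict[str, np.ndarray] = {}
        self._probs: dict[str, np.ndarray] = {}
        self.pmfs = {}
        for entity in JUNCTION_ENTITIES:
            pmf = pmfs[entity]
            lengths = np.array(sorted(pmf), dtype=int)
            if lengths.min() < 0:
                raise ValueError(f"{entity}: lengths must be >= 0")
            p = np.array([pmf[int(k)] for k in lengths], dtype=float)
            if p.min() < 0 or p.sum() <= 0:
                raise ValueError(f"{entity}: invalid pmf")
            p = p / p.sum()
            self.pmfs[entity] = dict(zip(lengths.tolist(), p.tolist()))
            self._support[entity] = lengths
            self._probs[entity] = p
            self._cum = {e: np.cumsum(self._probs[e]) for e in self._probs}

    def draw(self, entity: str, rng: np.random.Generator) -> int:
        support = self._support[entity]
        i = min(int(np.searchsorted(self._cum[entity], rng.random(), side="right")),
                support.size - 1)
        return int(support[i])

    @classmethod
    def all_zero(cls) -> "JunctionModel":
        return cls({e: {0: 1.0} for e in JUNCTION_ENTITIES})

    @classmethod
    def from_tsv(cls, path) -> "JunctionModel":
        """Read pmfs from a TSV with columns entity, length, probability."""
        df = pd.read_csv(path, sep="\t")
        pmfs: dict[str, dict[int, float]] = {}
        for _, row in df.iterrows():
            pmfs.setdefault(row["entity"], {})[int(row["length"])] = float(
                row["probability"]
            )
        return cls(pmfs)

    def to_tsv(self, path) -> None:
        rows = [
            {"entity": e, "length": l, "probability": p}
            for e in JUNCTION_ENTITIES
            for l, p in self.pmfs[e].items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class JunctionPlan:
    """Sampled junctional modification lengths plus N-nucleotide strings."""

    lengths: dict[str, int]
    n1: str
    n2: str

    def __post_init__(self):
        for deletion, pal in _DELETION_SUPPRESSES.items():
            if self.lengths[deletion] > 0 and self.lengths[pal] > 0:
                raise ValueError(
                    f"{pal} > 0 while {deletion} > 0: P nucleotides occur "
                    "only on untrimmed ends"
                )
        if len(self.n1) != self.lengths["N1"] or len(self.n2) != self.lengths["N2"]:
            raise ValueError("N string lengths disagree with plan lengths")


def sample_junction(model: JunctionModel, rng: np.random.Generator) -> JunctionPlan:
    """Draw one junction plan; a deletion > 0 forces its paired P to 0."""
    lengths = {e: model.draw(e, rng) for e in JUNCTION_ENTITIES}
    for deletion, pal in _DELETION_SUPPRESSES.items():
        if lengths[deletion] > 0:
            lengths[pal] = 0
    n1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=lengths["N1"]))
    n2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=lengths["N2"]))
    return JunctionPlan(lengths=lengths, n1=n1, n2=n2)


@dataclass(frozen=True)
class Rearrangement:
    """One assembled V(D)J rearrangement with full truth provenance.

    ``v_end``, ``d_start``, ``d_end``, ``j_start`` are 1-based coordinates
    of the *templated* segment boundaries in ``sequence`` (P and N
    nucleotides lie between them).
    """

    id: str
    v_allele: str
    d_allele: str
    j_allele: str
    plan: JunctionPlan
    sequence: str
    v_end: int
    d_start: int
    d_end: int
    j_start: int
    productive: bool


def _pal(seq: str, end: str, k: int) -> str:
    """P nucleotides: reverse complement of the terminal ``k`` bases."""
    if k == 0:
        return ""
    if end == "3":
        return _revcomp(seq[-k:])
    return _revcomp(seq[:k])


def assemble_rearrangement(
    v: GermlineAllele,
    d: GermlineAllele,
    j: GermlineAllele,
    plan: JunctionPlan,
    rid: str = "rearr",
) -> Rearrangement:
    """Deterministically assemble the rearranged sequence from a plan.

    Layout: trimmed V + V-3' P + N1 + D-5' P + trimmed D + D-3' P + N2 +
    J-5' P + trimmed J.  P nucleotides are the reverse complement of the
    terminal bases of the adjacent untrimmed segment end.
    """
    L = plan.lengths
    if L["V3D"] >= len(v.sequence):
        raise ValueError("V3D deletion consumes the whole V segment")
    if L["D5D"] + L["D3D"] >= len(d.sequence):
        raise ValueError("D deletions consume the whole D segment")
    if L["J5D"] >= len(j.sequence):
        raise ValueError("J5D deletion consumes the whole J segment")

    v_part = v.sequence[: len(v.sequence) - L["V3D"]]
    d_part = d.sequence[L["D5D"]: len(d.sequence) - L["D3D"]]
    j_part = j.sequence[L["J5D"]:]
    v_pal = _pal(v.sequence, "3", L["V3P"])
    d_pal5 = _pal(d.sequence, "5", L["D5P"])
    d_pal3 = _pal(d.sequence, "3", L["D3P"])
    j_pal5 = _pal(j.sequence, "5", L["J5P"])

    seq = v_part + v_pal + plan.n1 + d_pal5 + d_part + d_pal3 + plan.n2 + j_pal5 + j_part
    v_end = len(v_part)
    d_start = v_end + len(v_pal) + len(plan.n1) + len(d_pal5) + 1
    d_end = d_start + len(d_part) - 1
    j_start = d_end + len(d_pal3) + len(plan.n2) + len(j_pal5) + 1

    rearr = Rearrangement(
        id=rid,
        v_allele=v.name,
        d_allele=d.name,
        j_allele=j.name,
        plan=plan,
        sequence=seq,
        v_end=v_end,
        d_start=d_start,
        d_end=d_end,
        j_start=j_start,
        productive=False,
    )
    return replace(rearr, productive=is_productive(rearr))


def is_productive(r: Rearrangement) -> bool:
    """In-frame (relative to V codon 1) and free of stop codons."""
    if len(r.sequence) % 3 != 0:
        return False
    return "*" not in str(Seq(r.sequence).translate())


def simulate_rearrangements(
    db: GermlineDatabase,
    usage: UsageModel,
    junction: JunctionModel,
    n: int,
    productive_fraction: float | None,
    seed: int,
    max_attempts_factor: int = 500,
) -> list[Rearrangement]:
    """Simulate ``n`` independent rearrangements.

    With ``productive_fraction`` set, rejection sampling delivers exactly
    ``floor(n * fraction)`` productive records; ``None`` disables the
    control and returns the first ``n`` draws regardless of productivity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Rearrangement] = []

    if productive_fraction is None:
        for i in range(n):
            out.append(_draw_one(db, usage, junction, rng, f"rearr_{i}"))
        return out

    if not (0 <= productive_fraction <= 1):
        raise ValueError("productive_fraction must be in [0, 1]")
    want_productive = int(np.floor(n * productive_fraction))
    want_nonproductive = n - want_productive
    got_p = got_np = 0
    attempts = 0
    max_attempts = max_attempts_factor * n
    while got_p < want_productive or got_np < want_nonproductive:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not reach productive quota ({got_p}/{want_productive} "
                f"productive, {got_np}/{want_nonproductive} nonproductive) "
                f"after {max_attempts} attempts; check reference frames"
            )
        r = _draw_one(db, usage, junction, rng, f"rearr_{len(out)}")
        if r.productive and got_p < want_productive:
            out.append(r)
            got_p += 1
        elif not r.productive and got_np < want_nonproductive:
            out.append(r)
            got_np += 1
    return out


def _draw_one(db, usage, junction, rng, rid) -> Rearrangement:
    v_name, d_name, j_name = sample_genes(usage, rng)
    v, d, j = db[v_name], db[d_name], db[j_name]
    # Re-draw plans whose deletions would consume a short segment.
    while True:
        plan = sample_junction(junction, rng)
        L = plan.lengths
        if (
            L["V3D"] < len(v.sequence)
            and L["D5D"] + L["D3D"] < len(d.sequence)
            and L["J5D"] < len(j.sequence)
        ):
            break
    return assemble_rearrangement(v, d, j, plan, rid)


def write_rearrangement_tsv(rearrangements: list[Rearrangement], path) -> None:
    """Write rearrangement truth as an AIRR-flavoured TSV."""
    rows = []
    for r in rearrangements:
        row = {
            "sequence_id": r.id,
            "sequence": r.sequence,
            "v_call": r.v_allele,
            "d_call": r.d_allele,
            "j_call": r.j_allele,
            "productive": "T" if r.productive else "F",
            "v_end": r.v_end,
            "d_start": r.d_start,
            "d_end": r.d_end,
            "j_start": r.j_start,
            "n1": r.plan.n1,
            "n2": r.plan.n2,
        }
        row.update(r.plan.lengths)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
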