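"""Somatic hypermutation lineages and power-law clonal expansion.

Affinity maturation is emulated iteratively: in each round a random
fraction of the current sequence pool is selected, point mutations are
drawn from a positional mutability profile and a 4x4 substitution matrix,
and the mutated copies join the pool.  The resulting nonredundant lineage
members are then assigned replicate counts from a truncated discrete power
law, mimicking clonal expansion.

Because empirical mutability profiles are estimated from *end* repertoires
that already carry several rounds of mutation, the per-round probability is
damped by ``mut_ability_fold`` (< 1) so that iterating does not produce
hyper-mutated sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .germline import GermlineDatabase
from .rearrange import Rearrangement

__all__ = [
    "MutabilityModel",
    "SubstitutionModel",
    "CloneLineage",
    "ClonalSizeModel",
    "mutate_once",
    "grow_lineages",
    "sample_clone_sizes",
    "compute_shm_rate",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


class MutabilityModel:
    """Positional per-round mutation probabilities plus a damping factor.

    ``profile[i]`` is the mutation probability of position ``i`` (0-based)
    per mutation event before damping; positions beyond the profile use the
    profile mean.  ``mut_ability_fold`` in (0, 1] scales every probability.
    """

    def __init__(self, profile, mut_ability_fold: float = 1.0):
        self.profile = np.asarray(profile, dtype=float)
        if self.profile.size == 0:
            raise ValueError("mutability profile is empty")
        if self.profile.min() < 0 or self.profile.max() > 1:
            raise ValueError("mutability probabilities must lie in [0, 1]")
        if not (0 < mut_ability_fold <= 1):
            raise ValueError("mut_ability_fold must be in (0, 1]")
        self.mut_ability_fold = float(mut_ability_fold)
        self._default = float(self.profile.mean())

    def rates(self, length: int) -> np.ndarray:
        """Effective (damped) per-position rates for a sequence of ``length``."""
        if length <= self.profile.size:
            p = self.profile[:length]
        else:
            p = np.concatenate(
                [self.profile, np.full(length - self.profile.size, self._default)]
            )
        return p * self.mut_ability_fold

    @classmethod
    def from_tsv(cls, path, mut_ability_fold: float = 1.0) -> "MutabilityModel":
        """Read a profile TSV with columns position (1-based), probability."""
        df = pd.read_csv(path, sep="\t").sort_values("position")
        return cls(df["probability"].to_numpy(), mut_ability_fold)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"position": np.arange(1, self.profile.size + 1),
             "probability": self.profile}
        ).to_csv(path, sep="\t", index=False)


class SubstitutionModel:
    """Row-stochastic 4x4 substitution matrix with zero diagonal.

    Rows and columns are ordered A, C, G, T; row ``b`` gives the
    distribution of the replacement base conditional on a mutation at a
    ``b`` position.
    """

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4 (A,C,G,T order)")
        if np.any(np.diag(m) != 0):
            raise ValueError("substitution matrix diagonal must be zero")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("each substitution row must sum to 1")
        self.matrix = m
        self._cum = np.cumsum(m, axis=1)

    @classmethod
    def uniform(cls) -> "SubstitutionModel":
        m = np.full((4, 4), 1 / 3)
        np.fill_diagonal(m, 0.0)
        return cls(m)

    @classmethod
    def from_tsv(cls, path) -> "SubstitutionModel":
        """Read a TSV with columns ref, A, C, G, T (one row per ref base)."""
        df = pd.read_csv(path, sep="\t").set_index("ref").loc[list(_BASES)]
        return cls(df[list(_BASES)].to_numpy())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(_BASES))
        df.insert(0, "ref", list(_BASES))
        df.to_csv(path, sep="\t", index=False)


def mutate_once(
    seq: str,
    mut: MutabilityModel,
    sub: SubstitutionModel,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Apply one round of SHM; returns the new sequence and 1-based loci.

    Each position mutates independently with probability
    ``mutability[pos] * mut_ability_fold``; the replacement base is drawn
    from the substitution row of the current base.
    """
    codes = _encode(seq)
    rates = mut.rates(len(seq))
    hits = np.flatnonzero(rng.random(len(seq)) < rates)
    if hits.size == 0:
        return seq, []
    u = rng.random(hits.size)
    for k, pos in enumerate(hits):
        cum = sub._cum[codes[pos]]
        codes[pos] = int(np.searchsorted(cum, u[k], side="right"))
    return _decode(codes), (hits + 1).tolist()


@dataclass
class LineageMember:
    """One sequence in a clone lineage with its parent link."""

    sequence: str
    parent: int | None  # index into CloneLineage.members; None for the root
    iteration: int
    n_mutations: int  # Hamming distance to parent


@dataclass
class CloneLineage:
    """A root rearrangement plus its SHM-derived descendants."""

    clone_id: str
    root: Rearrangement
    members: list[LineageMember]
    sizes: list[int] | None = None  # replicate count per member

    @property
    def sequences(self) -> list[str]:
        return [m.sequence for m in self.members]


def grow_lineages(
    roots: list[Rearrangement],
    iterations: int,
    select_fraction: float,
    mut: MutabilityModel,
    sub: SubstitutionModel,
    rng: np.random.Generator,
) -> list[CloneLineage]:
    """Build clonally related lineages by iterative SHM.

    Each lineage starts from one root; per iteration a random
    ``ceil(select_fraction * pool)`` subset (without replacement) is
    mutated and the new sequences are added to the pool.  Duplicate
    sequences are collapsed so pools stay nonredundant.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not (0 < select_fraction <= 1):
        raise ValueError("select_fraction must be in (0, 1]")
    lineages = []
    for root in roots:
        members = [LineageMember(root.sequence, None, 0, 0)]
        seen = {root.sequence}
        for it in range(1, iterations + 1):
            k = math.ceil(select_fraction * len(members))
            chosen = rng.choice(len(members), size=k, replace=False)
            for idx in chosen:
                new_seq, loci = mutate_once(members[idx].sequence, mut, sub, rng)
                if loci and new_seq not in seen:
                    seen.add(new_seq)
                    members.append(LineageMember(new_seq, int(idx), it, len(loci)))
        lineages.append(CloneLineage(clone_id=f"clone_{root.id}", root=root, members=members))
    return lineages


@dataclass(frozen=True)
class ClonalSizeModel:
    """Truncated discrete power law for clone sizes.

    ``P(s) ∝ s**(-alpha)`` on ``s in [1, max_size]``; ``max_sequences``
    caps the total emitted sequence count by dropping members.
    """

    alpha: float = 2.0
    max_size: int = 50
    max_sequences: int | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")


def sample_clone_sizes(
    n_members: int, model: ClonalSizeModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw one replicate count per member from the power law.

    If the total exceeds ``max_sequences`` a random subset of members is
    retained (sizes of dropped members set to 0) so the emitted total fits
    under the cap.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    support = np.arange(1, model.max_size + 1)
    weights = support.astype(float) ** (-model.alpha)
    weights /= weights.sum()
    sizes = rng.choice(support, size=n_members, p=weights)
    if model.max_sequences is not None and sizes.sum() > model.max_sequences:
        order = rng.permutation(n_members)
        kept = np.zeros(n_members, dtype=bool)
        total = 0
        for idx in order:
            if total + sizes[idx] <= model.max_sequences:
                kept[idx] = True
                total += sizes[idx]
        sizes = np.where(kept, sizes, 0)
    return sizes


def expand_lineages(
    lineages: list[CloneLineage],
    model: ClonalSizeModel,
    rng: np.random.Generator,
) -> None:
    """Assign power-law replicate counts to every lineage member in place."""
    for lin in lineages:
        lin.sizes = sample_clone_sizes(len(lin.members), model, rng).tolist()


def compute_shm_rate(
    lineages: list[CloneLineage], db: GermlineDatabase
) -> tuple[np.ndarray, float]:
    """V-region mismatch fraction of every lineage member vs its germline.

    The compared window is the templated V portion of the root
    rearrangement (positions 1..v_end), matched against the same prefix of
    the true source V allele.  Returns per-sequence rates (in member
    order, lineages concatenated) and their mean.
    """
    rates = []
    for lin in lineages:
        root = lin.root
        if root.v_allele not in db:
            raise KeyError(f"unknown source V allele: {root.v_allele}")
        germ = _encode(db[root.v_allele].sequence[: root.v_end])
        for m in lin.members:
            obs = _encode(m.sequence[: root.v_end])
            rates.append(float((obs != germ).mean()))
    arr = np.array(rates)
    return arr, float(arr.mean())


def write_lineage_tsv(lineages: list[CloneLineage], path) -> None:
    """Write lineage truth: sequence_id, clone_id, parent_id, n_mutations, size."""
    rows = []
    for lin in lineages:
        sizes = lin.sizes if lin.sizes is not None else [1] * len(lin.members)
        for i, (m, size) in enumerate(zip(lin.members, sizes)):
            rows.append(
                {
                    "sequence_id": f"{lin.clone_id}_{i}",
                    "clone_id": lin.clone_id,
                    "parent_id": "" if m.parent is None else f"{lin.clone_id}_{m.parent}",
                    "iteration": m.iteration,
                    "n_mutations": m.n_mutations,
                    "size": size,
                    "sequence": m.sequence,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
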