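"""Paired-end Illumina-like read simulation.

Source molecules are drawn from the expanded repertoire proportional to
clone-size weights; each pair reads the amplicon from both ends (mate 2 is
reverse-complement oriented from the 3' end).  Substitution errors are
injected per sequencing cycle from a configurable error-rate profile, and
Phred qualities are reported consistently with the per-cycle error
probability (Q = -10*log10(e), rounded).  Substitutions only — no INDEL
errors are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["ReadProfile", "ReadPair", "generate_reads", "write_fastq"]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BATCH = 10_000


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


@dataclass(frozen=True)
class ReadProfile:
    """Read length plus a per-cycle substitution-error-rate vector.

    The default profile rises linearly from 0.001 at cycle 1 to 0.01 at the
    last cycle, a coarse approximation of MiSeq quality decay; any profile
    can be supplied instead (rates capped at 0.1).
    """

    read_length: int = 250
    error_rates: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.error_rates is None:
            rates = np.linspace(0.001, 0.01, self.read_length)
            object.__setattr__(self, "error_rates", tuple(rates.tolist()))
        rates = np.asarray(self.error_rates, dtype=float)
        if rates.size != self.read_length:
            raise ValueError("error_rates length must equal read_length")
        if rates.min() < 0 or rates.max() > 0.1:
            raise ValueError("per-cycle error rates must lie in [0, 0.1]")

    def quality_string(self, length: int | None = None) -> str:
        """Phred+33 qualities implied by the per-cycle error rates."""
        rates = np.asarray(self.error_rates)[: length or self.read_length]
        q = np.round(-10 * np.log10(np.maximum(rates, 1e-9))).astype(int)
        q = np.clip(q, 0, 93)
        return "".join(chr(33 + int(x)) for x in q)

    @classmethod
    def from_tsv(cls, path, read_length: int | None = None) -> "ReadProfile":
        """Read a profile TSV with columns cycle (1-based), error_rate."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t").sort_values("cycle")
        rates = tuple(df["error_rate"].astype(float).tolist())
        return cls(read_length=read_length or len(rates), error_rates=rates)


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: id, mate sequences and Phred+33 qualities."""

    id: str
    read1: str
    qual1: str
    read2: str
    qual2: str


def generate_reads(
    sequences: Sequence[str],
    weights: Sequence[float] | None,
    profile: ReadProfile,
    n_reads: int,
    rng: np.random.Generator,
    id_prefix: str = "read",
) -> Iterator[ReadPair]:
    """Yield exactly ``n_reads`` read pairs from weighted source molecules.

    Mate 1 covers the amplicon 5' end, mate 2 the reverse complement of
    the 3' end; amplicons shorter than the read length yield truncated
    mates.  Pair ids encode the source sequence index.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not sequences:
        raise ValueError("repertoire is empty")
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights sum to zero")
        w = w / w.sum()

    L = profile.read_length
    rates = np.asarray(profile.error_rates)
    full_qual = profile.quality_string()

    # Pre-encode each distinct source once; mate 2 is the reverse
    # complement so its template is encoded separately.
    enc_fwd = [_encode(s[:L]) for s in sequences]
    enc_rev = [
        _encode(s[max(0, len(s) - L):].translate(_COMPLEMENT)[::-1])
        for s in sequences
    ]

    emitted = 0
    pair_index = 0
    while emitted < n_reads:
        batch = min(_BATCH, n_reads - emitted)
        sources = rng.choice(len(sequences), size=batch, p=w)
        for src in sources:
            r1 = _with_errors(enc_fwd[src], rates, rng)
            r2 = _with_errors(enc_rev[src], rates, rng)
            yield ReadPair(
                id=f"{id_prefix}_{pair_index}_src{src}",
                read1=r1,
                qual1=full_qual[: len(r1)],
                read2=r2,
                qual2=full_qual[: len(r2)],
            )
            pair_index += 1
        emitted += batch


def _with_errors(codes: np.ndarray, rates: np.ndarray, rng) -> str:
    n = codes.size
    hits = np.flatnonzero(rng.random(n) < rates[:n])
    if hits.size:
        codes = codes.copy()
        # shift by 1..3 mod 4: uniform over the three wrong bases
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return _BASE_ARR[codes].tobytes().decode()


def write_fastq(pairs: Iterable[ReadPair], path_r1, path_r2) -> None:
    """Write mates to two FASTQ files (Phred+33, /1 and /2 id suffixes)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.read1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.read2}\n+\n{p.qual2}\n")
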