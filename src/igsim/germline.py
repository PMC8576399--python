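"""Germline allele references and artificial novel-allele injection.

A germline database holds named V/D/J allele sequences (IMGT-style names,
``gene*allele``).  To benchmark novel-allele detection we plant artificial
single-nucleotide variants into selected V alleles: the *altered* copy keeps
the public allele name and becomes part of the reference handed to a
detection tool, while the untouched real sequence becomes the "novel" allele
the tool is expected to rediscover.  Variant loci are restricted to the
first 280 bp of the V gene so junctional trimming cannot erase them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GermlineAllele",
    "GermlineDatabase",
    "SNPSpec",
    "NovelAlleleTruth",
    "load_germline_fasta",
    "write_germline_fasta",
    "snp_notation",
    "parse_snp_notation",
    "inject_artificial_snps",
    "prune_confusable",
    "normalize_degenerate",
    "SNP_REGION_BP",
]

#: Variants are planted only within this 5' window of a V gene, clear of
#: junctional trimming.
SNP_REGION_BP = 280

_BASES = "ACGT"

# IUPAC nucleotide codes -> the set of bases each denotes.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Deterministic resolution: each degenerate code maps to the alphabetically
# first base it denotes.
_DEGENERATE_MAP = {code: bases[0] for code, bases in _IUPAC.items()}


def normalize_degenerate(seq: str) -> str:
    """Resolve IUPAC degenerate codes to plain A/C/G/T.

    Each degenerate code is replaced by the alphabetically first base it
    denotes (R -> A, Y -> C, N -> A, ...); A/C/G/T pass through unchanged
    and the length is preserved.  Raises ``ValueError`` on any character
    that is not an IUPAC nucleotide code.
    """
    out = []
    for ch in seq.upper():
        try:
            out.append(_DEGENERATE_MAP[ch])
        except KeyError:
            raise ValueError(f"non-IUPAC nucleotide character: {ch!r}") from None
    return "".join(out)


@dataclass(frozen=True)
class GermlineAllele:
    """One germline segment sequence.

    Parameters
    ----------
    name:
        Allele identifier, ``gene*allele`` (e.g. ``IGHV1-S1*01``).
    sequence:
        Uppercase A/C/G/T, 5'->3'.
    segment:
        ``"V"``, ``"D"`` or ``"J"``.
    regions:
        Optional ordered map of region label (FR1, CDR1, FR2, CDR2, FR3) to
        a 1-based closed interval ``(start, end)`` on the sequence.
    """

    name: str
    sequence: str
    segment: str
    regions: dict[str, tuple[int, int]] | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"allele {self.name}: empty sequence")
        bad = set(self.sequence) - set(_BASES)
        if bad:
            raise ValueError(
                f"allele {self.name}: non-ACGT characters {sorted(bad)}; "
                "apply normalize_degenerate first"
            )
        if self.segment not in ("V", "D", "J"):
            raise ValueError(f"allele {self.name}: segment must be V/D/J")
        if self.regions:
            prev_end = 0
            for label, (start, end) in self.regions.items():
                if not (1 <= start <= end <= len(self.sequence)):
                    raise ValueError(
                        f"allele {self.name}: region {label} {start}-{end} "
                        "outside sequence bounds"
                    )
                if start <= prev_end:
                    raise ValueError(
                        f"allele {self.name}: region {label} overlaps or is "
                        "out of order"
                    )
                prev_end = end

    @property
    def gene(self) -> str:
        return self.name.split("*")[0]


class GermlineDatabase:
    """Collection of :class:`GermlineAllele` keyed by unique name."""

    def __init__(self, alleles: list[GermlineAllele] | None = None):
        self._alleles: dict[str, GermlineAllele] = {}
        for a in alleles or []:
            self.add(a)

    def add(self, allele: GermlineAllele) -> None:
        if allele.name in self._alleles:
            raise ValueError(f"duplicate allele name: {allele.name}")
        self._alleles[allele.name] = allele

    def __getitem__(self, name: str) -> GermlineAllele:
        return self._alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self._alleles

    def __len__(self) -> int:
        return len(self._alleles)

    def __iter__(self):
        return iter(self._alleles.values())

    @property
    def names(self) -> list[str]:
        return list(self._alleles)

    def by_segment(self, segment: str) -> list[GermlineAllele]:
        return [a for a in self._alleles.values() if a.segment == segment]

    def copy(self) -> "GermlineDatabase":
        return GermlineDatabase(list(self._alleles.values()))

    def replace_sequence(self, name: str, sequence: str) -> None:
        self._alleles[name] = replace(self._alleles[name], sequence=sequence)

    def remove(self, name: str) -> None:
        del self._alleles[name]


def _name_from_header(header: str) -> str:
    # IMGT-style headers pack fields with "|"; the allele name is the first
    # |- or whitespace-delimited token containing "*".  Plain headers are
    # used verbatim.
    for token in re.split(r"[|\s]+", header.strip()):
        if "*" in token:
            return token
    return header.strip().split()[0] if header.strip() else header


def _segment_from_name(name: str) -> str:
    # IGHV... / IGHD... / IGHJ...: the 4th character of the gene name
    # carries the segment type.
    gene = name.split("*")[0]
    if len(gene) >= 4 and gene[3] in "VDJ":
        return gene[3]
    raise ValueError(f"cannot infer segment (V/D/J) from allele name {name!r}")


def load_germline_fasta(
    path, regions: dict[str, dict[str, tuple[int, int]]] | None = None
) -> GermlineDatabase:
    """Read a germline allele FASTA into a :class:`GermlineDatabase`.

    Sequences are uppercased, IMGT alignment gaps (``.``/``-``) are
    stripped, and degenerate bases resolved via :func:`normalize_degenerate`.
    ``regions`` optionally supplies FR/CDR interval maps keyed by allele
    name.
    """
    db = GermlineDatabase()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = _name_from_header(rec.description)
        seq = str(rec.seq).upper().replace(".", "").replace("-", "")
        seq = normalize_degenerate(seq)
        db.add(
            GermlineAllele(
                name=name,
                sequence=seq,
                segment=_segment_from_name(name),
                regions=(regions or {}).get(name),
            )
        )
    if len(db) == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return db


def write_germline_fasta(db: GermlineDatabase, path) -> None:
    """Write the database as FASTA, 60-column wrapped."""
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description="") for a in db
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class SNPSpec:
    """A single-nucleotide variant on a germline V sequence.

    ``locus`` is 1-based; ``ref`` is the base carried by the (customized)
    germline reference at that locus and ``alt`` the base carried by the
    novel sequence.
    """

    locus: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"SNP at locus {self.locus}: ref equals alt")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"SNP bases must be A/C/G/T, got {self.ref}/{self.alt}")
        if self.locus < 1:
            raise ValueError("SNP locus is 1-based and must be >= 1")


def snp_notation(snp: SNPSpec) -> str:
    """Render a SNP as ``<ref><locus><alt>``, e.g. ``G92A``."""
    return f"{snp.ref}{snp.locus}{snp.alt}"


def parse_snp_notation(s: str) -> SNPSpec:
    """Parse ``<ref><locus><alt>`` notation back into a :class:`SNPSpec`."""
    m = re.fullmatch(r"([ACGT])(\d+)([ACGT])", s.strip().upper())
    if not m:
        raise ValueError(f"malformed SNP notation: {s!r}")
    return SNPSpec(locus=int(m.group(2)), ref=m.group(1), alt=m.group(3))


@dataclass(frozen=True)
class NovelAlleleTruth:
    """Ground truth for one artificially created novel allele.

    ``source_allele`` names the reference allele whose copy was altered;
    ``novel_sequence`` is the real (unaltered) germline sequence that a
    detection tool should rediscover.  Each SNP is oriented from the
    altered reference toward the novel sequence.
    """

    source_allele: str
    snps: tuple[SNPSpec, ...]
    novel_name: str
    novel_sequence: str

    @property
    def snp_loci(self) -> tuple[int, ...]:
        return tuple(s.locus for s in self.snps)


def inject_artificial_snps(
    db: GermlineDatabase,
    target_alleles: list[str],
    n_snps: int,
    seed: int,
) -> tuple[GermlineDatabase, list[NovelAlleleTruth]]:
    """Plant ``n_snps`` random substitutions into each target V allele.

    For every target the altered sequence replaces the original under the
    original allele name in the returned database, while the untouched real
    sequence is recorded as the novel allele to be rediscovered.  Loci are
    drawn uniformly without replacement from ``[1, 280]`` and the new base
    uniformly from the three alternatives.  Identical seeds give identical
    outputs.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_snps > SNP_REGION_BP:
        raise ValueError(f"n_snps must be <= {SNP_REGION_BP}")
    rng = np.random.default_rng(seed)
    out = db.copy()
    truths: list[NovelAlleleTruth] = []
    for name in target_alleles:
        if name not in db:
            raise KeyError(f"target allele not in database: {name}")
        allele = db[name]
        if allele.segment != "V":
            raise ValueError(f"target allele {name} is not a V allele")
        if len(allele.sequence) < SNP_REGION_BP:
            raise ValueError(
                f"target allele {name} shorter than {SNP_REGION_BP} bp"
            )
        loci = np.sort(rng.choice(SNP_REGION_BP, size=n_snps, replace=False) + 1)
        altered = list(allele.sequence)
        snps = []
        for locus in loci:
            original = allele.sequence[locus - 1]
            choices = [b for b in _BASES if b != original]
            injected = choices[rng.integers(3)]
            altered[locus - 1] = injected
            # Oriented for a detector that compares the altered reference
            # against the real sequence: ref = injected, alt = original.
            snps.append(SNPSpec(locus=int(locus), ref=injected, alt=original))
        out.replace_sequence(name, "".join(altered))
        truths.append(
            NovelAlleleTruth(
                source_allele=name,
                snps=tuple(snps),
                novel_name=name + "_" + "-".join(snp_notation(s) for s in snps),
                novel_sequence=allele.sequence,
            )
        )
    return out, truths


def edit_distance(a: str, b: str) -> int:
    """Global (Needleman-Wunsch, unit-cost) edit distance."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def prune_confusable(
    db: GermlineDatabase, truths: list[NovelAlleleTruth]
) -> tuple[GermlineDatabase, list[tuple[str, str]]]:
    """Drop reference alleles that out-compete an altered target.

    If another reference allele is strictly closer (global edit distance)
    to a truth's novel sequence than the altered target itself, simulated
    reads from the novel allele would align to that competitor instead and
    the injection would be unrecoverable, so the competitor is removed.
    Ties are kept.  Returns the pruned database and a ``(removed_name,
    truth_novel_name)`` log.
    """
    protected = {t.source_allele for t in truths}
    removals: list[tuple[str, str]] = []
    out = db.copy()
    for truth in truths:
        own_dist = edit_distance(db[truth.source_allele].sequence, truth.novel_sequence)
        for allele in db:
            if allele.name in protected or allele.name not in out:
                continue
            if edit_distance(allele.sequence, truth.novel_sequence) < own_dist:
                out.remove(allele.name)
                removals.append((allele.name, truth.novel_name))
    return out, removals


def write_truth_tsv(truths: list[NovelAlleleTruth], path) -> None:
    """Write injected-novel-allele truth as a TSV."""
    with open(path, "w") as fh:
        fh.write("novel_name\tsource_allele\tsnp_notation\tnovel_sequence\n")
        for t in truths:
            nots = ";".join(snp_notation(s) for s in t.snps)
            fh.write(f"{t.novel_name}\t{t.source_allele}\t{nots}\t{t.novel_sequence}\n")


def read_truth_tsv(path) -> list[NovelAlleleTruth]:
    """Read a truth TSV written by :func:`write_truth_tsv`."""
    truths = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            snps = tuple(
                parse_snp_notation(s)
                for s in row[idx["snp_notation"]].split(";")
                if s
            )
            truths.append(
                NovelAlleleTruth(
                    source_allele=row[idx["source_allele"]],
                    snps=snps,
                    novel_name=row[idx["novel_name"]],
                    novel_sequence=row[idx["novel_sequence"]],
                )
            )
    return truths
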