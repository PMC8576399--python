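"""Consensus filtration of novel allele candidates (NACs) across tools.

Individual detection tools differ widely in sensitivity and precision, and
their error modes depend strongly on how much somatic hypermutation a
dataset carries.  Datasets are therefore first classified by isotype
content: IgM/IgD clones are SHM-sparse, IgG/IgA/IgE clones SHM-rich.  A
candidate survives filtration only with multi-tool support, with the
voting panel chosen per dataset class.  Surviving candidates can be
cross-validated against external allele collections and their SNPs
classified as replacement or silent by antibody region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from Bio.Seq import Seq

from .germline import GermlineAllele, SNPSpec, normalize_degenerate

__all__ = [
    "IsotypeProfile",
    "DatasetClass",
    "ToolCallSet",
    "NACRecord",
    "classify_dataset",
    "filter_nacs",
    "cross_validate",
    "rs_classify",
    "TRUSTED_TOOLS",
    "SHM_RICH_PANEL",
]

#: Tools given extra credit in SHM-sparse (IgM) datasets.
TRUSTED_TOOLS = frozenset({"TIgGER", "IgDiscover"})
#: Voting panel for SHM-rich (IgG) datasets.
SHM_RICH_PANEL = frozenset({"TIgGER", "IgDiscover", "Partis"})

_SPARSE_ISOTYPES = ("IgM", "IgD")
_RICH_ISOTYPES = ("IgG", "IgA", "IgE")


class DatasetClass(Enum):
    SHM_SPARSE = "IgM"
    SHM_RICH = "IgG"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class IsotypeProfile:
    """Clone-level isotype counts for one repertoire dataset."""

    counts: dict[str, int]
    total_clones: int
    assigned_clones: int

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("isotype counts must be >= 0")
        if self.assigned_clones > self.total_clones:
            raise ValueError("assigned_clones cannot exceed total_clones")
        if self.total_clones <= 0:
            raise ValueError("total_clones must be > 0")


def classify_dataset(profile: IsotypeProfile) -> DatasetClass:
    """Classify a dataset by SHM richness of its isotype composition.

    Requires a constant-gene assignment for more than half of the clones
    (strict); otherwise unclassifiable.  IgM class iff SHM-sparse clones
    (IgM + IgD) strictly outnumber SHM-rich clones (IgG + IgA + IgE); ties
    fall to the IgG class.
    """
    if profile.assigned_clones <= profile.total_clones / 2:
        return DatasetClass.UNCLASSIFIABLE
    sparse = sum(profile.counts.get(i, 0) for i in _SPARSE_ISOTYPES)
    rich = sum(profile.counts.get(i, 0) for i in _RICH_ISOTYPES)
    return DatasetClass.SHM_SPARSE if sparse > rich else DatasetClass.SHM_RICH


@dataclass(frozen=True)
class ToolCallSet:
    """The NAC sequences reported by one detection tool.

    Sequences are normalized (degenerate codes resolved, uppercased) so
    identity across tools is plain string equality.
    """

    tool: str
    sequences: frozenset[str]

    @classmethod
    def from_sequences(cls, tool: str, sequences) -> "ToolCallSet":
        return cls(tool=tool, sequences=frozenset(normalize_degenerate(s) for s in sequences))


def filter_nacs(
    calls: list[ToolCallSet], dataset_class: DatasetClass
) -> set[str]:
    """Retain NAC sequences with class-appropriate multi-tool support.

    SHM-sparse (IgM) datasets: a sequence needs >= 2 supporting tools, at
    least one of them TIgGER or IgDiscover.  SHM-rich (IgG) datasets: a
    sequence needs >= 2 supporters among {TIgGER, IgDiscover, Partis};
    votes from any other tool are ignored.
    """
    if dataset_class is DatasetClass.UNCLASSIFIABLE:
        raise ValueError("cannot filter NACs for an unclassifiable dataset")
    support: dict[str, set[str]] = {}
    for cs in calls:
        for seq in cs.sequences:
            support.setdefault(seq, set()).add(cs.tool)
    retained = set()
    for seq, tools in support.items():
        if dataset_class is DatasetClass.SHM_SPARSE:
            if len(tools) >= 2 and tools & TRUSTED_TOOLS:
                retained.add(seq)
        else:
            if len(tools & SHM_RICH_PANEL) >= 2:
                retained.add(seq)
    return retained


def cross_validate(
    nac_sequence: str, collections: dict[str, list[str]]
) -> list[str]:
    """Names of external collections containing the NAC sequence verbatim.

    Collection sequences are degenerate-normalized before comparison;
    matching is exact full-sequence identity (substrings do not count).
    """
    nac = normalize_degenerate(nac_sequence)
    return [
        name
        for name, seqs in collections.items()
        if any(normalize_degenerate(s) == nac for s in seqs)
    ]


def rs_classify(snp: SNPSpec, germline: GermlineAllele) -> tuple[str, str]:
    """Classify a SNP as replacement/silent and locate its region.

    The codon frame starts at position 1 of the germline V sequence; the
    codon containing the locus is translated before and after the
    substitution ("R" iff the amino acid changes).  The region is "CDR"
    for CDR1/CDR2 intervals and "FR" for FR1/FR2/FR3.
    """
    if not germline.regions:
        raise ValueError(f"allele {germline.name} has no region annotations")
    region = None
    for label, (start, end) in germline.regions.items():
        if start <= snp.locus <= end:
            region = "CDR" if label.upper().startswith("CDR") else "FR"
            break
    if region is None:
        raise ValueError(
            f"locus {snp.locus} outside annotated regions of {germline.name}"
        )
    seq = germline.sequence
    if seq[snp.locus - 1] != snp.ref:
        raise ValueError(
            f"germline base at locus {snp.locus} is {seq[snp.locus - 1]}, "
            f"not {snp.ref}"
        )
    codon_start = ((snp.locus - 1) // 3) * 3
    codon = seq[codon_start: codon_start + 3]
    if len(codon) < 3:
        raise ValueError(f"locus {snp.locus} falls in an incomplete terminal codon")
    offset = (snp.locus - 1) % 3
    mutated = codon[:offset] + snp.alt + codon[offset + 1:]
    before = str(Seq(codon).translate())
    after = str(Seq(mutated).translate())
    return ("S" if before == after else "R"), region


@dataclass
class NACRecord:
    """A consensus-retained NAC with its annotations."""

    sequence: str
    nearest_allele: str
    snps: list[SNPSpec] = field(default_factory=list)
    snp_classes: list[tuple[str, str]] = field(default_factory=list)  # (R/S, FR/CDR)
    supporting_tools: list[str] = field(default_factory=list)
    supporting_datasets: list[str] = field(default_factory=list)
    cross_validation_sources: list[str] = field(default_factory=list)


def rs_ratio(classes: list[str]) -> float:
    """Replacement/silent count ratio; ``inf`` when no silent SNPs."""
    r = sum(1 for c in classes if c == "R")
    s = sum(1 for c in classes if c == "S")
    return r / s if s else float("inf")
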