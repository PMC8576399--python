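"""Personal germline V-allele inference from annotated contigs.

Given BCR contigs annotated with a V allele call, the V-segment sequence of
each contig is tallied per gene.  Short segments are merged into longer
ones that contain them (same allele annotation), low-support and short
entries are discarded, and per gene the most frequent segment is called as
the primary germline allele.  A second allele is retained only when its
support is at least one tenth of the primary's — heterozygous genes carry
at most two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "AnnotatedContig",
    "VSegmentTally",
    "GeneCall",
    "InferredGenotype",
    "tally_contigs",
    "merge_nested_segments",
    "filter_segments",
    "call_genotype",
    "allele_ratio",
    "read_contig_tsv",
    "MIN_SEGMENT_LENGTH",
    "MIN_SEGMENT_COUNT",
    "SECONDARY_MIN_FRACTION",
]

#: V segments shorter than this are discarded before genotype calling.
MIN_SEGMENT_LENGTH = 290
#: V segments supported by fewer contigs than this are discarded.
MIN_SEGMENT_COUNT = 10
#: A secondary allele needs at least this fraction of the primary's support.
SECONDARY_MIN_FRACTION = 0.1


@dataclass(frozen=True)
class AnnotatedContig:
    """One annotated contig: id, V allele call and V-segment sequence."""

    contig_id: str
    v_call: str
    v_sequence: str
    count: int = 1

    def __post_init__(self):
        if not self.v_sequence or not self.v_call:
            raise ValueError(f"contig {self.contig_id}: empty v_call or sequence")

    @property
    def gene(self) -> str:
        return self.v_call.split("*")[0]


@dataclass(frozen=True)
class SegmentEntry:
    """A unique V-segment sequence with its annotation and contig support."""

    sequence: str
    v_call: str
    count: int


#: Per-gene tally: gene name -> list of unique segment entries.
VSegmentTally = dict[str, list[SegmentEntry]]


def tally_contigs(contigs: list[AnnotatedContig]) -> VSegmentTally:
    """Count each unique (sequence, v_call) pair, grouped by gene."""
    counts: dict[str, dict[tuple[str, str], int]] = {}
    for c in contigs:
        gene_tab = counts.setdefault(c.gene, {})
        key = (c.v_sequence, c.v_call)
        gene_tab[key] = gene_tab.get(key, 0) + c.count
    return {
        gene: [SegmentEntry(seq, call, n) for (seq, call), n in tab.items()]
        for gene, tab in counts.items()
    }


def merge_nested_segments(tally: VSegmentTally) -> VSegmentTally:
    """Fold shorter segments into longer ones that contain them.

    A sequence that is a substring of a longer sequence with the same V
    allele annotation is removed and its count added to the longer entry.
    Merging runs longest-first so containment chains collapse transitively
    onto the longest representative.
    """
    out: VSegmentTally = {}
    for gene, entries in tally.items():
        kept: list[SegmentEntry] = []
        for entry in sorted(entries, key=lambda e: (-len(e.sequence), e.sequence)):
            host = next(
                (
                    i
                    for i, k in enumerate(kept)
                    if k.v_call == entry.v_call and entry.sequence in k.sequence
                ),
                None,
            )
            if host is None:
                kept.append(entry)
            else:
                k = kept[host]
                kept[host] = SegmentEntry(k.sequence, k.v_call, k.count + entry.count)
        out[gene] = kept
    return out


def filter_segments(
    tally: VSegmentTally,
    min_length: int = MIN_SEGMENT_LENGTH,
    min_count: int = MIN_SEGMENT_COUNT,
) -> VSegmentTally:
    """Drop entries shorter than ``min_length`` or rarer than ``min_count``.

    Both thresholds are strict "less than" cut-offs: a 290 bp segment with
    10 supporting contigs is retained.
    """
    out: VSegmentTally = {}
    for gene, entries in tally.items():
        kept = [
            e
            for e in entries
            if len(e.sequence) >= min_length and e.count >= min_count
        ]
        if kept:
            out[gene] = kept
    return out


def allele_ratio(minor_count: int, major_count: int) -> float:
    """Minor/major contig-count ratio, half-up rounded to two decimals."""
    if major_count <= 0:
        raise ValueError("major_count must be > 0")
    if not (0 < minor_count <= major_count):
        raise ValueError("require 0 < minor_count <= major_count")
    ratio = Decimal(minor_count) / Decimal(major_count)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneCall:
    """Inferred germline allele(s) for one gene."""

    gene: str
    primary: SegmentEntry
    secondary: SegmentEntry | None = None

    @property
    def ratio(self) -> float | None:
        if self.secondary is None:
            return None
        return allele_ratio(self.secondary.count, self.primary.count)


#: Inferred genotype: gene name -> GeneCall.
InferredGenotype = dict[str, GeneCall]


def call_genotype(tally: VSegmentTally) -> InferredGenotype:
    """Call at most two germline alleles per gene from a filtered tally.

    The top-count sequence is the primary allele; the runner-up is kept
    only when its count is at least one tenth of the primary's.  Ties are
    broken lexicographically by sequence so calls are deterministic.
    """
    genotype: InferredGenotype = {}
    for gene, entries in tally.items():
        if not entries:
            continue
        ranked = sorted(entries, key=lambda e: (-e.count, e.sequence))
        primary = ranked[0]
        secondary = None
        if len(ranked) > 1 and ranked[1].count >= SECONDARY_MIN_FRACTION * primary.count:
            secondary = ranked[1]
        genotype[gene] = GeneCall(gene=gene, primary=primary, secondary=secondary)
    return genotype


def infer_genotype(contigs: list[AnnotatedContig]) -> InferredGenotype:
    """End-to-end inference: tally, merge nested, filter, call."""
    return call_genotype(filter_segments(merge_nested_segments(tally_contigs(contigs))))


def read_contig_tsv(path) -> list[AnnotatedContig]:
    """Read contigs from a TSV with columns contig_id, v_call, v_sequence."""
    df = pd.read_csv(path, sep="\t")
    return [
        AnnotatedContig(
            contig_id=str(row["contig_id"]),
            v_call=row["v_call"],
            v_sequence=row["v_sequence"],
        )
        for _, row in df.iterrows()
    ]


def write_genotype_tsv(genotype: InferredGenotype, path) -> None:
    """Write the genotype as TSV: gene, rank, v_call, count, ratio, sequence."""
    rows = []
    for gene in sorted(genotype):
        call = genotype[gene]
        rows.append(
            {
                "gene": gene,
                "rank": 1,
                "v_call": call.primary.v_call,
                "count": call.primary.count,
                "ratio": "",
                "sequence": call.primary.sequence,
            }
        )
        if call.secondary is not None:
            rows.append(
                {
                    "gene": gene,
                    "rank": 2,
                    "v_call": call.secondary.v_call,
                    "count": call.secondary.count,
                    "ratio": f"{call.ratio:.2f}",
                    "sequence": call.secondary.sequence,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
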