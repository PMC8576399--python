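"""Scoring of novel-allele detection calls against injected truth.

Calls are scored at two levels.  At the SNP level a call is a true
positive only when its nearest allele, locus and nucleotide variant all
match an injected truth SNP.  At the allele level a reported sequence
(partial or full length) is a true positive only when it covers every
genuine SNP locus of its best-matching truth and carries zero mismatches
against the genuine novel sequence over the whole aligned span.

Sensitivity is the fraction of truths recovered; "specificity" follows the
source field's repertoire-benchmarking usage and is the fraction of calls
that are true positives — i.e. precision / positive predictive value.  The
name is kept for table compatibility; see :class:`BenchmarkResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib

from .germline import NovelAlleleTruth

__all__ = [
    "SNPCall",
    "AlleleCall",
    "BenchmarkResult",
    "match_snp_call",
    "match_allele_call",
    "score",
]


@dataclass(frozen=True)
class SNPCall:
    """A SNP reported by a detection tool: nearest allele, locus, variant."""

    nearest_allele: str
    locus: int
    alt: str
    tool: str = ""

    def __post_init__(self):
        if self.locus < 1:
            raise ValueError("locus is 1-based and must be >= 1")


@dataclass(frozen=True)
class AlleleCall:
    """A novel allele sequence reported by a detection tool."""

    sequence: str
    tool: str = ""
    nearest_allele: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("allele call sequence is empty")


@dataclass(frozen=True)
class BenchmarkResult:
    """Counts and metrics for one tool at one level.

    ``specificity`` is precision (TP / all calls); ``None`` when no calls
    were made.  ``sensitivity`` counts distinct truths hit, so a truth
    recovered twice counts once.
    """

    level: str  # "SNP" or "allele"
    tp: int
    called: int
    truth_total: int
    sensitivity: float
    specificity: float | None


def match_snp_call(call: SNPCall, truths: list[NovelAlleleTruth]) -> bool:
    """True positive iff allele, locus and variant match some truth SNP."""
    for truth in truths:
        if truth.source_allele != call.nearest_allele:
            continue
        for snp in truth.snps:
            if snp.locus == call.locus and snp.alt == call.alt:
                return True
    return False


def match_allele_call(
    call: AlleleCall, truths: list[NovelAlleleTruth]
) -> tuple[bool, NovelAlleleTruth | None]:
    """Label an allele call TP/FP and return its best-matching truth.

    The call is slid ungapped along each truth's novel sequence (infix
    alignment); the best truth is the one at minimum edit distance, ties
    broken by truth name.  The call is a TP only if it occurs verbatim in
    that truth's novel sequence at an offset whose span covers every SNP
    locus — i.e. all genuine SNPs covered, zero mismatches elsewhere.
    """
    if not truths:
        return False, None
    best: tuple[int, str, NovelAlleleTruth] | None = None
    for truth in truths:
        target = truth.novel_sequence
        if len(call.sequence) > len(target):
            # cannot be a mismatch-free infix; rank by global distance
            d = edlib.align(call.sequence, target, mode="NW", task="distance")[
                "editDistance"
            ]
        else:
            d = edlib.align(call.sequence, target, mode="HW", task="distance")[
                "editDistance"
            ]
        key = (d, truth.novel_name, truth)
        if best is None or key[:2] < best[:2]:
            best = key
    d, _, truth = best
    if len(call.sequence) > len(truth.novel_sequence):
        warnings.warn(
            "allele call longer than every candidate novel sequence; "
            "scored as false positive",
            stacklevel=2,
        )
        return False, truth
    if d != 0:
        return False, truth
    # exact infix: check that some occurrence covers all SNP loci
    target = truth.novel_sequence
    loci = truth.snp_loci
    start = target.find(call.sequence)
    while start != -1:
        lo, hi = start + 1, start + len(call.sequence)  # 1-based closed span
        if all(lo <= locus <= hi for locus in loci):
            return True, truth
        start = target.find(call.sequence, start + 1)
    return False, truth


def score(
    calls: list[SNPCall] | list[AlleleCall],
    truths: list[NovelAlleleTruth],
    level: str,
) -> BenchmarkResult:
    """Aggregate TP/FP labels into sensitivity and specificity.

    Calls are de-duplicated first; sensitivity counts distinct truths hit
    (distinct truth SNPs at the SNP level) over the truth total, and
    specificity is TP calls over all calls (``None`` when no calls).
    """
    if not truths:
        raise ValueError("empty truth set")
    if level not in ("SNP", "allele"):
        raise ValueError("level must be 'SNP' or 'allele'")

    unique_calls = list(dict.fromkeys(calls))
    tp = 0
    if level == "SNP":
        truth_keys = {
            (t.source_allele, s.locus, s.alt) for t in truths for s in t.snps
        }
        hit = set()
        for call in unique_calls:
            key = (call.nearest_allele, call.locus, call.alt)
            if key in truth_keys:
                tp += 1
                hit.add(key)
        truth_total = len(truth_keys)
        n_hit = len(hit)
    else:
        hit = set()
        for call in unique_calls:
            is_tp, truth = match_allele_call(call, truths)
            if is_tp:
                tp += 1
                hit.add(truth.novel_name)
        truth_total = len(truths)
        n_hit = len(hit)

    called = len(unique_calls)
    return BenchmarkResult(
        level=level,
        tp=tp,
        called=called,
        truth_total=truth_total,
        sensitivity=n_hit / truth_total,
        specificity=(tp / called) if called else None,
    )
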