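"""Strand-specific RNA normalisation, quantification and antisense assignment.

Normalisation follows the sense-anchored convention: the total signal
attributable to annotated sense (coding) transcripts is scaled to 1e8
arbitrary units and the *same* factor is applied to the opposite strand,
so sense:antisense ratios are preserved.  Per-transcript levels are then
signal per kilobase of transcript length.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .genome import CoverageTrack, Transcript, TranscriptCatalog

__all__ = [
    "StrandedExpression",
    "AntisenseAssignment",
    "normalize_stranded",
    "quantify_transcripts",
    "classify_antisense",
]

SENSE_TOTAL_TARGET = 1e8


@dataclass
class StrandedExpression:
    """Plus/minus coverage for one condition x replicate, plus scaling state."""

    condition: str
    replicate: str
    plus: CoverageTrack
    minus: CoverageTrack
    scale_factor: float = 1.0

    def track_for(self, strand: str) -> CoverageTrack:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True)
class AntisenseAssignment:
    """A noncoding transcript assigned antisense to a host coding gene."""

    transcript_id: str
    host_gene_id: str
    overlap_fraction: float
    excluded_convergent: bool


def _sense_total(expr: StrandedExpression, catalog: TranscriptCatalog, whole_strand: bool) -> float:
    if whole_strand:
        return expr.plus.total() + expr.minus.total()
    total = 0.0
    for t in catalog.coding():
        total += expr.track_for(t.strand).sum_over(t.interval)
    return total


def normalize_stranded(
    expr: StrandedExpression,
    catalog: TranscriptCatalog,
    whole_strand_total: bool = False,
) -> StrandedExpression:
    """Scale both strands so that total sense-transcript signal equals 1e8.

    With ``whole_strand_total`` the normalisation denominator is the grand
    total over both strands instead of the annotated-sense sum.
    """
    total = _sense_total(expr, catalog, whole_strand_total)
    if total <= 0:
        raise ValueError("zero sense signal: cannot normalise")
    factor = SENSE_TOTAL_TARGET / total
    return StrandedExpression(
        expr.condition,
        expr.replicate,
        expr.plus.scaled(factor),
        expr.minus.scaled(factor),
        scale_factor=expr.scale_factor * factor,
    )


def quantify_transcripts(
    expr: StrandedExpression, catalog: TranscriptCatalog
) -> pd.Series:
    """Per-transcript level: strand-matched signal per kilobase of length."""
    levels = {}
    for t in catalog:
        if t.length == 0:
            raise ValueError(f"{t.id}: zero-length transcript")
        total = expr.track_for(t.strand).sum_over(t.interval)
        levels[t.id] = total / (t.length / 1000.0)
    return pd.Series(levels, name="level")


def classify_antisense(
    noncoding: list[Transcript],
    coding: list[Transcript],
    min_overlap: float = 0.5,
) -> tuple[list[AntisenseAssignment], list[str]]:
    """Assign each noncoding transcript to an opposite-strand host gene.

    The host is the coding gene on the opposite strand with the largest
    overlap, accepted when the overlapping fraction of the noncoding
    transcript is at least ``min_overlap`` (ties break on gene id).
    Candidates that also overlap a coding gene on their *own* strand are
    indistinguishable from convergent read-through and are flagged
    ``excluded_convergent`` (they are dropped from antisense level
    quantification downstream).  Returns ``(assignments, orphan_ids)``.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in coding:
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    assignments: list[AntisenseAssignment] = []
    orphans: list[str] = []
    for t in sorted(noncoding, key=lambda t: t.id):
        opp = "-" if t.strand == "+" else "+"
        hits = trees.get((t.chrom, opp), IntervalTree()).overlap(
            t.interval.start, t.interval.end
        )
        host, best_ov = None, 0
        for hit in hits:
            ov = hit.data.interval.overlap(t.interval)
            if ov > best_ov or (ov == best_ov and host and hit.data.id < host.id):
                host, best_ov = hit.data, ov
        if host is None:
            orphans.append(t.id)
            continue
        frac = best_ov / t.length
        if frac < min_overlap:
            orphans.append(t.id)
            continue
        same = trees.get((t.chrom, t.strand), IntervalTree()).overlap(
            t.interval.start, t.interval.end
        )
        assignments.append(
            AntisenseAssignment(t.id, host.id, float(frac), bool(same))
        )
    return assignments, orphans


def assignment_frame(assignments: list[AntisenseAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in assignments],
            "host_gene_id": [a.host_gene_id for a in assignments],
            "overlap_fraction": [a.overlap_fraction for a in assignments],
            "excluded_convergent": [a.excluded_convergent for a in assignments],
        }
    ).set_index("transcript_id")
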