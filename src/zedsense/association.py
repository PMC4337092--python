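"""Linking 3'-end occupancy peaks to antisense transcription.

Three pieces: the >3-fold downstream/upstream RNA rule that associates a
peak with a transcript; the 2x2 contingency of high-vs-none 3' occupancy
against antisense presence; and a randomisation null that redraws peak
positions from the 3' ends of genes and counts co-localisation with
antisense transcript starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chip import EndEnrichment
from .genome import GenomicInterval, TranscriptCatalog, region_of
from .rna import AntisenseAssignment, StrandedExpression
from .stats import ContingencyResult, fisher_exact

__all__ = [
    "PeakTranscriptLink",
    "RandomizationResult",
    "associate_peak",
    "overlap_contingency",
    "randomization_test",
]


@dataclass(frozen=True)
class PeakTranscriptLink:
    """Result of the downstream/upstream fold rule for one peak."""

    gene_id: str
    peak: GenomicInterval
    downstream_mean: float
    upstream_mean: float
    fold: float
    associated: bool


@dataclass
class RandomizationResult:
    """Observed antisense co-localisation count against a resampled null."""

    observed_count: int
    null_counts: np.ndarray
    empirical_p: float
    fdr_estimate: float
    seed: int

    @property
    def iters(self) -> int:
        return len(self.null_counts)

    def to_dict(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "iters": self.iters,
            "null_mean": float(self.null_counts.mean()),
            "null_max": int(self.null_counts.max()),
            "empirical_p": self.empirical_p,
            "fdr_estimate": self.fdr_estimate,
            "seed": self.seed,
        }


def associate_peak(
    peak: GenomicInterval,
    expr: StrandedExpression,
    gene_id: str = "",
    window: int = 150,
    fold_threshold: float = 3.0,
    pseudocount: float = 0.1,
) -> PeakTranscriptLink:
    """Associate a 3'-end peak with a putative antisense transcript.

    The peak's ``strand`` field carries the putative transcription
    direction (opposite to the host gene for antisense candidates).  The
    peak is associated when mean RNA signal on that strand in the
    ``window`` bp downstream of the peak exceeds the upstream mean by more
    than ``fold_threshold`` (a pseudocount keeps the zero/zero case at
    fold 1).
    """
    if peak.strand not in ("+", "-"):
        raise ValueError("peak must carry a putative transcription direction")
    track = expr.track_for(peak.strand)
    chrom_len = len(track.values[peak.chrom])
    if peak.start >= chrom_len or peak.end <= 0:
        raise ValueError("peak lies outside the chromosome")
    if peak.strand == "+":
        down = GenomicInterval(peak.chrom, peak.end, peak.end + window)
        up = GenomicInterval(peak.chrom, max(peak.start - window, 0), peak.start)
    else:
        down = GenomicInterval(peak.chrom, max(peak.start - window, 0), peak.start)
        up = GenomicInterval(peak.chrom, peak.end, peak.end + window)
    d = track.mean_over(down)
    u = track.mean_over(up)
    fold = (d + pseudocount) / (u + pseudocount)
    return PeakTranscriptLink(gene_id, peak, d, u, fold, fold > fold_threshold)


def overlap_contingency(
    end_calls: list[EndEnrichment],
    as_set: list[AntisenseAssignment],
    which: str = "high_vs_none",
) -> ContingencyResult:
    """2x2 test of 3'-occupancy call against antisense presence.

    Rows are genes called ``high`` vs ``none`` for 3' occupancy
    (intermediate genes are excluded); columns are has/has-no antisense
    transcript (convergent-excluded assignments do not count).  Expected
    counts under independence, Fisher p and odds ratio are attached.
    """
    if which != "high_vs_none":
        raise ValueError(f"unknown contingency construction {which!r}")
    hosts = {a.host_gene_id for a in as_set if not a.excluded_convergent}
    a = b = c = d = 0
    for e in end_calls:
        has_as = e.transcript_id in hosts
        if e.three_call == "high":
            a, b = a + has_as, b + (not has_as)
        elif e.three_call == "none":
            c, d = c + has_as, d + (not has_as)
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("empty high or none class in contingency table")
    return fisher_exact(a, b, c, d)


def _window_hit_flags(
    catalog: TranscriptCatalog,
    as_set: list[AntisenseAssignment],
    width: int,
    tolerance: int,
) -> tuple[list[str], np.ndarray]:
    """For every coding gene: does its 3'-inner window contain an antisense TSS?

    Antisense TSS positions come from the assigned (non-excluded)
    noncoding transcripts; 'contain' means strictly inside the window,
    optionally widened by ``tolerance`` bp on both sides.
    """
    kept = {a.transcript_id: a.host_gene_id for a in as_set if not a.excluded_convergent}
    tss_by_chrom: dict[str, list[int]] = {}
    for t in catalog.noncoding():
        if t.id in kept:
            tss_by_chrom.setdefault(t.chrom, []).append(t.tss)
    tss_arrays = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    gene_ids, hits = [], []
    for g in catalog.coding():
        win = region_of(g, "three_prime_inner", width, catalog.chrom_sizes[g.chrom])
        if win.is_empty:
            continue
        arr = tss_arrays.get(g.chrom)
        lo, hi = win.start - tolerance, win.end + tolerance
        hit = bool(arr is not None and np.searchsorted(arr, lo, "left") < np.searchsorted(arr, hi, "left"))
        gene_ids.append(g.id)
        hits.append(hit)
    return gene_ids, np.array(hits, dtype=bool)


def randomization_test(
    catalog: TranscriptCatalog,
    as_set: list[AntisenseAssignment],
    high_gene_ids: set[str],
    n_regions: int | None = None,
    width: int = 150,
    iters: int = 1000,
    seed: int = 0,
    tolerance: int = 0,
) -> RandomizationResult:
    """Randomisation null for peak/antisense co-localisation.

    The observed statistic is the number of high-3'-occupancy genes whose
    3'-inner window (``width`` bp upstream of the TES) contains an
    antisense transcript start.  Each of ``iters`` iterations draws
    ``n_regions`` genes uniformly without replacement from all genes with
    a defined 3' window and counts the same overlap.  The empirical p uses
    the add-one estimator, so it is never exactly zero.
    """
    gene_ids, hits = _window_hit_flags(catalog, as_set, width, tolerance)
    pool = len(gene_ids)
    high_mask = np.array([g in high_gene_ids for g in gene_ids])
    if n_regions is None:
        n_regions = int(high_mask.sum())
    if n_regions > pool:
        raise ValueError(f"n_regions={n_regions} exceeds the pool of {pool} genes")
    if n_regions < 1:
        raise ValueError("n_regions must be positive")
    observed = int(hits[high_mask].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(iters, dtype=int)
    for i in range(iters):
        pick = rng.choice(pool, size=n_regions, replace=False)
        null[i] = int(hits[pick].sum())
    empirical_p = (1 + int((null >= observed).sum())) / (iters + 1)
    fdr = float(null.mean() / observed) if observed > 0 else float("nan")
    return RandomizationResult(observed, null, empirical_p, fdr, seed)
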