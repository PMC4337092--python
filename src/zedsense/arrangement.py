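"""Gene-arrangement typology and the four-class 5'/3' occupancy scheme.

Each gene is classified by the neighbour on its *3' side* (where antisense
transcripts initiate): same transcription direction gives tandem, facing
transcription gives convergent, and the pair is "close" when the gap is
strictly below 300 bp.  Separately, genes are split into four classes by
whether their 5' and 3' occupancy levels clear cohort-average thresholds
(class 1: 5' only, 2: both, 3: neither, 4: 3' only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .chip import EndEnrichment
from .genome import TranscriptCatalog
from .stats import ContingencyResult, fisher_exact, one_sample_t_test, welch_t_test

__all__ = [
    "ArrangementCall",
    "HtzPatternClass",
    "classify_arrangement",
    "category_signal",
    "category_enrichment",
    "classify_htz_pattern",
    "class_fold_change_comparison",
]

CATEGORIES = ("tandem_close", "tandem_far", "convergent_close", "convergent_far")


@dataclass(frozen=True)
class ArrangementCall:
    gene_id: str
    category: str  # tandem_close/tandem_far/convergent_close/convergent_far/undefined
    neighbor_id: str | None
    gap: int | None


@dataclass(frozen=True)
class HtzPatternClass:
    gene_id: str
    pattern_class: int  # 1: 5' only, 2: both, 3: neither, 4: 3' only
    tau_five: float
    tau_three: float


def classify_arrangement(
    catalog: TranscriptCatalog, close_threshold: int = 300
) -> list[ArrangementCall]:
    """Arrangement category for every coding gene, judged at its 3' side.

    The gap runs from the gene's TES-side boundary to the neighbour's
    proximal boundary (clamped at 0 for overlapping annotations); a gap of
    exactly ``close_threshold`` is "far" (strict <).  The last gene on a
    chromosome arm, with no 3'-side neighbour, is ``undefined``.
    """
    calls: list[ArrangementCall] = []
    for chrom, genes in catalog.sorted_by_chrom().items():
        coding = [g for g in genes if g.kind == "coding"]
        for i, g in enumerate(coding):
            if g.strand == "+":
                nb = coding[i + 1] if i + 1 < len(coding) else None
                gap = None if nb is None else nb.interval.start - g.interval.end
            else:
                nb = coding[i - 1] if i > 0 else None
                gap = None if nb is None else g.interval.start - nb.interval.end
            if nb is None:
                calls.append(ArrangementCall(g.id, "undefined", None, None))
                continue
            gap = max(int(gap), 0)
            orientation = "tandem" if nb.strand == g.strand else "convergent"
            distance = "close" if gap < close_threshold else "far"
            calls.append(ArrangementCall(g.id, f"{orientation}_{distance}", nb.id, gap))
    return calls


def arrangement_frame(calls: list[ArrangementCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "category": [c.category for c in calls],
            "neighbor_id": [c.neighbor_id for c in calls],
            "gap": [c.gap for c in calls],
        }
    ).set_index("gene_id")


def category_signal(
    end_enrichments: list[EndEnrichment], calls: list[ArrangementCall]
) -> pd.DataFrame:
    """Total and per-gene mean 3' occupancy for each arrangement category."""
    levels = {e.transcript_id: e.three_prime_level for e in end_enrichments}
    cat = {c.gene_id: c.category for c in calls}
    rows: dict[str, list[float]] = {}
    for gid, lv in levels.items():
        rows.setdefault(cat.get(gid, "undefined"), []).append(lv)
    out = pd.DataFrame(
        [
            (c, float(np.sum(v)), float(np.mean(v)), len(v))
            for c, v in sorted(rows.items())
        ],
        columns=["category", "total_three_prime", "mean_three_prime", "n_genes"],
    ).set_index("category")
    total = out["total_three_prime"].sum()
    out["fraction_of_total"] = out["total_three_prime"] / total if total > 0 else 0.0
    return out


def category_enrichment(
    down_genes: Iterable[str], calls: list[ArrangementCall]
) -> dict[str, ContingencyResult]:
    """Per-category Fisher test: is the down-regulated-antisense set
    over-represented in that arrangement category relative to the genome?
    """
    down = set(down_genes)
    cat = {c.gene_id: c.category for c in calls}
    unknown = down - set(cat)
    if unknown:
        raise ValueError(f"down-set genes missing arrangement calls: {sorted(unknown)[:5]}")
    results: dict[str, ContingencyResult] = {}
    for category in CATEGORIES:
        in_cat = {g for g, c in cat.items() if c == category}
        if not in_cat:
            continue
        a = len(down & in_cat)
        b = len(down - in_cat)
        c_ = len(in_cat - down)
        d = len(cat) - a - b - c_
        results[category] = fisher_exact(a, b, c_, d)
    return results


def classify_htz_pattern(
    end_enrichments: list[EndEnrichment],
    universe: set[str] | None = None,
    positive_only_mean: bool = False,
) -> list[HtzPatternClass]:
    """Four-class occupancy pattern from cohort-average thresholds.

    tau5/tau3 are the arithmetic means of the 5'/3' levels over the
    classified universe (all genes' levels including zeros by default;
    ``positive_only_mean`` restricts the averages to non-zero levels).
    Class 1 = 5' only, 2 = both, 3 = neither, 4 = 3' only; classes are
    invariant under a positive rescaling of all levels.
    """
    pool = [
        e for e in end_enrichments if universe is None or e.transcript_id in universe
    ]
    if not pool:
        raise ValueError("empty universe for pattern classification")
    five = np.array([e.five_prime_level for e in pool])
    three = np.array([e.three_prime_level for e in pool])
    if positive_only_mean:
        tau5 = float(five[five > 0].mean()) if (five > 0).any() else np.inf
        tau3 = float(three[three > 0].mean()) if (three > 0).any() else np.inf
    else:
        tau5, tau3 = float(five.mean()), float(three.mean())
    out = []
    for e in pool:
        hi5 = e.five_prime_level >= tau5
        hi3 = e.three_prime_level >= tau3
        cls = 1 if (hi5 and not hi3) else 2 if (hi5 and hi3) else 3 if not hi3 else 4
        out.append(HtzPatternClass(e.transcript_id, cls, tau5, tau3))
    return out


def class_fold_change_comparison(
    classes: list[HtzPatternClass], de: pd.DataFrame
) -> pd.DataFrame:
    """Sense log2 fold-change distributions per occupancy class.

    For each class with at least two members that have DE results:
    median/quartiles of log2FC, a one-sample two-tailed t-test of mean
    log2FC != 0, and Welch tests against every other class.  Classes with
    fewer than two testable genes are skipped.
    """
    lfc_by_class: dict[int, np.ndarray] = {}
    for cls in sorted({c.pattern_class for c in classes}):
        ids = [c.gene_id for c in classes if c.pattern_class == cls]
        vals = de.loc[de.index.intersection(ids), "log2FC"].to_numpy(dtype=float)
        if vals.size >= 2:
            lfc_by_class[cls] = vals
    rows = []
    for cls, vals in lfc_by_class.items():
        try:
            p_vs_zero, t_stat, _ = one_sample_t_test(vals, 0.0)
        except ValueError:
            p_vs_zero, t_stat = np.nan, np.nan
        pairwise = {}
        for other, ov in lfc_by_class.items():
            if other == cls:
                continue
            try:
                pw_p, _, _ = welch_t_test(vals, ov)
            except ValueError:
                pw_p = np.nan
            pairwise[other] = pw_p
        rows.append(
            {
                "pattern_class": cls,
                "n": vals.size,
                "mean_log2FC": float(vals.mean()),
                "median_log2FC": float(np.median(vals)),
                "q1_log2FC": float(np.quantile(vals, 0.25)),
                "q3_log2FC": float(np.quantile(vals, 0.75)),
                "t_stat": t_stat,
                "p_vs_zero": p_vs_zero,
                **{f"p_vs_class_{o}": p for o, p in sorted(pairwise.items())},
            }
        )
    if not rows:
        return pd.DataFrame(columns=["n", "mean_log2FC"]).rename_axis("pattern_class")
    return pd.DataFrame(rows).set_index("pattern_class")
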