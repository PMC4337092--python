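"""ChIP-seq signal processing for variant-histone occupancy.

The background model works on the per-base ChIP:input ratio r(x) after
both tracks are scaled to reads per million (RPM).  The background level
B is the mean of r plus ``k`` sample standard deviations (k = 1.2 by
default); the final signal is ``max(r(x) - B, 0)``, i.e. any position at
or below background is zeroed.  Positions with zero input coverage carry
no ratio information and are masked: excluded from the moments and set to
zero in the output.

Downstream summaries — gene-anatomy partition, metagene profiles,
25-window occupancy vectors, hierarchical clustering, and 5'/3' end
enrichment with a none/intermediate/high call — all consume this
background-subtracted signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .genome import CoverageTrack, GenomicInterval, Transcript, TranscriptCatalog, region_of

__all__ = [
    "SignalTrack",
    "CategoryPartition",
    "EndEnrichment",
    "normalize_rpm",
    "subtract_background",
    "partition_signal",
    "metagene_profile",
    "feature_vector",
    "cluster_profiles",
    "quantify_end_enrichment",
    "classify_occupancy",
]

logger = logging.getLogger(__name__)

#: category precedence when anatomy windows of neighbouring genes overlap;
#: later entries win (painted last)
PARTITION_ORDER = ("igr", "cds", "three_prime", "five_prime")


@dataclass
class SignalTrack:
    """Background-subtracted ChIP signal (ratio units) plus model scalars."""

    values: dict[str, np.ndarray]
    background: float
    ratio_mean: float
    ratio_sd: float
    k: float

    def mean_over(self, iv: GenomicInterval) -> float:
        arr = self.values[iv.chrom]
        c = iv.clipped(len(arr))
        if c.is_empty:
            return 0.0
        return float(arr[c.start:c.end].mean())

    def sum_over(self, iv: GenomicInterval) -> float:
        arr = self.values[iv.chrom]
        c = iv.clipped(len(arr))
        if c.is_empty:
            return 0.0
        return float(arr[c.start:c.end].sum())

    def total(self) -> float:
        return float(sum(a.sum() for a in self.values.values()))

    def as_coverage(self) -> CoverageTrack:
        return CoverageTrack(
            {c: a.copy() for c, a in self.values.items()},
            total_mapped=self.total(),
        )


@dataclass(frozen=True)
class EndEnrichment:
    """Per-transcript 5'/3' occupancy levels and categorical calls."""

    transcript_id: str
    five_prime_level: float
    three_prime_level: float
    five_call: str = "none"
    three_call: str = "none"


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Scale a track to reads per million mapped reads."""
    if track.total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPM normalisation")
    return track.scaled(1e6 / track.total_mapped)


def subtract_background(
    chip: CoverageTrack,
    input_: CoverageTrack,
    k: float = 1.2,
    per_chromosome: bool = False,
) -> SignalTrack:
    """Ratio-based background subtraction of ChIP against input.

    Both tracks are expected in RPM.  With ``per_chromosome`` the ratio
    moments (and hence B) are computed separately per chromosome;
    genome-wide moments are the default.
    """
    if set(chip.values) != set(input_.values):
        raise ValueError("chip and input tracks cover different chromosomes")
    ratios: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for chrom, inp in input_.values.items():
        ch = chip.values[chrom]
        if len(ch) != len(inp):
            raise ValueError(f"{chrom}: chip/input length mismatch")
        mask = inp > 0
        r = np.zeros_like(ch)
        np.divide(ch, inp, out=r, where=mask)
        ratios[chrom] = r
        masks[chrom] = mask

    def _signal(chroms):
        pooled = np.concatenate([ratios[c][masks[c]] for c in chroms])
        if pooled.size == 0:
            raise ValueError("no usable input coverage")
        mean = float(pooled.mean())
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        b = mean + k * sd
        out = {}
        for c in chroms:
            sig = np.maximum(ratios[c] - b, 0.0)
            sig[~masks[c]] = 0.0
            out[c] = sig
        return out, mean, sd, b

    if per_chromosome:
        values: dict[str, np.ndarray] = {}
        means, sds, bs = [], [], []
        for chrom in ratios:
            v, m, s, b = _signal([chrom])
            values.update(v)
            means.append(m), sds.append(s), bs.append(b)
        return SignalTrack(values, float(np.mean(bs)), float(np.mean(means)), float(np.mean(sds)), k)
    values, mean, sd, b = _signal(sorted(ratios))
    return SignalTrack(values, b, mean, sd, k)


# ---------------------------------------------------------------------------
# Gene-anatomy partition

_CAT_CODES = {name: i for i, name in enumerate(PARTITION_ORDER)}


@dataclass
class CategoryPartition:
    """Signal split across 5' / CDS / 3' / intergenic territory."""

    table: pd.DataFrame  # index: category; columns: total, percent, length_bp, density

    def percent(self, category: str) -> float:
        return float(self.table.loc[category, "percent"])


def _category_labels(signal: SignalTrack, catalog: TranscriptCatalog, flank: int):
    labels = {
        chrom: np.zeros(len(arr), dtype=np.int8) for chrom, arr in signal.values.items()
    }
    coding = catalog.coding()
    paint = {
        "cds": [t.interval for t in coding],
        "three_prime": [
            region_of(t, "three_prime_flank", flank, catalog.chrom_sizes[t.chrom])
            for t in coding
        ],
        "five_prime": [
            region_of(t, "five_prime_flank", flank, catalog.chrom_sizes[t.chrom])
            for t in coding
        ],
    }
    for cat in PARTITION_ORDER[1:]:
        code = _CAT_CODES[cat]
        for iv in paint[cat]:
            if iv.chrom in labels:
                c = iv.clipped(len(labels[iv.chrom]))
                labels[iv.chrom][c.start:c.end] = code
    return labels


def partition_signal(
    signal: SignalTrack, catalog: TranscriptCatalog, flank: int = 300
) -> CategoryPartition:
    """Assign every base to 5'/3'/CDS/IGR and tally signal, percent and density.

    5' = TSS +/- flank, 3' = TES +/- flank, CDS = the rest of the gene body,
    IGR = more than ``flank`` bp from any gene.  Overlapping windows of
    neighbouring genes resolve by precedence 5' > 3' > CDS > IGR.  Density
    is RPKM-like: signal share x 1e9 / (category length x total signal).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not catalog.coding():
        raise ValueError("catalog contains no coding transcripts")
    labels = _category_labels(signal, catalog, flank)
    total_all = signal.total()
    rows = []
    for cat, code in _CAT_CODES.items():
        tot = 0.0
        length = 0
        for chrom, lab in labels.items():
            sel = lab == code
            length += int(sel.sum())
            tot += float(signal.values[chrom][sel].sum())
        rows.append((cat, tot, length))
    df = pd.DataFrame(rows, columns=["category", "total", "length_bp"]).set_index(
        "category"
    )
    df["percent"] = 100.0 * df["total"] / total_all if total_all > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = df["total"] * 1e9 / (df["length_bp"] * total_all)
    df["density"] = dens.replace([np.inf, -np.inf], 0.0).fillna(0.0)
    return CategoryPartition(df[["total", "percent", "length_bp", "density"]])


# ---------------------------------------------------------------------------
# Metagene profiles


@dataclass
class Profile:
    """Per-position mean signal across genes, with contributing-gene counts."""

    positions: np.ndarray  # offsets (tss/tes modes) or bin indices (scaled)
    mean: np.ndarray
    n: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "mean": self.mean, "n": self.n}
        )


def _offset_positions(t: Transcript, anchor: int, offsets: np.ndarray) -> np.ndarray:
    """Genomic positions for strand-aware offsets around an anchor edge."""
    if t.strand == "+":
        return anchor + offsets
    return anchor - 1 - offsets


def metagene_profile(
    signal: SignalTrack,
    catalog: TranscriptCatalog,
    mode: str = "tss_aligned",
    span: int = 300,
    n_bins: int = 100,
    transcripts: list[Transcript] | None = None,
) -> Profile:
    """Average signal across genes after aligning at TSS/TES or rescaling CDS.

    ``tss_aligned``/``tes_aligned`` average at each strand-aware offset in
    [-span, span); offsets falling off the chromosome do not contribute.
    ``scaled_cds`` linearly interpolates each transcript's CDS core
    (gene body minus 300 bp at each end) onto ``n_bins`` bins; transcripts
    with a degenerate core are skipped.
    """
    genes = transcripts if transcripts is not None else catalog.coding()
    if mode in ("tss_aligned", "tes_aligned"):
        if span <= 0:
            raise ValueError("span must be positive")
        offsets = np.arange(-span, span)
        total = np.zeros(offsets.size)
        count = np.zeros(offsets.size)
        used = 0
        for t in genes:
            arr = signal.values[t.chrom]
            anchor = t.tss if mode == "tss_aligned" else t.tes
            pos = _offset_positions(t, anchor, offsets)
            valid = (pos >= 0) & (pos < len(arr))
            total[valid] += arr[pos[valid]]
            count[valid] += 1
            used += 1
        if used == 0:
            raise ValueError("no eligible genes for metagene profile")
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
        return Profile(offsets, mean, count, mode)
    if mode == "scaled_cds":
        if n_bins < 1:
            raise ValueError("n_bins must be at least 1")
        total = np.zeros(n_bins)
        used = 0
        centres = (np.arange(n_bins) + 0.5) / n_bins
        for t in genes:
            core = region_of(t, "cds_core", 300, catalog.chrom_sizes[t.chrom])
            if core.is_empty:
                continue
            arr = signal.values[t.chrom][core.start:core.end]
            if t.strand == "-":
                arr = arr[::-1]
            x = (np.arange(arr.size) + 0.5) / arr.size
            total += np.interp(centres, x, arr)
            used += 1
        if used == 0:
            raise ValueError("no genes with a non-degenerate CDS core")
        return Profile(
            np.arange(n_bins), total / used, np.full(n_bins, used), mode
        )
    raise ValueError(f"unknown metagene mode {mode!r}")


# ---------------------------------------------------------------------------
# 25-window occupancy vectors and clustering

#: window layout: 9 x 50 bp covering [TSS-300, TSS+150) — the -2/-1/+1
#: nucleosome region; 10 equal bins over the CDS core; 6 x 50 bp covering
#: [TES-150, TES+150) — the nucleosomes flanking the TES
N_TSS_WINDOWS = 9
N_CDS_WINDOWS = 10
N_TES_WINDOWS = 6
WINDOW_BP = 50


def feature_vector(signal: SignalTrack, t: Transcript, chrom_length: int) -> np.ndarray:
    """25-dimensional occupancy vector (9 TSS + 10 CDS + 6 TES window means).

    Transcripts of length <= 300 bp have a degenerate CDS core and are
    rejected (callers exclude them with a logged reason).
    """
    if t.length <= 300:
        raise ValueError(f"{t.id}: transcript too short for a 25-window vector")
    arr = signal.values[t.chrom]
    out = np.empty(N_TSS_WINDOWS + N_CDS_WINDOWS + N_TES_WINDOWS)

    def window_mean(iv: GenomicInterval) -> float:
        c = iv.clipped(chrom_length)
        if c.is_empty:
            return 0.0
        return float(arr[c.start:c.end].mean())

    def directed(anchor: int, off0: int, off1: int) -> GenomicInterval:
        # [off0, off1) in transcription direction relative to anchor edge
        if t.strand == "+":
            s, e = anchor + off0, anchor + off1
        else:
            s, e = anchor - off1, anchor - off0
        return GenomicInterval(t.chrom, max(s, 0), max(e, max(s, 0)), t.strand)

    for j in range(N_TSS_WINDOWS):
        out[j] = window_mean(directed(t.tss, -300 + WINDOW_BP * j, -300 + WINDOW_BP * (j + 1)))
    core = region_of(t, "cds_core", 150, chrom_length)
    edges = np.linspace(core.start, core.end, N_CDS_WINDOWS + 1).round().astype(int)
    cds_means = [
        window_mean(GenomicInterval(t.chrom, s, max(e, s), t.strand))
        for s, e in zip(edges[:-1], edges[1:])
    ]
    if t.strand == "-":
        cds_means = cds_means[::-1]
    out[N_TSS_WINDOWS:N_TSS_WINDOWS + N_CDS_WINDOWS] = cds_means
    for j in range(N_TES_WINDOWS):
        out[N_TSS_WINDOWS + N_CDS_WINDOWS + j] = window_mean(
            directed(t.tes, -150 + WINDOW_BP * j, -150 + WINDOW_BP * (j + 1))
        )
    return out


def occupancy_vectors(
    signal: SignalTrack, catalog: TranscriptCatalog
) -> pd.DataFrame:
    """25-window vectors for all coding transcripts longer than 300 bp."""
    rows, index = [], []
    for t in catalog.coding():
        if t.length <= 300:
            logger.info("excluding %s from occupancy vectors: length %d <= 300", t.id, t.length)
            continue
        rows.append(feature_vector(signal, t, catalog.chrom_sizes[t.chrom]))
        index.append(t.id)
    cols = (
        [f"tss_w{j}" for j in range(N_TSS_WINDOWS)]
        + [f"cds_w{j}" for j in range(N_CDS_WINDOWS)]
        + [f"tes_w{j}" for j in range(N_TES_WINDOWS)]
    )
    return pd.DataFrame(rows, index=index, columns=cols)


def cluster_profiles(vectors: pd.DataFrame, n_clusters: int):
    """Agglomerative clustering of occupancy vectors (Euclidean, average linkage).

    Rows are sorted by transcript id first so the result is independent of
    input order.  Returns ``(labels, linkage_matrix)`` with labels a
    pandas Series indexed by transcript id (cluster ids 1..n_clusters).
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors to cluster")
    if n_clusters > len(vectors):
        raise ValueError("n_clusters exceeds the number of vectors")
    ordered = vectors.sort_index()
    z = linkage(ordered.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=ordered.index, name="cluster"), z


# ---------------------------------------------------------------------------
# End enrichment


def quantify_end_enrichment(
    signal: SignalTrack,
    catalog: TranscriptCatalog,
    window: int = 150,
) -> list[EndEnrichment]:
    """Mean signal over the first/last ``window`` bp of each coding gene.

    Windows are clipped for short transcripts (the mean is over the actual
    clipped length).  Calls are assigned with :func:`classify_occupancy`
    separately for the 5' and 3' levels.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    genes = catalog.coding()
    five = np.array(
        [
            signal.mean_over(
                region_of(t, "five_prime_inner", window, catalog.chrom_sizes[t.chrom])
            )
            for t in genes
        ]
    )
    three = np.array(
        [
            signal.mean_over(
                region_of(t, "three_prime_inner", window, catalog.chrom_sizes[t.chrom])
            )
            for t in genes
        ]
    )
    five_calls = classify_occupancy(five)
    three_calls = classify_occupancy(three)
    return [
        EndEnrichment(t.id, float(f), float(h), fc, tc)
        for t, f, h, fc, tc in zip(genes, five, three, five_calls, three_calls)
    ]


def classify_occupancy(levels, high_threshold: float | None = None) -> list[str]:
    """Three-tier occupancy call per level: none / intermediate / high.

    Default rule: ``none`` iff the background-subtracted level is exactly 0;
    ``high`` iff the level is at least the mean of all strictly positive
    levels (or an explicit ``high_threshold``); otherwise ``intermediate``.
    Calls are invariant under a positive rescaling of all levels.
    """
    lv = np.asarray(levels, dtype=float)
    if np.any(lv < 0):
        raise ValueError("levels must be non-negative")
    if high_threshold is None:
        pos = lv[lv > 0]
        high_threshold = float(pos.mean()) if pos.size else np.inf
    out = []
    for v in lv:
        if v == 0:
            out.append("none")
        elif v >= high_threshold:
            out.append("high")
        else:
            out.append("intermediate")
    return out


def end_enrichment_frame(enrichments: list[EndEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [e.transcript_id for e in enrichments],
            "five_prime_level": [e.five_prime_level for e in enrichments],
            "three_prime_level": [e.three_prime_level for e in enrichments],
            "five_call": [e.five_call for e in enrichments],
            "three_call": [e.three_call for e in enrichments],
        }
    ).set_index("transcript_id")
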