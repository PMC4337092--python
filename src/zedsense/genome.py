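"""Genomic domain types and I/O for annotation and coverage.

All internal coordinates are 0-based, half-open ``[start, end)`` on the
forward reference strand; GFF3's 1-based closed convention is converted at
the file boundary and nowhere else.  Transcript ends are strand-aware: the
TSS of a minus-strand transcript is the *right* edge of its interval and
all flank arithmetic runs in the direction of transcription.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "Transcript",
    "TranscriptCatalog",
    "CoverageTrack",
    "read_annotation",
    "write_annotation",
    "read_coverage",
    "write_coverage",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "region_of",
]

Strand = Literal["+", "-", "."]

RegionKind = Literal[
    "five_prime_flank",
    "three_prime_flank",
    "five_prime_inner",
    "three_prime_inner",
    "cds_core",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named chromosome.

    ``start == end`` denotes an empty (degenerate) interval, produced only
    by region arithmetic on short transcripts; catalogued features are
    always non-empty.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.end == self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs, ignoring strand."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def clipped(self, chrom_length: int) -> "GenomicInterval":
        s = min(max(self.start, 0), chrom_length)
        e = min(max(self.end, 0), chrom_length)
        return GenomicInterval(self.chrom, s, max(s, e), self.strand)


@dataclass(frozen=True)
class Transcript:
    """A stranded transcript unit (coding ORF-T or candidate non-coding)."""

    id: str
    interval: GenomicInterval
    kind: Literal["coding", "noncoding"] = "coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id} must be stranded")
        if self.interval.is_empty:
            raise ValueError(f"transcript {self.id} has an empty interval")
        if self.kind not in ("coding", "noncoding"):
            raise ValueError(f"transcript {self.id}: bad kind {self.kind!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start: left edge for +, right edge for -."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        """Transcription end: the edge opposite the TSS."""
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class TranscriptCatalog:
    """All annotated transcripts plus the chromosome sizes they live on."""

    transcripts: list[Transcript]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.transcripts:
            if t.id in seen:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            seen.add(t.id)
            size = self.chrom_sizes.get(t.chrom)
            if size is None:
                raise ValueError(f"{t.id}: unknown chromosome {t.chrom!r}")
            if t.interval.end > size:
                raise ValueError(
                    f"{t.id}: interval end {t.interval.end} exceeds "
                    f"{t.chrom} length {size}"
                )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def by_id(self, tid: str) -> Transcript:
        try:
            return self._index[tid]
        except AttributeError:
            self._index = {t.id: t for t in self.transcripts}
            return self._index[tid]

    def coding(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.kind == "coding"]

    def noncoding(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.kind == "noncoding"]

    def sorted_by_chrom(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in sorted(self.transcripts, key=lambda t: (t.chrom, t.interval.start, t.id)):
            out.setdefault(t.chrom, []).append(t)
        return out


@dataclass
class CoverageTrack:
    """Per-base-pair non-negative coverage, one array per chromosome."""

    values: dict[str, np.ndarray]
    total_mapped: float
    strand: Strand = "."

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: coverage must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative coverage values")
            self.values[chrom] = arr

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.values.items()}

    def total(self) -> float:
        return float(sum(a.sum() for a in self.values.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: a * factor for c, a in self.values.items()},
            total_mapped=self.total_mapped,
            strand=self.strand,
        )

    def mean_over(self, iv: GenomicInterval) -> float:
        """Mean value over an interval, clipped to the chromosome.

        Empty or fully-clipped intervals yield 0.
        """
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


# ---------------------------------------------------------------------------
# Region arithmetic


def region_of(
    t: Transcript,
    which: RegionKind,
    flank: int,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware anatomical region of a transcript.

    ``five_prime_flank``/``three_prime_flank`` are symmetric windows around
    the TSS/TES; the ``inner`` variants are the first/last ``flank`` bp
    inside the transcript in the direction of transcription; ``cds_core``
    is the transcript minus both inner flanks and may be empty (degenerate)
    for transcripts shorter than ``2 * flank``.  Regions are clipped to the
    chromosome when its length is given.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    s, e = t.interval.start, t.interval.end
    plus = t.strand == "+"
    tss, tes = t.tss, t.tes
    if which == "five_prime_flank":
        start, end = tss - flank, tss + flank
    elif which == "three_prime_flank":
        start, end = tes - flank, tes + flank
    elif which == "five_prime_inner":
        start, end = (tss, min(tss + flank, e)) if plus else (max(tss - flank, s), tss)
    elif which == "three_prime_inner":
        start, end = (max(tes - flank, s), tes) if plus else (tes, min(tes + flank, e))
    elif which == "cds_core":
        start, end = s + flank, e - flank
        if end <= start:  # degenerate: shorter than two inner flanks
            mid = (s + e) // 2
            start = end = mid
    else:
        raise ValueError(f"unknown region kind {which!r}")
    start = max(start, 0)
    end = max(end, start)
    iv = GenomicInterval(t.chrom, start, end, t.strand)
    if chrom_length is not None:
        iv = iv.clipped(chrom_length)
    return iv


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            chrom, size = parts
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# Annotation I/O


def read_annotation(
    path: str | os.PathLike,
    format: Literal["gff3", "bed12"] = "gff3",
    chrom_sizes: Mapping[str, int] | None = None,
) -> TranscriptCatalog:
    """Read a transcript catalogue from GFF3 or BED12.

    GFF3 chromosome lengths come from ``##sequence-region`` pragmas unless
    ``chrom_sizes`` is given; BED12 always requires ``chrom_sizes``.
    Noncoding transcripts are marked in BED12 by ``thickStart == thickEnd``
    and in GFF3 by a ``noncoding_transcript``/``ncRNA`` feature type.
    """
    if format == "gff3":
        return _read_gff3(path, chrom_sizes)
    if format == "bed12":
        if chrom_sizes is None:
            raise ValueError("BED12 input requires chrom_sizes")
        return _read_bed12(path, chrom_sizes)
    raise ValueError(f"unknown annotation format {format!r}")


_GFF_CODING_TYPES = {"transcript", "mRNA", "gene"}
_GFF_NONCODING_TYPES = {"noncoding_transcript", "ncRNA", "antisense_RNA"}


def _read_gff3(path, chrom_sizes):
    import gffutils

    sizes: dict[str, int] = dict(chrom_sizes) if chrom_sizes else {}
    if not chrom_sizes:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, start, end = line.split()
                    sizes[chrom] = int(end)
                elif not line.startswith("#"):
                    break
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several parser error types
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc
    transcripts: list[Transcript] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in _GFF_CODING_TYPES | _GFF_NONCODING_TYPES:
            continue
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"{path}: feature {feat.id!r} lacks a strand"
            )
        kind = "noncoding" if feat.featuretype in _GFF_NONCODING_TYPES else "coding"
        # GFF3 is 1-based closed; internal is 0-based half-open.
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        transcripts.append(Transcript(feat.id, iv, kind))
    return TranscriptCatalog(transcripts, sizes)


def _read_bed12(path, chrom_sizes):
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            thick_start, thick_end = int(parts[6]), int(parts[7])
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing strand")
            kind = "noncoding" if thick_start == thick_end else "coding"
            iv = GenomicInterval(chrom, int(start), int(end), strand)
            transcripts.append(Transcript(name, iv, kind))
    return TranscriptCatalog(transcripts, dict(chrom_sizes))


def write_annotation(
    catalog: TranscriptCatalog,
    path: str | os.PathLike,
    format: Literal["gff3", "bed12"] = "gff3",
) -> None:
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(catalog.chrom_sizes):
                fh.write(f"##sequence-region {chrom} 1 {catalog.chrom_sizes[chrom]}\n")
            for t in sorted(
                catalog.transcripts, key=lambda t: (t.chrom, t.interval.start, t.id)
            ):
                ftype = "transcript" if t.kind == "coding" else "noncoding_transcript"
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "zedsense",
                            ftype,
                            str(t.interval.start + 1),
                            str(t.interval.end),
                            ".",
                            t.strand,
                            ".",
                            f"ID={t.id}",
                        ]
                    )
                    + "\n"
                )
    elif format == "bed12":
        with open(path, "w") as fh:
            for t in sorted(
                catalog.transcripts, key=lambda t: (t.chrom, t.interval.start, t.id)
            ):
                s, e = t.interval.start, t.interval.end
                thick_e = e if t.kind == "coding" else s
                fh.write(
                    "\t".join(
                        [
                            t.chrom, str(s), str(e), t.id, "0", t.strand,
                            str(s), str(thick_e), "0", "1",
                            f"{e - s},", "0,",
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Coverage I/O (bedGraph)


def read_coverage(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int],
    strand: Strand = ".",
    total_mapped: float | None = None,
) -> CoverageTrack:
    """Read a bedGraph into per-bp arrays; uncovered bases are 0.

    Overlapping intervals are rejected (the per-bp value would be
    ambiguous).  ``total_mapped`` defaults to the summed signal.
    """
    values = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = parts
            if chrom not in values:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            s, e, v = int(start), int(end), float(value)
            if s < 0 or e > len(values[chrom]) or s >= e:
                raise ValueError(f"{path}:{lineno}: interval out of bounds")
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative value")
            if covered[chrom][s:e].any():
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph intervals")
            covered[chrom][s:e] = True
            values[chrom][s:e] = v
    track = CoverageTrack(values, total_mapped=0.0, strand=strand)
    track.total_mapped = float(total_mapped) if total_mapped is not None else track.total()
    return track


def write_coverage(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a run-length-encoded bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    # .17g round-trips IEEE doubles exactly
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")
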