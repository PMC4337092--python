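"""Shared fixtures: a genome-scale simulation processed once per session,
plus factories for tiny hand-built catalogs and tracks."""

import numpy as np
import pytest

from zedsense.chip import (
    normalize_rpm,
    quantify_end_enrichment,
    subtract_background,
)
from zedsense.genome import CoverageTrack, GenomicInterval, Transcript, TranscriptCatalog
from zedsense.rna import classify_antisense
from zedsense.simulate import (
    SimulationConfig,
    simulate_chip,
    simulate_genome,
    simulate_rna,
)


@pytest.fixture(scope="session")
def paper_sim():
    """4000-gene simulation at study-condition rates, fully processed.

    Built once per session: genome + planted truth, ChIP/input tracks,
    background-subtracted signal, end-enrichment calls and antisense
    assignments.  All structure-recovery tests share it.
    """
    cfg = SimulationConfig(seed=11)
    catalog, truth = simulate_genome(cfg)
    chip, inp = simulate_chip(catalog, truth, cfg)
    signal = subtract_background(normalize_rpm(chip), normalize_rpm(inp), k=1.2)
    enrichment = quantify_end_enrichment(signal, catalog, window=150)
    assignments, orphans = classify_antisense(catalog.noncoding(), catalog.coding())
    return {
        "config": cfg,
        "catalog": catalog,
        "truth": truth,
        "chip": chip,
        "input": inp,
        "signal": signal,
        "enrichment": enrichment,
        "assignments": assignments,
        "orphans": orphans,
    }


@pytest.fixture(scope="session")
def paper_sim_rna(paper_sim):
    """Replicated two-condition RNA counts for the session simulation."""
    return simulate_rna(
        paper_sim["catalog"], paper_sim["truth"], paper_sim["config"], tracks_for=[]
    )


def make_transcript(tid, start, end, strand="+", chrom="chrI", kind="coding"):
    return Transcript(tid, GenomicInterval(chrom, start, end, strand), kind)


def make_catalog(transcripts, chrom_sizes=None):
    if chrom_sizes is None:
        chrom_sizes = {}
        for t in transcripts:
            chrom_sizes[t.chrom] = max(chrom_sizes.get(t.chrom, 0), t.interval.end + 1000)
    return TranscriptCatalog(list(transcripts), chrom_sizes)


def make_track(values, chrom="chrI", strand=".", total_mapped=None):
    arr = np.asarray(values, dtype=float)
    if total_mapped is None:
        total_mapped = float(arr.sum()) or 1.0
    return CoverageTrack({chrom: arr}, total_mapped=total_mapped, strand=strand)
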