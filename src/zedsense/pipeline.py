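"""End-to-end orchestration: simulate -> chip -> rna -> associate -> de -> arrange.

Every stage is a pure function of (inputs, parameters, seed); the report
directory is written with stable schemas and sorted keys so a rerun with
the same config and seed is byte-identical.  The pipeline never looks at
the simulator's ground truth — antisense presence, occupancy calls and
differential expression are all inferred from the generated data, exactly
as they would be from real tracks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrangement import (
    arrangement_frame,
    category_enrichment,
    category_signal,
    class_fold_change_comparison,
    classify_arrangement,
    classify_htz_pattern,
)
from .association import associate_peak, overlap_contingency, randomization_test
from .chip import (
    cluster_profiles,
    end_enrichment_frame,
    metagene_profile,
    normalize_rpm,
    occupancy_vectors,
    partition_signal,
    quantify_end_enrichment,
    subtract_background,
)
from .diffexpr import test_differential, write_de_table
from .genome import region_of, write_coverage
from .rna import assignment_frame, classify_antisense, normalize_stranded, quantify_transcripts
from .simulate import (
    CONDITIONS,
    SimulationConfig,
    simulate_chip,
    simulate_genome,
    simulate_rna,
)
from .stats import quantile_bins

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline"]

logger = logging.getLogger(__name__)

#: fixed offset separating the randomisation-test stream from the
#: simulator streams fanned out from the same master seed
_RANDOMIZATION_OFFSET = 104729


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters plus the simulation block and master seed."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    k: float = 1.2  # background threshold multiplier (mean + k*SD of ratios)
    flank: int = 300  # 5'/3' anatomy window half-width
    window: int = 150  # end-enrichment / peak window
    fold_threshold: float = 3.0  # downstream/upstream RNA association rule
    pseudocount: float = 0.1
    n_regions: int | None = None  # randomisation draw size; default = n high genes
    iters: int = 1000
    alpha: float = 0.05
    close_threshold: int = 300
    min_overlap: float = 0.5
    k_quantiles: int = 7
    n_clusters: int = 4
    run_clustering: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig.from_dict(self.simulate)
        if self.k < 0 or self.flank <= 0 or self.window <= 0:
            raise ValueError("k must be >= 0 and flank/window positive")
        if self.fold_threshold <= 0 or self.pseudocount <= 0:
            raise ValueError("fold_threshold and pseudocount must be positive")
        if self.iters < 1 or self.k_quantiles < 2 or self.n_clusters < 1:
            raise ValueError("iters, k_quantiles, n_clusters out of range")
        if not 0 < self.min_overlap <= 1 or not 0 < self.alpha < 1:
            raise ValueError("min_overlap in (0,1], alpha in (0,1)")
        # fan the master seed out to the simulator
        self.simulate = dataclasses.replace(self.simulate, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    """In-memory copies of every pipeline output plus the summary dict."""

    partition: pd.DataFrame
    end_enrichment: pd.DataFrame
    contingency: dict
    randomization: dict
    links: pd.DataFrame
    de: pd.DataFrame
    arrangement: pd.DataFrame
    category_signal: pd.DataFrame
    category_enrichment: dict
    pattern_classes: pd.DataFrame
    class_comparison: pd.DataFrame
    quantile_summary: pd.DataFrame
    replicate_qc: dict
    summary: dict


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> ReportBundle:
    """Execute every stage in dependency order and write the report.

    Raises :class:`PipelineError` naming the failing stage; outputs of a
    failed run are flagged by a ``<stage>.incomplete`` marker file left in
    the output directory.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    state: dict = {}

    def stage(name, fn):
        marker = os.path.join(outdir, f"{name}.incomplete")
        with open(marker, "w") as fh:
            fh.write("stage in progress\n")
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        os.remove(marker)
        logger.info("stage %s complete", name)

    def _simulate():
        catalog, truth = simulate_genome(config.simulate)
        chip, inp = simulate_chip(catalog, truth, config.simulate)
        state.update(catalog=catalog, truth=truth, chip=chip, input=inp)
        inputs = os.path.join(outdir, "inputs")
        os.makedirs(inputs, exist_ok=True)
        from .genome import write_annotation, write_chrom_sizes

        write_annotation(catalog, os.path.join(inputs, "annotation.gff3"))
        write_chrom_sizes(catalog.chrom_sizes, os.path.join(inputs, "chrom.sizes"))
        write_coverage(chip, os.path.join(inputs, "chip.bedgraph"))
        write_coverage(inp, os.path.join(inputs, "input.bedgraph"))
        truth.genes.to_csv(os.path.join(inputs, "ground_truth_genes.tsv"), sep="\t")

    def _chip():
        catalog = state["catalog"]
        signal = subtract_background(
            normalize_rpm(state["chip"]), normalize_rpm(state["input"]), k=config.k
        )
        state["signal"] = signal
        write_coverage(signal.as_coverage(), os.path.join(outdir, "chip_signal.bedgraph"))
        part = partition_signal(signal, catalog, flank=config.flank)
        state["partition"] = part
        _write_tsv(part.table, os.path.join(outdir, "partition.tsv"))
        for mode in ("tss_aligned", "tes_aligned"):
            prof = metagene_profile(signal, catalog, mode, span=config.flank)
            _write_tsv(
                prof.to_frame().set_index("position"),
                os.path.join(outdir, f"metagene_{mode}.tsv"),
            )
        enr = quantify_end_enrichment(signal, catalog, window=config.window)
        state["end_enrichment"] = enr
        state["end_frame"] = end_enrichment_frame(enr)
        _write_tsv(state["end_frame"], os.path.join(outdir, "end_enrichment.tsv"))
        if config.run_clustering:
            vectors = occupancy_vectors(signal, catalog)
            _write_tsv(vectors, os.path.join(outdir, "occupancy_vectors.tsv"))
            labels, _ = cluster_profiles(vectors, config.n_clusters)
            _write_tsv(labels.to_frame(), os.path.join(outdir, "clusters.tsv"))

    def _rna():
        catalog = state["catalog"]
        rna = simulate_rna(catalog, state["truth"], config.simulate)
        if rna is None:
            raise FileNotFoundError("no RNA input available")
        state["rna"] = rna
        inputs = os.path.join(outdir, "inputs")
        rna.counts.to_csv(os.path.join(inputs, "counts.tsv"), sep="\t")
        for (cond, rep), expr in rna.expressions.items():
            write_coverage(expr.plus, os.path.join(inputs, f"rna_{cond}_{rep}.plus.bedgraph"))
            write_coverage(expr.minus, os.path.join(inputs, f"rna_{cond}_{rep}.minus.bedgraph"))
        normalized = {
            key: normalize_stranded(expr, catalog) for key, expr in rna.expressions.items()
        }
        state["normalized"] = normalized
        levels = {}
        for (cond, rep), expr in normalized.items():
            levels[f"{cond}_{rep}"] = quantify_transcripts(expr, catalog)
        state["levels"] = pd.DataFrame(levels)
        _write_tsv(state["levels"], os.path.join(outdir, "transcript_levels.tsv"))
        # a noncoding transcript is "detected" when it has any reads in the
        # exosome-mutant (first) condition
        base_cols = [c for c in rna.counts.columns if c.startswith(f"{CONDITIONS[0]}_rep")]
        detected = rna.counts.loc[
            [t.id for t in catalog.noncoding()], base_cols
        ].sum(axis=1)
        detected_ids = set(detected[detected > 0].index)
        noncoding = [t for t in catalog.noncoding() if t.id in detected_ids]
        assignments, orphans = classify_antisense(
            noncoding, catalog.coding(), min_overlap=config.min_overlap
        )
        state["assignments"] = assignments
        state["orphans"] = orphans
        _write_tsv(assignment_frame(assignments), os.path.join(outdir, "antisense_assignments.tsv"))

    def _associate():
        catalog = state["catalog"]
        enr_df = state["end_frame"]
        high = set(enr_df.index[enr_df["three_call"] == "high"])
        state["contingency"] = overlap_contingency(
            state["end_enrichment"], state["assignments"]
        )
        expr = next(iter(state["normalized"].values()))
        rows = []
        for t in state["catalog"].coding():
            if t.id not in high:
                continue
            win = region_of(t, "three_prime_inner", config.window, catalog.chrom_sizes[t.chrom])
            peak = dataclasses.replace(win, strand="-" if t.strand == "+" else "+")
            link = associate_peak(
                peak,
                expr,
                gene_id=t.id,
                window=config.window,
                fold_threshold=config.fold_threshold,
                pseudocount=config.pseudocount,
            )
            rows.append(
                (t.id, link.downstream_mean, link.upstream_mean, link.fold, link.associated)
            )
        links = pd.DataFrame(
            rows, columns=["gene_id", "downstream_mean", "upstream_mean", "fold", "associated"]
        ).set_index("gene_id")
        state["links"] = links
        _write_tsv(links, os.path.join(outdir, "peak_links.tsv"))
        rand = randomization_test(
            catalog,
            state["assignments"],
            high,
            n_regions=config.n_regions,
            width=config.window,
            iters=config.iters,
            seed=config.seed + _RANDOMIZATION_OFFSET,
        )
        state["randomization"] = rand
        pd.DataFrame({"null_count": rand.null_counts}).to_csv(
            os.path.join(outdir, "randomization_null.tsv"), sep="\t", index_label="iteration"
        )
        with open(os.path.join(outdir, "contingency.json"), "w") as fh:
            json.dump(
                {
                    "contingency": state["contingency"].to_dict(),
                    "randomization": rand.to_dict(),
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    def _de():
        rna = state["rna"]
        de = test_differential(
            rna.counts, rna.design, alpha=config.alpha, strand_class=rna.strand_class
        )
        state["de"] = de
        write_de_table(de, os.path.join(outdir, "differential_expression.tsv"))

    def _arrange():
        catalog = state["catalog"]
        de = state["de"]
        calls = classify_arrangement(catalog, close_threshold=config.close_threshold)
        state["arrangement"] = calls
        _write_tsv(arrangement_frame(calls), os.path.join(outdir, "arrangement.tsv"))
        cat_sig = category_signal(state["end_enrichment"], calls)
        state["category_signal"] = cat_sig
        _write_tsv(cat_sig, os.path.join(outdir, "category_signal.tsv"))
        hosts = {
            a.transcript_id: a.host_gene_id
            for a in state["assignments"]
            if not a.excluded_convergent
        }
        down_as = de[(de["class"] == "antisense") & (de["call"] == "down")]
        down_hosts = {hosts[t] for t in down_as.index if t in hosts}
        state["down_hosts"] = down_hosts
        cat_enr = {
            c: r.to_dict() for c, r in category_enrichment(down_hosts, calls).items()
        }
        state["category_enrichment"] = cat_enr
        with open(os.path.join(outdir, "category_enrichment.json"), "w") as fh:
            json.dump(cat_enr, fh, indent=2, sort_keys=True)
        # default universe: genes with a detected antisense transcript;
        # fall back to all genes when none were detected (tiny runs)
        universe = set(hosts.values()) or None
        classes = classify_htz_pattern(state["end_enrichment"], universe=universe)
        state["pattern_classes"] = classes
        cls_df = pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in classes],
                "pattern_class": [c.pattern_class for c in classes],
            }
        ).set_index("gene_id")
        _write_tsv(cls_df, os.path.join(outdir, "pattern_classes.tsv"))
        sense_de = de[de["class"] == "sense"]
        comparison = class_fold_change_comparison(classes, sense_de)
        state["class_comparison"] = comparison
        _write_tsv(comparison, os.path.join(outdir, "class_fold_change.tsv"))
        # occupancy-vs-antisense-level quantile bins (7 by default)
        enr_df = state["end_frame"]
        as_levels = state["levels"].filter(regex=f"^{CONDITIONS[0]}_rep").mean(axis=1)
        rows = []
        host_level = {
            g: as_levels.get(t, np.nan) for t, g in hosts.items()
        }
        pool = enr_df.loc[enr_df.index.intersection(host_level.keys())]
        if len(pool) >= config.k_quantiles:
            bins = quantile_bins(pool["three_prime_level"].to_numpy(), config.k_quantiles)
            lv = np.array([host_level[g] for g in pool.index])
            for b in range(config.k_quantiles):
                sel = bins == b
                rows.append(
                    (b, int(sel.sum()), float(np.nanmean(lv[sel])) if sel.any() else np.nan)
                )
        qdf = pd.DataFrame(rows, columns=["bin", "n_genes", "mean_antisense_level"]).set_index("bin")
        state["quantile_summary"] = qdf
        _write_tsv(qdf, os.path.join(outdir, "quantile_bins.tsv"))

    def _report():
        rna = state["rna"]
        qc = {}
        for cond in sorted(set(rna.design)):
            cols = [c for c in rna.counts.columns if c.startswith(f"{cond}_rep")]
            if len(cols) >= 2:
                r = float(np.corrcoef(rna.counts[cols[0]], rna.counts[cols[1]])[0, 1])
                qc[cond] = r
        state["qc"] = qc
        enr_df = state["end_frame"]
        cls = state["pattern_classes"]
        summary = {
            "provenance": {
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "zedsense_version": __version__,
            },
            "partition_percent": {
                c: round(state["partition"].percent(c), 6)
                for c in state["partition"].table.index
            },
            "n_genes": len(state["catalog"].coding()),
            "n_detected_antisense": len(state["assignments"]),
            "n_orphans": len(state["orphans"]),
            "three_call_counts": enr_df["three_call"].value_counts().to_dict(),
            "contingency": state["contingency"].to_dict(),
            "randomization": state["randomization"].to_dict(),
            "peak_links": {
                "n_high_genes": int(len(state["links"])),
                "n_associated": int(state["links"]["associated"].sum()),
            },
            "de_calls": state["de"]["call"].value_counts().to_dict(),
            "n_down_antisense_hosts": len(state["down_hosts"]),
            "pattern_class_counts": pd.Series(
                [c.pattern_class for c in cls]
            ).value_counts().sort_index().to_dict(),
            "replicate_pearson_r": qc,
        }
        state["summary"] = summary
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)

    stage("simulate", _simulate)
    stage("chip", _chip)
    stage("rna", _rna)
    stage("associate", _associate)
    stage("de", _de)
    stage("arrange", _arrange)
    stage("report", _report)

    return ReportBundle(
        partition=state["partition"].table,
        end_enrichment=state["end_frame"],
        contingency=state["contingency"].to_dict(),
        randomization=state["randomization"].to_dict(),
        links=state["links"],
        de=state["de"],
        arrangement=arrangement_frame(state["arrangement"]),
        category_signal=state["category_signal"],
        category_enrichment=state["category_enrichment"],
        pattern_classes=pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in state["pattern_classes"]],
                "pattern_class": [c.pattern_class for c in state["pattern_classes"]],
            }
        ).set_index("gene_id"),
        class_comparison=state["class_comparison"],
        quantile_summary=state["quantile_summary"],
        replicate_qc=state["qc"],
        summary=state["summary"],
    )
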