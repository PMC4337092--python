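# zedsense

Analysis toolkit linking 3′-end occupancy of the histone variant H2A.Z
(Htz1 in budding yeast) to antisense transcript initiation and abundance,
built for compact, gene-dense genomes and runnable at desk scale on
simulated data with planted ground truth.

H2A.Z is best known for occupying the nucleosomes flanking the
transcription start sites (TSSs) of protein-coding genes. In yeast strains
lacking the exosome subunit Rrp6, normally unstable non-coding transcripts
become visible, and many of them initiate on the antisense strand within
the 3′ end of a protein-coding gene — exactly where a secondary class of
H2A.Z peaks sits. This package implements the full chain of inference for
that association, for anyone who wants to run it on their own ChIP-seq and
strand-specific RNA-seq tracks or to study its statistical behaviour on
simulations:

- **ChIP background model.** Both ChIP and input are scaled to reads per
  million; the per-base ratio r(x) = ChIP(x)/input(x) defines a background
  B = mean(r) + k·SD(r) with k = 1.2, and the final signal is
  max(r(x) − B, 0). Positions without input coverage are masked.
- **Gene-anatomy summaries.** Signal partition into 5′ (TSS ± 300 bp),
  CDS, 3′ (TES ± 300 bp) and intergenic territory with RPKM-like
  densities; TSS/TES-aligned and length-rescaled metagene profiles;
  25-window occupancy vectors (9 TSS + 10 CDS + 6 TES windows of 50 bp)
  with Euclidean average-linkage clustering.
- **End enrichment.** Mean signal over the first/last 150 bp of each gene,
  with a three-tier call (none / intermediate / high) and a four-class
  5′/3′ pattern scheme (class 1 = 5′ only … class 4 = 3′ only).
- **Strand-specific RNA.** Sense-anchored normalisation (total annotated
  sense signal scaled to 10⁸ arbitrary units, the same factor applied to
  the antisense strand), per-kilobase transcript levels, and antisense
  assignment to opposite-strand host genes with exclusion of candidates
  that overlap a same-strand convergent gene.
- **Association statistics.** The >3-fold downstream/upstream RNA rule for
  linking a peak to a transcript; the high-vs-none 2×2 contingency with
  log-space two-sided Fisher p-values (stable down past 10⁻³⁰⁰) and
  independence expectations; and a randomisation null that redraws peak
  positions from gene 3′ ends 1000 times (add-one empirical p, never
  exactly zero).
- **Differential expression stand-in.** A calibrated negative-binomial
  likelihood-ratio test (median-of-ratios size factors, trended dispersion
  with conservative maximum sharing, Benjamini–Hochberg adjustment), plus
  an import path for externally computed DE tables.
- **Gene arrangement.** Tandem/convergent classification of each gene's
  3′-side neighbour with a 300 bp close/far threshold, per-category signal
  shares and Fisher enrichment of down-regulated-antisense hosts.
- **Simulator.** `zedsense.simulate` generates an annotated genome of
  tandem/convergent gene pairs, ChIP/input coverage with planted 5′ and 3′
  peaks, and replicated two-condition NB counts in which antisense
  transcripts of 3′-marked genes are knocked down and their host sense
  transcripts reciprocally increased — so every stage of the pipeline can
  be validated against known truth.

## Worked example

```python
from zedsense.simulate import SimulationConfig, simulate_genome, simulate_chip
from zedsense.chip import (normalize_rpm, subtract_background,
                           quantify_end_enrichment, end_enrichment_frame)
from zedsense.rna import classify_antisense
from zedsense.association import overlap_contingency, randomization_test

cfg = SimulationConfig(n_genes=1000, seed=7)
catalog, truth = simulate_genome(cfg)
chip, inp = simulate_chip(catalog, truth, cfg)
signal = subtract_background(normalize_rpm(chip), normalize_rpm(inp), k=1.2)
print(f"background B = {signal.background:.3f}")

enrichment = quantify_end_enrichment(signal, catalog, window=150)
assignments, orphans = classify_antisense(catalog.noncoding(), catalog.coding())
res = overlap_contingency(enrichment, assignments)
print("table:", res.table, f"odds ratio {res.odds_ratio:.1f}, Fisher p {res.p_value:.3g}")

high = set(end_enrichment_frame(enrichment).query("three_call == 'high'").index)
rand = randomization_test(catalog, assignments, high, iters=1000, seed=8)
print(f"observed {rand.observed_count}, null mean {rand.null_counts.mean():.1f}, "
      f"empirical p {rand.empirical_p:.4g}")
```

Output:

```
background B = 1.762
table: ((104, 84), (32, 654)) odds ratio 25.3, Fisher p 1.88e-53
observed 104, null mean 27.5, empirical p 0.000999
```

Reading this: of 188 genes called `high` for 3′ occupancy, 104 host an
antisense transcript versus 32 of 686 genes called `none` — an odds ratio
of 25 with an overwhelming Fisher p. Redrawing 188 random gene 3′ windows
1000 times never reaches the observed 104 co-localisations, so the
empirical p is at its add-one floor 1/1001.

The same analysis runs from the shell:

```bash
zedsense simulate --seed 7 --out sim/
zedsense chip --chip sim/chip.bedgraph --input sim/input.bedgraph \
              --annotation sim/annotation.gff3 --out chip_out/
zedsense run --seed 7 --out full_run/        # all stages + report.json
```

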