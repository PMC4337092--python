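# Methods

This note documents the models, conventions and numerical choices behind
zedsense, and what its simulation-based validation does and does not show.

## Coordinates and regions

All internal coordinates are 0-based half-open on the forward strand;
GFF3's 1-based closed convention is converted only at file I/O. TSS and
TES are strand-aware interval edges: for a minus-strand transcript the TSS
is the right edge and all flank arithmetic runs in the direction of
transcription. Regions extending past a chromosome end are clipped, and
window means divide by the clipped length, so short transcripts and
chromosome edges carry no systematic bias. A transcript shorter than twice
the inner flank has an empty (degenerate) CDS core; such transcripts are
excluded from length-rescaled profiles and from 25-window vectors, with a
logged reason. Empty intervals are representable (`start == end`) purely
as outputs of region arithmetic; catalogued features must be non-empty.

## ChIP background model

Both ChIP and input tracks are scaled to reads per million (RPM). The
per-base ratio r(x) = ChIP(x)/input(x) is defined where input coverage is
positive; zero-input positions are masked — excluded from the moments and
zeroed in the output — rather than pseudocounted, to avoid inventing a
smoothing constant. The background is

    B = mean(r) + k · SD(r),    k = 1.2 (sample SD, ddof = 1)

computed genome-wide by default (a per-chromosome flag exists), and the
signal is max(r(x) − B, 0) in ratio units. Subtracting B from the *ratio*
is the only dimensionally consistent reading of a threshold defined on
ratios; k and the moments' scope are configuration-exposed. With k = 0 and
symmetric ratio noise, half of all positions are zeroed (B is then the
mean); with constant ratios the signal is identically zero.

## Gene-anatomy partition and profiles

Each base is assigned to exactly one category — 5′ (TSS ± 300 bp), 3′
(TES ± 300 bp), CDS (rest of the gene body), IGR (everything else) — with
precedence 5′ > 3′ > CDS > IGR when windows of neighbouring genes overlap.
The precedence is deliberately conservative for the central claim: in a
compact genome a gene's 3′ window often abuts the next gene's promoter,
and any contested base is credited to the promoter, so 3′ signal is never
inflated by neighbouring 5′ peaks. Densities are RPKM-like:
share of signal × 10⁹ / (category length × total signal).

Metagene profiles average signal at strand-aware offsets around the TSS
or TES, or linearly interpolate each CDS core onto a fixed number of bins;
each output position records how many genes contributed. The 25-window
occupancy vector spans [TSS−300, TSS+150) in nine 50-bp windows (the
−2/−1/+1 nucleosome region at canonical ~150 bp spacing), ten equal-width
windows over the CDS core, and [TES−150, TES+150) in six 50-bp windows.
The exact placement is an interpretation — only the window counts are
fixed by the design — and is documented here and configurable. Clustering
uses Euclidean distance with average linkage (the linkage was an open
choice); rows are sorted by transcript id first so results are independent
of input order.

## End enrichment and occupancy calls

5′ and 3′ levels are mean signal over the first/last 150 bp inside the
transcript. The three-tier call is: `none` iff the background-subtracted
level is exactly 0; `high` iff the level is at least the mean of all
strictly positive levels; `intermediate` otherwise. No published threshold
exists for these tiers; the positive-mean rule is scale-invariant, has no
free constant, and cleanly separates planted peaks from residual noise
(noise-only windows are mostly exactly zero after subtraction, and the few
positive stragglers sit far below the positive mean). The four-class
5′/3′ pattern scheme instead uses the arithmetic mean over *all* genes in
the classified universe (including zeros) as the threshold pair (τ₅, τ₃),
the literal reading of "average occupancy"; a positive-only variant is
available. The classified universe defaults to genes with a detected
antisense transcript, falling back to all genes when none are detected.

## Strand-specific RNA

Normalisation is sense-anchored: the total signal attributable to
annotated coding transcripts is scaled to 10⁸ arbitrary units and the same
factor is applied to the antisense strand, preserving sense:antisense
ratios. (Whether the original convention summed annotated transcripts or
whole-strand totals is ambiguous; annotated-sum is the default and a
whole-strand flag exists.) Transcript levels are strand-matched signal per
kilobase. A non-coding transcript is assigned antisense to the
opposite-strand coding gene with the largest overlap when at least half of
the transcript overlaps (threshold configurable); candidates that also
overlap a coding gene on their own strand are flagged and excluded from
antisense quantification, since their signal is indistinguishable from
convergent read-through.

## Association statistics

A 3′ peak is associated with a transcript when mean RNA signal on the
putative antisense strand in the 150 bp downstream of the peak exceeds
the upstream mean more than 3-fold; a pseudocount of 0.1 signal units
keeps the zero/zero case at fold 1. The headline 2×2 table crosses
high-vs-none 3′ calls (intermediate genes excluded) with antisense
presence. Expected counts are the standard independence expectations
e_ij = (row_i × col_j)/N. The two-sided Fisher p sums hypergeometric point
masses no larger than the observed one (relative slack 10⁻⁷ for floating
ties), accumulated in log space, so genome-scale tables with p ≈ 10⁻²⁰⁰
are computed stably.

The randomisation null draws, in each of 1000 iterations, as many genes as
there are high-3′ genes, uniformly without replacement from all genes with
a defined 3′ window, and counts windows containing an antisense TSS
(strictly inside; a tolerance flag exists). The empirical p uses the
add-one estimator (1 + #{null ≥ observed})/(iterations + 1) and therefore
never returns literal zero; on small pools the null is exactly the
hypergeometric law, which the tests verify.

## Differential-expression stand-in

The DE stage is a deliberately simple NB likelihood-ratio test, not a
reimplementation of any published caller; when fidelity to a specific tool
matters, its output table can be imported instead (`load_de_table`).
Size factors are median-of-ratios over transcripts positive in every
sample. Per-transcript dispersions are method-of-moments estimates within
conditions; a trend α(m) = a₀ + a₁/m is fitted across transcripts and each
transcript uses the *larger* of its raw estimate and the trend ("maximum"
sharing). This conservative choice is what keeps the χ²(1) LRT from being
anti-conservative at two replicates per condition: on null simulations
(dispersion 0.1, mean ~100) the raw type-I error is ≈0.03–0.04 at nominal
0.05. Mean parameters are maximised by a monotone fixed-point iteration on
the score equation with size-factor offsets. Fold changes are
log2((q₂ + ½)/(q₁ + ½)) of size-factor-scaled condition means, monotone in
the counts. Sense and antisense transcripts are tested in one merged
matrix. All-zero transcripts get p = 1. BH adjustment and an α = 0.05 call
threshold complete the stage; α, the dispersion floor (10⁻³) and the
pseudocount are configurable.

## Gene arrangement

Each coding gene is classified by the nearest coding neighbour on its 3′
side (the side where antisense transcripts initiate): same transcription
direction → tandem, facing → convergent; the gap runs from the gene's TES
to the neighbour's proximal boundary and "close" means gap < 300 bp
(strictly; 300 itself is far). A minus-strand gene looks left, so a
divergent (5′–5′) pair is, by construction, never anyone's 3′-side
arrangement. The last gene on an arm is `undefined`. Overlapping
annotations clamp the gap at 0.

## The simulator

The generator emulates the study conditions end to end. Genes are placed
left-to-right on one chromosome; each consecutive pair draws an
arrangement category (defaults: tandem close 0.40, tandem far 0.20,
convergent close 0.25, convergent far 0.15; close gaps 60–299 bp, far gaps
301–1200 bp). A drawn convergent category is realisable only when the
current gene is on the plus strand; after a minus-strand gene a divergent
far spacer is inserted and the drawn category applies to the next pair, so
realised per-gene fractions only approximate the draw probabilities — the
realised arrangement of every gene is recorded in the ground truth and is
what downstream checks compare against.

Planted occupancy: 49% of genes get 5′ peaks (two Gaussian bumps, SD
50 bp, at the −1/+1 nucleosome positions); 3′ peaks go to 30% of tandem
and 5% of convergent genes (one bump centred in the 3′-inner window),
reproducing the finding that 3′ occupancy concentrates at tandem genes.
Antisense incidence is 0.52 given a 3′ peak and 0.05 without — the
genome-scale rates the analysis targets. Antisense TSSs are uniform within
the host's 3′-inner 150 bp window, on the opposite strand, extending into
the gene body. ChIP and input are independent truncated-normal noise
around a flat background (mean 20, SD 3); peak height 60 gives peak:input
ratios ≈ 4 against a background threshold B ≈ 1.8.

RNA counts are negative binomial (dispersion 0.1; sense mean 200,
antisense mean 60 — antisense transcripts are genuinely less abundant)
with two replicates per condition. In the deletion condition, antisense
transcripts of 3′-marked hosts are scaled by 0.25 (a 4-fold knock-down)
and their hosts by 1.5 (the reciprocal sense coupling). Coverage tracks
spread counts uniformly over the transcript span on its own strand.
Determinism: one RNG stream per artifact (genome, ChIP, RNA), derived from
the master seed by fixed offsets, so regenerating one artifact never
perturbs another and identical configs are bit-identical.

What the simulation does *not* emulate: mappability and GC bias, fragment
size effects, nucleosome-scale signal autocorrelation, transcript boundary
uncertainty, multiple chromosomes, and overlapping or nested gene
annotations. Passing recovery tests therefore shows the inference chain is
correct and well-calibrated under the stated generative model, not that
the biological conclusions hold for any particular real data set.

## Pipeline and problem sizes

The pipeline (simulate → chip → rna → associate → de → arrange → report)
is a pure function of config + seed; reruns are byte-identical, and the
report embeds the config, its hash and the package version. Default
validation problem sizes were chosen to make every statistical check
well-powered while keeping the whole suite around a minute: 4000 genes for
structure-recovery runs (the contingency then carries hundreds of counts
per cell), 2000 transcripts for DE calibration, 1000 randomisation
iterations (the add-one p floor is then 1/1001), and 60–200 genes for
smoke and determinism tests.

## Known limitations

- The three-tier occupancy rule keys `none` to an exact zero after
  background subtraction; data with pervasive low-level signal would push
  most genes into `intermediate` and thin out the high-vs-none table.
- The DE stand-in trades power for calibration (maximum dispersion
  sharing); with two replicates its calls are conservative, which is the
  right failure mode for the downstream enrichment tests but understates
  the number of affected transcripts.
- Arrangement classification considers only the nearest neighbour;
  operon-like multi-gene structures and nested genes are out of scope.
- The randomisation null redraws whole gene windows (not positions within
  them); a within-region uniform-placement alternative is available
  behind a flag.
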