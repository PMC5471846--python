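# Methods

This note documents the models, conventions, parameter choices and known
limitations of `compartmir`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and alphabets

All sequence positions are 1-based and inclusive. Within a 3' UTR,
position 1 is the first nucleotide after the stop codon, and a site's
`distance_to_stop` is `utr_start - 1` — the number of nucleotides strictly
between the stop codon and the site. Planting a site "at distance d"
therefore writes the seed match at UTR positions d+1..d+6, and scanning
recovers distance d. PAS records are written BED-style with half-open
coordinates. Transcript sequences are normalized to the DNA alphabet on
input; miRNAs are stored as RNA and compared internally in DNA.

## Transcript models and UTR annotation

The CDS is called as the longest ATG..stop ORF over all three frames, ties
broken toward the 5'-most start (a common longest-ORF convention; the
choice only matters for pathological sequences). 5'/3' UTRs are the
flanks; their lengths always partition the sequence.

PAS-based 3'-end correction moves the annotated end to the
highest-support PAS within ±`window` nt (default 50 nt, the typical scale
of cleavage-site heterogeneity; the true tolerance used in comparable
analyses is never stated, so it is exposed as a parameter). Ties break to
the record nearest the annotated end, then 3'-most. A correction that
would cut into the CDS is rejected and logged. Correction is deliberately
one-shot — an already-corrected transcript is returned unchanged — because
re-selection around a moved end could otherwise cascade through PAS
records that were outside the original window, and the operation is meant
to be idempotent. Records beyond the available sequence cannot extend it
(the generator provides no sequence past the true end); the end is clamped
to the sequence length.

## Normalization

Four routes, selected per run:

* **Internal-control regression** (default): per sample, the zero-intercept
  least-squares slope of its control-gene counts against a reference
  sample's; normalized value = value / slope. The regression goes through
  the origin because scale factors are multiplicative — an intercept would
  absorb background into the scale. The reference defaults to one global
  sample (first stage, RNP replicate 1). A per-stage reference was
  considered and rejected: the control panel is flat in both stage and
  fraction, and per-stage references rescale each stage by an arbitrary
  sample depth, which biases every between-stage differential call.
* **Geometric-median** and **median-of-ratios size factors**: the same
  median-of-ratios statistic (entities with any zero are excluded from the
  reference; an optional pseudocount is available and logged). These
  factors are defined up to a common rescaling; all recovery checks
  compare factor *ratios*.
* **Quantile**: sorted values replaced by cross-sample rank means, tied
  ranks interpolated.

The expression floor removes entities below the threshold (default 1) in
every sample. No FPKM is computed from reads — alignment is out of scope —
so the floor applies to whatever expression matrix is supplied.

With 24 control genes, the regression factor per sample carries a sampling
SD of a few percent even at small dispersion, because the zero-intercept
estimator is dominated by the largest controls (small effective n) and the
negative-binomial shot-noise term 1/mean persists at shallow depth. The
factor-recovery experiments therefore use the near-noiseless regime
(dispersion 0.001, control baselines 2000–20000 counts); at routine depths
the regression route is a few percent noisier than the 2000-gene
median-of-ratios routes, which the cross-method agreement check reflects.

## Enrichment calls and stage dynamics

Compartment calls use a two-sided Welch t on log2(count + 0.5) — the
offset absorbs zeros, the log matches the roughly lognormal counts, and
the Welch variant drops the equal-variance assumption, which is safer than
a pooled-variance t when fraction variances differ. A Wilcoxon rank-sum
p-value is reported alongside every t p-value but does not drive the call:
at the default three replicates its smallest attainable two-sided p is
0.1, so it serves as a cross-check at larger n. Defaults follow the
conventions of fractionation studies: α = 0.05 for small RNAs, α = 0.1 for
mRNA compartment calls, a minimum mean normalized count of 1 in at least
one fraction, and raw p-values (no multiple-testing correction) — an
optional Benjamini–Hochberg switch exists and is off by default, which
makes the calls anticonservative in exchange for comparability with the
raw-p convention; the BH route is strictly more conservative.

Between-stage differentials are the same Welch t within one fraction.
A miRNA "shifter" is RNP-classed at the earlier stage, significantly down
in RNPs and up in polysomes at the later stage. The conjunction of three
tests at three replicates detects roughly 60–80% of planted shifters, so
the reported shift fraction understates the planted one; it is reported,
never asserted against a target.

## Seed sites and duplex energies

A canonical site is an exact occurrence of the reverse complement of the
seed (miRNA nt 2–7) in the 3' UTR; types extend TargetScan-style (7mer-m8
requires a Watson–Crick m8 pair; 7mer-A1 an A opposite nt 1; 8mer both).
`utr_start/utr_end` always span the 6-nt seed match regardless of type.

The hybridization model is an intermolecular-only duplex: antiparallel,
non-crossing pairs with per-strand bulges/internal loops up to `max_loop`
(default 8) nucleotides between consecutive pairs. Two energy models:

* **simple** (default): −1 per Watson–Crick pair, −0.5 per G:U pair, +0.5
  per unpaired loop nucleotide — chosen so closed forms exist (a perfect
  n-pair duplex scores −n) and the dynamic program can be verified exactly
  against exhaustive enumeration;
* **nn**: an approximate RNA nearest-neighbor stack table (ten standard
  Watson–Crick stacks plus common G:U stacks; missing stacks contribute no
  bonus), with the same loop penalty.

Absolute energies are not calibrated to any published folding engine; all
downstream use is comparative (ranking and filtering sites), which is also
how such figures of merit are used in practice. `force_seed` clamps the
seed helix (Watson–Crick only — G:U is disallowed inside the forced seed,
matching the strict canonical-seed analysis; it is allowed outside) at an
exact seed-match offset and optimizes the 3'-supplementary arm and the
optional nt-1 pair; a window without a seed match returns +inf as the
"no site" sentinel. Energies are computed on a local window (default
60 nt) centered on each seed match rather than folding the whole UTR:
hybridization is local, and the window keeps the dynamic program
desk-scale. The DP and the exhaustive oracle in the tests share one
transition-cost definition, so their agreement (1000+ random instances,
free and forced, both models) is exact, not approximate.

## Association statistics

The compartment association is the 2×2 Pearson χ² (no Yates correction by
default, matching the plain-χ² convention; a flag exists) of mRNA class
(RNP/polysome) against "targeted by ≥1 RNP-enriched miRNA", with a
Haldane 0.5 correction for the odds ratio when a cell is zero. Pipeline
association and positional statistics default to **8mer sites only**: a
bare 6mer match occurs by chance every ~4 kb per miRNA, so with a pool of
miRNAs essentially every long UTR contains chance 6mers and a
presence/absence association would measure UTR length, not targeting.
8mers occur by chance every ~65 kb, giving a usable signal-to-background
ratio; the filter is configurable (`site_types_for_stats`).

Positional comparisons report Welch t, a log-scale t when all values are
positive, and the Wilcoxon rank-sum. The Wilcoxon p is exact (classic
count recurrence for the null distribution of U) whenever n_a + n_b ≤ 10
with no ties, and the tie-corrected normal approximation otherwise.
Multiple sites per (miRNA, mRNA) pair all enter positional comparisons by
default, with a best-(minimum-energy)-site-only mode available, since
which aggregation comparable analyses used is unstated; the target map
flags the minimum-energy site per pair so either view is a filter away.

Position-threshold discovery fits a random forest (default 200 trees in
the library, 100 in the pipeline; depth ≤ 3; √p feature subsampling) over
distance-to-stop, |energy|, site type and UTR length, and reports the
modal (rounded) split threshold on distance, a permutation importance for
distance, and stratified k-fold accuracy. The cited data-mining procedure
names no hyperparameters, so reproducibility won over fidelity: every fit
is seeded, and a single depth-1 stump mode (deterministic given the data)
exists for tests and for the pipeline's repeated-run settings.

## The synthetic-data generator

The generator's defaults are the study conditions; they are fixed once:

* 60 genes × 2 isoforms sharing a CDS (450–900 nt, no internal in-frame
  stop) and 5' UTR; 3' UTR lengths 10^Normal(2.7, 0.15) (short isoform)
  and 10^Normal(3.0, 0.15) (long) — log10-normal by construction, medians
  ~500 and ~1000 nt, chosen so proximal (365 nt) and distal (461 nt) sites
  usually fit their host UTRs;
* 24 miRNAs (20–23 nt), half RNP-assigned and half polysome-assigned per
  stage, with 37% of the RNP set flipping to polysomes at the last stage;
* planted sites are 8mers: short-UTR (RNP-destined) transcripts get 2
  proximal sites (Normal(365, 30)) of RNP miRNAs; long-UTR
  (polysome-destined) transcripts get 2 distal sites (Normal(461, 30)) of
  polysome miRNAs, plus — with probability 0.3 — one distal site of an RNP
  miRNA (the configuration under which distal targeting expels transcripts
  from RNPs). Distances are redrawn up to 10 times when they do not fit,
  then clipped to the largest feasible distance (logged), and only skipped
  when the UTR cannot host a site at all — clipping preserves the
  proximal < distal ordering on short UTRs instead of silently corrupting
  the truth;
* counts are negative-binomial (variance = mean + 0.05·mean²) around
  baseline × stage trend × fraction effect × per-sample depth factor
  (log-uniform 0.5–2 by default). Planted entities split a log2 fold
  change of 2 symmetrically between fractions; the 24 control transcripts
  have a fraction effect of exactly 1; RNP-destined transcripts trend up
  and polysome-destined down by 1 log2 unit per stage step, providing the
  between-stage differential structure. Three replicates per
  stage × fraction (replicate counts per fraction are never stated for
  such designs; three is the smallest testable choice and is noted as
  arbitrary). Dispersion 0 degenerates to deterministic rounded means,
  giving exact closed-form tests;
* PAS records cover 90% of transcripts at the true 3' end ± Normal(0, 10)
  nt;
* a no-effect switch (`positional_effect=False`) randomizes compartment
  assignment, miRNA identity and site placement jointly, giving a genuine
  null in which compartment, UTR length and site position are mutually
  independent;
* the miRNA-depleted scenario removes a configurable fraction (default
  0.8) of the miRNA pool before planting: depleted miRNAs' sites are never
  written, their counts collapse to ~1% of baseline, and transcripts
  recruited only by depleted miRNAs lose their planted enrichment. The
  knockout's transcriptome-wide destabilization is deliberately not
  modeled quantitatively — the scenario exists to test that the
  position–compartment association degrades, not to reproduce knockout
  biology.

Every generator draws from its own seeded substream, so outputs are
byte-identical across runs and independent of which other generators ran.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence composition beyond uniform random
background (no secondary structure, no conservation, no RBP motifs), read-
level artifacts (no FASTQ, no alignment, no positional coverage bias),
isoform-expression coupling beyond the planted trends, piRNAs, and any
non-canonical (seedless) miRNA targeting.

## Problem sizes and numerical choices

The default pipeline run (60 genes, 24 miRNAs, 3 stages × 2 fractions × 3
replicates) analyzes ~120 transcripts and ~600–800 scored sites and
completes in about a second, which is what makes the repeated-seed
experiments (50 matched wildtype/depleted/null runs) practical; the
recovery experiments use 2000 entities. Zeros in ratios are handled by the
+0.5 log offset; degenerate t-tests (zero variance in both groups)
resolve to p = 1 when means agree and p = 0 otherwise; degenerate 2×2
margins are reported as such with an undefined p (treated as "no
association" by scenario comparisons). The annotation step can mis-call a
CDS when a random out-of-frame ORF happens to outrun the planted one
(probability well under 1% per transcript at the default CDS lengths);
this is left in deliberately as realistic annotation noise.

## Known limitations

* Energies are model-based and uncalibrated; only comparisons are
  meaningful. The two shipped models' concordance is observable in the
  target map but is not asserted against any external engine.
* The compartment-call convention (raw p-values, per-context α) is
  anticonservative by design; the BH option changes the calls.
* The Wilcoxon exact path requires tie-free data; planted-distance data
  with heavy rounding fall back to the asymptotic approximation.
* PAS correction cannot lengthen a transcript beyond its available
  sequence.
* The shift-fraction estimate is power-limited at three replicates (see
  above).
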