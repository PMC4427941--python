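# Methods

## Setting

Circulating cell-free DNA (ccf DNA) in plasma is nucleosome-protected
fragmented DNA, in non-pregnant donors derived predominantly from
hematopoietic cells. In pregnancy it is a mixture: a fraction *f* (the fetal
fraction, typically 0.05–0.20) originates from the placenta. The placenta is
globally distinctive in its methylome — beyond focal differentially
methylated regions (DMRs) it carries megabase-scale hypomethylated domains
in regions of low CpG and gene density, analogous to the partially
methylated domains of tumors. This package implements the downstream
analyses of that setting on per-cytosine methylation counts, and a
generator that produces all inputs with planted ground truth.

## Coordinates and strand collapsing

All internal coordinates are 0-based half-open; the cytosine-report dialect
is 1-based and converted on read. A CpG dinucleotide produces a plus-strand
C call at position *p* and a minus-strand call at *p+1*; under the standard
assumption that strand-specific CpG methylation is rare, collapsing sums the
read counts of both strands onto the plus-strand coordinate and levels are
recalculated from the pooled counts (never averaged), so per-chromosome
methylated/unmethylated totals are conserved and the operation is
idempotent. Collapsing counts rather than averaging levels keeps deeply
covered strands from being under-weighted.

## Site statistics and DMR calling

Per group, each covered CpG site gets the mean and sample standard deviation
(n−1) of per-sample methylation fractions; a site requires coverage in at
least `min_samples` samples (default 2). The per-site statistic is the Welch
two-sample t from group summaries,
`t = (μ_A − μ_B)/sqrt(s_A²/n_A + s_B²/n_B)`, chosen over the pooled-variance
form because plasma cohorts are small and unbalanced and there is no
justification for equal variances; with equal group sizes the two statistics
coincide anyway. Sites with `|t| < 5` are removed (strict), survivors less
than 300 bp apart (strict) and with a common sign of the difference are
grouped, and groups of ≥ 9 CpGs are DMRs with end = last CpG + 2 so the
half-open interval covers the final dinucleotide. No multiple-testing
correction is applied — the fixed `|t| ≥ 5` cut is the procedure.

Degenerate sites where both groups have zero variance but unequal means get
a signed infinite sentinel so that maximally separated (fully methylated vs
fully unmethylated) sites pass any finite threshold instead of being
silently dropped; when the means also agree, t = 0.

## Domain detection

Chromosomes are tiled with fixed half-open bins (default 50 kbp; the last
bin may be short). A bin's group mean is the unweighted mean of per-site
group means in the bin (consistent with the summary layer); CpG density is
the site count and gene density counts overlapping gene intervals, so one
gene may contribute to several bins. A domain is a maximal run of
consecutive qualifying bins — both means defined, `cpg_count ≥ 10`, and
`μ_ref − μ_target ≥ δ` — of at least `min_run` bins, with no gap tolerance.
Defaults δ = 0.15 and min_run = 10 (500 kbp) are conservative: they call
nothing under the null while recovering megabase-scale planted domains
exactly. Domain-level means weight bins by CpG count so the summary reflects
site mass rather than bin count. The density-stratified differential
methylation table and its LOWESS smooth (span 0.3) are descriptive output
only and never used for calling.

## Fragment statistics

Fragment length is end − start of the sequenced pair. The long/short fold
ratio is implemented as a per-cytosine methylation-*rate* ratio: within each
size class the methylated-call count is divided by the total calls measured
in that class (this is the "scaling by cytosines measured"; odds-ratio and
raw-count readings are possible but less interpretable, and the rate ratio
is the one the generator can invert analytically). Fragments of exactly the
200 bp cutoff fall in the short class by default — a documented closed/open
split instead of silently dropping boundary data; `boundary="drop"` excludes
them. MCIp pair filtering discards pairs with start-to-start size > 500 bp
or discordant mate chromosomes; a negative size is an error rather than a
discard because it indicates mis-ordered input. Region membership of a
fragment uses its midpoint, which is unambiguous for border-straddling
fragments.

## Robust chromosome-21 z-score

Counts are restricted to a subset of hypomethylated domains, where
enrichment for unmethylated DNA preferentially retains placental DNA and so
multiplies the effective fetal fraction. Within each treatment
independently, the chr21 fraction's median and MAD come from known-euploid
samples only; the MAD is unscaled (plain median of absolute deviations),
matching the formula as printed, with the 1.4826-scaled variant behind a
flag. Test samples never contribute to the anchor, even if euploid. A zero
MAD is an error naming the stratum. Because 3 unscaled MADs ≈ 2.02 σ under
normality, the asymptotic two-sided rate beyond |z| = 3 is ≈ 4.3 %, and
small reference panels inflate it substantially (≈ 9 % at n = 9); the
calibration and power experiments therefore use a 192-sample euploid
reference panel — a realistic production panel size — while the default
simulated cohort remains the 12-donor proof-of-concept design (9 euploid +
3 trisomy-21). With only 9 references individual cohorts also show widely
varying enrichment folds; the panel size, not the statistic, is the remedy.

## Synthetic data

The generator emulates the statistical structure of the study rather than
sequence-level realism (no reads, no conversion errors, no mappability or
GC bias).

* **Sites.** CpG positions follow exponential spacing (mean 500 bp,
  ~2 kb⁻¹ density of measured non-CpG cytosines at a constant 0.2 %
  methylation); planted DMR loci are dense clusters (12 CpGs at 25 bp) and
  planted domains may thin the background (the experiments use 1250 bp
  spacing inside domains — 2.5× sparser than background — so domains sit in
  low-CpG-density regions while each 50 kbp bin still holds ~40 sites;
  much sparser spacing lets Poisson density fluctuations break the
  no-gap run rule at the 10-CpG bin floor).
* **Levels.** A shared "blood" base level per site from a beta mixture:
  10 % low (mean 0.05), 10 % intermediate, 80 % high (mean 0.90),
  concentration 20. The placenta shares this base outside planted features —
  an independent per-group draw would make group comparisons reject
  genome-wide. Planted domains scale placenta levels multiplicatively so the
  expected mean drop equals the configured depth (default 0.25) and no site
  leaves [0,1]; high-mode sites land in the intermediate band, which is
  exactly how the placental intermediate-methylation excess arises in this
  model. Planted DMRs overwrite both groups deterministically at
  0.97 vs 0.57 (effect 0.4): DMR loci are anchored near-fully methylated on
  the hypermethylated side because at ~15× coverage and 6 + 6 samples the
  Welch-t site power depends strongly on the binomial variance term
  p(1−p)/cov — a 0.9/0.5 contrast yields ~75 % per-site pass and poor
  region-level recovery, while 0.97/0.57 gives ~95 % (a power analysis done
  when the generator was designed). Configurations that would push any mean
  outside [0,1] are rejected, never clamped.
* **Counts.** Coverage ~ Poisson(15) per site and sample (echoing a
  >10× whole-genome regime without modeling mappability); per-sample levels
  are Beta-distributed around the site truth with concentration 200
  (between-sample SD ≈ 0.03 at intermediate levels), and methylated reads
  are binomial — i.e., beta-binomial counts. Pregnant ccf DNA is a per-read
  mixture: each read is placental with probability f. Optionally calls are
  split back onto two strands for strand-resolved reports.
* **Fragments.** Lengths from a three-component discretized gamma mixture —
  sub-nucleosomal (mode 80), mono-nucleosome (mode 168, weight 0.83) and
  di-nucleosome (mode 320, weight 0.12; this shoulder is what MCIp size
  fractionation separates). Per-cytosine methylation probability is
  logistic in length, `expit(α_ctx + β(len − 200)/100)`; the analytic fold
  ratio under the model is computed on the discretized length grid and β
  can be solved (Brent) for a target ratio. The sheared-genomic mode keeps
  the same lengths but severs the coupling (true ratio exactly 1). The
  adapter-trimming dip seen in real data near 92–98 bp and the 10 bp
  periodicity are deliberately not modeled; without the periodicity the
  1 bp-histogram argmax carries a few bp of multinomial jitter around
  168 at realistic sample sizes.
* **MCIp.** Each fragment enters the methylated fraction with probability
  `expit(a + b·m)`, m = methylated-CpG count (defaults a = −2, b = 1); the
  partition is exhaustive and exclusive.
* **Trisomy counts.** Per sample and treatment, multinomial over the 22
  autosomes with hg19-length-proportional baseline shares; trisomy-21
  scales the chr21 share by (1 + f_eff/2), f_eff = f (unenriched) or
  f × enrichment factor capped at 1 (enriched), 0 for euploids.
* **Seeding.** One global seed feeds a stable per-purpose seed tree
  (SHA-256 of the purpose key), so identical configurations are
  byte-identical across runs and products can be regenerated independently.

### What passing tests do and do not show

The generator's planted effects are homogeneous and its noise is exchangeable
across samples; real cohorts add covariate structure (age, gestational age),
batch effects, mappability holes, bisulfite-conversion failure and biological
heterogeneity of effect sizes. Recovery at the reference conditions therefore
demonstrates correctness of the procedures and their calibration under the
stated model, not expected field performance on clinical data.

## Experiment sizes

The validation experiments (`cfmethylome.experiments`) use: a 20 Mbp
single-chromosome genome with 50 planted DMRs (and 20 matched null seeds);
a 2 × 16 Mbp genome with ten 2 Mbp domains (20 null seeds); 60 k fragments
(~1.1 × 10⁵ CpG calls) for the fold-ratio recovery and 20 × 8 k for MCIp;
100 seeded cohorts each for z-score calibration and power; fetal fractions
0.05/0.10/0.20 on an 8 Mbp genome for the mixture recapitulation. These
sizes give comfortable Monte-Carlo margins for every asserted property
while keeping a full run in the minutes range on one CPU.

## Known limitations

* The DMR caller is the fixed-threshold procedure by design — no smoothing,
  HMMs or FDR control (out of scope).
* Domain calling has no gap tolerance; a single disqualified bin splits a
  domain. Real data with coverage holes may need the bin floor lowered or
  bins pre-filtered.
* The fold-ratio definition is one of several readings of
  "scaling for cytosines measured"; alternatives are selectable but not the
  default.
* `enrichment_fold` divides possibly near-zero unenriched z-scores; folds
  are reported per sample with NaN for z = 0 rather than winsorized.
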