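# cfmethylome

Downstream analysis of whole-genome bisulfite sequencing (WGBS) of
circulating cell-free DNA (ccf DNA) and its tissue contributors — the
methylome setting of non-invasive prenatal testing, where pregnant plasma
carries a mixture of maternal (hematopoietic) DNA and a minority fetal
fraction shed by the placenta.

The package is aimed at computational epigenomics work on plasma methylomes:
it consumes per-cytosine methylation reports (the Bismark-style CX dialect),
BED region sets, fragment tables and per-region count tables, and provides

* **Methylome I/O** — strand-aware cytosine-report parsing with collapsing of
  CpG calls onto the plus-strand C coordinate (counts summed, levels
  recalculated from pooled reads).
* **Summaries** — per-context methylation, 1 %-bin histograms of per-site
  mean methylation, low (<20 %) / intermediate / high (>75 %) classification,
  region profiles against a matched random background, group correlation.
* **DMR calling** — per-CpG group mean/SD over per-sample methylation
  fractions, a Welch t-statistic per site
  `t = (μ_A − μ_B) / sqrt(s_A²/n_A + s_B²/n_B)`,
  removal of sites with `|t| < 5`, grouping of surviving sites separated by
  `< 300` bp (with uniform sign of the difference), and a call when a group
  holds `≥ 9` CpG sites.
* **Hypomethylated-domain detection** — 50 kbp genomic bins with per-group
  mean methylation, CpG and gene density; maximal runs of consecutive bins
  with `μ_ref − μ_target ≥ δ` become placenta hypomethylated domains (PHDs);
  density-stratified differential methylation with a LOWESS smooth.
* **Fragment statistics** — length histograms (the dominant ccf length is
  one nucleosome, ~168 bp), the long/short (>200 bp vs <200 bp) per-cytosine
  methylation-rate fold ratio per context, MBD-capture (MCIp) pair filters
  and size-fraction comparison, short-fragment (<100 bp) enrichment in
  regulatory regions.
* **Robust z-scores** — PHD-restricted chromosome-21 fractions and
  `Z = (frac_sample − median_euploid) / MAD_euploid` with the unscaled MAD,
  computed per treatment (unenriched vs enriched for unmethylated DNA) from
  known-euploid samples only; `Z > 3` flags chromosome-21 overrepresentation.
* **A synthetic-data generator** with known ground truth for all of the
  above (planted DMRs and megabase-scale domains, per-read maternal/placental
  mixtures at a chosen fetal fraction, length-coupled methylation, MBD
  capture, euploid/trisomy-21 count tables).

## Worked example

Simulate a small study and run the whole pipeline (all stages are seeded and
byte-reproducible):

```bash
cfme run --seed 3 --out-dir run1
cfme zscore --counts run1/counts.tsv --out z.tsv
```

prints

```
simulate: ran, 31 outputs
summary: ran, 5 outputs
dmr: ran, 2 outputs
phd: ran, 5 outputs
fragments: ran, 2 outputs
zscore: ran, 2 outputs
manifest -> run1/manifest.json
24 z-scores -> z.tsv; z>3: euploid_07, trisomy_01, trisomy_02, trisomy_03
```

All three simulated trisomy-21 pregnancies are flagged at `z > 3` (one
euploid sample crosses the cutoff too — with only nine euploid references
the unscaled MAD is noisy, which is why the calibration experiments below
use a larger panel). The called DMRs in `run1/dmrs.tsv`,

```
chrom  start   end     n_cpg  direction   mean_diff  mean_abs_t
chr1   200000  200277  9      hyper_in_B  -0.390     6.42
chr1   450000  450277  10     hyper_in_A  0.400      8.85
```

sit on the planted loci (`run1/truth_dmrs.tsv`) with the planted effect of
0.4, and `run1/phds.tsv` recovers the planted 2 Mbp domain on chr2 with
placenta at 52 % vs 77 % methylation in non-pregnant ccf DNA.
`run1/fragment_stats.json` reports the modal fragment length (168 bp), the
long/short methylation fold ratio per context (CpG ≈ 5, the calibrated
truth) and the MCIp >300 bp size-fraction fold.

The same analyses are available as library functions
(`cfmethylome.dmr.call_dmrs`, `cfmethylome.phd.call_phds`,
`cfmethylome.trisomy.robust_z`, ...) on pandas-backed containers.

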