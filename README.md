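# striatal-ensembles

Quantification of cocaine-recruited neuronal ensembles in the mouse
dorsal striatum, for researchers analysing single-molecule FISH (smFISH)
puncta tables and bulk 3′-RNA-seq time courses from psychostimulant
sensitization experiments.

Repeated cocaine exposure recruits immediate-early-gene (IEG) expressing
ensembles — *Arc*, *Egr2*, *Fos*, *Nr4a1* — whose spatial distribution
over the medial (MS) and ventrolateral (VLS) subdomains of the dorsal
striatum, and whose cell-type composition over *Drd1*⁺/*Drd2*⁺ spiny
projection neurons, changes with the history of drug exposure. This
package implements the quantitative machinery for that analysis:

**smFISH arm**

- *Robust-expressor thresholds.* For each IEG, control cells with 0–1
  puncta are discarded as non-expressing; the remaining N′ cells are
  ranked by puncta count and the cutoff is the count at rank
  k = ⌊N′/3⌋ from the top — the minimum expression of the top tertile.
  A cell is suprathreshold when `puncta ≥ cutoff`. Receptor classes use
  a fixed cutoff of 8 puncta/cell.
- *Hotspot demarcation.* Per section, a product-Gaussian kernel density
  estimate of the suprathreshold cells is evaluated on a square grid
  (normal-reference bandwidth `1.06·min(σ̂, IQR/1.34)·m^(−1/5)` per
  axis) and the minimal superlevel set containing at least 20% of the
  cells is extracted as iso-contour polygons: λ\* is the largest level
  whose per-point-density upper tail reaches the coverage target.
- *Recruitment statistics.* Per-section suprathreshold fractions and
  puncta/cell means, aggregated per condition as mean ± SD over
  sections; single-cell IEG–receptor and IEG–IEG correlations (OLS
  slope, r², Spearman ρ); one/two-way fixed-effects ANOVA with Tukey
  HSD post hoc tests on the studentized range.

**bulk RNA-seq arm**

- *QC and normalization.* Samples under 10⁶ usable reads are dropped;
  samples over 8×10⁶ reads are binomially thinned to 50%; size factors
  by the median-of-ratios method.
- *Induction screen.* Per gene, a negative-binomial log-linear GLM with
  log-size-factor offset. Stage 1 tests
  `~ experience + time + experience:time` against `~ experience`
  (genes changing over time in at least one experience, BH-corrected);
  stage 2 refits `~ time` per experience. A gene is induced when the
  stage-2 BH-adjusted p < 0.05 and its maximal normalized fold change
  versus 0 h exceeds 1.2. Dispersion is per-gene Cox–Reid adjusted
  profile ML; LRT statistics use a quasi-F reference (denominator df =
  dispersion-design residual df) for calibrated small-sample tails.
- *Peak times and programs.* Peak time ∈ {1, 2, 4} h by argmax of the
  log normalized induction (NI for non-induced genes); program overlap
  across structures/experiences partitioned into early (1 h) and late
  (2–4 h) waves, with k-way core intersections and a conservation
  matrix; baseline shifts at 0 h by per-gene NB Wald contrasts.
- *Enrichment.* One-sided hypergeometric gene-set enrichment
  (BH or Bonferroni) and redundancy clustering of enriched terms that
  share ≥ 50% of their differentially expressed members (overlap
  coefficient, connected components).

A synthetic-data generator (`simulate_section`, `simulate_experiment`,
`simulate_counts`) emulates both modalities with known ground truth —
spatially clustered recruitment driven by one latent activation per
cell, mutually exclusive receptor classes, and NB bulk counts with
planted triangular induction profiles — so every stage supports
parameter-recovery testing without any data download.

## Worked example

```sh
python examples/smfish_recruitment.py
```

simulates four cocaine conditions (6 sections × 5000 cells each),
derives cutoffs from the control cells, and prints:

```
tertile cutoffs (puncta/cell): {'Arc': 4, 'Egr2': 4, 'Fos': 4, 'Nr4a1': 5}

Egr2 suprathreshold fraction (mean +/- SD over sections):
      acute MS: 0.400 +/- 0.013 (6 sections)
      acute VLS: 0.087 +/- 0.006 (6 sections)
  ...
   repeated MS: 0.201 +/- 0.002 (6 sections)
   repeated VLS: 0.048 +/- 0.002 (6 sections)

one-way ANOVA on VLS fractions: F = 114.7, p = 8.1e-10
  level_a   level_b      diff        p_adj
    acute challenge -0.006671 6.436948e-02
    acute  repeated -0.038403 1.237912e-09
challenge  repeated -0.031732 1.726496e-08
```

The recovered fractions track the planted truth: repeated exposure was
simulated at half the acute recruitment probability (0.201 vs 0.400 in
the MS), the challenge dose restores 90% of it, and the VLS values are
lower because recruitment there is concentrated in a spatial hotspot
rather than uniform. Tukey tests resolve the dampening
(acute vs repeated, p ≈ 10⁻⁹) from the near-complete reinstatement
(acute vs challenge, p ≈ 0.06). The other examples demonstrate hotspot
demarcation (`hotspot_demarcation.py`), the induction screen
(`induction_screen.py`), and enrichment clustering
(`enrichment_clustering.py`). A thin CLI mirrors the stages:
`striatal-ensembles --help`.

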