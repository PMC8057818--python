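# Methods

This note documents the models, estimators, defaults, and numerical
choices behind `striatal_ensembles`, and what the synthetic-data tests
do and do not establish about real data.

## smFISH model and estimators

**Data model.** One row per segmented cell: section, mouse, condition
(control / acute / repeated / challenge cocaine), striatal subdomain
(MS = medial, VLS = ventrolateral; an anatomical label, not recomputed
from coordinates), section-local coordinates in µm (origin top-left),
and an integer puncta count per probed gene (IEGs *Arc*, *Egr2*, *Fos*,
*Nr4a1*; receptors *Drd1*, *Drd2*).

**Tertile thresholds.** Cells with 0–1 puncta are non-expressing and
removed; with N′ expressing control cells, k = ⌊N′/3⌋ and the cutoff is
the k-th largest count — the minimum puncta among the top-tertile
("robust expressor") cells. Choices:

- *Rank tertiles, not equal-width bins.* "Top third of cells" is a rank
  statement; equal-width value bins would make the cutoff depend on the
  maximum count, which is an extreme order statistic.
- *Inclusive cutoff with tie absorption.* All cells sharing the rank-k
  value count as suprathreshold even when ties push coverage past 33%,
  because the published cutoffs are stated as minimum counts
  ("at least n puncta"). A `ceiling` variant (k = ⌈N′/3⌉) is provided
  for reproducing deposits whose derivation rounded the other way.
- *Pooled control cells.* The default control pool spans sections and
  regions; `per_region=True` derives (gene, region) cutoffs instead.
  Which mode matches a given deposit is an empirical question the
  accession test records.
- Receptor classes use the fixed cutoff 8 puncta/cell; cells high for
  both receptors are labelled `dual` and excluded from receptor-specific
  correlations (receptor populations treated as disjoint).

**Kernel density and superlevel sets.** The KDE is an axis-aligned
product Gaussian evaluated on an n×n grid (default n = 100) spanning
the data bounding box padded by three bandwidths; the default per-axis
bandwidth is the normal reference rule 1.06·min(σ̂, IQR/1.34)·m^(−1/5).
The demarcated region at coverage c (default 0.20) uses the level
λ\* = the largest density such that the fraction of cells whose
bilinearly interpolated density is ≥ λ\* reaches c — the c-quantile
from above of per-point densities, which makes "fraction of the cells"
literal rather than a probability-mass statement. Numerics:

- Iso-contours come from marching squares on the grid padded with a
  sub-level border, so rings touching the data boundary close; nested
  rings become holes.
- Contours are drawn midway between the λ\* point density and the next
  lower one, and the drawn level steps down point-by-point (the
  reported level stays λ\*) until the point-in-polygon count meets the
  coverage target: marching-squares chords otherwise clip an occasional
  boundary cell.
- All coincident points with an explicit bandwidth yield a small ring
  around the common location enclosing every cell.
- KDE input is suprathreshold cells only (the object demarcated is the
  region of maximal density of high-expressing cells); pass
  `use_all_cells=True` for a background comparison. Sections with < 2
  qualifying cells are skipped with a warning.

**Statistics.** The section is the unit of replication: condition-level
values are mean ± SD over sections, and ANOVA (one- or two-way fixed
effects, interaction included) runs on section-level summaries. Tukey
HSD p-values use the studentized range with the model MSE and the
harmonic mean of pair sizes (Tukey–Kramer) when groups are unbalanced.
`mean_puncta` defaults to the mean over all cells of the stratum;
`mean_over="supra"` restricts to suprathreshold cells — both are exposed
because "puncta/cell" summaries in the literature are ambiguous between
the two. Correlation scatter statistics include zero-puncta cells by
default (`include_zero=False` to drop them).

## Bulk RNA-seq model and screen

Counts follow NB(µ = s·q, var = µ + αµ²) with per-sample size factor s
(median-of-ratios over genes expressed in all samples, rescaled to
geometric mean 1) entering as a log offset.

**Dispersion.** Per gene, α maximises the Cox–Reid adjusted profile
likelihood (the GLM profile log-likelihood minus ½·log det X'WX),
with a method-of-moments value from a Poisson fit bracketing the
search; α is clipped to [10⁻⁸, 30]. The CR adjustment compensates the
downward bias of plain ML when the mean model consumes a third of the
samples. No empirical-Bayes shrinkage across genes is applied, so each
gene's test stands on its own.

**Two-stage screen.** Stage 1 compares
`~ experience + time + experience:time` against `~ experience` (df 9
with three experiences and four time points): genes changing over time
in at least one experience, BH-corrected per structure. Stage 2 refits
`~ time` vs intercept per experience (df 3) at the stage-1 dispersion;
BH is applied within experience across stage-1 survivors, and a gene is
induced when adjusted p < 0.05 (default) and its maximal normalized
fold change vs 0 h exceeds 1.2. Fold changes are computed on linear
scale with a 0.5 normalized-count floor; only increases qualify (the
screen targets induction; baseline contrasts are two-sided). Reduced
model = experience-only is the implemented reading of "changing over
time, not merely between experiments". Stage-2 statistics are reported
for every gene so calibration can be audited; the induced call is
still gated on stage 1.

**Quasi-F reference.** With 3 replicates per cell, referring the LRT to
χ² is anti-conservative (observed null tail ≈ 2× nominal at p = 0.05
and worse further out) because it ignores dispersion-estimation noise.
LRT/df is therefore referred to F(df, d), d = residual df of the design
the dispersion was estimated on (24 in the default layout), in both
stages — the quasi-likelihood convention. Null simulations show raw
stage-2 rejection of 0.04–0.05 at nominal 0.05, and BH then controls
the empirical FDR of the full two-stage procedure below its nominal
level in the planted-recovery tests.

**Peak times.** Per (gene, experience), peak = argmax over {1, 2, 4} h
of log(normalized mean / 0-h mean); NI when not induced. For
gene-level parameter recovery, `consensus_peak` takes the majority
vote across the experiences where the gene is detected (ties broken
toward the earlier time): each program is an independent measurement
of the same underlying peak, and single-program calls cannot reliably
separate a 1 h peak from its 2 h shoulder when those means differ by
only ~30%.

**Baseline contrasts.** At 0 h, per-gene NB GLM on the group factor
(naive reference); Wald z = β/SE per contrast, BH across genes within
contrast, log2 fold change reported.

**Enrichment.** One-sided hypergeometric tail on DEG/term overlaps
against a universe defaulting to the detected genes (not the whole
annotation — enrichment against undetectable genes is spurious);
annotation is file-based (GMT or term–gene TSV), never downloaded, so
results are database-version independent. Redundancy clustering links
terms sharing ≥ 50% of their differentially expressed members in any
analysed structure — overlap coefficient |A∩B|/min(|A|,|B|) by default,
Jaccard as the alternative — and takes connected components; the
representative is the largest member set. Raising the threshold only
refines clusters.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
study conditions used throughout the test suite.

**Sections.** Cells are a uniform spatial Poisson process over a
3000 × 2000 µm rectangle; x < 1500 µm is MS, the rest VLS. Cell types
Drd1/Drd2/other in proportions 0.45/0.45/0.10, mutually exclusive at
truth level (dual-high observations arise only through NB noise). Each
cell draws one latent recruitment flag z with probability
`recruit_prob[(region, condition, cell type)]`, multiplied inside the
VLS by a Gaussian bump exp(−d²/2σ²) around the hotspot centre
(default: VLS centre, σ = 400 µm). All IEG counts of a cell share that
single z (`independent_iegs=True` breaks the coupling for null tests),
which is what makes IEG co-expression strictly positive — matching the
coherent multi-IEG commitment seen in recruited striatal neurons. IEG
counts are NB with mean 0.8 (background) or 18 (recruited), size 20;
receptor counts NB mean 25 for the cell's own receptor and 1.0
otherwise, so the fixed cutoff 8 recovers the planted class for ~96%
of cells.

Default recruitment probabilities: control 0.13 everywhere (baseline
ensemble activity, which gives the control pool the bimodal shape the
tertile rule needs — a pure-background control would put the cutoff
inside the noise floor); acute MS-Drd1 0.46, MS-Drd2 0.40, VLS-Drd1
0.46, VLS-Drd2 0.08, other 0.05; repeated = 0.5 × acute (the planted
dampening); challenge = 0.9 × acute. Because the VLS bump makes the
per-cell probability spatially varying, the planted value of a stratum
is the mean of the per-cell truth stored in `GroundTruth`, and all
recovery tests compare against that.

The hotspot-demarcation tests use a dedicated scenario (VLS-Drd1 0.65
concentrated at the bump, MS 0.08): under the paper-like defaults the
MS is strongly and uniformly recruited and legitimately contributes
demarcated area, so "centroid near the planted centre" is only a
well-posed recovery question when the VLS hotspot is the dominant
density mode.

**Bulk counts.** 200 genes (default), baseline means log-uniform on
[20, 2000], dispersion α = 0.05, three experiences × four time points ×
3 replicates, log-normal library-size factors (σ = 0.15). Induced genes
(default 20) rise linearly to fold 4 at their peak (1, 2, or 4 h) and
decay linearly back to baseline at the end of the time course; the peak
fold is multiplied by a per-experience dampening (acute 1.0, repeated
0.6, challenge 0.9), mirroring the dampening-and-reinstatement
structure of repeated-exposure transcription. Profile shape is
configurable.

**What the generator does not emulate.** No anatomy beyond one
rectangle and one boundary; no atlas registration or cross-animal
alignment; no segmentation errors, optical crowding, or probe-specific
detection efficiency in puncta counts; no batch effects, GC/length
bias, or outlier samples in bulk counts; mouse-level correlation enters
only through section grouping (no random-effects structure). Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to these real-data artefacts.

## Problem sizes and degenerate inputs

The test suite and acceptance script run experiments of 5000
cells/section with 6 sections/condition (three seeds) for the smFISH
chain, 12 acute sections for hotspot recovery, and 200-gene screens
(null and planted) per seed — sizes at which every recovery target has
comfortable Monte-Carlo margin while the whole suite stays in the
minutes range on one CPU. Degenerate inputs are contracts, not crashes:
fewer than three expressing control cells, empty DEG lists after
harmonization, zero-variance regressors, all-identical KDE points
without an explicit bandwidth, and samples failing QC wholesale all
raise informative errors; empty strata and sections with < 2
suprathreshold cells are skipped with logged warnings.

## Known limitations

- The quasi-F reference is a calibration device, not an exact
  small-sample distribution; at very low counts (baseline mean < 5)
  the screen has not been characterised here.
- Tertile cutoffs from small control pools (N′ in the tens) are noisy
  integer statistics; provenance counts are attached so downstream
  users can judge.
- The overlap-coefficient reading of "50% shared genes" merges a small
  term into any superset; Jaccard is stricter and available where that
  matters.
- GeoJSON output stores section-local µm coordinates; features from
  different sections share no common frame.
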