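# Methods

## The mosaic-female design

Random X-chromosome inactivation makes a heterozygous (`-/+`) female a
mosaic of mutant-expressing and wild-type-expressing cells. Comparing these
populations against each other and against wild-type animals factorizes a
mutation's transcriptional impact:

| contrast | groups | what a hit means |
|---|---|---|
| 1 | `-/y` vs `+/y` males (all cells) | total effect, hemizygous |
| 2 | `-/+` vs `+/+` females (all cells) | total effect, mosaic |
| 3 | WT-allele cells of `-/+` vs WT cells of `+/+` | non-cell-autonomous: the cells themselves are genetically "wild type expressing", so any change comes from their environment |
| 4 | MUT-allele cells of `-/+` vs WT cells of `+/+` | cell-autonomous + environmental |
| 5 | MUT- vs WT-allele cells within `-/+` | cell-autonomous, environment held constant |

The effect-mode rule (significant in 3 and not 5 → non-cell-autonomous;
significant in 5 and 4 but not 3 → cell-autonomous; 3 and 5 → mixed) is a
formalization of this logic; it is exposed in config because the boundary
cases (e.g. a gene sitting exactly at threshold in one table) are a
convention, not a theorem. Experiments 3–5 use only allele-called (WT/MUT)
cells; ambiguous and uncalled cells are excluded. Cross-sex contrasts are
never formed; P120 (males) and P150 (females) are the two "late" stages.

## Allele genotyping

The reference is the 100-nt window `[start−50, start+50)` around the start
codon, codon at offsets 50–52. The printed description of the window ("50 bp
upstream and 50 bp downstream") is ambiguous about whether the codon itself
is inside the second 50; we take the half-open reading, and the codon
position is a parameter throughout. At this reference size exhaustive
ungapped placement on both strands is exact and faster than any index; the
engineered variant is a substitution, so gaps are not modeled. Placement
requires ≥ 30 nt overlap, ≤ 3 non-codon mismatches, and full codon coverage;
codon-position mismatches are exempt from the threshold so that the variant
itself cannot penalize placement. Codon bases under Q20 make a read vote
OTHER. Per (barcode, UMI) the majority codon class wins; ties and
OTHER-majorities make the UMI ambiguous. A cell is called WT or MUT by
strict UMI majority, with no additional purity threshold — conflicting-UMI
cells were evidently assigned rather than dropped in the motivating study,
and majority is our convention for them.

## Count model of the simulator

Counts are negative binomial: `count ~ NB(mean = L_c · q_g · 2^η,
variance = μ + φμ²)` with library sizes `L_c` log-normal
(meanlog ln 5000, sdlog 0.3 — 10x-scale nuclei), dispersion φ = 0.1, and
gene abundances `q_g` log-normal (σ = 1.2) normalized to sum to one. The
exponent η stacks: a marker boost (+2 log2 on a cell type's markers, which
makes nearest-centroid typing well-posed), the animal random intercept, and
planted effects — cell-autonomous effects apply only to MUT-allele cells,
non-cell-autonomous effects to every cell of a mutant animal. Gene means are
*not* renormalized per cell: renormalization couples genes through a shared
compositional term and breaks the independence the calibration benchmarks
rely on.

**Intra-animal correlation.** The animal intercept is Gaussian on the log2
mean, but log *expression* responds to it with slope < 1 at low counts (the
+0.5 pseudo-count floor compresses), and the within-cell variance of
log counts itself depends on the shifted mean. The per-gene intercept sd is
therefore solved by bisection so that the realized between-animal variance
of `E[log2(count+0.5)]` equals `icc/(1−icc)` times the realized mean
within-cell variance, both evaluated by Gauss–Hermite quadrature over the
intercept and library-size distributions using exact NB log-moments
(pmf summation below mean 300, delta method above). The naive delta-method
solution undershoots the realized correlation by ~0.05 at icc = 0.3.

**Reads.** Each expressing cell draws Poisson(mean 3 by default) UMIs — the
UMI depth of start-codon-informative cells is not reported anywhere, so this
is a free parameter chosen to make a ~3-UMI median realistic for 5'
libraries — and each UMI emits ≥ 1 read from the cell's allele window with
i.i.d. substitution errors on a random strand. 20% of reads are decoys from
unrelated random sequence to exercise matcher specificity.

**Disease score** is `min(7, round(stage_baseline × genotype_severity))`
with null males above het females and wild types at zero; only the 0–7 scale
and these orderings are externally constrained, the generative form is ours.
Default timepoint baselines 1/2/3.5 (P30/P60/late).

**What the simulator does not model:** doublets, ambient RNA, batch
effects, cell-type-specific library sizes, gene–gene correlation outside
planted modules, and isoform structure. Passing benchmarks therefore show
the statistics behave correctly under the stated generative model, not that
they are robust to every real-data artifact.

## DEG engine

- Genes detected in < 25% (strict) of a stratum's cells are excluded from
  the linear-model path and optionally tested with the ZINB LRT; those
  results are reported in a separate lower-confidence table and never enter
  the headline DEG counts.
- Groups are balanced by down-sampling to the minimum group size, once, with
  a logged seed (whether the motivating workflow resampled repeatedly is
  unstated; once-with-seed is reproducible).
- Library sizes are composition-corrected: counts pooled per animal × group
  are compared to the pooled profile and the 30%-trimmed mean of per-gene
  log-ratios rescales that stratum's totals (the TMM idea applied at the
  stratum level). Without this, a minority of strongly shifted genes drags
  an artificial fold change into every other gene of the affected group.
- log2-CPM `log2((count+0.5)/(L+1)·10⁶)`; the sqrt-sd mean–variance trend is
  a lowess with span 0.5, interpolated linearly and held **constant** beyond
  its fitted range — linear extrapolation can cross zero and produce
  unbounded weights for low-detection genes. Weights are trend⁻⁴ at each
  observation's fitted log2-count, floored at (10⁻³)⁻⁴.
- The consensus intra-animal correlation maximizes, per gene, the REML
  profile likelihood of a block-exchangeable correlation on a 29-point grid
  with quadratic refinement, then pools estimates by a 15%-trimmed mean on
  the Fisher-z scale. The estimation uses the *unweighted* log2-CPM: the
  animal intercept is additive on log expression, whereas the weighted
  covariance model D·R·D forces block covariance to scale with each
  observation's sd, which empirically inflates ρ (0.31 vs a realized 0.17)
  and makes null p-values conservative. The weighted variant remains
  available (`use_weights=True`).
- The moderated fit whitens per gene (block Cholesky with the consensus ρ,
  precision weights), runs weighted least squares, moment-matches a scaled
  inverse-chi-square prior to the residual variances via the
  digamma/trigamma identities (trigamma inverted by Newton), and tests the
  contrast against t with d₀ + d_g df. `prior_df=0` reproduces plain GLS
  (and exactly OLS at ρ=0 with unit weights); `prior_df=inf` pools to the
  common prior variance. With one animal per group ρ is unidentifiable and
  forced to 0 with a warning.
- ZINB LRT: per group and pooled, bounded L-BFGS-B MLE of (π, μ, θ) with
  π ∈ [0, 1−10⁻⁶], θ ∈ [10⁻³, 10⁵]; the π=0 boundary (plain NB) fit is
  preferred unless freeing π improves the log-likelihood by more than
  ln(n)/2 — π and θ trade off on data without excess zeros, and this
  BIC-style charge keeps π̂ near zero there without affecting genuinely
  zero-inflated fits. Statistic 2(ℓ_A + ℓ_B − ℓ_pooled) against χ²₃;
  log2FC compares zero-deflated means (1−π)μ. Non-convergent rows get
  p = NaN and a flag.

## Enrichment, overlap, lengths

One-sided Fisher p-values are hypergeometric upper tails; odds ratios are
the sample OR of the 2×2 table. The enrichment universe defaults to the
genes passing the 25% filter in the same stratum (the motivating analysis
does not print its universe). Both the raw-p ≤ 0.05 input convention and an
adjusted-p alternative are config options. The gene-length trend test pairs
a Spearman correlation of log2FC with log10 length with a two-sample KS of
significant-DEG lengths against background — no specific test is prescribed
by the source analyses, these are the field's defaults. Ortholog mapping is
exact-match first with a mouse-Title-case ↔ human-UPPER fallback.

## Co-expression

Genes detected in ≥ 5% of cells enter the network. Metacells are greedy
k-nearest-neighbor groups (k = 25) in 20-PC space within animal × cell type,
averaged; the grouping partitions the cells. The soft power is the smallest
integer β ∈ 1..20 whose signed adjacency reaches scale-free fit R² ≥ 0.8
(equal-width degree bins, signed R²); when none does — which is expected
for, e.g., equal-loading planted blocks, whose degree distribution is
bimodal rather than power-law — the argmax is used and flagged. The phrase
"softpower of 0.8" in the source methods is read as this R² threshold,
since soft powers are integers by construction; a fixed power can be forced
in config. Modules come from average-linkage clustering of 1 − TOM cut
statically at height 0.99 (a deliberate simplification of dynamic tree
cutting), minimum module size 30, colors assigned by size rank, leftovers
grey. Eigengenes are PC1 of the standardized module expression, sign-chosen
so the mean gene–eigengene correlation is positive; kME is the Pearson
correlation with the eigengene (ddof = 1 consistent); hubs are the top 10
members by kME. Module–trait relations use per-sample (per-animal) mean
eigengenes — n = animals, not cells — with BH across the whole grid.
Module scores rank genes per cell (ties averaged, ranks capped at 1,500)
and map the mean set rank onto [0, 1].

## Benchmarks and problem sizes

The validation suite (`snmosaic.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 500 mosaic
cells at 1% read error and 20% decoys for genotyping; 2,000 genes ×
(2 groups × 4 animals × 50 cells) at icc 0.2 for null calibration; 200
genes × 8 animals × 50 cells for correlation recovery at icc 0/0.1/0.3;
600 genes × (4+4 animals × 300 cells) with 10% + 10% planted effects at
|log2FC| = 1 and icc 0.05 for effect-mode discrimination; 3 modules × 80
genes at loading 0.8 over 300 metacells for module recovery; and 200-cell
groups for ZINB null/power. The discrimination benchmark's icc = 0.05 is
the magnitude typically estimated for intra-animal consensus correlation in
single-nucleus data; detection power for experiment 3 falls to ~0.75 at
icc = 0.1 with four animals per group — between-animal variance, not cell
count, is the binding constraint there.

## Known limitations

The nearest-centroid typing is a transparent stand-in for reference label
transfer and is only as good as the marker panel. The five-experiment
engine assumes allele calls are attached upstream; allele-ambiguous cells
silently drop out of experiments 3–5. The ZINB optimizer can hit its θ
bounds on degenerate data (all-zero groups). The static TOM cut can merge
adjacent modules that dynamic cutting would split. Human-cohort analyses
reuse the mouse QC thresholds unless overridden — the human thresholds are
not printed anywhere authoritative.
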