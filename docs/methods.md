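# Methods

This note documents the models, numerical conventions, and fixture design
behind `landgea`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Genotype filtering

Dosage matrices hold alt-allele counts {0, 1, 2} with NaN as the missing
sentinel — missing is never conflated with the reference-homozygous 0. All
filters are pure and idempotent, and each appends an entry (operation,
parameters, before/after counts) to the matrix's provenance log.

Boundary semantics follow common whole-genome GEA practice: a site is kept
only if its missing fraction is *strictly below* the threshold (default
0.30; an exactly-30% site is removed), while an individual is removed only
if *strictly above* its threshold (default 0.30). SV genotypes with fewer
than 3 supporting read pairs are recoded missing (support = 3 is kept)
before the stricter 20% SV site-missingness filter. For SNPs, per-genotype
depth filtering is treated as an upstream property of the input VCF — the
package consumes called genotypes — whereas the SV support recode is
implemented explicitly because SV callers export the support count.

LD pruning takes only a threshold (r² > 0.5) and a window (200 kb) as
givens; the scan order is a documented convention, not a community standard:
windows slide by half their width, and within each window a greedy
left-to-right pass drops the later locus of any surviving pair above the
threshold, with pairwise-complete Pearson correlations over non-missing
individuals. The unit suite checks the result against an O(n²) re-
implementation with identical window membership and greedy order.

Mode imputation breaks frequency ties toward the smaller dosage —
determinism matters more than the (arbitrary) direction. Heterozygosity is
computed on the filtered but unpruned, *unimputed* matrix: mode imputation
replaces missing entries mostly with homozygous genotypes and would bias
heterozygote proportions downward.

## Mixed models for diversity

`het ~ env + (1 | population)` is fit by REML (statsmodels MixedLM). The
slope test refits nested models by ML and compares them with a χ²₁
likelihood-ratio test; a Wald p is also reported. Because the optimizer can
hit singular Hessians when the random-intercept variance approaches zero,
fitting cascades through BFGS, L-BFGS, Powell and Nelder–Mead before
failing. Variance explained follows the Nakagawa–Schielzeth decomposition:
marginal R² = Var(Xβ̂) / (Var(Xβ̂) + σ²_pop + σ²_res); conditional R² adds
σ²_pop to the numerator. Both are reported since "model R²" is ambiguous
between them in the mixed-model literature; the marginal value is the
headline. Calibration is verified by Monte-Carlo: at 20 populations × 10
individuals the LRT rejects a true-null slope at ~5% (the acceptance suite
measures 4–7% over 500 replicates, within the 5% ± 2% band).

## Ordination

PCA and RDA are implemented directly from SVD — no ordination package is
assumed. RDA: center Y (optionally unit-scale loci; default off, exposed as
`scale_loci`), standardize X, project Y onto the column space of X, and
eigen-decompose the fitted covariance. Partial RDA residualizes both Y and X
on the centered conditioning table first. Conventions:

* **Axes.** k = min(p, n−1, m). Eigenvector signs are fixed so each axis's
  largest-magnitude loading is positive, making runs platform-reproducible.
* **Rank deficiency.** Projection uses an SVD pseudo-inverse with a
  combined relative/absolute singular-value cutoff (10⁻⁸·√n on the
  standardized scale), so a predictor fully absorbed by the conditioning
  set contributes exactly nothing rather than a noise axis. A strict
  `check_collinearity` helper names collinear columns for user-assembled
  predictor tables; `rda` itself never fails on rank deficiency because
  variance partitioning legitimately conditions sets on overlapping spans.
* **R² scales.** `RDAResult.r2` is constrained variance over the total
  variance *at that stage* (after conditioning). The variance-partition
  table instead expresses every fraction against the original centered
  response total, so that for mutually orthogonal predictor sets the
  marginal R²s sum exactly to the full-model R². Adjusted values use the
  Ezekiel correction 1 − (1−R²)(n−1)/(n−p−1).
* **Scores.** Variable ("biplot") scores are the Pearson correlations of
  each standardized predictor with each axis's sample scores. Outlier
  detection consumes raw locus loadings and z-scores them per axis, so it is
  invariant to any global axis rescaling.

The implementation is cross-checked in the test suite against a hand-rolled
regression-then-eigendecomposition oracle (1e-8) and against vegan's `rda`
through Rscript (eigenvalues, R², adjusted R² to 1e-10 on a 12×6 matrix).

## Candidate detection and annotation

Per axis, loading z-scores use that axis's own mean and SD (per-axis rather
than pooled — the cited convention for RDA outlier scans); candidates are
the union over the first three axes of |z| > 3, each locus reported once
with its max-|z| axis. The 3 SD cutoff corresponds to a two-tailed normal
tail probability of 0.0027. Candidate loci are then assigned to the
environmental variable with the largest |Pearson r| against their imputed
individual-level dosages (population-level climate broadcast to
individuals; ties break by variable order; constant loci are flagged and
excluded), and candidates with best r² > 0.5 (strict) form the strong set.
Nearest-gene annotation indexes only `gene` features of a GFF3, takes the
containing gene when the position falls inside one (distance 0), otherwise
the nearest gene by edge distance on the same chromosome, ties to the
lower-coordinate gene; `upstream`/`downstream` describe the locus relative
to the gene interval, ignoring strand.

## Adaptive index

The adaptively enriched pRDA refits the climate model on candidate loci
only, after dropping lake-idiosyncratic variables (surface area, pH) and
the candidates assigned to them — those variables have no projected future
layer. The adaptive index for axis a is the dot product of the axis's
variable scores with the cell's standardized climate. Grid cells are
standardized with the *recent sampling-site* statistics (an open design
point: site vs grid statistics; site statistics keep map values on the same
scale as the sampled populations, which is what the index is for). The
index is linear, zero at mean climate, and flips sign with the axis — maps
from two panels can legitimately show opposite extremes.

## Gradient forest

Each locus's response (population allele frequency by default;
individual-dosage mode available) is fit with a forest of regression trees:
bootstrap resampling of sites, mtry = max(1, ⌊p/3⌋) random predictors per
split, variance-reduction splitting, minimum terminal node 2. The forest is
assembled from sklearn `DecisionTreeRegressor`s with an explicit bootstrap
loop so that out-of-bag bookkeeping, split extraction, and seeding are fully
controlled; per-locus fit is OOB R² = 1 − SSE_oob/SST, and loci with R² ≤ 0
are discarded.

Every internal node contributes (split value, impurity decrease) to its
predictor's mass list. Per locus, masses across all predictors are rescaled
to sum to that locus's R², then averaged over retained loci. This guarantees
the documented invariants: turnover functions F_p (right-continuous step
functions of cumulative mass) are non-decreasing from 0 to the predictor's
R²-weighted importance, and Σ_p importance = mean retained R². The
"correlation threshold" parameter only groups highly correlated predictors
in reporting; turnover masses come from impurity decreases, not conditional
permutation importance — a documented approximation to the original GF
machinery.

Genomic offset is the Euclidean distance between turnover-transformed
current and future climate, computed on **raw** predictor values (split
values live on the raw scale). It is a pseudometric: symmetric, triangle
inequality, zero when future equals current. Offsets are relative
vulnerability rankings; they say nothing about absolute fitness.

Two behaviors found while validating at desk scale are worth knowing:

* With ~20 training sites, a few iid-noise loci can clear the OOB R² > 0
  retention bar by chance, so a pure-noise panel yields small but nonzero
  importance (the suite bounds it well below the causal fixture's) rather
  than exactly zero.
* The offset–warming dose–response is only identified when the dose is the
  controlled variable: the verification grid holds current climate at the
  landscape median and sweeps warming 0–8 °C, giving Spearman ≈ 1. Across
  cells that differ in both baseline and dose, turnover saturation (cells
  already beyond the last split) makes offsets baseline-dominated, and the
  rank correlation with dose alone is uninformative.

Ecotype offsets recompute allele frequencies per population × ecotype group
(unlabeled individuals form a `none` group), refit the forest at group
level with each group's site climate, and report per-group offsets;
populations with one ecotype emit one row.

## Synthetic data

The generator produces the statistical structure the pipeline assumes — and
deliberately nothing more (no recombination, linkage, migration, or
sequence-level reads), so passing tests demonstrate correctness of the
*analysis machinery*, not realism of any particular organism:

* **Landscape.** Variables run linearly along x or y over bioclim-plausible
  ranges (defaults: bio5 18–33 °C and bio6 −20…−2 °C south–north; bio15,
  bio16, pH, surface area coast–inland), plus a smooth Gaussian random
  field with SD = 0.25 of each variable's range — enough to keep pairwise
  r² below the 0.7 pruning threshold for same-axis variables. Future layers
  add a per-cell change field; the default bio5 warming spans 3.7–8.9 °C
  (best case) and 5.1–11.2 °C (worst case) across the grid.
* **Population structure.** Nested Balding–Nichols: ancestral frequency
  p ~ U(0.05, 0.5) drifts into regional lineages with F_region = 0.15
  (4 lineages by default, assigned round-robin along the gradient so
  ancestry is decoupled from climate, as post-glacial lake colonization
  typically is), then into populations with per-population F (default
  0.05). The hierarchy matters: in a flat exchangeable design the planted
  adaptive loci themselves form the leading PCA axes, and conditioning on
  genotype PCs removes exactly the signal under test; with realistic
  lineage structure the PCs capture ancestry and the climate signal
  survives conditioning.
* **Adaptive loci.** q_k = logistic(a + b z_k) with z_k the causal
  variable standardized over the population cells, a = logit(p), |b| ~
  U(2, 3) with random sign; dosages ~ Binomial(2, q_k); independent
  missingness (5% SNPs, 10–15% SVs). The SV panel carries DEL/DUP/INS/INV
  classes and Poisson(6) support counts in a `SR` FORMAT field.
* **Scale.** Defaults are 20 populations × 10 individuals, 2000 neutral +
  50 adaptive SNPs, 500 SVs — the stated desk-scale study conditions; per-
  population sample size (10) is a free choice since only totals are
  constrained. Fixture generation at this scale takes ~1 s; a full
  pipeline run ~30 s on one CPU. The determinism check runs a reduced
  configuration (12 × 6, 500 + 25 SNPs, 120 SVs, 80 trees) twice — scale is
  immaterial to byte-identity.

All randomness flows from one `numpy.random.default_rng` seed recorded in
the fixture metadata and the run manifest; reruns with one seed are
byte-identical, including the forest fits.

## Known limitations

* No genotype likelihoods, phasing, multi-allelic decomposition, or kinship
  random effects; no permutation tests for RDA axes.
* Gradient-forest masses use impurity importance, not conditional
  permutation importance; with strongly correlated predictors the split
  masses divide credit among them (report the correlated groups the model
  records alongside the importance table).
* Simulated missingness is missing-completely-at-random; real missingness
  correlates with depth and repeat content.
* The offset is only as comparable across panels or species as the
  underlying turnover scale (mean retained R²), which depends on locus
  choice.
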