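# Methods

`cnmir` infers miRNA–gene regulatory interactions that are driven by
recurrent somatic copy-number aberrations (CNAs). The working hypothesis is
that a miRNA residing inside a recurrently amplified or deleted chromosomal
region is dosage-affected, and that its expression change propagates to
target genes *outside* the region. The pipeline therefore (1) finds
recurrent aberration regions, (2) finds genes differentially expressed
between region-aberrated and non-aberrated samples, (3) assembles, for each
differentially expressed *trans* gene, a multi-omics predictor matrix, and
(4) selects cis-miRNA predictors by repeated cross-validated LASSO.

## 1. Recurrent regions and aberration status

**Model.** Each sample contributes a segmented copy-number profile
(log2 tumor/normal ratio per segment). The genome is binned
(`bin_size`, default 100 kb); a sample's value in a bin is the bp-overlap-
weighted mean log2 ratio of its covering segments. The amplification score
of bin *b* is

    G_amp(b) = Σ_s max(0, x_sb − 0.1),

and symmetrically `G_del(b) = Σ_s max(0, −0.1 − x_sb)`. Significance comes
from a permutation null: each sample's genome-wide bin vector is cyclically
shifted by an independent uniform offset (`n_permutations`, default 500),
which preserves each profile's marginal structure while destroying
cross-sample alignment. Per-bin empirical p-values (with the +1
pseudo-count) are Benjamini–Hochberg adjusted over covered bins; bins with
q ≤ `q_cutoff` (default 0.25) are merged when contiguous. Amplifications
and deletions are scored independently, so one locus can yield both. This
is deliberately a simple recurrence caller, not a reimplementation of
GISTIC's marker-level statistics; externally computed region tables are a
first-class entry point.

**Status rule.** A sample is *aberrated* for an amp region iff its
overlap-weighted mean log2 ratio over the region is strictly greater than
+0.1 (strictly less than −0.1 for del regions). Values exactly at the
threshold are non-aberrated. Samples with no covering segment are
non-aberrated (logged). The same bp-weighted mean is used for gene- and
miRNA-centric copy number, so the two operations agree exactly when a
feature coincides with a region.

## 2. Differential expression

Raw counts are normalized with TMM factors (trim 30% of M and 5% of A per
tail, precision-weighted mean, reference = sample with the most typical
upper quartile; factors rescaled to geometric mean 1). A common
negative-binomial dispersion is estimated by conditional maximum likelihood
on library-size-equalized pseudo-counts (grid search over log-spaced
dispersions with golden-section refinement; a boundary maximum returns 0).
Library equalization maps counts through a gamma approximation of the NB
distribution function, switching to the survival function above the median
for numerical stability and falling back to linear scaling when tail
probabilities underflow.

The test is the classic two-sided NB exact test on group sums of
pseudo-counts: all splits of the observed total are enumerated and
probabilities not exceeding the observed split's (1 + 1e-7 tie slack) are
summed; at dispersion 0 this reduces to a binomial test. When both group
sums exceed 900 (or the total exceeds 20 000) a beta-distribution
approximation to the double tail is used instead — the proportion
y1/(y1+y2) is approximately Beta(n1·μ/(1+φμ), n2·μ/(1+φμ)). log2 fold
changes are damped with `prior_count` (default 0.5) so that label swap
negates logFC exactly.

BH adjustment is applied *within each region* (the unit at which DE gene
lists are formed). A gene is DE iff |logFC| ≥ 1 and adjusted p < 0.05.
Regions with an aberrated or non-aberrated group smaller than
`min_group_size` (default 3; two groups of ≥ 3 are the minimum for a
meaningful dispersion estimate) are skipped, not failed. A distribution-
free Wilcoxon mode is available for robustness checks. Numerical equality
with any specific DE package is not a goal; the engine's contract is
calibrated type-I error, correct signs, and exact antisymmetry.

## 3. Predictor assembly

Per region, DE genes overlapping the region by ≥ 1 bp are *cis*, all others
*trans*. The any-overlap rule (rather than full containment) avoids
dropping boundary-straddling genes and is switchable in code. Cis miRNAs
are all expression-filtered miRNAs (RPM ≥ 0.01 in ≥ 30% of samples)
overlapping the region — deliberately not DE-filtered, since the handful of
miRNAs per region makes a DE filter needlessly destructive.

Each eligible trans gene (≥ 1 cis miRNA available) receives a design
matrix: cis gene expression, cis miRNA expression, its own gene-centric
copy number, its own promoter methylation (mean beta over probes in the
strand-aware TSS −2000/+500 bp window for 450K arrays; all probes for 27K),
and expression of TFs with known interactions targeting it (optionally
filtered by confidence grade A–E). Expression enters as log2(normalized
value + 1); copy number and methylation keep their native scales; all
columns are standardized inside the LASSO step. Constant columns are
dropped with a log entry; a missing methylation value drops the column
rather than imputing. A duplicate predictor (a cis gene that is also a TF
of the target) is kept once under the cis_gene class.

## 4. Stability-selection LASSO

For each trans gene the model is

    y = X β + ε,  minimize (1/2n)‖y − Xβ‖² + λ‖β‖₁

on standardized predictors and centered response, solved by cyclic
coordinate descent with covariance updates and warm starts along a
descending log-spaced grid of 100 λ values from λ_max = max_j |x_jᵀy|/n
down to λ_max·1e-3 (numba-compiled; convergence when the largest
coefficient change in a sweep is below 1e-7; coefficients at λ ≥ λ_max are
exactly zero by the KKT conditions).

The regression is repeated 100 times. Each run draws fresh 10-fold CV
splits (seeded; fold assignment is the only randomness), computes the CV
mean squared error along the shared grid, and picks λ* as the **largest λ
whose CV error is within one standard error of the minimum** — the
"simplest model at the minimal CV error". The run's coefficients are the
full-data path values at λ*; a predictor counts as selected when its
coefficient exceeds 1e-9 in magnitude. cis-miRNA predictors selected in at
least 70 of 100 runs become edges, with the sign of the mean coefficient
over selected runs (reported on the standardized scale). Both signs are
kept: repression is canonically negative, but indirect regulation can be
positive. Duplicate (miRNA, gene) pairs arising from several regions merge
into one edge (union of regions, maximal count, coefficient of the
max-count record).

The exact-tie "largest λ at the minimal CV error" rule is available as
`lambda_rule: min`. It is not the default because, with strong predictors
present, the CV minimum lands at penalties small enough that every
chance-correlated predictor enters the refit in essentially every run —
selection frequencies then carry no information. The one-SE rule restores
the sparsity/stability trade-off that frequency thresholding at 70/100
presupposes.

Per-gene jobs are independent: each gene's base seed derives from
(global seed, region id, gene id), so results are identical regardless of
execution order, and two runs with the same config and seed are
byte-identical.

**Two-phase mode** (off by default): phase 1 runs the stability LASSO on
the transcriptional covariates only (cn, methylation, tf, cis_gene);
consensus predictors (count ≥ 70) are refit by ordinary least squares and
their fit subtracted; phase 2 runs the stability LASSO of the residual on
the cis miRNA columns alone. An empty phase-1 consensus falls back to the
centered response.

## 5. Evaluation statistics

Ground-truth miRNA–target pairs are expanded with TF targets: for each
validated pair (m, g) where g is a TF, every known target t of g adds
(m, t) tagged `tf_expanded` (direct tags win on collision). Per computed
miRNA, a one-sided hypergeometric test measures over-representation of its
computed targets in the truth, inside an explicit gene universe; a miRNA is
*eligible* when ≥ 1 of its computed targets is a known target, and
*significant* when additionally p < 0.05. Method comparison restricts to
miRNAs eligible under both methods and compares significant counts
(win/loss/draw; empty overlap → not comparable). Enrichment of computed
miRNAs in a known oncogenic-miRNA list uses a two-sided Fisher exact test
against the background of all miRNAs that entered the LASSO step. A generic
over-representation analysis (hypergeometric + BH across terms) accepts
user-supplied term→gene-set files. Spearman correlation (mid-ranked ties)
between miRNA-centric copy number and miRNA expression summarizes dosage
sensitivity; constant vectors or < 3 paired samples give missing values.
Universes are always explicit arguments because the right background
differs per test.

## 6. The synthetic cohort

The generator emulates the study conditions end to end. Defaults: 150
samples, 300 genes, 30 miRNAs on a 3×30 Mb genome; 3 planted 2 Mb regions
(2 amp at log2 +0.8, 1 del at −0.8), each carried by exactly 90 samples
(recurrence 0.6); segment noise N(0, 0.03); 5 true miRNA→trans-gene edges
with standardized effect 0.9 and negative sign; NB dispersion 0.1; library
sizes ≈ 5·10⁶ with log-normal sample factors.

Planted structure and the reasoning behind the noise scales:

- **cis miRNAs** (3 per region) gain `dosage_effect`·log2CN (default 0.5)
  on their log2 RPM, with residual sd 0.2. A cis miRNA's carrier-status
  loading is therefore tied to its target's fold change (loading ≈ 0.545 ×
  target logFC): the residual sd is chosen so planted targets clear the
  |logFC| ≥ 1 DE filter with margin (≈ 1.3) while cis features remain
  imperfect proxies of carrier status — if they were near-perfect proxies,
  any z-correlated predictor could masquerade as the miRNA.
- **cis genes** (4 per region) are dosage-sensitive drivers with slope 1.8,
  so they pass the DE filter and appear as cis predictors.
- **true-edge targets** lie outside all regions and subtract
  0.9·standardize(log2 miRNA RPM) from their log2 mean.
- **decoy trans genes** (4 per region) are DE through a *measured
  confounder*: carrier status shifts their promoter beta by ±0.25
  (hyper- or hypomethylation, alternating), with measurement noise
  sd ≈ 0.18, and expression responds with slope −5 log2 per beta unit
  (strong promoter silencing; decoy logFC ≈ 1.25). Decoys make specificity
  measurable: the LASSO can explain them via their own methylation column,
  so any miRNA edge onto a decoy is a false positive. The beta shift and
  measurement noise are sized so that the methylation column's correlation
  with the cis miRNAs (through shared carrier status) stays low enough
  that the one-SE penalty's shrinkage residual does not recruit miRNAs —
  the collinearity-leakage margin discussed above.
- **TFs** (5) regulate 6 null genes each with standardized effect 0.5 and
  are recorded in the TF table with confidence grades.
- two miRNAs are nearly silent (RPM ≈ 0.001) to exercise the expression
  filter; remaining genes are null.

What the generator does **not** emulate: realistic marker density and
focal/arm-level lesion mixtures, subtype structure, batch effects,
miRNA-target sequence specificity, count-level miRNA data (RPM is drawn
log-normally, matching its use as a regressor), or correlated methylation
beyond the planted decoys. Passing tests therefore demonstrate that the
machinery recovers planted dosage-driven regulation under calibrated noise
— not that it would achieve the same precision on tumor cohorts.

## 7. Numerical and policy choices

- Internal coordinates are 0-based half-open everywhere; SEG/GFF3 convert
  on input (dialect overridable). Overlapping segments within a sample are
  rejected rather than averaged.
- Boundary cases exactly at ±0.1 are non-aberrated (strict inequality).
- Fisher two-sided p-values use a 1 + 1e-7 tie slack; the hypergeometric
  upper tail is computed via the stable survival function.
- BH has one implementation shared by the DE and evaluation modules.
- Coordinate-descent tolerance 1e-7; selection tolerance 1e-9 (descent
  returns exact zeros; the tolerance guards accumulated error).
- Per-trans-gene seeds come from SHA-256 of (global seed, region, gene),
  kept below 2³¹.
- Problem sizes in the test suite: the full default cohort for end-to-end
  checks (≈ 15 s per pipeline run), a reduced cohort (100 samples, 80
  genes) for stage-level tests, 2000-gene simulations for DE calibration.

## 8. Known limitations

- The region caller has bin-level resolution and no arm-level correction;
  highly focal events below `bin_size` are invisible.
- Common dispersion only; genes with atypical dispersion are mis-calibrated
  individually (the region-level FDR is still controlled approximately).
- Selection frequencies are driven solely by CV-fold resampling; with very
  strong signals frequencies saturate at 0 or 100, so the 70/100 threshold
  mainly separates "always" from "sometimes" predictors.
- The TF-expansion of ground truth can inflate the truth set for promiscuous
  TFs; eligibility is evaluated against computed targets, which bounds the
  effect on the enrichment test.
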