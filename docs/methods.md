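# Methods

This note documents the statistical models implemented in `diffcoexpr`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Co-expression network and modules

The network is **unsigned**: adjacency is a_ij = |cor(x_i, x_j)|^β, so
strongly negatively correlated genes are treated as connected. Pearson
correlation is used throughout; zero-variance genes must be removed first
(`filter_invariant_genes`, which in two-condition mode also removes genes
constant within either single condition, since their per-condition
correlations are undefined).

**Soft-threshold selection.** For each candidate power the per-gene
connectivity k_i = Σ_{u≠i} a_iu is binned into 10 equal-occupancy bins
(quantile edges, deduplicated); the log10 per-bin frequency density
(count / (N·width)) is regressed on the log10 mean connectivity over
non-empty bins. The fit index is the regression R², **forced to 0 when the
slope is positive**: a scale-free degree law requires the frequency of
highly connected genes to *fall* with connectivity, and rewarding an
anti-scale-free fit would let degenerate data pass. The chosen power is the
smallest candidate with R² ≥ 0.8 (the conventional floor); if none reaches
it, the best candidate is used and a warning is logged. Fewer than 3
non-empty bins (possible only for pathological, near-constant connectivity)
is an error for that power.

**Module detection.** Average-linkage hierarchical clustering of the
dissimilarity 1 − TOM, with a **static cut** at `cut_height` (default
0.995) times the maximal merge height. A static cut was chosen over dynamic
tree cutting because it is reproducible, has one interpretable parameter,
and recovers planted blocks exactly in the regimes the package is tested
in; dynamic variants trade that transparency for sensitivity on real data
where cluster density varies (a known limitation, see below). Clusters
smaller than `min_module_size` (default 30, the scale of the smallest
module the method is expected to resolve) are relabelled grey. Surviving
modules are named from a fixed, documented 180-color palette by decreasing
size — largest is always "turquoise" — so labels are stable across runs;
ties in size break by the smallest contained gene index.

**Eigengenes.** Genes are standardized (mean 0, SD 1 with ddof=1 across
samples); the module eigengene is the first right singular vector of the
standardized block, scaled to unit variance and sign-flipped if it
correlates negatively with the module's mean profile, so "module up" always
means "eigengene up". `variance_explained` is s₁²/Σs². Single-gene modules
(possible only through pathological configurations) fall back to the gene's
standardized profile with a log message. The module–trait correlation uses
the 0/1 coding normal=0 / tumor=1, so a tumor-elevated module gets a
positive r_mt; its p-value comes from t = r·√((n−2)/(1−r²)) with n−2 df.

## Differential correlation

Fisher's transform z = ½·log((1+r)/(1−r)) is variance-stabilizing with
variance 1/(n−3), hence the requirement n > 3 per condition and the
difference statistic Z = (z_A − z_B)/√(1/(n_A−3) + 1/(n_B−3)). Empirical
correlations of exactly ±1 (duplicated profiles) are clamped to
±(1 − 1e-12) inside the vectorized pipeline so they map to a large finite z
rather than infinity; the public `fisher_z` keeps the strict |r| < 1
contract.

**Local FDR.** The two-component model lfdr(z) = η₀·φ(z)/f(z) uses the
*theoretical* standard normal null — justified because Z is standard normal
under the null by construction — rather than an empirically re-fitted null.
η₀ = min(1, 2·mean[p > 0.5]) exploits the fact that two-sided p-values
above ½ are almost surely null. f is a Gaussian KDE with Silverman
bandwidth; outputs are clipped to [0,1] and non-finite ratios (far tails
with no density support) are set to 1, which is conservative. Below 200
statistics a KDE is unreliable, so the function falls back to BH-adjusted
p-values with a log notice. Simulation-based calibration (see the
acceptance suite): on pure null ensembles η̂₀ ∈ [0.99, 1.0] and under 0.1%
of pairs reach lfdr < 0.05; on a 10% mixture with |Z| ~ N(6,1) about 98% of
non-null pairs are detected at lfdr < 0.05.

**Switching pairs** must flip correlation sign, reach lfdr < 0.05 (the
conventional significance level for this statistic), and — when a
differential-expression table is supplied — both member genes must be DE at
BH-adjusted p < 0.05. The both-genes rule is the conservative reading of
"switching with differential expression at the same time"; a flag switches
to "either". A minimum |r| filter per condition exists but defaults to 0:
it is a magnitude filter the base method does not prescribe, exposed only
because practitioners often want it. Output ordering (lfdr ascending, |Z|
descending, pair name) is fully deterministic.

**Eigen-molecule networks.** Within a gene set of interest, genes are
clustered per condition by average linkage on the *signed* distance
d = 1 − r (range [0,2]) cut at height 1 − 0.6, i.e. genes correlated above
0.6 merge. Signed distance is deliberate: anti-correlated genes belong to
different eigen-modules here, unlike in the unsigned global network. For
cross-condition testing the clusters of a reference condition (default:
normal, where regulation is presumed intact) define the entities; each
cluster's eigen-molecule is computed separately within each condition's
samples and all eigen-pairs get the z-difference treatment. Defining
entities in one condition is the only way to make "the same module in both
conditions" well-posed when the two clusterings disagree.

## Downstream statistics

- **Differential expression:** pooled-variance Student's t per gene
  (Welch behind a flag), BH across all genes, direction = sign of
  tumor-minus-normal mean. Zero pooled variance yields p = 1 with a flag
  rather than an exception, so one degenerate gene cannot abort a run.
- **Benjamini–Hochberg** is implemented directly (sort, p·m/rank, reverse
  cumulative minimum, cap at 1) and cross-checked in the tests against both
  a quadratic-time literal definition and statsmodels. Note BH is *not*
  idempotent — adjusting (0.01, 0.5) gives (0.02, 0.5) and adjusting again
  gives (0.04, 0.5) — so the suite asserts the properties that do hold:
  a second pass never decreases values and the significance ranking is
  preserved.
- **Hypergeometric enrichment:** upper-tail p = P(overlap ≥ k) with the
  universe restricted to the analyzed genes; k = 0 gives p = 1 by the
  observed-tail convention. Equivalent to one-sided Fisher's exact (tested
  to 1e-10).
- **Survival scan:** cutoff grid of `n_cutoffs` (default 90) evenly spaced
  quantile levels on [0.05, 0.95] *inclusive* — the reading of "from 5 to
  95%" with both endpoints, step 0.9/89 ≈ 0.0101. Quantiles use linear
  interpolation between order statistics; ties at a cutoff go to the high
  group (split is low = x < c, high = x ≥ c). Cutoffs yielding an empty
  group are skipped; p-ties between cutoffs resolve to the lower quantile.
  The log-rank test keeps subjects censored exactly at an event time in the
  risk set for that time. The reported minimum p is raw: with ~90 highly
  correlated tests per gene the null distribution of min-p is strongly
  anti-conservative (≈47% of pure-noise genes reach min-p < 0.05 at n=300
  in the acceptance run), which is why the scan's `significant` flag should
  be read as a screening label, not a calibrated test. A univariate Cox fit
  (Newton–Raphson on the Breslow partial likelihood, binary high/low
  covariate) reports a descriptive hazard ratio at the best cutoff; it
  plays no role in cutoff selection.

## Synthetic data: what it emulates, and what it does not

`simulate` plants structure through a shared-factor construction
x = λ·f + √(1−λ²)·ε, giving closed-form targets: within-module correlation
λ² (default λ = 0.8 → r ≈ 0.64, a strongly co-regulated module), switching
pairs with expected correlation +r in normal and −r in tumor via a
sign-flipped loading √r (default r = 0.6, the magnitude typical of the
strongest reported switch pairs), mean-shift DE in tumor (δ in residual-SD
units, default 1), and exponential survival for tumor samples with hazard
h₀·exp(Σβ·x) censored at a horizon (defaults h₀ = 0.1, horizon 20 time
units → roughly 85% event rate for a null gene). Default sample sizes are
58 normal / 468 tumor, mirroring the imbalanced tumor/normal designs this
method is aimed at. One root seed spawns independent per-stage streams, so
enabling survival simulation never perturbs the expression draws.

The generator does **not** emulate RNA-seq count noise (negative-binomial
mean–variance coupling), library-size or batch effects, heavy-tailed
expression, copy-number-driven correlation blocks, or censoring patterns
beyond a fixed administrative horizon. Passing tests therefore establish
that the *statistics* behave as claimed under their own model assumptions
(Gaussian factors, independent samples), not that any biological discovery
on real FPKM data is validated. The deliberately simple generative model is
what makes the recovery targets (recall, FDR, ARI) exact and auditable.

`simulate_scale_free` is a separate single-factor construction for the
power-selection benchmark: gene loadings are laid down as exact quantiles
of p(u) ∝ u^(γ−1) on [0.25, 0.9] with γ = 0.8·β*, so connectivity under
soft threshold β scales as u^β and the log-log degree density has slope
γ/β − 1. Below the generating power β* the slope is positive — the fit
index is zero there by the negative-slope rule — and at β* the degree
sequence is an exact, shallow decreasing power law, so the auto-selector's
first admissible power is β* itself. The large default sample count
(10,000) is what keeps correlation sampling noise from blurring the shallow
law; it is a property of this benchmark construction, not a recommendation
for real designs.

## Numerical and engineering choices

- Correlation matrices come from `numpy.corrcoef` with clipping to [−1, 1];
  TOM is computed with one matrix product (the u = i, j self-terms vanish
  because the adjacency diagonal is 0) and clipped to [0, 1].
- Log-rank and Cox use sorted-time suffix sums (`np.add.reduceat`) instead
  of per-event-time loops; this makes the 500-gene × 90-cutoff null scan
  run in seconds and is verified against lifelines to machine precision.
- Hierarchical clustering is scipy's average linkage on condensed
  distances; cutting uses `fcluster(criterion="distance")`.
- All result orderings (switching table, enrichment table, module labels)
  have documented deterministic tie-breaks; identical config + seed gives
  byte-identical output files.
- Problem sizes in the test and acceptance suites (e.g. 2,000 genes for
  module recovery, 20,000 null pairs for calibration, 50 seeds for the
  survival power estimate) were chosen as the smallest sizes at which the
  binomial/Monte-Carlo error of each estimate is well inside the asserted
  band.

## Known limitations

- Static tree cut with a global height cannot separate nested or
  density-varying clusters the way dynamic tree cutting can; module counts
  on real cohort data will differ from dynamic-cut analyses.
- The lfdr estimator assumes the null statistics are N(0,1); strong
  dependence between pairs (shared genes within a module) thins the
  effective number of independent tests and can make η̂₀ noisy on small
  gene sets, which is why the BH fallback exists below 200 pairs.
- The minimum-p survival cutoff scan is reported uncorrected by design; any
  downstream use should treat its p-values as screening scores.
- No blockwise decomposition is implemented: the all-pairs TOM is dense, so
  matrices beyond ~20,000 genes are memory-bound.
- Only two conditions are supported; time courses and multi-group designs
  are out of scope.
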