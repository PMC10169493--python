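# Methods

This note documents the models, numerical choices and design decisions
behind `enterolink`, and what the synthetic benchmarks do and do not show.

## Enterotyping

Distances between samples are the metric form of the Jensen-Shannon
divergence, `D = sqrt(JSD)` with natural logarithms, so `D ∈ [0, sqrt(ln 2)]`.
KL terms are undefined at zeros, so a pseudocount (default 1e-6, small
relative to typical amplicon sequencing depths in the tens of thousands) is
added and rows renormalized; the pseudocount, like the metric itself, is
configurable because published descriptions of enterotyping pipelines rarely
state either.

PAM clustering is deterministic. For every problem size this pipeline
targets (`C(n, k) ≤ 1000`, e.g. 12 samples at k ≤ 6) the exact optimum over
medoid sets is found by enumeration; larger problems fall back to the
classic BUILD + SWAP heuristic with ties broken toward the lowest sample
index. This removes both randomness and the local-optimum failure mode of
SWAP at small n.

The cluster count is the argmax of the Calinski-Harabasz index over
k = 2..k_max (default 6). CH is computed on the full positive-eigenvalue
PCoA embedding of the distance matrix rather than on raw distances, which
makes the between/within sum-of-squares decomposition well-defined for
non-Euclidean metrics. Stratification strength is screened against a
permutation null in which every taxon column is shuffled independently
(destroying sample structure, preserving marginal abundance distributions)
and the whole distance → PAM → CH pipeline is re-run; if the observed
CH(k_best) does not exceed the null's 95th percentile the result carries a
"no strong stratification" flag. A label-permutation null would be wrong
here: PAM-optimized labels beat shuffled labels even on structureless data.

BCA projects samples onto the principal axes of the size-weighted,
column-centered class-mean matrix (k − 1 axes for k classes).

## Community statistics

Rarefaction draws from the exact multivariate hypergeometric distribution.
Shannon entropy uses natural log; "Simpson" is reported in the Gini-Simpson
form 1 − Σp² (the direction is ambiguous in common usage, and the raw Σp² is
recoverable); Chao1 is bias-corrected; ACE uses the standard rare cutoff of
10. These four go through scikit-bio.

ANOSIM is implemented directly (scikit-bio's version is not seedable):
R = (mean between-group rank − mean within-group rank)/(M/2) over the
M = n(n−1)/2 pairwise distances, with one-sided permutation p =
(1 + #{R_perm ≥ R_obs})/(1 + n_perm). At n = 6 with two groups of three only
20 distinct label splits exist, so the smallest attainable p is 0.05 and the
p for a perfectly separated configuration is 0.10 — tests assert these exact
small-sample values rather than a conventional threshold.

Mann-Whitney U tests use the exact null distribution when the combined
sample size is ≤ 20 and there are no ties, and the tie-corrected normal
approximation otherwise (both available explicitly). BH adjustment comes
from statsmodels.

VFA summaries report per-group means, a single pooled SEM per item
(`sqrt(MS_within / harmonic-mean group size)`), and one-way ANOVA p (which
reduces to the equal-variance t-test at two groups, F = t²). TVFA is the sum
of the six acid group means; A:P is the group mean of per-sample
acetate/propionate ratios — the ratio-of-means convention gives a different
number and does not match how such tables are usually computed.

## Co-occurrence networks

Edges require |Spearman ρ| > 0.5 and p < 0.05 (t approximation,
`t = |ρ|√((n−2)/(1−ρ²))`). The sign is stored; `positive_only` restricts to
positive associations and `fdr` gates on BH-adjusted p instead of raw p. At
n = 12 the t approximation is rough — this is inherent to the design being
reproduced, and the thresholds are parameters. Betweenness is Brandes'
algorithm (networkx), normalized by (n−1)(n−2)/2. Hubs are nodes in the top
5% of the degree ranking (extended through ties) *and* the top 20% of the
betweenness ranking; a completely flat degree sequence yields no hubs. The
random-graph comparison uses Erdős–Rényi G(n, m) ensembles with matched node
and edge counts, reporting z-scores for clustering coefficient, mean path
length (largest component) and greedy modularity.

Compositional closure means proportion-space correlations are not
independent of the denominator; SparCC-style corrections are out of scope,
matching the method being reproduced.

## Weighted co-expression modules

The construction is the signed-hybrid recipe: Pearson correlation,
`a_ij = cor_ij^β` for positive correlations and 0 otherwise. The soft power
β defaults per layer to 7 (microbiome), 18 (rumen metabolome), 16 (serum)
and 20 (milk); `pick_soft_power` chooses the smallest candidate whose
scale-free fit index reaches 0.8. The fit index is the r² of log₁₀ p(k) vs
log₁₀ k over 10 connectivity bins, signed negative when the slope is
positive.

TOM follows `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`. Module
detection cuts the average-linkage dendrogram of 1 − TOM at a fixed quantile
of its merge heights and discards branches below `min_module_size`
(default 5, appropriate for layers of 60–260 features). The cut quantile
default is **0.90**: at these layer sizes a handful of top merges join the
distinct correlation blocks, so the cut must sit below roughly the top 5–10%
of merge heights; 0.90 recovers planted blocks with ARI ≈ 0.96 while 0.99
leaves only ~3 merges above the cut and collapses blocks. This static
quantile cut is a deliberate, reproducible simplification of adaptive
dynamic branch cutting, adequate at these feature counts.

Module eigengenes are the first left singular vector of the per-feature
z-scored module submatrix, unit-norm over samples, sign-oriented to positive
mean member correlation (downstream SEM signs depend on this convention, so
it is fixed and documented). Modules merge iteratively while any eigengene
pair correlates above 0.75, highest pair first, to a fixed point.
Module–trait association is Pearson r with the two-sided Student-t p at
n − 2 df. A module's "expression level" is taken to be its eigengene.

## Metabolome statistics

Preprocessing order: (1) detection filter — a feature is kept if observed in
≥ 80% of the samples of at least one group (feature-wise filtering is
standard even where workflow descriptions read as sample-wise; the axis is
configurable); (2) minimum-value imputation; (3) QC RSD filter at 30% when a
QC matrix is given; (4) per-sample sum normalization scaled to the mean
total; (5) log₁₀ with a per-feature half-minimum offset for zeros. The
normalization stage is idempotent, so re-running preprocessing on processed
data changes nothing.

OPLS-DA: columns are autoscaled, y is the centered ±1 class code. Orthogonal
components are extracted by orthogonal signal correction (weights
orthogonalized against the predictive weight vector) and removed before the
single predictive component is fit; with zero orthogonal components the
model *is* one-component PLS-DA, and a test verifies score equality against
scikit-learn's NIPALS PLS. Q²Y = 1 − PRESS/SS from stratified 7-fold
cross-validation, seeded (no CV design is canonical; 7-fold stratified is a
common default). With one predictive component VIP_j = √p·|w_j|, so
mean VIP² = 1 exactly.

Differential metabolites: Student's t on the log scale with BH q, the
group-mean ratio on the pre-log (sum-normalized) scale, and the VIP gate.
Two presets exist because practice varies: "methods" (VIP ≥ 1 AND ratio ≥ 2
or ≤ ½ AND q ≤ 0.05, the default) and "results" (q < 0.05 AND VIP > 1, no
ratio gate). Pathway enrichment is the one-sided hypergeometric tail with BH
q reported alongside raw p.

## SEM path models

Observed-variable recursive path analysis only (module eigengenes and single
metabolites are observed; no latent measurement model). The implied
covariance is Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ with B the path matrix and Ψ diagonal
except for explicitly freed exogenous covariances (`x ~~ y`). The ML
discrepancy is minimized with a per-equation OLS warm start — for recursive
models with diagonal Ψ that start is already the exact optimum, which a test
asserts to 1e-6 — and a BFGS polish otherwise; convergence requires gradient
∞-norm < 1e-4. Optimization runs on the correlation scale (module eigengenes
are unit-norm over samples, so raw variances are ~1/n and badly condition
the surface) and the solution is rescaled; F_ML and all fit statistics are
invariant under this rescaling. Standard errors come from the observed
information (2/(n−1) × inverse numerical Hessian).

Fit statistics: T = (n−1)F_ML reported as χ²;
RMSEA = sqrt(max(χ²−df, 0)/(df(n−1))), defined 0 at df = 0;
CFI = 1 − max(χ²−df, 0)/max(χ²₀−df₀, χ²−df, 0) against the independence
baseline (free variances only, χ²₀ = −(n−1)ln|R| in closed form). A
just-identified model therefore prints RMSEA = 0.000 and CFI = 1.000.

`chain_search` makes the module-screening step explicit: every combination
of one eigengene per layer defines a pure chain ending at the phenotype;
candidates are ranked by CFI (desc), RMSEA (asc), then weakest-path p (asc)
— the last breaks the frequent CFI = 1 ties at small n toward the chain with
the strongest evidence on its weakest link — and the winner is the
best-ranked candidate with every path significant at 0.05. Screening uses
the ML = OLS identity (χ² from the OLS solution, per-path p from the simple-
regression t-test) for speed; the winner is then refit with the full ML
machinery.

## Synthetic cohort generator

The generator emulates the reference study design rather than generic data:

- **Cohort**: 4 + 8 samples in two enterotypes; 60 genera.
- **Genus table**: log-normal intensities closed to proportions. Two driver
  genera receive group-specific mean masses whose expected closed
  proportions match the published profiles — (36.76%, 4.74%) in type 1,
  (22.46%, 24.67%) in type 2 — interpolated on the log scale by
  `driver_shift` (0 = no planted effect, 1 = full effect). Each driver
  carries 8 satellite genera whose masses follow the driver's group pattern
  (mass-renormalized so driver targets are preserved) and whose log-noise
  shares the driver's sample-level noise at correlation 0.7: enterotypes in
  real data are whole sub-community shifts, and this is what makes the
  microbiome layer yield a module tracking the enterotype contrast.
- **Metabolomes**: 260/113/94 features in 10/5/7 blocks per layer; feature =
  √ρ·block factor + √(1−ρ)·noise gives exact within-block correlation ρ
  (default 0.8) and ~0 between blocks.
- **Causal chain**: the microbiome latent is the standardized log driver
  contrast; each downstream layer's designated block factor is
  `coef × upstream + noise`, with noise SDs defaulting to √(1−coef²) so all
  latents are standardized and the implied microbiome→MPY correlation is
  the product of the path coefficients. MPY is rescaled to 1.16 ± 0.17 kg/d
  (the published mean, SD back-computed from SEM 0.050 at n = 12).
- **VFAs**: normal draws around the published group means with
  SD = printed pooled SEM × √(16/3), the reference design's harmonic-mean
  group size; negatives truncate at 0 with a warning.

Free noise magnitudes were calibrated once to the generator's design
contract — the default cohort must be recoverable (enterotype ARI ≥ 0.9,
CH-selected k = 2, planted chain recovered) while remaining noisy enough to
be non-trivial: genus σ = 0.35 and chain coefficients 0.9 put the planted
ANOSIM R near 0.88, the same regime as the published R = 0.74.

**What the benchmarks do not show.** The generator has no zero inflation, no
compositional overdispersion beyond log-normal noise, no batch or diet
effects, equal-variance Gaussian metabolite blocks, and a single linear
causal chain. Passing the planted-recovery suite demonstrates the machinery
is correct and calibrated on data satisfying its assumptions; it does not
certify performance on real rumen data, where block structure is weaker,
noise is heavier-tailed and causal structure is not a single chain.

## Pipeline and reproducibility

Every randomized operation takes an explicit integer seed (package default
20230509); the pipeline expands one global seed into per-stage seeds by a
fixed affine scheme and records everything in a manifest with artifact
checksums, so reruns are byte-identical and completed stages are skipped on
resume. Stage artifacts live on disk between stages so each stage can be
re-run or inspected alone.

Default problem sizes throughout the test and acceptance suites (12-sample
cohorts, 20-replicate ensembles, n = 1000 for coefficient-bias checks) keep
a full run around two minutes on one CPU while leaving the planted-recovery
statistics stable.
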