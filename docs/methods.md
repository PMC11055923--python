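# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices that were genuinely open.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and normalization

A dataset is a rats × variables matrix with a per-rat group label (NS =
no shock, IS = inescapable shock) and per-variable metadata: test membership
(OF, FST, SIT, EPM, NOR, PPI, SPT, SB) and valence — *resilience* if higher
values indicate adaptive coping, *susceptibility* if they indicate
stress-induced maladaptation.

All multivariate analyses operate on column-wise Z-scores pooled over both
groups: `z = (x − mean) / sd` with the sample SD (n−1 denominator; the
common default of scientific computing environments — the n vs n−1 choice
was open and is recorded here). Constant columns are rejected, not imputed;
missing values are rejected at load, with an explicit drop-row option
mirroring the practice of excluding animals rather than imputing.

Derived behavioral indices follow the standard formulas: daily sucrose
preference `(SI/(SI+WI))·100` (%), novel-object discrimination `TN/(TF+TN)`,
social preference `OC/EC`, startle habituation `100 − 100·(HAB1/HAB0)` (%),
and prepulse inhibition `100 − ((PP+P)/P)·100` (%), where PP+P denotes the
startle amplitude on prepulse+pulse trials. Denominators must be positive;
indices built purely from ratios are invariant to common positive rescaling.

## Univariate statistics

- **Normality gate.** One-sample Kolmogorov–Smirnov on the standardized
  sample against the standard normal. Because mean and SD are fitted, the
  classic p value is conservative; a Lilliefors-corrected variant
  (statsmodels) is available by flag.
- **Group comparison.** `route="auto"` uses Student's t (equal-variance,
  df = nₓ+nᵧ−2) when both samples pass the KS gate at α = 0.05, else the
  Wilcoxon rank-sum test. The rank-sum route reports W of the first sample;
  the Mann–Whitney U (= W − nₓ(nₓ+1)/2) is carried alongside because the two
  conventions are often conflated in published statistics. Its p value uses
  exact enumeration when the smaller group has n ≤ 10 with no ties,
  otherwise the tie-corrected normal approximation with continuity
  correction.
- **Variance equality.** Levene's test centered at the group means (the
  median-centered Brown–Forsythe variant is deliberately not substituted).
- **Association.** Pearson χ² without Yates continuity correction,
  df = (r−1)(c−1); every expected count must be positive. The continuity
  correction is omitted because cluster × class tables in this workflow are
  analyzed as-is; with correction a 2×2 table such as [[20,8],[3,14]] drops
  from χ² ≈ 12.24 to ≈ 10.19.
- **Agreement.** Cohen's κ from marginal chance agreement (κ = 1 when both
  raters are constant and identical); ICC(2,1) — two-way random effects,
  absolute agreement, single measure — from the ANOVA mean squares
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)`. Zero
  between-subject variance yields a value ≤ 0, reported as-is.

## Feature structure

**Sign-independent distance.** `d(x, y) = min(‖x−y‖₂, ‖x+y‖₂)` on Z-scored
variable vectors. It satisfies `d(x, −x) = 0` and `d ≤` Euclidean with
equality whenever `x·y ≥ 0`. It is not a metric in the strict sense (the
triangle inequality can fail), so Ward agglomeration treats the distances
*as if* Euclidean via the Lance–Williams update — the standard practical
approximation, shared with the common implementations. Variable trees can
alternatively be built on `1 − |Spearman ρ|` (`metric="one_minus_abs_spearman"`);
which distance a given study used for its variable dendrogram is often
ambiguous, so the choice is a logged keyword, defaulting to the
sign-independent Euclidean.

Tree validity is summarized by the cophenetic coefficient (Pearson
correlation between tree-implied and original distances). Cuts use the
standard maxclust criterion; cuts are nested across k. Cluster × label
association (valence or test membership) uses the χ² above.

**Permutation reliability.** Each iteration subsamples 70% of rats (or of
variables), rebuilds the tree, cuts at k = 2, and records the valence χ² p;
the summary is the fraction of iterations with p < α. Subsample sizes round
to nearest with ties up. The companion null repeats the procedure on
column-shuffled data — each variable independently permuted across rats,
destroying all covariance while preserving marginals exactly (a row-label
shuffle is available as an option; the per-column scheme is the default
because the procedures here test covariance structure). Iterations whose
subsample makes the test degenerate count as non-significant, which is
conservative.

**Factor analysis.** Iterated principal-axis factoring on the correlation
matrix: communalities start at the squared multiple correlations, the
reduced matrix is eigendecomposed, and loadings/communalities iterate to a
1e-8 fixed point (Heywood cases clip at communality 1 and are flagged).
Principal-axis was chosen over maximum likelihood so that uniqueness =
1 − communality holds identically. Varimax rotation (Kaiser-normalized,
SVD-based updates) is orthogonal and therefore preserves communalities;
factors are ordered by explained variance and sign-fixed
(largest-|loading| entry positive).

## PCA patterns

PCA is computed by SVD of the column-centered matrix; with n rats at most
n−1 components exist. Components are ordered by explained variance and
sign-fixed so each component's largest-|coefficient| entry is positive — an
arbitrary but necessary convention for reproducible coefficient tables.

- **Shuffled variance null.** Per iteration, shuffle columns and re-run PCA;
  a component is flagged when its observed explained % exceeds the null's
  95th percentile. On pure noise ~0–1 components flag (the 5% false-positive
  bound); on planted factor structure the leading components flag and the
  trailing ones are *depressed* below their null, so false positives beyond
  the structure are rare.
- **Split-data reliability.** Per iteration, PCA on a 70% subsample of rats;
  each full-data PC is matched to the subsample PC maximizing the absolute
  Pearson correlation — coefficients compared over all variables, scores
  over the shared rats. Absolute correlation with post-hoc matching is
  required because a subsample can flip a component's sign or permute
  near-degenerate components. Reported values are medians over iterations;
  the shuffled companion gives the chance level.
- **VIF.** `1/(1−R²)` from OLS of each variable on its peers (with
  intercept); values above 1.1 are flagged as multicollinear — an unusually
  strict threshold appropriate for choosing *representative* variables, one
  per test, for a reduced PCA. In the synthetic default world the six
  representative variables share planted latent factors and their VIFs
  exceed 1.1; the screen is expected to pass only on data whose
  representative measures are nearly independent, as in the study data the
  threshold comes from.
- **LDA on cumulative PCs.** For each PC set PC1..k, a linear discriminant
  with pooled covariance (no shrinkage; SVD solver, so singular covariances
  degrade gracefully) is trained on random unstratified 70/30 splits
  (redrawn if a class is missing from training) and evaluated on the held
  out 30%; the accuracy is the mean over iterations. The null runs the
  identical procedure on column-shuffled scores, and p =
  (1 + #{null ≥ observed mean})/(n_iter + 1) — an empirical permutation p,
  used because no analytic reference distribution fits this procedure.
  Note a subtlety the test suite documents: on a *single* finite dataset,
  null accuracy deviates from 0.5 (chance train/test-shared alignment, and a
  below-chance bias under exactly balanced label permutations); 0.5 is the
  expectation over independent datasets.

## Individual profiles

- **Helplessness.** The two shuttle-box escape measures (failures, mean
  latency) are Z-scored — making the classifier invariant to affine
  rescaling — and k-means clustered with the cluster count chosen by mean
  silhouette over k ∈ {2, 3, 4}; the cluster with the higher mean escape
  failures is H (the assignment rule is implied but rarely stated in the
  literature; it is made explicit here).
- **k-means.** Lloyd's algorithm, squared-Euclidean objective, initial
  centroids drawn uniformly from the observations, best (lowest-inertia)
  of many restarts — 10⁴ by default, matching the full-scale procedure;
  tests use fewer since the small problems converge identically.
- **Silhouette.** `s = (b − a)/max(a, b)` with squared-Euclidean distances,
  consistent with the k-means objective (plain Euclidean by flag).
  Conventions, each flagged: singletons get s = 1; all-zero distances give
  s = 0.
- **Semi-supervised k selection.** Among candidate k whose mean silhouette
  is within δ = 0.02 (absolute) of the maximum, the largest k whose
  cluster × group χ² is significant at α = 0.05. δ makes "silhouette said
  six and seven were both suitable" operational; no qualifying k is an
  explicit no-selection outcome, not an error.
- **Profiles and correspondence.** Per-cluster mean Z ± SEM (singleton SEM
  is undefined → NaN), sizes, NS/IS composition. Two clusterings are
  compared by optimal one-to-one cluster matching (Hungarian algorithm on
  the contingency table), reporting per-pair Jaccard and overall matched
  overlap / n.

## Synthetic battery generator

The default configuration states the world the analyses assume: 22 NS +
23 IS rats, 26 variables over the 8 tests. Rat i, variable v in test t:

```
x_iv = λ_test·f_it + sign_v·λ_sus·s_i + λ_val·g_i,val(v)
       + H_i·δ_sb·[v ∈ SB susceptibility] + offset[c_i, v] + σ·ε_iv
```

- `f_it ~ N(0,1)`: per-test factors (λ_test = 0.8) → strong intra-test
  correlation.
- `s_i ~ N(0,1) + δ_H·H_i`: the bipolar resilience–susceptibility axis
  (λ_sus = 0.5, δ_H = 1.0) loading with sign +1 on susceptibility and −1 on
  resilience variables.
- `g_i,res, g_i,sus ~ N(0,1)`: per-valence factors (λ_val = 0.6). These are
  essential and deliberate: the bipolar axis alone is *antisymmetric* in
  valence, and the sign-independent distance is blind to antisymmetric
  structure (a resilience variable's negation is indistinguishable from a
  susceptibility variable), so a generator without them cannot produce
  valence-separable variable clusters no matter how strong the axis. Real
  batteries separate valences because susceptibility measures share
  covariance that is not the mirror image of the resilience measures'.
- `H_i`: latent helplessness, Bernoulli(20/23) in IS and Bernoulli(8/22) in
  NS — the observed helpless proportions of a 45-rat shock experiment.
  δ_sb = 3.0 adds a dedicated shift on the shuttle-box susceptibility
  variables: helpless animals fail most escape trials, sitting several SD
  above the population on exactly those measures, which is what makes a
  2-variable k-means classifier viable at all. (Routing the same separation
  through the global axis would require δ_H ≈ 6 and make helpless rats ~3 SD
  deviant on *every* variable, destroying the weak-inter-test-correlation
  structure.)
- Profile clusters (3 by default): cluster 0 baseline; intermediate clusters
  add +0.8 on one test block; the last cluster is a "generalized
  susceptibility" profile (+0.8·sign_v on every variable). Latent-H rats
  fall into it with probability 0.8, tying profile structure to
  helplessness the way observed profile clusters track shock exposure.
- `σ = 0.6` residual noise.

Default loadings were frozen after verifying the planted-structure
calibration targets the generator is specified to meet (valence-separable
variable clusters in ≥90% of seeds; subsample reliability well above the
shuffled control) — they were not revisited afterward, and no acceptance
tolerance was adjusted to them.

**What the generator does not emulate.** Raw trial-level behavior
(trajectories, per-trial shocks), bounded/count-valued measures (everything
is Gaussian on the Z scale), missing data, batch or litter effects, and
heavier-tailed individual variation. A green test on synthetic data
establishes that a procedure detects the structure it targets at the stated
effect sizes and rejects its absence — not that real batteries contain that
structure.

**Permutation utilities.** Column-wise shuffling (exact marginal
preservation) and uniform subsampling without replacement (nearest-integer
size, ties up — with an epsilon guard against binary-float artifacts like
0.7·45 = 31.499999999999996) are shared by every reliability procedure, all
driven by explicit seeds.

## Pipeline and reproducibility

`run_pipeline` composes the stages in battery order: univariate statistics →
helplessness classification → feature structure (+ reliability) → PCA / VIF
/ LDA → individual profiles, writing TSV artifacts and a JSON manifest. A
master seed spawns per-stage seeds through a fixed counter scheme
(`SeedSequence([master, stage_index])`), so stages are independently
reproducible and changing one stage's workload leaves the others'
randomness untouched. Default iteration counts are the full-scale ones
(10⁴ reliability iterations, 1000 LDA iterations, 10⁴ k-means restarts);
`RunConfig.fast()` scales them down for exploration and CI-speed runs.

## Known limitations

- Ward on the sign-independent (and 1−|ρ|) distances is a Lance–Williams
  approximation; heights are not guaranteed monotone for arbitrary
  non-Euclidean input (they are monotone in practice on these data).
- Linkage tie-breaking follows scipy's deterministic nearest-neighbor-chain
  order; ties between merge candidates (measure-zero on continuous data)
  could order differently on other implementations.
- The KS normality gate at n ≈ 22 per group has limited power; the auto
  route therefore favors the t-test on small samples.
- χ² p values for tables with small expected counts (fine cuts of 45 rats)
  are approximate; `hierarchy_scan` flags cuts with expected counts < 1.
- Factor analysis assumes enough rats per variable for a stable correlation
  matrix; with 45 rats and 26 variables the 7-factor solution is usable but
  near the edge of identifiability.
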