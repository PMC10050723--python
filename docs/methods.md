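# Methods

## Problem setting and model

trimint looks for *cross-omics modules* that separate two phenotype classes:
a miRNA and a CpG probe with strongly correlated profiles, plus the mRNAs
jointly correlated with both. The biological intuition is that a miRNA and a
methylation site acting in the same regulatory programme leave a correlated
footprint, and the genes tied to both are candidate effectors of that
programme. The pipeline is a grouping–scoring–modeling (G-S-M) design:
groups are formed from data alone (correlation thresholds, no target
databases), scored by supervised discriminative ability, and combined into
cumulative classifiers whose held-out performance is the headline output.

All statistics are feature-wise or pairwise Pearson correlations and
classical two-sample tests; the classifier is a random forest throughout. A
run is a pure function of (input matrices, labels, configuration, master
seed).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.6 | minimum absolute Pearson correlation for a miRNA–CpG pair (strict inequality) |
| `pair_p_max` | 0.05 | two-sided p-value gate on pair correlations (t-transform, n−2 df) |
| `beta` | 0.6 | minimum correlation of a gene with *both* pair members; absolute value by default, signed via flag |
| `ttest_p_max` | 0.05 | per-feature two-class Welch t-test gate applied to all three omics |
| `max_missing_fraction` | 0.2 | CpG probes missing in strictly more than this fraction of samples are dropped; survivors mean-imputed |
| `min_iqr` | 0.1 | CpG probes must have interquartile range strictly above this (linear-interpolation quantiles) |
| `n_outer_splits` | 100 | outer Monte Carlo train/test splits |
| `test_fraction` | 0.1 | held-out fraction per outer split (stratified) |
| `inner_cv_iterations` | 5 | Monte Carlo iterations of the group-scoring CV |
| `inner_test_fraction` | 0.1 | inner held-out fraction, mirroring the outer regime |
| `top_k_groups` | 10 | cumulative models are built for k = 1..top_k |
| `min_group_frequency` | 5 | groups seen in ≤ this many splits are filtered from aggregates |
| `rf_trees` | 100 | trees per random forest (sqrt feature sampling) |
| `score_metric_weights` | accuracy = 1 | weighted metric mix for group scores; `auc` may be added |
| `leakage_mode` | `global` | where the supervised/correlation feature selection sees data (below) |

## Design choices where the design was open

- **t-test flavour.** "t-test" admits pooled or unequal-variance forms; the
  default is Welch's, the robust choice for omics group comparison, with the
  pooled form behind a flag. Features constant in both classes carry no
  information and are treated as p = 1.
- **Absolute vs signed β.** The group condition is applied to |cor| by
  default: miRNA repression and methylation silencing make strong *negative*
  gene correlations biologically meaningful, and the pairing stage is
  already sign-symmetric. `use_abs_beta=False` restores the literal signed
  reading `cor > β`.
- **Leakage mode.** The original workflow applies the t-test filter and the
  correlation scans before splitting, i.e. the held-out samples influence
  feature selection. `leakage_mode="global"` reproduces that order (and is
  the default for fidelity); `"train_only"` recomputes the filter, the
  pairs and the groups inside each split from training samples only and is
  the statistically safer choice when honest generalization estimates
  matter.
- **Inner CV shape.** Group scoring uses stratified Monte Carlo splitting
  (5 iterations, 90/10), mirroring the outer regime; k-fold was deliberately
  not added to keep one split code path. All groups of a split are scored on
  the *same* inner partitions — otherwise score differences between groups
  would partly reflect partition luck, not gene-set quality.
- **Determinism and tie-breaks.** Pairs sort by (|r| desc, miRNA ID, CpG
  ID); genes within a group by descending min(|cor(a,c)|, |cor(c,b)|) then
  ID; score ties break toward larger gene sets (more informative for the
  cumulative models), then name. Sample order and within-group gene order
  are canonicalized (sorted) before classifier fits, so scores cannot depend
  on input file order. All randomness flows from one master seed: outer
  split i uses `seed + i`, and consumers derive children via numpy
  `SeedSequence` mixing.
- **Aggregation counting.** A group counts as "detected in a split" when it
  appears in the split's scored list at all; `count_top_k_only` restricts
  counting to each split's top-k for the stricter reading. Feature-level
  average score/rank are occurrence-weighted over (split, group) events.
- **Across-split performance summary.** Per k the summary reports both the
  maximum union size over splits ("unique genes") and the mean union size
  ("average gene count"), plus mean ± standard error of each metric over the
  splits where k was available.
- **Rank-matrix clustering.** Splits are clustered by average linkage on
  Euclidean distances of their rank columns; non-detections are imputed one
  worse than the worst observed rank *for the distance computation only* —
  exported tables keep them missing.
- **AUC.** Computed as the Mann–Whitney rank statistic with ties counted
  1/2, on the forest's positive-class vote fraction. Single-class test truth
  yields a missing AUC rather than an arbitrary value.

## Synthetic data generator

Each planted module is a single-factor Gaussian model: per sample the latent
is `z = effect_size·1[y = positive] + N(0,1)`, and each planted feature is
`sign·(loading·z + √(1−loading²)·noise_sd·N(0,1))` with an independent
random sign per feature. Background features are independent standard
normals. Defaults — 60 samples per class, 3 modules of 5 genes, loading
0.8, effect 2.0, 200 background features per role — were chosen so that the
design is analytically transparent: with no class effect two module features
correlate at exactly `loading² = 0.64`, just above the default α = 0.6, and
the class effect (latent variance 1 → 2 with balanced classes) raises the
population correlation to ≈ 0.78, giving planted pairs a comfortable margin
at n = 120 while cross-module correlations (≈ 0.39, induced by the shared
class effect) stay safely below threshold. `expected_pair_correlation`
returns the zero-effect value for test design.

The generator emulates structure, not marginals: no count overdispersion,
no library-size or normalization artifacts, no beta-value bimodality
(optional logistic squashing gives the (0,1) range only), no correlated
probe blocks beyond the planted modules. Passing tests therefore demonstrate
that the machinery recovers the intended structure under the stated model,
not that it is robust to every pathology of real TCGA matrices.

## Calibration and problem sizes

The test suite checks, against independent oracles: all-pairs detection vs
a naive double loop with the textbook correlation formula; group membership
by independent re-verification and β-monotone nesting; confusion metrics vs
brute-force tabulation on an enumerated grid; AUC vs the pairwise-comparison
definition including ties; clustering order vs an independent agglomerative
implementation. Simulation experiments check planted-module recovery (50
seeds × 10 outer splits: the three planted groups must occupy ranks 1–3 in
≥ 90 % of splits with exact gene sets in ≥ 95 % of detections) and null
calibration (effect 0: k = 1 held-out AUC averaged over seeds within
[0.35, 0.65]; background t-test rejection within 3 binomial SD of 5 %). In
the null experiment the t-test gate is disabled so that groups still form —
group formation is label-free there, which is exactly what makes the
held-out AUC an honest null probe of the scoring/modeling path.

Simulation-heavy experiments use 25-tree forests and 5–10 outer splits per
seed; group ranking on the planted signals is insensitive to forest size
well below the 100-tree default, and the reduced sizes keep the full
experiment grid fast on one CPU. `scripts/acceptance.py` uses 8 seeds × 5
splits (signal) and 8 seeds × 3 splits (null) for the same reason.

## Known limitations

- The all-pairs scan is dense O(|A|·|B|) in memory for the correlation
  matrix; at the intended post-filter scales (10³–10⁴ features) this is a
  few hundred MB at most, but unfiltered 450k-probe methylation arrays must
  pass the variability/missingness filters first.
- Only Pearson correlation and random forests ship; the classifier registry
  accepts alternatives but none are bundled.
- `leakage_mode="global"` reproduces the original ordering and therefore
  inherits its optimism; use `train_only` for unbiased performance claims.
- Aggregate tables are undefined guidance when `n_outer_splits` is small
  relative to `min_group_frequency`; lower the threshold for short runs.
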