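# phenoclust

Multidimensional behavioural phenotyping for small case-control cohorts:
sparse k-means clustering of task-derived behavioural measures with
data-driven cluster-number selection, bootstrap stability assessment, and a
permutation/bootstrap inference suite for comparing diagnostic groups and
clusters.

The intended user is a clinical-research analyst with a participant table
(one row per participant: diagnosis, demographics, clinical scales, and the
ten behavioural measures from a Novelty Exploration Task and an Activity
Preference Task) who wants to ask: *do participants fall into behaviourally
distinct subgroups, how many, how stable are they, and do the subgroups
differ clinically?*

## The method

Let `X` be the n x 10 matrix of task measures after power transformation
(Box-Cox, or Yeo-Johnson for variables with non-positive values) and
standardization.  Sparse k-means jointly chooses a partition and
non-negative feature weights `w` maximising

    sum_j w_j BCSS_j(partition)   s.t.  ||w||_2 = 1,  ||w||_1 <= l,

where `BCSS_j` is the between-cluster sum of squares of feature j.  The
number of clusters k in [2, 10] is selected by the concurrence of the gap
statistic, the weighted gap statistic, and Clest, all against uniform
reference data aligned with the principal components of `X`.  Cluster-wise
stability is the mean Jaccard similarity to the best-matching cluster across
bootstrap reclusterings (> 0.75 stable, > 0.85 highly stable).  Group and
cluster comparisons use Freedman-Lane permutation MANCOVA (Pillai's trace),
cluster-stratified bootstrap ANOVA with nullified between-cluster means,
residual-bootstrap interaction tests, and BCa confidence intervals for
pairwise contrasts.  Because the motivating study's participant-level data
are not deposited, the package ships a synthetic-cohort generator with a
planted three-cluster structure (Low Exploration / Low Activity / High
Performance) that reproduces the study's sample sizes, composition, skewed
physical measurement scales, block missingness, and clinical effect pattern.

## Worked example

```python
import numpy as np
from phenoclust.simdata import CohortSpec, generate_cohort, inject_missingness
from phenoclust.prep import prepare_task_matrix
from phenoclust.spkmeans import SparseKMeansConfig, sparse_kmeans
from phenoclust.clusterval import bootstrap_stability
from phenoclust.clusterstats import boot_oneway_anova

spec = CohortSpec(seed=1)                      # 45 SZ + 47 HC, planted k=3
table = inject_missingness(generate_cohort(spec), spec)
prepared = prepare_task_matrix(table)          # winsorize, transform, scale

sol = sparse_kmeans(prepared.values, SparseKMeansConfig(k=3, n_start=50, seed=2))
print("cluster sizes:", np.bincount(sol.labels).tolist())
print("weights:", sol.weights.round(2).tolist())

stab = bootstrap_stability(prepared.values, sol, B=150, seed=3, n_start=10)
print("mean Jaccard:", stab.mean_jaccard.round(3).tolist(), stab.labels)

aes = boot_oneway_anova(table["AES"].to_numpy(), sol.labels, B=1999, seed=4)
print(f"AES omnibus F={aes.value:.2f}, P_boot={aes.p_empirical:.4f}")
```

Output:

```
cluster sizes: [30, 34, 28]
weights: [0.3, 0.39, 0.29, 0.32, 0.33, 0.35, 0.36, 0.3, 0.29, 0.18]
mean Jaccard: [0.995, 0.967, 0.956] ['highly stable', 'highly stable', 'highly stable']
AES omnibus F=18.70, P_boot=0.0005
```

The three recovered clusters match the planted 39/23/30 structure up to
boundary cases (adjusted Rand index 0.847 on this seed); all ten features
keep non-zero weights; and the planted apathy (AES) elevation in the two
low-performance clusters is detected by the stratified-bootstrap ANOVA.

A command-line interface mirrors the library
(`phenoclust simulate | prep | cluster | select-k | stability |
group-compare | cluster-compare | correlate | run-all |
run-groups-separated | run-covariate-adjusted`); `--published-scale` restores
published-scale resampling budgets (1000 starts, 2000-fold resampling,
50,000 permutations).

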