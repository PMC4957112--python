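# Methods

This note defines the model the package implements, the parameters and
their defaults, the numerical conventions that make results reproducible,
and the scope of the synthetic benchmarks. Notation: `n` samples, `m` raw
features, `B` boosting chains, `S` steps per chain, `C` candidates per
step, pool size `P = B * S`.

## Model

### Standardization

Features are standardized once at fit time: subtract the per-feature mean,
divide by the per-feature sample standard deviation (the `n - 1`
convention). A zero-variance feature gets divisor 1 and becomes an all-zero
column, which no network can split on. The fitted scaler is stored and
applied to prediction inputs, so the model is invariant to affine rescaling
of any raw feature.

### Random bits

A *random bit* is the output of a sparse 3-layer threshold network:

* `twist2` hidden nodes, each wired to `twist1` **distinct** input features
  chosen uniformly at random, with i.i.d. standard-normal weights;
* one top node combining the hidden outputs with standard-normal weights;
* both layers are **strict** threshold units: output 1 iff the linear
  summation strictly exceeds the threshold;
* every threshold is data-driven: it equals the node's own linear summation
  evaluated at one uniformly chosen training sample. In particular the
  sample a threshold was taken from emits 0 at that node, and roughly half
  the training sample lands on each side of every unit.

No weight is ever trained. With `twist1 = twist2 = 1` the network
degenerates to a threshold on one raw feature; this axis-parallel ablation
is used as an internal baseline.

### Boosting selection

The pool of `P` bits is built by `B` independent chains. A chain keeps a
working residual, initialized once to the working target (the regression
target, or the binary label recentred to ±0.5). Each of its `S` steps:

1. draws `C` candidate networks and evaluates their bits on the training
   sample;
2. scores each candidate by the *explained variance* — the between-group
   sum of squares of the residual split by the bit,
   `s1²/n1 + s0²/n0 − (s1+s0)²/n` with `s0`, `s1` the residual sums over
   the bit-0 and bit-1 groups;
3. keeps the strictly best candidate (first candidate wins ties, i.e. a
   `Var > MaxVar` scan from zero) and subtracts the bit's conditional group
   means from the residual: `residual(i) -= Mean[bit(i)]`.

The update removes exactly the explained component, so the chain's sum of
squared residuals is non-increasing; if no candidate explains anything the
first candidate is stored unchanged to keep the pool aligned. Chains run
from independently spawned seed streams, so the pool is identical
regardless of execution order, in chain-major order.

`C = 1` disables selection and reduces the pool to naive random
projections; the gap between `C = 128` and `C = 1` measures what selection
buys.

### The bit forest

Pool bits are packed one bit per sample into little-endian 64-bit words
(lowest sample index in the least significant bit). The forest departs from
a textbook random forest in that each tree receives a bootstrap of the
samples **and** a bootstrap (with replacement, then deduplicated) of
`bits_per_tree` pool bits, and every split scans that tree's whole bit set
for the best split — there is no fresh per-split feature draw. Splits are
inherently binary (left = 0, right = 1).

The split score is the same between-group sum of squares as in boosting.
For 0/1 targets the Gini decrease equals `2/n` times that quantity, so one
scorer serves variance reduction (regression) and Gini decrease
(classification) identically; ties go to the lowest pool bit index. Growth
stops on node purity, when a node has fewer than `2 * min_node_size`
samples, or when no bit attains a positive decrease. Prediction averages
leaf values over trees: leaf means for regression, leaf class-1 fractions
(a probability) for classification; `predict` thresholds the probability
at 0.5.

## Parameters and defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| `twist1` | 3 | inputs per hidden node; 3 keeps networks sparse yet oblique — wider wiring has not been observed to help |
| `twist2` | 3 | hidden nodes; a 3-layer network is already a universal approximator, additional depth bought nothing |
| `n_chains` (B) | 256 | with `S = 40` gives the ~10,000-bit pool the method is designed around |
| `n_steps` (S) | 40 | pool size `B * S = 10,240` |
| `n_candidates` (C) | 128 | selection pressure per step; values above ~100 are recommended, 1 disables selection |
| `n_trees` | 500 | standard forest size; error plateaus well before this |
| `bits_per_tree` | `ceil(sqrt(P)) * 8` | square-root feature bootstrap scaled up because single bits are weak features (809 for the default pool) |
| `sample_fraction` | 1.0 | bootstrap resample size as a fraction of `n`; lowering it regularizes small samples |
| `min_node_size` | 1 (classification), 5 (regression) | classic forest leaf-size defaults |
| `random_state` | None (treated as 0) | fitting is always deterministic |

The reduced configuration used in the acceptance benchmarks
(`B = 64, S = 20, C = 128`, 150 trees) keeps the suite inside a desk-scale
time budget; the pool is 1,280 bits instead of 10,240.

## Numerical conventions

These choices make the pipeline reproducible bit for bit and are asserted
by tests:

* **Strict inequalities everywhere.** Both network layers use `>`; a
  summation exactly equal to its threshold emits 0.
* **Batch-shape-independent evaluation.** The summations over `twist1`
  inputs and `twist2` hidden bits are accumulated term by term with
  elementwise operations in a fixed order, never with fused reductions
  (`matmul`/`einsum`), whose accumulation order — and hence the last ulp —
  can depend on the batch shape. Since stored thresholds *equal* training
  summations exactly, threshold ties are common, and a one-ulp difference
  would flip bits. With this convention, evaluating one sample or a
  thousand gives identical bits.
* **Complement-invariant split scoring.** Both group sums are computed
  directly (`s1 = y·b`, `s0 = y·(1−b)`), not one by subtraction, so a bit
  and its complement score exactly equally and the lowest-index tie-break
  is well defined.
* **Tie-breaks.** Boosting: first candidate attaining the maximum. Forest
  splits: lowest pool bit index. Youden threshold: lowest cut. SNP
  ranking: equal p-values order by SNP index.
* **Seeding.** All randomness flows from `random_state` through
  `numpy.random.SeedSequence` spawning: one stream per boosting chain, one
  per tree. Chains and trees are therefore independent and
  order-insensitive.
* **Sample standard deviation** (`n − 1`) in the scaler.

## Evaluation statistics

* **AUC** is the Mann–Whitney probability that a random positive outscores
  a random negative, computed from midranks with ties counted 1/2.
* **AUC confidence intervals** are Hanley–McNeil: with `A` the AUC,
  `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`,
  `SE² = (A(1−A) + (n₊−1)(Q1−A²) + (n₋−1)(Q2−A²)) / (n₊ n₋)`, interval
  `A ± 1.96·SE` clipped to [0, 1].
* **Optimal threshold** maximizes Youden's J = sensitivity + specificity − 1
  over observed cuts (call positive when score ≥ cut).
* **k-fold CV** is seeded and stratified for classifiers, so every fold
  contains both classes.
* **Wilcoxon signed-rank** (paired): zero differences dropped, absolute
  differences midranked, tie-corrected normal approximation
  (`var = n(n+1)(2n+1)/24 − Σ(t³−t)/48`) with a 0.5 continuity correction.
  These conventions reproduce the published benchmark comparison p-value
  (0.007185) from the 14 printed RMSE pairs exactly.

## GWAS pipeline

SNPs are scored on the training cohort with the allelic chi-square test:
each subject contributes two alleles to a 2×2 minor/major × case/control
table, `chi² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, p from the 1-df
chi-square distribution; a zero marginal gives chi² = 0 and any zero cell
leaves the odds ratio as missing (NaN). SNPs are ranked by p-value, the
number fed to the learner is swept by AUC on the independent test cohort,
and the final report combines 10-fold cross-validation on the training
cohort with the test-cohort ROC analysis. Choosing the SNP count on the
test cohort mirrors the original study design but is optimistically biased;
every report carries this caveat programmatically (`SELECTION_BIAS_NOTE`).

## Synthetic benchmarks: what they emulate and what they don't

* `gen_hill_valley` emulates bump-shape recognition on a shifted baseline:
  baseline U(0, 10), bump amplitude U(1, 5), centre in the middle 60% of
  the series, width U(5, 15), additive Gaussian noise. Because the
  amplitude is commensurate with the baseline spread, single time points
  retain some marginal signal — axis-parallel learners are *handicapped*
  here, not helpless, so the ablation gap on this family is real but
  smaller than on the harder public benchmark that inspired it.
* `gen_oblique` draws an exactly linear boundary deliberately misaligned
  with every axis, plus label noise — the cleanest probe of the oblique
  advantage.
* `gen_surface` is a smooth two-feature regression surface.
* `gen_genotypes` draws biallelic SNPs in Hardy–Weinberg equilibrium with
  a sparse additive liability model and logistic case/control sampling. It
  deliberately omits linkage disequilibrium, population structure, and
  genotyping error; recovery rates on it are upper bounds relative to real
  cohorts. Train/test cohorts must come from one population — the
  acceptance pipeline generates one panel and splits it.

Generator forms are frozen (`FIXTURE_VERSION`); any change must bump the
version so downstream expectations fail loudly.

## Limitations

* Binary classification only; multi-class targets are rejected.
* The whole training bit pool is held in memory during fit (packed, so
  `n * P / 8` bytes — ~13 MB for `n = 10,000` at the default pool).
* Saved models predict but do not resume training (training bits are not
  persisted).
* Missing values are rejected, not imputed.
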