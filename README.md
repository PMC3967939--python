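# chromcode

Maximum-entropy modeling of chromatin factor combinatorial binding
patterns.

Genome-wide profiling (ChIP-chip/ChIP-seq) measures dozens of histone
marks and chromatin proteins over the same genome, and their
co-occurrence patterns — the "chromatin code" at each genomic bin — are
shaped by direct molecular interactions tangled with indirect,
transitive correlations.  `chromcode` is for computational biologists
who want to dissect those dependencies quantitatively: it learns a
global probabilistic model of the binary occupancy vector
x ∈ {0,1}^n per bin,

    P(x) = exp(E(x)) / Z,
    E(x) = Σ_i h_i x_i + Σ_{i<j} J_ij x_i x_j + Σ_{i<j<k} K_ijk x_i x_j x_k,

the maximum-entropy distribution matching the observed single, pairwise
and triplet occurrence frequencies.  The self-energies h_i set each
factor's occurrence rate; an interaction energy J_ij (or K_ijk) is the
log fold change in pattern frequency attributable to that specific pair
(triple) after conditioning on all other modeled factors — unlike a
correlation, it is not inflated by indirect paths.

The package covers the full workflow:

- **discretize** — binarize continuous per-bin signal by fitting a
  symmetric-background + one-sided-signal mixture and thresholding at the
  equal-likelihood point (depletion-type factors such as linker/core
  histones binarize on the left tail); 200 bp binning, 50%-coverage
  filtering, and an RPKM variant for expression.
- **structure learning** — sparse J by L1-penalized pseudo-likelihood;
  hierarchical sparse K by overlapping group-L1 (a triplet can be nonzero
  only when all three member pairs are), with the penalty strength chosen
  on validation data.
- **fine-tuning** — maximum-likelihood refinement of the selected
  structure by Gibbs-sampled moment matching.
- **evaluation** — partition function via the all-zero-pattern estimator,
  held-out coherence score exp(mean log-likelihood), pattern-frequency
  prediction, contiguous genome-slice train/val/test splitting.
- **interactions** — ranked interaction-energy tables, bootstrap-averaged
  precision–recall against curated experimental standards, and
  correlation/mutual-information baselines.
- **inference** — impute an unmeasured factor's profile per bin from the
  others through the model's logistic conditionals, including
  cross-cell-type prediction over a shared factor set; AUC evaluation.
- **synthetic** — planted-truth generators powering every test.

## Worked example

Plant a sparse 10-factor model, sample 12,000 bins, split by genome
slices, learn the pairwise structure, fine-tune, and compare against the
independent-Bernoulli baseline:

```python
import numpy as np
from chromcode import (random_sparse_model, sample_dataset, fit_independent,
                       fit_mle_mcmc, coherence_score, interaction_energy_scores)
from chromcode.evaluation import split_matrix
from chromcode.structure_learning import default_lambda_grid, select_lambda
from chromcode.model_core import exact_log_partition

truth = random_sparse_model(10, pair_density=0.2, seed=42)
data = sample_dataset(truth, 12_000, seed=43, method="exact")
parts = split_matrix(data, n_slices=50, seed=44)

grid = default_lambda_grid(parts["train"], order=2, n_points=12)
lam, path = select_lambda(parts["train"], parts["val"], grid, order=2)
model = path.models[int(np.nonzero(path.lambdas == lam)[0][0])]
tuned, trace = fit_mle_mcmc(model, parts["train"], n_iter=200,
                            samples_per_iter=5000, step_size=0.05, seed=45)
tuned.logZ = exact_log_partition(tuned)

print("selected lambda: %.4g" % lam)
print("recovered pairs: %d (planted %d)" % (len(model.J), len(truth.J)))
print("coherence (order-2, tuned): %.4g" % coherence_score(tuned, parts["test"]))
print("coherence (independent):    %.4g"
      % coherence_score(fit_independent(parts["train"]), parts["test"]))
print("moment Pearson r after tuning: %.4f" % trace.pearson_r[-1])
print(interaction_energy_scores(model, order=2).table.head(3).to_string(index=False))
```

prints

```
selected lambda: 0.02308
recovered pairs: 5 (planted 6)
coherence (order-2, tuned): 0.003952
coherence (independent):    0.003318
moment Pearson r after tuning: 0.9994
factor_a factor_b    score  rank
     F00      F08 1.443661     1
     F01      F07 1.408103     2
     F02      F05 0.782726     3
```

The validation-selected penalty keeps 5 of the 6 planted pairs (the
missed one is the weakest), the tuned pairwise model assigns held-out
patterns ~19% higher geometric-mean probability than the independence
baseline (0.00395 vs 0.00332), and the top-ranked interaction energies
are the strongest planted couplings.  A moment correlation of 0.999
means the fine-tuned model reproduces the data's single and pairwise
occurrence frequencies almost exactly.

The same stages are scriptable from the shell (`chromcode simulate`,
`discretize`, `split`, `fit`, `finetune`, `evaluate`, `score`,
`evaluate-interactions`, `predict`, or `run` with a config file); see
`chromcode --help`.

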