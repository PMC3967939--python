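# Methods

## Model

`chromcode` models the chromatin code — the binary vector
x ∈ {0,1}^n of presence/absence calls for n chromatin factors at one
genomic bin — with a maximum-entropy (log-linear / Ising-type)
distribution

    P(x) = exp(E(x)) / Z,
    E(x) = Σ_i h_i x_i + Σ_{i<j} J_ij x_i x_j + Σ_{i<j<k} K_ijk x_i x_j x_k.

Maximum entropy subject to matching the observed single, pairwise and
triplet occurrence frequencies yields exactly this family; the maximum
likelihood fit in the family coincides with the constrained entropy
maximum because the log-likelihood is concave.  The sign convention is
P ∝ exp(+E): a positive J_ij means the pair co-occurs more often than its
marginals predict, which is what "positive interaction" means throughout
the interaction tables.  Two identities the code leans on:

- E(0) = 0, so Z = 1/P(all-zero).  The Monte-Carlo partition-function
  estimator inverts the observed all-zero fraction of Gibbs samples.
- The conditionals are logistic: P(x_t = 1 | rest) =
  σ(h_t + Σ_j J_tj x_j + Σ_{j<k} K_tjk x_j x_k).  This gives both the
  tractable pseudo-likelihood and closed-form profile imputation.

Bins are treated as exchangeable observations; no spatial coupling along
the genome is modeled.

## Binarization of continuous signal

Continuous per-bin signal (binned at 200 bp by default; bins under 50%
measurement coverage are withheld, and withheld bins are dropped jointly
across factors so every retained row is a complete pattern) is split into
background + signal assuming only that the background density is symmetric
about its mode and the signal lies on one side:

1. Kernel density estimate of the pooled values (Gaussian kernel,
   Silverman bandwidth, 1024-point grid).
2. Mode located by *local symmetry*, not raw argmax: the center m
   minimizing the integrated squared asymmetry of the density over offsets
   within the half-maximum width.  The argmax of a KDE jitters by a few
   hundredths of a bandwidth and a mode offset δ inflates the
   background-reflection excess by ≈ 2δ·f(mode), which at n = 50,000 was
   enough to push the recovered mixture weight from 0.10 to 0.14.
3. Signal side = heavier tail (overridable per factor); background =
   reflection of the signal-free side; signal = positive excess on the
   signal side, renormalized, with weight w = its mass.
4. Decision threshold = the signal-side point where w·f_sig = (1−w)·f_bg,
   located by an outward grid scan with linear interpolation.  If the
   densities never cross, the 0.95 background quantile is used and the fit
   is marked `used_fallback`.

The positive-part excess has a nonzero null level even for pure symmetric
noise (clipping of KDE sampling error).  Measured on simulated pure
backgrounds, its median is ≈ 3·n^(−0.6), so a track is only credited with
signal when w > max(0.005, 9·n^(−0.6)) (three times the null median);
below that it is flagged `low_signal` and, by default, dropped at
binarization.  Factors whose signal is depletion (left side) have their
calls mark depletion and their names annotated with a trailing `-`.
Expression is binarized by the same machinery on log2(RPKM + 1).

## Structure learning

The mean negative log pseudo-likelihood (per-row sum over factors of the
logistic conditional loss) is minimized with:

- **Order 2:** λ·Σ|J_ij| penalty (h never penalized), solved by proximal
  gradient (FISTA with backtracking and restart); soft-thresholding yields
  exact zeros, entries under 1e-8 are dropped, and convergence is declared
  at KKT residual < 1e-5.
- **Order 3:** overlapping group penalty λ·Σ_{i<j} ‖(J_ij, K_ij·)‖₂, the
  group of a pair holding its J and every candidate K containing both
  members.  A triplet belongs to three groups and can only enter when all
  three pay for their groups, which makes the selected support
  hierarchical; any K whose three member pairs did not survive is removed,
  so hierarchy holds by construction.  Solved by consensus ADMM
  (L-BFGS on the smooth augmented subproblem, group soft-threshold on the
  copies, Boyd-style combined stopping criteria with residual-balancing
  ρ adaptation).  All triples are candidates up to n = 40; beyond that a
  candidate list must be supplied (e.g. triangles of a pairwise pre-fit).

λ is chosen on a held-out validation set over a 30-point log grid from
λ_max (smallest λ with empty support, computed from the gradient at the
independence fit) down to λ_max/1000.  The validation score is a sample
mean, so scores within one standard error of the minimum are treated as
statistical ties and the tie goes to the larger λ — the one-standard-error
rule of penalized regression.  Plain argmin (`rule="min"`) is available
but, on planted-model simulations, systematically lands on supports
inflated with near-zero spurious pairs, as is typical of
prediction-optimal lasso selection.

## Fine-tuning

Pseudo-likelihood estimates rank interactions well but the implied
distribution is mis-calibrated, so a structure-frozen maximum-likelihood
refinement follows: the exponential-family likelihood gradient for each
active parameter is (empirical moment − model moment); model moments are
estimated by Gibbs sampling (persistent chain across iterations, burn-in
paid once) and parameters take fixed-size steps (default 0.05, 10,000
samples/iteration, up to 500 iterations).  Progress is monitored by the
Pearson correlation between observed and model moments; the run stops
early at r > 0.999 with max moment error < 0.02, and aborts if the mean
absolute parameter exceeds 50.

## Evaluation

- **log Z:** −log(all-zero fraction) over Gibbs samples (default 10^6, one
  sample per sequential sweep); exact enumeration with log-sum-exp backs
  models with n ≤ 20 and serves as the oracle in tests.
- **Coherence score:** exp(mean log-likelihood) on held-out data,
  equivalently exp(−cross-entropy), in (0, 1]; reported normalized to the
  best model under comparison.
- **Splitting:** the genome is cut into 50 contiguous near-equal slices;
  a seeded random half becomes training, the remainder alternates
  validation/test so held-out bins are not adjacent to training bins.
- **Pattern frequencies:** sub-pattern probabilities on a factor subset by
  Gibbs marginalization, compared with empirical test frequencies.

## Interaction scoring and validation

Pairwise scores are the nonzero J of the L1 order-2 fit; triplet scores
the nonzero K of the group-L1 order-3 fit.  Against a curated standard of
experimentally supported pairs, rankings are evaluated by bootstrap
precision–recall: the positive set is resampled with replacement 2000
times, a PR curve is computed per round over the universe of scored pairs,
and precision is averaged at 101 evenly spaced recall levels
(step-function interpolation).  Two conventions matter and are fixed as
follows: standard pairs *not* drawn in a round are excluded from that
round's universe (the resampled standard replaces the standard), which
makes a perfect ranking score exactly 1.0 at every recall regardless of
seed; and resample multiplicity counts in both the precision numerator
and denominator, which makes a random ranking recover the positive
fraction as its background precision.  That background identity is
asymptotic — at 10 positives among 100 pairs the first-crossing
precision-at-recall estimator is upward-biased by ≈ +0.04, so the
recovery test runs at 500 pairs / 50 positives where the bias is gone.
Baselines (Pearson and partial correlation on continuous signal, plug-in
mutual information on calls) are provided for comparison; partial
correlations come from the inverse covariance with optional ridge.

## Synthetic data

The generators define the study conditions for every test:

- `random_sparse_model`: pairs enter i.i.d. with the given density,
  triplets only among closed triangles (hierarchy by construction);
  magnitudes uniform in the given ranges, signs negative at the given
  rate; defaults h ∈ [−2.5, −0.5], |J| ∈ [0.8, 2.0], 30% negative —
  sparse occupancy with order-one couplings.
- `planted_hierarchical_model`: lays down a requested number of triangles
  first (independent pair planting almost never closes one), then random
  extra pairs — the fixture for triplet recovery.
- `connected_coupled_model`: ring plus chords so every factor has degree
  ≥ 2, with self-energies canceling half of each factor's coupling load;
  unbalanced strong positive couplings otherwise drive columns to
  near-constant, leaving nothing to impute.
- `sample_dataset`: exact categorical sampling (n ≤ 20) or Gibbs;
  `synthetic_signal_tracks`: Gaussian background of unit-order sd plus a
  one-sided shift per call (negated for depletion factors).

Versioned benchmarks (`synthetic.BENCHMARK`, `synthetic.TRIPLET_BENCHMARK`):
pairwise recovery at n = 15 factors, N = 20,000 training / 8,000
validation bins, model seeds 1–5, 16-point λ grid; triplet recovery at
n = 12, N = 30,000, 10 pairs + 2 planted triplets, λ = λ_max/20.  These
sizes keep a full recovery run in minutes on one core while leaving the
planted structure comfortably identifiable; they are the package's fixed
reference configuration, not tunable knobs.

What the generators do *not* emulate: spatial autocorrelation of real
chromatin tracks, mappability artifacts, antibody efficiency differences,
and cross-replicate structure.  Passing recovery tests therefore shows the
estimators work under the model's own assumptions (i.i.d. bins, symmetric
background), not that real ChIP data satisfies those assumptions.

## Numerical choices and degenerate inputs

- Jeffreys pseudocount 0.5 in the independence fit; |h| clamped to 15 with
  a warning for near-constant columns.
- Gibbs: fixed sequential site order, single chain, default burn-in 1000
  sweeps, mandatory seed; the numba kernel is deterministic given the seed.
- Enumeration capped at n = 20 (2^20 patterns); log-sum-exp throughout.
- Zero-identification threshold 1e-8 after optimization.
- Degenerate inputs raise: constant signal tracks, all-zero expression,
  single-class AUC labels, unreachable all-zero pattern in the Z
  estimator, ascending λ grids, non-hierarchical K on construction.

## Known limitations

- The ADMM group solver is first-order; at very small λ (dense supports)
  it needs many iterations and the order-3 path is therefore not fitted
  by default over a full 30-point grid.
- Pseudo-likelihood parameter values are biased at small N even when the
  support is right; downstream probability statements should use the
  fine-tuned model.
- Cross-cell-type prediction requires models trained on the shared factor
  set; no marginalization over non-shared factors is attempted.
- Multi-factor joint imputation is exposed only through single-target
  conditionals; imputing several missing factors at once would require
  conditional sampling.
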