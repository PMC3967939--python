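"""Held-out model evaluation.

The partition function Z is estimated from the identity P(all-zero) = 1/Z
(the all-zero pattern has energy 0): draw Gibbs samples and invert the
observed all-zero fraction.  Model quality on held-out data is summarized by
the coherence score, the exponential of the mean per-pattern log-likelihood
-- equivalently exp(-cross-entropy), in (0, 1], often reported normalized to
the best model under comparison.  Genome splitting assigns contiguous slices
(not individual bins) to train/validation/test so that the held-out sets are
not trivially correlated with training bins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import Bin, ChromatinCodeMatrix
from .model_core import (
    MaxEntModel,
    enumerate_patterns,
    gibbs_sample_raw,
    log_probabilities,
    pattern_energies,
)


def estimate_log_partition_mc(
    model: MaxEntModel,
    n_samples: int = 1_000_000,
    burn_in: int = 1000,
    seed: int = 0,
) -> float:
    """log Z = -log(fraction of all-zero patterns in Gibbs samples).

    One sample is retained per sequential Gibbs sweep.  Raises when no
    all-zero pattern is observed; warns when the estimate rests on fewer
    than 10 hits.
    """
    samples = gibbs_sample_raw(model, n_samples, burn_in=burn_in, seed=seed)
    zero_count = int((samples.sum(axis=1) == 0).sum())
    if zero_count == 0:
        raise RuntimeError(
            "no all-zero pattern among samples; the estimator 1/P(0) is "
            "undefined -- use exact enumeration or draw more samples"
        )
    if zero_count < 10:
        warnings.warn(
            f"only {zero_count} all-zero samples out of {n_samples}; "
            "log Z estimate is unstable", stacklevel=2
        )
    return float(-np.log(zero_count / n_samples))


def coherence_score(
    model: MaxEntModel, test: ChromatinCodeMatrix
) -> float:
    """exp(mean log-likelihood) of the test patterns under the model."""
    if model.logZ is None:
        raise ValueError("model.logZ not set; estimate or compute it first")
    if model.factors != test.factors:
        raise ValueError("model and data factor lists differ")
    lp = log_probabilities(test.calls, model)
    return float(np.exp(lp.mean()))


def normalize_scores(scores: dict[str, float]) -> dict[str, float]:
    """Coherence scores divided by the best score (best model -> 1.0)."""
    best = max(scores.values())
    return {k: v / best for k, v in scores.items()}


def predict_pattern_frequencies(
    model: MaxEntModel,
    factor_subset: list[str],
    observed: ChromatinCodeMatrix,
    n_samples: int = 100_000,
    seed: int = 0,
    burn_in: int = 1000,
    min_observed: int = 0,
) -> pd.DataFrame:
    """Predicted vs observed frequencies of sub-patterns on a factor subset.

    Predicted frequency = fraction of Gibbs samples matching the pattern on
    the subset coordinates (marginalization by sampling); observed = the
    empirical fraction in the test rows.  Rows cover every pattern seen in
    either source (zero-zero rows for requested patterns are retained).
    """
    missing = [f for f in factor_subset if f not in model.factors]
    if missing:
        raise ValueError(f"subset factors not in model: {missing}")
    cols_m = [model.factors.index(f) for f in factor_subset]
    cols_d = [observed.factors.index(f) for f in factor_subset]
    samples = gibbs_sample_raw(model, n_samples, burn_in=burn_in, seed=seed)
    sub_s = samples[:, cols_m]
    sub_o = observed.calls[:, cols_d]

    def counts(arr: np.ndarray) -> dict[tuple, int]:
        pats, cnt = np.unique(arr, axis=0, return_counts=True)
        return {tuple(int(v) for v in p): int(c) for p, c in zip(pats, cnt)}

    cs, co = counts(sub_s), counts(sub_o)
    all_pats = sorted(set(cs) | set(co), reverse=True)
    rows = []
    for p in all_pats:
        obs_n = co.get(p, 0)
        if obs_n < min_observed and p not in cs:
            continue
        rows.append({
            "pattern": "".join(map(str, p)),
            "predicted": cs.get(p, 0) / n_samples,
            "observed": obs_n / observed.n_bins,
        })
    return pd.DataFrame(rows, columns=["pattern", "predicted", "observed"])


def split_genome(
    bins: list[Bin], n_slices: int = 50, seed: int = 0
) -> np.ndarray:
    """Label bins train/val/test by contiguous genome slices.

    The genome (bins in (chrom, start) order) is cut into ``n_slices``
    near-equal contiguous slices (sizes differ by at most one bin).  Half the
    slices, chosen at random with the given seed, become training; the rest
    alternate validation / test so both are spread along the genome.
    Returns an array of labels aligned to ``bins``.
    """
    n = len(bins)
    if n < n_slices:
        raise ValueError(f"{n} bins cannot form {n_slices} slices")
    if sorted(bins, key=lambda b: (b[0], b[1])) != list(bins):
        raise ValueError("bins must be sorted by (chrom, start)")
    edges = np.linspace(0, n, n_slices + 1).round().astype(int)
    slice_of = np.zeros(n, dtype=int)
    for s in range(n_slices):
        slice_of[edges[s]: edges[s + 1]] = s
    rng = np.random.default_rng(seed)
    n_train = n_slices // 2
    train_slices = set(rng.choice(n_slices, size=n_train, replace=False).tolist())
    rest = [s for s in range(n_slices) if s not in train_slices]
    labels_by_slice = {}
    for s in train_slices:
        labels_by_slice[s] = "train"
    for r, s in enumerate(rest):
        labels_by_slice[s] = "val" if r % 2 == 0 else "test"
    return np.array([labels_by_slice[s] for s in slice_of])


def split_matrix(
    data: ChromatinCodeMatrix, n_slices: int = 50, seed: int = 0
) -> dict[str, ChromatinCodeMatrix]:
    """Convenience wrapper: apply split_genome and partition the matrix."""
    labels = split_genome(data.bins, n_slices=n_slices, seed=seed)
    out = {}
    for name in ("train", "val", "test"):
        mask = labels == name
        out[name] = ChromatinCodeMatrix(
            bins=[b for b, m in zip(data.bins, mask) if m],
            factors=list(data.factors),
            calls=data.calls[mask],
        )
    return out
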