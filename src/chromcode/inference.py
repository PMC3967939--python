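"""Context-based imputation of chromatin profiles.

Because the conditionals of the maximum-entropy model are logistic, a
factor's probability given the others is available in closed form:

    P(x_t = 1 | x_rest) = sigmoid( h_t + sum_j J_tj x_j + sum_{j<k} K_tjk x_j x_k )

with the sums running over the observed active coordinates.  This supports
the leave-one-out protocol (impute each factor per bin from the remaining
profiles), evaluated by the area under the ROC curve, and cross-model
prediction where a model trained in one cell type imputes profiles in
another over a shared factor set.
"""

from __future__ import annotations

import numpy as np

from .io_formats import ChromatinCodeMatrix
from .model_core import MaxEntModel


def _sigmoid(a):
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def conditional_probability(
    model: MaxEntModel, context: np.ndarray, target: str
) -> float:
    """P(target = 1 | all other factors) for one fully observed context.

    ``context`` is a length-n binary vector aligned to ``model.factors``;
    its entry at the target coordinate is ignored.
    """
    if target not in model.factors:
        raise ValueError(f"target {target!r} not in model")
    context = np.asarray(context)
    if context.shape != (model.n,):
        raise ValueError(f"context length {context.shape} != {model.n}")
    idx = model.index()
    t = idx[target]
    field = model.h.get(target, 0.0)
    for (a, b), v in model.J.items():
        if a == target and context[idx[b]]:
            field += v
        elif b == target and context[idx[a]]:
            field += v
    for (a, b, c), v in model.K.items():
        trio = (a, b, c)
        if target in trio:
            others = [f for f in trio if f != target]
            if context[idx[others[0]]] and context[idx[others[1]]]:
                field += v
    return float(1.0 / (1.0 + np.exp(-field)))


def impute_profile(
    model: MaxEntModel, data: ChromatinCodeMatrix, target: str
) -> np.ndarray:
    """Per-bin P(target = 1 | observed factors), vectorized over bins.

    ``data`` must carry exactly the model's factors minus the target
    (row order is preserved in the output).
    """
    if target not in model.factors:
        raise ValueError(f"target {target!r} not in model")
    expected = [f for f in model.factors if f != target]
    if sorted(data.factors) != sorted(expected):
        raise ValueError(
            "data factors must equal model factors minus the target; "
            f"got {data.factors}"
        )
    h_vec, Jd, tidx, tval = model.to_dense()
    t = model.factors.index(target)
    # map data columns onto model coordinates, zero at the target slot
    X = np.zeros((data.n_bins, model.n))
    for j, f in enumerate(data.factors):
        X[:, model.factors.index(f)] = data.calls[:, j]
    field = h_vec[t] + X @ Jd[t]
    for (i, j, k), v in zip(tidx, tval):
        trio = (i, j, k)
        if t in trio:
            a, b = [c for c in trio if c != t]
            field = field + v * X[:, a] * X[:, b]
    return _sigmoid(np.asarray(field, dtype=float))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation with 1/2 tie credit.

    Equals the probability that the score of a random positive exceeds that
    of a random negative, with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    sorted_scores = scores[order]
    # midranks for ties
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def impute_all_factors(
    model: MaxEntModel, test: ChromatinCodeMatrix
) -> dict[str, float]:
    """Leave-one-out imputation AUC for every factor on test data."""
    if model.factors != test.factors:
        raise ValueError("model and data factor lists differ")
    out = {}
    for f in model.factors:
        probs = impute_profile(model, test.drop_factor(f), f)
        labels = test.column(f)
        if labels.min() == labels.max():
            continue  # single-class factor: AUC undefined
        out[f] = auc(probs, labels)
    return out


def cross_model_predict(
    model_other: MaxEntModel,
    data: ChromatinCodeMatrix,
    shared_factors: list[str],
    target: str,
) -> np.ndarray:
    """Impute a profile with a model trained in another cell type.

    The foreign model must have been trained on exactly the shared factor
    set (no marginalization over non-shared factors is attempted), and the
    target must be one of the shared factors.
    """
    if sorted(model_other.factors) != sorted(shared_factors):
        raise ValueError(
            "model factor set differs from the declared shared set; "
            "retrain the model on the shared factors"
        )
    if target not in shared_factors:
        raise ValueError(f"target {target!r} not in the shared set")
    return impute_profile(model_other, data, target)
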