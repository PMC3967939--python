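"""The exponential-family chromatin-code model.

A chromatin code x in {0,1}^n is assigned energy

    E(x) = sum_i h_i x_i + sum_{i<j} J_ij x_i x_j + sum_{i<j<k} K_ijk x_i x_j x_k

and probability P(x) = exp(E(x)) / Z.  With this sign convention a positive
J_ij means the pair co-occurs more often than its marginals predict (a
"positive interaction"); the all-zero pattern has energy 0, so Z is exactly
1 / P(all-zero) -- the identity exploited by the Monte-Carlo partition
function estimator in :mod:`chromcode.evaluation`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ChromatinCodeMatrix
from ._gibbs import gibbs_sweeps

ENUM_CAP = 20  # full enumeration of 2^n patterns allowed up to this n
H_CLAMP = 15.0  # |h| bound for degenerate marginals in the independent fit

Pair = tuple[str, str]
Triple = tuple[str, str, str]


def _pair(a: str, b: str) -> Pair:
    if a == b:
        raise ValueError(f"pair with repeated factor {a!r}")
    return (a, b) if a < b else (b, a)


def _triple(a: str, b: str, c: str) -> Triple:
    t = tuple(sorted((a, b, c)))
    if len(set(t)) != 3:
        raise ValueError(f"triple with repeated factor: {(a, b, c)}")
    return t  # type: ignore[return-value]


@dataclass
class MaxEntModel:
    """Sparse parameter set of the maximum-entropy chromatin-code model.

    ``h`` maps factor name to self-energy, ``J`` unordered name pairs to
    pairwise interaction energy, ``K`` unordered name triples to triplet
    interaction energy.  Zero-valued entries are dropped on construction so
    stored support equals nonzero support.  When ``hierarchy_flag`` is set,
    every K triple has all three member pairs present in J.
    """

    factors: list[str]
    h: dict[str, float] = field(default_factory=dict)
    J: dict[Pair, float] = field(default_factory=dict)
    K: dict[Triple, float] = field(default_factory=dict)
    logZ: float | None = None
    hierarchy_flag: bool = False

    def __post_init__(self) -> None:
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("factor names must be unique")
        universe = set(self.factors)
        for name in self.h:
            if name not in universe:
                raise ValueError(f"h references unknown factor {name!r}")
        self.h = {k: float(v) for k, v in self.h.items() if v != 0.0}
        J = {}
        for key, v in self.J.items():
            key = _pair(*key)
            if not set(key) <= universe:
                raise ValueError(f"J references unknown factor in {key}")
            if v != 0.0:
                J[key] = float(v)
        self.J = J
        K = {}
        for key, v in self.K.items():
            key = _triple(*key)
            if not set(key) <= universe:
                raise ValueError(f"K references unknown factor in {key}")
            if v != 0.0:
                K[key] = float(v)
        self.K = K
        if self.hierarchy_flag:
            self.check_hierarchy()

    # -- structure ----------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.factors)

    def check_hierarchy(self) -> None:
        for (a, b, c) in self.K:
            for p in (_pair(a, b), _pair(a, c), _pair(b, c)):
                if p not in self.J:
                    raise ValueError(
                        f"triplet {(a, b, c)} violates hierarchy: pair {p} absent"
                    )

    def index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.factors)}

    def to_dense(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (h, J, triplet_index, triplet_value) as arrays.

        J is a symmetric (n, n) matrix with zero diagonal; triplet_index is
        (m, 3) int with sorted indices, triplet_value (m,).
        """
        idx = self.index()
        h = np.zeros(self.n)
        for f, v in self.h.items():
            h[idx[f]] = v
        J = np.zeros((self.n, self.n))
        for (a, b), v in self.J.items():
            i, j = idx[a], idx[b]
            J[i, j] = J[j, i] = v
        tidx = np.zeros((len(self.K), 3), dtype=np.int64)
        tval = np.zeros(len(self.K))
        for r, ((a, b, c), v) in enumerate(sorted(self.K.items())):
            tidx[r] = sorted((idx[a], idx[b], idx[c]))
            tval[r] = v
        return h, J, tidx, tval

    @classmethod
    def from_dense(
        cls,
        factors: Sequence[str],
        h: np.ndarray,
        J: np.ndarray | None = None,
        triplet_index: np.ndarray | None = None,
        triplet_value: np.ndarray | None = None,
        logZ: float | None = None,
        hierarchy_flag: bool = False,
        tol: float = 0.0,
    ) -> "MaxEntModel":
        factors = list(factors)
        n = len(factors)
        hd = {factors[i]: float(h[i]) for i in range(n) if abs(h[i]) > tol}
        Jd: dict[Pair, float] = {}
        if J is not None:
            for i in range(n):
                for j in range(i + 1, n):
                    if abs(J[i, j]) > tol:
                        Jd[_pair(factors[i], factors[j])] = float(J[i, j])
        Kd: dict[Triple, float] = {}
        if triplet_index is not None and len(triplet_index):
            for (i, j, k), v in zip(triplet_index, triplet_value):
                if abs(v) > tol:
                    Kd[_triple(factors[i], factors[j], factors[k])] = float(v)
        return cls(factors, hd, Jd, Kd, logZ=logZ, hierarchy_flag=hierarchy_flag)


# ---------------------------------------------------------------------------
# energies and probabilities
# ---------------------------------------------------------------------------

def energy(x: np.ndarray | Sequence[int], model: MaxEntModel) -> float:
    """E(x): sum of active self-energies plus active interaction energies."""
    x = np.asarray(x)
    if x.shape != (model.n,):
        raise ValueError(f"pattern length {x.shape} != {model.n} factors")
    idx = model.index()
    e = sum(v for f, v in model.h.items() if x[idx[f]])
    e += sum(v for (a, b), v in model.J.items() if x[idx[a]] and x[idx[b]])
    e += sum(
        v for (a, b, c), v in model.K.items()
        if x[idx[a]] and x[idx[b]] and x[idx[c]]
    )
    return float(e)


def enumerate_patterns(n: int) -> np.ndarray:
    """All 2^n binary patterns as an (2^n, n) int8 array (n <= 20)."""
    if n > ENUM_CAP:
        raise ValueError(f"enumeration capped at n = {ENUM_CAP}, got {n}")
    codes = np.arange(2 ** n, dtype=np.int64)
    return ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)


def pattern_energies(patterns: np.ndarray, model: MaxEntModel) -> np.ndarray:
    """Vectorized E(x) for an (N, n) pattern array."""
    h, J, tidx, tval = model.to_dense()
    X = patterns.astype(float)
    e = X @ h + 0.5 * np.einsum("ni,ij,nj->n", X, J, X)
    for (i, j, k), v in zip(tidx, tval):
        e += v * X[:, i] * X[:, j] * X[:, k]
    return e


def exact_log_partition(model: MaxEntModel) -> float:
    """log Z by full enumeration (n <= 20), log-sum-exp stabilized."""
    pats = enumerate_patterns(model.n)
    e = pattern_energies(pats, model)
    m = e.max()
    return float(m + np.log(np.exp(e - m).sum()))


def log_probability(x: np.ndarray | Sequence[int], model: MaxEntModel) -> float:
    if model.logZ is None:
        raise ValueError("model.logZ not set; compute or estimate it first")
    return energy(x, model) - model.logZ


def log_probabilities(patterns: np.ndarray, model: MaxEntModel) -> np.ndarray:
    if model.logZ is None:
        raise ValueError("model.logZ not set; compute or estimate it first")
    return pattern_energies(patterns, model) - model.logZ


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _triplet_csr(n: int, tidx: np.ndarray, tval: np.ndarray):
    """Per-site adjacency of triplets: for site i, the (j, k) partners."""
    rows: list[list[tuple[int, int, float]]] = [[] for _ in range(n)]
    for (i, j, k), v in zip(tidx, tval):
        rows[i].append((j, k, v))
        rows[j].append((i, k, v))
        rows[k].append((i, j, v))
    ptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        ptr[i + 1] = ptr[i] + len(rows[i])
    jk = np.zeros((ptr[-1], 2), dtype=np.int64)
    val = np.zeros(ptr[-1])
    pos = 0
    for i in range(n):
        for j, k, v in rows[i]:
            jk[pos] = (j, k)
            val[pos] = v
            pos += 1
    return ptr, jk, val


def gibbs_sample_raw(
    model: MaxEntModel,
    n_samples: int,
    burn_in: int = 1000,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Sequential-scan Gibbs sampler; one retained sample per full sweep.

    Returns an (n_samples, n) int8 array.  Deterministic given ``seed``
    and ``x0`` (default all-zero start).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    h, J, tidx, tval = model.to_dense()
    ptr, jk, val = _triplet_csr(model.n, tidx, tval)
    if x0 is None:
        x0 = np.zeros(model.n, dtype=np.int8)
    return gibbs_sweeps(
        h, J, ptr, jk, val, int(n_samples), int(burn_in),
        int(seed) % (2 ** 32), x0.astype(np.int8),
    )


def gibbs_sample(
    model: MaxEntModel,
    n_samples: int,
    burn_in: int = 1000,
    seed: int = 0,
) -> ChromatinCodeMatrix:
    """Gibbs samples wrapped as a ChromatinCodeMatrix on a dummy chromosome."""
    samples = gibbs_sample_raw(model, n_samples, burn_in, seed)
    bins = [("chrSim", 200 * i, 200 * (i + 1)) for i in range(n_samples)]
    return ChromatinCodeMatrix(bins=bins, factors=list(model.factors), calls=samples)


# ---------------------------------------------------------------------------
# baseline and bookkeeping
# ---------------------------------------------------------------------------

def fit_independent(
    data: ChromatinCodeMatrix, pseudocount: float = 0.5
) -> MaxEntModel:
    """Independent-Bernoulli baseline: h_i = logit of the smoothed marginal.

    J and K are empty and log Z has the closed form sum_i log(1 + exp(h_i)).
    A Jeffreys-style pseudocount guards against degenerate marginals;
    constant columns are clamped to |h| <= 15 with a warning.
    """
    if data.n_bins < 1:
        raise ValueError("need at least one row of data")
    N = data.n_bins
    counts = data.calls.sum(axis=0).astype(float)
    p = (counts + pseudocount) / (N + 2 * pseudocount)
    h = np.log(p) - np.log1p(-p)
    if (np.abs(h) > H_CLAMP).any():
        bad = [data.factors[i] for i in np.nonzero(np.abs(h) > H_CLAMP)[0]]
        warnings.warn(f"near-constant columns clamped to |h| <= {H_CLAMP}: {bad}")
        h = np.clip(h, -H_CLAMP, H_CLAMP)
    logZ = float(np.log1p(np.exp(-np.abs(h))).sum() + np.maximum(h, 0).sum())
    return MaxEntModel.from_dense(data.factors, h, logZ=logZ)


def count_parameters(
    model: MaxEntModel, dense: bool = False
) -> tuple[int, int, int]:
    """(n_self, n_pair, n_triplet): dense parameterization or stored nonzeros."""
    n = model.n
    if dense:
        n_pair = n * (n - 1) // 2
        n_trip = n * (n - 1) * (n - 2) // 6 if model.K else 0
        return n, n_pair, n_trip
    return len(model.h), len(model.J), len(model.K)


# ---------------------------------------------------------------------------
# model JSON (sorted keys -> byte-stable output)
# ---------------------------------------------------------------------------

_SEP = "\t"


def serialize_model(model: MaxEntModel, path: str | Path) -> None:
    doc = {
        "factors": list(model.factors),
        "h": {k: v for k, v in sorted(model.h.items())},
        "J": {_SEP.join(k): v for k, v in sorted(model.J.items())},
        "K": {_SEP.join(k): v for k, v in sorted(model.K.items())},
        "hierarchy_flag": model.hierarchy_flag,
    }
    if model.logZ is not None:
        doc["logZ"] = model.logZ
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def deserialize_model(path: str | Path) -> MaxEntModel:
    with open(path) as fh:
        doc = json.load(fh)
    factors = doc["factors"]
    J = {tuple(k.split(_SEP)): v for k, v in doc.get("J", {}).items()}
    K = {tuple(k.split(_SEP)): v for k, v in doc.get("K", {}).items()}
    return MaxEntModel(
        factors=factors,
        h=dict(doc.get("h", {})),
        J=J,  # type: ignore[arg-type]
        K=K,  # type: ignore[arg-type]
        logZ=doc.get("logZ"),
        hierarchy_flag=doc.get("hierarchy_flag", False),
    )
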