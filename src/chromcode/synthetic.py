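"""Synthetic chromatin data with planted ground truth.

Generates (i) sparse maximum-entropy models with hierarchical triplet
support, (ii) binary chromatin-code datasets drawn from them exactly (small
n) or by Gibbs sampling, and (iii) continuous signal tracks around the calls
-- symmetric background noise plus a one-sided shift, negated for depletion
factors -- so the thresholding stage can be tested against known labels.
Bins are i.i.d. draws on a dummy chromosome at 200 bp pitch; spatial
autocorrelation of real genomic tracks is deliberately not simulated, since
the model itself treats bins as exchangeable observations.

The fixed recovery benchmark used by the acceptance machinery is
``BENCHMARK`` (n = 15 factors, N = 20,000 bins, seeds 1-5).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np

from .io_formats import ChromatinCodeMatrix, SignalMatrix
from .model_core import (
    MaxEntModel,
    enumerate_patterns,
    gibbs_sample_raw,
    pattern_energies,
)

BENCHMARK = {
    "n_factors": 15,
    "n_bins": 20_000,
    "n_val": 8_000,
    "seeds": (1, 2, 3, 4, 5),
    "pair_density": 0.12,
    "h_range": (-2.5, -0.5),
    "j_magnitude": (0.8, 2.0),
    "neg_fraction": 0.3,
    "grid_points": 16,
}

TRIPLET_BENCHMARK = {
    "n_factors": 12,
    "n_bins": 30_000,
    "n_pairs": 10,
    "n_triplets": 2,
    "seed": 4,
    "lambda_divisor": 20,
}


def _factor_names(n: int) -> list[str]:
    return [f"F{i:02d}" for i in range(n)]


def random_sparse_model(
    n_factors: int,
    pair_density: float = 0.1,
    triplet_density: float = 0.0,
    h_range: tuple[float, float] = (-2.5, -0.5),
    j_magnitude: tuple[float, float] = (0.8, 2.0),
    k_magnitude: tuple[float, float] = (0.5, 1.5),
    neg_fraction: float = 0.3,
    seed: int = 0,
) -> MaxEntModel:
    """Planted sparse model with hierarchical triplet support.

    Pairs enter independently with probability ``pair_density``; triplets are
    drawn (with probability ``triplet_density``) only among triples whose
    three pairs were all selected, so hierarchy holds by construction.
    Interaction magnitudes are uniform in the given ranges with sign negative
    at probability ``neg_fraction``; self-energies are uniform in ``h_range``
    (negative defaults keep patterns sparse, as chromatin calls are).
    """
    if not (0 <= pair_density <= 1 and 0 <= triplet_density <= 1):
        raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = _factor_names(n_factors)
    h = {f: float(rng.uniform(*h_range)) for f in names}

    J: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        if rng.random() < pair_density:
            mag = rng.uniform(*j_magnitude)
            sign = -1.0 if rng.random() < neg_fraction else 1.0
            J[(a, b)] = float(sign * mag)

    K: dict[tuple[str, str, str], float] = {}
    if triplet_density > 0:
        support = set(J)
        eligible = [
            t for t in combinations(names, 3)
            if all(p in support for p in combinations(t, 2))
        ]
        if not eligible:
            warnings.warn(
                "no triple has full pairwise support; planted model has no "
                "triplets", stacklevel=2
            )
        for t in eligible:
            if rng.random() < triplet_density:
                mag = rng.uniform(*k_magnitude)
                sign = -1.0 if rng.random() < neg_fraction else 1.0
                K[t] = float(sign * mag)
    return MaxEntModel(factors=names, h=h, J=J, K=K, hierarchy_flag=bool(K))


def connected_coupled_model(
    n_factors: int = 12,
    j_magnitude: tuple[float, float] = (1.5, 2.5),
    neg_fraction: float = 0.25,
    seed: int = 0,
) -> MaxEntModel:
    """Planted model in which every factor is strongly coupled.

    Pairs form a ring plus diameter chords, so each factor has degree >= 2
    and no column is informationally isolated.  Self-energies are set to
    roughly cancel half the interaction load of each factor
    (h_i ~ -0.5 * sum_j J_ij plus a negative offset): without this balance,
    strong positive couplings drive the system into near-constant columns
    whose profiles carry no signal to impute.
    """
    rng = np.random.default_rng(seed)
    names = _factor_names(n_factors)
    J: dict[tuple[str, str], float] = {}

    def draw():
        sign = -1.0 if rng.random() < neg_fraction else 1.0
        return float(sign * rng.uniform(*j_magnitude))

    for i in range(n_factors):
        pair = tuple(sorted((names[i], names[(i + 1) % n_factors])))
        J[pair] = draw()
    for i in range(n_factors // 2):
        pair = tuple(sorted((names[i], names[i + n_factors // 2])))
        if pair not in J:
            J[pair] = draw()
    load = {f: 0.0 for f in names}
    for (a, b), v in J.items():
        load[a] += v
        load[b] += v
    h = {f: float(rng.uniform(-1.0, -0.3) - 0.5 * load[f]) for f in names}
    return MaxEntModel(factors=names, h=h, J=J)


def planted_hierarchical_model(
    n_factors: int = 12,
    n_pairs: int = 10,
    n_triplets: int = 2,
    h_range: tuple[float, float] = (-2.0, -0.5),
    j_magnitude: tuple[float, float] = (0.8, 2.0),
    k_magnitude: tuple[float, float] = (0.8, 1.5),
    neg_fraction: float = 0.2,
    seed: int = 0,
) -> MaxEntModel:
    """Planted model with a guaranteed number of hierarchical triplets.

    Unlike :func:`random_sparse_model`, which plants pairs independently and
    may leave no closed triangle to hang a triplet on, this generator first
    lays down ``n_triplets`` triangles (three positive pairs each, so the
    triplet term acts on a pattern that actually occurs), then adds random
    extra pairs up to ``n_pairs``.
    """
    rng = np.random.default_rng(seed)
    names = _factor_names(n_factors)
    if 3 * n_triplets > n_factors:
        raise ValueError("need at least 3 factors per planted triplet")
    h = {f: float(rng.uniform(*h_range)) for f in names}
    perm = rng.permutation(n_factors)
    J: dict[tuple[str, str], float] = {}
    K: dict[tuple[str, str, str], float] = {}
    for t in range(n_triplets):
        trio = sorted(names[i] for i in perm[3 * t: 3 * t + 3])
        for p in combinations(trio, 2):
            J[p] = float(rng.uniform(*j_magnitude))
        sign = -1.0 if rng.random() < neg_fraction else 1.0
        K[tuple(trio)] = float(sign * rng.uniform(*k_magnitude))
    extra = [p for p in combinations(names, 2) if p not in J]
    rng.shuffle(extra)
    for p in extra[: max(0, n_pairs - len(J))]:
        mag = rng.uniform(*j_magnitude)
        sign = -1.0 if rng.random() < neg_fraction else 1.0
        J[p] = float(sign * mag)
    return MaxEntModel(factors=names, h=h, J=J, K=K, hierarchy_flag=True)


def sample_dataset(
    model: MaxEntModel,
    n_bins: int,
    seed: int = 0,
    method: str = "gibbs",
    burn_in: int = 1000,
) -> ChromatinCodeMatrix:
    """Draw a bins x factors dataset from a model.

    ``exact`` enumerates all 2^n patterns (n <= 20) and samples the
    categorical distribution directly; ``gibbs`` uses the sequential-sweep
    sampler.  Bin coordinates are synthetic: chrSim at 200 bp pitch.
    """
    if method == "exact":
        pats = enumerate_patterns(model.n)
        e = pattern_energies(pats, model)
        p = np.exp(e - e.max())
        p /= p.sum()
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(p), size=n_bins, p=p)
        calls = pats[idx]
    elif method == "gibbs":
        calls = gibbs_sample_raw(model, n_bins, burn_in=burn_in, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    bins = [("chrSim", 200 * i, 200 * (i + 1)) for i in range(n_bins)]
    return ChromatinCodeMatrix(bins=bins, factors=list(model.factors), calls=calls)


def synthetic_signal_tracks(
    code: ChromatinCodeMatrix,
    background_sd: float = 1.0,
    signal_shift: float = 4.0,
    depletion_factors: list[str] | None = None,
    seed: int = 0,
) -> SignalMatrix:
    """Continuous tracks around binary calls for testing binarization.

    value = symmetric Gaussian background (mean 0, sd ``background_sd``)
    plus ``signal_shift`` times the call, with the shift negated for
    depletion factors.  Full coverage.  ``signal_shift`` may be 0 to emulate
    a no-signal track.
    """
    if signal_shift < 0:
        raise ValueError("signal_shift must be nonnegative (use depletion_factors)")
    depletion = set(depletion_factors or [])
    unknown = depletion - set(code.factors)
    if unknown:
        raise ValueError(f"depletion factors not in matrix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, background_sd, size=code.calls.shape)
    shift = np.full(code.n_factors, signal_shift)
    for f in depletion:
        shift[code.factors.index(f)] = -signal_shift
    values = noise + code.calls * shift[None, :]
    return SignalMatrix(
        bins=list(code.bins),
        factors=list(code.factors),
        values=values,
    )
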