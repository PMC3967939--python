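"""Sparse structure learning by penalized pseudo-likelihood.

The likelihood of the maximum-entropy model is intractable at genome scale,
so learning replaces it with the pseudo-likelihood: the product over factors
of the conditional probability of each factor given the rest.  Each
conditional is logistic in the local field

    a_i(x) = h_i + sum_j J_ij x_j + sum_{j<k} K_ijk x_j x_k,

so the negative log pseudo-likelihood is convex and its gradient is exact.
Pairwise structure is selected with an L1 penalty on J; third-order structure
with an overlapping group-L1 penalty where the group of a pair (i, j)
contains J_ij and every K_ijk -- a triplet can then only enter when all three
of its member pairs pay for their groups, which yields a hierarchical support.
Self-energies h are never penalized.  The regularization strength is chosen
to minimize the validation-set pseudo-likelihood.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .io_formats import ChromatinCodeMatrix
from .model_core import MaxEntModel, fit_independent

ZERO_TOL = 1e-8  # entries below this magnitude are identified as exact zeros
GRAD_TOL = 1e-5


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the requested tolerance; carries diagnostics."""

    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class RegularizationPath:
    """Per-lambda fits and validation scores along a descending grid."""

    lambdas: np.ndarray
    models: list[MaxEntModel]
    val_scores: np.ndarray


# ---------------------------------------------------------------------------
# pseudo-likelihood core (dense arrays)
# ---------------------------------------------------------------------------

def _softplus(a: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, a)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


class _PLCore:
    """Precomputed design for repeated pseudo-likelihood evaluations.

    Caches X and, when triplets are in play, the matrix of all pairwise
    column products XX (N x n_pairs), so both the triplet contribution to
    the local fields and the K-gradient reduce to one matmul plus gathers.
    """

    def __init__(self, X: np.ndarray, tidx: np.ndarray):
        self.X = X
        self.N, self.n = X.shape
        self.tidx = tidx
        self.pairs = _triu_pairs(self.n)
        self._pair_pos = {p: r for r, p in enumerate(self.pairs)}
        if len(tidx):
            self.XX = np.empty((self.N, len(self.pairs)))
            for r, (i, j) in enumerate(self.pairs):
                self.XX[:, r] = X[:, i] * X[:, j]
            # per-triple entries: (site, opposite-pair) x 3
            site = np.empty((len(tidx), 3), dtype=np.int64)
            opp = np.empty((len(tidx), 3), dtype=np.int64)
            for r, (i, j, k) in enumerate(tidx):
                site[r] = (i, j, k)
                opp[r] = (
                    self._pair_pos[(j, k)],
                    self._pair_pos[(i, k)],
                    self._pair_pos[(i, j)],
                )
            self._site, self._opp = site, opp
        else:
            self.XX = None

    def fields(self, h: np.ndarray, Jd: np.ndarray, tval: np.ndarray) -> np.ndarray:
        A = h[None, :] + self.X @ Jd
        if self.XX is not None and len(tval):
            W = np.zeros((len(self.pairs), self.n))
            np.add.at(W, (self._opp.ravel(), self._site.ravel()),
                      np.repeat(tval, 3))
            A += self.XX @ W
        return A

    def value_grad(self, h, Jd, tval):
        A = self.fields(h, Jd, tval)
        value = float((_softplus(A) - self.X * A).sum() / self.N)
        R = _sigmoid(A) - self.X
        gh = R.mean(axis=0)
        GJ = (R.T @ self.X + self.X.T @ R) / self.N
        np.fill_diagonal(GJ, 0.0)
        if self.XX is not None and len(tval):
            G2 = self.XX.T @ R / self.N  # (n_pairs, n)
            gK = G2[self._opp.ravel(), self._site.ravel()].reshape(-1, 3).sum(axis=1)
        else:
            gK = np.zeros(len(tval))
        return value, gh, GJ, gK


def _pl_value_grad(
    X: np.ndarray, h: np.ndarray, Jd: np.ndarray,
    tidx: np.ndarray, tval: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Mean negative log pseudo-likelihood and its exact gradient.

    Returns (value, grad_h, grad_J_dense_symmetric, grad_K).
    """
    return _PLCore(X, tidx).value_grad(h, Jd, tval)


def _local_fields(
    X: np.ndarray, h: np.ndarray, Jd: np.ndarray,
    tidx: np.ndarray, tval: np.ndarray,
) -> np.ndarray:
    return _PLCore(X, tidx).fields(h, Jd, tval)


def _triu_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def all_triples(n: int) -> np.ndarray:
    t = list(itertools.combinations(range(n), 3))
    return np.array(t, dtype=np.int64).reshape(len(t), 3)


def neg_log_pseudolikelihood(
    model: MaxEntModel,
    data: ChromatinCodeMatrix,
    triplets: list[tuple[str, str, str]] | str | None = None,
) -> tuple[float, dict]:
    """Mean negative log pseudo-likelihood and a sparse gradient map.

    The gradient covers the dense h and J parameterization plus the model's
    stored triplets; pass extra ``triplets`` (name triples, or "dense" for
    every triple) to extend the K block.
    """
    if model.factors != data.factors:
        raise ValueError("model and data factor lists differ")
    X = data.calls.astype(float)
    h, Jd, tidx, tval = model.to_dense()
    idx = model.index()
    extra: list[tuple[int, int, int]] = []
    stored = {tuple(t) for t in tidx.tolist()}
    if triplets == "dense":
        extra = [t for t in map(tuple, all_triples(model.n).tolist())
                 if t not in stored]
    elif triplets:
        for names in triplets:
            t = tuple(sorted(idx[f] for f in names))
            if t not in stored:
                extra.append(t)  # type: ignore[arg-type]
    if extra:
        tidx = np.vstack([tidx, np.array(extra, dtype=np.int64)]) if len(tidx) \
            else np.array(extra, dtype=np.int64)
        tval = np.concatenate([tval, np.zeros(len(extra))])
    value, gh, GJ, gK = _pl_value_grad(X, h, Jd, tidx, tval)
    grad: dict = {}
    for i, f in enumerate(model.factors):
        grad[("h", f)] = float(gh[i])
    for i, j in _triu_pairs(model.n):
        a, b = sorted((model.factors[i], model.factors[j]))
        grad[("J", (a, b))] = float(GJ[i, j])
    for (i, j, k), g in zip(tidx, gK):
        t = tuple(sorted((model.factors[i], model.factors[j], model.factors[k])))
        grad[("K", t)] = float(g)
    return value, grad


def pseudolikelihood_rows(
    model: MaxEntModel, data: ChromatinCodeMatrix
) -> np.ndarray:
    """Per-row negative log pseudo-likelihood contributions."""
    if model.factors != data.factors:
        raise ValueError("model and data factor lists differ")
    X = data.calls.astype(float)
    h, Jd, tidx, tval = model.to_dense()
    A = _local_fields(X, h, Jd, tidx, tval)
    return (_softplus(A) - X * A).sum(axis=1)


def pseudolikelihood_value(model: MaxEntModel, data: ChromatinCodeMatrix) -> float:
    """Mean negative log pseudo-likelihood (no gradient)."""
    return float(pseudolikelihood_rows(model, data).mean())


# ---------------------------------------------------------------------------
# lambda_max
# ---------------------------------------------------------------------------

def lambda_max(data: ChromatinCodeMatrix, order: int = 2) -> float:
    """Smallest penalty strength at which the interaction support is empty.

    Computed from the pseudo-likelihood gradient at the independence fit:
    the largest |grad J_ij| (order 2) or the largest group norm
    ||(grad J_ij, grad K_ij.)||_2 (order 3).
    """
    base = fit_independent(data)
    X = data.calls.astype(float)
    h, _, _, _ = base.to_dense()
    n = data.n_factors
    if order == 2:
        tidx = np.zeros((0, 3), dtype=np.int64)
        tval = np.zeros(0)
        _, _, GJ, _ = _pl_value_grad(X, h, np.zeros((n, n)), tidx, tval)
        return float(np.abs(GJ[np.triu_indices(n, 1)]).max())
    tidx = all_triples(n)
    _, _, GJ, gK = _pl_value_grad(X, h, np.zeros((n, n)), tidx, np.zeros(len(tidx)))
    best = 0.0
    for i, j in _triu_pairs(n):
        gsq = GJ[i, j] ** 2
        for r, (a, b, c) in enumerate(tidx):
            if i in (a, b, c) and j in (a, b, c):
                gsq += gK[r] ** 2
        best = max(best, float(np.sqrt(gsq)))
    return best


# ---------------------------------------------------------------------------
# pairwise L1 fit: FISTA with backtracking
# ---------------------------------------------------------------------------

def _fit_l1_arrays(
    X: np.ndarray,
    lam: float,
    h0: np.ndarray,
    J0: np.ndarray,
    max_iter: int = 3000,
    tol: float = GRAD_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Proximal gradient (FISTA, backtracking, restart) for the L1 problem."""
    n = X.shape[1]
    empty_t = (np.zeros((0, 3), dtype=np.int64), np.zeros(0))
    h, Jd = h0.copy(), J0.copy()
    yh, yJ = h.copy(), Jd.copy()
    t_mom = 1.0
    step = 1.0
    f_y, gh, GJ, _ = _pl_value_grad(X, yh, yJ, *empty_t)
    for it in range(max_iter):
        # backtracking on the smooth part from the momentum point
        while True:
            h_new = yh - step * gh
            J_new = yJ - step * GJ
            np.fill_diagonal(J_new, 0.0)
            J_new = np.sign(J_new) * np.maximum(np.abs(J_new) - step * lam, 0.0)
            f_new, gh_new, GJ_new, _ = _pl_value_grad(X, h_new, J_new, *empty_t)
            dh = h_new - yh
            dJ = J_new - yJ
            quad = (
                f_y + gh @ dh + 0.5 * (GJ * dJ).sum()
                + (dh @ dh + 0.5 * (dJ * dJ).sum()) / (2 * step)
            )
            if f_new <= quad + 1e-12 or step < 1e-10:
                break
            step *= 0.5
        # optimality check at the new point
        ut = np.triu_indices(n, 1)
        gJu, Ju = GJ_new[ut], J_new[ut]
        viol = np.where(
            Ju != 0,
            np.abs(gJu + lam * np.sign(Ju)),
            np.maximum(np.abs(gJu) - lam, 0.0),
        )
        kkt = max(np.abs(gh_new).max(), viol.max() if viol.size else 0.0)
        if kkt < tol:
            return h_new, J_new
        # momentum with restart on non-descent
        t_next = 0.5 * (1 + np.sqrt(1 + 4 * t_mom * t_mom))
        beta = (t_mom - 1) / t_next
        pen_new = f_new + lam * np.abs(J_new[ut]).sum()
        pen_old = _pl_value_grad(X, h, Jd, *empty_t)[0] + lam * np.abs(Jd[ut]).sum()
        if pen_new > pen_old:
            yh, yJ = h.copy(), Jd.copy()
            t_mom = 1.0
        else:
            yh = h_new + beta * (h_new - h)
            yJ = J_new + beta * (J_new - Jd)
            h, Jd = h_new, J_new
            t_mom = t_next
        f_y, gh, GJ, _ = _pl_value_grad(X, yh, yJ, *empty_t)
        step = min(step * 2.0, 1e3)
    raise ConvergenceError(
        f"pairwise L1 fit did not reach KKT tolerance {tol} in {max_iter} iterations",
        {"kkt": float(kkt), "lambda": lam},
    )


def fit_pairwise_l1(
    data: ChromatinCodeMatrix,
    lam: float,
    init: MaxEntModel | None = None,
    max_iter: int = 3000,
    tol: float = GRAD_TOL,
) -> MaxEntModel:
    """L1-penalized pseudo-likelihood fit of the pairwise (order-2) model.

    Minimizes the mean negative log pseudo-likelihood plus
    ``lam * sum_{i<j} |J_ij|``; h is unpenalized.  Proximal soft-thresholding
    produces exact zeros; entries below 1e-8 are dropped.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = data.calls.astype(float)
    n = data.n_factors
    if init is not None and init.factors == data.factors:
        h0, J0, _, _ = init.to_dense()
    else:
        h0, _, _, _ = fit_independent(data).to_dense()
        J0 = np.zeros((n, n))
    h, Jd = _fit_l1_arrays(X, lam, h0, J0, max_iter=max_iter, tol=tol)
    return MaxEntModel.from_dense(data.factors, h, Jd, tol=ZERO_TOL)


# ---------------------------------------------------------------------------
# hierarchical overlapping group-L1 fit: consensus ADMM
# ---------------------------------------------------------------------------

def _group_structure(n: int, tidx: np.ndarray):
    """Group of pair (i, j) = its J entry plus every candidate K_ijk.

    Parameters are flattened as [J over upper-tri pairs, K over tidx];
    returns per-group member index arrays into that flat vector.
    """
    pairs = _triu_pairs(n)
    pair_pos = {p: r for r, p in enumerate(pairs)}
    nJ = len(pairs)
    members = [[pair_pos[p]] for p in pairs]
    for r, (i, j, k) in enumerate(tidx):
        for p in ((i, j), (i, k), (j, k)):
            members[pair_pos[p]].append(nJ + r)
    return [np.array(m, dtype=np.int64) for m in members]


def fit_hierarchical_group_l1(
    data: ChromatinCodeMatrix,
    lam: float,
    triplet_candidates: np.ndarray | None = None,
    max_admm_iter: int = 200,
    rho: float = 2.0,
    tol: float = 1e-3,
) -> MaxEntModel:
    """Third-order fit with overlapping group-L1 penalty and hierarchy.

    The penalty is ``lam * sum_{i<j} || (J_ij, K_ij.) ||_2`` over overlapping
    groups, solved by consensus ADMM: the smooth pseudo-likelihood subproblem
    by L-BFGS, the group copies by block soft-thresholding.  A triplet
    survives only when all three of its pair groups are active, so the output
    support is hierarchical by construction (``hierarchy_flag`` set).
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = data.calls.astype(float)
    n = data.n_factors
    if triplet_candidates is None:
        if n > 40:
            raise ValueError(
                "full triplet candidate set requires n <= 40; "
                "pass triplet_candidates explicitly"
            )
        tidx = all_triples(n)
    else:
        tidx = np.asarray(triplet_candidates, dtype=np.int64).reshape(-1, 3)
        tidx = np.sort(tidx, axis=1)
    pairs = _triu_pairs(n)
    nJ, nK = len(pairs), len(tidx)
    groups = _group_structure(n, tidx)
    ut = np.triu_indices(n, 1)
    core = _PLCore(X, tidx)

    h, _, _, _ = fit_independent(data).to_dense()
    theta = np.zeros(nJ + nK)  # [J_ut, K]
    z = [np.zeros(len(g)) for g in groups]
    u = [np.zeros(len(g)) for g in groups]

    def unpack(th):
        Jd = np.zeros((n, n))
        Jd[ut] = th[:nJ]
        Jd += Jd.T
        return Jd, th[nJ:]

    def smooth_obj(v):
        h_, th = v[:n], v[n:]
        Jd, K = unpack(th)
        val, gh, GJ, gK = core.value_grad(h_, Jd, K)
        g = np.concatenate([gh, GJ[ut], gK])
        # augmented-Lagrangian quadratic terms
        for gi, grp in enumerate(groups):
            d = th[grp] - z[gi] + u[gi]
            val += 0.5 * rho * float(d @ d)
            g[n + grp] += rho * d
        return val, g

    v0 = np.concatenate([h, theta])
    n_dup = sum(len(g) for g in groups)  # duplicated-parameter count
    for it in range(max_admm_iter):
        res = minimize(
            smooth_obj, v0, jac=True, method="L-BFGS-B",
            options={"maxiter": 40, "ftol": 1e-12, "gtol": 1e-8},
        )
        v0 = res.x
        h, theta = v0[:n], v0[n:]
        primal_sq = dual_sq = th_sq = z_sq = 0.0
        for gi, grp in enumerate(groups):
            val = theta[grp] + u[gi]
            nrm = float(np.linalg.norm(val))
            z_new = np.zeros_like(val) if nrm == 0 else \
                max(0.0, 1.0 - (lam / rho) / nrm) * val
            dual_sq += float(((z_new - z[gi]) ** 2).sum()) * rho * rho
            z[gi] = z_new
            u[gi] += theta[grp] - z[gi]
            primal_sq += float(((theta[grp] - z[gi]) ** 2).sum())
            th_sq += float((theta[grp] ** 2).sum())
            z_sq += float((z[gi] ** 2).sum())
        primal = np.sqrt(primal_sq)
        dual = np.sqrt(dual_sq)
        # Boyd-style combined absolute/relative stopping criteria
        eps_pri = np.sqrt(n_dup) * tol * 0.1 + tol * np.sqrt(max(th_sq, z_sq))
        eps_dual = np.sqrt(n_dup) * tol * 0.1 + tol * rho * np.sqrt(
            sum(float((u[gi] ** 2).sum()) for gi in range(len(groups)))
        )
        if primal < eps_pri and dual < eps_dual:
            break
        # residual balancing keeps the two residuals comparable
        if primal > 10 * dual:
            rho *= 2.0
            u = [ug / 2.0 for ug in u]
        elif dual > 10 * primal:
            rho /= 2.0
            u = [ug * 2.0 for ug in u]
    else:
        if primal > 100 * eps_pri:
            raise ConvergenceError(
                f"group-L1 ADMM residual {primal:.2e} after {max_admm_iter} iters",
                {"primal": primal, "dual": dual, "lambda": lam},
            )
        warnings.warn(
            f"group-L1 ADMM stopped at residual {primal:.2e} "
            f"(target {eps_pri:.2e})", stacklevel=2,
        )

    # consensus support from the z copies (exact zeros live there)
    z_flat = np.zeros(nJ + nK)
    z_count = np.zeros(nJ + nK)
    for gi, grp in enumerate(groups):
        z_flat[grp] += z[gi]
        z_count[grp] += 1
    z_flat /= np.maximum(z_count, 1)
    active = np.zeros(nJ + nK, dtype=bool)
    for gi, grp in enumerate(groups):
        active[grp] |= np.abs(z[gi]) > ZERO_TOL
    # K needs every copy (all three groups) active
    for r in range(nK):
        copies = []
        for gi, grp in enumerate(groups):
            hit = np.nonzero(grp == nJ + r)[0]
            if hit.size:
                copies.append(abs(z[gi][hit[0]]) > ZERO_TOL)
        active[nJ + r] = bool(copies) and all(copies)

    Jd, K = unpack(np.where(active, z_flat, 0.0))
    # hierarchy by construction: a triplet needs all three member pairs
    Jsup = {p for p in pairs if abs(Jd[p]) > ZERO_TOL}
    keep = np.array([
        all(p in Jsup for p in ((i, j), (i, k), (j, k)))
        for (i, j, k) in tidx
    ], dtype=bool) if nK else np.zeros(0, dtype=bool)
    K = np.where(keep, K, 0.0)
    return MaxEntModel.from_dense(
        data.factors, h, Jd, tidx, K, hierarchy_flag=True, tol=ZERO_TOL
    )


# ---------------------------------------------------------------------------
# regularization-strength selection
# ---------------------------------------------------------------------------

def default_lambda_grid(
    data: ChromatinCodeMatrix, order: int = 2, n_points: int = 30, span: float = 1000.0
) -> np.ndarray:
    lmax = lambda_max(data, order=order)
    return np.geomspace(lmax, lmax / span, n_points)


def select_lambda(
    train: ChromatinCodeMatrix,
    val: ChromatinCodeMatrix,
    grid: np.ndarray,
    order: int = 2,
    rule: str = "1se",
) -> tuple[float, RegularizationPath]:
    """Fit along a descending lambda grid; pick the validation optimum.

    Warm starts propagate along the path for the order-2 fits.  The
    validation score is a sample mean, so values within its Monte-Carlo
    uncertainty are statistical ties; ties go to the larger lambda (the
    sparser model).  ``rule = "1se"`` (default) therefore picks the largest
    lambda whose score is within one standard error of the minimum -- the
    standard one-SE rule of penalized regression; ``rule = "min"`` is the
    plain argmin with exact-tie breaking only.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be descending")
    models: list[MaxEntModel] = []
    scores = np.zeros(grid.size)
    ses = np.zeros(grid.size)
    prev: MaxEntModel | None = None
    for r, lam in enumerate(grid):
        if order == 2:
            m = fit_pairwise_l1(train, lam, init=prev)
        elif order == 3:
            m = fit_hierarchical_group_l1(train, lam)
        else:
            raise ValueError("order must be 2 or 3")
        models.append(m)
        rows = pseudolikelihood_rows(m, val)
        scores[r] = rows.mean()
        ses[r] = rows.std(ddof=1) / np.sqrt(rows.size) if rows.size > 1 else 0.0
        prev = m
    imin = int(np.argmin(scores))
    if rule == "1se":
        cutoff = scores[imin] + ses[imin]
    elif rule == "min":
        cutoff = scores[imin] + 1e-12
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    best = int(np.nonzero(scores <= cutoff)[0][0])
    path = RegularizationPath(lambdas=grid, models=models, val_scores=scores)
    return float(grid[best]), path
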