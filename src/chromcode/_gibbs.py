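"""Numba kernel for the sequential-scan Gibbs sampler.

Single chain, fixed site order (factor index); the conditional of each site
is logistic in its local field h_i + sum_j J_ij x_j + sum_{j<k} K_ijk x_j x_k.
One sample is retained per full sweep after burn-in.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweeps(h, J, t_ptr, t_jk, t_val, n_samples, burn_in, seed, x0):
    np.random.seed(seed)
    n = h.shape[0]
    x = x0.copy()
    out = np.empty((n_samples, n), dtype=np.int8)
    for sweep in range(burn_in + n_samples):
        for i in range(n):
            f = h[i]
            for j in range(n):
                if x[j] == 1:
                    f += J[i, j]  # J[i, i] is zero
            for p in range(t_ptr[i], t_ptr[i + 1]):
                if x[t_jk[p, 0]] == 1 and x[t_jk[p, 1]] == 1:
                    f += t_val[p]
            p1 = 1.0 / (1.0 + np.exp(-f))
            x[i] = 1 if np.random.random() < p1 else 0
        if sweep >= burn_in:
            out[sweep - burn_in] = x
    return out
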