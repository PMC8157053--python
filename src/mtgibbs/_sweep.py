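"""Jit-compiled Gauss-Seidel sweep over the mixed-model equations.

One call performs a full Gibbs scan of the location effects: every fixed
effect coefficient is updated single-site, then every animal's breeding
values are updated as a k-trait block (its full conditional given all other
animals, which couples parents/progeny/mates through A-inverse).  The
residual matrix ``e`` (records x traits, complete after augmentation) is
kept consistent in place, so no design-matrix products are ever formed.

Standard-normal innovations are pre-drawn by the caller (``z_b``, ``z_u``)
so all randomness flows through one seeded generator stream.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_small(P, L):
    """In-place Cholesky of small PD matrix P into L; returns False on failure."""
    k = P.shape[0]
    for i in range(k):
        for j in range(i + 1):
            s = P[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                if s <= 0.0 or not np.isfinite(s):
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, k):
            L[i, j] = 0.0
    return True


@njit(cache=True)
def location_sweep(
    b,
    u,
    e,
    Rinv,
    Ginv,
    coef_trait,
    coef_ptr,
    coef_rec,
    coef_x,
    sum_x2,
    rec_of_animal,
    ainv_indptr,
    ainv_indices,
    ainv_data,
    z_b,
    z_u,
):
    """One full location scan; mutates b, u, e. Returns (code, index).

    code 0: success; 1: non-finite fixed-effect conditional (index = coef);
    2: breeding-value precision block not PD (index = animal).
    """
    p = b.shape[0]
    k = Rinv.shape[0]
    n_ped = u.shape[0]

    for j in range(p):
        t = coef_trait[j]
        c = Rinv[t, t] * sum_x2[j]
        if not np.isfinite(c) or c <= 0.0:
            return 1, j
        num = 0.0
        for ptr in range(coef_ptr[j], coef_ptr[j + 1]):
            i = coef_rec[ptr]
            acc = 0.0
            for tt in range(k):
                acc += Rinv[t, tt] * e[i, tt]
            num += coef_x[ptr] * acc
        new = b[j] + num / c + z_b[j] / np.sqrt(c)
        delta = new - b[j]
        b[j] = new
        for ptr in range(coef_ptr[j], coef_ptr[j + 1]):
            e[coef_rec[ptr], t] -= coef_x[ptr] * delta

    P = np.empty((k, k))
    L = np.empty((k, k))
    rhs = np.empty(k)
    w = np.empty(k)
    s = np.empty(k)
    for a in range(n_ped):
        aii = 0.0
        for tt in range(k):
            s[tt] = 0.0
        for ptr in range(ainv_indptr[a], ainv_indptr[a + 1]):
            jj = ainv_indices[ptr]
            v = ainv_data[ptr]
            if jj == a:
                aii = v
            else:
                for tt in range(k):
                    s[tt] += v * u[jj, tt]
        rec = rec_of_animal[a]
        for t1 in range(k):
            acc = 0.0
            for t2 in range(k):
                P[t1, t2] = aii * Ginv[t1, t2]
                acc -= Ginv[t1, t2] * s[t2]
            rhs[t1] = acc
        if rec >= 0:
            for t1 in range(k):
                for t2 in range(k):
                    P[t1, t2] += Rinv[t1, t2]
                    rhs[t1] += Rinv[t1, t2] * (e[rec, t2] + u[a, t2])
        if not _chol_small(P, L):
            return 2, a
        # mean = P^-1 rhs via forward+back substitution
        for t1 in range(k):
            acc = rhs[t1]
            for t2 in range(t1):
                acc -= L[t1, t2] * w[t2]
            w[t1] = acc / L[t1, t1]
        for t1 in range(k - 1, -1, -1):
            acc = w[t1] + z_u[a, t1]  # add noise in whitened space
            for t2 in range(t1 + 1, k):
                acc -= L[t2, t1] * s[t2]
            s[t1] = acc / L[t1, t1]
        # s now holds the new draw: mean + L^-T z
        for t1 in range(k):
            delta = s[t1] - u[a, t1]
            u[a, t1] = s[t1]
            if rec >= 0:
                e[rec, t1] -= delta
    return 0, -1
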