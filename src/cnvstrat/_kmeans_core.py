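"""Compiled Lloyd/k-means++ core.

The gap statistic clusters ~1000 reference datasets per run, so the inner
loop is JIT-compiled with numba; a pure-numpy fallback keeps the package
importable without it.  Both paths are deterministic given a seed, but they
draw from different generators, so results are reproducible per path, not
across paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _lloyd_restarts_nb(x, k, n_restarts, seed, max_iter, tol):  # pragma: no cover
    n, p = x.shape
    np.random.seed(seed)
    xsq = np.empty(n)
    for i in range(n):
        xsq[i] = np.dot(x[i], x[i])
    best_inertia = 1e300
    best_assign = np.zeros(n, np.int64)
    best_centers = np.zeros((k, p))
    best_niter = 0
    for _ in range(n_restarts):
        # --- k-means++ initialization ---
        centers = np.empty((k, p))
        centers[0] = x[np.random.randint(0, n)]
        d2min = np.empty(n)
        for i in range(n):
            diff = x[i] - centers[0]
            d2min[i] = np.dot(diff, diff)
        for c in range(1, k):
            tot = d2min.sum()
            if tot <= 0.0:
                centers[c] = centers[0]
                continue
            u = np.random.random() * tot
            acc = 0.0
            idx = n - 1
            for i in range(n):
                acc += d2min[i]
                if acc >= u:
                    idx = i
                    break
            centers[c] = x[idx]
            for i in range(n):
                diff = x[i] - centers[c]
                d = np.dot(diff, diff)
                if d < d2min[i]:
                    d2min[i] = d
        # --- Lloyd iterations ---
        assign = np.zeros(n, np.int64)
        inertia = 0.0
        prev = -1.0
        niter = 0
        for it in range(max_iter):
            niter = it + 1
            csq = np.empty(k)
            for c in range(k):
                csq[c] = np.dot(centers[c], centers[c])
            xc = np.dot(x, centers.T)
            inertia = 0.0
            for i in range(n):
                bi = 0
                bd = xsq[i] - 2.0 * xc[i, 0] + csq[0]
                for c in range(1, k):
                    d = xsq[i] - 2.0 * xc[i, c] + csq[c]
                    if d < bd:
                        bd = d
                        bi = c
                if bd < 0.0:
                    bd = 0.0
                assign[i] = bi
                inertia += bd
            counts = np.zeros(k, np.int64)
            sums = np.zeros((k, p))
            for i in range(n):
                counts[assign[i]] += 1
                sums[assign[i]] += x[i]
            for c in range(k):
                if counts[c] > 0:
                    centers[c] = sums[c] / counts[c]
                else:
                    # empty cluster: reseed at the farthest point
                    far = 0
                    fd = -1.0
                    for i in range(n):
                        d = xsq[i] - 2.0 * xc[i, assign[i]] + csq[assign[i]]
                        if d > fd:
                            fd = d
                            far = i
                    centers[c] = x[far]
            if prev >= 0.0 and prev - inertia <= tol * abs(prev):
                break
            prev = inertia
        if inertia < best_inertia:
            best_inertia = inertia
            best_assign = assign.copy()
            best_centers = centers.copy()
            best_niter = niter
    return best_inertia, best_assign, best_centers, best_niter


def lloyd_restarts(
    x: np.ndarray, k: int, n_restarts: int, seed: int, max_iter: int, tol: float
):
    """Best-of-restarts Lloyd k-means; returns (inertia, assignments, centers, n_iter)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if _HAVE_NUMBA:
        return _lloyd_restarts_nb(x, k, n_restarts, int(seed) & 0x7FFFFFFF, max_iter, tol)
    return _lloyd_restarts_py(x, k, n_restarts, seed, max_iter, tol)


def _lloyd_restarts_py(x, k, n_restarts, seed, max_iter, tol):
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    xsq = (x**2).sum(axis=1)
    best = None
    for _ in range(max(1, n_restarts)):
        centers = _pp_init(x, k, rng)
        prev = -1.0
        for it in range(1, max_iter + 1):
            d2 = xsq[:, None] - 2.0 * (x @ centers.T) + (centers**2).sum(axis=1)[None, :]
            np.maximum(d2, 0.0, out=d2)
            assign = d2.argmin(axis=1)
            inertia = float(d2[np.arange(n), assign].sum())
            for j in range(k):
                mask = assign == j
                if mask.any():
                    centers[j] = x[mask].mean(axis=0)
                else:
                    centers[j] = x[d2[np.arange(n), assign].argmax()]
            if prev >= 0.0 and prev - inertia <= tol * abs(prev):
                break
            prev = inertia
        if best is None or inertia < best[0]:
            best = (inertia, assign, centers, it)
    return best


def _pp_init(x, k, rng):
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        s = d2.sum()
        if s <= 0:
            centers[i:] = centers[0]
            break
        centers[i] = x[rng.choice(n, p=d2 / s)]
        d2 = np.minimum(d2, ((x - centers[i]) ** 2).sum(axis=1))
    return centers
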