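"""Logistic-regression likelihood machinery for the branch scan.

Implements maximum-likelihood and Firth-penalized logistic regression with a
Newton solver, plus a permutation kernel that recomputes every eligible
branch's likelihood-ratio statistic under shuffled subject-to-haplotype
assignments. Firth's penalty (Jeffreys-prior term 0.5 log|X'WX| added to the
log-likelihood) keeps estimates and the penalized LRT finite under complete
separation -- the situation of a clade containing no cases, which is exactly
the kind of signal this scan must be able to rank.

The solver hand-rolls its dense linear algebra: design matrices here are
tall and narrow (hundreds of rows, <= ~10 columns), where LAPACK call
overhead dominates, and the permutation scan performs millions of fits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_ITER = 25
TOL = 1e-5
_RIDGE = 1e-10
_MAX_STEP = 5.0  # per-iteration coefficient step cap (plain ML under separation)


@njit(cache=True, fastmath=True)
def _cholesky(A, L, p):
    """Lower Cholesky of A into L. Returns False if not positive definite."""
    for r in range(p):
        for c in range(r + 1):
            s = A[r, c]
            for k in range(c):
                s -= L[r, k] * L[c, k]
            if r == c:
                if s <= 0.0:
                    return False
                L[r, r] = np.sqrt(s)
            else:
                L[r, c] = s / L[c, c]
        for c in range(r + 1, p):
            L[r, c] = 0.0
    return True


@njit(cache=True, fastmath=True)
def _chol_solve(L, b, x, p):
    """Solve L L' x = b (b preserved)."""
    for r in range(p):
        s = b[r]
        for k in range(r):
            s -= L[r, k] * x[k]
        x[r] = s / L[r, r]
    for r in range(p - 1, -1, -1):
        s = x[r]
        for k in range(r + 1, p):
            s -= L[k, r] * x[k]
        x[r] = s / L[r, r]


@njit(cache=True, fastmath=True)
def _chol_inverse(L, Ainv, col, p):
    """A^{-1} from its Cholesky factor, column by column."""
    for c in range(p):
        for r in range(p):
            col[r] = 1.0 if r == c else 0.0
        _chol_solve(L, col, col, p)
        for r in range(p):
            Ainv[r, c] = col[r]


@njit(cache=True, fastmath=True)
def _weights_info(X, beta, mu, w, A, L):
    """Fill mu, w, A = X'WX + ridge, and its Cholesky L at beta.

    Returns False when the information matrix is not positive definite.
    """
    n, p = X.shape
    for r in range(p):
        for c in range(p):
            A[r, c] = 0.0
    for i in range(n):
        e = 0.0
        for r in range(p):
            e += X[i, r] * beta[r]
        if e > 0.0:
            m = 1.0 / (1.0 + np.exp(-e))
        else:
            t = np.exp(e)
            m = t / (1.0 + t)
        mu[i] = m
        wi = m * (1.0 - m)
        if wi < 1e-12:
            wi = 1e-12
        w[i] = wi
        for r in range(p):
            xr = X[i, r] * wi
            for c in range(p):
                A[r, c] += xr * X[i, c]
    for r in range(p):
        A[r, r] += _RIDGE
    return _cholesky(A, L, p)


@njit(cache=True, fastmath=True)
def _plain_ll(X, y, beta):
    """Unpenalized Bernoulli log-likelihood at beta."""
    n, p = X.shape
    ll = 0.0
    for i in range(n):
        e = 0.0
        for r in range(p):
            e += X[i, r] * beta[r]
        if e > 0.0:
            ll += y[i] * e - (e + np.log1p(np.exp(-e)))
        else:
            ll += y[i] * e - np.log1p(np.exp(e))
    return ll


@njit(cache=True, fastmath=True)
def _fit_logistic(X, y, firth, beta0, max_iter, tol):
    """Newton fit of (penalized) logistic regression.

    Full Newton steps on the (Firth-modified) score; convergence when the
    largest coefficient update falls below ``tol`` (such an update is not
    applied -- at that point the log-likelihood is stationary to O(tol^2)).
    Oversized steps are damped, which keeps plain-ML fits bounded under
    separation until the iteration cap. Returns (beta, loglik, converged)
    where loglik includes the Jeffreys penalty when ``firth``.
    """
    n, p = X.shape
    beta = beta0.copy()
    mu = np.empty(n)
    w = np.empty(n)
    A = np.empty((p, p))
    L = np.empty((p, p))
    Ainv = np.empty((p, p))
    col = np.empty(p)
    U = np.empty(p)
    delta = np.empty(p)
    converged = False
    fresh = False  # do mu/w/A/L correspond to current beta?
    for _ in range(max_iter):
        if not _weights_info(X, beta, mu, w, A, L):
            return beta, -np.inf, False
        fresh = True
        for r in range(p):
            U[r] = 0.0
        if firth:
            _chol_inverse(L, Ainv, col, p)
            for i in range(n):
                h = 0.0
                for r in range(p):
                    s = 0.0
                    for c in range(p):
                        s += Ainv[r, c] * X[i, c]
                    h += X[i, r] * s
                h *= w[i]
                resid = y[i] - mu[i] + h * (0.5 - mu[i])
                for r in range(p):
                    U[r] += X[i, r] * resid
        else:
            for i in range(n):
                resid = y[i] - mu[i]
                for r in range(p):
                    U[r] += X[i, r] * resid
        _chol_solve(L, U, delta, p)
        moved = 0.0
        for r in range(p):
            d = abs(delta[r])
            if d > moved:
                moved = d
        if moved < tol:
            converged = True
            break
        if moved > _MAX_STEP:
            scale = _MAX_STEP / moved
            for r in range(p):
                delta[r] *= scale
        for r in range(p):
            beta[r] += delta[r]
        fresh = False
    if not fresh:
        if not _weights_info(X, beta, mu, w, A, L):
            return beta, -np.inf, False
    ll = _plain_ll(X, y, beta)
    if firth:
        for r in range(p):
            ll += np.log(L[r, r])
    return beta, ll, converged


@njit(cache=True, fastmath=True)
def _lrt_statistic(X, y, firth, beta_red0, max_iter, tol):
    """2(ll_full - ll_reduced) for the last column of X. Returns (stat, beta_last, conv)."""
    n, p = X.shape
    beta_r, ll_r, conv_r = _fit_logistic(X[:, : p - 1].copy(), y, firth, beta_red0, max_iter, tol)
    beta_f0 = np.zeros(p)
    for r in range(p - 1):
        beta_f0[r] = beta_r[r]
    beta_f, ll_f, conv_f = _fit_logistic(X, y, firth, beta_f0, max_iter, tol)
    stat = 2.0 * (ll_f - ll_r)
    if stat < 0.0:
        stat = 0.0
    return stat, beta_f[p - 1], conv_r and conv_f


@njit(cache=True)
def _scan_kernel(G, perms, idx, y, C, firth, beta_red_full, ll_red_full, max_iter, tol):
    """Branch LRT statistics for every permutation.

    G        : (K, N) int8, per-branch genotype of every subject (-1 missing)
    perms    : (B, N) int64 permutations of 0..N-1 (subject i takes the
               haplotype of subject perms[b, i])
    idx      : (m,) int64, subject indices with phenotype + complete covariates
    y        : (m,) float64 case status
    C        : (m, q) float64 covariates incl. intercept column
    beta_red_full, ll_red_full : reduced-model fit on all m rows (cached;
               reused whenever a branch-permutation has no missing genotypes)

    Returns S: (B, K) float64. A branch whose genotype is constant after
    listwise deletion in a given permutation scores 0.
    """
    B = perms.shape[0]
    K = G.shape[0]
    m, q = C.shape
    S = np.zeros((B, K))
    Xfull = np.empty((m, q + 1))
    for t in range(m):
        for c in range(q):
            Xfull[t, c] = C[t, c]
    Xbuf = np.empty((m, q + 1))
    ybuf = np.empty(m)
    beta_f0 = np.empty(q + 1)
    for b in range(B):
        for k in range(K):
            cnt = 0
            ones = 0
            for t in range(m):
                g = G[k, perms[b, idx[t]]]
                if g >= 0:
                    Xbuf[cnt, q] = g
                    cnt += 1
                    ones += g
            if cnt == 0 or ones == 0 or ones == cnt:
                continue
            if cnt == m:
                # fast path: no missing genotypes, covariate block unchanged
                for t in range(m):
                    Xfull[t, q] = G[k, perms[b, idx[t]]]
                for r in range(q):
                    beta_f0[r] = beta_red_full[r]
                beta_f0[q] = 0.0
                _, ll_f, _ = _fit_logistic(Xfull, y, firth, beta_f0, max_iter, tol)
                stat = 2.0 * (ll_f - ll_red_full)
            else:
                cnt = 0
                for t in range(m):
                    g = G[k, perms[b, idx[t]]]
                    if g >= 0:
                        for c in range(q):
                            Xbuf[cnt, c] = C[t, c]
                        Xbuf[cnt, q] = g
                        ybuf[cnt] = y[t]
                        cnt += 1
                stat, _, _ = _lrt_statistic(
                    Xbuf[:cnt].copy(), ybuf[:cnt].copy(), firth, np.zeros(q), max_iter, tol
                )
            S[b, k] = stat if stat > 0.0 else 0.0
    return S


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    firth: bool = True,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> tuple[np.ndarray, float, bool]:
    """Python entry point: fit and return (beta, loglik, converged)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    return _fit_logistic(X, y, firth, np.zeros(X.shape[1]), max_iter, tol)


def lrt_last_column(
    X: np.ndarray,
    y: np.ndarray,
    firth: bool = True,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> tuple[float, float, bool]:
    """LRT for the last design column: (statistic, fitted beta, converged)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    return _lrt_statistic(X, y, firth, np.zeros(X.shape[1] - 1), max_iter, tol)
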