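"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the SVR oracle solves
the epsilon-insensitive dual QP by exhaustive KKT state enumeration, the
GLM oracle uses raw normal equations, the structure-coefficient oracle
loops over voxels with np.cov, BH-FDR scans all thresholds, and the
binomial oracle sums the pmf from factorials.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

ZERO, UP, LOW, FREE_POS, FREE_NEG = range(5)


def svr_kkt_oracle(X: np.ndarray, y: np.ndarray, C: float = 1.0, epsilon: float = 0.1,
                   tol: float = 1e-9):
    """Solve the linear epsilon-SVR by enumerating KKT active sets.

    Dual in beta = alpha - alpha*:
        max  -1/2 beta' Q beta + y' beta - eps * sum|beta_i|
        s.t. sum(beta) = 0,  -C <= beta_i <= C,   Q = X X'.
    Each sample is assigned a state (zero / at +C / at -C / free positive /
    free negative); for every assignment the stationarity system is solved
    and KKT feasibility checked.  Returns (w, b, b_unique) of the best
    feasible solution; b is unique only when free support vectors exist
    (otherwise the optimum is flat over an interval of b and the midpoint
    is returned).  Only intended for n <= 6 samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = X @ X.T
    best = None

    for states in itertools.product(range(5), repeat=n):
        beta = np.zeros(n)
        fixed_mask = np.zeros(n, dtype=bool)
        for i, s in enumerate(states):
            if s == UP:
                beta[i] = C
                fixed_mask[i] = True
            elif s == LOW:
                beta[i] = -C
                fixed_mask[i] = True
            elif s == ZERO:
                fixed_mask[i] = True
        free = [i for i, s in enumerate(states) if s in (FREE_POS, FREE_NEG)]
        signs = np.array([1.0 if states[i] == FREE_POS else -1.0 for i in free])

        if free:
            k = len(free)
            A = np.zeros((k + 1, k + 1))
            rhs = np.zeros(k + 1)
            A[:k, :k] = Q[np.ix_(free, free)]
            A[:k, k] = 1.0
            A[k, :k] = 1.0
            fixed_contrib = Q[np.ix_(free, np.flatnonzero(fixed_mask))] @ beta[fixed_mask]
            rhs[:k] = y[free] - epsilon * signs - fixed_contrib
            rhs[k] = -beta[fixed_mask].sum()
            sol, residuals, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(A @ sol - rhs) > 1e-8:
                continue
            beta[free] = sol[:k]
            b = sol[k]
            # free variables must respect sign and lie strictly inside bounds
            if np.any(signs * beta[free] < -tol) or np.any(np.abs(beta[free]) > C + 1e-8):
                continue
        else:
            if abs(beta.sum()) > 1e-10:
                continue
            # b constrained to an interval by the bound/zero conditions
            resid = y - Q @ beta
            lo, hi = -np.inf, np.inf
            for i, s in enumerate(states):
                if s == UP:
                    hi = min(hi, resid[i] - epsilon)
                elif s == LOW:
                    lo = max(lo, resid[i] + epsilon)
                elif s == ZERO:
                    lo = max(lo, resid[i] - epsilon)
                    hi = min(hi, resid[i] + epsilon)
            if lo > hi + 1e-10:
                continue
            b = (lo + hi) / 2.0 if np.isfinite(lo) and np.isfinite(hi) else 0.0

        # KKT feasibility for fixed states
        resid = y - Q @ beta - b
        ok = True
        for i, s in enumerate(states):
            if s == UP and resid[i] < epsilon - 1e-8:
                ok = False
            elif s == LOW and resid[i] > -epsilon + 1e-8:
                ok = False
            elif s == ZERO and abs(resid[i]) > epsilon + 1e-8:
                ok = False
            if not ok:
                break
        if not ok:
            continue
        obj = -0.5 * beta @ Q @ beta + y @ beta - epsilon * np.abs(beta).sum()
        if best is None or obj > best[0] + 1e-12:
            best = (obj, X.T @ beta, b, bool(free))
    if best is None:
        raise RuntimeError("no feasible KKT state found")
    return best[1], best[2], best[3]


def ols_normal_equations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Brute-force OLS via (X'X)^-1 X'Y."""
    X = np.asarray(X, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(Y, dtype=float))


def haufe_brute_force(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Voxelwise cov(x_v, yhat)/Var(yhat) with np.cov, one voxel at a time."""
    X = np.asarray(X, dtype=float)
    yhat = X @ np.asarray(W, dtype=float)
    var = np.cov(yhat, ddof=1)
    return np.array([np.cov(X[:, v], yhat, ddof=1)[0, 1] / var for v in range(X.shape[1])])


def bh_brute_force(p: np.ndarray, q: float) -> np.ndarray:
    """BH by scanning every observed p as a candidate threshold."""
    p = np.asarray(p, dtype=float)
    m = p.size
    best_thr = 0.0
    for candidate in p:
        k = np.sum(p <= candidate)
        if candidate <= k * q / m:
            best_thr = max(best_thr, candidate)
    return p <= best_thr if best_thr > 0 else np.zeros(m, dtype=bool)


def binom_two_sided_brute(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p by summing pmf terms <= pmf(k)."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    ref = pmf[k] * (1 + 1e-10)
    return float(sum(v for v in pmf if v <= ref))


def flood_fill_components(mask3d: np.ndarray) -> int:
    """Count 6-connected components by explicit flood fill (no scipy.label)."""
    mask3d = np.asarray(mask3d, dtype=bool)
    seen = np.zeros_like(mask3d)
    count = 0
    for start in zip(*np.nonzero(mask3d)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                ni, nj, nk = i + di, j + dj, k + dk
                if (
                    0 <= ni < mask3d.shape[0]
                    and 0 <= nj < mask3d.shape[1]
                    and 0 <= nk < mask3d.shape[2]
                    and mask3d[ni, nj, nk]
                    and not seen[ni, nj, nk]
                ):
                    seen[ni, nj, nk] = True
                    stack.append((ni, nj, nk))
    return count
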