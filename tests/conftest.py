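"""Shared fixtures and independent reference oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# independent oracles (brute force / first principles; kept solver-free)


def soft_threshold(x: float, t: float) -> float:
    return float(np.sign(x) * max(abs(x) - t, 0.0))


def glasso_oracle(s: np.ndarray, lam: float, tol: float = 1e-6, max_sweeps: int = 500) -> np.ndarray:
    """Reference graphical lasso via textbook block coordinate descent.

    Follows the Friedman et al. column-by-column scheme with an inner
    lasso coordinate descent, leaving the covariance diagonal
    unpenalized.  Written independently of the package's solver path.
    """
    p = s.shape[0]
    w = s.copy()
    b = np.zeros((p, p))
    for _ in range(max_sweeps):
        w_old = w.copy()
        for j in range(p):
            idx = np.array([i for i in range(p) if i != j])
            w11 = w[np.ix_(idx, idx)]
            s12 = s[idx, j]
            beta = b[idx, j].copy()
            for _ in range(1000):
                delta = 0.0
                for k in range(p - 1):
                    r = s12[k] - w11[k] @ beta + w11[k, k] * beta[k]
                    bnew = soft_threshold(r, lam) / w11[k, k]
                    delta = max(delta, abs(bnew - beta[k]))
                    beta[k] = bnew
                if delta < tol * 1e-2:
                    break
            b[idx, j] = beta
            w12 = w11 @ beta
            w[idx, j] = w12
            w[j, idx] = w12
        if np.abs(w - w_old).max() < tol:
            break
    theta = np.zeros((p, p))
    for j in range(p):
        idx = np.array([i for i in range(p) if i != j])
        beta = b[idx, j]
        tjj = 1.0 / (w[j, j] - w[idx, j] @ beta)
        theta[j, j] = tjj
        theta[idx, j] = -beta * tjj
    return (theta + theta.T) / 2.0


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks computed from first principles (no scipy)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_edges_oracle(values: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Brute-force Spearman network: explicit ranks, Pearson formula on
    ranks, t-approximation p-value, Bonferroni cutoff."""
    from scipy.stats import t as t_dist

    p, n = values.shape
    ranks = np.array([average_ranks(row) for row in values])
    adj = np.zeros((p, p), dtype=int)
    n_tests = p * (p - 1) // 2
    for i in range(p):
        for j in range(i + 1, p):
            a = ranks[i] - ranks[i].mean()
            bb = ranks[j] - ranks[j].mean()
            denom = np.sqrt((a @ a) * (bb @ bb))
            rho = float(a @ bb / denom) if denom > 0 else np.nan
            if not np.isfinite(rho):
                continue
            rho = min(1.0, max(-1.0, rho))
            if abs(rho) >= 1.0:
                pval = 0.0
            else:
                tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
                pval = 2.0 * t_dist.sf(abs(tstat), df=n - 2)
            if pval <= alpha / n_tests:
                adj[i, j] = adj[j, i] = 1
    return adj


def clustering_oracle(adj: np.ndarray) -> float:
    """Mean local clustering by exhaustive triangle counting."""
    adj = np.asarray(adj)
    p = adj.shape[0]
    coeffs = []
    for v in range(p):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    links += 1
        coeffs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(coeffs))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def monthly_predictors():
    """Standard 200-sample monthly time axis."""
    day = np.arange(1, 201)
    month = (day - 1) % 12 + 1
    return month, day


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
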