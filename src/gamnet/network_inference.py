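"""Association-network inference backends.

Two backends operate on a (detrended or raw) species x sample table:
pairwise Spearman correlation with Bonferroni-thresholded significance
(SCC), and L1-penalized Gaussian precision estimation (graphical lasso)
with StARS stability selection of the regularization strength.  A
nonparanormal rank transform Gaussianizes marginals beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.covariance import graphical_lasso

__all__ = [
    "InferredNetwork",
    "StarsConfig",
    "nonparanormal_transform",
    "scc_network",
    "glasso_path",
    "stars_select",
    "BACKENDS",
]


@dataclass
class InferredNetwork:
    """Binary association network plus backend-specific detail."""

    adjacency: np.ndarray
    backend: str  # scc | glasso
    detail: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class StarsConfig:
    """StARS stability-selection settings (the defaults published with the StARS method)."""

    n_lambda: int = 30
    n_subsamples: int = 50
    instability_threshold: float = 0.05
    lambda_min_ratio: float = 0.01
    #: solver settings for the subsampled stability runs only; the final
    #: full-data estimate always uses the tight defaults (1e-4, 200)
    subsample_tol: float = 1e-3
    subsample_max_iter: int = 30

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0.0 < self.instability_threshold < 0.5:
            raise ValueError("instability_threshold must be in (0, 0.5)")

    def subsample_size(self, n: int) -> int:
        return min(n - 1, int(np.floor(10.0 * np.sqrt(n))))


def nonparanormal_transform(values: np.ndarray) -> np.ndarray:
    """Per-species rank -> standard-normal-quantile map, unit variance.

    Ranks use the average-tie method and are mapped through
    Phi^{-1}(rank / (n + 1)) (the shrunken nonparanormal), then each
    species is scaled to unit sample variance.  Constant species cannot
    be ranked meaningfully and are mapped to zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    p, n = x.shape
    out = np.empty_like(x)
    for i in range(p):
        if np.ptp(x[i]) == 0.0:
            warnings.warn(f"species {i} is constant; nonparanormal maps it to zeros")
            out[i] = 0.0
            continue
        ranks = stats.rankdata(x[i], method="average")
        q = stats.norm.ppf(ranks / (n + 1.0))
        out[i] = q / q.std(ddof=1)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation networks


def scc_network(values: np.ndarray, alpha: float = 0.01) -> InferredNetwork:
    """Bonferroni-thresholded Spearman correlation network.

    All C(p,2) tie-corrected Spearman correlations are computed with
    two-sided t-approximation p-values; a pair is an edge iff
    p <= alpha / C(p,2).  Pairs involving a constant species get p = 1.
    """
    x = np.asarray(values, dtype=float)
    p, n = x.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    ranks = np.vstack([stats.rankdata(row, method="average") for row in x])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    pvals = np.ones((p, p))
    iu = np.triu_indices(p, k=1)
    r = rho[iu]
    valid = np.isfinite(r)
    pv = np.ones(len(r))
    rr = r[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
        perfect = np.abs(rr) >= 1.0
        t[perfect] = np.inf * np.sign(rr[perfect])
    pv[valid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals[iu] = pv
    pvals = np.minimum(pvals, pvals.T)
    np.fill_diagonal(pvals, 1.0)

    n_tests = p * (p - 1) // 2
    cutoff = alpha / n_tests
    adjacency = (pvals <= cutoff).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return InferredNetwork(
        adjacency=adjacency,
        backend="scc",
        detail={"p_values": pvals, "rho": rho, "alpha": alpha, "cutoff": cutoff},
    )


# ---------------------------------------------------------------------------
# graphical lasso


def _lambda_path(cov: np.ndarray, n_lambda: int, ratio: float) -> np.ndarray:
    off = cov - np.diag(np.diag(cov))
    lam_max = float(np.abs(off).max())
    if lam_max <= 0.0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), n_lambda)


def _glasso_one(
    cov: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 200,
    support_eps: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """One glasso solve with exact connected-component block screening.

    The solution is block-diagonal over the connected components of the
    graph with edges |S_ij| > lambda, so each component is solved
    independently — a large speedup on the sparse end of the path.
    """
    p = cov.shape[0]
    mask = np.abs(cov) > lam
    np.fill_diagonal(mask, False)
    n_comp, labels = connected_components(csr_matrix(mask), directed=False)
    prec = np.zeros_like(cov)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in range(n_comp):
            idx = np.flatnonzero(labels == c)
            if len(idx) == 1:
                # sklearn's convention: the diagonal is not penalized
                prec[idx[0], idx[0]] = 1.0 / cov[idx[0], idx[0]]
                continue
            sub = cov[np.ix_(idx, idx)]
            _, sub_prec = graphical_lasso(sub, alpha=float(lam), tol=tol, max_iter=max_iter)
            prec[np.ix_(idx, idx)] = sub_prec
    supp = (np.abs(prec) > support_eps).astype(np.int8)
    np.fill_diagonal(supp, 0)
    supp = np.maximum(supp, supp.T)
    return supp, prec


def _glasso_supports(
    cov: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[list[np.ndarray | None], list[np.ndarray | None]]:
    """Glasso supports along a lambda path; failures flagged as None."""
    supports: list[np.ndarray | None] = []
    precisions: list[np.ndarray | None] = []
    for lam in lambdas:
        try:
            supp, prec = _glasso_one(cov, float(lam), tol=tol, max_iter=max_iter)
            supports.append(supp)
            precisions.append(prec)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            supports.append(None)
            precisions.append(None)
    return supports, precisions


def glasso_path(
    values: np.ndarray,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
    return_precisions: bool = False,
):
    """Graphical-lasso support path over a log-spaced lambda grid.

    The path runs from lambda_max (the smallest penalty giving an empty
    graph: the largest absolute off-diagonal sample covariance) down to
    ``lambda_min_ratio * lambda_max``.  Lambdas where the solver fails
    are flagged as None and the path continues.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    cov = np.cov(x)
    lambdas = _lambda_path(cov, n_lambda, lambda_min_ratio)
    supports, precisions = _glasso_supports(cov, lambdas)
    if return_precisions:
        return lambdas, supports, precisions
    return lambdas, supports


def stars_select(
    values: np.ndarray,
    config: StarsConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> InferredNetwork:
    """StARS: pick the densest lambda whose edge set is stable.

    Draws ``n_subsamples`` subsamples of size b(n) = floor(10 sqrt(n))
    without replacement, computes per-lambda edge frequencies theta and
    the instability 2*theta*(1-theta) averaged over pairs, monotonizes
    the instability path from the sparse end by a cumulative max, and
    selects the smallest lambda still under the threshold.  The final
    adjacency is the glasso support at that lambda on the full table.
    """
    cfg = config or StarsConfig()
    x = np.asarray(values, dtype=float)
    p, n = x.shape
    rng = np.random.default_rng(seed)
    b = cfg.subsample_size(n)

    cov_full = np.cov(x)
    lambdas = _lambda_path(cov_full, cfg.n_lambda, cfg.lambda_min_ratio)
    cov_subs = [np.cov(x[:, rng.choice(n, size=b, replace=False)]) for _ in range(cfg.n_subsamples)]

    iu = np.triu_indices(p, k=1)

    def _instability_at(k: int) -> float:
        freq = np.zeros(len(iu[0]))
        cnt = 0
        for cov_sub in cov_subs:
            try:
                supp, _ = _glasso_one(
                    cov_sub,
                    float(lambdas[k]),
                    tol=cfg.subsample_tol,
                    max_iter=cfg.subsample_max_iter,
                )
            except (FloatingPointError, np.linalg.LinAlgError, ValueError):
                continue
            freq += supp[iu]
            cnt += 1
        if cnt == 0:
            return float("inf")
        theta = freq / cnt
        return float((2.0 * theta * (1.0 - theta)).mean())

    # lambdas are sorted descending: index 0 is the sparsest graph.  The
    # monotonized (cumulative-max) instability can only grow along the
    # path, so once it exceeds the threshold no denser lambda is
    # selectable and the rest of the path need not be computed.
    instability = np.full(cfg.n_lambda, np.nan)
    monotone = np.full(cfg.n_lambda, np.nan)
    running_max = -np.inf
    last_eligible = None
    for k in range(cfg.n_lambda):
        instability[k] = _instability_at(k)
        running_max = max(running_max, instability[k])
        monotone[k] = running_max
        if running_max <= cfg.instability_threshold:
            last_eligible = k
        else:
            break

    if last_eligible is not None:
        sel = last_eligible
        fallback = False
    else:
        # even the sparsest lambda is unstable: fall back to the most
        # stable lambda over the whole path
        for k in range(cfg.n_lambda):
            if np.isnan(instability[k]):
                instability[k] = _instability_at(k)
        monotone = np.maximum.accumulate(instability)
        sel = int(np.nanargmin(instability))
        fallback = True
        warnings.warn("no lambda met the instability threshold; using the most stable one")

    adjacency = None
    try:
        adjacency, _ = _glasso_one(cov_full, float(lambdas[sel]))
    except (FloatingPointError, np.linalg.LinAlgError, ValueError):
        pass
    if adjacency is None:  # solver failed at the selected lambda on full data
        supports_full, _ = _glasso_supports(cov_full, lambdas)
        good = [k for k, s in enumerate(supports_full) if s is not None]
        sel = min(good, key=lambda k: abs(k - sel)) if good else sel
        adjacency = supports_full[sel] if supports_full[sel] is not None else np.zeros((p, p), np.int8)
    return InferredNetwork(
        adjacency=adjacency.astype(np.int8),
        backend="glasso",
        detail={
            "lambdas": lambdas,
            "selected_lambda": float(lambdas[sel]),
            "selected_index": sel,
            "instability": instability,
            "monotone_instability": monotone,
            "fallback": fallback,
            "subsample_size": b,
        },
    )


#: backend registry; third-party methods can be plugged in by name
BACKENDS = {
    "scc": scc_network,
    "glasso": stars_select,
}
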