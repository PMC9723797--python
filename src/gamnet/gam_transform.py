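"""Normalization and per-species GAM detrending of time-series tables.

Each species' normalized abundance series is modelled as

    y_t = beta0 + f_cyc(month_t) + f_smooth(day_t) + eps_t

where ``f_cyc`` is a cyclic P-spline with period 12 months, ``f_smooth``
a penalized B-spline over the sample index, and ``eps`` follows one of
six serial-correlation families (continuous AR1 by default).  Smoothing
parameters are chosen by GCV inside an iterated feasible-GLS loop; the
response-scale residuals ``y - fitted mean`` become the detrended
abundance values used for network inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, cho_factor, cho_solve, cholesky, solve_triangular
from statsmodels.stats.diagnostic import acorr_ljungbox

from .simulate import SEASONAL_PERIOD, CountTable

__all__ = [
    "NormalizedTable",
    "GamFitResult",
    "TransformedTable",
    "AutocorrCheck",
    "normalize",
    "fit_species_gam",
    "check_residual_autocorrelation",
    "revise_correlation_structure",
    "gam_detrend",
    "CORRELATION_FAMILIES",
    "REVISION_CANDIDATES",
]

CORRELATION_FAMILIES = ("car1", "ar1", "compsymm", "exp", "gauss", "none")
#: revision candidates in the fixed tie-break order
REVISION_CANDIDATES = ("ar1", "compsymm", "exp", "gauss")


# ---------------------------------------------------------------------------
# containers


@dataclass
class NormalizedTable:
    values: np.ndarray  # p x n
    method: str
    month: np.ndarray | None = None
    day: np.ndarray | None = None
    species_ids: list[str] = field(default_factory=list)


@dataclass
class GamFitResult:
    """Outcome of one per-species GAM fit."""

    species_id: str
    residuals: np.ndarray  # response-scale residuals, length n
    corr_structure: str
    converged: bool
    autocorr_ok: bool | None = None
    whitened_residuals: np.ndarray | None = None
    fit_stats: dict = field(default_factory=dict)
    warning: str | None = None


@dataclass
class TransformedTable:
    """Detrended table: row i holds per_species[i].residuals."""

    values: np.ndarray
    per_species: list[GamFitResult]
    species_ids: list[str] = field(default_factory=list)


@dataclass
class AutocorrCheck:
    ok: bool
    p_value: float
    reason: str | None = None


# ---------------------------------------------------------------------------
# normalization

def _as_matrix(counts) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, list[str]]:
    if isinstance(counts, CountTable):
        return counts.rel_abundance, counts.month, counts.day, list(counts.species_ids)
    x = np.asarray(counts, dtype=float)
    return x, None, None, [f"sp{i + 1}" for i in range(x.shape[0])]


def normalize(counts, method: str = "clr") -> NormalizedTable:
    """Normalize a nonnegative species x sample table.

    clr
        centered log-ratio per sample; zeros are first replaced by a
        pseudocount of half the smallest nonzero value in the table.
    tss
        total sum scaling (closure to proportions).
    css
        cumulative sum scaling: each sample is divided by the summed
        counts up to its median nonzero quantile, rescaled by the median
        of those scaling factors, then log1p-transformed.
    mclr
        CLR over the nonzero entries of each sample, globally shifted so
        transformed nonzeros stay positive; zeros map to 0.
    """
    x, month, day, ids = _as_matrix(counts)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(x.sum(axis=0) == 0):
        raise ValueError("table contains an all-zero sample")

    if method == "clr":
        work = x.astype(float).copy()
        if np.any(work == 0):
            pseudo = 0.5 * work[work > 0].min()
            work[work == 0] = pseudo
        logs = np.log(work)
        values = logs - logs.mean(axis=0, keepdims=True)
    elif method == "tss":
        values = x / x.sum(axis=0, keepdims=True)
    elif method == "css":
        values = _css(x)
    elif method == "mclr":
        values = _mclr(x)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return NormalizedTable(values=values, method=method, month=month, day=day, species_ids=ids)


def _css(x: np.ndarray, quantile: float = 0.5) -> np.ndarray:
    p, n = x.shape
    scale = np.empty(n)
    for j in range(n):
        col = x[:, j]
        nz = col[col > 0]
        q = np.quantile(nz, quantile)
        scale[j] = col[col <= q].sum()
        if scale[j] == 0:  # all mass above the quantile
            scale[j] = nz.sum()
    norm = x / scale * np.median(scale)
    return np.log1p(norm)


def _mclr(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        nz = col > 0
        logs = np.log(col[nz])
        out[nz, j] = logs - logs.mean()
    nzvals = out[x > 0]
    if nzvals.size:
        shift = -nzvals.min() + 1.0
        out[x > 0] += shift
    return out


# ---------------------------------------------------------------------------
# spline bases (P-splines: B-spline bases with difference penalties)


def cyclic_bspline_basis(x: np.ndarray, period: float, n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic cubic B-spline basis on [0, period) with wrapped columns.

    Returns the n x n_basis design matrix and the n_basis x n_basis
    cyclic second-difference penalty.
    """
    k = n_basis
    h = period / k
    knots = h * np.arange(-3, k + 4, dtype=float)
    xm = np.mod(np.asarray(x, dtype=float), period)
    full = BSpline.design_matrix(xm, knots, 3).toarray()  # k + 3 active columns
    basis = np.zeros((len(xm), k))
    for j in range(full.shape[1]):
        basis[:, j % k] += full[:, j]
    d = np.zeros((k, k))
    for j in range(k):
        d[j, (j - 1) % k] = 1.0
        d[j, j] = -2.0
        d[j, (j + 1) % k] = 1.0
    return basis, d.T @ d


def bspline_basis(x: np.ndarray, n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis over the range of x with a 2nd-difference penalty."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    nseg = n_basis - 3
    if nseg < 1:
        raise ValueError("n_basis must be at least 4")
    h = (hi - lo) / nseg
    knots = lo + h * np.arange(-3, nseg + 4, dtype=float)
    basis = BSpline.design_matrix(np.clip(x, lo, hi), knots, 3).toarray()
    d = np.diff(np.eye(n_basis), n=2, axis=0)
    return basis, d.T @ d


def _absorb_constant(basis: np.ndarray, penalty: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absorb the sum-to-zero identifiability constraint into a smooth block.

    B-spline bases form a partition of unity, so the all-ones coefficient
    direction duplicates the intercept and (for difference penalties) is
    unpenalized, making the normal matrix exactly singular.  Reparametrize
    onto the orthogonal complement of that direction and centre columns.
    """
    k = basis.shape[1]
    u = np.full((k, 1), 1.0 / np.sqrt(k))
    q_full, _ = np.linalg.qr(np.hstack([u, np.eye(k)[:, : k - 1]]))
    q = q_full[:, 1:]  # orthonormal complement of the constant direction
    b = basis @ q
    b -= b.mean(axis=0, keepdims=True)
    return b, q.T @ penalty @ q


def _design(month: np.ndarray, day: np.ndarray, month_df: int, day_df: int):
    bm, pm = cyclic_bspline_basis(np.asarray(month, float) - 1.0, SEASONAL_PERIOD, month_df)
    bd, pd_ = bspline_basis(day, day_df)
    bm, pm = _absorb_constant(bm, pm)
    bd, pd_ = _absorb_constant(bd, pd_)
    n = len(month)
    z = np.hstack([np.ones((n, 1)), bm, bd])
    km, kd = bm.shape[1], bd.shape[1]
    k = 1 + km + kd
    pen_m = np.zeros((k, k))
    pen_m[1 : 1 + km, 1 : 1 + km] = pm
    pen_d = np.zeros((k, k))
    pen_d[1 + km :, 1 + km :] = pd_
    return z, pen_m, pen_d


# ---------------------------------------------------------------------------
# correlation families


def _estimate_theta(resid: np.ndarray, family: str) -> float:
    n = len(resid)
    r = resid - resid.mean()
    denom = float(r @ r)
    if denom <= 1e-300:
        return 0.0
    phi1 = float(r[:-1] @ r[1:]) / denom
    if family == "car1":
        return float(np.clip(phi1, 0.0, 0.95))
    if family == "ar1":
        return float(np.clip(phi1, -0.95, 0.95))
    if family == "compsymm":
        total = float(r.sum())
        sigma2 = denom / n
        rho = (total**2 / sigma2 - n) / (n * (n - 1))
        return float(np.clip(rho, 0.0, 0.95))
    if family in ("exp", "gauss"):
        return float(np.clip(phi1, 1e-3, 0.95))
    return 0.0


def _correlation_matrix(theta: float, days: np.ndarray, family: str) -> np.ndarray | None:
    """Working correlation R(theta); None signals the identity."""
    if family == "none" or theta == 0.0:
        return None
    d = np.abs(days[:, None] - days[None, :]).astype(float)
    if family in ("car1", "ar1"):
        return theta**d
    if family == "compsymm":
        n = len(days)
        return (1.0 - theta) * np.eye(n) + theta * np.ones((n, n))
    if family == "exp":
        rng = -1.0 / np.log(theta)  # lag-1 correlation = theta
        return np.exp(-d / rng)
    if family == "gauss":
        rng = 1.0 / np.sqrt(-np.log(theta))
        return np.exp(-((d / rng) ** 2))
    raise ValueError(f"unknown correlation family {family!r}")


# ---------------------------------------------------------------------------
# penalized GLS fitting


_LAMBDA_GRID = 10.0 ** np.arange(-2.0, 6.0, 1.5)  # 6 values per smooth


def _pgls_solve(
    zw: np.ndarray,
    yw: np.ndarray,
    pen_m: np.ndarray,
    pen_d: np.ndarray,
    fixed_lambdas: tuple[float, float] | None = None,
):
    """Penalized LS on whitened data; GCV grid search unless lambdas fixed."""
    n = len(yw)
    g = zw.T @ zw
    c = zw.T @ yw
    if fixed_lambdas is not None:
        grid = [fixed_lambdas]
    else:
        grid = [(lm, ld) for lm in _LAMBDA_GRID for ld in _LAMBDA_GRID]
    best = None
    for lam_m, lam_d in grid:
        m = g + lam_m * pen_m + lam_d * pen_d
        try:
            cf = cho_factor(m, lower=True)
        except LinAlgError:
            continue
        beta = cho_solve(cf, c)
        edf = float(np.trace(cho_solve(cf, g)))
        rss = float(np.sum((yw - zw @ beta) ** 2))
        if n - edf <= 1.0:
            continue
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, beta, edf, lam_m, lam_d)
    if best is None:
        raise LinAlgError("penalized GLS solve failed on the whole smoothing grid")
    return best


def fit_species_gam(
    y: np.ndarray,
    month: np.ndarray,
    day: np.ndarray,
    corr_structure: str = "car1",
    species_id: str = "sp",
    month_df: int = 8,
    day_df: int = 10,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> GamFitResult:
    """Fit one species' GAM by iterated feasible GLS.

    Alternates (i) a penalized weighted least-squares fit of the mean on
    the whitened data with GCV smoothing selection and (ii) a moment
    estimate of the correlation-family parameter from the current
    residuals, until the parameter stabilizes.  Residuals are reported
    on the response scale (``y`` minus the fitted mean).
    """
    if corr_structure not in CORRELATION_FAMILIES:
        raise ValueError(f"unknown correlation structure {corr_structure!r}")
    y = np.asarray(y, dtype=float)
    day = np.asarray(day, dtype=float)
    n = len(y)
    if len(month) != n or len(day) != n:
        raise ValueError("month/day predictors must align with y")
    z, pen_m, pen_d = _design(np.asarray(month), day, month_df, day_df)

    theta = 0.0
    beta = None
    stats: dict = {}
    converged = False
    whitened = None
    fixed = None
    try:
        for it in range(max_iter):
            r = _correlation_matrix(theta, day, corr_structure)
            if r is None:
                zw, yw = z, y
            else:
                lchol = cholesky(r + 1e-8 * np.eye(n), lower=True)
                zw = solve_triangular(lchol, z, lower=True)
                yw = solve_triangular(lchol, y, lower=True)
            # full GCV search on the identity fit and the first whitened
            # refit; afterwards the smoothing parameters are frozen
            gcv, beta, edf, lam_m, lam_d = _pgls_solve(zw, yw, pen_m, pen_d, fixed_lambdas=fixed)
            if it >= 1:
                fixed = (lam_m, lam_d)
            resid = y - z @ beta
            whitened = yw - zw @ beta
            stats = {
                "gcv": gcv,
                "edf": edf,
                "lambda_month": lam_m,
                "lambda_day": lam_d,
                "theta": theta,
            }
            if corr_structure == "none":
                converged = True
                break
            theta_new = _estimate_theta(resid, corr_structure)
            if abs(theta_new - theta) < tol:
                converged = True
                theta = theta_new
                stats["theta"] = theta
                break
            theta = theta_new
    except (LinAlgError, np.linalg.LinAlgError, FloatingPointError) as exc:
        return GamFitResult(
            species_id=species_id,
            residuals=y - (z @ beta if beta is not None else y.mean()),
            corr_structure=corr_structure,
            converged=False,
            whitened_residuals=whitened,
            fit_stats=stats,
            warning=f"fit failed: {exc}",
        )

    # response-scale residuals, centred: under GLS the intercept is
    # orthogonal to the residuals only in the whitened metric, and the
    # downstream rank/correlation backends are location-invariant
    resid = y - z @ beta
    resid = resid - resid.mean()
    return GamFitResult(
        species_id=species_id,
        residuals=resid,
        corr_structure=corr_structure,
        converged=converged,
        whitened_residuals=whitened if whitened is not None else resid,
        fit_stats=stats,
    )


# ---------------------------------------------------------------------------
# residual autocorrelation check


def check_residual_autocorrelation(
    residuals: np.ndarray,
    alpha: float = 0.05,
    lags: int | None = None,
) -> AutocorrCheck:
    """Ljung–Box portmanteau test for leftover serial correlation.

    The default lag window is min(12, n // 5), covering the seasonal lag
    when the series is long enough.  Degenerate (constant) inputs fail
    the check with a reason rather than raising.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 8 or float(np.std(r)) < 1e-12:
        return AutocorrCheck(ok=False, p_value=float("nan"), reason="degenerate")
    lag = lags if lags is not None else max(1, min(12, n // 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = acorr_ljungbox(r, lags=[lag], return_df=True)
    p = float(table["lb_pvalue"].iloc[0])
    if not np.isfinite(p):
        return AutocorrCheck(ok=False, p_value=p, reason="test undefined")
    return AutocorrCheck(ok=p >= alpha, p_value=p)


# ---------------------------------------------------------------------------
# group revision of the correlation structure


def _fit_and_check(y, month, day, structure, species_id, alpha, **kw) -> GamFitResult:
    fit = fit_species_gam(y, month, day, corr_structure=structure, species_id=species_id, **kw)
    if fit.converged:
        check = check_residual_autocorrelation(fit.whitened_residuals, alpha=alpha)
        fit.autocorr_ok = check.ok
        fit.fit_stats["lb_pvalue"] = check.p_value
    else:
        fit.autocorr_ok = False
        fit.fit_stats["lb_pvalue"] = float("nan")
    return fit


def revise_correlation_structure(
    failed_species: Sequence[int],
    values: np.ndarray,
    month: np.ndarray,
    day: np.ndarray,
    species_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    **fit_kw,
) -> tuple[dict[int, str], dict[int, GamFitResult]]:
    """Refit species that failed under CAR1 with 4 alternative structures.

    Every candidate (AR1, CompSymm, Exp, Gauss) is fit to every failed
    species; the single candidate that fixes (converged and no residual
    autocorrelation) the most species is adopted for the whole group,
    ties broken by the fixed candidate order.  Species the winner still
    fails keep the winner's fit, flagged with a warning.
    """
    failed = list(failed_species)
    if not failed:
        return {}, {}
    ids = list(species_ids) if species_ids is not None else [f"sp{i + 1}" for i in range(values.shape[0])]
    fits_by_candidate: dict[str, dict[int, GamFitResult]] = {}
    n_fixed: dict[str, int] = {}
    for cand in REVISION_CANDIDATES:
        fits = {
            i: _fit_and_check(values[i], month, day, cand, ids[i], alpha, **fit_kw)
            for i in failed
        }
        fits_by_candidate[cand] = fits
        n_fixed[cand] = sum(1 for f in fits.values() if f.converged and f.autocorr_ok)
    winner = max(REVISION_CANDIDATES, key=lambda c: (n_fixed[c], -REVISION_CANDIDATES.index(c)))
    mapping = {i: winner for i in failed}
    chosen = fits_by_candidate[winner]
    for i, fit in chosen.items():
        if not (fit.converged and fit.autocorr_ok):
            fit.warning = (fit.warning or "") + " unresolved after revision"
    return mapping, chosen


# ---------------------------------------------------------------------------
# whole-table transform


def gam_detrend(
    table: NormalizedTable | np.ndarray,
    month: np.ndarray | None = None,
    day: np.ndarray | None = None,
    alpha: float = 0.05,
    **fit_kw,
) -> TransformedTable:
    """Detrend every species and return the residual table.

    Pipeline per species: CAR1 GAM fit, Ljung–Box check on the whitened
    residuals, then a single group revision of the correlation structure
    for species the CAR1 model could not resolve.
    """
    if isinstance(table, NormalizedTable):
        values = table.values
        month = table.month if month is None else month
        day = table.day if day is None else day
        ids = table.species_ids
    else:
        values = np.asarray(table, dtype=float)
        ids = [f"sp{i + 1}" for i in range(values.shape[0])]
    if month is None or day is None:
        raise ValueError("month and day predictors are required")
    month = np.asarray(month)
    day = np.asarray(day)

    fits: list[GamFitResult] = []
    failed: list[int] = []
    for i in range(values.shape[0]):
        fit = _fit_and_check(values[i], month, day, "car1", ids[i], alpha, **fit_kw)
        fits.append(fit)
        if not (fit.converged and fit.autocorr_ok):
            failed.append(i)
    if failed:
        _, revised = revise_correlation_structure(
            failed, values, month, day, species_ids=ids, alpha=alpha, **fit_kw
        )
        for i, fit in revised.items():
            fits[i] = fit
    residual_matrix = np.vstack([f.residuals for f in fits])
    return TransformedTable(values=residual_matrix, per_species=fits, species_ids=list(ids))
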