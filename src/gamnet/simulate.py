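"""Truth-labelled mock time-series community simulator.

Generates species abundance tables with a predetermined association
network, multiplicative seasonal contamination (a 12-sample-period
cosine envelope, either gradual or its 10th power, "abrupt"), additive
long-term linear trends, exponentiation and compositional closure to
relative abundances — the world in which the detrending transform is
benchmarked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TrueNetwork",
    "SimulationCondition",
    "CountTable",
    "Dataset",
    "make_er_graph",
    "make_ba_graph",
    "user_graph",
    "graph_to_covariance",
    "draw_abundances",
    "seasonal_vector",
    "apply_seasonal",
    "longterm_vector",
    "apply_longterm",
    "to_count_table",
    "enumerate_conditions",
    "simulate_dataset",
    "COVARIANCE_LEVELS",
]

#: covariance placed on true association edges: "high" and "low" regimes
COVARIANCE_LEVELS = {"high": 100.0, "low": 10.0}

SEASONAL_PERIOD = 12


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class TrueNetwork:
    """Ground-truth association structure of a mock community.

    ``adjacency`` is a symmetric 0/1 matrix with zero diagonal;
    ``covariance`` carries the level value (100 or 10) exactly on the
    edge support, with the diagonal loaded just enough to be positive
    definite (the loading applied is recorded in ``diag_loading``).
    """

    adjacency: np.ndarray
    covariance: np.ndarray
    topology_label: str
    covariance_level: float
    diag_loading: float = 0.0

    @property
    def n_species(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation grid."""

    topology: str  # er | ba | user_supplied
    covariance_level: str  # high | low
    seasonal_fraction: float  # 0, 0.25, 0.5 or 1.0
    seasonal_shape: str | None  # gradual | abrupt | None when fraction == 0
    longterm_fraction: float  # 0 or 0.5
    n_species: int = 400
    n_samples: int = 200

    def label(self) -> str:
        shape = self.seasonal_shape or "none"
        return (
            f"{self.topology}-{self.covariance_level}"
            f"-seas{self.seasonal_fraction:g}{shape}"
            f"-lt{self.longterm_fraction:g}"
        )


@dataclass
class CountTable:
    """Compositional relative-abundance table with time predictors.

    Columns (samples) sum to one; ``month`` is 1..12 cycling with the
    assumed monthly cadence and ``day`` is the 1-based sample index.
    """

    rel_abundance: np.ndarray
    month: np.ndarray
    day: np.ndarray
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species_ids:
            p = self.rel_abundance.shape[0]
            self.species_ids = [f"sp{i + 1}" for i in range(p)]


@dataclass
class Dataset:
    """A fully simulated dataset bundle: truth, latent signal, counts."""

    truth: TrueNetwork
    latent: np.ndarray  # contaminated abundances X before exp/closure
    counts: CountTable
    condition: SimulationCondition
    seasonal_species: np.ndarray
    longterm_species: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# graph topologies


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(adj, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    return adj.astype(np.int8)


def make_er_graph(p: int, edge_prob: float = 0.01, seed: int | None = None) -> np.ndarray:
    """Erdős–Rényi adjacency: each unordered pair is an edge w.p. ``edge_prob``."""
    if p < 2:
        raise ValueError("need at least 2 species")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must be in [0, 1], got {edge_prob}")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    edges = rng.random(len(iu[0])) < edge_prob
    adj = np.zeros((p, p), dtype=np.int8)
    adj[iu] = edges
    return adj + adj.T


def make_ba_graph(p: int, m_attach: int = 1, seed: int | None = None) -> np.ndarray:
    """Barabási–Albert preferential-attachment adjacency (a tree for m=1)."""
    if p < 2:
        raise ValueError("need at least 2 species")
    g = nx.barabasi_albert_graph(p, m_attach, seed=int(seed) if seed is not None else None)
    return nx.to_numpy_array(g, dtype=np.int8)


def user_graph(adjacency: np.ndarray) -> np.ndarray:
    """Validate a user-supplied adjacency (e.g. derived from a real dataset)."""
    return _check_adjacency(adjacency)


# ---------------------------------------------------------------------------
# covariance and abundance draws


def graph_to_covariance(
    adjacency: np.ndarray,
    covariance_level: float,
    base_variance: float = 25.0,
) -> tuple[np.ndarray, float]:
    """Place ``covariance_level`` on every edge and condition to PD.

    The diagonal starts at ``base_variance``; if the smallest eigenvalue
    is not positive, |lambda_min| + 1e-3 is added to the whole diagonal
    (diagonal loading).  Returns ``(covariance, loading_applied)``.
    """
    adj = _check_adjacency(adjacency)
    cov = adj.astype(float) * float(covariance_level)
    np.fill_diagonal(cov, base_variance)
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    loading = 0.0
    if lam_min <= 0.0:
        loading = -lam_min + 1e-3
        cov[np.diag_indices_from(cov)] += loading
        lam_min_after = float(np.linalg.eigvalsh(cov)[0])
        if lam_min_after <= 0.0:
            raise np.linalg.LinAlgError(
                f"covariance conditioning failed: smallest eigenvalue {lam_min_after:g}"
            )
    return cov, loading


def draw_abundances(
    covariance: np.ndarray,
    n_samples: int,
    seed: int | None = None,
    mean_loc: float = 10.0,
    mean_var: float = 1.0,
) -> np.ndarray:
    """Draw a p x n abundance matrix from MVN(mu, covariance).

    Per-species means mu_i are drawn once from Normal(mean_loc, mean_var);
    the n sample columns are i.i.d. draws sharing those means.
    """
    cov = np.asarray(covariance, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    rng = np.random.default_rng(seed)
    p = cov.shape[0]
    mu = rng.normal(mean_loc, np.sqrt(mean_var), size=p)
    z = rng.standard_normal((p, n_samples))
    return mu[:, None] + chol @ z


# ---------------------------------------------------------------------------
# time-series contamination


def seasonal_vector(shape: str, n: int, phase_start: int = 0) -> np.ndarray:
    """12-period cosine seasonal envelope S_t in [0, 1].

    gradual: S_t = cos(N_t * 2π/12)/2 + 0.5 with N_t = phase_start, phase_start+1, ...
    abrupt:  the gradual form raised to the 10th power (narrow annual peak).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_t = np.arange(phase_start, phase_start + n, dtype=float)
    s = np.cos(n_t * 2.0 * np.pi / SEASONAL_PERIOD) / 2.0 + 0.5
    if shape == "gradual":
        return s
    if shape == "abrupt":
        return s**10
    raise ValueError(f"unknown seasonal shape {shape!r}")


def apply_seasonal(
    values: np.ndarray,
    which_species: Sequence[int],
    shape: str,
    seed: int | None = None,
) -> np.ndarray:
    """Multiply selected species rows by a seasonal envelope.

    Each selected species receives an independent random phase (uniform
    over the 12 months) so peaks centre on different months.
    """
    out = np.array(values, dtype=float, copy=True)
    rng = np.random.default_rng(seed)
    n = out.shape[1]
    for i in which_species:
        phase = int(rng.integers(0, SEASONAL_PERIOD))
        out[i] *= seasonal_vector(shape, n, phase)
    return out


def longterm_vector(
    n: int,
    seed: int | None = None,
    recursion_mode: str = "additive",
    slope: float | None = None,
    sign: int | None = None,
) -> np.ndarray:
    """Long-term linear trend vector L_t.

    The slope m is drawn from Normal(0.01, variance 0.01) and negated
    with probability 1/2 unless ``slope``/``sign`` are given.  The
    default ``additive`` mode builds the line L_1 = 0.01,
    L_t = L_{t-1} ± m; ``as_printed`` iterates the literal recursion
    L_t = (±m)·L_{t-1} + 0.01, which converges to a constant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = float(rng.normal(0.01, np.sqrt(0.01))) if slope is None else float(slope)
    s = (1 if rng.random() < 0.5 else -1) if sign is None else int(sign)
    trend = np.empty(n)
    trend[0] = 0.01
    if recursion_mode == "additive":
        trend = 0.01 + s * m * np.arange(n, dtype=float)
    elif recursion_mode == "as_printed":
        for t in range(1, n):
            trend[t] = s * m * trend[t - 1] + 0.01
    else:
        raise ValueError(f"unknown recursion_mode {recursion_mode!r}")
    return trend


def apply_longterm(
    values: np.ndarray,
    which_species: Sequence[int],
    seed: int | None = None,
    recursion_mode: str = "additive",
) -> np.ndarray:
    """Add an independent long-term trend to each selected species row."""
    out = np.array(values, dtype=float, copy=True)
    rng = np.random.default_rng(seed)
    n = out.shape[1]
    for i in which_species:
        out[i] += longterm_vector(n, seed=rng, recursion_mode=recursion_mode)
    return out


# ---------------------------------------------------------------------------
# count table construction


def to_count_table(
    values: np.ndarray,
    zero_inflation_frac: float = 0.0,
    seed: int | None = None,
    species_ids: Iterable[str] | None = None,
) -> CountTable:
    """Exponentiate abundances and close each sample to relative abundance.

    Exponentiation (base e) skews the community so few species dominate,
    emulating tag-sequencing relative abundances.  An optional fraction
    of entries is zeroed uniformly at random before closure to mimic
    zero-inflation.  The month predictor assumes monthly cadence:
    month = ((day-1) mod 12) + 1.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("abundance values must be finite")
    counts = np.exp(x)
    if zero_inflation_frac:
        if not 0.0 <= zero_inflation_frac < 1.0:
            raise ValueError("zero_inflation_frac must be in [0, 1)")
        rng = np.random.default_rng(seed)
        n_zero = int(round(zero_inflation_frac * counts.size))
        flat = rng.choice(counts.size, size=n_zero, replace=False)
        counts.flat[flat] = 0.0
    col_sums = counts.sum(axis=0)
    if np.any(col_sums == 0.0):
        raise ValueError("a sample lost all species to zero-inflation; cannot close")
    rel = counts / col_sums
    n = x.shape[1]
    day = np.arange(1, n + 1)
    month = (day - 1) % SEASONAL_PERIOD + 1
    ids = list(species_ids) if species_ids is not None else []
    return CountTable(rel_abundance=rel, month=month, day=day, species_ids=ids)


# ---------------------------------------------------------------------------
# the condition grid and full-dataset assembly

_DEFAULT_TOPOLOGIES = ("er", "ba", "user_supplied")
_DEFAULT_SEASONAL_FRACTIONS = (0.25, 0.5, 1.0)


def enumerate_conditions(
    topologies: Sequence[str] = _DEFAULT_TOPOLOGIES,
    covariance_levels: Sequence[str] = ("high", "low"),
    longterm_fractions: Sequence[float] = (0.0, 0.5),
    seasonal_shapes: Sequence[str] = ("gradual", "abrupt"),
    seasonal_fractions: Sequence[float] = _DEFAULT_SEASONAL_FRACTIONS,
    n_species: int = 400,
    n_samples: int = 200,
) -> list[SimulationCondition]:
    """Enumerate the simulation grid, collapsing duplicate cells.

    A 0% seasonal fraction makes the seasonal shape irrelevant, so the
    no-seasonality cell appears once per (topology, covariance,
    long-term) combination.  The default grid therefore has
    3 x 2 x 2 x (1 + 2 x 3) = 84 conditions.
    """
    seasonal_cells: list[tuple[float, str | None]] = [(0.0, None)]
    for shape in seasonal_shapes:
        for frac in seasonal_fractions:
            if frac > 0.0:
                seasonal_cells.append((frac, shape))
    conditions = []
    for topo, cov, lt, (sf, shape) in itertools.product(
        topologies, covariance_levels, longterm_fractions, seasonal_cells
    ):
        conditions.append(
            SimulationCondition(
                topology=topo,
                covariance_level=cov,
                seasonal_fraction=sf,
                seasonal_shape=shape,
                longterm_fraction=lt,
                n_species=n_species,
                n_samples=n_samples,
            )
        )
    return conditions


def simulate_dataset(
    condition: SimulationCondition,
    seed: int | np.random.SeedSequence,
    edge_prob: float = 0.01,
    base_variance: float = 25.0,
    zero_inflation_frac: float = 0.0,
    user_adjacency: np.ndarray | None = None,
    recursion_mode: str = "additive",
) -> Dataset:
    """Assemble one truth-labelled dataset for a grid condition.

    Pipeline: topology -> covariance -> MVN abundances -> multiplicative
    seasonal envelope on a random species subset -> additive long-term
    trends on a random subset -> exponentiation and compositional
    closure with time predictors.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    seeds = ss.spawn(5)
    p, n = condition.n_species, condition.n_samples

    if condition.topology == "er":
        adj = make_er_graph(p, edge_prob, seed=seeds[0])
    elif condition.topology == "ba":
        adj = make_ba_graph(p, seed=int(np.random.default_rng(seeds[0]).integers(2**31)))
    elif condition.topology == "user_supplied":
        if user_adjacency is None:
            raise ValueError("user_supplied topology requires user_adjacency")
        adj = user_graph(user_adjacency)
        if adj.shape[0] != p:
            raise ValueError("user adjacency size does not match condition n_species")
    else:
        raise ValueError(f"unknown topology {condition.topology!r}")

    level = COVARIANCE_LEVELS[condition.covariance_level]
    cov, loading = graph_to_covariance(adj, level, base_variance=base_variance)
    truth = TrueNetwork(adj, cov, condition.topology, level, loading)

    x = draw_abundances(cov, n, seed=seeds[1])

    rng = np.random.default_rng(seeds[2])
    n_seasonal = int(round(condition.seasonal_fraction * p))
    seasonal_species = np.sort(rng.choice(p, size=n_seasonal, replace=False))
    if n_seasonal:
        x = apply_seasonal(x, seasonal_species, condition.seasonal_shape, seed=rng)

    rng_lt = np.random.default_rng(seeds[3])
    n_lt = int(round(condition.longterm_fraction * p))
    longterm_species = np.sort(rng_lt.choice(p, size=n_lt, replace=False))
    if n_lt:
        x = apply_longterm(x, longterm_species, seed=rng_lt, recursion_mode=recursion_mode)

    counts = to_count_table(x, zero_inflation_frac=zero_inflation_frac, seed=seeds[4])
    seed_int = int(ss.generate_state(1)[0] % 2**31)
    return Dataset(
        truth=truth,
        latent=x,
        counts=counts,
        condition=condition,
        seasonal_species=seasonal_species,
        longterm_species=longterm_species,
        seed=seed_int,
    )
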