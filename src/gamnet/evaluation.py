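"""Scoring inferred networks against ground truth.

Edge-recovery metrics (confusion counts, precision/recall/F1 over
unordered species pairs), structural summaries (average clustering
coefficient, degree distribution), and the paired comparison of
detrended vs raw inference runs (Wilcoxon signed-rank with Bonferroni
correction, fraction-of-runs-improved summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EdgeConfusion",
    "confusion",
    "f1_score",
    "precision_recall",
    "avg_clustering",
    "degree_distribution",
    "compare_methods",
    "fraction_improved",
]


@dataclass(frozen=True)
class EdgeConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _upper(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    iu = np.triu_indices(adj.shape[0], k=1)
    return adj[iu].astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> EdgeConfusion:
    """Edge confusion counts over the strict upper triangle."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("adjacency shapes differ")
    a, b = _upper(pred), _upper(truth)
    return EdgeConfusion(
        tp=int(np.sum(a & b)),
        fp=int(np.sum(a & ~b)),
        fn=int(np.sum(~a & b)),
        tn=int(np.sum(~a & ~b)),
    )


def precision_recall(conf: EdgeConfusion) -> tuple[float, float]:
    precision = conf.tp / (conf.tp + conf.fp) if conf.tp + conf.fp else 0.0
    recall = conf.tp / (conf.tp + conf.fn) if conf.tp + conf.fn else 0.0
    return precision, recall


def f1_score(conf: EdgeConfusion) -> float:
    """Harmonic mean of edge precision and recall; 0 when tp = 0."""
    p, r = precision_recall(conf)
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def avg_clustering(adjacency: np.ndarray, include_low_degree: bool = True) -> float:
    """Mean local clustering coefficient.

    Nodes of degree < 2 contribute 0 by default (the common convention);
    set ``include_low_degree=False`` to average over degree >= 2 nodes only.
    """
    g = nx.from_numpy_array(np.asarray(adjacency))
    if include_low_degree:
        return float(nx.average_clustering(g))
    nodes = [v for v, d in g.degree() if d >= 2]
    if not nodes:
        return 0.0
    cc = nx.clustering(g, nodes)
    return float(np.mean(list(cc.values())))


def degree_distribution(adjacency: np.ndarray) -> pd.DataFrame:
    """Normalized degree histogram with log-log plotting coordinates."""
    adj = np.asarray(adjacency)
    degrees = adj.sum(axis=1).astype(int)
    values, counts = np.unique(degrees, return_counts=True)
    prob = counts / counts.sum()
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "degree": values,
                "count": counts,
                "probability": prob,
                "log10_degree": np.log10(values, where=values > 0, out=np.full(len(values), -np.inf)),
                "log10_probability": np.log10(prob),
            }
        )


# ---------------------------------------------------------------------------
# method comparison


def fraction_improved(f1_with: np.ndarray, f1_without: np.ndarray) -> float:
    """Fraction of paired runs where the detrended variant's F1 is strictly higher."""
    a = np.asarray(f1_with, dtype=float)
    b = np.asarray(f1_without, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired F1 vectors must have equal length")
    if a.size == 0:
        return float("nan")
    return float(np.mean(a > b))


_PAIRED = {"glasso": ("gam_glasso", "glasso"), "scc": ("gam_scc", "scc")}


def compare_methods(records: pd.DataFrame, alpha: float = 0.01) -> dict:
    """Per-condition paired Wilcoxon comparison of detrended vs raw runs.

    ``records`` needs columns: condition, replicate, method, f1 with
    methods named scc/gam_scc/glasso/gam_glasso.  Zero differences are
    handled with the Pratt method; p-values are Bonferroni-corrected
    over the condition-level comparisons actually performed.  Returns a
    dict with the per-condition table and the global fraction of runs
    improved per backend.
    """
    required = {"condition", "replicate", "method", "f1"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    rows = []
    overall: dict[str, float] = {}
    for backend, (gam_m, raw_m) in _PAIRED.items():
        sub = records[records["method"].isin([gam_m, raw_m])]
        if sub.empty:
            continue
        wide = sub.pivot_table(
            index=["condition", "replicate"], columns="method", values="f1", aggfunc="first"
        )
        wide = wide.dropna()
        if wide.empty:
            continue
        overall[backend] = fraction_improved(wide[gam_m].to_numpy(), wide[raw_m].to_numpy())
        for cond, grp in wide.groupby(level="condition"):
            a = grp[gam_m].to_numpy()
            b = grp[raw_m].to_numpy()
            diff = a - b
            if np.allclose(diff, 0.0):
                pval = 1.0
            else:
                pval = float(stats.wilcoxon(a, b, zero_method="pratt").pvalue)
            rows.append(
                {
                    "condition": cond,
                    "backend": backend,
                    "n_pairs": len(a),
                    "mean_f1_gam": float(a.mean()),
                    "mean_f1_raw": float(b.mean()),
                    "wilcoxon_p": pval,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        n_tests = len(table)
        table["wilcoxon_p_adj"] = np.minimum(table["wilcoxon_p"] * n_tests, 1.0)
        table["significant"] = table["wilcoxon_p_adj"] <= alpha
    return {
        "per_condition": table,
        "fraction_improved": overall,
        "n_comparisons": int(len(table)),
        "alpha": alpha,
    }
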