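"""On-disk dataset bundles.

A simulated dataset is written as plain-text files in one directory:
``counts.tsv`` (species rows x sample columns), ``predictors.tsv``
(sample_id, month, day), ``truth_adjacency.tsv`` and ``meta.yaml``
(condition, seed, covariance conditioning).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CountTable, Dataset, SimulationCondition, TrueNetwork

__all__ = ["write_dataset", "read_count_table", "read_truth_adjacency", "read_meta"]


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct = dataset.counts
    sample_ids = [f"s{d}" for d in ct.day]
    pd.DataFrame(ct.rel_abundance, index=ct.species_ids, columns=sample_ids).to_csv(
        out / "counts.tsv", sep="\t", index_label="species_id"
    )
    pd.DataFrame({"sample_id": sample_ids, "month": ct.month, "day": ct.day}).to_csv(
        out / "predictors.tsv", sep="\t", index=False
    )
    np.savetxt(out / "truth_adjacency.tsv", dataset.truth.adjacency, fmt="%d", delimiter="\t")
    meta = {
        "condition": asdict(dataset.condition),
        "seed": int(dataset.seed),
        "diag_loading": float(dataset.truth.diag_loading),
        "covariance_level": float(dataset.truth.covariance_level),
        "topology": dataset.truth.topology_label,
        "seasonal_species": [int(i) for i in dataset.seasonal_species],
        "longterm_species": [int(i) for i in dataset.longterm_species],
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return out


def read_count_table(bundle_dir: str | Path) -> CountTable:
    d = Path(bundle_dir)
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col="species_id")
    pred = pd.read_csv(d / "predictors.tsv", sep="\t")
    return CountTable(
        rel_abundance=counts.to_numpy(float),
        month=pred["month"].to_numpy(int),
        day=pred["day"].to_numpy(int),
        species_ids=list(counts.index),
    )


def read_truth_adjacency(bundle_dir: str | Path) -> np.ndarray:
    return np.loadtxt(Path(bundle_dir) / "truth_adjacency.tsv", delimiter="\t").astype(np.int8)


def read_meta(bundle_dir: str | Path) -> dict:
    return yaml.safe_load((Path(bundle_dir) / "meta.yaml").read_text())
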