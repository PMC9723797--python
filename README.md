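# gamnet

GAM-based detrending of microbial time-series abundance data prior to
co-occurrence network inference — plus a truth-labelled community
simulator and an edge-recovery benchmark for validating it.

## Why

Ecological association networks are routinely inferred from
time-series tag-sequencing surveys.  Shared temporal structure —
seasonal blooms, long-term trends, serial autocorrelation — makes
species co-occur without interacting, and network methods read that as
association.  `gamnet` fits each species a generalized additive model

    y_t = β₀ + f_cyc(month_t) + f_smooth(day_t) + ε_t,   ε_t ~ corCAR1 (default)

with a cyclic spline over month-of-year, a penalized spline over the
sample index, and serially correlated errors, then hands the *residuals*
to the network backend.  Residual covariation is a far better proxy for
biotic association than raw abundances when time structure is present.

The package also contains the full validation world: mock communities
with a known association network (Erdős–Rényi, Barabási–Albert, or
user-supplied), "high"/"low" covariance (100/10) on true edges,
gradual or abrupt (10th-power cosine) seasonal envelopes, additive
long-term trends, compositional closure; Spearman-Bonferroni ("SCC")
and graphical-lasso + StARS backends; F1/precision/recall scoring
against the planted truth and paired Wilcoxon method comparison.

## Worked example

```sh
python examples/03_infer_network.py
```

simulates one 60-species community in which *every* species has a
gradual seasonal cycle and half also have long-term trends, then infers
networks from the raw CLR table and from the GAM residuals:

```
truth: 14 edges;  method -> F1 (precision / recall / edges)
            raw    scc -> 0.092 (0.05 / 0.43 / 117)
            raw glasso -> 0.135 (0.08 / 0.36 / 60)
  GAM-detrended    scc -> 0.600 (1.00 / 0.43 / 6)
  GAM-detrended glasso -> 0.558 (0.41 / 0.86 / 29)
```

Raw inference drowns in seasonal false positives (117 edges for 14 true
associations); after detrending both backends recover the truth far
better.  The other examples cover the simulator
(`01_simulate_dataset.py`), the per-species detrending diagnostics
(`02_gam_detrending.py`) and a miniature benchmark grid with paired
Wilcoxon comparison (`04_benchmark_grid.py`).

Library use mirrors the examples:

```python
from gamnet import normalize, gam_detrend, scc_network, nonparanormal_transform

norm = normalize(count_table, method="clr")      # species x samples + month/day
detrended = gam_detrend(norm)               # per-species GAM residuals
net = scc_network(nonparanormal_transform(detrended.values), alpha=0.01)
```

## Benchmark / acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the reduced benchmark grid from scratch — 32 simulation
conditions (2 topologies × 2 covariance levels × 2 long-term fractions
× 4 seasonal cells) × 5 replicates of 60 species × 200 monthly samples
— inferring every dataset with both backends, with and without the GAM
transform, and writes the percentage of paired runs in which detrending
strictly increased the F1 score (one entry per backend).  Takes about
10 minutes on one CPU.

## Layout

- `src/gamnet/simulate.py` — truth networks, covariance construction, MVN
  abundances, seasonal/long-term contamination, count tables, the 84-cell
  condition grid
- `src/gamnet/gam_transform.py` — CLR/mCLR/CSS/TSS normalization, per-species
  penalized-spline GLS GAMs, Ljung–Box residual check, correlation-structure
  revision
- `src/gamnet/network_inference.py` — nonparanormal transform, SCC,
  glasso path, StARS selection
- `src/gamnet/evaluation.py` — confusion/F1, clustering coefficient, degree
  distributions, paired Wilcoxon reports
- `src/gamnet/pipeline.py` — seeded, checkpointable experiment runner and the
  reduced benchmark preset
- `docs/methods.md` — model, estimation, simulator assumptions, limitations
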