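# Methods

## The problem

Co-occurrence networks inferred from microbial time-series abundance
data are confounded by shared temporal structure: two species that both
bloom in summer co-occur strongly without any biotic association, and
long-term monotone trends have the same effect.  `gamnet` removes these
signals per species *before* network inference by fitting each species
a generalized additive model (GAM) of time and passing only the
residuals to the network backend.

## The detrending model

For each species, with `y_t` its normalized abundance at sample `t`:

    y_t = beta0 + f_cyc(month_t) + f_smooth(day_t) + eps_t

- `f_cyc` — cyclic P-spline over month-of-year (period 12): a cyclic
  cubic B-spline basis (default 8 functions, wrapped knots) with a
  cyclic second-difference penalty, so the fitted annual curve matches
  at the December/January seam.
- `f_smooth` — cubic P-spline over the sample index (default 10 basis
  functions, second-difference penalty), absorbing long-term trends.
- `eps_t` — serially correlated errors under one of six working
  correlation families: continuous AR1 (default), discrete AR1,
  compound symmetry (exchangeable), exponential and Gaussian
  distance-decay in |Δday|, or independence.

Identifiability: B-spline bases form a partition of unity, so the
constant-coefficient direction of each smooth duplicates the intercept
and is unpenalized by difference penalties.  Each block is
reparameterized onto the orthogonal complement of that direction and
column-centred (the analogue of mgcv's sum-to-zero constraints);
without this the normal matrix is exactly singular.

Estimation is iterated feasible GLS: (1) penalized weighted least
squares on data whitened by the current working correlation, with the
two smoothing parameters chosen by GCV over a log-spaced grid
(10^-2 … 10^5.5, 6 points per smooth); (2) a moment estimate of the
correlation parameter from the current response residuals (lag-1
autocorrelation for the AR-type and distance-decay families, the
standard between/within moment ratio for compound symmetry); repeat
until the parameter moves less than 1e-6, at most 20 iterations.  The
GCV grid search runs on the first two iterations and the smoothing
parameters are then frozen — on our data the selected values are stable
after the first whitened refit, and this keeps the per-species cost a
few milliseconds.

Residuals handed downstream are on the response scale (`y` minus the
fitted mean), centred to exact zero mean.  Centring is harmless because
every downstream backend is location-invariant, and it makes the
residual-centering invariant exact; the GLS intercept alone guarantees
zero mean only in the whitened metric.

## Residual autocorrelation check and model revision

After the default continuous-AR1 fit, the *whitened* residuals are
tested with a Ljung–Box portmanteau test at lags up to min(12, n/5),
alpha 0.05.  Whitened (normalized) residuals are the right object: the
correlation structure accounts for serial dependence in the whitened
domain, and testing the raw residuals would flag every species whose
serial structure the model had in fact absorbed.  Constant residual
vectors fail the check with reason "degenerate" rather than raising.

Species whose fit failed to converge or failed the check are refit with
the four alternative families (AR1, CompSymm, Exp, Gauss); the single
family that fixes the most species is adopted for the whole failed
group (ties broken in that fixed order), and species it still cannot
fix keep its best available fit with a warning flag.  The per-species
choice, Ljung–Box p-value and convergence flags are retained in the
transform output.

## Normalization

CLR is the primary normalization: zeros are replaced by a pseudocount
of half the smallest nonzero relative abundance in the table, then
`ln(x / geometric column mean)`.  TSS (closure), CSS (median-quantile
cumulative-sum scaling, rescaled by the median scale factor and
log1p-transformed) and mCLR (CLR over nonzeros with a global positive
shift, zeros fixed at 0) are provided as variants.  The CSS and mCLR
forms are standard adaptations, not line-by-line ports of
metagenomeSeq/SPRING.

## Network backends

Both backends first apply a nonparanormal transform per species:
average-tie ranks mapped through Phi^{-1}(rank/(n+1)), scaled to unit
sample variance (the shrunken variant, the common default; a
truncation variant also exists and gives nearly identical ranks at
n = 200).

- **SCC**: all C(p,2) tie-corrected Spearman correlations, two-sided
  p-values from the t approximation, edge iff p ≤ alpha / C(p,2) with
  alpha = 0.01 (Bonferroni over all pairs).
- **Glasso + StARS**: L1-penalized Gaussian precision estimation
  (scikit-learn's coordinate descent, tol 1e-4, 200 sweeps) over a
  log-spaced 30-point lambda path from lambda_max (largest absolute
  off-diagonal sample covariance — the smallest penalty giving an empty
  graph) down to 0.01·lambda_max.  StARS draws 50 subsamples of size
  floor(10·sqrt(n)) without replacement, computes per-lambda edge
  frequencies theta and instability mean(2·theta·(1−theta)), monotonizes
  the instability from the sparse end by cumulative max, and selects the
  smallest lambda (densest graph) with monotonized instability ≤ 0.05.
  If no lambda qualifies the most stable one is used, with a warning.

Two exact performance devices keep this desk-scale: (1) every glasso
solve first splits the problem into the connected components of the
graph with edges |S_ij| > lambda — the solution is provably
block-diagonal over these components; (2) the StARS path stops as soon
as the monotonized instability exceeds the threshold, since no denser
lambda can then be selected (the cumulative max cannot decrease).  The
subsampled stability solves use tol 1e-3 and 30 sweeps (supports were
verified identical to the tight settings on development data); the
final full-data estimate at the selected lambda always uses tol 1e-4
and 200 sweeps.

## The simulator

The generator's defaults are the stated benchmark world:

- **Topology**: Erdős–Rényi (edge probability 1%), Barabási–Albert
  preferential attachment (m = 1, a tree), or a user-supplied adjacency
  (the entry point for topologies derived from real datasets); default
  400 species × 200 samples.
- **Covariance**: the level 100 ("high") or 10 ("low") is placed on
  every edge.  The levels fix only the off-diagonal entries, leaving the
  diagonal a free modelling choice; we use base variance 25 (a single low-covariance edge then has
  correlation 10/25 = 0.4) and, when the smallest eigenvalue is not
  positive, add |lambda_min| + 1e-3 to the whole diagonal.  The loading
  is recorded in the dataset metadata.  One consequence worth knowing:
  after loading, edge correlations are roughly comparable between the
  high and low regimes (~0.5 vs ~0.4).
- **Abundances**: per-species means from Normal(10, variance 1)
  ("variance" read literally; configurable), then i.i.d. MVN columns.
- **Seasonality**: multiplicative envelope
  `S_t = cos(N_t·2π/12)/2 + 0.5` (gradual) or its 10th power (abrupt),
  with a uniform random integer phase per species; applied to 0/25/50/100%
  of species, selected at random.
- **Long-term trend**: additive line, slope drawn from
  Normal(0.01, variance 0.01) and negated with probability 1/2, starting
  at 0.01.  The recursion as literally typeset
  (`L_t = ±m·L_{t−1} + 0.01`) is multiplicative and converges to a
  constant, contradicting its description as a line of slope m;
  `recursion_mode="as_printed"` reproduces the literal formula,
  `"additive"` (default) the described behaviour.
- **Counts**: `exp(X)` (natural base), optional uniform-at-random
  zeroing of a stated fraction of entries (a simple stand-in for
  zero-inflation; the real mechanism in sequencing data is
  abundance-dependent), then closure to column sums of 1.  Month is
  `((day−1) mod 12) + 1` — one sample per month.

What the simulator does *not* emulate: sequencing depth and counting
noise, abundance-dependent zeros, taxonomic structure, irregular
sampling, batch effects.  A green benchmark here establishes that the
transform removes the stated contamination without destroying planted
covariance — not that it handles every artefact of real surveys.

## The benchmark

The full-scale benchmark grid is 84 conditions (3 topologies × 2 covariance
levels × 2 long-term fractions × 7 seasonal cells) × 100 replicates =
8400 datasets of 400 species — cluster scale.  The desk-scale
`reduced_preset` keeps the design (2 topologies × 2 covariance levels ×
2 long-term fractions × 4 seasonal cells = 32 conditions, 5 replicates,
60 species, StARS at 20 subsamples / 15 lambdas) and runs in ~10
minutes on one CPU.  Runs are compared by paired Wilcoxon signed-rank
tests (Pratt handling of zero differences, since identical failures are
common), Bonferroni-corrected over the condition-level comparisons in
the report, and by the fraction of paired runs whose F1 strictly
increased under detrending.

Per-dataset seeds derive from `SeedSequence([master_seed, condition
index, replicate index])`, so datasets are independent work units and
scheduling cannot change results.

## Known limitations

- The GAM machinery approximates mgcv's `gamm` (penalized splines +
  nlme correlation structures); the detrending contract is reproduced,
  not bit-level residuals.
- Abrupt (10th-power) seasonality is only partially captured by the
  smooth cyclic basis; detrending helps less there, and with heavy
  abrupt contamination both backends can remain poor.
- The compound-symmetry and distance-decay families estimate their
  parameter from the lag-1 autocorrelation only — adequate for
  detrending, crude as inference about the error process.
- CCLasso/SPRING-style backends are not implemented; the backend
  registry (`network_inference.BACKENDS`) is the plug-in point.
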