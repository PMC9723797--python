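"""Run a miniature benchmark grid and compare methods.

A 4-condition, 2-replicate slice of the reduced benchmark: simulate,
infer with all four approaches, and summarize with paired Wilcoxon
tests and the fraction of runs improved by detrending.  (The full
reduced preset — 32 conditions x 5 replicates — is what
scripts/acceptance.py runs; this example finishes in under a minute.)
"""

from gamnet import evaluation, pipeline, simulate
from gamnet.network_inference import StarsConfig

conditions = [
    simulate.SimulationCondition("er", "high", sf, shape, 0.5, n_species=30, n_samples=200)
    for sf, shape in [(0.0, None), (1.0, "gradual"), (0.5, "gradual"), (0.5, "abrupt")]
]
plan = pipeline.ExperimentPlan(
    conditions=conditions,
    replicates=2,
    master_seed=3,
    stars=StarsConfig(n_lambda=10, n_subsamples=10),
)
runs = pipeline.run_experiment(plan, progress=True)

report = evaluation.compare_methods(runs)
print("\nmean F1 per condition and backend:")
cols = ["condition", "backend", "mean_f1_gam", "mean_f1_raw", "wilcoxon_p_adj"]
print(report["per_condition"][cols].to_string(index=False))
print("\nfraction of runs improved by the GAM transform:")
for backend, frac in report["fraction_improved"].items():
    print(f"  {backend}: {100 * frac:.0f}%")
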