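"""Fit Scheffe mixture models to simulated runs and locate the best blend.

Simulates a noisy egfp-like mixture experiment, fits the three response
models (Log(Vp), % full, viability), checks whole-model significance, and
maximizes the combined desirability over the bounded simplex.
"""

import numpy as np

from aavdoe import (
    MixtureBounds,
    NoiseModel,
    SimplexRegion,
    anova_model,
    attach_derived_responses,
    d_optimal_select,
    equal_weight_thresholds,
    fit_scheffe,
    make_archetype,
    optimize_desirability,
    simplex_candidates,
    simulate_runs,
    threshold_region,
)

bounds = MixtureBounds()
design = d_optimal_select(simplex_candidates(bounds, 0.05), n_runs=13, seed=1)
archetype = make_archetype("egfp_like")
table = attach_derived_responses(
    simulate_runs(design, archetype, NoiseModel(), seed=7)
)

models = {}
for resp in ("log_vp", "pct_full", "viability"):
    models[resp] = fit_scheffe(design, table[resp].to_numpy())
    p = anova_model(models[resp]).p_value
    print(f"{resp:10s} whole-model ANOVA p = {p:.2e}")

region = SimplexRegion(bounds, grid_step=0.02)
result = optimize_desirability(models, region)
h, r, g = result.best.point
print(f"\nbest blend pHelper:pRepCap:pGOI = {h:.2f}:{r:.2f}:{g:.2f}  D = {result.best.D:.3f}")
for resp, val in result.best.predictions.items():
    print(f"  predicted {resp} = {val:.2f}  (d = {result.best.d_individual[resp]:.2f})")

thr = equal_weight_thresholds(models, region, level=0.5)
mask = threshold_region(models, thr, region)
print(
    f"\nequal-weight thresholds at d=0.5: "
    + ", ".join(f"{k}={v:.2f}" for k, v in thr.items())
)
print(
    f"white (all-responses-pass) region: {int(mask.combined.sum())} of "
    f"{len(mask.combined)} grid blends"
)

# The blend with the highest geometric-mean desirability balances the three
# conflicting responses; the white region is where every fitted response
# clears its equal-weight threshold — the profiler's feasible window.
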