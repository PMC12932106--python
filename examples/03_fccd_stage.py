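"""FCCD stage: optimize total DNA and reagent ratio at a fixed blend.

With the plasmid ratio fixed at the mixture-stage optimum, a two-factor
face-centered central composite design varies total DNA (1-3 ug/mL) and the
FectoVIR:DNA ratio (0.5-2) on the coded square; second-order models are
fitted and the combined desirability is maximized.
"""

import numpy as np

from aavdoe import (
    NoiseModel,
    SquareRegion,
    attach_derived_responses,
    fccd_design,
    fit_rsm,
    make_archetype,
    optimize_desirability,
    simulate_runs,
)

archetype = make_archetype("egfp_like")
blend = archetype.true_md_optima().best.point
print("fixed blend (pHelper, pRepCap, pGOI):", np.round(blend, 3))

fccd = fccd_design(n_center=3, limits={"dna": (1.0, 3.0), "fv": (0.5, 2.0)})
print(f"FCCD: {fccd.n_runs} runs ({fccd.n_center} center replicates)")

table = attach_derived_responses(
    simulate_runs(fccd, archetype, NoiseModel(), seed=11, ratio=blend)
)
models = {
    resp: fit_rsm(fccd, table[resp].to_numpy())
    for resp in ("log_vp", "pct_full", "viability")
}

result = optimize_desirability(models, SquareRegion(grid_step=0.05))
coded = result.best.point
actual = fccd.decode(coded)[0]
print(
    f"optimal coded (DNA, FV) = ({coded[0]:+.2f}, {coded[1]:+.2f})"
    f"  ->  {actual[0]:.2f} ug/mL DNA, {actual[1]:.2f} FV:DNA"
)
for resp, val in result.best.predictions.items():
    print(f"  predicted {resp} = {val:.2f}")

# Coded -1/0/+1 map to the low/mid/high physical levels; the optimum says
# how much DNA and transfection reagent to use once the blend is fixed.
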