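# aavdoe

Design-of-experiments toolkit for optimizing upstream production of
recombinant adeno-associated virus (rAAV) by triple transient transfection.

## The problem

rAAV is produced in HEK293 cells by co-transfecting three plasmids — pHelper
(adenoviral helper genes), pRepCap (AAV *rep*/*cap*), and pGOI (the
ITR-flanked gene of interest). Three responses matter and usually conflict:

* **Log(Vp)** — log10 volumetric productivity, `log10(titer / time)` in
  vg·mL⁻¹·day⁻¹ (qPCR vector-genome titer);
* **% full** — the fraction of assembled capsids that actually carry a
  genome, `100 × genome_titer / capsid_titer` (qPCR over ELISA);
* **viability** — percentage of live cells at harvest.

The optimal plasmid blend depends strongly on the gene of interest, so the
workflow has to be re-run per construct. `aavdoe` implements the two-stage
strategy used in practice:

1. **Mixture design (MD).** The plasmid mass fractions x₁+x₂+x₃ = 1, each
   bounded (default 10–60 %), form a constrained simplex. A D-optimal set of
   runs (Fedorov point exchange maximizing log |X′X|) supports the
   intercept-free Scheffé quadratic
   `y = Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ`.
2. **FCCD / response-surface stage.** With the blend fixed at the MD
   optimum, a two-factor face-centered central composite design varies total
   DNA and the transfection-reagent:DNA ratio on the coded ±1 square and
   fits the full second-order polynomial
   `y = β₀ + Σβᵢxᵢ + Σβᵢᵢxᵢ² + Σβᵢⱼxᵢxⱼ`.

Each response is mapped to a Derringer desirability
`d = ((y−L)/(T−L))^r` clipped to [0, 1], and responses are combined as the
geometric mean `D = Π dᵢ^{1/k}`; optima are located by a dense grid scan
plus Nelder-Mead polish, with top-m reporting for constructs whose
productivity and packaging optima disagree. Whole-model significance is a
single ANOVA F test; 95 % coefficient intervals come from the usual t
quantiles.

Because wet-lab run tables are rarely shareable, a synthetic module provides
three ground-truth archetypes (`egfp_like`, `msh2_like`, `bdnf_like`) whose
surface geometry reproduces the qualitative landscapes seen across GOIs —
opposing Log(Vp)/% full gradients, a viability saddle, a RepCap-dominated
optimum — so the whole pipeline is testable in silico.

## Worked example

```python
from aavdoe import (MixtureBounds, simplex_candidates, d_optimal_select,
                    make_archetype, simulate_runs, attach_derived_responses,
                    fit_scheffe, optimize_desirability, SimplexRegion, NoiseModel)

bounds = MixtureBounds()                                  # 10-60% per plasmid
design = d_optimal_select(simplex_candidates(bounds, 0.05), n_runs=13, seed=1)
table  = attach_derived_responses(
    simulate_runs(design, make_archetype("egfp_like"), NoiseModel(), seed=7))
models = {r: fit_scheffe(design, table[r].to_numpy())
          for r in ("log_vp", "pct_full", "viability")}
best   = optimize_desirability(models, SimplexRegion(bounds, 0.02)).best
print(best.point, best.D)
```

Running `python examples/02_fit_and_optimize.py` (which is the script form
of the snippet above) prints:

```
log_vp     whole-model ANOVA p = 9.37e-07
pct_full   whole-model ANOVA p = 2.85e-05
viability  whole-model ANOVA p = 1.19e-02

best blend pHelper:pRepCap:pGOI = 0.53:0.10:0.37  D = 0.678
  predicted log_vp = 9.82  (d = 0.51)
  predicted pct_full = 43.72  (d = 0.96)
  predicted viability = 83.34  (d = 0.64)

equal-weight thresholds at d=0.5: log_vp=9.81, pct_full=33.66, viability=81.96
white (all-responses-pass) region: 57 of 501 grid blends
```

All three fitted models are significant (p < 0.05); the best blend trades a
little productivity (d = 0.51) for near-maximal packaging (d = 0.96), and
57 of the 501 lattice blends clear every equal-weight threshold — the
"white area" a mixture profiler would shade as acceptable.

The other examples cover design construction (`01`), the FCCD stage at a
fixed blend (`03`), and the full two-stage pipeline with fold-improvement
reporting against the unoptimized 1:1:1 blend (`04`).

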