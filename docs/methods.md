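# Methods

This note records the statistical models, the synthetic ground truth, the
numerical choices, and the limitations of `aavdoe`.

## Models and procedure

**Mixture stage.** The three plasmid mass fractions (pHelper, pRepCap,
pGOI) live on the simplex x₁+x₂+x₃ = 1 with per-component bounds, default
0.1–0.6 — low enough that every plasmid is always present, high enough to
explore strong skews. Candidate runs are the regular barycentric lattice at
a configurable step (default 0.05, which resolves the 0.05-granularity
ratios practitioners quote). A D-optimal subset of n_runs = 13 (default) is
selected by Fedorov point exchange on the Scheffé-quadratic model matrix:
starting from a random distinct subset, the best strictly-improving
(design-point, candidate) swap is applied until none exists, over 10 random
starts. Selection is **without replacement**: the design is a subset of
distinct candidates, and replicate measurements are a property of the
measurement layer (`replicates` in the simulator), not of the support. This
makes two contracts exact: with n_runs equal to the candidate count there is
no selection freedom, and on small instances the search is comparable to
exhaustive subset enumeration (which the tests do, at |candidates| ≤ 12,
n_runs = 6). Acceptance of a swap is decided on the *recomputed*
log-determinant, which both removes rounding drift from the batched
update and guarantees a strictly increasing, terminating criterion trace
(the trace is kept on the design object and asserted monotone in tests).
13 runs = 6 model terms + 7 residual degrees of freedom, the smallest
design that leaves a comfortable ANOVA denominator.

The Scheffé quadratic has no intercept; because the fractions sum to one,
the constant vector lies in its column span anyway. Consequently the
mean-corrected ANOVA partition applies with df_model = p − 1 = 5, exactly as
for the intercept-bearing RSM model — this is what makes the whole-model F
test properly calibrated (the type-I simulation in the acceptance suite
recovers the nominal 5 % within Monte-Carlo error).

**FCCD stage.** Total DNA (µg/mL) and the FectoVIR:DNA ratio are coded so
their limits map to ±1 and the midpoint to 0. The face-centered central
composite design is the 4 factorial corners + 4 face centers + n_center
center replicates (default 3, giving pure-error degrees of freedom). The
default physical ranges — DNA ∈ [1, 3] µg/mL, reagent ratio ∈ [0.5, 2] —
bracket the mixture-stage conditions (2 µg/mL, 1:1), which is where a
follow-up design should be centered. Fits are ordinary least squares via
statsmodels; rank deficiency is reported with the names of the collinear
terms.

**Desirability.** Each response is larger-is-better with
d = ((y−L)/(T−L))^r on [L, T], clipped outside. Defaults: r = 1 (linear —
the neutral "equal weight" choice) and L/T equal to the minimum/maximum
prediction over the search region, i.e. optimization is relative to what
the explored space can deliver. The overall score is the geometric mean,
so one dead response vetoes a blend. The optimizer scans the region lattice
(default steps: 0.02 barycentric, 0.05 coded), finds grid local maxima via
the lattice neighbor graph (k-d tree, radius 1.5 steps), keeps the top-m
separated by at least 3 steps, and polishes each with Nelder-Mead capped at
200 iterations; polished optima that collapse into the same basin are
deduplicated. `top_m = 2` reproduces the dual-point strategy needed when
productivity and packaging optima disagree. Threshold-region masks
(`threshold_region`, `equal_weight_thresholds`) reconstruct the profiler
view: the "white area" is where every fitted response clears the y-value at
which its individual desirability equals a common level.

**Derived responses and conversions.** Log(Vp) = log10(titer/time);
% full = 100 × genome titer / capsid titer, returned above 100 % only with
a warning (a qPCR/ELISA inconsistency, not a physical state); plasmid mass
→ copy number uses 650 g·mol⁻¹·bp⁻¹ double-stranded (330 single-stranded
behind a flag), since plasmid dosing is dsDNA. When a table carries both a
48 h and a 72 h harvest per run, `select_harvest` keeps the row with the
higher Log(Vp) by default (the harvest a process developer would report),
with the paired % full and viability from that same harvest.

## Synthetic ground truth

Each archetype defines one quadratic per response in the reduced
(pHelper, pGOI) coordinates — any such quadratic has a unique exact
Scheffé representation on the simplex, obtained by solving the 6×6
interpolation system — plus a zero-intercept deviation quadratic on the
coded square; the FCCD-stage truth at a fixed blend is the Scheffé value at
that blend plus the deviation. This additive composition makes the
sequential MD → FCCD strategy exactly optimal at zero noise, which is the
property the pipeline tests lean on.

The coefficients are fixed constants chosen once to encode the qualitative
landscape geometry (steepness is not recoverable from published summaries
and is a package choice):

* `egfp_like` — Log(Vp) decreases and viability increases along the
  "more pGOI, less pHelper/pRepCap" direction; % full peaks in the interior
  near the 0.4 : 0.25 : 0.35 blend. Single desirability optimum.
* `msh2_like` — all three responses share a peak at 0.2 : 0.6 : 0.2
  (RepCap-dominated), with % full an order of magnitude below the other
  archetypes; FCCD deviations favor high DNA / low reagent.
* `bdnf_like` — % full rises linearly with pGOI while Log(Vp) falls
  (centroid gradient cosine −1), and viability is a pure saddle
  (indefinite Hessian). The saddle is what makes the combined desirability
  bimodal: a productivity-focused mode at high pHelper and a
  packaging-focused mode at high pGOI.

Constructors self-verify all of this — gradient signs, Hessian eigenvalues,
optimum locations, bimodality, and physical ranges (viability and % full in
[0, 100] on the simplex and on the coded square at every true optimum
blend) — and raise rather than return a non-conforming archetype.

**Noise model.** Gaussian, per response: σ = 0.1 log10 units for Log(Vp),
2 percentage points for % full and viability — chosen once as realistic
assay-level scatter. % full is clipped to [10⁻³, 100] after noise (the tiny
positive floor keeps the back-computed capsid titer finite) and viability
to [0, 100]; clip events are counted on the returned table. Titers are
back-computed at a fixed 2-day harvest so the derived Log(Vp) and % full
round-trip exactly through the response transforms.

**What the simulator does not emulate:** mechanistic transfection/packaging
biology, non-Gaussian or heteroscedastic assay error, batch effects,
harvest-time kinetics, and any coupling between blend and process factors
beyond additivity. Passing tests therefore demonstrate that the
*statistical machinery* — design selection, fitting, calibration,
multi-response optimization — behaves correctly on surfaces of realistic
shape; they say nothing about how steep or smooth a particular wet-lab
construct will be.

## Recovery scoring

`end_to_end_recovery` reports the distance of each recovered optimum to the
*nearest* true optimum (for the bimodal archetype, noise can swap which
near-equal mode ranks first; nearest-mode distance is the meaningful error).
Distances are quoted in grid cells, one cell = step × √2 (the lattice
neighbor spacing). The true-desirability improvement from stage 1 to
stage 2 scores both the center factor levels and the recovered FCCD point
on the true surfaces, normalized over the same coded-square region the
optimizer searched — at zero noise the stage-2 score therefore cannot be
below stage 1.

Problem sizes used throughout the test and acceptance runs: 13-run mixture
designs on the 0.05 lattice, 11-run FCCDs, 0.02/0.05 optimization grids,
1000 Monte-Carlo replicates for the F-test and coverage calibrations, 100
repetitions for the noisy-recovery median, 20 random instances for the
exchange-vs-enumeration and optimizer-vs-analytic checks.

## Design choices and limitations

* The package is a library: the public API plus `examples/` scripts are the
  interface; there is no command-line entry point, since every operation is
  one or two function calls from Python.
* Model matrices are generic in the number of components/factors, but only
  the 3-plasmid / 2-factor system is exercised; I-optimality and other
  alphabetic criteria are out of scope.
* Desirability is one-sided (maximize-only); target-is-best transforms are
  not implemented.
* ANOVA is the whole-model F test only; no lack-of-fit decomposition and no
  blocking/random effects (single-batch quantification makes them
  unnecessary in the intended use).
* The grid+polish optimizer is exact only to grid resolution for
  non-smooth desirability landscapes (clipped d's have gradient kinks);
  the tests bound its error by one coarse grid cell against analytic or
  fine-grid references.
* Fold improvements compare *model predictions* at the optimized and
  reference conditions; they are not forecasts of wet-lab effect sizes.
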