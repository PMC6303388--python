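# Methods

This note documents the models, estimators and numerical conventions
behind `ssxmerge`, the free choices that were made where several
defensible designs exist, and what the synthetic-data tests do and do not
demonstrate about real serial-crystallography data.

## Reflection substrate

d-spacings come from the reciprocal metric tensor, `1/d² = h G⁻¹ hᵀ`,
valid for any cell geometry. Space groups are stored as explicit operator
tables (integer rotation + fractional translation, centring expanded);
only P1, P2₁2₁2₁ and C222₁ are tabulated because the pipeline needs
nothing beyond the Laue operations and the absence rule, both derived
generically from the table:

* **Absences** — a reflection is absent iff some operator fixes its index
  (`h R = h`) while `h·t` is non-integral. This single rule reproduces
  C-centring (`h+k` odd) and screw-axis (`00l`, `l` odd) conditions
  without per-group code, and is cross-checked against gemmi in the test
  suite.
* **ASU convention** — the canonical representative of an index is the
  lexicographically greatest tuple among its Laue equivalents (Friedel
  mate included by default; an `anomalous`-style flag keeps I⁺/I⁻
  separate). For mmm this is the all-non-negative octant. Any consistent
  convention works; this one is stable, total and cheap to vectorise.
* **Complete set** — enumeration bound `|h_i| ≤ a_i/d_min` per axis
  (exact, from `h_i = s·a_i`, `|s| = 1/d`), then filter, reduce, dedupe,
  drop absences. Equality with a scalar brute-force triple loop is
  asserted on small cells.

Resolution shells partition `(d_min, d_max]` half-open with the shared
edge belonging to the higher-resolution shell; `equal_volume` spaces
edges uniformly in 1/d³, `equal_count` uses quantiles (populations differ
by ≤ 1). Ten equal-volume shells is the reporting default — published
tables print only overall + highest shell, so the layout is a free,
configurable choice.

## Synthetic data model

The generator emulates the statistical structure of multi-crystal wedge
data, not the diffraction physics:

* True intensities are acentric-Wilson (exponential) with mean
  `C·exp(−B_w/2d²)`. Defaults `C = 2000`, `B_w = 73.6 Å²` at
  `d_min = 2.6 Å` on a 52 × 60 × 108 Å C222₁ cell — a realistic
  falloff for a membrane-protein crystal diffracting to ~2.6 Å, sized to
  give ≈ 5,400 unique reflections. Centric zones are not treated
  specially; this slightly misstates the intensity distribution of a few
  hundred zone reflections and is irrelevant to the scaling/merging
  machinery under test.
* Each dataset observes a uniform random fraction (default draw
  0.25–0.45) of the unique set with mean multiplicity 2.5–4 — the
  coverage/multiplicity regime of 10° wedges in an orthorhombic Laue
  group. Each observation is emitted under a random symmetry equivalent
  so ASU reduction is genuinely exercised. Partiality is not modelled
  separately; like the experimental procedure itself, the pipeline
  absorbs it into per-dataset scales and the error model.
* Observed `I = K·exp(−B_rel/2d²)·I_true + ε`, with reported
  `σ_raw = √max(I_exp, 0.25) + 0.5` (Poisson-like with a 0.5
  intensity-unit floor keeping sigmas positive) and
  `Var(ε) = a·(σ²_raw + b·I²_exp)`. The planted
  `ISa = (a·b)^(−1/2)`.
* Benchmark composition: good datasets draw ISa ∈ [10, 40] (typical for
  well-measured synchrotron wedges), planted outliers ISa ∈ [0.5, 2.0],
  mis-indexed datasets get ≥ 4 % deviation on one cell axis with an
  otherwise good error model — so only the cell filter can catch them.
* The first good dataset is the *reference crystal* (`K = 1`,
  `B_rel = 0`). Relative scales are only defined up to a gauge, and the
  pipeline fixes its gauge on the first retained dataset; making the two
  frames coincide by construction is what makes "recover the planted K,
  B_rel and Wilson B" well-posed.
* One collection seed expands to per-dataset seeds via
  `numpy.random.SeedSequence(seed).spawn` in dataset order; every output
  is bit-reproducible.

What passing these tests shows: the estimators are consistent and
unbiased under the generative model they assume, at realistic counts.
What they do not show: robustness to radiation damage gradients,
non-Gaussian outlier observations, partiality correlated with wedge
geometry, or detector artefacts — none of which the generator emulates.

## Scaling

Alternating refinement: (i) merged reference per ASU index =
inverse-variance mean of currently scaled observations; (ii) per dataset,
weighted least squares of `log(I_obs/I_ref)` on `(1, −1/2d²)` giving
`(log K, B)`. Only observations with `I_obs > 0.1·σ_raw` (configurable)
and a positive reference enter the log fit; everything enters the
reference. Weights are `(I_ref·g/σ_raw)²` — the *predicted* signal-to-
noise — rather than the observed one, so a weak observation's own noise
cannot select it into or bias the fit. Convergence: RMS Δlog K < 10⁻⁶ or
100 iterations, whichever first; non-convergence is a flagged state on
the returned model, never silent. Datasets must form a single connected
component under shared-reflection edges; a disconnected input is an error
naming the smallest component.

## Error model and ISa

For each observation, the residual against the *leave-one-out* merged
reference (all other observations of the same reflection, any dataset) is
binned by reference intensity (5 quantile bins, ≥ 3; ≥ 50 pairs
required). Matching empirical bin variance — with the reference's own
variance subtracted — to `a·(σ² + b·I²)` is linear in `(a, a·b)` and is
solved by count-weighted least squares; this is exactly the condition
that normalised residuals have unit variance per bin, and the analytic
solution is verified against a brute-force grid search over the same
objective in the tests. Degenerate cases: near-constant intensities fall
back to an overall-variance fit with `b = 0`; an unphysical `a ≤ 0`
(all variance in the I² term) pins `a = 1` and refits `b` alone.
`b < 10⁻¹²` reports ISa as infinity (serialised `"inf"`), never an
overflow.

Two subtleties matter quantitatively:

* **Self-consistency.** The reference variance must be computed with
  *adjusted* sigmas, or datasets with large planted errors contaminate
  the reference-variance subtraction for clean ones (the fitted b of a
  good dataset absorbed the low-ISa datasets' excess variance, biasing
  its ISa low by 2× in early experiments). `fit_error_models` therefore
  iterates all fits to a fixed point (4 rounds), recomputing reference
  weights and variances from the current models.
* **Merging weights.** After fitting, the adjusted sigma used for
  merging takes the I² term at the reflection's *group-mean* intensity,
  not the observation's own value: weighting by a function of an
  observation's own noise anti-correlates weight and error and biases
  merged means low for strong reflections (observed as a +6–19 Å²
  Wilson-B bias before the change).

Rejection is strict (`ISa < cutoff`; a dataset exactly at the cutoff is
kept — the procedure's wording is ambiguous, so the boundary is
documented and tested). The default is exactly two rounds — one
rejection pass, one clean re-scale/re-fit of the survivors — with an
opt-in `iterate` mode that repeats rejection to a fixed point.

## Merging statistics

* Merged intensity: inverse-variance mean with adjusted sigmas;
  propagated sigma `(Σw)^(−1/2)`. Negative merged intensities are kept.
* R factors use the unweighted group mean, sums over multiply-observed
  reflections only: `R_meas` multiplies each group's deviations by
  `√(n/(n−1))`, `R_pim` by `√(1/(n−1))`. An empty sum is reported as an
  explicit null, never 0.
* CC<sub>1/2</sub>: observations of each multiply-observed reflection are
  randomly halved (10 seeded splits by default, averaged), Pearson
  correlation of the half-merged vectors per shell. Random splits were
  chosen over odd/even assignment because no splitting rule is canonical;
  the split count and seed are configuration. Shells with < 3 usable
  reflections report null.
* Completeness: observed unique ∩ complete set per shell; the few
  complete-set entries at lower resolution than the observed range are
  counted in the first shell, matching how a table's resolution range is
  quoted from the lowest observed d.
* Wilson B: −slope of `ln⟨I⟩` vs `1/2d²` over equal-count shells
  restricted to d ≤ 4.5 Å (low-resolution data violate the Wilson
  approximation for real macromolecules); non-positive shell means are
  skipped with a warning, < 3 usable shells is an error.
* Resolution cutoff: d_min of the last shell in the initial contiguous
  run (from low resolution) with CC<sub>1/2</sub> ≥ threshold; a failing
  first shell is an error recommending inspection rather than a silent
  cut.

## Geometry classification

Ligand directions (unit vectors from the metal) are compared against
ideal tetrahedron / octahedron / pentagonal-bipyramid templates by
exhaustive assignment search: for every injective assignment of observed
ligands to template vertices (all drop-subsets of larger templates
included), the optimal superposition rotation is computed by a batched
Kabsch SVD and the angular RMSD (degrees, between matched unit vectors)
evaluated; the minimum over assignments wins. The rotation minimises the
chord metric rather than the angular RMSD itself — for the sub-10°
misfits that matter here the two optima coincide to well below the
reported precision, and the procedure is exactly rotation-invariant
(asserted to < 10⁻⁶ °). A larger template (dropped vertices) only earns
its "incomplete" prefix when it beats the best equal-vertex-count
template by > 5°, so a noisy octahedron is not over-labelled as an
incomplete pentagonal bipyramid. With ≤ 8 ligands the largest search is
7P7 = 5040 assignments, ~30 ms per site.

Coordination spheres use conventional first-sphere cutoffs (Zn–N/O/S
2.6 Å, Ca–O 3.0 Å, fully configurable); a residue contributing ≥ 2
ligand atoms is reported multidentate. Altloc duplicates resolve to the
highest occupancy (ties by altloc letter) so every census count is
deterministic. Disulfides are SG–SG pairs from distinct Cys residues
within 2.5 Å.

## Problem sizes and defaults

The standard test crystal (52 × 60 × 108 Å, C222₁, 2.6 Å) gives 5,447
unique reflections; the selection benchmark (28 wedges, ≈ 160k
observations) and the 30-dataset recovery collection each run in a few
seconds, and the full acceptance script in ~15 s on one CPU. Parameter-
recovery tolerances asserted by the tests: planted-outlier recovery is
exact; K median relative error < 3 % (observed ≲ 1 %); relative B within
2 Å² (observed ≲ 0.9); ISa median relative error < 15 % (observed 3–7 %;
individual datasets with ISa near 40 can deviate by ~20 % because b is
then a small difference of large variances — the median is the asserted
statistic for this reason); Wilson B within 5 % of the planted 73.6 Å²
(observed ≤ 2 %).

## Known limitations

* Only the three tabulated space groups; no cell reduction, twinning
  tests, or general 230-group engine.
* No image-level simulation, spot integration or geometry refinement —
  input begins at unmerged intensity lists.
* No French–Wilson conversion to amplitudes and no anisotropy analysis.
* The error-model functional form is a modelling convention shared by
  generator and fitter; the tests demonstrate self-consistency, not that
  real detectors obey the form.
* The XDS_ASCII import shim is best-effort and not guaranteed across
  format versions.
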