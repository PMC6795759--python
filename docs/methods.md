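# Methods

This note records the measurement conventions, generator design, and
statistical definitions implemented in `musclemorph`, with the rationale for
each fixed parameter. Units are mm for raw contour coordinates and slice
positions, cm/cm²/cm³ for reported morphology.

## Model

For one muscle, given its measured volume `V`, maximal anatomical
cross-sectional area `ACSA_max` and length `L`:

- shape factor: `p = V / (ACSA_max × L)` (dimensionless, ≤ 1 for convex-ish
  profiles; a cylinder has p = 1, a cone 1/3, a spheroid 2/3),
- simplified estimate: `V_est = p̄ × ACSA_max × L`, where `p̄` is the
  cohort-mean factor for that muscle.

The model assumes the within-muscle ACSA profile shape is stable across
subjects of a cohort, so that a single mean factor per muscle transfers; the
cohort validation report quantifies how well that holds.

## Morphometry from contour stacks

- **Per-slice ACSA**: the shoelace (Gauss) formula on each outer contour,
  minus the shoelace area of any contour marked as a hole on the same slice.
  Contours are validated as simple polygons (no self-intersection, checked
  with Shapely) and holes must lie inside an outer contour. An ACSA is
  rejected if holes exceed the outer area.
- **Muscle length** `L`: axial distance between the most distal and most
  proximal slice that carries any contour.
- **Volume**: trapezoidal integration of the ACSA profile over slice
  position. The trapezoid rule is O(h²) in the slice spacing h; at the 2 mm
  spacing used throughout, analytic-solid tests bound the shape-factor error
  below 0.5 %.
- **ACSA_max position**: `100 × (z_peak − z_distal_landmark) /
  (z_proximal_landmark − z_distal_landmark)` in percent of shank length
  (0 % = distal). Ties in the per-slice maximum resolve to the most distal
  slice. `ACSA_max` is the maximum of the *sampled* profile; a peak between
  slices is slightly underestimated, another O(h²) effect.
- **Masks**: binary segmentation slices (NIfTI, TIFF or arrays) are converted
  to contours with marching squares at level 0.5 on zero-padded slices;
  hole/outer classification uses polygon-containment nesting parity.
  Pixel-center coordinates are scaled by the in-plane spacing, so areas are
  resolution-dependent and converge with refinement (tested).

## Synthetic cohorts

- **ACSA profile family**: along normalized length t ∈ [0,1],
  `ACSA(t) ∝ t^(α−1)(1−t)^(β−1)` (a beta-density kernel). It is the simplest
  smooth unimodal family with independent control of (a) the mode location m
  and (b) the mean-to-max ratio — which equals the shape factor p in the
  continuum limit. Given a target (p, m), (α, β) are solved on the ray
  α = 1 + s·m, β = 1 + s·(1−m) by bracketed root finding; the symmetric case
  (p = 2/3, m = 0.5) recovers (2, 2), the parabolic/spheroid profile.
  Infeasible targets (p ≥ 1, p too small, m ∉ (0,1)) raise an error.
- **Cross-sections**: circles discretized as regular 64-gons with radius
  chosen so the *polygon* area equals the target ACSA exactly (the n-gon
  area formula is inverted), making the shoelace measurement exact per slice.
- **Zero-area sections**: cone apices, spheroid poles and beta-kernel
  endpoints are floored to a tiny positive area (10⁻⁶–10⁻⁵ of the maximum)
  so marginal slices remain valid simple polygons; the effect on measured p
  is below 10⁻⁴ and is covered by the closure-test tolerances.
- **Cohort draws**: per muscle, (p, ACSA_max, L, peak position) are drawn
  independently from normal distributions truncated at ±3 SD (SciPy
  truncnorm), using published older-female triceps-surae means/SDs as the
  default preset. Independence is a simplification — real p, A, L covary —
  and is the main caveat for cross-cohort significance results (see
  Limitations).
- **Shank placement**: the shank is fixed at 360 mm (no published value; a
  representative adult shank). Each muscle's profile mode is fixed per muscle
  (SOL 0.50, GM 0.65, GL 0.70) and the muscle's axial offset is solved so the
  mode lands at the drawn peak-% position. Muscles may extend up to 80 mm
  proximal of the proximal landmark (the gastrocnemii originate above the
  knee); draws violating feasibility are redrawn (bounded retry), and
  impossible specifications raise an error. Slice spacing defaults to 2 mm.
- **Reproducibility**: one integer seed per cohort; all randomness flows
  through a single NumPy Generator, so identical seeds give bit-identical
  cohorts.

## Statistics

- **Relative RMS difference** (%): default is the RMS of per-subject relative
  differences `(est − meas)/meas`; a pooled alternative
  (RMS of absolute differences divided by the mean measured volume) is
  available via `definition="pooled"` / `--rms-definition pooled`.
- **R²**: squared Pearson correlation between estimated and measured volumes
  (not the regression coefficient of determination); undefined (NaN) for
  zero-variance inputs.
- **CV** (%): 100 × sample SD (ddof=1) / mean.
- **Paired comparison**: differences are screened for normality with the
  Lilliefors test (Kolmogorov–Smirnov with estimated parameters,
  statsmodels); the comparison itself is a two-sided paired t-test
  (scipy `ttest_rel`). The report carries the normality p-value so
  borderline cases are visible rather than silently switching tests.
- **Across-muscle comparison**: one-way ANOVA (`f_oneway`) on shape factors
  with pooled-variance pairwise t-tests, Bonferroni-adjusted
  (p_adj = min(1, p × number of pairs)). Muscles are repeated measures
  within subject; the between-groups analysis ignores that correlation and
  the report says so explicitly.

## Problem sizes and runtime

Unit and property tests use cohorts of 8–21 subjects; cohort-recovery tests
and `scripts/acceptance.py` use single-muscle cohorts of n = 1000 (≈180
slices × 64 vertices per muscle). The full test suite runs in about one
minute; the acceptance script in under 30 s.

## Limitations

- The independent-draw cohort model reproduces the published means, SDs and
  CVs, but not between-parameter covariances. Consequences that depend on
  covariance structure — notably the statistical power of small-cohort
  paired comparisons when the factor gap is small relative to its SD (the
  soleus young-vs-older gap is ≈0.44 SD, giving ≈0.47 power at n = 21) —
  should not be expected to match real-data findings seed-for-seed.
- `ACSA_max` is taken from the sampled profile; no interpolation of the peak
  is attempted.
- The generator produces circular cross-sections; it validates the pipeline's
  arithmetic, not anatomical realism of contour shapes.
- The ANOVA is between-groups despite repeated measures (flagged in every
  report).
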