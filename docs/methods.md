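# Methods

## Scientific setting

An F2 population derived from a cross between two tetraploid wheats
segregates for species-specific spike characters (presence of awns on both
lemma and glume — "tetraaristatum", spike colour, awn type, glume teeth).
Two complementary routes are used to infer the genetic control of a trait:

1. **Hybridological (qualitative) route.** Plants are scored into two
   phenotype classes; the observed split is tested against the two-class
   ratios expected under standard modes of inheritance.
2. **Quantitative (mixture) route.** A morphometric trait measured from
   spike images — canonically the awn area, SAA — is modelled as a
   two-component Gaussian mixture; the maximum-posterior split into a
   low-mean and a high-mean group plays the role of the phenotype classes
   and is tested against the same ratios.

Each spike is photographed in four standardized projections (front, two
lateral, back).  A split is attributed to the trait only when the ratio is
not rejected in *all four* projections; single-projection splits are treated
as measurement artefacts.

## Inheritance models and the chi-square test

A model is a collapse of the joint F2 genotype categories onto two phenotype
classes.  Per locus, F2 selfing gives the 1:2:1 genotype ratio and hence a
3/4 : 1/4 phenotype margin under complete dominance; independent loci
multiply.  The library carries:

| ratio | loci | mechanism (class with the minority phenotype) |
|-------|------|-----------------------------------------------|
| 3:1   | 1    | monogenic recessive (`aa`) |
| 13:3  | 2    | dominant epistasis (`aaB_`) |
| 15:1  | 2    | duplicate dominant genes (`aabb`) |
| 61:3  | 3    | trigenic epistatic variant (`aabbC_`) |
| 63:1  | 3    | triplicate dominant genes (`aabbcc`) |

For 61:3 and 63:1 only the numeric ratio is used downstream; the specific
three-locus collapse is one valid representative (any class map summing to
3/64 resp. 1/64 gives the same test).  Custom ratios (e.g. 9:7) can be added
through the YAML/JSON library config; every model is validated against the
exact (rational-arithmetic) F2 frequencies at construction.

Goodness of fit is Pearson's statistic, Q = Σ (Oᵢ−Eᵢ)²/Eᵢ with Eᵢ = n·pᵢ
and df = classes − 1, **without** continuity correction: the classical worked
splits of this cross (125:54 vs 3:1 → 2.549; 144:28 vs 13:3 → 0.689;
133:46 vs 3:1 → 0.047; 175:10 vs 15:1 → 0.225) reproduce to three decimals
only for the uncorrected statistic.  Yates' correction is available behind
an off-by-default flag.  α defaults to 0.05 (1-df critical value 3.84);
p-values come from the χ² survival function.  When the caller does not fix
an orientation, the majority class is assigned the dominant slot, matching
the convention of giving the 3-part of a 3:1 ratio to the majority
phenotype.

Expected counts are reported both as real numbers (n·pᵢ) and as a display
rounding that rounds the larger class to the nearest integer and gives the
remainder to the smaller class, so both presentations sum to n (187 under
3:1 → 140.25/46.75 → 140/47).  Testing always uses the unrounded values.

Group-level comparisons of a trait across labelled phenotype groups
(awnless / awned / tetraaristatum) use one-way ANOVA for the overall
equality of means and two-sided Mann–Whitney rank-sum tests for all pairs;
both are reporting conveniences around `scipy.stats`.

## Two-component Gaussian mixture EM

The mixture density is f(x) = w·N(x; μ₁, σ₁²) + (1−w)·N(x; μ₂, σ₂²) with all
five parameters free.  Fitting is expectation–maximization written directly
on the log scale (log-sum-exp E-step; responsibility-weighted moments in the
M-step).  Choices that matter:

- **Initialization.** The first start places the component means at the
  25th/75th sample percentiles with the sample variance as shared initial
  variance and equal weights.  `restarts − 1` (default 9) further starts
  draw a seeded random percentile pair in (5, 95) and a random weight in
  (0.2, 0.8).  The restart with the best final log-likelihood wins.
- **Variance floor.** Component variances are floored at 10⁻⁶ × sample
  variance to prevent the classical singularity of a component collapsing
  onto one observation.
- **Convergence.** |Δℓ| ≤ tol · max(|ℓ|, 1) with tol = 10⁻⁸, capped at
  `max_iter` = 500 iterations; the returned fit reports `converged` and the
  full per-iteration log-likelihood trace, which is non-decreasing by
  construction (asserted throughout the test suite).  On genuinely unimodal
  data EM crawls along a likelihood plateau and may need thousands of
  iterations at this tolerance; the fit is still valid and flagged
  unconverged rather than silently accepted.
- **Canonical order.** Components are returned sorted by ascending mean, so
  component 1 is the "fewer awns" group and component 2 the "more awns"
  group; observations are assigned by maximum posterior.  Only k = 2 is
  supported (the `k` argument is reserved).

The split counts (num1, num2) feed the same Pearson test as the qualitative
route.  In the reporting table the columns mirror the quantitative-report
convention: mean1, var1, mean2, var2, num1, num2, numratio_1vs2, chisq,
chisq_p, one row per trait × projection.

## Morphometry

Inputs are co-registered binary body and awn masks (identical dimensions)
with a mm-per-pixel scale.  Traits:

- **SA, SAA** — body and awn pixel counts × scale².  An empty awn mask is a
  valid awnless spike (SAA = 0); an empty body mask is an error.
- **SP** — length of the outer contour of the largest 8-connected body
  component.  The sub-pixel marching-squares contour is simplified by
  Douglas–Peucker with a 1-px tolerance before measuring; this suppresses
  the staircase bias of raw pixel contours (≤ 0.5 % length error for
  objects ≥ 100 px: digitized circle 315.1 px vs 2π·50 = 314.2; rectangle
  478 px vs 480).
- **SL** — extent of the body pixels along the first principal axis of
  their coordinates (+1 px for the pixel footprint), × scale.
- **SRO** — roundness, the isoperimetric quotient 4π·SA/SP² (1 for a disc;
  discretization can push it a fraction of a percent above 1).
- **SSO** — solidity ("integrity"): SA divided by the convex-hull area of
  the body.  The hull area is the hull polygon through pixel centers plus
  the Pick-style correction perimeter/2 + 1, which upper-bounds the hull's
  lattice-point count, so SSO ≤ 1 holds exactly (and equals 1 exactly for
  an axis-aligned rectangle).
- **Kite (two-quadrilateral) model** — the spike axis is the first
  principal axis through the pixel centroid; base and tip are the extreme
  projections onto it (q_L = extent); the half-width q_ym is the mean of
  the maximal left and right perpendicular excursions (+0.5 px each),
  symmetrizing the outline; q_S = q_L × q_ym.  For a rhombus with diagonals
  d₁ ≥ d₂ the model is exact (q_L = d₁, q_ym = d₂/2, q_S = d₁d₂/2), which
  is the analytic oracle used in the tests.  Bodies with length/width < 1.5
  are rejected — the model presumes an elongated spike.  Whether the
  upstream tool's q_ym is a half- or full width could not be confirmed;
  the half-width convention here is internally consistent (q_S = q_L·q_ym
  equals the kite area) and documented.

All traits are exactly translation invariant and exactly scale covariant
(lengths ∝ scale, areas ∝ scale², SRO/SSO invariant), asserted bit-for-bit
in the suite.  Batch processing records per-mask failures without aborting
and refuses duplicate (spike_id, projection) keys.

## Synthetic data generator

The generator emulates the study conditions so every stage is testable
without the original greenhouse images:

- **Population.** n = 187 plants by default (the study reports 185 grown
  plants and 187 phenotyped spikes; n is a parameter), genotypes drawn
  multinomially from the exact F2 category frequencies of the chosen model,
  phenotypes through its class map.
- **Traits.** Per (class, projection) Gaussian values.  The default preset
  puts the dominant class at mean 10, variance 1, and the recessive
  (tetraaristatum-like, more awns) class `separation_sd` pooled SDs higher
  in all four projections.  The default separation is 4.5 SDs.  Rationale:
  with weights 0.75/0.25 and unit variances the Bayes-optimal assignment
  misclassifies ≈ 5.5 % of observations at 3 SDs (decision boundary
  μ₁ + 1.5σ + ln3/(3σ)) and the resulting split distortion drops the 3:1
  non-rejection rate to ≈ 0.6, whereas at 4.5 SDs Bayes error is ≈ 1 % and
  the non-rejection rate is ≈ 0.93–0.95 — the cleanly bimodal regime the
  awn-area trait actually exhibits.  The marginal-separation behaviour is
  itself pinned by a seeded test.
- **Projection correlation.** Projections are conditionally independent
  given the class by default; an optional common per-plant random effect
  (variance fraction f, conventionally 0.5 when enabled) models the
  physical correlation of four views of one spike while preserving the
  marginal per-class variance: x = μ + √(f·σ²)·z_plant + √((1−f)·σ²)·z_proj.
- **Masks.** A rendered spike is a filled ellipse (major axis vertical)
  plus thin awn segments radiating from the apical quarter of the boundary
  at seeded angles within ±50° of the axis, dilated to the requested
  thickness and clipped against the body.  The ground-truth record (analytic
  ellipse area, axes, awn pixel count) is the oracle linking the image and
  statistics halves of the pipeline.
- **Seeding.** One integer seed drives per-operation child streams
  (`numpy SeedSequence` spawn keys), so isolated stages and end-to-end runs
  are equally reproducible; per-(trait, projection) EM seeds are derived
  from the config seed and a CRC of the trait name, independent of
  processing order.

What the generator does *not* model: photorealistic spike texture and
colour, modifier genes ("partial awnedness") beyond variance inflation,
segmentation errors, linkage between loci, and correlated measurement error
across traits.  Passing tests therefore demonstrate the statistical
machinery and its calibration on idealized class-conditional Gaussians and
clean masks, not robustness to segmentation noise or non-Gaussian trait
distributions.

## Calibration facts worth knowing

- Type-I error of the ratio test at n = 187, α = 0.05: 3:1 → 0.052,
  13:3 → 0.049, 15:1 → 0.047, 61:3 → 0.054 (all within [0.03, 0.07]).
  For 63:1 the expected recessive count is 2.9 and the test's exact
  rejection probability, by binomial enumeration, is 0.0286 — conservatively
  *below* the nominal band because the discrete tail jumps from
  P(X ≥ 7) ≈ 0.029 straight past 0.05.  This is a property of the Pearson
  approximation at tiny expected counts, not of the implementation; at such
  expectations an exact binomial test is the better instrument.
- EM calibration (200 seeded replicates, n = 187, weights 0.75/0.25,
  4.5-SD separation): mean absolute error of recovered means ≈ 2 % of the
  separation, misclassification ≈ 1.2 %, 3:1 non-rejection ≈ 93 %.
- The probability that a well-separated trait passes the four-projection
  consistency rule is ≈ 0.88 (the four per-projection tests share the
  plant-class draw, so their rejections are positively correlated).

## Numerical and degenerate-input conventions

- Mixture fitting requires ≥ 8 finite, not-all-identical observations.
- `expected_counts` requires n > 0; a zero *expected* class count (never
  possible for the library ratios) is an error; a zero *observed* count is
  valid.
- Report tables round χ² and p to 3 decimals for display; full precision is
  kept in JSON sidecars.  All table writers use fixed float formats so that
  identical config + seed reproduce byte-identical files.
- The pipeline marks a trait × projection with < 8 observations as a failed
  row and the trait's four-projection verdict as `not_evaluable` rather
  than aborting the run.
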