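# Methods

## Contact mechanics background

A rigid sphere of radius R indenting an elastic half-space (modulus E,
Poisson ratio v) to depth h obeys the exact parametric solution

    F  = (E*/2) [ (rc² + R²) ln((R + rc)/(R − rc)) − 2 rc R ],
    h  = (rc/2) ln((R + rc)/(R − rc)),         E* = E/(1 − v²),

where rc is the contact radius. The pair has no closed F(h); this package
inverts the depth relation by bracketed root search (Brent's method on
rc/R ∈ [0, 1 − 1e−12], converged far below 1e−10 relative — the bracket makes
the log singularity at rc = R unreachable).

A practical closed form follows from expanding the contact radius,
rc/R = c1 (h/R)^{1/2} + c2 (h/R) + … + cN (h/R)^{N−1}, and integrating the
axisymmetric stiffness relation dF/dh = 2 E* rc:

    F = 2E* [ (2/3) c1 R^{1/2} h^{3/2} + (1/2) c2 h² + (1/3) c3 R^{−1} h³
              + … + (1/N) cN R^{2−N} h^N ].

Two coefficient sets are built in: N=3 {1.022, −0.1133, −0.0742}, valid to
h/R = 1.32, and N=6 {1.0100000, −0.0730300, −0.1357000, 0.0359800,
−0.0040240, 0.0001653}, valid to h/R = 4.9512. Domain enforcement carries a
1% relative grace because published lookup tables for the six-term set extend
to h/R = 5.00, marginally past the nominal bound. `fit_coefficient_set`
regenerates such sets from the exact relation (2000 uniformly spaced rc/R
samples, unweighted least squares on the {x^{1/2}, x, …, x^{N−1}} basis) for
validation and custom domains; the printed sets remain the defaults. The
printed three-term set deviates from the parametric relation by up to 0.0038
in rc/R near its domain edge (the six-term set by ~0.001); refitted sets
match or better those residuals, so a tighter agreement should not be
expected of them.

The Hertz law F = (4/3) E* R^{1/2} h^{3/2} is the h ≪ R limit. Using it at
h = R underestimates E by ≈ 10% — reproduced exactly by the benchmark in
`fit_hertz_modulus` tests and the acceptance script.

## Tangent-line calibration

The tangent to the force curve at maximum depth, F = S h + b with
S = dF/dh|_{hmax}, has two informative intercepts:

* **Indentation axis**, hcom = −b/S. Both S and −b are proportional to E*, so
  their ratio depends only on hmax/R. The dimensionless map

      hcom/hmax = [ (1/3) c1 x^{3/2} + (1/2) c2 x² + (2/3) c3 x³ + …
                    + ((N−1)/N) cN x^N ] / ( x · rc(x)/R ),   x = hmax/R,

  is strictly decreasing from 1/3 (Hertz limit, x → 0) to ≈ 0.1002 at x = 5
  (where hcom/R ≈ 0.5). `solve_radius` inverts it by bracketed root search
  (monotone, so Brent on x ∈ [1e−4, domain_max], rtol 1e−12) and returns
  R = hmax/x. No modulus enters: radius calibration requires no knowledge of
  the sample.

* **Force axis**, b = −2E* R² [ (1/3) c1 x^{3/2} + (1/2) c2 x² + … ]. With R
  known, `solve_modulus` returns E = −b (1 − v²)/(2B), B the bracket at
  (hmax, R).

**Degeneracy.** Under the Hertz law, hcom = hmax/3 identically: shallow
curves carry no radius information. When |hcom/hmax − 1/3| < 0.005 (default,
configurable) the calibration refuses to return R and flags the curve. The
threshold reflects the granularity of the tabulated relation at small
depth ratios (~0.0005 of hcom/hmax per 0.01 of hmax/R).

**Coefficient-set policy.** By default the wide six-term set solves first;
if the recovered ratio lies within the three-term domain (≤ 1.32) the result
is re-solved and reported with the simpler set, the one used at the bench.

**Worked bench example** (agarose gel, nominal 1 μm borosilicate sphere).
From the published tangent S = 0.2505 N/m and b = −3.363e−8 N at
hmax = 432 nm: hcom = 1.342e−7 m, hcom/hmax = 0.3106, and the three-term
inversion gives hmax/R = 0.4692, R = 0.921 μm — matching the probe's
grating-calibrated radius (0.92 μm). Substituting the same printed values
into the modulus relation yields E = 161.8 kPa; the source experiment quotes
132.5 kPa for this curve, which does not follow from its own printed S, b,
hmax and R. We implement the equation verbatim and leave the published
number unreconciled (its batch modulus range, 102–174 kPa, brackets both
values).

**Known print inconsistency in the tabulated relation.** The fine-grid
table prints 0.2802 at ratio 1.00 while the coarse-grid table prints 0.2803;
the six-term evaluation gives 0.280287, so 0.2803 is the self-consistent
rounding and is what this package produces.

## Quartic convenience map and the naive-coefficient pitfall

`fit_inverse_quartic` least-squares fits hmax/R as a quartic in hcom/hmax on
a uniform ratio grid (step 0.01). The fit's coefficient of determination
rounds to 1.0000, but a quartic cannot follow the square-root-like approach
to the Hertz limit pointwise: residuals reach ~0.008 in hmax/R, e.g. 0.4724
instead of the exact 0.4692 at intercept ratio 0.3106. The map is a bench
convenience; `solve_radius` (exact inversion) is the accurate path and is
what the pipeline uses. The map is regenerated rather than stored because
its coefficients are individually huge and mutually cancelling — evaluation
is hypersensitive to their rounding.

Reading (E, R) directly off the cubic-fit coefficients via
a = 4c1 E* R^{1/2}/3, b = c2 E*, c = 2c3 E*/(3R) is exact on noiseless model
data but catastrophically unstable on noisy curves: many (a, b, c) triples
produce near-identical curves. A seeded 30-curve Monte Carlo at 1% force
noise and depth ratio 1 gives a naive-R coefficient of variation of ~1.5 and
a ~4× mean bias, against ~0.14 and no bias for the tangent construction
built from the same fit. `naive_coefficient_recovery` exists to document
this failure mode.

## Curve processing

**Contact point.** Every admissible sample of the raw approach curve is
tried as the contact point: a polynomial (default degree 1, configurable
0–3) is fitted to the pre-contact deflection and the {h^{3/2}, h², h³}
contact basis to the post-contact force–indentation data; the index with the
lowest combined sum of squared residuals wins (exhaustive scan up to 5000
points, stride 2 beyond). Two refinements sharpen the minimum: the contact
offset is anchored at the pre-contact fit's value rather than the noisy
single sample, and trailing points at non-positive depth are charged their
full force against a zero model. Both residual sums are computed in force
units so they are commensurate. Measured accuracy on the default synthetic
curve at 1% force noise (50 seeds): max |offset| 5 samples, median 1.5,
88% within ±3.

**Conversion.** F = k(d − d_c), h = (z − z_c) − (d − d_c) on the post-contact
segment. Retract data are rejected by a drawdown test (depth falling more
than 5% of its range below its running maximum); sub-sample jitter from
noise is stably sorted instead of rejected. hmax is the largest post-contact
depth; no smoothing is applied by default.

**Fitting.** F = a h^{3/2} + b h² + c h³ is linear in (a, b, c); ordinary
unweighted, unconstrained least squares (column-normalized for conditioning
at nanometer scales) reproduces bench practice. The physical sign pattern
a > 0, b < 0, c < 0 is reported, never enforced. Beyond depth ratio ~1.32
this cubic is only an approximation to the six-term law; the tangent it
implies biases recovered R by roughly 6% at ratio 2. Deep-indentation users
should treat recovered radii as approximate or supply analytic tangents.

**Sensitivities (measured on the default 200-point, 432 nm curve).**
Contact mislocation by ±3 samples (±6.5 nm) moves recovered R by up to ~9%
(≈1.4% per nm) — an early contact both offsets every depth and injects
baseline points into the fit. The radius inversion also amplifies intercept
noise: at depth ratio 0.47 a 1% change in hcom/hmax moves R by ~5%.

## Synthetic data generator

`SimulationSpec` defaults emulate the bench experiment: E = 132.5 kPa,
v = 0.5, R = 0.921 μm, hmax = 432 nm (depth ratio 0.47), 200 post-contact
points, 200 baseline points, noiseless unless a noise fraction and seed are
given. Batches fix R (one probe, many spots) and draw E uniformly from
102–174 kPa, the spread observed on a 2.5% agarose gel. Noise is additive
Gaussian on force only, with sd expressed as a fraction of Fmax —
photodiode-dominated error; depth noise, drift, adhesion and viscoelasticity
are not modelled. Raw curves synthesize z = h + F/k with an optional tilted,
noisy baseline and record the true contact index.

What passing tests therefore show: the pipeline is exact on data that follow
the model and degrades gracefully under white force noise. What they do not
show: robustness to the systematic model misfit, adhesion rings and drift of
real curves. Notably, under white noise at the default depth ratio the
single-curve radius estimate tolerates only ~0.1% noise for a 5% spread
(hcom/hmax needs ~0.001 accuracy); the 1.5% radius spread reported for the
real 80-curve experiment is consistent with its residuals being systematic
(shared curve shape) rather than white. Deeper indentation (ratio ≥ 1)
relaxes this considerably: at 1% noise and ratio 1 the spread is ~15%, and
averaging a batch recovers the mean radius to ~1%.

## Numerical choices

* All lengths SI meters internally; nm/nN conversion only at I/O.
* Root searches: Brent with brackets fixed by monotonicity; rtol ≤ 1e−12.
* Lookup-table export rounds half-even to 4 decimals (numpy default),
  matching published table precision; the CSV header is
  `hmax_over_R,hcom_over_hmax`.
* Least squares throughout via `numpy.linalg.lstsq` on column-normalized
  design matrices.
* Degenerate inputs raise typed errors (`DomainError`,
  `DegenerateCurveError`) with actionable messages; the estimator converts
  degeneracy into a flag plus NaN results so batch drivers can count rather
  than crash; the CLI maps it to exit code 2.

## Problem sizes

Simulation-backed tests use 200–1000 point curves, 25–50 seed Monte Carlo
repeats and batches of 40–80 curves; the full suite and the acceptance
script each run in well under a minute on one CPU.

## Limitations

Adhesive contact (JKR/DMT), conical/pyramidal/flat indenters, substrate
thickness corrections, viscoelastic loading-rate effects, plastic
deformation, and instrument-side calibration (deflection sensitivity, spring
constant) are out of scope. Proprietary instrument file formats are not
read; curves enter as delimited text.
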