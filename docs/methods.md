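# Methods

## Model

The outcome is weekly time spent walking or cycling to and from work,
reported in hours and rounded to the nearest half hour; the number of
half-hour units is a non-negative integer and is modelled as Poisson with a
log link. Rounding ties (x.25, x.75 hours) round half away from zero — the
choice is a convention, and the generator's "continuous hours" mode
exercises it explicitly.

The semiparametric geographically weighted Poisson regression (GWPR) lets
the coefficients of the *environmental* terms vary with residential
location while the *individual-level* coefficients stay fixed:

    log λ_i = Σ_k β_k(u_i, v_i) x_ik + Σ_m γ_m x_im

A spatially varying intercept belongs to the local set by default. With an
empty local set the model degenerates, exactly, to the global Poisson
regression (GPR); with constant true surfaces the two are asymptotically
equivalent, which the tests exploit.

## Estimation

**Local fits.** At each observation site *i*, local coefficients maximize
the geographically weighted log-likelihood Σ_j w_ij [y_j η_j − exp(η_j)]
by Fisher scoring, with the fixed part as an offset. Weights come from the
kernel; the regression point itself always has weight 1.

**Kernels and bandwidths.** Two families: bi-square
(1 − (d/b)²)² for d < b, else 0, and Gaussian exp(−½(d/b)²). Bandwidths are
fixed (meters) or adaptive — b_i is the distance from site *i* to its N-th
nearest *other* point, so each local regression sees a constant number of
neighbours regardless of density. Consequences of that definition, stated
so neighbour counts are interpretable: the N-th neighbour itself receives
bi-square weight 0 (strict d < b), and only points strictly inside b_i have
positive weight. Distances are planar Euclidean; coordinates that look like
longitude/latitude degrees are refused by the pipeline unless overridden.

**Back-fitting.** The fixed coefficients γ are initialised from a global
GLM on all columns; the algorithm then alternates (a) local fits at every
site with offset X_global γ and (b) a global Poisson fit for γ with each
observation's own-location local predictor as offset, stopping when the
largest absolute coefficient change drops below 1e-5 or after 50 cycles.
The tolerances are implementation choices. Internally the fixed columns are
mean-centered during the alternation: the local intercept surface and the
fixed-term means are otherwise nearly collinear, which makes the iteration
crawl along a flat ridge (hundreds of cycles, with tiny deviance drift);
after centering it converges in about five cycles, and the intercept
surface is shifted back so all reported coefficients refer to the original
columns. The deviance trace is non-increasing across cycles up to solver
tolerance, and this is asserted in tests.

**Effective parameters and AICc.** Model complexity is
k = trace(S) + p_global, with S the local-step hat matrix at convergence
(row i: λ_i x_iᵀ (X_localᵀ W_i A X_local)⁻¹ x_i contribution on the
diagonal, A = diag(λ)). AICc is reported on the deviance scale,
**AICc = D + 2k**. The classical small-sample correction term
2k(k+1)/(n−k−1) is available behind a flag but off by default: the
deviance-scale form is the one used for the global/local comparison, and it
is what the bandwidth search minimizes. The grid search is exhaustive over
a descending neighbour-count grid (default from min(4000, n−1) down to 50
in steps of 50); no golden-section refinement.

**Standard errors.** Local standard errors use the sandwich form
C = (XᵀWAX)⁻¹ (XᵀW²AX) (XᵀWAX)⁻¹, the correct variance of the weighted
estimator when observations are independent Poisson; the naive inverse
information is available via `se_type="naive"` and the choice is recorded
in output metadata. Pseudo t-values are β/se, with |t| strictly greater
than 1.96 flagged significant; γ standard errors are conditional on the
converged local part. Under a true-zero surface the pooled flag fraction
sits near the 5% nominal level (checked over 20 simulated cohorts).

## Environmental composites

The 15 neighbourhood variables are compressed by PCA of the correlation
matrix; components with eigenvalues above 1 are retained (Kaiser rule) and
varimax-rotated. Varimax uses Kaiser row normalization, convergence 1e-8,
at most 100 sweeps; the rotation is authored in-package with the classic
pairwise-angle algorithm (atan2 form) because gradient-projection
implementations can stall on symmetric saddle configurations. Rotation
preserves communalities to 1e-8 (asserted). Sampling adequacy is reported
as the overall KMO statistic (anti-image partial correlations) and
Bartlett's sphericity chi-square. Component scores are unit-variance;
score signs are fixed by anchor variables (facility density positive on
the built composite, median income positive on the socio-economic one).

The perceived-environment index is the first principal component of three
5-level Likert items (bike safety, pollution, aesthetics). The aesthetics
item loads negatively while the index is described as "higher = better
perceived"; because that description is internally ambiguous, orientation
is anchored on the bike-safety loading being positive, only.

GIS constructions: kernel density uses the quartic (biweight) kernel with
the bandwidth as its support radius, densities in units per km², mass
conserved to quadrature accuracy; polylines are densified every 10 m with
length-share weights. Zone attributes transfer to the 200 m grid by the
cell-center rule (areal weighting is deliberately not the default; counts
must be converted to densities upstream — the transfer is only valid for
intensive attributes). Buffer linkage is the mean of cell centers within
500 m; station access is the nearest-feature Euclidean distance.

## Synthetic cohorts

The generator emulates the statistical structure of a web-cohort spread
over an irregular urban region ~30 km across:

* **Locations** — uniform proposals thinned by exp(−d/τ) decay from the
  centroid (τ = 6 km) inside an irregular octagon with two circular 1.8 km
  "park" holes; exactly n points, fully seeded.
* **Environment** — two smooth latent surfaces (a radial built-density
  factor, σ = 9 km, and a bump-mixture socio-economic factor), standardized
  over the sample; 15 variables are signed loadings (|ℓ| = 0.85 for the 11
  block variables, weak cross-loadings 0.45/0.35 for 4 others) times the
  factors plus unit-completing noise. This puts the first-two-component
  variance share at ~0.66 and makes the Kaiser rule retain exactly two
  components, which the tests require over 10 seeds.
* **Individual covariates** — marginals of the emulated study population:
  78% women, 83.1% ≥ high school, 36.7% workplace parking, 45.8% transit
  pass, balanced commuting-time tertiles, Poisson vehicle/bike counts
  capped at 8/4, age from a normal truncated to [18, 87] whose parent mean
  (42.6, sd 13.3) is located so the truncated mean is 43.6.
* **Perception items** — one latent factor with generative loadings
  (+0.47, +0.45, −0.45), discretized at fixed cutpoints into 5 levels,
  which puts the index's first-component share just under one half.
* **Outcome** — counts drawn directly in half-hour units from the
  log-linear intensity, so discretization is the identity on synthetic
  data by default. True surfaces are closed-form (constant, linear
  gradient, Gaussian bump) and evaluable anywhere, enabling exact recovery
  scoring. The default intercept (0.85) calibrates the mean outcome to
  ~1.4 h/week; fixed coefficients follow the global-fit magnitudes (the
  commuting-time tertile enters as a 0/1/2 score with coefficient 0.33 per
  step). Zero inflation exists only as an option (off by default — the
  fitted model is plain Poisson; switching it on emulates a 41%
  non-commuter share as a deliberate misspecification stressor).

What the generator does **not** emulate: real street-network geography,
census-zone semantics, spatially correlated reporting error, or outcome
overdispersion beyond what the log-linear spread induces. Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to the full messiness of cohort
data.

## Benchmark scenarios and problem sizes

The recovery benchmark ("G1") uses n = 1000 with a linear east-west
gradient of amplitude 0.3 on the built-environment coefficient and a
reduced bandwidth grid {100, 200, 400, 800}; its stationary clone differs
only by a constant coefficient. Null calibration uses n = 600, N = 200,
20 seeds. The model-selection comparison uses the grid
{100, 200, 400, 800, 950}, whose top sits near n so that a stationary
truth can express its preference for the largest bandwidth while a
nonstationary one pulls the minimum into the interior. These sizes keep
the simulation suites to a few minutes while leaving the Monte-Carlo
margins comfortable; the full-cohort shape (n = 4164, 80-point grid) runs
through exactly the same code path.

## Numerical choices and degenerate inputs

IRLS/Fisher scoring converge on relative deviance change 1e-8 (global,
max 100 iterations) and coefficient change 1e-9 (local, max 50). Rank
deficiency raises an error naming the collinear columns in global fits;
locally it flags the site unstable, which excludes it from summaries and
increments a warning count. λ overflow guards trip at a linear predictor of
30 (generator) and 700 (fits). Nagelkerke's R² uses full log-likelihoods
including the log y! term in numerator and denominator consistently. Mean
ORs in local summaries are exp(mean log-odds) (matching how the global and
local tables are compared); min/max/range ORs exponentiate each local
estimate first. IDW display surfaces use power 2 and a 12-neighbour
truncation — display-only defaults, config-exposed, never used in fitting.

## Known limitations

Local multicollinearity beyond rank checks is not diagnosed; residual
spatial autocorrelation is not tested; border sites necessarily have larger
adaptive kernels (an inherent edge effect); binomial/Gaussian
geographically weighted families and negative-binomial or zero-inflated
likelihoods are out of scope. The pseudo-t surfaces are pointwise and carry
no multiplicity correction, matching standard practice for these displays.
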