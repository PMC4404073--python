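# gwcommute

Spatially varying associations between the residential environment and
active commuting (walking and cycling to/from work), estimated with a
semiparametric **geographically weighted Poisson regression (GWPR)**.

## The problem

Studies of environmental correlates of physical activity usually fit one
global regression and implicitly assume the association is the same
everywhere in the study area. That assumption — spatial stationarity — is
frequently wrong for geographic data: the same one-unit increase in, say,
neighbourhood facility density may matter in a low-density suburb and be
irrelevant in a saturated city core. This package implements the analysis
chain needed to test and map that heterogeneity for a count-like outcome
(weekly hours of active commuting, rounded to half-hour units), aimed at
spatial epidemiologists and health-geography researchers.

## The model

Weekly active-commuting half-hours for participant *i* at residential
location (*u_i*, *v_i*) are modelled as Poisson with log-linear intensity

    log λ_i = Σ_k β_k(u_i, v_i) x_ik + Σ_m γ_m x_im

where the *x_ik* are environmental covariates whose coefficients
β_k(u, v) vary with location and the *x_im* are individual-level
covariates with fixed coefficients γ_m (the *semiparametric* or mixed GWR
form). Local coefficients are estimated at every observation site by
maximizing a geographically weighted log-likelihood, with weights from an
**adaptive bi-square kernel**: w = (1 − (d/b)²)² for d < b, where b is the
distance to the site's N-th nearest neighbour. The neighbour count N is
selected by minimizing **AICc = D + 2k** (deviance plus twice the effective
number of parameters, k = trace(S) + p_global); the global and local models
are compared with the minimum-AICc rule (**MAICE**), a difference above 2
counting as substantial. Local significance is summarized by pseudo
t-values (β/se, sandwich standard errors), with |t| > 1.96 flagging p < 0.05.

The environmental covariates themselves are built in-package: varimax PCA
composites (Kaiser retention, KMO and Bartlett diagnostics) of 15 collinear
neighbourhood variables, a perceived-environment index from three Likert
items, kernel-density rasters, 200 m grid disaggregation, 500 m buffer
means and nearest-station distances. A synthetic-cohort generator
reproduces the statistical structure such a study assumes — irregular urban
point pattern with park "holes", two latent spatial factors behind the
environmental block, realistic individual-covariate marginals, and exactly
evaluable true coefficient surfaces — so the whole chain is testable
without any cohort download.

## Worked example

`examples/02_gwpr_bandwidth_and_surfaces.py` generates a 1,000-participant
cohort whose built-environment coefficient rises linearly from west
(0.05 − 0.3) to east (0.05 + 0.3), selects the bandwidth and fits the GWPR:

```
AICc trace over candidate neighbour counts:
  N   aicc  deviance    k  cycles
100 1157.6     999.9 78.8       8
200 1134.7    1043.0 45.8       6
400 1129.2    1072.1 28.5       5
800 1130.7    1094.8 18.0       5

selected N = 400, delta AICc (GWPR - GPR) = -38.4, substantial = True, preferred = GWPR

local estimate summary (per locally varying term):
            mean_log_odds  std_log_odds  mean_OR  min_OR  max_OR  range_OR
Intercept           0.780         0.095    2.181   1.626   2.656     1.029
env_built           0.050         0.113    1.051   0.812   1.317     0.505
env_socio          -0.002         0.098    0.998   0.784   1.284     0.500
perception          0.022         0.045    1.022   0.953   1.137     0.184

correlation of fitted env_built surface with the generative truth: r = 0.761
```

Reading the output: the AICc minimum at N = 400 picks the kernel size; the
negative ΔAICc (−38.4, far beyond the ±2 substantiality threshold) says the
local model is worth its 28.5 effective parameters; the `env_built` row
recovers the generative mean (0.05) and its OR range (0.81–1.32, straddling
1) is the signature of a locally varying association — positive in the
east, negative in the west, matching the truth with r = 0.76 at this n.
The other examples cover the global model (`01`), the PCA composites and
perception index (`03`), and the KDE/buffer/IDW geometry (`04`). A thin CLI
(`gwcommute simulate|composites|fit-global|fit-gwpr|run-all`) wraps the
same pipeline for shell use.

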