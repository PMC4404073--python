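"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a web-cohort of adults spread over an irregular urban
region roughly 30 km across, with a dense core, sparse boundary and two
excluded "park" holes. It produces:

* an inhomogeneous residential point pattern (density decaying from the
  core, no points inside the parks);
* fifteen collinear neighbourhood variables driven by two smooth latent
  spatial factors (a built-density factor peaking at the core and an
  independent socio-economic factor), calibrated so the first two principal
  components carry 55–75 % of the variance;
* individual covariates with marginals matching the study population
  (78 % women, 83 % ≥ high school, balanced commuting-time tertiles, ...);
* three 5-level Likert perception items from one latent factor with the
  +/+/− loading pattern of the perceived-environment index;
* a half-hour-unit Poisson outcome from a log-linear intensity with
  spatially varying environmental coefficients and fixed individual ones.

True coefficient surfaces are exact closed-form functions (constant, linear
gradient, or Gaussian bump mixtures), so parameter-recovery can be scored
against them at any location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .glm import discretize_outcome

__all__ = [
    "SurfaceSpec",
    "TrueSurfaces",
    "ScenarioConfig",
    "SyntheticCohort",
    "default_region",
    "gen_locations",
    "gen_environment",
    "gen_individual_covariates",
    "gen_likert",
    "gen_outcome",
    "generate_cohort",
    "scenario_g1",
    "scenario_stationary",
    "scenario_null",
    "individual_design",
    "ENV_LOADINGS",
]

# Individual-level coefficients, patterned on the global-fit magnitudes of
# the study population (age per year, tertile per step).
DEFAULT_GAMMA = {
    "age_c": 0.004,
    "female": 0.04,
    "educ_high": -0.12,
    "parking_work": -0.29,
    "transit_pass": -0.05,
    "commute_tertile": 0.33,
    "n_vehicles": -0.19,
    "n_bikes": 0.09,
}

# Default true surfaces: spatially constant, magnitudes near the global
# estimates; the intercept is calibrated so the mean outcome matches the
# study population (~1.4 h/week, i.e. ~2.7 half-hour units).
DEFAULT_SURFACES = {
    "Intercept": {"kind": "constant", "value": 0.85},
    "env_built": {"kind": "constant", "value": 0.05},
    "env_socio": {"kind": "constant", "value": 0.01},
    "perception": {"kind": "constant", "value": 0.04},
}

# 15 environmental variables: (name, loading on built-density factor,
# loading on socio-economic factor). Signs follow the observed pattern:
# dense, walkable cores have collective housing, facilities and bike
# sharing, few cars and parking spots; well-off areas have high income and
# graduates, few unemployed and foreign residents. Four variables carry only
# weak cross-loadings.
ENV_LOADINGS = [
    ("pct_parking_spot", -0.85, 0.0),
    ("pct_car_owners", -0.85, 0.0),
    ("pct_individual_housing", -0.85, 0.0),
    ("pct_collective_housing", 0.85, 0.0),
    ("pct_home_owners", 0.85, 0.0),
    ("facility_density", 0.85, 0.0),
    ("bikeshare_density", 0.85, 0.0),
    ("median_income", 0.0, 0.85),
    ("pct_university", 0.0, 0.85),
    ("pct_unemployed", 0.0, -0.85),
    ("pct_foreign", 0.0, -0.85),
    ("pct_part_time", 0.45, -0.35),
    ("pct_vegetation", -0.45, 0.35),
    ("dist_transit", -0.45, -0.35),
    ("bikepath_density", 0.45, 0.35),
]

# Perception items: generative loadings sized so the first principal
# component of the three items carries just under half the variance, as in
# the study's index. Aesthetics loads negatively.
LIKERT_ITEMS = [("bike_safety", 0.47), ("pollution", 0.45), ("aesthetics", -0.45)]
LIKERT_CUTPOINTS = (-1.2, -0.4, 0.4, 1.2)


def default_region(center=(15000.0, 15000.0), mean_radius=13500.0):
    """Irregular octagonal study region ~30 km across with two circular
    'park' holes (west and east of the core)."""
    cx, cy = center
    angles = np.linspace(0, 2 * np.pi, 9)[:-1]
    wiggle = np.array([1.05, 0.88, 1.10, 0.95, 1.02, 0.85, 1.08, 0.92])
    shell = [
        (cx + mean_radius * w * np.cos(a), cy + mean_radius * w * np.sin(a))
        for a, w in zip(angles, wiggle)
    ]
    holes = [
        Point(cx - 5500, cy + 500).buffer(1800),
        Point(cx + 6000, cy - 500).buffer(1800),
    ]
    return Polygon(shell, [list(h.exterior.coords) for h in holes])


@dataclass(frozen=True)
class SurfaceSpec:
    """Closed-form true coefficient surface β(u, v).

    kinds: ``constant`` (value); ``gradient`` (base + amplitude, linear in a
    direction, scaled so the coefficient spans base ± amplitude across the
    region's bounding box); ``bump`` (base + amplitude · Gaussian at a
    center with scale sigma_m).
    """

    kind: str = "constant"
    value: float = 0.0          # constant value, or the base for gradient/bump
    amplitude: float = 0.0
    direction: tuple = (1.0, 0.0)
    center: tuple = (15000.0, 15000.0)
    sigma_m: float = 5000.0
    extent: tuple = (0.0, 30000.0)  # projection range for the gradient

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceSpec":
        return cls(**d)

    def __call__(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "constant":
            return np.full(np.broadcast(x, y).shape, self.value)
        if self.kind == "gradient":
            dx, dy = self.direction
            nrm = np.hypot(dx, dy)
            s = (x * dx + y * dy) / nrm
            lo, hi = self.extent
            t = 2.0 * ((s - lo) / (hi - lo) - 0.5)  # -1 at lo edge, +1 at hi
            return self.value + self.amplitude * t
        if self.kind == "bump":
            cx, cy = self.center
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return self.value + self.amplitude * np.exp(-d2 / (2.0 * self.sigma_m**2))
        raise ValueError(f"unknown surface kind: {self.kind!r}")


@dataclass
class TrueSurfaces:
    """The generative counterpart of the locally varying coefficients:
    one evaluable surface per local term."""

    surfaces: dict

    def __getitem__(self, term):
        return self.surfaces[term]

    def terms(self):
        return list(self.surfaces)

    def table(self, points) -> pd.DataFrame:
        pts = np.asarray(points, float)
        return pd.DataFrame(
            {t: f(pts[:, 0], pts[:, 1]) for t, f in self.surfaces.items()}
        )

    @classmethod
    def from_specs(cls, specs: dict) -> "TrueSurfaces":
        out = {}
        for term, s in specs.items():
            out[term] = s if callable(s) else SurfaceSpec.from_dict(dict(s))
        return cls(out)


@dataclass
class ScenarioConfig:
    """Full description of one synthetic cohort.

    ``surfaces`` maps each locally varying term to a surface spec dict;
    ``gamma`` gives the fixed individual-level coefficients. ``seed`` fixes
    every random draw. Zero inflation is off by default (the fitted model is
    plain Poisson); switching it on emulates the large non-commuter share as
    a model-misspecification stressor.
    """

    n: int = 4164
    seed: int = 0
    region: Polygon = None
    surfaces: dict = field(default_factory=lambda: dict(DEFAULT_SURFACES))
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    density_decay_m: float = 6000.0
    built_factor_sigma_m: float = 9000.0
    zero_inflation: float = 0.0
    continuous_hours: bool = False   # add jitter so rounding is exercised
    likert_spatial: bool = False
    name: str = "default"

    def __post_init__(self):
        if self.n < 50:
            raise ValueError("n must be >= 50")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.region is None:
            self.region = default_region()

    def true_surfaces(self) -> TrueSurfaces:
        return TrueSurfaces.from_specs(self.surfaces)

    def to_jsonable(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "surfaces": {
                k: (dict(v) if isinstance(v, dict) else vars(v))
                for k, v in self.surfaces.items()
            },
            "gamma": dict(self.gamma),
            "density_decay_m": self.density_decay_m,
            "built_factor_sigma_m": self.built_factor_sigma_m,
            "zero_inflation": self.zero_inflation,
            "continuous_hours": self.continuous_hours,
            "likert_spatial": self.likert_spatial,
            "name": self.name,
        }


# ---------------------------------------------------------------------------
# scenario presets

def scenario_g1(n: int = 1000, seed: int = 1, amplitude: float = 0.3) -> ScenarioConfig:
    """Nonstationary benchmark: the built-environment coefficient follows a
    linear east–west gradient of the given amplitude; everything else is
    spatially constant."""
    surfaces = dict(DEFAULT_SURFACES)
    surfaces["env_built"] = {
        "kind": "gradient", "value": 0.05, "amplitude": amplitude,
        "direction": (1.0, 0.0), "extent": (1500.0, 28500.0),
    }
    return ScenarioConfig(n=n, seed=seed, surfaces=surfaces, name="G1")


def scenario_stationary(n: int = 1000, seed: int = 1) -> ScenarioConfig:
    """Stationary clone of G1: identical in every respect except that the
    built-environment coefficient is constant."""
    return ScenarioConfig(n=n, seed=seed, surfaces=dict(DEFAULT_SURFACES),
                          name="stationary")


def scenario_null(n: int = 1000, seed: int = 1, term: str = "env_built") -> ScenarioConfig:
    """All surfaces constant and the named term's true coefficient ≡ 0,
    for significance-calibration checks."""
    surfaces = dict(DEFAULT_SURFACES)
    surfaces[term] = {"kind": "constant", "value": 0.0}
    return ScenarioConfig(n=n, seed=seed, surfaces=surfaces, name="null")


# ---------------------------------------------------------------------------
# generators

def gen_locations(config: ScenarioConfig, rng=None) -> np.ndarray:
    """Inhomogeneous residential point pattern inside the region.

    Proposals are uniform over the bounding box, thinned by an exponential
    density decay from the region centroid and rejected outside the region
    (hole interiors included). Deterministic for a fixed seed.
    """
    import shapely

    rng = np.random.default_rng(config.seed) if rng is None else rng
    region = config.region
    minx, miny, maxx, maxy = region.bounds
    cx, cy = region.centroid.x, region.centroid.y
    tau = config.density_decay_m
    out = np.empty((config.n, 2))
    got = 0
    proposals = 0
    batch = max(4 * config.n, 1000)
    while got < config.n:
        if proposals > 1_000_000:
            raise RuntimeError("could not place points: region too small or "
                               "density decay too sharp after 1e6 proposals")
        x = rng.uniform(minx, maxx, batch)
        y = rng.uniform(miny, maxy, batch)
        u = rng.uniform(size=batch)
        proposals += batch
        d = np.hypot(x - cx, y - cy)
        keep = u < np.exp(-d / tau)
        keep &= shapely.contains_xy(region, x, y)
        xk, yk = x[keep], y[keep]
        take = min(len(xk), config.n - got)
        out[got:got + take, 0] = xk[:take]
        out[got:got + take, 1] = yk[:take]
        got += take
    return out


def _built_factor(points, config: ScenarioConfig) -> np.ndarray:
    cx = config.region.centroid.x
    cy = config.region.centroid.y
    d2 = (points[:, 0] - cx) ** 2 + (points[:, 1] - cy) ** 2
    return np.exp(-d2 / (2.0 * config.built_factor_sigma_m**2))


def _socio_factor(points, config: ScenarioConfig) -> np.ndarray:
    # fixed mixture of Gaussian bumps, independent of the radial pattern
    cx = config.region.centroid.x
    cy = config.region.centroid.y
    bumps = [((cx - 4000, cy - 6000), 6000.0, 1.0),
             ((cx + 7000, cy + 5000), 5000.0, 0.8),
             ((cx - 2000, cy + 9000), 4500.0, -0.9)]
    v = np.zeros(len(points))
    for (bx, by), s, a in bumps:
        d2 = (points[:, 0] - bx) ** 2 + (points[:, 1] - by) ** 2
        v += a * np.exp(-d2 / (2.0 * s**2))
    return v


def _standardize(v):
    return (v - v.mean()) / v.std(ddof=0)


def gen_environment(points, config: ScenarioConfig, rng=None):
    """Fifteen collinear neighbourhood variables from two latent spatial
    factors plus idiosyncratic noise.

    Returns ``(variables, factors)``: a DataFrame of the 15 raw variables
    and a DataFrame with the standardized latent factor values
    (``env_built``, ``env_socio``) at each participant location.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    pts = np.asarray(points, float)
    f1 = _standardize(_built_factor(pts, config))
    f2 = _standardize(_socio_factor(pts, config))
    cols = {}
    for name, l1, l2 in ENV_LOADINGS:
        noise_sd = np.sqrt(max(1.0 - l1**2 - l2**2, 1e-6))
        cols[name] = l1 * f1 + l2 * f2 + noise_sd * rng.standard_normal(len(pts))
    variables = pd.DataFrame(cols)
    factors = pd.DataFrame({"env_built": f1, "env_socio": f2})
    return variables, factors


def gen_individual_covariates(config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Individual covariates with marginals matching the study population."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n = config.n
    # parent normal located so the [18, 87]-truncated distribution has the
    # study population's mean age of 43.6 (truncation at 18 lifts the mean)
    age = rng.normal(42.6, 13.3, size=n)
    bad = (age < 18) | (age > 87)
    while np.any(bad):
        age[bad] = rng.normal(42.6, 13.3, size=bad.sum())
        bad = (age < 18) | (age > 87)
    tertile = np.tile(np.array([0, 1, 2]), n // 3 + 1)[:n]
    rng.shuffle(tertile)
    return pd.DataFrame({
        "age": age,
        "female": (rng.uniform(size=n) < 0.780).astype(int),
        "educ_high": (rng.uniform(size=n) < 0.831).astype(int),
        "parking_work": (rng.uniform(size=n) < 0.367).astype(int),
        "transit_pass": (rng.uniform(size=n) < 0.458).astype(int),
        "commute_tertile": tertile,
        "n_vehicles": np.minimum(rng.poisson(1.03, size=n), 8),
        "n_bikes": np.minimum(rng.poisson(1.30, size=n), 4),
    })


def individual_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design matrix of the fixed individual-level terms (age centered)."""
    X = pd.DataFrame({
        "age_c": covariates["age"] - 43.6,
        "female": covariates["female"],
        "educ_high": covariates["educ_high"],
        "parking_work": covariates["parking_work"],
        "transit_pass": covariates["transit_pass"],
        "commute_tertile": covariates["commute_tertile"],
        "n_vehicles": covariates["n_vehicles"],
        "n_bikes": covariates["n_bikes"],
    })
    return X.astype(float)


def gen_likert(points, config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Three 5-level Likert items from one latent perception factor.

    Items are built as signed loading × factor + noise and discretized at
    fixed cutpoints into levels 1–5; aesthetics loads negatively, mirroring
    the perceived-environment index structure.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    pts = np.asarray(points, float)
    n = len(pts)
    if config.likert_spatial:
        g = _standardize(_socio_factor(pts, config) + 0.5 * _built_factor(pts, config))
        g = 0.7 * g + 0.7 * rng.standard_normal(n)
    else:
        g = rng.standard_normal(n)
    out = {}
    for name, load in LIKERT_ITEMS:
        z = load * g + np.sqrt(1.0 - load**2) * rng.standard_normal(n)
        out[name] = np.digitize(z, LIKERT_CUTPOINTS) + 1  # levels 1..5
    return pd.DataFrame(out), g


def gen_outcome(points, env_scores, indiv_design, surfaces: TrueSurfaces,
                gamma: dict, config: ScenarioConfig, rng=None) -> dict:
    """Weekly active-commuting hours from the log-linear Poisson intensity.

    λ_i = exp(Σ_k β_k(u_i, v_i) x_ik + Σ_m γ_m x_im), with counts drawn in
    half-hour units and hours = counts / 2. The ``Intercept`` surface
    multiplies a constant 1. Optional zero inflation multiplies counts by an
    independent Bernoulli. Returns hours, counts, the true λ and the true
    per-location coefficient table.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    pts = np.asarray(points, float)
    n = len(pts)
    beta = surfaces.table(pts)
    eta = np.zeros(n)
    for term in beta.columns:
        x = np.ones(n) if term == "Intercept" else np.asarray(env_scores[term], float)
        eta += beta[term].to_numpy() * x
    for term, g in gamma.items():
        eta += g * np.asarray(indiv_design[term], float)
    if np.any(eta > 30):
        raise ValueError("linear predictor exceeds 30: reduce surface "
                         "amplitudes or coefficient magnitudes")
    lam = np.exp(eta)
    counts = rng.poisson(lam)
    if config.zero_inflation > 0:
        counts = counts * (rng.uniform(size=n) >= config.zero_inflation)
    hours = counts / 2.0
    if config.continuous_hours:
        # jitter below the rounding half-width so discretization recovers counts
        hours = np.maximum(hours + rng.uniform(-0.2, 0.2, size=n), 0.0)
    return {"hours": hours, "counts": counts, "lam": lam, "eta": eta,
            "true_beta": beta}


@dataclass
class SyntheticCohort:
    """Everything one synthetic study generates, aligned on participants."""

    config: ScenarioConfig
    points: np.ndarray
    env_variables: pd.DataFrame     # 15 raw collinear variables
    env_factors: pd.DataFrame       # standardized latent factors (truth)
    covariates: pd.DataFrame
    likert: pd.DataFrame
    perception_factor: np.ndarray   # latent perception factor (truth)
    hours: np.ndarray
    counts: np.ndarray
    lam: np.ndarray
    true_beta: pd.DataFrame
    surfaces: TrueSurfaces

    @property
    def n(self) -> int:
        return len(self.hours)

    def env_design(self) -> pd.DataFrame:
        """True latent environmental covariates used by the generative model
        (built factor, socio factor, standardized perception factor)."""
        return pd.DataFrame({
            "env_built": self.env_factors["env_built"],
            "env_socio": self.env_factors["env_socio"],
            "perception": _standardize(np.asarray(self.perception_factor, float)),
        })

    def individual_design(self) -> pd.DataFrame:
        return individual_design(self.covariates)

    def participant_frame(self) -> pd.DataFrame:
        """Participant table as exported to CSV."""
        df = pd.DataFrame({
            "x_m": self.points[:, 0],
            "y_m": self.points[:, 1],
            "hours_per_week": self.hours,
        })
        return pd.concat([df, self.covariates.reset_index(drop=True),
                          self.likert.reset_index(drop=True),
                          self.env_variables.reset_index(drop=True)], axis=1)


def generate_cohort(config: ScenarioConfig) -> SyntheticCohort:
    """Run every generator with one master seed and assemble the cohort."""
    points = gen_locations(config)
    env_vars, factors = gen_environment(points, config)
    covariates = gen_individual_covariates(config)
    likert, g = gen_likert(points, config)
    surfaces = config.true_surfaces()
    env_scores = pd.DataFrame({
        "env_built": factors["env_built"],
        "env_socio": factors["env_socio"],
        "perception": _standardize(np.asarray(g, float)),
    })
    out = gen_outcome(points, env_scores, individual_design(covariates),
                      surfaces, config.gamma, config)
    return SyntheticCohort(
        config=config, points=points, env_variables=env_vars,
        env_factors=factors, covariates=covariates, likert=likert,
        perception_factor=g, hours=out["hours"], counts=out["counts"],
        lam=out["lam"], true_beta=out["true_beta"], surfaces=surfaces,
    )
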