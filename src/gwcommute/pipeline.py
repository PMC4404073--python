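"""Config-driven end-to-end analysis runner.

One call executes the full study sequence on either a synthetic scenario or
a participant CSV: composite construction → outcome discretization → global
Poisson regression → adaptive-bandwidth search → semiparametric GWPR →
MAICE comparison → local-estimate summaries → inverse-distance-weighted
coefficient and pseudo-t surfaces. Every stage is logged with timings, and
the whole run is a pure function of (inputs, config, seed) in synthetic
mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import __version__
from .composites import pca_composites, perception_index
from .glm import deviance_stats, discretize_outcome, fit_poisson_glm, wald_summary
from .gwpr import (
    KernelSpec,
    SemiparametricSpec,
    bandwidth_grid,
    bandwidth_search,
    compare_models,
    summarize_local,
)
from .io import write_geojson
from .kernels import looks_like_degrees
from .raster import RasterGrid, write_ascii_grid
from .synthetic import ScenarioConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "ResultBundle", "PipelineError", "run_pipeline",
           "idw_interpolate", "export_results"]

log = logging.getLogger("gwcommute")

LIKERT_COLUMNS = ("bike_safety", "pollution", "aesthetics")
ENV_VARIABLE_COUNT = 15

# machine-readable error codes, also used as CLI exit codes
CODE_CONFIG = 2
CODE_DATA = 3
CODE_CONVERGENCE = 4


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``scenario`` (synthetic mode) or ``participants_csv``
    (real-input mode) must be set. ``local_columns`` name the environmental
    terms whose coefficients vary with location (a local intercept is always
    added); ``global_columns`` the fixed individual-level terms.
    """

    scenario: ScenarioConfig = None
    participants_csv: str = None
    local_columns: tuple = ("pc1", "pc2", "perception_index")
    global_columns: tuple = ("age_c", "female", "educ_high", "parking_work",
                             "transit_pass", "commute_tertile", "n_vehicles",
                             "n_bikes")
    kernel_family: str = "bisquare"
    bandwidth_grid: tuple = None     # explicit neighbour counts; None = full sweep
    grid_upper: int = 4000
    grid_lower: int = 50
    grid_step: int = 50
    se_type: str = "sandwich"
    surface_cell_m: float = 500.0
    idw_power: float = 2.0
    idw_max_neighbors: int = 12
    allow_degrees: bool = False
    seed: int = 0
    out_dir: str = None

    def __post_init__(self):
        if (self.scenario is None) == (self.participants_csv is None):
            raise ValueError("exactly one of scenario / participants_csv must be set")

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "scenario"}
        d["bandwidth_grid"] = list(self.bandwidth_grid) if self.bandwidth_grid else None
        d["local_columns"] = list(self.local_columns)
        d["global_columns"] = list(self.global_columns)
        d["scenario"] = self.scenario.to_jsonable() if self.scenario else None
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = d.pop("scenario", None)
        if sc is not None:
            sc = ScenarioConfig(**{k: v for k, v in sc.items()})
        for key in ("local_columns", "global_columns", "bandwidth_grid"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(scenario=sc, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a run configuration from a JSON or YAML file."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_jsonable(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class ResultBundle:
    """All outputs of one pipeline run."""

    config: RunConfig
    participants: pd.DataFrame
    points: np.ndarray
    composites: object = None
    perception: dict = None
    glm_fit: object = None
    glm_stats: dict = None
    wald: pd.DataFrame = None
    search: dict = None
    gwpr_fit: object = None
    maice: dict = None
    local_summary: pd.DataFrame = None
    surfaces: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    cohort: SyntheticCohort = None


def idw_interpolate(sites, values, grid: RasterGrid, power: float = 2.0,
                    max_neighbors: int = 12) -> RasterGrid:
    """Inverse-distance-weighted interpolation of site values onto a grid.

    Each cell takes Σ w_j z_j / Σ w_j over its ``max_neighbors`` nearest
    sites with w_j = d_j^(−power); a cell whose center coincides with a site
    takes that site's value exactly. Interpolated values therefore never
    leave the [min, max] range of the inputs.
    """
    pts = np.asarray(sites, float).reshape(-1, 2)
    z = np.asarray(values, float)
    if len(pts) == 0:
        raise ValueError("empty site set")
    if power <= 0:
        raise ValueError("power must be > 0")
    k = min(max_neighbors, len(pts))
    tree = cKDTree(pts)
    centers = grid.centers_flat()
    dist, idx = tree.query(centers, k=k)
    dist = np.atleast_2d(dist.reshape(len(centers), k))
    idx = np.atleast_2d(idx.reshape(len(centers), k))
    exact = dist[:, 0] == 0.0
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[~np.isfinite(w)] = 0.0
    num = np.sum(w * z[idx], axis=1)
    den = np.sum(w, axis=1)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    out[exact] = z[idx[exact, 0]]
    return grid.copy_with(out.reshape(grid.n_rows, grid.n_cols))


def _stage(name, timings):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage=%s status=start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = dt
            if exc_type is None:
                log.info("stage=%s status=ok elapsed_s=%.2f", name, dt)
            else:
                log.error("stage=%s status=failed elapsed_s=%.2f error=%s",
                          name, dt, exc)
            return False

    return _Timer()


def _orient_scores(comp, anchors=(("pc1", "facility_density"),
                                  ("pc2", "median_income"))):
    """Fix the sign indeterminacy of component scores using anchor
    variables (built-density anchor loads positively on the first composite,
    income on the second)."""
    scores = comp.scores.copy()
    scores.columns = [f"pc{j + 1}" for j in range(scores.shape[1])]
    loadings = comp.rotated_loadings.copy()
    loadings.columns = scores.columns
    for col, anchor in anchors:
        if col in scores.columns and anchor in loadings.index:
            if loadings.loc[anchor, col] < 0:
                scores[col] = -scores[col]
                loadings[col] = -loadings[col]
    return scores, loadings


def _build_inputs(config: RunConfig, timings):
    """Stage 1: obtain the participant table and model covariates."""
    cohort = None
    if config.scenario is not None:
        with _stage("simulate", timings):
            cohort = generate_cohort(config.scenario)
            df = cohort.participant_frame()
            points = cohort.points
    else:
        with _stage("load", timings):
            try:
                df = pd.read_csv(config.participants_csv)
            except OSError as exc:
                raise PipelineError("load", CODE_DATA, str(exc))
            if not {"x_m", "y_m"}.issubset(df.columns):
                raise PipelineError("load", CODE_DATA,
                                    "participant CSV needs x_m and y_m columns")
            points = df[["x_m", "y_m"]].to_numpy(float)
            if looks_like_degrees(points) and not config.allow_degrees:
                raise PipelineError(
                    "load", CODE_DATA,
                    "coordinates look like lon/lat degrees; project to planar "
                    "meters or set allow_degrees",
                )
    return df, points, cohort


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis and return a :class:`ResultBundle`."""
    timings = {}
    t_start = time.time()
    df, points, cohort = _build_inputs(config, timings)
    bundle = ResultBundle(config=config, participants=df, points=points,
                          cohort=cohort, timings=timings)
    n = len(df)
    log.info("stage=inputs rows=%d", n)

    # --- composites -------------------------------------------------------
    with _stage("composites", timings):
        env_cols = [name for name in df.columns
                    if name not in ("x_m", "y_m", "hours_per_week")
                    and name not in LIKERT_COLUMNS
                    and df[name].dtype.kind in "fi"]
        needed = set(config.local_columns) - {"pc1", "pc2", "perception_index"}
        missing = needed - set(df.columns)
        if missing:
            raise PipelineError("composites", CODE_CONFIG,
                                f"local columns not in input: {sorted(missing)}")
        X_parts = {}
        if {"pc1", "pc2"} & set(config.local_columns):
            from .synthetic import ENV_LOADINGS
            names = [name for name, _, _ in ENV_LOADINGS if name in df.columns]
            if len(names) < 2:
                raise PipelineError("composites", CODE_DATA,
                                    "no environmental variable block in input")
            comp = pca_composites(df[names], kaiser=True, rotation="varimax")
            bundle.composites = comp
            scores, _ = _orient_scores(comp)
            for col in scores.columns:
                X_parts[col] = scores[col].to_numpy()
        if "perception_index" in config.local_columns:
            if not set(LIKERT_COLUMNS).issubset(df.columns):
                raise PipelineError("composites", CODE_DATA,
                                    "no Likert items in input")
            perc = perception_index(df[list(LIKERT_COLUMNS)])
            bundle.perception = perc
            X_parts["perception_index"] = perc["index"]
        for col in config.local_columns:
            if col not in X_parts:
                X_parts[col] = df[col].to_numpy(float)
        X_local = pd.DataFrame({c: X_parts[c] for c in config.local_columns})

        if config.scenario is not None:
            from .synthetic import individual_design
            X_global = individual_design(cohort.covariates)[list(config.global_columns)]
        else:
            missing = set(config.global_columns) - set(df.columns)
            if missing:
                raise PipelineError("composites", CODE_CONFIG,
                                    f"global columns not in input: {sorted(missing)}")
            X_global = df[list(config.global_columns)].astype(float)

    # --- outcome ----------------------------------------------------------
    with _stage("discretize", timings):
        if "hours_per_week" not in df.columns:
            raise PipelineError("discretize", CODE_DATA,
                                "input lacks hours_per_week")
        y = discretize_outcome(df["hours_per_week"].to_numpy(float))

    # --- global model -----------------------------------------------------
    with _stage("gpr", timings):
        pooled = pd.concat(
            [pd.Series(1.0, index=X_local.index, name="Intercept"),
             X_local, X_global.reset_index(drop=True)], axis=1)
        try:
            glm_fit = fit_poisson_glm(y, pooled)
        except (RuntimeError, ValueError) as exc:
            raise PipelineError("gpr", CODE_CONVERGENCE, str(exc))
        bundle.glm_fit = glm_fit
        bundle.glm_stats = deviance_stats(glm_fit)
        bundle.wald = wald_summary(glm_fit)

    # --- bandwidth search + GWPR ------------------------------------------
    with _stage("bandwidth_search", timings):
        p_local = X_local.shape[1] + 1
        grid = (list(config.bandwidth_grid) if config.bandwidth_grid
                else bandwidth_grid(n, config.grid_upper, config.grid_lower,
                                    config.grid_step, p_local=p_local))
        spec = SemiparametricSpec(
            tuple(config.local_columns), tuple(config.global_columns),
            KernelSpec(config.kernel_family, "adaptive",
                       neighbor_count=grid[0]),
            local_intercept=True, se_type=config.se_type)
        try:
            search = bandwidth_search(y, X_local, X_global, points, spec,
                                      grid=grid)
        except RuntimeError as exc:
            raise PipelineError("bandwidth_search", CODE_CONVERGENCE, str(exc))
        bundle.search = {"selected": search["selected"],
                         "trace": search["trace"],
                         "failures": search["failures"]}
        bundle.gwpr_fit = search["fit"]

    # --- comparison + summaries -------------------------------------------
    with _stage("summaries", timings):
        bundle.maice = compare_models(bundle.gwpr_fit, bundle.glm_fit,
                                      names=("GWPR", "GPR"))
        bundle.local_summary = summarize_local(bundle.gwpr_fit)

    # --- IDW surfaces ------------------------------------------------------
    with _stage("surfaces", timings):
        xmin, ymin = points.min(axis=0)
        xmax, ymax = points.max(axis=0)
        proto = RasterGrid.from_extent(xmin, ymin, xmax, ymax,
                                       config.surface_cell_m)
        t = bundle.gwpr_fit.pseudo_t_values
        for j, term in enumerate(bundle.gwpr_fit.local_labels):
            est = idw_interpolate(points,
                                  bundle.gwpr_fit.local_coefficients[:, j],
                                  proto, config.idw_power,
                                  config.idw_max_neighbors)
            tsurf = idw_interpolate(points, t[:, j], proto,
                                    config.idw_power, config.idw_max_neighbors)
            bundle.surfaces[term] = {"log_odds": est, "pseudo_t": tsurf}

    bundle.manifest = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n": int(n),
        "package_version": __version__,
        "selected_neighbors": int(bundle.search["selected"]),
        "timestamp_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime(t_start)),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return bundle


# ---------------------------------------------------------------------------
# export

def _glm_report(bundle) -> dict:
    wald = bundle.wald
    return {
        "model": "global Poisson regression",
        "coefficients": {
            name: {
                "log_odds": float(row.log_odds), "OR": float(row.OR),
                "CI_low": float(row.CI_low), "CI_high": float(row.CI_high),
                "p": float(row.p),
            }
            for name, row in wald.iterrows()
        },
        **{k: float(v) for k, v in bundle.glm_stats.items()},
    }


def export_results(bundle: ResultBundle, out_dir) -> list:
    """Write the bundle to ``out_dir``; returns the list of files written.

    Fails before writing anything if the directory is not writable, and
    removes partial outputs if any write fails midway.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PipelineError("export", CODE_DATA, f"unwritable directory: {out_dir}")
    written = []

    def _path(name):
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    try:
        bundle.participants.to_csv(_path("participants.csv"), index=False)
        est = bundle.gwpr_fit.to_dataframe()
        est.to_csv(_path("local_estimates.csv"), index=False)
        write_geojson(bundle.gwpr_fit.to_geojson(), _path("local_estimates.geojson"))
        with open(_path("report_glm.json"), "w") as fh:
            json.dump(_glm_report(bundle), fh, indent=1, sort_keys=True)
        with open(_path("report_gwpr.json"), "w") as fh:
            report = bundle.gwpr_fit.report()
            report["maice"] = bundle.maice
            report["local_summary"] = json.loads(
                bundle.local_summary.to_json(orient="index"))
            json.dump(report, fh, indent=1, sort_keys=True)
        bundle.search["trace"].to_csv(_path("bandwidth_trace.csv"), index=False)
        os.makedirs(os.path.join(out_dir, "surfaces"), exist_ok=True)
        for term, pair in bundle.surfaces.items():
            safe = term.replace("/", "_")
            write_ascii_grid(pair["log_odds"],
                             _path(os.path.join("surfaces", f"{safe}_log_odds.asc")))
            write_ascii_grid(pair["pseudo_t"],
                             _path(os.path.join("surfaces", f"{safe}_t.asc")))
        with open(_path("manifest.json"), "w") as fh:
            json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    except Exception:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise
    return written
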