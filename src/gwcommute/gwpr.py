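"""Semiparametric geographically weighted Poisson regression (GWPR).

The model is a log-linear Poisson regression in which the coefficients of
the *environmental* terms vary smoothly with residential location while the
coefficients of the *individual-level* terms stay globally fixed:

    log λ_i = Σ_k β_k(u_i, v_i) x_ik + Σ_m γ_m x_im

Local coefficients β_k(u_i, v_i) are estimated at every observation site by
maximizing a geographically weighted Poisson log-likelihood, with weights
from a distance-decay kernel (:mod:`gwcommute.kernels`). The fixed γ_m and
the local surfaces are reconciled by back-fitting: local fits take the fixed
part as an offset, and a global Poisson fit for γ takes each observation's
own-location local predictor as an offset, iterated to convergence.

Model complexity is the real-valued effective number of parameters
k = trace(S) + p_global, with S the local-step hat matrix, and models are
compared on AICc = D + 2k (the minimum-AICc model, MAICE, wins when the
difference exceeds 2). Bandwidths — the neighbour count N of the adaptive
kernel — are selected by minimizing AICc over a grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial import cKDTree

from .glm import (
    GlmFit,
    _irls,
    fit_poisson_glm,
    poisson_deviance,
    poisson_loglik,
)
from .kernels import KernelSpec, adaptive_bandwidths, kernel_weights

__all__ = [
    "SemiparametricSpec",
    "LocalFit",
    "GwprFit",
    "fit_local_poisson",
    "fit_gwpr",
    "pseudo_t",
    "bandwidth_search",
    "bandwidth_grid",
    "compare_models",
    "summarize_local",
]

BACKFIT_TOL = 1e-5
BACKFIT_MAX_CYCLES = 50


def _fingerprint(y) -> str:
    return hashlib.sha1(np.ascontiguousarray(np.asarray(y, float)).tobytes()).hexdigest()


@dataclass(frozen=True)
class SemiparametricSpec:
    """Which terms vary locally, which stay fixed, and the kernel.

    ``local_columns`` name the environmental terms whose coefficients vary
    with location (a local intercept is included by default);
    ``global_columns`` name the individual-level terms with fixed
    coefficients. The two sets must be disjoint. An empty local set
    degenerates to an ordinary global GLM.
    """

    local_columns: tuple = ()
    global_columns: tuple = ()
    kernel: KernelSpec = KernelSpec("bisquare", "adaptive", neighbor_count=100)
    local_intercept: bool = True
    se_type: str = "sandwich"  # or "naive" (inverse information)

    def __post_init__(self):
        overlap = set(self.local_columns) & set(self.global_columns)
        if overlap:
            raise ValueError(f"local and global column sets overlap: {sorted(overlap)}")
        if self.se_type not in ("sandwich", "naive"):
            raise ValueError("se_type must be 'sandwich' or 'naive'")


@dataclass
class LocalFit:
    """Local regression result at one location."""

    index: int
    coords: tuple
    coefficients: np.ndarray
    se: np.ndarray
    pseudo_t: np.ndarray
    labels: list
    stable: bool = True


@dataclass
class GwprFit:
    """Fitted semiparametric GWPR."""

    coords: np.ndarray                 # (n, 2)
    local_labels: list
    global_labels: list
    local_coefficients: np.ndarray     # (n, p_local) log-odds scale
    local_se: np.ndarray
    gamma: np.ndarray                  # fixed coefficients
    gamma_se: np.ndarray
    fitted: np.ndarray                 # λ_i
    deviance: float
    null_deviance: float
    loglik: float
    null_loglik: float
    trace_S: float
    k: float                           # effective number of parameters
    aicc: float
    kernel: KernelSpec
    n_cycles: int
    converged: bool
    stable: np.ndarray = None          # per-location stability flags
    unstable_count: int = 0
    se_type: str = "sandwich"
    fingerprint: str = ""
    deviance_trace: list = field(default_factory=list)
    degenerate: bool = False           # True when the local set was empty

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def pseudo_t_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.local_coefficients / self.local_se

    def local_fit(self, i: int) -> LocalFit:
        t = self.pseudo_t_values
        return LocalFit(i, tuple(self.coords[i]), self.local_coefficients[i].copy(),
                        self.local_se[i].copy(), t[i].copy(), list(self.local_labels),
                        bool(self.stable[i]))

    def to_dataframe(self) -> pd.DataFrame:
        """Per-location table: coordinates plus log-odds, se, pseudo-t and a
        significance flag for each locally varying term."""
        out = {"x_m": self.coords[:, 0], "y_m": self.coords[:, 1]}
        t = self.pseudo_t_values
        for j, lab in enumerate(self.local_labels):
            out[f"{lab}_log_odds"] = self.local_coefficients[:, j]
            out[f"{lab}_se"] = self.local_se[:, j]
            out[f"{lab}_t"] = t[:, j]
            out[f"{lab}_sig"] = np.abs(t[:, j]) > 1.96
        out["stable"] = self.stable
        return pd.DataFrame(out)

    def report(self) -> dict:
        return {
            "model": "semiparametric GWPR" if not self.degenerate else "global GLM (degenerate: equals GPR)",
            "kernel": {
                "family": self.kernel.family,
                "mode": self.kernel.mode,
                "bandwidth_m": self.kernel.bandwidth_m,
                "neighbor_count": self.kernel.neighbor_count,
            },
            "gamma": dict(zip(self.global_labels, map(float, self.gamma))),
            "gamma_se": dict(zip(self.global_labels, map(float, self.gamma_se))),
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "deviance_explained": 1.0 - self.deviance / self.null_deviance
            if self.null_deviance > 0 else 0.0,
            "trace_S": self.trace_S,
            "effective_parameters": self.k,
            "aicc": self.aicc,
            "n": int(self.n),
            "cycles": self.n_cycles,
            "converged": self.converged,
            "unstable_locations": int(self.unstable_count),
            "se_type": self.se_type,
        }

    def to_geojson(self) -> dict:
        df = self.to_dataframe()
        feats = []
        for _, row in df.iterrows():
            props = {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                     for k, v in row.items() if k not in ("x_m", "y_m")}
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row.x_m), float(row.y_m)]},
                "properties": props,
            })
        return {"type": "FeatureCollection", "features": feats}


# ---------------------------------------------------------------------------
# local fitting

def _local_newton(ys, Xs, ws, offs, beta0, tol=1e-9, max_iter=50):
    """Fisher scoring for one geographically weighted Poisson fit.

    Maximizes sum_j w_j [y_j eta_j - exp(eta_j)] with eta = Xs beta + offs.
    Returns (beta, M, lam) where M = Xs' diag(w lam) Xs is the weighted
    information. Raises LinAlgError on a singular weighted design.
    """
    beta = np.array(beta0, float)
    for _ in range(max_iter):
        eta = Xs @ beta + offs
        if np.any(eta > 700):
            raise FloatingPointError("linear predictor overflow in local fit")
        lam = np.exp(eta)
        wl = ws * lam
        M = Xs.T @ (Xs * wl[:, None])
        score = Xs.T @ (ws * (ys - lam))
        step = linalg.solve(M, score, assume_a="pos")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = Xs @ beta + offs
    lam = np.exp(eta)
    M = Xs.T @ (Xs * (ws * lam)[:, None])
    return beta, M, lam


def _local_se(Xs, ws, lam, M, se_type):
    if se_type == "naive":
        C = linalg.inv(M)
    else:  # sandwich: M^-1 (X' W^2 A X) M^-1
        Minv = linalg.inv(M)
        B = Xs.T @ (Xs * (ws * ws * lam)[:, None])
        C = Minv @ B @ Minv
    return np.sqrt(np.maximum(np.diag(C), 0.0))


def fit_local_poisson(i, y, X_local, offset=None, weights=None, labels=None,
                      coords=None, se_type="sandwich", start=None) -> LocalFit:
    """Fit the local Poisson regression at location ``i`` with given
    geographic weights.

    With uniform weights and no offset this is identical to the global
    Poisson GLM on the same columns. The regression point itself always
    carries weight 1 when the weights come from :mod:`gwcommute.kernels`.
    """
    if isinstance(X_local, pd.DataFrame):
        labels = list(X_local.columns) if labels is None else labels
        X_local = X_local.to_numpy(float)
    X = np.asarray(X_local, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if labels is None:
        labels = [f"b{j}" for j in range(p)]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    off = np.zeros(n) if offset is None else np.asarray(offset, float)
    pos = w > 0
    if pos.sum() < p:
        raise ValueError("fewer positively weighted observations than local parameters")
    Xs, ys, ws, offs = X[pos], y[pos], w[pos], off[pos]
    if start is None:
        mu0 = max(np.sum(ws * ys) / np.sum(ws * np.exp(offs)), 1e-8)
        start = np.zeros(p)
        if np.allclose(Xs[:, 0], 1.0):
            start[0] = np.log(mu0)
    try:
        beta, M, lam = _local_newton(ys, Xs, ws, offs, start)
        se = _local_se(Xs, ws, lam, M, se_type)
        stable = bool(np.all(se > 0) and np.all(np.isfinite(beta)))
    except (linalg.LinAlgError, FloatingPointError):
        beta = np.full(p, np.nan)
        se = np.full(p, np.nan)
        stable = False
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    xy = tuple(coords[i]) if coords is not None else (np.nan, np.nan)
    return LocalFit(int(i), xy, beta, se, t, labels, stable)


# ---------------------------------------------------------------------------
# neighbourhood structure

def _weight_structure(points, kernel: KernelSpec):
    """Per-location support indices and kernel weights.

    For the compact bi-square kernel only points strictly inside the
    bandwidth are kept; the Gaussian kernel has full support.
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    idx_list, w_list = [], []
    if kernel.mode == "adaptive":
        N = kernel.neighbor_count
        if not 2 <= N <= n - 1:
            raise ValueError(f"neighbor_count {N} out of range [2, {n - 1}]")
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=min(N + 1, n))
        bw = adaptive_bandwidths(pts, N)
        if kernel.family == "bisquare":
            for i in range(n):
                keep = dist[i] < bw[i]
                idx_list.append(idx[i][keep])
                w_list.append(kernel_weights(dist[i][keep], bw[i], "bisquare"))
        else:
            all_idx = np.arange(n)
            for i in range(n):
                d = np.sqrt(np.sum((pts - pts[i]) ** 2, axis=1))
                idx_list.append(all_idx)
                w_list.append(kernel_weights(d, bw[i], "gaussian"))
    else:
        b = kernel.bandwidth_m
        if kernel.family == "bisquare":
            tree = cKDTree(pts)
            for i in range(n):
                nbr = np.array(sorted(tree.query_ball_point(pts[i], b)), dtype=int)
                d = np.sqrt(np.sum((pts[nbr] - pts[i]) ** 2, axis=1))
                keep = d < b
                idx_list.append(nbr[keep])
                w_list.append(kernel_weights(d[keep], b, "bisquare"))
        else:
            all_idx = np.arange(n)
            for i in range(n):
                d = np.sqrt(np.sum((pts - pts[i]) ** 2, axis=1))
                idx_list.append(all_idx)
                w_list.append(kernel_weights(d, b, "gaussian"))
    return idx_list, w_list


# ---------------------------------------------------------------------------
# the semiparametric fit

def _prepare_design(X, labels_attr):
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.atleast_2d(np.asarray(X, float))
    return X, [f"{labels_attr}{j}" for j in range(X.shape[1])]


def fit_gwpr(y, X_local, X_global, points, spec: SemiparametricSpec) -> GwprFit:
    """Fit the semiparametric GWPR by back-fitting.

    Parameters
    ----------
    y : counts of half-hour commuting units.
    X_local : environmental terms whose coefficients vary with location
        (a leading intercept column is prepended unless ``spec.local_intercept``
        is False or the matrix already starts with a constant column).
    X_global : individual-level terms with fixed coefficients (may be None).
    points : (n, 2) planar coordinates in meters.
    spec : :class:`SemiparametricSpec`.

    The algorithm initialises the fixed coefficients γ from a global GLM on
    all columns, then alternates (a) local fits at every location with the
    fixed part as offset and (b) a global Poisson fit for γ with each
    observation's own-location local predictor as offset, stopping when the
    largest absolute coefficient change falls below 1e-5 (or 50 cycles).
    """
    y = np.asarray(y, float)
    pts = np.asarray(points, float)
    n = y.shape[0]
    Xl, local_labels = _prepare_design(X_local, "env")
    Xg, global_labels = _prepare_design(X_global, "ind")
    if Xl.size == 0 and not spec.local_intercept:
        return _degenerate_fit(y, Xg, global_labels, pts, spec)

    if spec.local_intercept:
        if Xl.size == 0:
            Xl = np.ones((n, 1))
            local_labels = ["Intercept"]
        elif not np.allclose(Xl[:, 0], Xl[0, 0]) or Xl[0, 0] != 1.0:
            Xl = np.column_stack([np.ones(n), Xl])
            local_labels = ["Intercept"] + local_labels
    p_local = Xl.shape[1]
    p_global = Xg.shape[1] if Xg.size else 0
    has_global = p_global > 0

    # Center the fixed columns when a local intercept is present: the
    # intercept surface absorbs the shift, which removes the flat ridge
    # between it and the fixed-term means and lets back-fitting converge in
    # a handful of cycles. Coefficients are reported on the original scale.
    has_local_intercept = np.allclose(Xl[:, 0], 1.0)
    xg_mean = np.zeros(p_global)
    if has_global and has_local_intercept:
        xg_mean = Xg.mean(axis=0)
        Xg = Xg - xg_mean

    # (1) initial global fit on the pooled design
    pooled = np.column_stack([Xl, Xg]) if has_global else Xl
    init = fit_poisson_glm(y, pooled, labels=local_labels + global_labels)
    B = np.tile(init.coefficients[:p_local], (n, 1))
    gamma = init.coefficients[p_local:].copy() if has_global else np.zeros(0)
    gamma_cov = np.zeros((0, 0))

    idx_list, w_list = _weight_structure(pts, spec.kernel)

    eta_local = np.einsum("ij,ij->i", Xl, B)
    converged = False
    dev_trace = []
    n_cycles = 0
    for cycle in range(1, BACKFIT_MAX_CYCLES + 1):
        n_cycles = cycle
        off_global = Xg @ gamma if has_global else np.zeros(n)
        # (a) local sweep
        B_old = B.copy()
        for i in range(n):
            nbr = idx_list[i]
            try:
                beta_i, _, _ = _local_newton(
                    y[nbr], Xl[nbr], w_list[i], off_global[nbr], B[i]
                )
                B[i] = beta_i
            except (linalg.LinAlgError, FloatingPointError):
                B[i] = np.nan
        eta_local = np.einsum("ij,ij->i", Xl, B)
        if np.any(~np.isfinite(eta_local)):
            bad = np.nonzero(~np.isfinite(eta_local))[0]
            raise RuntimeError(
                f"local fits failed at {bad.size} locations (first: {bad[:5].tolist()})"
            )
        # (b) global step
        if has_global:
            gamma_old = gamma.copy()
            gamma, mu_g, _ = _irls(y, Xg, np.ones(n), eta_local, start=gamma)
            d_gamma = np.max(np.abs(gamma - gamma_old))
        else:
            d_gamma = 0.0
        lam = np.exp(eta_local + (Xg @ gamma if has_global else 0.0))
        dev_trace.append(poisson_deviance(y, lam))
        d_local = np.max(np.abs(B - B_old))
        if max(d_gamma, d_local) < BACKFIT_TOL:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"back-fitting did not converge in {BACKFIT_MAX_CYCLES} cycles; "
            f"deviance trace: {[round(d, 4) for d in dev_trace[-5:]]}"
        )

    # undo the centering: shift the intercept surface so that coefficients
    # refer to the original (uncentered) fixed columns
    if has_global and has_local_intercept:
        shift = float(xg_mean @ gamma)
        B[:, 0] -= shift
        eta_local -= shift
        Xg = Xg + xg_mean

    # final quantities at convergence
    off_global = Xg @ gamma if has_global else np.zeros(n)
    lam = np.exp(eta_local + off_global)
    dev = poisson_deviance(y, lam)
    ll = poisson_loglik(y, lam)
    mu0 = np.full(n, y.mean())
    dev0 = poisson_deviance(y, mu0)
    ll0 = poisson_loglik(y, mu0)

    se = np.empty((n, p_local))
    stable = np.ones(n, bool)
    trace_S = 0.0
    for i in range(n):
        nbr = idx_list[i]
        ws = w_list[i]
        Xs = Xl[nbr]
        lam_s = lam[nbr]
        M = Xs.T @ (Xs * (ws * lam_s)[:, None])
        try:
            Minv = linalg.inv(M)
            se[i] = _local_se(Xs, ws, lam_s, M, spec.se_type)
            # hat-matrix diagonal: w_ii = 1 at the regression point itself
            xi = Xl[i]
            trace_S += float(lam[i] * xi @ Minv @ xi)
            if not np.all(se[i] > 0):
                stable[i] = False
        except linalg.LinAlgError:
            se[i] = np.nan
            stable[i] = False
    if has_global:
        # γ covariance from the final global step's information
        Wg = lam
        info = Xg.T @ (Xg * Wg[:, None])
        gamma_cov = linalg.inv(info)
        gamma_se = np.sqrt(np.diag(gamma_cov))
    else:
        gamma_se = np.zeros(0)

    k = trace_S + p_global
    aicc = dev + 2.0 * k
    return GwprFit(
        coords=pts, local_labels=local_labels, global_labels=global_labels,
        local_coefficients=B, local_se=se, gamma=gamma, gamma_se=gamma_se,
        fitted=lam, deviance=dev, null_deviance=dev0, loglik=ll,
        null_loglik=ll0, trace_S=trace_S, k=k, aicc=aicc, kernel=spec.kernel,
        n_cycles=n_cycles, converged=converged, stable=stable,
        unstable_count=int((~stable).sum()), se_type=spec.se_type,
        fingerprint=_fingerprint(y), deviance_trace=dev_trace,
    )


def _degenerate_fit(y, Xg, global_labels, pts, spec) -> GwprFit:
    """Empty local set: the model is the ordinary global GLM."""
    n = len(y)
    fit = fit_poisson_glm(y, Xg, labels=global_labels)
    p = fit.p
    return GwprFit(
        coords=pts, local_labels=[], global_labels=global_labels,
        local_coefficients=np.empty((n, 0)), local_se=np.empty((n, 0)),
        gamma=fit.coefficients, gamma_se=fit.se, fitted=fit.fitted,
        deviance=fit.deviance, null_deviance=fit.null_deviance,
        loglik=fit.loglik, null_loglik=fit.null_loglik, trace_S=0.0,
        k=float(p), aicc=fit.deviance + 2.0 * p, kernel=spec.kernel,
        n_cycles=0, converged=True, stable=np.ones(n, bool),
        se_type=spec.se_type, fingerprint=_fingerprint(y), degenerate=True,
    )


# ---------------------------------------------------------------------------
# significance, bandwidth selection, comparison, summaries

def effective_parameters(fit: GwprFit) -> float:
    """Real-valued model complexity k = trace(S) + p_global, with S the
    local-step hat matrix at convergence."""
    if not fit.converged:
        raise ValueError("effective parameters are defined only at convergence")
    return fit.k


def pseudo_t(fit: GwprFit, threshold: float = 1.96) -> pd.DataFrame:
    """Per-location pseudo t-values (β/se) and significance flags.

    A location is flagged significant for a term when |t| is *strictly*
    greater than the threshold (|t| > 1.96 marks p < 0.05). Zero standard
    errors give undefined (NaN) t, flagged separately.
    """
    t = fit.pseudo_t_values
    out = {"x_m": fit.coords[:, 0], "y_m": fit.coords[:, 1]}
    for j, lab in enumerate(fit.local_labels):
        tj = t[:, j]
        out[f"{lab}_t"] = tj
        out[f"{lab}_sig"] = np.where(np.isfinite(tj), np.abs(tj) > threshold, False)
        out[f"{lab}_sign"] = np.sign(fit.local_coefficients[:, j])
        out[f"{lab}_undefined"] = ~np.isfinite(tj)
    return pd.DataFrame(out)


def bandwidth_grid(n: int, upper: int = 4000, lower: int = 50, step: int = 50,
                   p_local: int = 1) -> list:
    """Descending neighbour-count grid: from min(upper, n-1) down to lower,
    every ``step``, clipped to the valid range [p_local + 2, n - 1]."""
    lo = max(lower, p_local + 2)
    hi = min(upper, n - 1)
    grid = list(range(hi, lo - 1, -step)) if hi >= lo else []
    if hi >= lo and grid and grid[0] != hi:
        grid = [hi] + grid
    if not grid:
        raise ValueError(f"empty bandwidth grid for n={n}")
    return grid


def bandwidth_search(y, X_local, X_global, points, spec: SemiparametricSpec,
                     grid=None) -> dict:
    """Select the adaptive-kernel neighbour count by minimizing AICc.

    Fits the full semiparametric model at every candidate neighbour count
    and returns the minimizer together with the AICc trace. The default grid
    descends from min(4000, n-1) to 50 in steps of 50.
    """
    n = len(y)
    p_local = (X_local.shape[1] if X_local is not None and np.ndim(X_local) == 2 else 0)
    p_local += int(spec.local_intercept)
    if grid is None:
        grid = bandwidth_grid(n, p_local=p_local)
    grid = [int(N) for N in grid]
    for N in grid:
        if not p_local + 2 <= N <= n - 1:
            raise ValueError(f"grid value {N} outside [{p_local + 2}, {n - 1}]")
    rows, fits, failures = [], {}, {}
    for N in grid:
        sp = SemiparametricSpec(spec.local_columns, spec.global_columns,
                                spec.kernel.with_neighbor_count(N),
                                spec.local_intercept, spec.se_type)
        try:
            f = fit_gwpr(y, X_local, X_global, points, sp)
        except (RuntimeError, ValueError, linalg.LinAlgError) as exc:
            failures[N] = str(exc)
            continue
        fits[N] = f
        rows.append({"N": N, "aicc": f.aicc, "deviance": f.deviance,
                     "k": f.k, "cycles": f.n_cycles})
    if not rows:
        raise RuntimeError(f"all candidate bandwidths failed: {failures}")
    trace = pd.DataFrame(rows)
    best_N = int(trace.loc[trace.aicc.idxmin(), "N"])
    return {"selected": best_N, "trace": trace, "fit": fits[best_N],
            "failures": failures}


def _aicc_of(fit) -> float:
    if isinstance(fit, GwprFit):
        return fit.aicc
    if isinstance(fit, GlmFit):
        return fit.deviance + 2.0 * fit.p
    raise TypeError(f"cannot extract AICc from {type(fit).__name__}")


def _fingerprint_of(fit) -> str:
    if isinstance(fit, GwprFit):
        return fit.fingerprint
    return ""


def compare_models(fit_a, fit_b, names=("A", "B")) -> dict:
    """MAICE comparison of two fits on the same data.

    Reports ΔAICc = AICc(A) − AICc(B); the difference is *substantial* only
    when |ΔAICc| > 2 (strict), in which case the lower-AICc model is named.
    """
    fa, fb = _fingerprint_of(fit_a), _fingerprint_of(fit_b)
    if fa and fb and fa != fb:
        raise ValueError("model comparison refused: fits are not on identical data")
    a, b = _aicc_of(fit_a), _aicc_of(fit_b)
    delta = a - b
    substantial = abs(delta) > 2.0
    preferred = None
    if substantial:
        preferred = names[0] if a < b else names[1]
    return {"aicc": {names[0]: a, names[1]: b}, "delta_aicc": delta,
            "substantial": substantial, "preferred": preferred}


def summarize_local(fit: GwprFit) -> pd.DataFrame:
    """Distribution of the local estimates, one row per locally varying term.

    Log-odds are summarized by their mean and standard deviation over stable
    locations; ORs by exponentiating each local log-odds before taking
    min/max/range, with the mean OR reported as exp(mean log-odds).
    """
    if fit.local_coefficients.shape[1] == 0:
        raise ValueError("no locally varying terms to summarize")
    ok = fit.stable
    if not np.any(ok):
        raise ValueError("all local fits are unstable")
    B = fit.local_coefficients[ok]
    ors = np.exp(B)
    return pd.DataFrame(
        {
            "mean_log_odds": B.mean(axis=0),
            "std_log_odds": B.std(axis=0, ddof=1) if B.shape[0] > 1 else np.zeros(B.shape[1]),
            "mean_OR": np.exp(B.mean(axis=0)),
            "min_OR": ors.min(axis=0),
            "max_OR": ors.max(axis=0),
            "range_OR": ors.max(axis=0) - ors.min(axis=0),
        },
        index=fit.local_labels,
    )
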