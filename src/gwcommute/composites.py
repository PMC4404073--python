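"""Construction of environmental covariates.

The raw neighbourhood exposures — land-use shares, facility and bike
infrastructure densities, socio-economic census attributes — are strongly
multicollinear. Instead of dropping variables, the analysis compresses them
into principal-component composites: components with eigenvalues above one
(Kaiser criterion) are retained and varimax-rotated, and component scores
become the regression covariates. Sampling adequacy is reported through the
overall KMO score and Bartlett's sphericity test.

The module also provides the GIS-side exposure constructions: kernel density
rasters (quartic kernel) for point and polyline infrastructure, zone-to-grid
disaggregation onto a 200 m cell net, 500 m residential buffer means, and
nearest-station distances; and the perceived-environment index built from
three Likert items (bike safety, pollution, aesthetics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .raster import RasterGrid

__all__ = [
    "PcaComposites",
    "pca_composites",
    "perception_index",
    "kde_raster",
    "densify_polyline",
    "disaggregate_to_grid",
    "buffer_mean",
    "BufferMean",
    "nearest_distance",
    "kmo_statistic",
    "bartlett_sphericity",
    "varimax_rotation",
]


# ---------------------------------------------------------------------------
# factor-analytic diagnostics

def kmo_statistic(R: np.ndarray) -> float:
    """Overall Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = Σ r²  / (Σ r² + Σ q²) over off-diagonal entries, where q are the
    anti-image partial correlations obtained from the inverse correlation
    matrix. Values in [0, 1]; above ~0.7 indicates the correlation matrix is
    factorable.
    """
    R = np.asarray(R, float)
    S = linalg.inv(R)
    d = 1.0 / np.sqrt(np.diag(S))
    Q = -S * np.outer(d, d)  # partial correlations
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple:
    """Bartlett's test of sphericity (H0: identity correlation matrix).

    Returns (chi2, p) from the chi-square approximation with p(p-1)/2 df.
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


def varimax_rotation(L, normalize: bool = True, tol: float = 1e-8,
                     max_iter: int = 100):
    """Varimax rotation of a loading matrix (Kaiser's pairwise algorithm).

    Maximizes the variance of squared loadings within each column over
    orthogonal rotations. With ``normalize`` (Kaiser normalization) rows are
    scaled to unit communality during rotation and rescaled afterwards.
    Returns ``(rotated_loadings, rotation_matrix)`` with
    ``rotated = L @ rotation_matrix``.

    The pairwise angle uses atan2, so symmetric saddle configurations (e.g.
    two variables loading equally on two components) still rotate to the
    axis-aligned optimum.
    """
    A = np.array(L, float)
    p, k = A.shape
    R = np.eye(k)
    if k < 2:
        return A, R
    h = np.sqrt((A**2).sum(axis=1)) if normalize else np.ones(p)
    h = np.where(h == 0, 1.0, h)
    A = A / h[:, None]
    for _ in range(max_iter):
        total = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                a, b = A[:, i], A[:, j]
                u = a * a - b * b
                v = 2.0 * a * b
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                A[:, [i, j]] = A[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
                total += abs(phi)
        if total < tol:
            break
    return A * h[:, None], R


# ---------------------------------------------------------------------------
# PCA composites

@dataclass
class PcaComposites:
    """Varimax-rotated principal-component composites of the environmental
    variable block."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    retained_count: int
    loadings: pd.DataFrame            # unrotated, retained block
    rotated_loadings: pd.DataFrame    # varimax (or copy of loadings if none)
    scores: pd.DataFrame              # per-observation scores, retained comps
    scores_unrotated: pd.DataFrame
    communalities: pd.Series
    kmo: float
    bartlett_chi2: float
    bartlett_p: float
    rotation: str


def pca_composites(X, kaiser: bool = True, rotation: str = "varimax",
                   n_components: int = None) -> PcaComposites:
    """Principal components of the correlation matrix with Kaiser retention
    and optional varimax rotation.

    Columns are standardized internally (zero mean, unit variance). With
    ``kaiser`` on, the number of retained components is the number of
    eigenvalues strictly greater than one; ``n_components`` overrides it.
    Scores have unit variance; unrotated scores of distinct components are
    uncorrelated. Varimax is applied to the retained loading block only and
    preserves per-variable communalities.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        V = X.to_numpy(float)
    else:
        V = np.asarray(X, float)
        names = [f"v{j}" for j in range(V.shape[1])]
    n, p = V.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n <= p:
        raise ValueError(f"need n > p; got n={n}, p={p}")
    sd = V.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant column(s): {bad}")
    Z = (V - V.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]

    if n_components is not None:
        m = int(n_components)
    elif kaiser:
        m = int(np.sum(evals > 1.0))
        m = max(m, 1)
    else:
        m = p
    comp_names = [f"PC{j + 1}" for j in range(m)]

    L = evecs[:, :m] * np.sqrt(evals[:m])
    F = (Z @ evecs[:, :m]) / np.sqrt(np.maximum(evals[:m], 1e-12))

    if rotation == "varimax" and m >= 2:
        Lr, T = varimax_rotation(L)
        Fr = F @ T
        rot = "varimax"
    elif rotation in ("none", None) or m < 2:
        Lr, Fr, rot = L.copy(), F.copy(), "none"
    else:
        raise ValueError(f"unknown rotation: {rotation!r}")

    return PcaComposites(
        eigenvalues=evals,
        variance_fractions=evals / p,
        retained_count=m,
        loadings=pd.DataFrame(L, index=names, columns=comp_names),
        rotated_loadings=pd.DataFrame(Lr, index=names, columns=comp_names),
        scores=pd.DataFrame(Fr, columns=comp_names),
        scores_unrotated=pd.DataFrame(F, columns=comp_names),
        communalities=pd.Series((L**2).sum(axis=1), index=names),
        kmo=kmo_statistic(R),
        bartlett_chi2=bartlett_sphericity(R, n)[0],
        bartlett_p=bartlett_sphericity(R, n)[1],
        rotation=rot,
    )


def perception_index(items, anchor: str = None) -> dict:
    """Perceived-environment index: first principal component of the three
    Likert items (bike safety, pollution, aesthetics).

    The index is sign-oriented so that the anchor item (default: the first
    column, bike safety) loads positively — higher index values indicate a
    safer-perceived cycling environment. Returns the per-respondent index,
    the item loadings and the variance fraction of the first component.
    """
    if isinstance(items, pd.DataFrame):
        names = list(items.columns)
        V = items.to_numpy(float)
    else:
        V = np.asarray(items, float)
        names = [f"item{j}" for j in range(V.shape[1])]
    n, p = V.shape
    sd = V.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance item(s): {bad}")
    if np.unique(V, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct response patterns")
    Z = (V - V.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = linalg.eigh(R)
    j = int(np.argmax(evals))
    e1, v1 = evals[j], evecs[:, j]
    a = 0 if anchor is None else names.index(anchor)
    if v1[a] < 0:
        v1 = -v1
    loadings = v1 * np.sqrt(e1)
    scores = (Z @ v1) / np.sqrt(e1)
    return {
        "index": scores,
        "loadings": pd.Series(loadings, index=names),
        "variance_fraction": float(e1 / p),
    }


# ---------------------------------------------------------------------------
# GIS exposure constructions

def densify_polyline(coords, spacing: float = 10.0):
    """Turn a polyline into points every ``spacing`` meters along its
    length, each carrying its length share (meters) as weight."""
    coords = np.asarray(coords, float)
    pts, wts = [], []
    for a, b in zip(coords[:-1], coords[1:]):
        seg = np.asarray(b) - np.asarray(a)
        length = float(np.hypot(*seg))
        if length == 0:
            continue
        k = max(1, int(np.ceil(length / spacing)))
        # k sample points at segment-interior midpoints, equal length shares
        t = (np.arange(k) + 0.5) / k
        for ti in t:
            pts.append(a + ti * seg)
            wts.append(length / k)
    if not pts:
        return np.empty((0, 2)), np.empty(0)
    return np.asarray(pts), np.asarray(wts)


def kde_raster(features, grid: RasterGrid, bandwidth: float = 500.0,
               weights=None, line_spacing: float = 10.0) -> RasterGrid:
    """Quartic (biweight) kernel density raster, in units per km².

    ``features`` is either an (m, 2) array of points or a list of polylines
    (each an array of vertices); polylines are densified into points every
    ``line_spacing`` meters, each carrying its length share as weight. The
    kernel has compact support: cells farther than ``bandwidth`` from every
    feature get density zero, and total mass is conserved (each unit-weight
    feature integrates to 1 over the plane).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if isinstance(features, (list, tuple)) and len(features) and np.ndim(features[0]) == 2:
        parts, wparts = [], []
        for line in features:
            p, w = densify_polyline(line, line_spacing)
            parts.append(p)
            wparts.append(w)
        pts = np.vstack(parts) if parts else np.empty((0, 2))
        w = np.concatenate(wparts) if wparts else np.empty(0)
    else:
        pts = np.asarray(features, float).reshape(-1, 2)
        w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)
    out = grid.copy_with(np.zeros((grid.n_rows, grid.n_cols)))
    if len(pts) == 0:
        return out
    X, Y = grid.cell_centers()
    norm = 3.0 / (np.pi * bandwidth**2)  # quartic kernel, unit mass in 2-D
    vals = out.values
    cs = grid.cell_size
    for (px, py), wi in zip(pts, w):
        # only the cell window within the kernel support
        c0 = max(0, int((px - bandwidth - grid.x0) / cs) - 1)
        c1 = min(grid.n_cols, int((px + bandwidth - grid.x0) / cs) + 2)
        r0 = max(0, grid.n_rows - int((py + bandwidth - grid.y0) / cs) - 2)
        r1 = min(grid.n_rows, grid.n_rows - int((py - bandwidth - grid.y0) / cs) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = X[r0:r1, c0:c1] - px
        dy = Y[r0:r1, c0:c1] - py
        u2 = (dx * dx + dy * dy) / bandwidth**2
        vals[r0:r1, c0:c1] += wi * norm * np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)
    out.values = vals * 1e6  # per m² -> per km²
    return out


def disaggregate_to_grid(zones, grid: RasterGrid, attribute: str = None) -> RasterGrid:
    """Assign zone attribute values to grid cells by the cell-center rule.

    ``zones`` is a sequence of ``(geometry, value)`` pairs (shapely
    geometries) or GeoJSON-like features with ``properties[attribute]``.
    Each cell takes the value of the zone covering its center; cells outside
    all zones are nodata; a center covered by two or more zones is an error
    (the zone layer should be a partition). Intensive attributes only —
    counts must be converted to densities upstream.
    """
    from shapely.geometry import shape as shp_shape
    from shapely.prepared import prep

    pairs = []
    for z in zones:
        if isinstance(z, (tuple, list)) and len(z) == 2:
            geom, val = z
        else:  # GeoJSON feature
            geom = shp_shape(z["geometry"])
            val = z["properties"][attribute]
        pairs.append((prep(geom), float(val)))
    out = grid.copy_with(np.full((grid.n_rows, grid.n_cols), grid.nodata))
    X, Y = grid.cell_centers()
    from shapely.geometry import Point

    vals = out.values
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            pt = Point(X[r, c], Y[r, c])
            hits = [v for g, v in pairs if g.covers(pt)]
            if len(hits) > 1:
                raise ValueError(
                    f"overlapping zones at cell center ({X[r, c]:.1f}, {Y[r, c]:.1f})"
                )
            if hits:
                vals[r, c] = hits[0]
    return out


@dataclass
class BufferMean:
    value: float
    n_cells: int
    missing: bool


def buffer_mean(raster: RasterGrid, location, radius: float = 500.0) -> BufferMean:
    """Mean of raster values whose cell centers lie within ``radius`` of the
    location (Euclidean buffer); nodata cells never contribute."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    x, y = float(location[0]), float(location[1])
    X, Y = raster.cell_centers()
    inside = (X - x) ** 2 + (Y - y) ** 2 <= radius**2
    ok = inside & raster.mask()
    n = int(ok.sum())
    if n == 0:
        return BufferMean(float("nan"), 0, True)
    return BufferMean(float(raster.values[ok].mean()), n, False)


def nearest_distance(location, features) -> float:
    """Euclidean distance (meters) to the nearest feature point."""
    pts = np.asarray(features, float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("empty feature set")
    x, y = float(location[0]), float(location[1])
    return float(np.sqrt(((pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2)).min())
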