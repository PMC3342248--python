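"""Spatial point-pattern statistics and Monte-Carlo inference.

Second-order analysis of stem maps in a rectangular window:

* Ripley's K̂ and its variance-stabilized L transform, with the closed-form
  isotropic (circle-fraction) edge correction for rectangles,
* the bivariate K̂₁₂ / L̂₁₂ for two marked subpatterns,
* null models: complete spatial randomness (CSR, a binomial process with
  the observed point count) and population independence (each subpattern
  kept rigid and displaced by an independent random toroidal shift),
* pointwise simulation envelopes,
* the Loosmore–Ford Monte-Carlo goodness-of-fit test (integrated squared
  deviation of the summary function over a distance interval, rank
  p-value),
* the Bonferroni threshold for families of such tests,
* a distance-class correlogram for transect-level quantities (Pearson by
  class, permutation p-values).

Sign convention: L̂ is reported centered, ``L(r) − r``, so positive values
mean clustering/attraction and negative values inhibition/repulsion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stand_model import PlotGeometry, StemRecord

__all__ = [
    "PointPattern",
    "LResult",
    "EnvelopeResult",
    "GoFResult",
    "isotropic_weight",
    "k_hat_isotropic",
    "l_hat",
    "k12_hat_isotropic",
    "l12_hat",
    "simulate_csr",
    "toroidal_shift",
    "envelope",
    "envelope_bounds",
    "gof_loosmore_ford",
    "bonferroni",
    "transect_correlogram",
    "default_r_grid",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointPattern:
    """Marked points in a rectangular window (coordinates in meters)."""

    points: np.ndarray          # (n, 2)
    window: PlotGeometry
    mark: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if len(pts):
            if (pts[:, 0].min() < 0 or pts[:, 0].max() > self.window.width_m
                    or pts[:, 1].min() < 0 or pts[:, 1].max() > self.window.height_m):
                raise ValueError("points outside window")

    @property
    def n(self) -> int:
        return len(self.points)

    @classmethod
    def from_stems(cls, stems: Sequence[StemRecord], window: PlotGeometry,
                   mark: str | None = None) -> "PointPattern":
        pts = np.array([[s.x_m, s.y_m] for s in stems], dtype=float).reshape(-1, 2)
        return cls(points=pts, window=window, mark=mark)


@dataclass(frozen=True)
class LResult:
    """A centered L curve: ``l_hat[k] = L(r_grid[k]) − r_grid[k]``."""

    r_grid: np.ndarray
    l_hat: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EnvelopeResult:
    """Observed curve plus the full set of null-model curves."""

    observed: LResult
    simulated: np.ndarray       # (n_sim, len(r_grid))
    null_model: str

    @property
    def r_grid(self) -> np.ndarray:
        return self.observed.r_grid


@dataclass(frozen=True)
class GoFResult:
    """Loosmore–Ford deviation statistic and its rank p-value."""

    u_observed: float
    u_simulated: np.ndarray
    p_value: float
    r_min: float
    r_max: float


def default_r_grid(r_max: float = 80.0, step: float = 0.25) -> np.ndarray:
    return np.arange(0.0, r_max + step / 2, step)


# ---------------------------------------------------------------------------
# Isotropic edge correction
# ---------------------------------------------------------------------------

def isotropic_weight(x: np.ndarray, y: np.ndarray, t: np.ndarray,
                     window: PlotGeometry) -> np.ndarray:
    """Fraction of the circle of radius ``t`` centered at (x, y) lying
    inside the rectangular window (closed-form arc formula).

    The exterior arc is the sum of the arcs cut off by each near edge minus
    the double-counted corner sectors where two perpendicular edges both
    cut the circle.  Valid while t < min(width, height)/2, which holds for
    every supported ``r_max``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    w, h = window.width_m, window.height_m
    with np.errstate(invalid="ignore", divide="ignore"):
        aL = np.arccos(np.clip(x / t, -1.0, 1.0))
        aR = np.arccos(np.clip((w - x) / t, -1.0, 1.0))
        aB = np.arccos(np.clip(y / t, -1.0, 1.0))
        aT = np.arccos(np.clip((h - y) / t, -1.0, 1.0))
    exterior = 2.0 * (aL + aR + aB + aT)
    half_pi = np.pi / 2.0
    for ae, af in ((aL, aB), (aB, aR), (aR, aT), (aT, aL)):
        exterior -= np.maximum(0.0, ae + af - half_pi)
    return 1.0 - exterior / (2.0 * np.pi)


def _check_r_grid(r_grid: np.ndarray, window: PlotGeometry, override: bool) -> None:
    limit = min(window.width_m, window.height_m) / 4.0
    if r_grid[-1] > limit + 1e-9 and not override:
        warnings.warn(
            f"r_max {r_grid[-1]:.1f} m exceeds one quarter of the minimum "
            f"window dimension ({limit:.1f} m); edge-corrected estimates "
            "become unstable at large r",
            stacklevel=3,
        )
    hard = min(window.width_m, window.height_m) / 2.0
    if r_grid[-1] >= hard:
        raise ValueError(f"r_max must be below min(width, height)/2 = {hard} m")


def k_hat_isotropic(pattern: PointPattern, r_grid: np.ndarray,
                    allow_large_r: bool = False) -> np.ndarray:
    """Ripley's K with isotropic edge correction.

    ``K̂(r) = |A|/(n(n−1)) · ΣΣ_{i≠j} w_ij⁻¹ · 1(d_ij ≤ r)`` where ``w_ij``
    is the in-window fraction of the circle of radius ``d_ij`` centered on
    point i.  Each unordered pair contributes both directed terms.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if pattern.n < 2:
        raise ValueError("K estimation needs at least 2 points")
    _check_r_grid(r_grid, pattern.window, allow_large_r)
    pts = pattern.points
    tree = cKDTree(pts)
    pairs = tree.query_pairs(float(r_grid[-1]), output_type="ndarray")
    n = pattern.n
    area = pattern.window.area_m2
    if len(pairs) == 0:
        return np.zeros_like(r_grid)
    diff = pts[pairs[:, 0]] - pts[pairs[:, 1]]
    d = np.hypot(diff[:, 0], diff[:, 1])
    w_i = isotropic_weight(pts[pairs[:, 0], 0], pts[pairs[:, 0], 1], d, pattern.window)
    w_j = isotropic_weight(pts[pairs[:, 1], 0], pts[pairs[:, 1], 1], d, pattern.window)
    contrib = 1.0 / w_i + 1.0 / w_j
    # cumulative weighted counts over the grid
    order = np.argsort(d)
    d_sorted = d[order]
    c_sorted = np.concatenate([[0.0], np.cumsum(contrib[order])])
    idx = np.searchsorted(d_sorted, r_grid, side="right")
    return area / (n * (n - 1)) * c_sorted[idx]


def l_hat(pattern: PointPattern, r_grid: np.ndarray, centered: bool = True,
          allow_large_r: bool = False) -> LResult:
    """Variance-stabilized L transform, ``sqrt(K̂/π) − r`` when centered.

    Positive values indicate clustering, negative values inhibition.
    """
    k = k_hat_isotropic(pattern, r_grid, allow_large_r=allow_large_r)
    l = np.sqrt(k / np.pi)
    if centered:
        l = l - np.asarray(r_grid, dtype=float)
    return LResult(r_grid=np.asarray(r_grid, dtype=float), l_hat=l,
                   meta={"n": pattern.n, "edge_correction": "isotropic",
                         "centered": centered, "statistic": "L"})


def _k12_raw(pts1: np.ndarray, pts2: np.ndarray, window: PlotGeometry,
             r_grid: np.ndarray) -> np.ndarray:
    tree1 = cKDTree(pts1)
    tree2 = cKDTree(pts2)
    pairs = tree1.sparse_distance_matrix(tree2, float(r_grid[-1]), output_type="coo_matrix")
    area = window.area_m2
    n1, n2 = len(pts1), len(pts2)
    if pairs.nnz == 0:
        return np.zeros_like(r_grid)
    i, j, d = pairs.row, pairs.col, pairs.data
    w_i = isotropic_weight(pts1[i, 0], pts1[i, 1], d, window)
    w_j = isotropic_weight(pts2[j, 0], pts2[j, 1], d, window)
    # symmetrized pair weight: mean of the two directed contributions, so
    # the type-1-centric and type-2-centric estimates coincide exactly
    contrib = 0.5 * (1.0 / w_i + 1.0 / w_j)
    order = np.argsort(d)
    d_sorted = d[order]
    c_sorted = np.concatenate([[0.0], np.cumsum(contrib[order])])
    idx = np.searchsorted(d_sorted, r_grid, side="right")
    return area / (n1 * n2) * c_sorted[idx]


def k12_hat_isotropic(pattern1: PointPattern, pattern2: PointPattern,
                      r_grid: np.ndarray, allow_large_r: bool = False) -> np.ndarray:
    """Bivariate K̂₁₂: type-2 neighbors of type-1 points, edge corrected."""
    if pattern1.window != pattern2.window:
        raise ValueError("patterns must share a window")
    if pattern1.n < 1 or pattern2.n < 1:
        raise ValueError("both patterns must be non-empty")
    r_grid = np.asarray(r_grid, dtype=float)
    _check_r_grid(r_grid, pattern1.window, allow_large_r)
    return _k12_raw(pattern1.points, pattern2.points, pattern1.window, r_grid)


def l12_hat(pattern1: PointPattern, pattern2: PointPattern, r_grid: np.ndarray,
            centered: bool = True, allow_large_r: bool = False) -> LResult:
    """Centered bivariate L: positive = attraction, negative = repulsion."""
    k12 = k12_hat_isotropic(pattern1, pattern2, r_grid, allow_large_r=allow_large_r)
    l = np.sqrt(k12 / np.pi)
    if centered:
        l = l - np.asarray(r_grid, dtype=float)
    return LResult(r_grid=np.asarray(r_grid, dtype=float), l_hat=l,
                   meta={"n1": pattern1.n, "n2": pattern2.n,
                         "edge_correction": "isotropic", "centered": centered,
                         "statistic": "L12"})


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

def simulate_csr(n: int, window: PlotGeometry, rng: np.random.Generator) -> PointPattern:
    """Binomial process: n points placed independently and uniformly."""
    if n < 0:
        raise ValueError("n must be non-negative")
    pts = np.column_stack([
        rng.uniform(0.0, window.width_m, n),
        rng.uniform(0.0, window.height_m, n),
    ])
    return PointPattern(points=pts, window=window)


def toroidal_shift(pattern: PointPattern, shift: tuple[float, float],
                   window: PlotGeometry | None = None) -> PointPattern:
    """Translate a pattern with wrap-around on the window-as-torus.

    Preserves the point count and all pairwise toroidal-metric distances.
    """
    window = window or pattern.window
    sx, sy = shift
    pts = pattern.points.copy()
    pts[:, 0] = np.mod(pts[:, 0] + sx, window.width_m)
    pts[:, 1] = np.mod(pts[:, 1] + sy, window.height_m)
    return PointPattern(points=pts, window=window, mark=pattern.mark)


# ---------------------------------------------------------------------------
# Envelopes and goodness of fit
# ---------------------------------------------------------------------------

def envelope(
    observed: PointPattern | tuple[PointPattern, PointPattern],
    null_model: str,
    n_sim: int,
    rng: np.random.Generator,
    r_grid: np.ndarray | None = None,
    statistic: str = "L",
    allow_large_r: bool = False,
) -> EnvelopeResult:
    """Observed summary curve plus ``n_sim`` null-model curves.

    ``null_model='csr'`` resimulates point positions uniformly (univariate
    pattern).  ``null_model='population_independence'`` takes a pair of
    patterns, keeps each internally rigid, and applies an independent
    random toroidal shift to each before recomputing the bivariate
    statistic (``mode='single'`` shifts only the second pattern; the two
    are distributionally equivalent for the relative displacement).
    The full simulated distribution is returned for exploratory comparison.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if statistic not in ("L", "K"):
        raise ValueError("statistic must be 'L' or 'K'")

    def curve_uni(p: PointPattern, grid: np.ndarray) -> np.ndarray:
        k = k_hat_isotropic(p, grid, allow_large_r=allow_large_r)
        return np.sqrt(k / np.pi) - grid if statistic == "L" else k

    def curve_biv(p1: PointPattern, p2: PointPattern, grid: np.ndarray) -> np.ndarray:
        k = k12_hat_isotropic(p1, p2, grid, allow_large_r=allow_large_r)
        return np.sqrt(k / np.pi) - grid if statistic == "L" else k

    if null_model == "csr":
        if not isinstance(observed, PointPattern):
            raise TypeError("csr null takes a single PointPattern")
        window = observed.window
        grid = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
        obs_curve = curve_uni(observed, grid)
        sims = np.empty((n_sim, len(grid)))
        for s in range(n_sim):
            sims[s] = curve_uni(simulate_csr(observed.n, window, rng), grid)
        meta = {"n": observed.n, "statistic": statistic}
    elif null_model == "population_independence":
        if isinstance(observed, PointPattern):
            raise TypeError("population independence takes a (pattern1, pattern2) pair")
        p1, p2 = observed
        if p1.window != p2.window:
            raise ValueError("patterns must share a window")
        window = p1.window
        grid = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
        obs_curve = curve_biv(p1, p2, grid)
        sims = np.empty((n_sim, len(grid)))
        for s in range(n_sim):
            s1 = toroidal_shift(p1, (rng.uniform(0, window.width_m),
                                     rng.uniform(0, window.height_m)))
            s2 = toroidal_shift(p2, (rng.uniform(0, window.width_m),
                                     rng.uniform(0, window.height_m)))
            sims[s] = curve_biv(s1, s2, grid)
        meta = {"n1": p1.n, "n2": p2.n, "statistic": statistic}
    else:
        raise ValueError(f"unknown null model {null_model!r}")

    obs = LResult(r_grid=grid, l_hat=obs_curve, meta=meta)
    return EnvelopeResult(observed=obs, simulated=sims, null_model=null_model)


def envelope_bounds(result: EnvelopeResult, alpha: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise lower/upper simulation quantiles at level alpha."""
    lo = np.quantile(result.simulated, alpha / 2.0, axis=0)
    hi = np.quantile(result.simulated, 1.0 - alpha / 2.0, axis=0)
    return lo, hi


def gof_loosmore_ford(result: EnvelopeResult, r_min: float = 0.0,
                      r_max: float = 9.0) -> GoFResult:
    """Loosmore–Ford Monte-Carlo goodness-of-fit test.

    For every curve i (observed and simulated alike)
    ``uᵢ = Σ_k (Hᵢ(r_k) − H̄₍₋ᵢ₎(r_k))²·Δr`` over the grid points in
    [r_min, r_max], where H̄₍₋ᵢ₎ averages all *other* curves; the p-value
    is the rank of the observed deviation,
    ``p = (1 + #{sims with uᵢ ≥ u_obs}) / (n_sim + 1)``, ties counted as
    extreme (conservative).
    """
    grid = result.r_grid
    if len(result.simulated) < 2:
        raise ValueError("need at least 2 simulated curves")
    sel = (grid >= r_min - 1e-12) & (grid <= r_max + 1e-12)
    if not sel.any():
        raise ValueError("integration bounds outside the r grid")
    if r_min < grid[0] - 1e-12 or r_max > grid[-1] + 1e-12:
        raise ValueError("integration bounds outside the r grid")
    dr = float(grid[1] - grid[0]) if len(grid) > 1 else 1.0
    curves = np.vstack([result.observed.l_hat[sel], result.simulated[:, sel]])
    m = len(curves)
    total = curves.sum(axis=0)
    mean_excl = (total[None, :] - curves) / (m - 1)
    u = np.sum((curves - mean_excl) ** 2, axis=1) * dr
    u_obs = float(u[0])
    u_sim = u[1:]
    p = (1.0 + int(np.sum(u_sim >= u_obs))) / (len(u_sim) + 1.0)
    return GoFResult(u_observed=u_obs, u_simulated=u_sim, p_value=p,
                     r_min=r_min, r_max=r_max)


def bonferroni(alpha: float, m_tests: int) -> float:
    """Family-wise threshold alpha/m, reported to 3 decimals."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return round(alpha / m_tests, 3)


# ---------------------------------------------------------------------------
# Transect correlogram
# ---------------------------------------------------------------------------

def transect_correlogram(
    values: Sequence[float],
    midpoints: Sequence[tuple[float, float]],
    distance_classes: Sequence[float],
    rng: np.random.Generator | None = None,
    n_perm: int = 999,
) -> pd.DataFrame:
    """Distance-class correlogram of transect-level quantities.

    Pairs of sampling units are binned by inter-midpoint distance; within
    each class the Pearson correlation of paired values is computed with
    both orderings of every unordered pair (so the statistic is symmetric,
    Mantel-correlogram style) and tested against ``n_perm`` random
    permutations of the values across units (two-sided rank p-value).
    Classes with no pairs or zero variance are flagged not estimable.
    """
    vals = np.asarray(values, dtype=float)
    pts = np.asarray(midpoints, dtype=float).reshape(-1, 2)
    if len(vals) != len(pts):
        raise ValueError("values and midpoints must align")
    edges = np.asarray(distance_classes, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least one distance class")
    rng = rng or np.random.default_rng()

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    iu = np.triu_indices(len(vals), k=1)
    d_pairs = dist[iu]
    i_idx, j_idx = iu

    def class_corr(v: np.ndarray, mask: np.ndarray) -> float:
        a = np.concatenate([v[i_idx[mask]], v[j_idx[mask]]])
        b = np.concatenate([v[j_idx[mask]], v[i_idx[mask]]])
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d_pairs >= lo) & (d_pairs < hi)
        n_pairs = int(mask.sum())
        if n_pairs < 2:
            rows.append({"class_lo": lo, "class_hi": hi, "n_pairs": n_pairs,
                         "correlation": np.nan, "p_value": np.nan,
                         "estimable": False})
            continue
        r_obs = class_corr(vals, mask)
        if np.isnan(r_obs):
            rows.append({"class_lo": lo, "class_hi": hi, "n_pairs": n_pairs,
                         "correlation": np.nan, "p_value": np.nan,
                         "estimable": False})
            continue
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(vals)
            r_p = class_corr(perm, mask)
            if not np.isnan(r_p) and abs(r_p) >= abs(r_obs):
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        rows.append({"class_lo": lo, "class_hi": hi, "n_pairs": n_pairs,
                     "correlation": r_obs, "p_value": p, "estimable": True})
    return pd.DataFrame(rows)
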