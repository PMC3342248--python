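"""Seeded generator of synthetic stem-mapped stands.

The generator produces :class:`~standforge.stand_model.StandDataset` objects
with the statistical structure typical of old-growth Sierra Nevada
mixed-conifer forest, so every downstream analysis stage can be exercised
without field data:

* small-diameter trees follow a Thomas cluster process (aggregation at
  scales below ~20 m),
* large-diameter trees follow a hard-core-thinned Poisson process
  (small-scale inhibition from non-overlapping boles),
* small trees are thinned near large trees, inducing bivariate segregation
  at short range,
* diameters follow a negative-exponential or rotated-sigmoid model,
* roughly a fifth of the ≥10 cm stems have a standing-dead counterpart,
* shrub cover is a Boolean disc model hitting a target cover fraction,
* coarse woody debris is a field of straight, constant-diameter segments
  sampled by line-intercept transects with exact segment–line geometry.

All randomness flows from one ``rng_seed`` through NumPy's PCG64 generator;
each census layer draws from its own spawned child stream so layers can be
regenerated independently and the full dataset is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Point, Polygon, box
from shapely.ops import unary_union

from .stand_model import (
    CoarseIntercept,
    FuelTransect,
    PlotGeometry,
    ShrubDemographyPlot,
    ShrubPatch,
    SnagRecord,
    StandDataset,
    StemRecord,
)

__all__ = [
    "StandConfig",
    "NegativeExponentialDBH",
    "RotatedSigmoidDBH",
    "sample_thomas",
    "sample_hardcore",
    "apply_segregation",
    "sample_dbh",
    "generate_stand",
]


# ---------------------------------------------------------------------------
# Diameter models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NegativeExponentialDBH:
    """dbh ~ 1 + Exponential(1/rate) cm, i.e. a negative-exponential
    size-frequency curve truncated at the 1 cm census threshold."""

    rate_per_cm: float = 0.104

    def __post_init__(self) -> None:
        if self.rate_per_cm <= 0:
            raise ValueError("rate must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return 1.0 + rng.exponential(1.0 / self.rate_per_cm, size=n)


@dataclass(frozen=True)
class RotatedSigmoidDBH:
    """Mixture of a truncated exponential and a mid-diameter Gaussian hump.

    A stand-in parametric form for the rotated-sigmoid size-frequency
    shape (excess of mid-sized stems relative to a negative exponential);
    no canonical parametric family exists for it, so this mixture is a
    documented modeling choice, not a literature form.
    """

    weight_exponential: float = 0.75
    rate_per_cm: float = 0.05
    hump_mean_cm: float = 80.0
    hump_sd_cm: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_exponential <= 1.0:
            raise ValueError("mixture weight must be in [0, 1]")
        if self.rate_per_cm <= 0 or self.hump_sd_cm <= 0:
            raise ValueError("rate and hump sd must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        take_exp = rng.random(n) < self.weight_exponential
        out = np.empty(n)
        n_exp = int(take_exp.sum())
        out[take_exp] = 1.0 + rng.exponential(1.0 / self.rate_per_cm, size=n_exp)
        n_hump = n - n_exp
        # Gaussian hump truncated at the 1 cm threshold by resampling
        vals = rng.normal(self.hump_mean_cm, self.hump_sd_cm, size=n_hump)
        bad = vals < 1.0
        while bad.any():
            vals[bad] = rng.normal(self.hump_mean_cm, self.hump_sd_cm, size=int(bad.sum()))
            bad = vals < 1.0
        out[~take_exp] = vals
        return out


def sample_dbh(n: int, model, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` diameters (cm) from a dbh model; all values ≥ 1 cm."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty(0)
    return model.sample(n, rng)


# ---------------------------------------------------------------------------
# Point-process samplers
# ---------------------------------------------------------------------------

def sample_thomas(
    kappa: float,
    mu: float,
    sigma: float,
    window: PlotGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thomas cluster process: Poisson parents, Gaussian-dispersed offspring.

    Parents are simulated on the window expanded by 4σ on every side so
    clusters centred just outside still contribute offspring (edge-effect
    free up to a negligible Gaussian tail); offspring falling outside the
    window are discarded.  Returns an (n, 2) coordinate array.
    """
    if kappa < 0 or mu < 0 or sigma < 0:
        raise ValueError("Thomas parameters must be non-negative")
    pad = 4.0 * sigma
    w, h = window.width_m + 2 * pad, window.height_m + 2 * pad
    n_parents = rng.poisson(kappa * w * h)
    if n_parents == 0 or mu == 0:
        return np.empty((0, 2))
    parents = np.column_stack([
        rng.uniform(-pad, window.width_m + pad, n_parents),
        rng.uniform(-pad, window.height_m + pad, n_parents),
    ])
    n_off = rng.poisson(mu, size=n_parents)
    centers = np.repeat(parents, n_off, axis=0)
    pts = centers + rng.normal(0.0, sigma, size=centers.shape)
    keep = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= window.width_m)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= window.height_m)
    )
    return pts[keep]


def sample_hardcore(
    lam: float,
    hard_core_m: float,
    window: PlotGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hard-core-thinned Poisson process (Matérn-II-style sequential thinning).

    A Poisson(λ·|A|) proposal set is visited in random order; a proposal is
    accepted only if it lies at least ``hard_core_m`` from every previously
    accepted point.  The result has minimum pairwise spacing ≥ h.  When the
    intensity is infeasibly high for the core radius the achievable (jammed)
    pattern is returned.
    """
    if hard_core_m < 0:
        raise ValueError("hard core radius must be non-negative")
    if lam < 0:
        raise ValueError("intensity must be non-negative")
    n = rng.poisson(lam * window.area_m2)
    pts = np.column_stack([
        rng.uniform(0.0, window.width_m, n),
        rng.uniform(0.0, window.height_m, n),
    ])
    if hard_core_m == 0.0 or n <= 1:
        return pts
    order = rng.permutation(n)
    pts = pts[order]
    accepted: list[np.ndarray] = []
    h2 = hard_core_m * hard_core_m
    for p in pts:
        ok = True
        for q in accepted:
            dx = p[0] - q[0]
            dy = p[1] - q[1]
            if dx * dx + dy * dy < h2:
                ok = False
                break
        if ok:
            accepted.append(p)
    return np.array(accepted) if accepted else np.empty((0, 2))


def apply_segregation(
    small: np.ndarray,
    large: np.ndarray,
    seg_radius_m: float,
    seg_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thin small points near large points, inducing bivariate repulsion.

    Each small point lying within ``seg_radius_m`` of any large point is
    removed with probability ``seg_prob``; with seg_prob = 1 no survivor is
    closer than the radius to a large point.
    """
    if not 0.0 <= seg_prob <= 1.0:
        raise ValueError("seg_prob must be in [0, 1]")
    if seg_radius_m < 0:
        raise ValueError("seg_radius_m must be non-negative")
    if len(small) == 0 or len(large) == 0 or seg_prob == 0.0:
        return np.asarray(small, dtype=float).reshape(-1, 2).copy()
    tree = cKDTree(large)
    dist, _ = tree.query(small, k=1)
    near = dist < seg_radius_m
    # Draw one uniform per small point (not per near point) so the thinning
    # outcome does not depend on how many points happen to be near.
    u = rng.random(len(small))
    drop = near & (u < seg_prob)
    return np.asarray(small)[~drop]


# ---------------------------------------------------------------------------
# Stand configuration
# ---------------------------------------------------------------------------

#: Default demography-subplot densities (species, stems/m2, kg/m2) for the
#: generated shrub layer; values are plausible montane-chaparral magnitudes.
_DEFAULT_DEMOGRAPHY: tuple[tuple[str, float, float], ...] = (
    ("ARPA", 5.333, 14.747),
    ("CECO", 1.667, 1.189),
    ("CHSE", 3.167, 1.464),
    ("COCO", 1.000, 1.565),
)


@dataclass
class StandConfig:
    """Everything the generator needs; defaults emulate a 25.6 ha
    old-growth mixed-conifer plot (≈1,350 stems/ha, ≈19 large/ha,
    ≈20% snag frequency, ≈15% shrub cover)."""

    width_m: float = 800.0
    height_m: float = 320.0
    quadrat_m: float = 20.0

    # live-stem species mixture (relative weights)
    species_weights: dict[str, float] = field(default_factory=lambda: {
        "ABCO": 0.710, "PILA": 0.138, "CONU": 0.069, "CADE": 0.046,
        "QUKE": 0.032, "PRSP": 0.005,
    })

    # small-tree Thomas process (clustering below ~20 m)
    parent_intensity: float = 0.020      # parents / m2
    mean_offspring: float = 9.0
    dispersal_sd_m: float = 4.0

    # large-tree hard-core process
    large_intensity: float = 0.0019      # trees / m2 (≈19 / ha)
    hard_core_m: float = 2.0

    # large–small segregation
    seg_radius_m: float = 10.0
    seg_prob: float = 0.8

    # diameter models
    dbh_model: str = "negative_exponential"   # or "rotated_sigmoid"
    dbh_rate_per_cm: float = 0.104
    sigmoid_weight: float = 0.75
    sigmoid_rate_per_cm: float = 0.05
    sigmoid_hump_mean_cm: float = 80.0
    sigmoid_hump_sd_cm: float = 25.0
    large_dbh_scale_cm: float = 20.0     # large trees: 100 + Exp(scale)

    # snags
    snag_fraction: float = 0.199         # snags per live stem ≥10 cm

    # shrubs (Boolean disc model)
    shrub_cover: float = 0.15
    shrub_radius_logmean: float = 1.0    # ln-scale mean of disc radius (m)
    shrub_radius_logsd: float = 0.5

    # coarse woody debris field
    coarse_intensity: float = 0.025      # pieces / m2
    coarse_length_mean_m: float = 8.0
    coarse_diam_scale_cm: float = 10.0   # d = 10 + Exp(scale) for common pieces
    coarse_large_prob: float = 0.015      # fraction of pieces ≥100 cm
    coarse_large_scale_cm: float = 30.0  # d = 100 + Exp(scale) for those

    # transects and fine fuels
    n_transects: int = 112
    transect_length_m: float = 20.0
    mean_count_1h: float = 35.0
    mean_count_10h: float = 8.0
    mean_count_100h: float = 2.0
    litter_mean_cm: float = 1.05
    litter_sd_cm: float = 0.38
    duff_mean_cm: float = 1.20
    duff_sd_cm: float = 0.68

    rng_seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "StandConfig":
        """Load a flat key-value TOML config; ``species_weights`` may be a
        TOML table.  Unknown keys are rejected."""
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def geometry(self) -> PlotGeometry:
        return PlotGeometry(self.width_m, self.height_m, self.quadrat_m)

    def small_dbh_model(self):
        if self.dbh_model == "negative_exponential":
            return NegativeExponentialDBH(self.dbh_rate_per_cm)
        if self.dbh_model == "rotated_sigmoid":
            return RotatedSigmoidDBH(
                self.sigmoid_weight, self.sigmoid_rate_per_cm,
                self.sigmoid_hump_mean_cm, self.sigmoid_hump_sd_cm,
            )
        raise ValueError(f"unknown dbh model {self.dbh_model!r}")

    def validate(self) -> None:
        if not 0.0 <= self.seg_prob <= 1.0:
            raise ValueError("seg_prob must lie in [0, 1]")
        if not 0.0 <= self.shrub_cover < 1.0:
            raise ValueError("shrub cover target must lie in [0, 1)")
        if min(self.parent_intensity, self.large_intensity,
               self.coarse_intensity) < 0:
            raise ValueError("intensities must be non-negative")
        if self.hard_core_m < 0:
            raise ValueError("hard core must be non-negative")
        if not 0.0 <= self.snag_fraction <= 1.0:
            raise ValueError("snag fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Layer builders
# ---------------------------------------------------------------------------

def _sample_species(weights: dict[str, float], n: int, rng: np.random.Generator) -> np.ndarray:
    codes = np.array(sorted(weights))
    p = np.array([weights[c] for c in codes], dtype=float)
    p /= p.sum()
    return rng.choice(codes, size=n, p=p)


def _truncated_normal(mean: float, sd: float, n: int, rng: np.random.Generator,
                      lo: float = 0.0) -> np.ndarray:
    vals = rng.normal(mean, sd, size=n)
    bad = vals < lo
    while bad.any():
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = vals < lo
    return vals


def _build_stems(cfg: StandConfig, geom: PlotGeometry,
                 rng_small: np.random.Generator,
                 rng_large: np.random.Generator,
                 rng_seg: np.random.Generator,
                 rng_dbh: np.random.Generator) -> list[StemRecord]:
    small_xy = sample_thomas(cfg.parent_intensity, cfg.mean_offspring,
                             cfg.dispersal_sd_m, geom, rng_small)
    large_xy = sample_hardcore(cfg.large_intensity, cfg.hard_core_m, geom, rng_large)
    small_xy = apply_segregation(small_xy, large_xy, cfg.seg_radius_m,
                                 cfg.seg_prob, rng_seg)

    model = cfg.small_dbh_model()
    # small-tree diameters: conditioned < 100 cm by resampling
    small_dbh = sample_dbh(len(small_xy), model, rng_dbh)
    bad = small_dbh >= 100.0
    while bad.any():
        small_dbh[bad] = sample_dbh(int(bad.sum()), model, rng_dbh)
        bad = small_dbh >= 100.0
    large_dbh = 100.0 + rng_dbh.exponential(cfg.large_dbh_scale_cm, size=len(large_xy))

    xy = np.vstack([small_xy, large_xy]) if len(large_xy) else small_xy
    dbh = np.concatenate([small_dbh, large_dbh])
    species = _sample_species(cfg.species_weights, len(xy), rng_dbh)
    # large-diameter stems are conifers: hardwoods here do not reach 100 cm
    conifers = {sp: w for sp, w in cfg.species_weights.items()
                if sp in ("ABCO", "PILA", "CADE", "ABMA", "PSME", "PIPO")}
    if len(large_xy) and conifers:
        species[len(small_xy):] = _sample_species(conifers, len(large_xy), rng_dbh)
    return [
        StemRecord(tag=f"S{i:06d}", species=str(species[i]),
                   dbh_cm=float(dbh[i]), x_m=float(xy[i, 0]),
                   y_m=float(xy[i, 1]), status="live")
        for i in range(len(xy))
    ]


def _build_snags(cfg: StandConfig, geom: PlotGeometry, stems: Sequence[StemRecord],
                 rng: np.random.Generator) -> list[SnagRecord]:
    n_ref = sum(1 for s in stems if s.dbh_cm >= 10.0)
    n_snags = int(rng.binomial(n_ref, cfg.snag_fraction)) if n_ref else 0
    out = []
    # decay classes weighted toward mid decay, as in field populations
    decay_p = np.array([0.15, 0.25, 0.30, 0.20, 0.10])
    for i in range(n_snags):
        if rng.random() < 0.078:      # large-diameter snag share (Table-1-like)
            dbh = 100.0 + rng.exponential(25.0)
        else:
            dbh = 10.0 + rng.exponential(1.0 / 0.104)
            if dbh >= 100.0:
                dbh = 99.0
        # snags are broken-topped: height well below a live tree of equal dbh
        height = float(np.clip(1.8 + 0.15 * dbh + rng.normal(0.0, 2.0), 1.8, 26.0))
        top = dbh * rng.uniform(0.2, 0.7)
        out.append(SnagRecord(
            tag=f"D{i:05d}", species="UNKN", dbh_cm=float(dbh),
            height_m=height, top_diameter_cm=float(top),
            decay_class=int(rng.choice(5, p=decay_p)) + 1,
            x_m=float(rng.uniform(0.0, geom.width_m)),
            y_m=float(rng.uniform(0.0, geom.height_m)),
        ))
    return out


def _build_shrubs(cfg: StandConfig, geom: PlotGeometry,
                  rng: np.random.Generator) -> list[ShrubPatch]:
    """Boolean disc model: add discs until the clipped union area reaches
    the cover target; patches are the connected components ≥ 2 m²."""
    target = cfg.shrub_cover * geom.area_m2
    if target == 0.0:
        return []
    window = box(0.0, 0.0, geom.width_m, geom.height_m)
    mean_disc = math.pi * math.exp(2 * cfg.shrub_radius_logmean
                                   + 2 * cfg.shrub_radius_logsd ** 2)
    # Boolean-model coverage: union fraction = 1 - exp(-n a / A)
    n0 = max(1, int(-geom.area_m2 * math.log(max(1e-12, 1.0 - cfg.shrub_cover)) / mean_disc))

    def _discs(k: int) -> list[Polygon]:
        xs = rng.uniform(0.0, geom.width_m, k)
        ys = rng.uniform(0.0, geom.height_m, k)
        rs = rng.lognormal(cfg.shrub_radius_logmean, cfg.shrub_radius_logsd, k)
        return [Point(x, y).buffer(r, quad_segs=8) for x, y, r in zip(xs, ys, rs)]

    discs = _discs(n0)
    union = unary_union(discs).intersection(window)
    batch = max(1, n0 // 20)
    for _ in range(200):
        if union.area >= target:
            break
        discs.extend(_discs(batch))
        union = unary_union(discs).intersection(window)
    else:
        raise ValueError("shrub cover target not reachable")

    parts = list(union.geoms) if isinstance(union, MultiPolygon) else [union]
    shrub_species = [d[0] for d in _DEFAULT_DEMOGRAPHY]
    out = []
    for i, poly in enumerate(parts):
        shell = Polygon(poly.exterior)   # patches are simple polygons (no holes)
        if shell.area < 2.0:
            continue
        avg_h = float(_truncated_normal(1.2, 0.4, 1, rng, lo=0.2)[0])
        out.append(ShrubPatch(
            patch_id=f"P{i:05d}",
            species=shrub_species[int(rng.integers(len(shrub_species)))],
            polygon=tuple((float(x), float(y)) for x, y in shell.exterior.coords[:-1]),
            area_m2=float(shell.area),
            avg_height_m=avg_h,
            max_height_m=avg_h * float(rng.uniform(1.2, 2.0)),
        ))
    return out


def _segment_crossings(
    t0: np.ndarray, t1: np.ndarray,
    a: np.ndarray, b: np.ndarray,
) -> np.ndarray:
    """Boolean mask of debris segments (a→b, arrays (n,2)) that properly
    cross the transect t0→t1.  Exact orientation-test geometry."""
    def cross(o, p, q):
        return (p[..., 0] - o[..., 0]) * (q[..., 1] - o[..., 1]) \
             - (p[..., 1] - o[..., 1]) * (q[..., 0] - o[..., 0])

    d1 = cross(t0[None, :], t1[None, :], a)
    d2 = cross(t0[None, :], t1[None, :], b)
    d3 = cross(a, b, np.broadcast_to(t0, a.shape))
    d4 = cross(a, b, np.broadcast_to(t1, a.shape))
    return (d1 * d2 < 0) & (d3 * d4 < 0)


def _build_debris_and_transects(
    cfg: StandConfig, geom: PlotGeometry,
    rng_debris: np.random.Generator,
    rng_transects: np.random.Generator,
) -> list[FuelTransect]:
    # debris field: straight segments with constant diameter
    n_pieces = rng_debris.poisson(cfg.coarse_intensity * geom.area_m2)
    mid = np.column_stack([
        rng_debris.uniform(0.0, geom.width_m, n_pieces),
        rng_debris.uniform(0.0, geom.height_m, n_pieces),
    ])
    theta = rng_debris.uniform(0.0, math.pi, n_pieces)
    length = np.clip(rng_debris.lognormal(math.log(cfg.coarse_length_mean_m) - 0.125,
                                          0.5, n_pieces), 1.0, 40.0)
    half = np.column_stack([np.cos(theta), np.sin(theta)]) * (length[:, None] / 2.0)
    a, b = mid - half, mid + half
    is_large = rng_debris.random(n_pieces) < cfg.coarse_large_prob
    diam = np.where(
        is_large,
        100.0 + rng_debris.exponential(cfg.coarse_large_scale_cm, n_pieces),
        10.0 + rng_debris.exponential(cfg.coarse_diam_scale_cm, n_pieces),
    )
    decay = rng_debris.integers(1, 6, size=n_pieces)

    out = []
    for i in range(cfg.n_transects):
        # rejection-place the line fully inside the window
        while True:
            x0 = float(rng_transects.uniform(0.0, geom.width_m))
            y0 = float(rng_transects.uniform(0.0, geom.height_m))
            az = float(rng_transects.uniform(0.0, 360.0))
            x1 = x0 + cfg.transect_length_m * math.sin(math.radians(az))
            y1 = y0 + cfg.transect_length_m * math.cos(math.radians(az))
            if geom.contains(x1, y1):
                break
        t0 = np.array([x0, y0])
        t1 = np.array([x1, y1])
        if n_pieces:
            hits = np.nonzero(_segment_crossings(t0, t1, a, b))[0]
        else:
            hits = np.empty(0, dtype=int)
        intercepts = tuple(
            CoarseIntercept(diameter_cm=float(diam[j]), decay_class=int(decay[j]),
                            species="UNKN")
            for j in hits
        )
        out.append(FuelTransect(
            transect_id=f"T{i:03d}", x_m=x0, y_m=y0, azimuth_deg=az,
            length_m=cfg.transect_length_m,
            count_1h=int(rng_transects.poisson(cfg.mean_count_1h)),
            count_10h=int(rng_transects.poisson(cfg.mean_count_10h)),
            count_100h=int(rng_transects.poisson(cfg.mean_count_100h)),
            coarse_intercepts=intercepts,
            litter_cm=float(_truncated_normal(cfg.litter_mean_cm, cfg.litter_sd_cm,
                                              1, rng_transects)[0]),
            duff_cm=float(_truncated_normal(cfg.duff_mean_cm, cfg.duff_sd_cm,
                                            1, rng_transects)[0]),
        ))
    return out


def generate_stand(config: StandConfig) -> StandDataset:
    """Compose all layer samplers into a complete, validated StandDataset.

    Identical configuration (including seed) yields an identical dataset;
    each layer uses its own spawned PCG64 stream.
    """
    config.validate()
    geom = config.geometry()
    streams = np.random.SeedSequence(config.rng_seed).spawn(8)
    rngs = [np.random.Generator(np.random.PCG64(s)) for s in streams]
    (rng_small, rng_large, rng_seg, rng_dbh,
     rng_snag, rng_shrub, rng_debris, rng_tr) = rngs

    stems = _build_stems(config, geom, rng_small, rng_large, rng_seg, rng_dbh)
    snags = _build_snags(config, geom, stems, rng_snag)
    shrubs = _build_shrubs(config, geom, rng_shrub)
    transects = _build_debris_and_transects(config, geom, rng_debris, rng_tr)
    demography = [
        ShrubDemographyPlot(species=sp, plot_area_m2=4.0,
                            stems_per_m2=d, biomass_kg_per_m2=b)
        for sp, d, b in _DEFAULT_DEMOGRAPHY
    ]
    return StandDataset(
        geometry=geom, stems=stems, snags=snags,
        shrub_patches=shrubs, demography=demography, transects=transects,
    )
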