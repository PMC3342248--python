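"""End-to-end pipeline: from census layers to table/figure data products.

``run_all`` reads a stand, computes every pool and statistic, and writes a
report bundle of CSV tables plus a JSON run log:

* ``composition_live.csv`` / ``composition_snags.csv`` — density, basal
  area, stem counts by diameter class, large-diameter proportions,
* ``shrubs.csv`` — patch cover and demography-based extrapolation,
* ``biomass.csv`` — all pools with SDs and large-diameter shares,
* ``quadrats.csv`` — per-quadrat stem count / basal area / biomass,
* ``diameter_bins.csv`` / ``scaling_fits.csv`` — size-distribution data
  and fitted scaling-form constants,
* ``spatial_curves.csv`` / ``gof_summary.csv`` — envelope curves and
  Monte-Carlo goodness-of-fit results per analysis,
* ``correlogram.csv`` — debris-volume correlogram over transects,
* ``run_log.json`` — seed, config hash, package versions, stage log.

Every number is regenerated from the raw layers on each run; a fixed seed
gives a byte-identical bundle.  Rounding is round-half-even at the
precision of the corresponding table (1 d.p. percentages and densities,
3 d.p. Mg/ha).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry as alm
from . import ppa
from . import scaling as scl
from .stand_model import (
    PlotGeometry,
    StandDataset,
    basal_area_m2,
    classify_diameter,
    quadratize,
    read_stand,
)

__all__ = ["RunConfig", "proportions", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


def proportions(subset: float, total: float) -> float:
    """Percentage ``100·subset/total`` rounded half-even to 1 decimal.

    Raises ``ValueError`` when the denominator is zero (undefined) or the
    subset exceeds the total.
    """
    if total == 0:
        raise ValueError("proportion undefined: total is zero")
    if subset < 0 or subset > total:
        raise ValueError("subset must satisfy 0 <= subset <= total")
    return round(100.0 * subset / total, 1)


@dataclass
class RunConfig:
    """Everything one report run needs."""

    stand_dir: str
    out_dir: str
    equations_csv: str | None = None       # None -> packaged demonstration registry
    substitutions_csv: str | None = None
    decay_densities_csv: str | None = None
    fuel_coefficients_toml: str | None = None
    large_threshold_cm: float = 100.0
    spatial_species: list[str] = field(default_factory=lambda: ["ABCO", "PILA", "CADE"])
    n_sim: int = 999
    r_max_m: float = 80.0
    r_step_m: float = 0.25
    gof_r_min_m: float = 0.0
    gof_r_max_m: float = 9.0
    min_points_spatial: int = 10
    litter_bulk_density: float = alm.DEFAULT_LITTER_BULK_DENSITY
    duff_bulk_density: float = alm.DEFAULT_DUFF_BULK_DENSITY
    seed: int = 1

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir does not affect the analysis, only where it is written
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _fmt_cell(v, nd: int) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "-"
    return f"{round(float(v), nd):.{nd}f}"


def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_composition(stand: StandDataset, cfg: RunConfig, out: Path) -> None:
    geom = stand.geometry
    live = stand.live_stems
    rows = []
    species = sorted({s.species for s in live})
    for sp in species + ["TOTAL"]:
        sel = live if sp == "TOTAL" else [s for s in live if s.species == sp]
        n1 = len(sel)
        n10 = sum(1 for s in sel if s.dbh_cm >= 10.0)
        n100 = sum(1 for s in sel if s.dbh_cm >= cfg.large_threshold_cm)
        ba = sum(basal_area_m2(s.dbh_cm) for s in sel) / geom.area_ha
        prop = proportions(n100, n1) if n1 > 0 and n100 > 0 else None
        rows.append([
            sp, _fmt_cell(n1 / geom.area_ha, 1), _fmt_cell(ba, 2),
            str(n1), str(n10), str(n100),
            _fmt_cell(prop, 1) if prop is not None else "-",
        ])
    _write_csv(out / "composition_live.csv",
               ["species", "density_per_ha", "basal_area_m2_ha",
                "stems_ge1", "stems_ge10", "stems_ge100", "large_prop_pct"],
               rows)

    rows = []
    snag_species = sorted({s.species for s in stand.snags})
    for sp in snag_species + ["TOTAL"]:
        sel = stand.snags if sp == "TOTAL" else [s for s in stand.snags if s.species == sp]
        n10 = len(sel)
        n100 = sum(1 for s in sel if s.dbh_cm >= cfg.large_threshold_cm)
        prop = proportions(n100, n10) if n10 > 0 and n100 > 0 else None
        rows.append([sp, str(n10), str(n100),
                     _fmt_cell(prop, 1) if prop is not None else "-"])
    _write_csv(out / "composition_snags.csv",
               ["species", "snags_ge10", "snags_ge100", "large_prop_pct"], rows)


def _stage_shrubs(stand: StandDataset, cfg: RunConfig, out: Path) -> pd.DataFrame:
    table = alm.shrub_extrapolate(stand.shrub_patches, stand.demography,
                                  alm.DEFAULT_SHRUB_PROXIES, stand.geometry)
    rows = []
    for sp, r in table.iterrows():
        rows.append([str(sp), _fmt_cell(r.cover_m2, 1),
                     _fmt_cell(r.stems_per_ha, 0),
                     _fmt_cell(r.biomass_mg_per_ha, 3)])
    _write_csv(out / "shrubs.csv",
               ["species", "cover_m2", "stems_per_ha", "biomass_mg_per_ha"], rows)
    return table


def _compute_pools(stand: StandDataset, cfg: RunConfig,
                   registry: alm.EquationRegistry,
                   densities: alm.DecayDensityTable,
                   fuel_coeffs: alm.FuelCoefficients,
                   shrub_table: pd.DataFrame) -> tuple[alm.BiomassReport, dict]:
    live_masses = [alm.tree_biomass(s, registry) for s in stand.live_stems]
    snag_masses = [(s, alm.snag_biomass(s, densities)) for s in stand.snags]
    if stand.transects:
        debris_total, debris_large = alm.coarse_debris_biomass(
            stand.transects, densities, cfg.large_threshold_cm)
        fuels = alm.fine_fuel_biomass(stand.transects, fuel_coeffs)
        litter = alm.litter_duff_biomass([t.litter_cm for t in stand.transects],
                                         cfg.litter_bulk_density)
        duff = alm.litter_duff_biomass([t.duff_cm for t in stand.transects],
                                       cfg.duff_bulk_density)
    else:
        zero = alm.PoolEstimate(0.0, 0.0, 0)
        debris_total = debris_large = litter = duff = zero
        fuels = {"1h": zero, "10h": zero, "100h": zero}
    report = alm.aggregate_report(
        live_masses, snag_masses, debris_total, debris_large, shrub_table,
        fuels, litter, duff, stand.geometry.area_ha, cfg.large_threshold_cm)
    by_tag = {tb.tag: tb.total_kg for tb in live_masses}
    return report, by_tag


def _stage_biomass(report: alm.BiomassReport, out: Path) -> None:
    rows = []
    for sp, r in report.live_by_species.iterrows():
        prop = (proportions(r.bio_ge100, r.bio_ge1)
                if r.bio_ge1 > 0 and r.bio_ge100 > 0 else None)
        rows.append(["live", str(sp),
                     _fmt_cell(r.bio_ge1, 3), _fmt_cell(r.sd_ge1, 3),
                     _fmt_cell(r.bio_ge10, 3), _fmt_cell(r.sd_ge10, 3),
                     _fmt_cell(r.bio_ge100, 3), _fmt_cell(r.sd_ge100, 3),
                     _fmt_cell(prop, 1) if prop is not None else "-"])
    tot = report.live_total
    if len(report.live_by_species):
        rows.append(["live", "TOTAL",
                     _fmt_cell(tot.bio_ge1, 3), _fmt_cell(tot.sd_ge1, 3),
                     _fmt_cell(tot.bio_ge10, 3), _fmt_cell(tot.sd_ge10, 3),
                     _fmt_cell(tot.bio_ge100, 3), _fmt_cell(tot.sd_ge100, 3),
                     _fmt_cell(report.large_fraction_live(), 1)])
    for sp, r in report.snags_by_species.iterrows():
        prop = (proportions(r.bio_ge100, r.bio_ge10)
                if r.bio_ge10 > 0 and r.bio_ge100 > 0 else None)
        rows.append(["snag", str(sp), "-", "-",
                     _fmt_cell(r.bio_ge10, 3), "-",
                     _fmt_cell(r.bio_ge100, 3), "-",
                     _fmt_cell(prop, 1) if prop is not None else "-"])
    stot = report.snag_total
    if len(report.snags_by_species):
        rows.append(["snag", "TOTAL", "-", "-",
                     _fmt_cell(stot.bio_ge10, 3), "-",
                     _fmt_cell(stot.bio_ge100, 3), "-",
                     _fmt_cell(report.large_fraction_snags(), 1)])
    d, dl = report.debris_total, report.debris_large
    dprop = (proportions(dl.mean_mg_per_ha, d.mean_mg_per_ha)
             if d.mean_mg_per_ha > 0 and dl.mean_mg_per_ha > 0 else None)
    rows.append(["debris", "ALL", "-", "-",
                 _fmt_cell(d.mean_mg_per_ha, 3), _fmt_cell(d.sd_mg_per_ha, 3),
                 _fmt_cell(dl.mean_mg_per_ha, 3), _fmt_cell(dl.sd_mg_per_ha, 3),
                 _fmt_cell(dprop, 1) if dprop is not None else "-"])
    rows.append(["shrub", "TOTAL", _fmt_cell(report.shrub_total_mg_ha, 3),
                 "-", "-", "-", "-", "-", "-"])
    for name in ("100h", "10h", "1h"):
        p = report.fine_fuels[name]
        rows.append([f"fine_{name}", "ALL", _fmt_cell(p.mean_mg_per_ha, 3),
                     _fmt_cell(p.sd_mg_per_ha, 3), "-", "-", "-", "-", "-"])
    rows.append(["litter", "ALL", _fmt_cell(report.litter.mean_mg_per_ha, 3),
                 _fmt_cell(report.litter.sd_mg_per_ha, 3), "-", "-", "-", "-", "-"])
    rows.append(["duff", "ALL", _fmt_cell(report.duff.mean_mg_per_ha, 3),
                 _fmt_cell(report.duff.sd_mg_per_ha, 3), "-", "-", "-", "-", "-"])
    rows.append(["grand_total", "ALL", _fmt_cell(report.grand_total_mg_ha(), 1),
                 "-", "-", "-", "-", "-", "-"])
    _write_csv(out / "biomass.csv",
               ["pool", "species", "bio_ge1", "sd_ge1", "bio_ge10", "sd_ge10",
                "bio_ge100", "sd_ge100", "large_prop_pct"], rows)


def _stage_quadrats(stand: StandDataset, by_tag: dict, out: Path) -> None:
    table = quadratize(stand, biomass_by_tag=by_tag)
    rows = [
        [str(qx), str(qy), str(int(r.stem_count)),
         _fmt_cell(r.basal_area_m2, 4), _fmt_cell(r.biomass_kg, 1)]
        for (qx, qy), r in table.iterrows()
    ]
    _write_csv(out / "quadrats.csv",
               ["qx", "qy", "stem_count", "basal_area_m2", "biomass_kg"], rows)


def _stage_scaling(stand: StandDataset, by_tag: dict, out: Path) -> None:
    bins = scl.bin_diameters(stand.live_stems, by_tag)
    rows = [
        [_fmt_cell(bins.edges_cm[i], 1), _fmt_cell(bins.edges_cm[i + 1], 1),
         _fmt_cell(bins.radius_cm[i], 2), str(int(bins.counts[i])),
         _fmt_cell(bins.biomass_mg[i], 3)]
        for i in range(bins.n_bins)
    ]
    _write_csv(out / "diameter_bins.csv",
               ["dbh_lo_cm", "dbh_hi_cm", "radius_cm", "count", "biomass_mg"], rows)
    fit_rows = []
    for model in ("wbe_frequency", "wbe_biomass", "negative_exponential"):
        try:
            fit = scl.fit_scaling(bins, model)
            consts = ";".join(f"{c:.6g}" for c in fit.constants)
            fit_rows.append([model, consts, _fmt_cell(fit.r_squared, 2)])
        except ValueError as exc:
            fit_rows.append([model, "-", f"unfit:{exc}"])
    _write_csv(out / "scaling_fits.csv", ["model", "constants", "r_squared"], fit_rows)


def _stage_spatial(stand: StandDataset, cfg: RunConfig,
                   rng: np.random.Generator, out: Path) -> None:
    geom = stand.geometry
    grid = np.arange(0.0, cfg.r_max_m + cfg.r_step_m / 2, cfg.r_step_m)
    curve_rows: list[list[str]] = []
    gof_rows: list[list[str]] = []

    def record(name: str, env: ppa.EnvelopeResult) -> None:
        lo, hi = ppa.envelope_bounds(env)
        for k, r in enumerate(env.r_grid):
            curve_rows.append([name, f"{r:.2f}", f"{env.observed.l_hat[k]:.6f}",
                               f"{lo[k]:.6f}", f"{hi[k]:.6f}"])
        gof = ppa.gof_loosmore_ford(env, cfg.gof_r_min_m, cfg.gof_r_max_m)
        gof_rows.append([name, env.null_model, str(len(env.simulated)),
                         f"{gof.u_observed:.6g}", f"{gof.p_value:.3f}"])

    targets = list(cfg.spatial_species) + ["ALL"]
    for sp in targets:
        stems = stand.live_stems if sp == "ALL" else [
            s for s in stand.live_stems if s.species == sp]
        parts = classify_diameter(stems, cfg.large_threshold_cm)
        patterns = {
            "small": ppa.PointPattern.from_stems(parts["small"], geom, mark="small"),
            "large": ppa.PointPattern.from_stems(parts["large"], geom, mark="large"),
        }
        for label, pat in patterns.items():
            if pat.n < cfg.min_points_spatial:
                gof_rows.append([f"{sp}_{label}_csr", "csr", "0", "-", "-"])
                continue
            env = ppa.envelope(pat, "csr", cfg.n_sim, rng, r_grid=grid,
                               allow_large_r=True)
            record(f"{sp}_{label}_csr", env)
        if (patterns["small"].n >= cfg.min_points_spatial
                and patterns["large"].n >= cfg.min_points_spatial):
            env = ppa.envelope((patterns["large"], patterns["small"]),
                               "population_independence", cfg.n_sim, rng,
                               r_grid=grid, allow_large_r=True)
            record(f"{sp}_large_small_popindep", env)
        else:
            gof_rows.append([f"{sp}_large_small_popindep",
                             "population_independence", "0", "-", "-"])
    n_tests = sum(1 for row in gof_rows if row[4] != "-")
    thr = ppa.bonferroni(0.05, max(1, n_tests))
    gof_rows.append(["bonferroni_threshold", "-", str(n_tests), "-", f"{thr:.3f}"])
    _write_csv(out / "spatial_curves.csv",
               ["analysis", "r_m", "observed", "env_lo", "env_hi"], curve_rows)
    _write_csv(out / "gof_summary.csv",
               ["analysis", "null_model", "n_sim", "u_observed", "p_value"], gof_rows)


def _stage_correlogram(stand: StandDataset, densities: alm.DecayDensityTable,
                       rng: np.random.Generator, out: Path) -> None:
    if len(stand.transects) < 3:
        _write_csv(out / "correlogram.csv",
                   ["class_lo", "class_hi", "n_pairs", "correlation",
                    "p_value", "estimable"], [])
        return
    vols = []
    mids = []
    for tr in stand.transects:
        v = sum((ci.diameter_cm / 100.0) ** 2 for ci in tr.coarse_intercepts)
        vols.append(math.pi ** 2 * v / (8.0 * tr.length_m))
        x1, y1 = tr.endpoint()
        mids.append(((tr.x_m + x1) / 2.0, (tr.y_m + y1) / 2.0))
    classes = np.arange(0.0, 201.0, 25.0)
    table = ppa.transect_correlogram(vols, mids, classes, rng=rng, n_perm=999)
    rows = [
        [_fmt_cell(r.class_lo, 1), _fmt_cell(r.class_hi, 1), str(int(r.n_pairs)),
         _fmt_cell(r.correlation, 4) if r.estimable else "-",
         _fmt_cell(r.p_value, 3) if r.estimable else "-",
         str(bool(r.estimable))]
        for r in table.itertuples(index=False)
    ]
    _write_csv(out / "correlogram.csv",
               ["class_lo", "class_hi", "n_pairs", "correlation", "p_value",
                "estimable"], rows)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> Path:
    """Run every stage; abort (removing partial outputs) on any failure.

    Returns the output directory.  The run log records the seed, the
    config hash, and one line per completed stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    registry = (alm.EquationRegistry.from_files(cfg.equations_csv, cfg.substitutions_csv)
                if cfg.equations_csv else alm.load_default_registry())
    densities = (alm.DecayDensityTable.from_file(cfg.decay_densities_csv)
                 if cfg.decay_densities_csv else alm.load_default_densities())
    fuel_coeffs = (alm.FuelCoefficients.from_file(cfg.fuel_coefficients_toml)
                   if cfg.fuel_coefficients_toml else alm.load_default_fuel_coefficients())

    rng_spatial, rng_corr = [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(cfg.seed).spawn(2)
    ]

    log: list[str] = []
    stage = "read_stand"
    try:
        stand = read_stand(cfg.stand_dir)
        log.append(f"read_stand: {len(stand.stems)} stems, {len(stand.snags)} snags, "
                   f"{len(stand.shrub_patches)} patches, {len(stand.transects)} transects")

        for name in ("composition_live.csv", "composition_snags.csv", "shrubs.csv",
                     "biomass.csv", "quadrats.csv", "diameter_bins.csv",
                     "scaling_fits.csv", "spatial_curves.csv", "gof_summary.csv",
                     "correlogram.csv", "run_log.json"):
            track(name)

        stage = "composition"
        _stage_composition(stand, cfg, out)
        log.append("composition: done")
        stage = "shrubs"
        shrub_table = _stage_shrubs(stand, cfg, out)
        log.append("shrubs: done")
        stage = "biomass"
        report, by_tag = _compute_pools(stand, cfg, registry, densities,
                                        fuel_coeffs, shrub_table)
        _stage_biomass(report, out)
        log.append(f"biomass: grand total {report.grand_total_mg_ha():.1f} Mg/ha")
        stage = "quadrats"
        _stage_quadrats(stand, by_tag, out)
        log.append("quadrats: done")
        stage = "scaling"
        _stage_scaling(stand, by_tag, out)
        log.append("scaling: done")
        stage = "spatial"
        _stage_spatial(stand, cfg, rng_spatial, out)
        log.append("spatial: done")
        stage = "correlogram"
        _stage_correlogram(stand, densities, rng_corr, out)
        log.append("correlogram: done")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    import standforge
    run_log = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "standforge_version": standforge.__version__,
        "numpy_version": np.__version__,
        "stages": log,
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return out
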