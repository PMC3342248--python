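"""Aboveground biomass pools with error propagation.

Implements every biomass estimator a stem-mapped plot needs:

* per-tree component allometry (``mass = f(dbh)`` on a log or power scale)
  with species substitution rules and branch/foliage caps for diameters
  beyond any dissected tree,
* the lognormal back-transformation of a log-scale regression RMSE into an
  arithmetic per-tree standard deviation,
* snag bole volume as a frustum of a cone times a decay-class wood density,
* shrub biomass extrapolated from demography-subplot densities times mapped
  patch cover,
* planar (line) intercept coarse-debris volume, ``V/A = π²·Σd² / (8L)``,
* Brown-style fine-fuel loads per timelag class from transect tallies,
* litter and duff mass from mean depth times a bulk density,
* aggregation into a per-species, per-pool report with the fully-correlated
  SD convention (per-species SD = sum of per-tree SDs).

Public results are in Mg/ha unless a function name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stand_model import (
    FuelTransect,
    PlotGeometry,
    ShrubDemographyPlot,
    ShrubPatch,
    SnagRecord,
    StemRecord,
)

__all__ = [
    "AllometricEquation",
    "SubstitutionRule",
    "EquationRegistry",
    "DecayDensityTable",
    "FuelClassCoefficients",
    "FuelCoefficients",
    "TreeBiomass",
    "PoolEstimate",
    "BiomassReport",
    "UnresolvedSpeciesError",
    "DiameterRangeError",
    "tree_biomass",
    "rmse_to_sd",
    "snag_biomass",
    "shrub_extrapolate",
    "coarse_debris_biomass",
    "fine_fuel_biomass",
    "litter_duff_biomass",
    "aggregate_report",
    "load_default_registry",
    "load_default_densities",
    "load_default_fuel_coefficients",
    "DEFAULT_LITTER_BULK_DENSITY",
    "DEFAULT_DUFF_BULK_DENSITY",
    "DEFAULT_SHRUB_PROXIES",
]

#: Bulk densities (kg/m³) calibrated so that the plot-mean litter and duff
#: depths reproduce typical Sierra mixed-conifer forest-floor loads.
DEFAULT_LITTER_BULK_DENSITY = 125.2
DEFAULT_DUFF_BULK_DENSITY = 200.1

#: Demography proxies for shrub species without their own subplots:
#: species -> (proxy species, scale applied to the proxy's densities).
DEFAULT_SHRUB_PROXIES: dict[str, tuple[str, float]] = {
    "SARA": ("COCO", 1.0),
    "RHOC": ("VAUL", 1.0),
    "RINE": ("VAUL", 1.0),
    "RIRO": ("VAUL", 0.5),
}


class UnresolvedSpeciesError(KeyError):
    """No equation (directly or through a substitution rule) covers a species."""


class DiameterRangeError(ValueError):
    """A diameter falls outside the validity range of every candidate equation."""


# ---------------------------------------------------------------------------
# Equation registry
# ---------------------------------------------------------------------------

_FORMS = ("log10_linear", "ln_linear", "power")
_COMPONENTS = ("bole", "branch", "foliage", "bark", "whole")


@dataclass(frozen=True)
class AllometricEquation:
    """One component biomass model ``mass_kg = f(dbh_cm)``.

    Forms
    -----
    log10_linear : log10(mass) = c0 + c1·log10(dbh)
    ln_linear    : ln(mass)    = c0 + c1·ln(dbh)
    power        : mass        = c0 · dbh^c1

    ``rmse_log`` is the standard error of estimate on the equation's native
    log scale (absent for the power form unless supplied).
    """

    species: str
    component: str
    form: str
    coefficients: tuple[float, ...]
    dbh_min_cm: float
    dbh_max_cm: float
    rmse_log: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.component not in _COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if len(self.coefficients) != 2:
            raise ValueError("coefficients must be (c0, c1)")
        if not self.dbh_min_cm < self.dbh_max_cm:
            raise ValueError("dbh_min_cm must be < dbh_max_cm")

    @property
    def log_base(self) -> float | None:
        if self.form == "log10_linear":
            return 10.0
        if self.form == "ln_linear":
            return math.e
        return None

    def covers(self, dbh_cm: float) -> bool:
        return self.dbh_min_cm <= dbh_cm <= self.dbh_max_cm

    def evaluate(self, dbh_cm: float) -> float:
        """Predicted mass (kg): evaluated on the native scale, then
        back-transformed with no smearing correction (the lognormal
        correction enters only through :func:`rmse_to_sd`)."""
        c0, c1 = self.coefficients
        if self.form == "log10_linear":
            return 10.0 ** (c0 + c1 * math.log10(dbh_cm))
        if self.form == "ln_linear":
            return math.exp(c0 + c1 * math.log(dbh_cm))
        return c0 * dbh_cm ** c1


@dataclass(frozen=True)
class SubstitutionRule:
    """Use a proxy species' equations for some components above a dbh
    threshold, optionally capping branch/foliage at a fixed diameter."""

    species: str
    dbh_from_cm: float
    proxy_species: str
    components: frozenset[str]
    cap_dbh_cm: float | None = None

    def __post_init__(self) -> None:
        if self.dbh_from_cm < 0:
            raise ValueError("dbh_from_cm must be non-negative")


class EquationRegistry:
    """Lookup of allometric equations and substitution rules by species."""

    def __init__(
        self,
        equations: Iterable[AllometricEquation],
        rules: Iterable[SubstitutionRule] = (),
    ) -> None:
        self._eq: dict[tuple[str, str], list[AllometricEquation]] = {}
        for eq in equations:
            self._eq.setdefault((eq.species, eq.component), []).append(eq)
        self.rules = list(rules)
        for rule in self.rules:
            if not any(sp == rule.proxy_species for sp, _ in self._eq):
                raise ValueError(
                    f"substitution rule for {rule.species}: proxy "
                    f"{rule.proxy_species!r} not in registry"
                )

    def species(self) -> set[str]:
        return {sp for sp, _ in self._eq}

    def components_for(self, species: str) -> set[str]:
        return {comp for sp, comp in self._eq if sp == species}

    def lookup(self, species: str, component: str, dbh_cm: float) -> AllometricEquation:
        cands = self._eq.get((species, component), [])
        if not cands:
            raise UnresolvedSpeciesError(f"no {component} equation for {species!r}")
        for eq in cands:
            if eq.covers(dbh_cm):
                return eq
        lo = min(eq.dbh_min_cm for eq in cands)
        hi = max(eq.dbh_max_cm for eq in cands)
        raise DiameterRangeError(
            f"dbh {dbh_cm} cm outside [{lo}, {hi}] for {species} {component}"
        )

    def rule_for(self, species: str, component: str, dbh_cm: float) -> SubstitutionRule | None:
        best: SubstitutionRule | None = None
        for rule in self.rules:
            if rule.species != species or component not in rule.components:
                continue
            if dbh_cm >= rule.dbh_from_cm and (best is None or rule.dbh_from_cm > best.dbh_from_cm):
                best = rule
        return best

    @classmethod
    def from_files(cls, equations_csv: str | Path,
                   substitutions_csv: str | Path | None = None) -> "EquationRegistry":
        eq_df = pd.read_csv(equations_csv, dtype={"species": str, "component": str,
                                                  "form": str, "source_id": str})
        equations = [
            AllometricEquation(
                species=r.species, component=r.component, form=r.form,
                coefficients=(float(r.c0), float(r.c1)),
                dbh_min_cm=float(r.dbh_min_cm), dbh_max_cm=float(r.dbh_max_cm),
                rmse_log=None if pd.isna(r.rmse_log) else float(r.rmse_log),
                source_id=str(r.source_id),
            )
            for r in eq_df.itertuples(index=False)
        ]
        rules: list[SubstitutionRule] = []
        if substitutions_csv is not None:
            sub_df = pd.read_csv(substitutions_csv, dtype={"species": str,
                                                           "proxy_species": str,
                                                           "components": str})
            rules = [
                SubstitutionRule(
                    species=r.species, dbh_from_cm=float(r.dbh_from_cm),
                    proxy_species=r.proxy_species,
                    components=frozenset(r.components.split(";")),
                    cap_dbh_cm=None if pd.isna(r.cap_dbh_cm) else float(r.cap_dbh_cm),
                )
                for r in sub_df.itertuples(index=False)
            ]
        return cls(equations, rules)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("standforge").joinpath("data", name)))


def load_default_registry() -> EquationRegistry:
    """The packaged demonstration registry.

    Coefficients are plausible for Sierra Nevada conifers but are
    **demonstration values, not a published compendium**; supply your own
    ``equations.csv``/``substitutions.csv`` for real analyses.
    """
    return EquationRegistry.from_files(_data_path("equations.csv"),
                                       _data_path("substitutions.csv"))


# ---------------------------------------------------------------------------
# Per-tree biomass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeBiomass:
    """Component masses (kg) plus total and its arithmetic SD for one stem."""

    tag: str
    species: str
    dbh_cm: float
    components_kg: Mapping[str, float]
    total_kg: float
    sd_kg: float


def rmse_to_sd(m_hat_kg: float, rmse_log: float, log_base: float) -> float:
    """Arithmetic SD (kg) implied by a log-scale regression RMSE.

    Treats the prediction error as lognormal: for ``s`` in units of
    ``log_base``, ``SD = m̂·sqrt(exp((s·ln base)²) − 1)``.
    """
    if rmse_log < 0:
        raise ValueError("rmse_log must be non-negative")
    s_nat = rmse_log * math.log(log_base)
    return m_hat_kg * math.sqrt(math.expm1(s_nat * s_nat))


def tree_biomass(stem: StemRecord, registry: EquationRegistry) -> TreeBiomass:
    """Component biomass of one stem with substitutions and caps applied.

    For each component the registry is consulted; a substitution rule may
    redirect the lookup to a proxy species and/or cap the evaluation
    diameter (branch and foliage above the cap take the cap's value).
    The per-tree SD is the sum of per-component SDs (components of one tree
    are treated as perfectly correlated).
    """
    components = registry.components_for(stem.species)
    rule_comps: set[str] = set()
    for rule in registry.rules:
        if rule.species == stem.species and stem.dbh_cm >= rule.dbh_from_cm:
            rule_comps |= rule.components
    components = components | rule_comps
    if not components:
        raise UnresolvedSpeciesError(
            f"species {stem.species!r} has no equations and no substitution rule"
        )
    if "whole" in components and len(components & {"bole", "branch", "foliage", "bark"}) == 0:
        components = {"whole"}
    else:
        components = components - {"whole"}

    masses: dict[str, float] = {}
    sd_total = 0.0
    for comp in sorted(components):
        species = stem.species
        dbh_eval = stem.dbh_cm
        rule = registry.rule_for(stem.species, comp, stem.dbh_cm)
        if rule is not None:
            species = rule.proxy_species
            if rule.cap_dbh_cm is not None:
                dbh_eval = min(dbh_eval, rule.cap_dbh_cm)
        eq = registry.lookup(species, comp, dbh_eval)
        m = eq.evaluate(dbh_eval)
        masses[comp] = m
        if eq.rmse_log is not None and eq.log_base is not None:
            sd_total += rmse_to_sd(m, eq.rmse_log, eq.log_base)
    total = sum(masses.values())
    return TreeBiomass(tag=stem.tag, species=stem.species, dbh_cm=stem.dbh_cm,
                       components_kg=masses, total_kg=total, sd_kg=sd_total)


# ---------------------------------------------------------------------------
# Snags
# ---------------------------------------------------------------------------

class DecayDensityTable:
    """Wood density (kg/m³) by species group and decay class 1–5."""

    def __init__(self, densities: Mapping[str, Mapping[int, float]],
                 species_groups: Mapping[str, str] | None = None) -> None:
        for group, by_class in densities.items():
            prev = math.inf
            for cls in range(1, 6):
                if cls not in by_class:
                    raise ValueError(f"group {group!r}: missing decay class {cls}")
                d = by_class[cls]
                if d <= 0:
                    raise ValueError(f"group {group!r} class {cls}: density must be > 0")
                if d > prev:
                    raise ValueError(
                        f"group {group!r}: density must not increase with decay class"
                    )
                prev = d
        self._densities = {g: dict(v) for g, v in densities.items()}
        self._groups = dict(species_groups or {})
        if "default" not in self._densities:
            raise ValueError("a 'default' species group is required")

    def density(self, species: str, decay_class: int) -> float:
        if not 1 <= decay_class <= 5:
            raise ValueError(f"decay class {decay_class} outside 1–5")
        group = self._groups.get(species, "default")
        return self._densities[group][decay_class]

    @classmethod
    def from_file(cls, path: str | Path) -> "DecayDensityTable":
        df = pd.read_csv(path, dtype={"group": str})
        densities: dict[str, dict[int, float]] = {}
        groups: dict[str, str] = {}
        for r in df.itertuples(index=False):
            densities[r.group] = {c: float(getattr(r, f"class{c}")) for c in range(1, 6)}
            for sp in str(r.species_codes).split(";"):
                if sp and sp != "nan":
                    groups[sp] = r.group
        return cls(densities, groups)


def load_default_densities() -> DecayDensityTable:
    return DecayDensityTable.from_file(_data_path("decay_densities.csv"))


def frustum_volume_m3(dbh_cm: float, top_diameter_cm: float, height_m: float) -> float:
    """Bole volume as a frustum of a cone: V = πh/3 (R² + Rr + r²)."""
    big_r = dbh_cm / 200.0
    small_r = top_diameter_cm / 200.0
    return math.pi * height_m / 3.0 * (big_r * big_r + big_r * small_r + small_r * small_r)


def snag_biomass(snag: SnagRecord, densities: DecayDensityTable) -> float:
    """Mass of one snag (Mg): frustum volume times decay-class wood density."""
    vol = frustum_volume_m3(snag.dbh_cm, snag.top_diameter_cm, snag.height_m)
    return vol * densities.density(snag.species, snag.decay_class) / 1000.0


# ---------------------------------------------------------------------------
# Shrubs
# ---------------------------------------------------------------------------

def shrub_extrapolate(
    patches: Sequence[ShrubPatch] | Mapping[str, float],
    demography: Sequence[ShrubDemographyPlot],
    proxies: Mapping[str, tuple[str, float]] | None,
    geometry: PlotGeometry,
) -> pd.DataFrame:
    """Scale demography-subplot densities up to mapped patch cover.

    ``patches`` may be the mapped patch list or a precomputed
    ``{species: cover_m2}`` mapping.  For each species::

        biomass (Mg/ha) = cover_m2 · biomass_kg_per_m2 / (area_ha · 1000)
        stems   (1/ha)  = cover_m2 · stems_per_m2      /  area_ha

    Species without a demography subplot resolve through ``proxies`` —
    ``{species: (proxy, scale)}`` — where ``scale`` multiplies the proxy's
    densities (e.g. one half).  Returns a DataFrame indexed by species with
    ``cover_m2``, ``stems_per_ha`` and ``biomass_mg_per_ha`` columns plus a
    ``TOTAL`` row.
    """
    if isinstance(patches, Mapping):
        cover = dict(patches)
    else:
        cover = {}
        for p in patches:
            cover[p.species] = cover.get(p.species, 0.0) + p.area_m2
    dem = {d.species: d for d in demography}
    proxies = proxies or {}

    rows = []
    for sp in sorted(cover):
        scale = 1.0
        source = sp
        if sp not in dem:
            if sp not in proxies:
                raise UnresolvedSpeciesError(
                    f"shrub species {sp!r} has no demography plot and no proxy"
                )
            source, scale = proxies[sp]
            if source not in dem:
                raise UnresolvedSpeciesError(
                    f"proxy {source!r} for {sp!r} has no demography plot"
                )
        d = dem[source]
        rows.append({
            "species": sp,
            "cover_m2": cover[sp],
            "stems_per_ha": cover[sp] * d.stems_per_m2 * scale / geometry.area_ha,
            "biomass_mg_per_ha": cover[sp] * d.biomass_kg_per_m2 * scale
                                 / (geometry.area_ha * 1000.0),
        })
    out = pd.DataFrame(rows).set_index("species") if rows else pd.DataFrame(
        columns=["cover_m2", "stems_per_ha", "biomass_mg_per_ha"])
    out.loc["TOTAL"] = out.sum()
    return out


# ---------------------------------------------------------------------------
# Coarse woody debris (planar intercept)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolEstimate:
    """A plot-level pool value with its spread across sampling units."""

    mean_mg_per_ha: float
    sd_mg_per_ha: float
    n_units: int


def _transect_debris_kg_m2(tr: FuelTransect, densities: DecayDensityTable,
                           min_d: float = 0.0, max_d: float = math.inf) -> float:
    # mass/area = Σ π² d² ρ / (8 L) over intercepts, d in meters
    total = 0.0
    for ci in tr.coarse_intercepts:
        if not (min_d <= ci.diameter_cm < max_d):
            continue
        d_m = ci.diameter_cm / 100.0
        rho = densities.density(ci.species, ci.decay_class)
        total += math.pi ** 2 * d_m * d_m * rho / (8.0 * tr.length_m)
    return total


def coarse_debris_biomass(
    transects: Sequence[FuelTransect],
    densities: DecayDensityTable,
    large_threshold_cm: float = 100.0,
) -> tuple[PoolEstimate, PoolEstimate]:
    """Coarse-debris mass from line intercepts: total and ≥ threshold subset.

    Per transect the planar-intercept identity ``V/A = π²·Σdᵢ²/(8L)`` is
    applied piecewise with the decay-class density of each piece; the plot
    value is the mean over transects and the SD is the spread across
    transects (Mg/ha).
    """
    if not transects:
        raise ValueError("at least one transect is required")
    if any(tr.length_m <= 0 for tr in transects):
        raise ValueError("zero-length transect")
    per_total = np.array([
        _transect_debris_kg_m2(tr, densities) * 10.0 for tr in transects
    ])
    per_large = np.array([
        _transect_debris_kg_m2(tr, densities, min_d=large_threshold_cm) * 10.0
        for tr in transects
    ])
    return (
        PoolEstimate(float(per_total.mean()),
                     float(per_total.std(ddof=1)) if len(per_total) > 1 else 0.0,
                     len(transects)),
        PoolEstimate(float(per_large.mean()),
                     float(per_large.std(ddof=1)) if len(per_large) > 1 else 0.0,
                     len(transects)),
    )


# ---------------------------------------------------------------------------
# Fine fuels (Brown's planar-intercept tallies)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FuelClassCoefficients:
    """Per-timelag-class constants: squared quadratic-mean diameter and
    specific gravity of the tallied pieces."""

    qmd_cm: float
    specific_gravity: float


@dataclass(frozen=True)
class FuelCoefficients:
    """Brown-method coefficient set (1-h, 10-h, 100-h classes plus the
    nonhorizontal-lean and slope corrections shared by all classes)."""

    class_1h: FuelClassCoefficients
    class_10h: FuelClassCoefficients
    class_100h: FuelClassCoefficients
    angle_correction: float = 1.13
    slope_correction: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path) -> "FuelCoefficients":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        def cc(sec):  # noqa: E306 - tiny local helper
            return FuelClassCoefficients(qmd_cm=float(sec["qmd_cm"]),
                                         specific_gravity=float(sec["specific_gravity"]))
        return cls(
            class_1h=cc(raw["1h"]), class_10h=cc(raw["10h"]), class_100h=cc(raw["100h"]),
            angle_correction=float(raw.get("angle_correction", 1.13)),
            slope_correction=float(raw.get("slope_correction", 1.0)),
        )


def load_default_fuel_coefficients() -> FuelCoefficients:
    return FuelCoefficients.from_file(_data_path("fuel_coefficients.toml"))


#: Constant of the planar-intercept mass identity with QMD in meters and
#: wood density expressed as specific gravity × 1000 kg/m³:
#: mass (kg/m²) = K_INTERCEPT · n · QMD² · SG · c_angle · c_slope / L.
K_INTERCEPT = math.pi ** 2 / 8.0 * 1000.0


def fine_fuel_biomass(
    transects: Sequence[FuelTransect],
    coefficients: FuelCoefficients | None,
) -> dict[str, PoolEstimate]:
    """Fine-fuel load (Mg/ha) per timelag class from intercept tallies.

    Per transect and class,
    ``mass = K·n·QMD²·SG·c_angle·c_slope / L_class`` (kg/m², then ×10 for
    Mg/ha), identical to summing the planar-intercept identity over ``n``
    pieces of constant diameter QMD.
    """
    if coefficients is None:
        raise ValueError("a FuelCoefficients set is required")
    if not transects:
        raise ValueError("at least one transect is required")
    spec = {
        "1h": (coefficients.class_1h, "count_1h", "len_1h_m"),
        "10h": (coefficients.class_10h, "count_10h", "len_10h_m"),
        "100h": (coefficients.class_100h, "count_100h", "len_100h_m"),
    }
    out = {}
    for name, (cc, count_attr, len_attr) in spec.items():
        qmd_m = cc.qmd_cm / 100.0
        vals = []
        for tr in transects:
            n = getattr(tr, count_attr)
            sub_l = getattr(tr, len_attr)
            if sub_l <= 0:
                raise ValueError(f"transect {tr.transect_id}: zero sampled length for {name}")
            kg_m2 = (K_INTERCEPT * n * qmd_m * qmd_m * cc.specific_gravity
                     * coefficients.angle_correction * coefficients.slope_correction / sub_l)
            vals.append(kg_m2 * 10.0)
        arr = np.array(vals)
        out[name] = PoolEstimate(float(arr.mean()),
                                 float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                                 len(arr))
    return out


# ---------------------------------------------------------------------------
# Litter and duff
# ---------------------------------------------------------------------------

def litter_duff_biomass(depths_cm: Sequence[float], bulk_density_kg_m3: float) -> PoolEstimate:
    """Forest-floor mass from layer depths: Mg/ha = depth(m)·ρ(kg/m³)·10."""
    depths = np.asarray(depths_cm, dtype=float)
    if (depths < 0).any():
        raise ValueError("negative depth")
    per = depths / 100.0 * bulk_density_kg_m3 * 10.0
    return PoolEstimate(float(per.mean()),
                        float(per.std(ddof=1)) if len(per) > 1 else 0.0,
                        len(per))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class BiomassReport:
    """Per-species, per-pool biomass with SDs and large-diameter shares.

    ``live_by_species`` columns: ``bio_ge1``, ``sd_ge1``, ``bio_ge10``,
    ``sd_ge10``, ``bio_ge100``, ``sd_ge100`` (Mg/ha).
    ``snags_by_species`` columns: ``bio_ge10``, ``bio_ge100``.
    """

    live_by_species: pd.DataFrame
    snags_by_species: pd.DataFrame
    debris_total: PoolEstimate
    debris_large: PoolEstimate
    shrub_table: pd.DataFrame
    fine_fuels: dict[str, PoolEstimate]
    litter: PoolEstimate
    duff: PoolEstimate

    @property
    def live_total(self) -> pd.Series:
        return self.live_by_species.sum()

    @property
    def snag_total(self) -> pd.Series:
        return self.snags_by_species.sum()

    @property
    def shrub_total_mg_ha(self) -> float:
        return float(self.shrub_table.loc["TOTAL", "biomass_mg_per_ha"])

    @property
    def fine_fuel_total_mg_ha(self) -> float:
        """Fine fuels including the litter and duff layers."""
        return (sum(p.mean_mg_per_ha for p in self.fine_fuels.values())
                + self.litter.mean_mg_per_ha + self.duff.mean_mg_per_ha)

    def large_fraction_live(self) -> float:
        """≥100 cm share of live-tree biomass, in percent."""
        tot = self.live_total
        return 100.0 * tot["bio_ge100"] / tot["bio_ge1"]

    def large_fraction_snags(self) -> float:
        tot = self.snag_total
        return 100.0 * tot["bio_ge100"] / tot["bio_ge10"]

    def large_fraction_debris(self) -> float:
        return 100.0 * self.debris_large.mean_mg_per_ha / self.debris_total.mean_mg_per_ha

    def grand_total_mg_ha(self) -> float:
        """Live trees + snags + coarse debris + shrubs + fine fuels
        (fine fuels include litter and duff)."""
        return (float(self.live_total["bio_ge1"])
                + float(self.snag_total["bio_ge10"])
                + self.debris_total.mean_mg_per_ha
                + self.shrub_total_mg_ha
                + self.fine_fuel_total_mg_ha)


def aggregate_report(
    live_trees: Sequence[TreeBiomass],
    snag_masses: Sequence[tuple[SnagRecord, float]],
    debris_total: PoolEstimate,
    debris_large: PoolEstimate,
    shrub_table: pd.DataFrame,
    fine_fuels: dict[str, PoolEstimate],
    litter: PoolEstimate,
    duff: PoolEstimate,
    area_ha: float,
    large_threshold_cm: float = 100.0,
) -> BiomassReport:
    """Assemble per-pool results into one report.

    SD convention: per-species SD is the arithmetic sum of per-tree SDs and
    the plot SD the sum of species SDs — allometric errors are treated as
    fully correlated within and across trees of a species, the conservative
    convention for equation-driven uncertainty.
    """
    cols = ["bio_ge1", "sd_ge1", "bio_ge10", "sd_ge10", "bio_ge100", "sd_ge100"]
    live_rows: dict[str, np.ndarray] = {}
    for tb in live_trees:
        row = live_rows.setdefault(tb.species, np.zeros(len(cols)))
        mg = tb.total_kg / 1000.0 / area_ha
        sd = tb.sd_kg / 1000.0 / area_ha
        row[0] += mg
        row[1] += sd
        if tb.dbh_cm >= 10.0:
            row[2] += mg
            row[3] += sd
        if tb.dbh_cm >= large_threshold_cm:
            row[4] += mg
            row[5] += sd
    live_df = pd.DataFrame.from_dict(live_rows, orient="index", columns=cols).sort_index()
    if live_df.empty:
        live_df = pd.DataFrame(columns=cols, dtype=float)

    snag_rows: dict[str, np.ndarray] = {}
    for snag, mass_mg in snag_masses:
        row = snag_rows.setdefault(snag.species, np.zeros(2))
        row[0] += mass_mg / area_ha
        if snag.dbh_cm >= large_threshold_cm:
            row[1] += mass_mg / area_ha
    snag_df = pd.DataFrame.from_dict(snag_rows, orient="index",
                                     columns=["bio_ge10", "bio_ge100"]).sort_index()
    if snag_df.empty:
        snag_df = pd.DataFrame(columns=["bio_ge10", "bio_ge100"], dtype=float)

    return BiomassReport(
        live_by_species=live_df, snags_by_species=snag_df,
        debris_total=debris_total, debris_large=debris_large,
        shrub_table=shrub_table, fine_fuels=fine_fuels,
        litter=litter, duff=duff,
    )
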