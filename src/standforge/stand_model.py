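"""Domain types, census-layer I/O, validation, and plot bookkeeping.

A stem-mapped forest plot is represented as a :class:`StandDataset` — a
bundle of census layers (live stems, snags, shrub patches, shrub demography
subplots, fuel transects) sharing one rectangular :class:`PlotGeometry`.
Coordinates are metric, origin at the south-west corner, x increasing east
and y increasing north.

File formats are deliberately plain: one UTF-8 CSV per tabular layer with a
documented header, plus a GeoJSON FeatureCollection for shrub-patch
polygons.  Writers are bit-stable given a fixed record order so that
identical datasets serialize identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "PlotGeometry",
    "StemRecord",
    "SnagRecord",
    "ShrubPatch",
    "ShrubDemographyPlot",
    "CoarseIntercept",
    "FuelTransect",
    "StandDataset",
    "StandValidationError",
    "SchemaError",
    "read_stand",
    "write_stand",
    "classify_diameter",
    "quadratize",
    "basal_area_m2",
]

#: Column dictionaries for the delimited layers (order is the file order).
STEM_COLUMNS = ["tag", "species", "dbh_cm", "x_m", "y_m", "status"]
SNAG_COLUMNS = [
    "tag", "species", "dbh_cm", "height_m", "top_diameter_cm",
    "decay_class", "x_m", "y_m",
]
DEMOGRAPHY_COLUMNS = ["species", "plot_area_m2", "stems_per_m2", "biomass_kg_per_m2"]
TRANSECT_COLUMNS = [
    "transect_id", "x_m", "y_m", "azimuth_deg", "length_m",
    "count_1h", "count_10h", "count_100h",
    "len_1h_m", "len_10h_m", "len_100h_m",
    "litter_cm", "duff_cm", "coarse_intercepts",
]


class StandValidationError(ValueError):
    """A census record violates a documented invariant."""


class SchemaError(ValueError):
    """A layer file does not match its documented column dictionary."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular plot extent with a square quadrat grid.

    Parameters
    ----------
    width_m, height_m
        East–west and north–south extents in meters.  Both must be positive
        integer multiples of ``quadrat_m``.
    quadrat_m
        Quadrat edge length in meters (default 20, the conventional
        forest-dynamics-plot grid).
    """

    width_m: float
    height_m: float
    quadrat_m: float = 20.0

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.height_m <= 0:
            raise StandValidationError("plot dimensions must be positive")
        if self.quadrat_m <= 0:
            raise StandValidationError("quadrat edge must be positive")
        for dim, name in ((self.width_m, "width_m"), (self.height_m, "height_m")):
            ratio = dim / self.quadrat_m
            if abs(ratio - round(ratio)) > 1e-9:
                raise StandValidationError(
                    f"{name}={dim} is not an integer multiple of quadrat_m={self.quadrat_m}"
                )

    @property
    def area_m2(self) -> float:
        return self.width_m * self.height_m

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 10_000.0

    @property
    def n_quadrats(self) -> tuple[int, int]:
        """Number of quadrat columns (x) and rows (y)."""
        return (
            int(round(self.width_m / self.quadrat_m)),
            int(round(self.height_m / self.quadrat_m)),
        )

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width_m and 0.0 <= y <= self.height_m

    def quadrat_of(self, x: float, y: float) -> tuple[int, int]:
        """Quadrat index of a point, half-open intervals ``[k*q, (k+1)*q)``.

        The far boundaries x = width and y = height map into the last
        quadrat (documented closure), so every in-plot point has a quadrat.
        """
        nx, ny = self.n_quadrats
        ix = min(int(x // self.quadrat_m), nx - 1)
        iy = min(int(y // self.quadrat_m), ny - 1)
        return ix, iy


@dataclass(frozen=True)
class StemRecord:
    """One mapped live (or dead, for bookkeeping) stem ≥1 cm dbh."""

    tag: str
    species: str
    dbh_cm: float
    x_m: float
    y_m: float
    status: str = "live"


@dataclass(frozen=True)
class SnagRecord:
    """One standing dead tree ≥10 cm dbh and ≥1.8 m tall."""

    tag: str
    species: str
    dbh_cm: float
    height_m: float
    top_diameter_cm: float
    decay_class: int
    x_m: float
    y_m: float


@dataclass(frozen=True)
class ShrubPatch:
    """A mapped patch of continuous shrub cover ≥2 m²."""

    patch_id: str
    species: str
    polygon: tuple[tuple[float, float], ...]
    area_m2: float
    avg_height_m: float
    max_height_m: float

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class ShrubDemographyPlot:
    """Per-species stem and biomass density from a small demography subplot."""

    species: str
    plot_area_m2: float
    stems_per_m2: float
    biomass_kg_per_m2: float


@dataclass(frozen=True)
class CoarseIntercept:
    """One piece of coarse woody debris crossing a transect.

    ``diameter_cm`` is the intercept diameter measured perpendicular to the
    piece axis; only pieces ≥10 cm are recorded.
    """

    diameter_cm: float
    decay_class: int
    species: str = "UNKN"


@dataclass(frozen=True)
class FuelTransect:
    """One 20 m planar-intercept fuel line.

    Fine fuels are tallied on sub-lengths of the line (2 m for 1-h and
    10-h classes, 4 m for 100-h); coarse pieces ≥10 cm are recorded over
    the full length with their intercept diameters and decay classes.
    """

    transect_id: str
    x_m: float
    y_m: float
    azimuth_deg: float
    length_m: float = 20.0
    count_1h: int = 0
    count_10h: int = 0
    count_100h: int = 0
    len_1h_m: float = 2.0
    len_10h_m: float = 2.0
    len_100h_m: float = 4.0
    coarse_intercepts: tuple[CoarseIntercept, ...] = ()
    litter_cm: float = 0.0
    duff_cm: float = 0.0

    def endpoint(self) -> tuple[float, float]:
        """Far end of the line; azimuth measured clockwise from north."""
        az = math.radians(self.azimuth_deg)
        return (
            self.x_m + self.length_m * math.sin(az),
            self.y_m + self.length_m * math.cos(az),
        )


@dataclass
class StandDataset:
    """All census layers for one plot."""

    geometry: PlotGeometry
    stems: list[StemRecord] = field(default_factory=list)
    snags: list[SnagRecord] = field(default_factory=list)
    shrub_patches: list[ShrubPatch] = field(default_factory=list)
    demography: list[ShrubDemographyPlot] = field(default_factory=list)
    transects: list[FuelTransect] = field(default_factory=list)

    @property
    def live_stems(self) -> list[StemRecord]:
        return [s for s in self.stems if s.status == "live"]

    def shrub_cover_m2(self) -> float:
        return sum(p.area_m2 for p in self.shrub_patches)

    def shrub_cover_fraction(self) -> float:
        return self.shrub_cover_m2() / self.geometry.area_m2


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _validate_stem(rec: StemRecord, geom: PlotGeometry, line: int | None = None) -> None:
    where = f" (line {line})" if line is not None else ""
    if rec.status not in ("live", "dead"):
        raise StandValidationError(f"stem {rec.tag}{where}: status must be live|dead")
    if rec.status == "live" and rec.dbh_cm < 1.0:
        raise StandValidationError(f"stem {rec.tag}{where}: live stem dbh {rec.dbh_cm} < 1 cm")
    if not geom.contains(rec.x_m, rec.y_m):
        raise StandValidationError(
            f"stem {rec.tag}{where}: coordinates ({rec.x_m}, {rec.y_m}) outside plot"
        )


def _validate_snag(rec: SnagRecord, geom: PlotGeometry, line: int | None = None) -> None:
    where = f" (line {line})" if line is not None else ""
    if rec.dbh_cm < 10.0:
        raise StandValidationError(f"snag {rec.tag}{where}: dbh {rec.dbh_cm} < 10 cm")
    if rec.height_m < 1.8:
        raise StandValidationError(f"snag {rec.tag}{where}: height {rec.height_m} < 1.8 m")
    if not 1 <= rec.decay_class <= 5:
        raise StandValidationError(f"snag {rec.tag}{where}: decay class {rec.decay_class}")
    if rec.top_diameter_cm > rec.dbh_cm:
        raise StandValidationError(f"snag {rec.tag}{where}: top diameter exceeds dbh")
    if not geom.contains(rec.x_m, rec.y_m):
        raise StandValidationError(f"snag {rec.tag}{where}: coordinates outside plot")


def _validate_patch(patch: ShrubPatch, line: int | None = None) -> None:
    where = f" (feature {line})" if line is not None else ""
    if patch.area_m2 < 2.0:
        raise StandValidationError(f"patch {patch.patch_id}{where}: area {patch.area_m2} < 2 m2")
    poly = patch.shapely()
    if not poly.is_valid:
        raise StandValidationError(f"patch {patch.patch_id}{where}: polygon self-intersects")
    if abs(poly.area - patch.area_m2) > 0.01 * patch.area_m2:
        raise StandValidationError(
            f"patch {patch.patch_id}{where}: stored area {patch.area_m2:.3f} differs from "
            f"polygon area {poly.area:.3f} by more than 1%"
        )


def validate_stand(stand: StandDataset) -> None:
    """Check every layer invariant; raise ``StandValidationError`` on the first breach."""
    geom = stand.geometry
    tags = [s.tag for s in stand.stems]
    if len(set(tags)) != len(tags):
        dup = sorted({t for t in tags if tags.count(t) > 1})[:5]
        raise StandValidationError(f"duplicate stem tags: {dup}")
    for rec in stand.stems:
        _validate_stem(rec, geom)
    for rec in stand.snags:
        _validate_snag(rec, geom)
    for patch in stand.shrub_patches:
        _validate_patch(patch)
    for dem in stand.demography:
        if dem.stems_per_m2 < 0 or dem.biomass_kg_per_m2 < 0:
            raise StandValidationError(f"demography {dem.species}: negative density")
    for tr in stand.transects:
        if min(tr.count_1h, tr.count_10h, tr.count_100h) < 0:
            raise StandValidationError(f"transect {tr.transect_id}: negative tally")
        if tr.litter_cm < 0 or tr.duff_cm < 0:
            raise StandValidationError(f"transect {tr.transect_id}: negative depth")
        if max(tr.len_1h_m, tr.len_10h_m, tr.len_100h_m) > tr.length_m:
            raise StandValidationError(f"transect {tr.transect_id}: sub-length exceeds line")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    # repr gives the shortest decimal string that round-trips the float
    # exactly, so write -> read is lossless and byte-stable.
    return repr(float(v))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")


def _read_stems(path: Path, geom: PlotGeometry) -> list[StemRecord]:
    df = pd.read_csv(path, dtype={"tag": str, "species": str, "status": str},
                     float_precision="round_trip")
    _require_columns(df, STEM_COLUMNS, path)
    out: list[StemRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = StemRecord(
            tag=str(row.tag), species=str(row.species), dbh_cm=float(row.dbh_cm),
            x_m=float(row.x_m), y_m=float(row.y_m), status=str(row.status),
        )
        _validate_stem(rec, geom, line=i + 2)  # +2: header is line 1
        out.append(rec)
    tags = [s.tag for s in out]
    if len(set(tags)) != len(tags):
        raise StandValidationError(f"{path.name}: duplicate tags present")
    return out


def _read_snags(path: Path, geom: PlotGeometry) -> list[SnagRecord]:
    df = pd.read_csv(path, dtype={"tag": str, "species": str},
                     float_precision="round_trip")
    _require_columns(df, SNAG_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = SnagRecord(
            tag=str(row.tag), species=str(row.species), dbh_cm=float(row.dbh_cm),
            height_m=float(row.height_m), top_diameter_cm=float(row.top_diameter_cm),
            decay_class=int(row.decay_class), x_m=float(row.x_m), y_m=float(row.y_m),
        )
        _validate_snag(rec, geom, line=i + 2)
        out.append(rec)
    return out


def _read_demography(path: Path) -> list[ShrubDemographyPlot]:
    df = pd.read_csv(path, dtype={"species": str}, float_precision="round_trip")
    _require_columns(df, DEMOGRAPHY_COLUMNS, path)
    return [
        ShrubDemographyPlot(
            species=str(r.species), plot_area_m2=float(r.plot_area_m2),
            stems_per_m2=float(r.stems_per_m2),
            biomass_kg_per_m2=float(r.biomass_kg_per_m2),
        )
        for r in df.itertuples(index=False)
    ]


def _encode_intercepts(items: Iterable[CoarseIntercept]) -> str:
    # compact semicolon list: "d:decay:species;..."
    return ";".join(f"{_fmt(ci.diameter_cm)}:{ci.decay_class}:{ci.species}" for ci in items)


def _decode_intercepts(cell: str) -> tuple[CoarseIntercept, ...]:
    cell = "" if cell is None else str(cell).strip()
    if not cell or cell == "nan":
        return ()
    out = []
    for item in cell.split(";"):
        d, decay, sp = item.split(":")
        out.append(CoarseIntercept(diameter_cm=float(d), decay_class=int(decay), species=sp))
    return tuple(out)


def _read_transects(path: Path) -> list[FuelTransect]:
    df = pd.read_csv(path, dtype={"transect_id": str, "coarse_intercepts": str},
                     keep_default_na=False, float_precision="round_trip")
    _require_columns(df, TRANSECT_COLUMNS, path)
    out = []
    for r in df.itertuples(index=False):
        out.append(FuelTransect(
            transect_id=str(r.transect_id), x_m=float(r.x_m), y_m=float(r.y_m),
            azimuth_deg=float(r.azimuth_deg), length_m=float(r.length_m),
            count_1h=int(r.count_1h), count_10h=int(r.count_10h), count_100h=int(r.count_100h),
            len_1h_m=float(r.len_1h_m), len_10h_m=float(r.len_10h_m), len_100h_m=float(r.len_100h_m),
            coarse_intercepts=_decode_intercepts(r.coarse_intercepts),
            litter_cm=float(r.litter_cm), duff_cm=float(r.duff_cm),
        ))
    return out


def _read_patches(path: Path) -> list[ShrubPatch]:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path.name}: expected a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {})
        poly = shape(feat["geometry"])
        patch = ShrubPatch(
            patch_id=str(props["patch_id"]), species=str(props["species"]),
            polygon=tuple((float(x), float(y)) for x, y in poly.exterior.coords[:-1]),
            area_m2=float(props["area_m2"]),
            avg_height_m=float(props.get("avg_height_m", 0.0)),
            max_height_m=float(props.get("max_height_m", 0.0)),
        )
        _validate_patch(patch, line=i)
        out.append(patch)
    return out


def read_stand(directory: str | Path) -> StandDataset:
    """Read a full stand from its layer files in ``directory``.

    Expected files: ``geometry.json``, ``stems.csv``, ``snags.csv``,
    ``demography.csv``, ``transects.csv``, ``shrub_patches.geojson``.
    Missing optional layers (everything but geometry) yield empty lists.
    """
    directory = Path(directory)
    geom_path = directory / "geometry.json"
    if not geom_path.exists():
        raise FileNotFoundError(f"missing {geom_path}")
    with open(geom_path, encoding="utf-8") as fh:
        g = json.load(fh)
    geom = PlotGeometry(
        width_m=float(g["width_m"]), height_m=float(g["height_m"]),
        quadrat_m=float(g.get("quadrat_m", 20.0)),
    )
    stand = StandDataset(geometry=geom)
    if (directory / "stems.csv").exists():
        stand.stems = _read_stems(directory / "stems.csv", geom)
    if (directory / "snags.csv").exists():
        stand.snags = _read_snags(directory / "snags.csv", geom)
    if (directory / "demography.csv").exists():
        stand.demography = _read_demography(directory / "demography.csv")
    if (directory / "transects.csv").exists():
        stand.transects = _read_transects(directory / "transects.csv")
    if (directory / "shrub_patches.geojson").exists():
        stand.shrub_patches = _read_patches(directory / "shrub_patches.geojson")
    return stand


def write_stand(stand: StandDataset, directory: str | Path) -> None:
    """Write all layers; output is byte-stable for a fixed record order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geom = stand.geometry
    with open(directory / "geometry.json", "w", encoding="utf-8") as fh:
        json.dump({"width_m": geom.width_m, "height_m": geom.height_m,
                   "quadrat_m": geom.quadrat_m}, fh, sort_keys=True)
        fh.write("\n")

    with open(directory / "stems.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(STEM_COLUMNS) + "\n")
        for s in stand.stems:
            fh.write(f"{s.tag},{s.species},{_fmt(s.dbh_cm)},{_fmt(s.x_m)},{_fmt(s.y_m)},{s.status}\n")

    with open(directory / "snags.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(SNAG_COLUMNS) + "\n")
        for s in stand.snags:
            fh.write(
                f"{s.tag},{s.species},{_fmt(s.dbh_cm)},{_fmt(s.height_m)},"
                f"{_fmt(s.top_diameter_cm)},{s.decay_class},{_fmt(s.x_m)},{_fmt(s.y_m)}\n"
            )

    with open(directory / "demography.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(DEMOGRAPHY_COLUMNS) + "\n")
        for d in stand.demography:
            fh.write(
                f"{d.species},{_fmt(d.plot_area_m2)},{_fmt(d.stems_per_m2)},"
                f"{_fmt(d.biomass_kg_per_m2)}\n"
            )

    with open(directory / "transects.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRANSECT_COLUMNS) + "\n")
        for t in stand.transects:
            fh.write(
                f"{t.transect_id},{_fmt(t.x_m)},{_fmt(t.y_m)},{_fmt(t.azimuth_deg)},"
                f"{_fmt(t.length_m)},{t.count_1h},{t.count_10h},{t.count_100h},"
                f"{_fmt(t.len_1h_m)},{_fmt(t.len_10h_m)},{_fmt(t.len_100h_m)},"
                f"{_fmt(t.litter_cm)},{_fmt(t.duff_cm)},{_encode_intercepts(t.coarse_intercepts)}\n"
            )

    features = []
    for p in stand.shrub_patches:
        features.append({
            "type": "Feature",
            "geometry": mapping(p.shapely()),
            "properties": {
                "patch_id": p.patch_id, "species": p.species,
                "area_m2": p.area_m2,
                "avg_height_m": p.avg_height_m,
                "max_height_m": p.max_height_m,
            },
        })
    with open(directory / "shrub_patches.geojson", "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Plot bookkeeping
# ---------------------------------------------------------------------------

def basal_area_m2(dbh_cm: float) -> float:
    """Cross-sectional stem area at breast height, m² (π·(dbh/200)²)."""
    return math.pi * (dbh_cm / 200.0) ** 2


def classify_diameter(
    stems: Sequence[StemRecord], threshold_cm: float = 100.0
) -> dict[str, list[StemRecord]]:
    """Partition stems into large (dbh ≥ threshold) and small (dbh < threshold).

    The 100 cm default is the conventional large-diameter cutoff for
    Pacific-slope old-growth conifer forests.  The partition is exhaustive
    and disjoint; the threshold itself is inclusive on the large side.
    """
    if threshold_cm < 0:
        raise ValueError(f"threshold_cm must be non-negative, got {threshold_cm}")
    large = [s for s in stems if s.dbh_cm >= threshold_cm]
    small = [s for s in stems if s.dbh_cm < threshold_cm]
    return {"large": large, "small": small}


def quadratize(
    stand: StandDataset,
    biomass_by_tag: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-quadrat stem count, basal area, and (optionally) biomass.

    Each live stem is assigned to exactly one quadrat via half-open
    intervals; stems exactly on the far boundary fall into the last quadrat.
    Returns one row per quadrat (including empty ones), indexed by
    ``(qx, qy)``, with columns ``stem_count``, ``basal_area_m2`` and, when a
    ``biomass_by_tag`` map is supplied, ``biomass_kg``.
    """
    geom = stand.geometry
    nx, ny = geom.n_quadrats
    idx = pd.MultiIndex.from_product([range(nx), range(ny)], names=["qx", "qy"])
    counts = pd.Series(0, index=idx, dtype=int)
    ba = pd.Series(0.0, index=idx)
    bm = pd.Series(0.0, index=idx)
    for s in stand.live_stems:
        q = geom.quadrat_of(s.x_m, s.y_m)
        counts[q] += 1
        ba[q] += basal_area_m2(s.dbh_cm)
        if biomass_by_tag is not None:
            bm[q] += biomass_by_tag.get(s.tag, 0.0)
    out = pd.DataFrame({"stem_count": counts, "basal_area_m2": ba})
    if biomass_by_tag is not None:
        out["biomass_kg"] = bm
    return out
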