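"""Haplogroup geography: ranges, centers of gravity and the
longitude-gradient concordance test.

A serial-founder dispersal along a route predicts that clade coalescence
ages decrease with distance from the origin.  The route model here is the
one-dimensional version used for the out-of-Africa question: a straight
line in (longitude, age) between a western anchor (macrohaplogroup L3 at
the Djibouti longitude) and an eastern anchor (haplogroup S at the Darwin
longitude), with the anchors' 95% CIs interpolated into a confidence
band.  Each haplogroup, placed at the longitude of its geographic center
of gravity, is *concordant* when its observed age CI overlaps the model
band at that longitude and *discordant* otherwise; the Kendall-style
score is tau = (concordant - discordant) / tested.  A parametric Pearson
correlation between longitude and observed point ages is reported
alongside.

The center of gravity of a haplogroup's presence/absence range is the
crossing of the segment joining its extreme-latitude points with the
segment joining its extreme-longitude points, falling back to the
bounding-box center when the segments do not cross.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point

from .errors import ContractViolation, SchemaError, ValidationError
from .seqio import GeoPoint, parse_coordinates

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeoRange:
    """Presence/absence range of a haplogroup with its center of gravity."""

    haplogroup: str
    points: tuple[GeoPoint, ...]
    center: GeoPoint

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError(f"{self.haplogroup}: empty range cannot carry a center")


@dataclass(frozen=True)
class Anchor:
    """One end of the route model: a clade age pinned at a longitude."""

    name: str
    longitude: float
    age: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"anchor {self.name}: age must be positive")
        lo, hi = self.ci95
        if not lo <= self.age <= hi:
            raise ValidationError(f"anchor {self.name}: CI must contain the age")


@dataclass(frozen=True)
class RouteModel:
    """Linear longitude-to-age interpolation between two anchors."""

    anchor_west: Anchor
    anchor_east: Anchor

    def __post_init__(self) -> None:
        if not self.anchor_west.longitude < self.anchor_east.longitude:
            raise ValidationError("western anchor must lie west of the eastern anchor")


@dataclass(frozen=True)
class AgeBand:
    """Interpolated model age with its CI band at one longitude."""

    age: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class RouteObservation:
    """One tested haplogroup: its center longitude and observed age."""

    haplogroup: str
    longitude: float
    age: float
    ci95: tuple[float, float] | None = None
    place: str = ""
    latitude: float | None = None


@dataclass(frozen=True)
class ConcordanceResult:
    n_concordant: int
    n_discordant: int
    tau: float
    pearson_r: float
    pearson_p: float

    def __post_init__(self) -> None:
        total = self.n_concordant + self.n_discordant
        if total and abs(self.tau - (self.n_concordant - self.n_discordant) / total) > 1e-9:
            raise ValidationError("tau inconsistent with concordant/discordant counts")


def center_of_gravity(points: Sequence[GeoPoint]) -> GeoPoint:
    """Crossing of the extreme-latitude and extreme-longitude segments.

    Falls back to the bounding-box center (logged) when the two segments
    do not intersect; a degenerate intersection segment yields its
    midpoint.
    """
    if not points:
        raise ContractViolation("center_of_gravity needs at least one point")
    pts = list(points)
    if len(pts) == 1:
        return pts[0]
    lat_sorted = sorted(pts, key=lambda p: (p.latitude, p.longitude))
    lon_sorted = sorted(pts, key=lambda p: (p.longitude, p.latitude))
    lat_lo, lat_hi = lat_sorted[0], lat_sorted[-1]
    lon_lo, lon_hi = lon_sorted[0], lon_sorted[-1]
    bbox_center = GeoPoint(
        (lat_lo.latitude + lat_hi.latitude) / 2.0,
        (lon_lo.longitude + lon_hi.longitude) / 2.0,
    )
    seg_lat = LineString(
        [(lat_lo.longitude, lat_lo.latitude), (lat_hi.longitude, lat_hi.latitude)]
    )
    seg_lon = LineString(
        [(lon_lo.longitude, lon_lo.latitude), (lon_hi.longitude, lon_hi.latitude)]
    )
    if seg_lat.length == 0 or seg_lon.length == 0:
        return bbox_center
    inter = seg_lat.intersection(seg_lon)
    if inter.is_empty:
        logger.info("extreme segments do not cross; using bounding-box center")
        return bbox_center
    if isinstance(inter, Point):
        return GeoPoint(inter.y, inter.x)
    centroid = inter.centroid
    return GeoPoint(centroid.y, centroid.x)


def compute_range(haplogroup: str, points: Sequence[GeoPoint]) -> GeoRange:
    return GeoRange(haplogroup, tuple(points), center_of_gravity(points))


def expected_age(lon: float, model: RouteModel) -> AgeBand:
    """Linear interpolation of the route model at *lon*.

    Outside the anchor span the line is extrapolated with a warning; the
    CI band is interpolated from the anchor CI bounds the same way.
    """
    west, east = model.anchor_west, model.anchor_east
    if not west.longitude <= lon <= east.longitude:
        logger.warning(
            "longitude %.2f outside anchor span [%.2f, %.2f]; extrapolating",
            lon,
            west.longitude,
            east.longitude,
        )
    frac = (lon - west.longitude) / (east.longitude - west.longitude)
    age = west.age + frac * (east.age - west.age)
    lo = west.ci95[0] + frac * (east.ci95[0] - west.ci95[0])
    hi = west.ci95[1] + frac * (east.ci95[1] - west.ci95[1])
    return AgeBand(age=age, ci95=(min(lo, hi), max(lo, hi)))


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def concordance_test(
    observed: Sequence[RouteObservation], model: RouteModel
) -> ConcordanceResult:
    """CI-overlap concordance plus Pearson correlation along the route.

    A haplogroup is concordant when its observed 95% CI and the model
    band at its longitude overlap (closed intervals; zero-width CIs
    allowed).  Rows without a CI are skipped with a log notice.  Pearson
    r/p relate longitude to the observed point ages of the tested rows.
    """
    usable = []
    for obs in observed:
        if obs.ci95 is None:
            logger.info("skipping %s: no CI", obs.haplogroup)
            continue
        usable.append(obs)
    if len(usable) < 2:
        raise ContractViolation("need at least two haplogroups with CIs")
    n_con = n_dis = 0
    for obs in usable:
        band = expected_age(obs.longitude, model)
        lo, hi = min(obs.ci95), max(obs.ci95)
        if _intervals_overlap((lo, hi), band.ci95):
            n_con += 1
        else:
            n_dis += 1
    lons = np.array([o.longitude for o in usable])
    ages = np.array([o.age for o in usable])
    if np.ptp(ages) == 0 or np.ptp(lons) == 0:
        r, p = float("nan"), float("nan")  # correlation undefined on constant input
    else:
        r, p = stats.pearsonr(lons, ages)
    tau = (n_con - n_dis) / (n_con + n_dis)
    return ConcordanceResult(
        n_concordant=n_con,
        n_discordant=n_dis,
        tau=tau,
        pearson_r=float(r),
        pearson_p=float(p),
    )


# ---------------------------------------------------------------------------
# route tables and exports

ROUTE_COLUMNS = (
    "haplogroup",
    "place",
    "coordinates",
    "observed_age_ky",
    "observed_lo_ky",
    "observed_hi_ky",
)


def read_route_table(path: str | Path) -> list[RouteObservation]:
    """Read a route table TSV (columns as ROUTE_COLUMNS).

    Coordinates are degree-minute pair strings; CI bounds are normalised
    to (lo, hi) regardless of printed order.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ROUTE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        point = parse_coordinates(rec.coordinates)
        lo, hi = float(rec.observed_lo_ky), float(rec.observed_hi_ky)
        rows.append(
            RouteObservation(
                haplogroup=rec.haplogroup,
                longitude=point.longitude,
                latitude=point.latitude,
                age=float(rec.observed_age_ky),
                ci95=(min(lo, hi), max(lo, hi)),
                place=rec.place,
            )
        )
    return rows


def packaged_route_table(route: str) -> list[RouteObservation]:
    """The published southern/northern route tables shipped as fixtures."""
    if route not in ("southern", "northern"):
        raise ValidationError(f"unknown route {route!r}")
    source = resources.files("mtroute.data") / f"route_{route}.tsv"
    with resources.as_file(source) as p:
        return read_route_table(p)


def route_model_from_observations(
    observed: Sequence[RouteObservation], west: str = "L3", east: str = "S"
) -> RouteModel:
    """Build the anchor model from the named rows of a route table."""
    by_name = {o.haplogroup: o for o in observed}
    for name in (west, east):
        if name not in by_name or by_name[name].ci95 is None:
            raise ValidationError(f"route table lacks an anchor row {name!r} with a CI")
    w, e = by_name[west], by_name[east]
    return RouteModel(
        anchor_west=Anchor(w.haplogroup, w.longitude, w.age, w.ci95),
        anchor_east=Anchor(e.haplogroup, e.longitude, e.age, e.ci95),
    )


def ranges_to_geojson(ranges: Sequence[GeoRange]) -> dict:
    """GeoJSON FeatureCollection: one MultiPoint + center Point per range."""
    features = []
    for rng in ranges:
        features.append(
            {
                "type": "Feature",
                "properties": {"haplogroup": rng.haplogroup, "role": "range"},
                "geometry": {
                    "type": "MultiPoint",
                    "coordinates": [[p.longitude, p.latitude] for p in rng.points],
                },
            }
        )
        features.append(
            {
                "type": "Feature",
                "properties": {"haplogroup": rng.haplogroup, "role": "center"},
                "geometry": {
                    "type": "Point",
                    "coordinates": [rng.center.longitude, rng.center.latitude],
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
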