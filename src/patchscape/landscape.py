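"""Landscape-configuration metrics for fragmented habitat-patch networks.

Implements the spatial/temporal predictors of the analysis:

* patch isolation ``I_j = -log( sum_k A_k / d_jk^2 )`` over neighbours within
  a fixed radius (default 0.5 km), ``d_jk`` the edge-to-edge distance —
  higher values mean more isolated patches surrounded by smaller habitat;
* historical patch area ``A_era``: the fraction of a patch's present-day
  footprint covered by potential grassland habitat (PGH) on an era map;
* patch age from era-presence flags, with first appearance dated to the
  midpoint between consecutive maps;
* abiotic plausibility filtering of PGH units against the envelope of the
  old patches' abiotic variables (range limit ± SE);
* the topographic wetness index TWI = ln(As / tan b).

Geometries are either :class:`Disc` (centre + radius, the synthetic
first-class geometry) or any shapely geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .datatypes import ABIOTIC_VARS, ERA_YEARS, PatchTable, ValidationError

__all__ = [
    "Disc",
    "HabitatSnapshot",
    "Neighbor",
    "edge_distance",
    "neighbor_list",
    "isolation_index",
    "historical_area_fraction",
    "assign_patch_age",
    "filter_pgh_by_abiotic",
    "abiotic_reference_ranges",
    "twi",
    "derive_landscape_metrics",
]

RADIUS_M = 500.0  # neighbourhood radius for the isolation index


@dataclass(frozen=True)
class Disc:
    """A circular habitat footprint: centre (x, y) in planar metres, radius."""

    x: float
    y: float
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("disc radius must be positive")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def to_shapely(self):
        return Point(self.x, self.y).buffer(self.radius, quad_segs=64)


@dataclass
class HabitatSnapshot:
    """The habitat units visible on one era map.

    ``units`` is a DataFrame indexed by unit id with columns ``x``, ``y``,
    ``radius_m`` (disc geometry), ``area_m2`` and the abiotic variables.
    """

    era: object  # year or "survey"
    units: pd.DataFrame

    def __post_init__(self):
        if len(self.units) and (self.units["area_m2"] <= 0).any():
            raise ValidationError("snapshot unit areas must be positive")

    def disc(self, unit_id) -> Disc:
        row = self.units.loc[unit_id]
        return Disc(row["x"], row["y"], row["radius_m"])


@dataclass(frozen=True)
class Neighbor:
    id: object
    area_m2: float
    distance_m: float


def _is_disc(geom) -> bool:
    return isinstance(geom, Disc)


def edge_distance(geom_a, geom_b) -> float:
    """Minimum boundary-to-boundary distance in metres; 0 when touching or
    overlapping.  Accepts :class:`Disc` or shapely geometries."""
    for g in (geom_a, geom_b):
        if not _is_disc(g) and (not hasattr(g, "area") or g.area <= 0):
            raise ValidationError("degenerate (zero-area) geometry")
    if _is_disc(geom_a) and _is_disc(geom_b):
        centre_d = math.hypot(geom_a.x - geom_b.x, geom_a.y - geom_b.y)
        return max(0.0, centre_d - geom_a.radius - geom_b.radius)
    a = geom_a.to_shapely() if _is_disc(geom_a) else geom_a
    b = geom_b.to_shapely() if _is_disc(geom_b) else geom_b
    return float(a.distance(b))


def neighbor_list(
    focal_id,
    focal_geom,
    units: Iterable[tuple],
    radius_m: float = RADIUS_M,
) -> list:
    """Neighbours of a focal patch within ``radius_m`` edge-to-edge.

    ``units`` yields ``(id, geometry, area_m2)``; the focal patch itself
    (same id) is excluded.
    """
    out = []
    for uid, geom, area in units:
        if uid == focal_id:
            continue
        d = edge_distance(focal_geom, geom)
        if d <= radius_m:
            out.append(Neighbor(uid, float(area), float(d)))
    return out


def isolation_index(
    neighbors: Sequence[Neighbor],
    log_base: float = 10.0,
    epsilon_m: float = 1.0,
    empty_policy: float = math.nan,
) -> float:
    """Isolation of a patch from the areas and distances of its neighbours.

    ``I = -log_b( sum_k A_k / d_k^2 )``.  Touching neighbours (d = 0) have
    their distance replaced by ``epsilon_m``; an empty neighbourhood returns
    ``empty_policy`` (NaN sentinel by default, or a configured ceiling).
    """
    if not neighbors:
        return empty_policy
    total = 0.0
    for nb in neighbors:
        if nb.distance_m < 0:
            raise ValidationError("negative neighbour distance")
        d = nb.distance_m if nb.distance_m > 0 else epsilon_m
        total += nb.area_m2 / d**2
    return -math.log(total) / math.log(log_base)


def historical_area_fraction(
    patch_geom,
    snapshot: HabitatSnapshot,
    cell_m: float = 1.0,
) -> float:
    """Fraction of a patch footprint covered by the union of snapshot units.

    Evaluated on a regular grid of ``cell_m``-sized cells over the patch
    (converging to the exact overlap as the cell size shrinks), with exact
    shortcuts when no unit intersects the patch or one unit covers it fully.
    """
    if cell_m <= 0:
        raise ValidationError("grid cell size must be positive")
    units = snapshot.units
    if len(units) == 0:
        return 0.0
    if _is_disc(patch_geom):
        px, py, pr = patch_geom.x, patch_geom.y, patch_geom.radius
        dx = units["x"].to_numpy() - px
        dy = units["y"].to_numpy() - py
        centre_d = np.hypot(dx, dy)
        rr = units["radius_m"].to_numpy()
        touching = centre_d < rr + pr
        if not touching.any():
            return 0.0
        if (centre_d[touching] + pr <= rr[touching]).any():
            return 1.0  # some unit fully covers the patch
        # grid-sample the disc footprint against the touching discs
        n = max(2, int(math.ceil(2 * pr / cell_m)))
        coords = px - pr + (np.arange(n) + 0.5) * (2 * pr / n)
        gx, gy = np.meshgrid(coords, py - pr + (np.arange(n) + 0.5) * (2 * pr / n))
        gx, gy = gx.ravel(), gy.ravel()
        inside = (gx - px) ** 2 + (gy - py) ** 2 <= pr**2
        gx, gy = gx[inside], gy[inside]
        covered = np.zeros(gx.shape, dtype=bool)
        for _, row in units[touching].iterrows():
            covered |= (gx - row["x"]) ** 2 + (gy - row["y"]) ** 2 <= row[
                "radius_m"
            ] ** 2
            if covered.all():
                break
        return float(covered.mean()) if len(gx) else 0.0
    # shapely polygon: grid-sample its bounding box
    minx, miny, maxx, maxy = patch_geom.bounds
    nx = max(2, int(math.ceil((maxx - minx) / cell_m)))
    ny = max(2, int(math.ceil((maxy - miny) / cell_m)))
    xs = minx + (np.arange(nx) + 0.5) * (maxx - minx) / nx
    ys = miny + (np.arange(ny) + 0.5) * (maxy - miny) / ny
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    inside = shapely.contains(patch_geom, pts)
    if not inside.any():
        return 0.0
    union = shapely.unary_union(
        [snapshot.disc(uid).to_shapely() for uid in units.index]
    )
    covered = shapely.contains(union, pts[inside])
    return float(covered.mean())


def assign_patch_age(
    era_presence: Mapping[int, bool],
    survey_year: int = 2009,
    pre_map_anchor: int = 1788,
) -> float:
    """Years of continuous patch existence at the survey date.

    The first map on which the patch appears dates it to the midpoint of the
    interval since the preceding map; a patch already on the oldest map is
    anchored at ``pre_map_anchor``; a patch on no map (it exists only at the
    survey) appeared midway between the newest map and the survey.
    """
    years = sorted(era_presence)
    if not years:
        raise ValidationError("no era presence information")
    present = [y for y in years if era_presence[y]]
    if present:
        first = present[0]
        if first == years[0]:
            appearance = float(pre_map_anchor)
        else:
            prev = years[years.index(first) - 1]
            appearance = (prev + first) / 2.0
    else:
        appearance = (years[-1] + survey_year) / 2.0
    age = survey_year - appearance
    if age <= 0:
        raise ValidationError(
            f"non-positive age {age} (survey {survey_year}, appearance {appearance})"
        )
    return age


def abiotic_reference_ranges(
    patches: PatchTable, variables: Sequence[str] = ABIOTIC_VARS
) -> pd.DataFrame:
    """Per-variable min, max and standard error over (old) patches.

    The SE widens the plausibility envelope used by
    :func:`filter_pgh_by_abiotic`.
    """
    rows = {}
    for var in variables:
        vals = patches.df[var].dropna()
        rows[var] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "se": float(vals.std(ddof=1) / math.sqrt(len(vals))),
        }
    return pd.DataFrame(rows).T


def filter_pgh_by_abiotic(
    snapshot: HabitatSnapshot, reference: pd.DataFrame
) -> tuple:
    """Keep habitat units whose every abiotic value lies in [min-SE, max+SE].

    Units missing an abiotic value are removed.  Returns the filtered
    snapshot plus a per-variable tally of removals (a unit failing several
    variables counts under each).
    """
    units = snapshot.units
    keep = pd.Series(True, index=units.index)
    removed = {var: 0 for var in reference.index}
    removed["missing"] = 0
    for var in reference.index:
        lo = reference.loc[var, "min"] - reference.loc[var, "se"]
        hi = reference.loc[var, "max"] + reference.loc[var, "se"]
        vals = units[var]
        bad = (vals < lo) | (vals > hi)
        removed[var] = int(bad.sum())
        missing = vals.isna()
        removed["missing"] += int((missing & keep).sum())
        keep &= ~bad & ~missing
    return HabitatSnapshot(snapshot.era, units[keep].copy()), removed


def twi(catchment_area: float, slope_deg: float) -> float:
    """Topographic wetness index ln(As / tan b) for specific catchment area
    ``As`` (m² per unit contour width) and local slope ``b`` in degrees."""
    if catchment_area <= 0:
        raise ValidationError("specific catchment area must be positive")
    if not 0 < slope_deg < 90:
        raise ValidationError("slope must lie strictly between 0 and 90 degrees")
    return math.log(catchment_area / math.tan(math.radians(slope_deg)))


def _patch_discs(patches: PatchTable) -> dict:
    df = patches.df
    if not {"x", "y"}.issubset(df.columns):
        raise ValidationError("patch table lacks x/y coordinates for geometry")
    radius = (
        df["radius_m"]
        if "radius_m" in df.columns
        else np.sqrt(df["area_m2"] / math.pi)
    )
    return {
        pid: Disc(df.loc[pid, "x"], df.loc[pid, "y"], float(radius.loc[pid]))
        for pid in df.index
    }


def derive_landscape_metrics(
    patches: PatchTable,
    snapshots: Optional[Mapping[int, HabitatSnapshot]] = None,
    radius_m: float = RADIUS_M,
    log_base: float = 10.0,
    epsilon_m: float = 1.0,
    empty_policy: float = math.nan,
    cell_m: float = 1.0,
    survey_year: int = 2009,
    pre_map_anchor: int = 1788,
    filter_reference: Optional[pd.DataFrame] = None,
    isolation_eras: Sequence[int] = (1843, 1980),
) -> PatchTable:
    """Append the derived landscape columns to a patch table.

    Computes present-day isolation ``I_2000`` from the patch network itself;
    for each requested era, filters the PGH snapshot against
    ``filter_reference`` (defaulting to the old patches' abiotic envelope),
    then computes ``I_<era>`` and the covered-area fraction ``A_<era>``;
    finally assigns ``age`` from the era-presence flags.
    """
    df = patches.df.copy()
    discs = _patch_discs(patches)
    units_now = [(pid, discs[pid], df.loc[pid, "area_m2"]) for pid in df.index]
    df["I_2000"] = [
        isolation_index(
            neighbor_list(pid, discs[pid], units_now, radius_m),
            log_base,
            epsilon_m,
            empty_policy,
        )
        for pid in df.index
    ]
    if snapshots:
        if filter_reference is None:
            old = PatchTable(df[df["age_class"] == "old"])
            filter_reference = abiotic_reference_ranges(old)
        for era in isolation_eras:
            snap, _ = filter_pgh_by_abiotic(snapshots[era], filter_reference)
            units = [
                (uid, snap.disc(uid), snap.units.loc[uid, "area_m2"])
                for uid in snap.units.index
            ]
            df[f"I_{era}"] = [
                isolation_index(
                    neighbor_list(pid, discs[pid], units, radius_m),
                    log_base,
                    epsilon_m,
                    empty_policy,
                )
                for pid in df.index
            ]
            df[f"A_{era}"] = [
                historical_area_fraction(discs[pid], snap, cell_m)
                for pid in df.index
            ]
    pres_cols = [f"present_{y}" for y in ERA_YEARS if f"present_{y}" in df.columns]
    if pres_cols:
        df["age"] = [
            assign_patch_age(patches.era_presence(pid), survey_year, pre_map_anchor)
            for pid in df.index
        ]
    return PatchTable(df)
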