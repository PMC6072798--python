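"""Probability-weighted areas, carbon-stock changes, rates, region summaries.

Because speckle has no spatial pattern, expected class areas are obtained
by summing per-pixel class probabilities, and carbon-stock changes by
weighting the observed per-pixel AGC change with the class probability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .biomass import ChangeDefinition
from .change import CLASSES
from .raster import Raster

__all__ = [
    "LccSummary",
    "weighted_areas",
    "weighted_carbon_changes",
    "annual_rate",
    "summarize_regions",
    "regions_from_geojson",
]

log = logging.getLogger(__name__)

#: The four change classes (all but non-wooded) that carry carbon change.
CHANGE_CLASSES = ("deforested", "degraded", "gain", "minor_loss")


@dataclass
class LccSummary:
    region: str
    analysed_area_ha: float
    wooded_area_ha: float
    class_areas_ha: dict[str, float]
    class_pct_of_wooded: dict[str, float]
    class_carbon_change_mgc: dict[str, float]
    net_carbon_change_mgc: float
    deforestation_rate_pct_yr: float
    years: float

    def to_row(self) -> dict:
        row = {
            "region": self.region,
            "analysed_area_ha": self.analysed_area_ha,
            "wooded_area_ha": self.wooded_area_ha,
            "net_carbon_change_mgc": self.net_carbon_change_mgc,
            "deforestation_rate_pct_yr": self.deforestation_rate_pct_yr,
            "years": self.years,
        }
        for c in CLASSES:
            row[f"area_{c}_ha"] = self.class_areas_ha[c]
        for c in CLASSES:
            row[f"pct_wooded_{c}"] = self.class_pct_of_wooded[c]
        for c in CHANGE_CLASSES:
            row[f"dcarbon_{c}_mgc"] = self.class_carbon_change_mgc[c]
        return row

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _check_probs(prob_grids: dict[str, np.ndarray]) -> None:
    for name, g in prob_grids.items():
        vals = np.asarray(g, dtype=float)
        finite = np.isfinite(vals)
        if np.any((vals[finite] < 0) | (vals[finite] > 1)):
            raise ValueError(f"probabilities outside [0, 1] in grid {name!r}")


def _grid(prob_grids: dict[str, Raster | np.ndarray], name: str) -> np.ndarray:
    g = prob_grids[name]
    return g.data if isinstance(g, Raster) else np.asarray(g, dtype=float)


def weighted_areas(
    prob_grids: dict[str, Raster | np.ndarray],
    pixel_area_ha: float,
    region_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Probability-summed area per class: area_c = sum(p_c) * pixel area."""
    if pixel_area_ha <= 0:
        raise ValueError("pixel area must be positive")
    arrays = {name: _grid(prob_grids, name) for name in prob_grids}
    _check_probs(arrays)
    out = {}
    for name, g in arrays.items():
        sel = np.isfinite(g)
        if region_mask is not None:
            sel &= np.asarray(region_mask, dtype=bool)
        out[name] = float(np.sum(g[sel])) * pixel_area_ha
    return out


def weighted_carbon_changes(
    agc07: Raster | np.ndarray,
    agc10: Raster | np.ndarray,
    prob_grids: dict[str, Raster | np.ndarray],
    pixel_area_ha: float,
    region_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Probability-weighted carbon change per change class (MgC, signed).

    change_c = sum((AGC10 - AGC07) * p_c) * pixel area, for the four change
    classes; the non-wooded state carries no change by definition.
    """
    a07 = agc07.data if isinstance(agc07, Raster) else np.asarray(agc07, dtype=float)
    a10 = agc10.data if isinstance(agc10, Raster) else np.asarray(agc10, dtype=float)
    if a07.shape != a10.shape:
        raise ValueError("AGC maps have mismatched shapes")
    delta = a10 - a07
    out = {}
    for name in CHANGE_CLASSES:
        g = _grid(prob_grids, name)
        if g.shape != a07.shape:
            raise ValueError("probability grid shape mismatch")
        sel = np.isfinite(g) & np.isfinite(delta)
        if region_mask is not None:
            sel &= np.asarray(region_mask, dtype=bool)
        out[name] = float(np.sum(delta[sel] * g[sel])) * pixel_area_ha
    return out


def annual_rate(
    class_area: float, base_area: float, years: float, compound: bool = False
) -> float:
    """Annual change rate in % per year, pro-rata over the period by default."""
    if base_area <= 0:
        raise ValueError("base area must be positive")
    if years <= 0:
        raise ValueError("period length must be positive")
    frac = class_area / base_area
    if compound:
        return float(100.0 * (1.0 - (1.0 - frac) ** (1.0 / years)))
    return float(100.0 * frac / years)


def summarize_region(
    agc07: Raster,
    agc10: Raster,
    prob_grids: dict[str, Raster | np.ndarray],
    region: str = "total",
    region_mask: np.ndarray | None = None,
    years: float = 3.0,
) -> LccSummary:
    """One probability-weighted summary over a (masked) raster extent."""
    pixel_area = agc07.pixel_area_ha
    p_nw = _grid(prob_grids, "nonwooded")
    sel = np.isfinite(p_nw)
    if region_mask is not None:
        sel &= np.asarray(region_mask, dtype=bool)
    analysed = float(sel.sum()) * pixel_area
    if analysed == 0:
        log.warning("region %r contains no analysed pixels", region)
        zero = {c: 0.0 for c in CLASSES}
        return LccSummary(
            region=region,
            analysed_area_ha=0.0,
            wooded_area_ha=0.0,
            class_areas_ha=zero,
            class_pct_of_wooded=dict(zero),
            class_carbon_change_mgc={c: 0.0 for c in CHANGE_CLASSES},
            net_carbon_change_mgc=0.0,
            deforestation_rate_pct_yr=0.0,
            years=years,
        )
    areas = weighted_areas(prob_grids, pixel_area, region_mask=sel)
    wooded = float(np.sum(1.0 - p_nw[sel])) * pixel_area
    changes = weighted_carbon_changes(agc07, agc10, prob_grids, pixel_area, region_mask=sel)
    net = float(sum(changes.values()))
    pct = {c: (100.0 * areas[c] / wooded if wooded > 0 else 0.0) for c in CLASSES}
    rate = annual_rate(areas["deforested"], wooded, years) if wooded > 0 else 0.0
    return LccSummary(
        region=region,
        analysed_area_ha=analysed,
        wooded_area_ha=wooded,
        class_areas_ha=areas,
        class_pct_of_wooded=pct,
        class_carbon_change_mgc=changes,
        net_carbon_change_mgc=net,
        deforestation_rate_pct_yr=rate,
        years=years,
    )


def summarize_regions(
    agc07: Raster,
    agc10: Raster,
    prob_grids: dict[str, Raster | np.ndarray],
    regions: dict[str, np.ndarray] | None = None,
    years: float = 3.0,
) -> pd.DataFrame:
    """Per-region summaries plus a study-wide total, as one DataFrame row each."""
    summaries = [summarize_region(agc07, agc10, prob_grids, "total", None, years)]
    for name, mask in (regions or {}).items():
        summaries.append(summarize_region(agc07, agc10, prob_grids, name, mask, years))
    return pd.DataFrame([s.to_row() for s in summaries])


def regions_from_geojson(path: str, template: Raster, name_property: str = "name") -> dict[str, np.ndarray]:
    """Rasterise named polygons from a GeoJSON file onto a raster grid.

    A pixel belongs to a region if its centre falls inside the polygon.
    """
    from shapely import contains_xy
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    xs, ys = template.pixel_centres()
    out: dict[str, np.ndarray] = {}
    for feat in gj["features"]:
        name = str(feat.get("properties", {}).get(name_property, f"region_{len(out)}"))
        geom = shape(feat["geometry"])
        out[name] = contains_xy(geom, xs, ys)
    return out
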