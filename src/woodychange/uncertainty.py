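"""Uncertainty propagation by repeated 2-fold cross-validation.

The dominant uncertainty in the headline quantities is the
biomass-backscatter relationship (including its bias).  It is propagated
by refitting the regression many times on random halves of the
calibration plots, re-running the change pipeline for each replicate over
a spatial subsample of tiles, and taking empirical percentiles of the
replicate estimates as confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import CHANGE_CLASSES, summarize_region
from .biomass import BiomassModel, ChangeDefinition, fit_biomass_model, predict_agc
from .change import CLASSES, build_lookup_table, classify_rasters
from .raster import Raster
from .speckle import SpeckleModel

__all__ = [
    "UncertaintyConfig",
    "cv_replicate_models",
    "sample_tiles",
    "propagate_to_summaries",
]

log = logging.getLogger(__name__)


@dataclass
class UncertaintyConfig:
    """Replication settings.  Defaults are desk-scale; production runs used
    thousands of replicates over thousands of tiles."""

    n_replicates: int = 200
    n_tiles: int = 20
    tile_pixels: int = 40          # tile edge length in pixels
    percentiles: tuple[float, float] = (2.5, 97.5)
    lut_n_outer: int = 1000
    lut_n_inner: int = 20
    lut_bin_width: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        lo, hi = self.percentiles
        if not 0 < lo < hi < 100:
            raise ValueError("percentiles must satisfy 0 < lower < upper < 100")


def cv_replicate_models(
    plots: pd.DataFrame,
    n_replicates: int = 200,
    seed: int = 0,
    max_redraws: int = 100,
) -> list[BiomassModel]:
    """Refit the biomass regression on random half-splits of the plots.

    Each replicate fits on one half and records the signed mean prediction
    error on the withheld half as its bias.  Degenerate halves (no
    backscatter variance) are redrawn and counted.
    """
    if len(plots) < 6:
        raise ValueError("need at least 6 plots for 2-fold replication")
    rng = np.random.default_rng(seed)
    n = len(plots)
    half = n // 2
    models: list[BiomassModel] = []
    redraws = 0
    while len(models) < n_replicates:
        perm = rng.permutation(n)
        train = plots.iloc[perm[:half]]
        test = plots.iloc[perm[half:]]
        if np.ptp(train["gamma0_linear"].to_numpy()) == 0:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("too many degenerate half-splits")
            continue
        m = fit_biomass_model(train)
        pred = m.slope * test["gamma0_linear"].to_numpy() + m.intercept
        m.bias = float(np.mean(pred - test["agc_mgc_ha"].to_numpy()))
        models.append(m)
    if redraws:
        log.info("cv_replicate_models: %d degenerate half-splits redrawn", redraws)
    return models


def sample_tiles(
    shape: tuple[int, int], n_tiles: int, tile_pixels: int, seed: int = 0
) -> list[tuple[slice, slice]]:
    """Random non-aligned square tiles inside a raster extent."""
    nrows, ncols = shape
    if tile_pixels > min(nrows, ncols):
        raise ValueError("tile larger than raster")
    rng = np.random.default_rng(seed)
    tiles = []
    for _ in range(n_tiles):
        r = int(rng.integers(0, nrows - tile_pixels + 1))
        c = int(rng.integers(0, ncols - tile_pixels + 1))
        tiles.append((slice(r, r + tile_pixels), slice(c, c + tile_pixels)))
    return tiles


def _tile_quantities(
    img07: Raster,
    img10: Raster,
    model: BiomassModel,
    sm: SpeckleModel,
    defn: ChangeDefinition,
    tiles: list[tuple[slice, slice]],
    cfg: UncertaintyConfig,
    years: float,
) -> dict[str, float]:
    """Summary quantities for one biomass model, summed over the tile set."""
    sub07 = np.concatenate([img07.data[t].ravel() for t in tiles])
    sub10 = np.concatenate([img10.data[t].ravel() for t in tiles])
    stacked07 = Raster(sub07.reshape(1, -1), pixel_size=img07.pixel_size, year=img07.year)
    stacked10 = Raster(sub10.reshape(1, -1), pixel_size=img10.pixel_size, year=img10.year)

    finite = np.concatenate([sub07, sub10])
    finite = finite[np.isfinite(finite)]
    hi = float(finite.max()) if finite.size else 0.12
    table = build_lookup_table(
        model,
        sm,
        defn,
        gamma_range=(0.0, hi + cfg.lut_bin_width),
        bin_width=cfg.lut_bin_width,
        n_outer=cfg.lut_n_outer,
        n_inner=cfg.lut_n_inner,
        seed=cfg.seed,
    )
    probs = classify_rasters(stacked07, stacked10, table)
    agc07 = predict_agc(stacked07, model)
    agc10 = predict_agc(stacked10, model)
    s = summarize_region(agc07, agc10, probs, years=years)
    out = {
        "wooded_area_ha": s.wooded_area_ha,
        "deforestation_rate_pct_yr": s.deforestation_rate_pct_yr,
        "net_carbon_change_mgc": s.net_carbon_change_mgc,
    }
    for c in CLASSES:
        out[f"area_{c}_ha"] = s.class_areas_ha[c]
    for c in CHANGE_CLASSES:
        out[f"dcarbon_{c}_mgc"] = s.class_carbon_change_mgc[c]
    return out


def propagate_to_summaries(
    replicate_models: list[BiomassModel],
    img07: Raster,
    img10: Raster,
    sm: SpeckleModel,
    defn: ChangeDefinition = ChangeDefinition(),
    cfg: UncertaintyConfig = UncertaintyConfig(),
    point_model: BiomassModel | None = None,
    years: float = 3.0,
) -> pd.DataFrame:
    """Empirical percentile CIs for the headline quantities over a tile subsample.

    Each replicate model re-runs biomass prediction, lookup-table
    construction and aggregation on the same tiles; the returned frame has
    one row per quantity with the point estimate (from ``point_model`` or
    the published model) and the lower/upper percentiles, widened if
    necessary so the point estimate always lies inside its interval.
    """
    tiles = sample_tiles(img07.shape, cfg.n_tiles, cfg.tile_pixels, seed=cfg.seed)
    point_model = point_model or BiomassModel.published()
    point = _tile_quantities(img07, img10, point_model, sm, defn, tiles, cfg, years)

    rows = []
    for m in replicate_models:
        rows.append(_tile_quantities(img07, img10, m, sm, defn, tiles, cfg, years))
    reps = pd.DataFrame(rows)

    lo_p, hi_p = cfg.percentiles
    records = []
    for q in reps.columns:
        lo = float(np.percentile(reps[q], lo_p))
        hi = float(np.percentile(reps[q], hi_p))
        pt = point[q]
        records.append(
            {"quantity": q, "point": pt, "lo": min(lo, pt), "hi": max(hi, pt), "n_replicates": len(reps)}
        )
    return pd.DataFrame(records)
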