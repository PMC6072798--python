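"""Soil-moisture correction and moisture-difference masking.

L-band backscatter rises on wet soil, most strongly where the canopy is
sparse (Water Cloud logic: canopy water attenuates the soil term).  The
correction here is a deliberately minimal, configurable stand-in: a
tabulated, non-increasing correction strength as a function of AGC,
multiplied by an externally supplied moisture-difference proxy and
subtracted from the later-date backscatter.  It defaults to disabled so
headline results never depend silently on its parameters.  Pixels whose
moisture proxy changed markedly between dates are masked out instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raster import Raster

__all__ = ["MoistureCorrection", "correct_backscatter_change", "moisture_difference_mask"]

log = logging.getLogger(__name__)


@dataclass
class MoistureCorrection:
    """Strength table: linear-gamma0 correction per unit moisture difference,
    non-increasing in AGC.  ``cap`` bounds the absolute adjustment."""

    enabled: bool = False
    agc_levels: np.ndarray = field(default_factory=lambda: np.array([0.0, 10.0, 25.0, 50.0, 75.0]))
    strengths: np.ndarray = field(default_factory=lambda: np.array([0.004, 0.003, 0.0015, 0.0005, 0.0]))
    cap: float = 0.01

    def __post_init__(self) -> None:
        self.agc_levels = np.asarray(self.agc_levels, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if np.any(self.strengths < 0):
            raise ValueError("correction strengths must be non-negative")
        if np.any(np.diff(self.strengths) > 0):
            raise ValueError("strength must be non-increasing in AGC")
        if np.any(np.diff(self.agc_levels) <= 0):
            raise ValueError("AGC levels must be strictly increasing")

    def strength_at(self, agc: np.ndarray) -> np.ndarray:
        return np.interp(agc, self.agc_levels, self.strengths)


def correct_backscatter_change(
    img07: Raster,
    img10: Raster,
    agc07: Raster,
    moisture_diff: Raster,
    corr: MoistureCorrection,
) -> Raster:
    """Adjust the 2010 backscatter for between-date soil-moisture differences.

    gamma10' = gamma10 - strength(AGC07) * moisture_difference, with the
    adjustment capped at ``corr.cap`` and the result clamped at zero.
    Disabled corrections return the input unchanged (bit-exact).
    """
    if not corr.enabled:
        return img10
    for other in (img10, agc07, moisture_diff):
        if other.shape != img07.shape:
            raise ValueError("inputs are not co-registered")
    adj = corr.strength_at(agc07.data) * moisture_diff.data
    adj = np.clip(adj, -corr.cap, corr.cap)
    out = img10.data - adj
    n_clamped = int(np.sum(out[np.isfinite(out)] < 0))
    if n_clamped:
        log.warning("moisture correction clamped %d negative backscatter values", n_clamped)
    out = np.clip(out, 0.0, None)
    n_adj = int(np.sum(np.isfinite(adj) & (adj != 0)))
    log.info(
        "moisture correction adjusted %d pixels (mean |adj| %.2e)",
        n_adj,
        float(np.nanmean(np.abs(adj))) if n_adj else 0.0,
    )
    return img10.copy_with(out)


def moisture_difference_mask(moisture_diff: Raster, threshold: float) -> np.ndarray:
    """Boolean mask of pixels whose moisture proxy changed more than ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = moisture_diff.valid & (np.abs(moisture_diff.data) > threshold)
    frac = mask.sum() / max(moisture_diff.n_valid, 1)
    log.info("moisture-difference mask removes %.2f%% of valid pixels", 100 * frac)
    return mask
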