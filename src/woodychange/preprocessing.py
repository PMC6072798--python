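"""Radar preprocessing: DN calibration, speckle filtering, exclusion masks.

The mosaic products distribute amplitude digital numbers (DN); backscatter
gamma-naught is obtained as gamma0_dB = 10 log10(DN^2) + offset and then
converted to linear power so that spatial averaging uses arithmetic, not
geometric, means.  Speckle is reduced with the enhanced (three-regime) Lee
filter.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import uniform_filter

from .raster import Raster

__all__ = [
    "calibrate_dn",
    "db_to_linear",
    "linear_to_db",
    "enhanced_lee_filter",
    "apply_masks",
]

log = logging.getLogger(__name__)

#: Standard ALOS PALSAR mosaic calibration factor (dB).
DEFAULT_CALIBRATION_OFFSET_DB = -83.0


def db_to_linear(db: np.ndarray | float) -> np.ndarray | float:
    return 10.0 ** (np.asarray(db, dtype=float) / 10.0)


def linear_to_db(linear: np.ndarray | float) -> np.ndarray | float:
    return 10.0 * np.log10(np.asarray(linear, dtype=float))


def calibrate_dn(
    image: Raster,
    calibration_offset_db: float = DEFAULT_CALIBRATION_OFFSET_DB,
) -> Raster:
    """Convert raw digital numbers to calibrated gamma-naught in linear power.

    DN = 0 cannot be calibrated (log of zero) and becomes nodata.  Negative
    DN indicate a mis-read input and are rejected.
    """
    if not np.isfinite(calibration_offset_db):
        raise ValueError("calibration offset must be finite")
    dn = image.data
    valid = image.valid
    if np.any(dn[valid] < 0):
        raise ValueError("negative digital numbers: input is not an amplitude DN image")
    out = np.full(dn.shape, np.nan)
    ok = valid & (dn > 0)
    gamma_db = 10.0 * np.log10(dn[ok] ** 2) + calibration_offset_db
    out[ok] = db_to_linear(gamma_db)
    result = image.copy_with(out)
    if result.n_valid == 0:
        log.warning("calibration produced an all-nodata image")
    return result


def enhanced_lee_filter(
    image: Raster,
    window: int = 5,
    enl: float = 60.0,
    damping: float = 1.0,
) -> Raster:
    """Enhanced Lee speckle filter (three-regime) on a linear-power image.

    Below the speckle coefficient of variation ``cu = 1/sqrt(enl)`` the pixel
    is replaced by the local window mean (pure averaging); above
    ``cmax = sqrt(1 + 2/enl)`` the pixel is kept (assumed a real point
    feature); in between, centre and mean are blended with the exponential
    damping weight of the enhanced filter.  Nodata pixels are excluded from
    window statistics; windows containing only nodata stay nodata.

    ``enl`` is the equivalent number of looks of the imagery; for the mosaic
    product it equals the gamma shape parameter of the speckle model.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if min(image.shape) < window:
        raise ValueError("window larger than image")
    if enl <= 0:
        raise ValueError("equivalent number of looks must be positive")

    data = image.data
    valid = image.valid
    x = np.where(valid, data, 0.0)
    w = valid.astype(float)

    size = window
    # Window sums with zero padding; dividing by the valid count restricts
    # the statistics to valid pixels (partial windows near edges included).
    cnt = uniform_filter(w, size=size, mode="constant", cval=0.0) * size**2
    s1 = uniform_filter(x, size=size, mode="constant", cval=0.0) * size**2
    s2 = uniform_filter(x * x, size=size, mode="constant", cval=0.0) * size**2
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean**2, 0.0)
        ci = np.sqrt(var) / mean

    cu = 1.0 / np.sqrt(enl)
    cmax = np.sqrt(1.0 + 2.0 / enl)

    out = np.full(data.shape, np.nan)
    ok = valid & (cnt > 0) & np.isfinite(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        weight = np.exp(-damping * (ci - cu) / np.maximum(cmax - ci, 1e-12))
    blended = mean + weight * (data - mean)
    filtered = np.where(ci <= cu, mean, np.where(ci >= cmax, data, blended))
    out[ok] = filtered[ok]
    return image.copy_with(out)


def apply_masks(image: Raster, masks: list[np.ndarray]) -> tuple[Raster, int]:
    """Mark the union of boolean exclusion masks as nodata.

    Returns the masked raster and the count of newly invalidated pixels.
    """
    if not masks:
        return image.copy_with(image.data.copy()), 0
    union = np.zeros(image.shape, dtype=bool)
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != image.shape:
            raise ValueError(f"mask shape {m.shape} does not match raster {image.shape}")
        union |= m
    newly = int((union & image.valid).sum())
    out = np.where(union, np.nan, image.data)
    result = image.copy_with(out)
    if result.n_valid == 0:
        log.warning("masking removed every valid pixel")
    return result, newly
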