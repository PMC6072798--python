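"""Biomass-backscatter regression: fit, apply, invert; wooded classification.

Aboveground woody carbon density (AGC, MgC/ha) is a linear function of
HV-polarised gamma-naught in linear power units, valid up to a saturation
of roughly 75 MgC/ha.  The regional model fitted against 137 field plots is

    AGC = 715.67 * gamma0 - 5.97   (r2 = 0.57, CV-RMSE = 8.5, bias = 1.1)

and is the package-wide default (:meth:`BiomassModel.published`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .raster import Raster

__all__ = [
    "ChangeDefinition",
    "BiomassModel",
    "fit_biomass_model",
    "predict_agc",
    "invert_agc",
    "classify_wooded",
]

log = logging.getLogger(__name__)

#: AGC above which L-band HV backscatter saturates (MgC/ha).
SATURATION_AGC = 75.0


@dataclass(frozen=True)
class ChangeDefinition:
    """Thresholds defining the land-cover-change classes.

    ``woodland_threshold``: AGC (MgC/ha) separating wooded from non-wooded
    land (wooded means AGC >= threshold, inclusive).
    ``loss_ratio``: a pixel keeping at least this fraction of its initial
    AGC counts as minor loss; losing more is degradation or deforestation.
    """

    woodland_threshold: float = 10.0
    loss_ratio: float = 0.8

    def __post_init__(self) -> None:
        if self.woodland_threshold <= 0:
            raise ValueError("woodland threshold must be positive")
        if not 0 < self.loss_ratio < 1:
            raise ValueError("loss ratio must lie in (0, 1)")


@dataclass
class BiomassModel:
    """Linear backscatter -> AGC regression with its error statistics.

    ``sigma`` is the single-pixel prediction RMSE; ``model_se`` (sigma /
    sqrt(n_plots)) is the standard error of the model used as the biomass
    simulation SD in the probabilistic change detection — it reflects the
    uncertainty of the fitted mean response rather than single-plot scatter,
    which is what the Monte-Carlo adds on top of simulated speckle.
    ``bias`` is the mean signed cross-validation error; it is stored, not
    subtracted, unless bias correction is requested explicitly.
    """

    slope: float = 715.67
    intercept: float = -5.97
    sigma: float = 8.5
    bias: float = 1.1
    r2: float = 0.57
    n_plots: int = 137

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @classmethod
    def published(cls) -> "BiomassModel":
        """The regional model fitted on the 137 calibration plots."""
        return cls()

    @property
    def model_se(self) -> float:
        return self.sigma / np.sqrt(self.n_plots)

    # -- persistence (plain-text key=value) -----------------------------
    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in ("slope", "intercept", "sigma", "bias", "r2", "n_plots"):
                fh.write(f"{key} = {getattr(self, key)!r}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "BiomassModel":
        kv: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            if "=" in line:
                key, _, value = line.partition("=")
                kv[key.strip()] = float(value)
        kv["n_plots"] = int(kv["n_plots"])
        return cls(**kv)


def fit_biomass_model(plots: pd.DataFrame) -> BiomassModel:
    """Ordinary least squares of field AGC on plot-mean linear backscatter.

    ``plots`` needs columns ``agc_mgc_ha`` and ``gamma0_linear``.  The
    residual SD is degrees-of-freedom corrected; bias is the mean signed
    leave-one-out prediction error (prediction minus observation).
    """
    agc = np.asarray(plots["agc_mgc_ha"], dtype=float)
    g0 = np.asarray(plots["gamma0_linear"], dtype=float)
    n = len(agc)
    if n < 3:
        raise ValueError("need at least 3 calibration plots")
    if np.ptp(g0) == 0:
        raise ValueError("calibration plots have zero backscatter variance")
    if np.any(agc < 0) or np.any(g0 <= 0):
        raise ValueError("plots must have AGC >= 0 and gamma0 > 0")

    res = stats.linregress(g0, agc)
    pred = res.slope * g0 + res.intercept
    sse = float(np.sum((agc - pred) ** 2))
    sigma = float(np.sqrt(sse / (n - 2))) if sse > 0 else 0.0

    # Leave-one-out signed error via the hat-matrix shortcut.
    gbar = g0.mean()
    sxx = np.sum((g0 - gbar) ** 2)
    h = 1.0 / n + (g0 - gbar) ** 2 / sxx
    loo_err = (pred - agc) / (1.0 - h)
    bias = float(np.mean(loo_err))

    return BiomassModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        sigma=sigma,
        bias=bias,
        r2=float(res.rvalue**2),
        n_plots=n,
    )


def _predict_values(gamma0: np.ndarray, model: BiomassModel, clamp: bool) -> np.ndarray:
    agc = model.slope * gamma0 + model.intercept
    if clamp:
        agc = np.clip(agc, 0.0, None)
    return agc


def predict_agc(
    gamma0: Raster | np.ndarray,
    model: BiomassModel,
    clamp: bool = True,
    bias_correct: bool = False,
) -> Raster | np.ndarray:
    """Apply the regression to a linear-unit backscatter grid.

    Negative input values indicate a dB-scale image, which would be applied
    to the wrong scale, so they are rejected.  Negative predictions are
    clamped to zero by default; the clamp count is logged because clamped
    pixels sit at the non-wooded boundary.
    """
    is_raster = isinstance(gamma0, Raster)
    values = gamma0.data if is_raster else np.asarray(gamma0, dtype=float)
    finite = np.isfinite(values)
    if np.any(values[finite] < 0):
        raise ValueError(
            "negative backscatter values: input looks like dB; convert to linear power first"
        )
    agc = _predict_values(values, model, clamp=clamp)
    if bias_correct:
        agc = np.clip(agc - model.bias, 0.0, None) if clamp else agc - model.bias
    if clamp:
        n_clamped = int(np.sum((model.slope * values[finite] + model.intercept) < 0))
        if n_clamped:
            log.info("predict_agc: clamped %d negative predictions to 0", n_clamped)
    if is_raster:
        return gamma0.copy_with(agc)
    return agc


def invert_agc(agc: np.ndarray | float, model: BiomassModel) -> np.ndarray | float:
    """Backscatter whose expected AGC equals ``agc``: gamma0 = (AGC - b)/a.

    Right inverse of :func:`predict_agc` for AGC > 0; used to seed speckle
    simulations from carbon-density scenarios.
    """
    arr = np.asarray(agc, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("AGC must be non-negative")
    out = (arr - model.intercept) / model.slope
    return float(out) if np.isscalar(agc) else out


def classify_wooded(
    biomass: Raster, defn: ChangeDefinition = ChangeDefinition()
) -> tuple[np.ndarray, float]:
    """Boolean wooded grid (AGC >= threshold, inclusive) and wooded area in ha."""
    wooded = biomass.valid & (biomass.data >= defn.woodland_threshold)
    return wooded, float(wooded.sum()) * biomass.pixel_area_ha
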