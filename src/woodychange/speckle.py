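"""Mean-dependent gamma speckle model for L-band backscatter.

Over a homogeneous surface, multi-looked backscatter intensity follows a
gamma distribution Gamma(shape k, scale theta) with mean k*theta.  Fitted
over pseudo-homogeneous regions, the scale is a linear function of the mean:

    theta = alpha * mean + beta,      k = mean / theta

so k is roughly constant (the equivalent number of looks of the mosaic).
The regional estimates alpha = 0.0134, beta = 0.0001 are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "SpeckleModel",
    "gamma_params_for_mean",
    "fit_speckle_model",
    "simulate_backscatter",
]


@dataclass
class SpeckleModel:
    alpha: float = 0.0134
    beta: float = 0.0001
    alpha_se: float = 0.004
    beta_se: float = 0.0001
    r2: float = 0.49
    rmse: float = 0.00011
    n_regions: int = 20

    def __post_init__(self) -> None:
        if self.beta < 0 or (self.alpha <= 0 and self.beta <= 0):
            raise ValueError("theta(mean) = alpha*mean + beta must be positive for mean > 0")

    @classmethod
    def published(cls) -> "SpeckleModel":
        """Parameters estimated from 20 pseudo-homogeneous regions (3-98 km2)."""
        return cls()

    def enl(self, mean_gamma0: float) -> float:
        """Equivalent number of looks at a given mean backscatter (= shape k)."""
        k, _ = gamma_params_for_mean(self, mean_gamma0)
        return k

    # -- persistence ----------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in ("alpha", "beta", "alpha_se", "beta_se", "r2", "rmse", "n_regions"):
                fh.write(f"{key} = {getattr(self, key)!r}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeckleModel":
        kv: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            if "=" in line:
                key, _, value = line.partition("=")
                kv[key.strip()] = float(value)
        kv["n_regions"] = int(kv["n_regions"])
        return cls(**kv)


def gamma_params_for_mean(
    model: SpeckleModel, mean_gamma0: float | np.ndarray
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """(shape k, scale theta) whose gamma mean k*theta equals ``mean_gamma0``.

    A zero mean degenerates to k = 0 (simulation returns constant zero).
    """
    mean = np.asarray(mean_gamma0, dtype=float)
    if np.any(mean[np.isfinite(mean)] < 0):
        raise ValueError("mean backscatter must be non-negative")
    theta = model.alpha * mean + model.beta
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(mean > 0, mean / theta, 0.0)
    if np.isscalar(mean_gamma0):
        return float(k), float(theta)
    return k, theta


def fit_speckle_model(
    regions: dict[str, np.ndarray] | list[np.ndarray],
    method: str = "moments",
) -> SpeckleModel:
    """Estimate (alpha, beta) from per-region backscatter samples.

    Each region gets a gamma fit — method-of-moments by default
    (theta = var/mean, k = mean/theta), or maximum likelihood — then the
    per-region scales are regressed on the per-region means by unweighted
    OLS; the slope and intercept are alpha and beta.
    """
    samples = list(regions.values()) if isinstance(regions, dict) else list(regions)
    if len(samples) < 2:
        raise ValueError("need at least 2 homogeneous regions")
    means, thetas = [], []
    for s in samples:
        s = np.asarray(s, dtype=float)
        if np.any(s <= 0):
            raise ValueError("backscatter samples must be strictly positive linear power")
        m, v = float(s.mean()), float(s.var(ddof=1))
        if v <= 0:
            raise ValueError("region with non-positive sample variance")
        if method == "moments":
            theta = v / m
        elif method == "ml":
            shape, _, scale = stats.gamma.fit(s, floc=0.0)
            theta = float(scale)
        else:
            raise ValueError(f"unknown method {method!r}")
        means.append(m)
        thetas.append(theta)
    means_a, thetas_a = np.asarray(means), np.asarray(thetas)
    if np.ptp(means_a) == 0:
        raise ValueError("regions do not span distinct mean levels")
    res = stats.linregress(means_a, thetas_a)
    pred = res.slope * means_a + res.intercept
    rmse = float(np.sqrt(np.mean((thetas_a - pred) ** 2)))
    return SpeckleModel(
        alpha=float(res.slope),
        beta=float(res.intercept),
        alpha_se=float(res.stderr),
        beta_se=float(res.intercept_stderr),
        r2=float(res.rvalue**2),
        rmse=rmse,
        n_regions=len(samples),
    )


def simulate_backscatter(
    model: SpeckleModel,
    mean_gamma0: float,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` i.i.d. speckled backscatter values around ``mean_gamma0``.

    The same seed always yields the same draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k, theta = gamma_params_for_mean(model, mean_gamma0)
    if k == 0:
        return np.zeros(n)
    return rng.gamma(shape=k, scale=theta, size=n)
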