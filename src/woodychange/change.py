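"""Probabilistic land-cover-change classification by nested Monte Carlo.

For a pixel observed at backscatter (g07, g10), the chance that the apparent
change is real is estimated by simulating what could have been observed:
an outer loop of gamma-distributed speckle realisations of backscatter
around each observed value, and an inner loop of normal biomass
realisations around the regression mean of each speckle draw.  Pairing the
2007 and 2010 biomass realisations and applying the change definitions
gives the frequency of each of five mutually exclusive pixel states:

    deforested:  B07 >= T  and  B10 <  T  and  B10/B07 <  r
    degraded:    B07 >= T  and  B10 >= T  and  B10/B07 <  r
    gain:        B07 >= T  and  B10 >  B07
    minor loss:  B07 >= T  and  B07 >  B10 and  B10/B07 >= r
    non-wooded:  B07 <  T

with T the woodland threshold (10 MgC/ha) and r the loss ratio (0.8).
Exact ties B10 == B07 have probability zero under continuous noise and are
counted diagnostically.  Because per-pixel simulation over a whole mosaic
is wasteful, the probabilities are precomputed on a (g07, g10) grid — a
lookup table — and applied to rasters by nearest-bin (or bilinear) lookup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .biomass import BiomassModel, ChangeDefinition
from .raster import Raster
from .speckle import SpeckleModel, gamma_params_for_mean

__all__ = [
    "CLASSES",
    "StateProbabilities",
    "ChangeProbabilityTable",
    "state_probabilities",
    "build_lookup_table",
    "classify_rasters",
]

#: Canonical state order used everywhere (arrays, rasters, tables, CSVs).
CLASSES = ("deforested", "degraded", "gain", "minor_loss", "nonwooded")


@dataclass(frozen=True)
class StateProbabilities:
    p_deforested: float
    p_degraded: float
    p_gain: float
    p_minor_loss: float
    p_nonwooded: float
    p_tie: float = 0.0
    n_outer: int = 10_000
    n_inner: int = 200

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_deforested, self.p_degraded, self.p_gain, self.p_minor_loss, self.p_nonwooded]
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASSES, self.as_array()))

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


def _simulate_biomass(
    gamma_obs: float,
    bm: BiomassModel,
    sm: SpeckleModel,
    sigma: float,
    n_outer: int,
    n_inner: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n_outer*n_inner biomass realisations for one observed backscatter."""
    k, theta = gamma_params_for_mean(sm, gamma_obs)
    if k == 0:
        g = np.zeros(n_outer)
    else:
        g = rng.gamma(shape=k, scale=theta, size=n_outer)
    mu = bm.slope * g + bm.intercept
    # scale=0 is a valid degenerate normal; always drawing keeps the RNG
    # stream identical across sigma values, so runs differing only in sigma
    # share their speckle realisations.
    b = rng.normal(loc=mu[:, None], scale=sigma, size=(n_outer, n_inner)).ravel()
    return np.clip(b, 0.0, None)


def state_probabilities(
    gamma07: float,
    gamma10: float,
    bm: BiomassModel,
    sm: SpeckleModel,
    defn: ChangeDefinition = ChangeDefinition(),
    n_outer: int = 10_000,
    n_inner: int = 200,
    seed: int | np.random.SeedSequence = 0,
    sim_sigma: float | None = None,
    product_rule: bool = False,
) -> StateProbabilities:
    """Monte-Carlo state probabilities for one observed backscatter pair.

    ``sim_sigma`` is the SD of the normal biomass realisations; by default
    the model standard error ``bm.model_se`` (the uncertainty of the fitted
    regression mean), on top of the speckle already simulated.  With
    ``product_rule=True`` the class probabilities are composed as products
    of marginal condition probabilities instead of joint event frequencies
    (a cross-check; the two differ little away from the thresholds).
    """
    if gamma07 < 0 or gamma10 < 0:
        raise ValueError("observed backscatter must be non-negative")
    if n_outer < 1 or n_inner < 1:
        raise ValueError("simulation sizes must be >= 1")
    sigma = bm.model_se if sim_sigma is None else float(sim_sigma)
    if sigma < 0:
        raise ValueError("simulation sigma must be >= 0")

    rng = np.random.default_rng(seed)
    b07 = _simulate_biomass(gamma07, bm, sm, sigma, n_outer, n_inner, rng)
    b10 = _simulate_biomass(gamma10, bm, sm, sigma, n_outer, n_inner, rng)

    T, r = defn.woodland_threshold, defn.loss_ratio
    wooded = b07 >= T
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(b07 > 0, b10 / np.where(b07 > 0, b07, 1.0), np.inf)

    if product_rule:
        p = {
            "deforested": (b07 >= T).mean() * (b10 < T).mean() * (ratio < r).mean(),
            "degraded": (b07 > T).mean() * (b10 >= T).mean() * (ratio < r).mean(),
            "gain": (b07 >= T).mean() * (b10 >= T).mean() * (b10 > b07).mean(),
            "minor_loss": (b07 >= T).mean() * (b07 > b10).mean() * (ratio >= r).mean(),
            "nonwooded": (b07 < T).mean(),
        }
        tie = 0.0
    else:
        p = {
            "deforested": (wooded & (b10 < T) & (ratio < r)).mean(),
            "degraded": (wooded & (b10 >= T) & (ratio < r)).mean(),
            "gain": (wooded & (b10 > b07)).mean(),
            "minor_loss": (wooded & (b07 > b10) & (ratio >= r)).mean(),
            "nonwooded": (~wooded).mean(),
        }
        tie = float((wooded & (b10 == b07)).mean())

    return StateProbabilities(
        p_deforested=float(p["deforested"]),
        p_degraded=float(p["degraded"]),
        p_gain=float(p["gain"]),
        p_minor_loss=float(p["minor_loss"]),
        p_nonwooded=float(p["nonwooded"]),
        p_tie=tie,
        n_outer=n_outer,
        n_inner=n_inner,
    )


@dataclass
class ChangeProbabilityTable:
    """Gridded lookup from (g07, g10) bin centres to state probabilities.

    ``probs`` has shape (5, len(axis07), len(axis10)) in :data:`CLASSES`
    order.  Cells are simulated independently with per-cell seeds derived
    from the master seed, so any cell can be reproduced by a direct
    :func:`state_probabilities` call with :meth:`cell_seed`.
    """

    axis07: np.ndarray
    axis10: np.ndarray
    probs: np.ndarray
    bin_width: float
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis07 = np.asarray(self.axis07, dtype=float)
        self.axis10 = np.asarray(self.axis10, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(self.axis07) <= 0) or np.any(np.diff(self.axis10) <= 0):
            raise ValueError("table axes must be strictly increasing")
        if self.probs.shape != (len(CLASSES), len(self.axis07), len(self.axis10)):
            raise ValueError("probs shape does not match axes")

    def cell_seed(self, i: int, j: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, i, j])

    def _nearest(self, values: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.clip(np.searchsorted(axis, values) , 0, len(axis) - 1)
        left = np.clip(idx - 1, 0, len(axis) - 1)
        idx = np.where(
            np.abs(axis[left] - values) <= np.abs(axis[idx] - values), left, idx
        )
        out_of_range = (values < axis[0] - self.bin_width / 2) | (
            values > axis[-1] + self.bin_width / 2
        )
        return idx, out_of_range

    def lookup(
        self, gamma07: np.ndarray | float, gamma10: np.ndarray | float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-bin probabilities, shape (5, ...); second return flags
        values outside the table's covered range (clipped to edge cells)."""
        g07 = np.atleast_1d(np.asarray(gamma07, dtype=float))
        g10 = np.atleast_1d(np.asarray(gamma10, dtype=float))
        i, oor07 = self._nearest(g07, self.axis07)
        j, oor10 = self._nearest(g10, self.axis10)
        return self.probs[:, i, j], (oor07 | oor10)

    def lookup_bilinear(self, gamma07: np.ndarray, gamma10: np.ndarray) -> np.ndarray:
        """Bilinearly interpolated probabilities, renormalised to sum to 1."""
        from scipy.interpolate import RegularGridInterpolator

        g07 = np.clip(np.asarray(gamma07, dtype=float), self.axis07[0], self.axis07[-1])
        g10 = np.clip(np.asarray(gamma10, dtype=float), self.axis10[0], self.axis10[-1])
        pts = np.stack([g07.ravel(), g10.ravel()], axis=-1)
        out = np.empty((len(CLASSES), pts.shape[0]))
        for c in range(len(CLASSES)):
            interp = RegularGridInterpolator((self.axis07, self.axis10), self.probs[c])
            out[c] = interp(pts)
        out /= out.sum(axis=0, keepdims=True)
        return out.reshape((len(CLASSES),) + g07.shape)

    # -- persistence: JSON (text) ---------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "axis07": self.axis07.tolist(),
            "axis10": self.axis10.tolist(),
            "probs": self.probs.tolist(),
            "bin_width": self.bin_width,
            "seed": self.seed,
            "classes": list(CLASSES),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ChangeProbabilityTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            axis07=np.asarray(payload["axis07"]),
            axis10=np.asarray(payload["axis10"]),
            probs=np.asarray(payload["probs"]),
            bin_width=payload["bin_width"],
            seed=payload["seed"],
            meta=payload.get("meta", {}),
        )


def _make_axis(lo: float, hi: float, width: float) -> np.ndarray:
    n = max(int(np.ceil((hi - lo) / width)) + 1, 2)
    return lo + width * np.arange(n)


def build_lookup_table(
    bm: BiomassModel,
    sm: SpeckleModel,
    defn: ChangeDefinition = ChangeDefinition(),
    gamma_range: tuple[float, float] = (0.0, 0.12),
    bin_width: float = 0.001,
    n_outer: int = 10_000,
    n_inner: int = 200,
    seed: int = 0,
    sim_sigma: float | None = None,
) -> ChangeProbabilityTable:
    """Simulate state probabilities over a grid of observed (g07, g10) pairs.

    The grid must cover the observed backscatter range of the rasters it
    will classify; out-of-range pixels are flagged at apply time.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = gamma_range
    if not 0 <= lo < hi:
        raise ValueError("invalid gamma range")
    axis = _make_axis(lo, hi, bin_width)
    probs = np.empty((len(CLASSES), len(axis), len(axis)))
    for i, g07 in enumerate(axis):
        for j, g10 in enumerate(axis):
            sp = state_probabilities(
                g07,
                g10,
                bm,
                sm,
                defn,
                n_outer=n_outer,
                n_inner=n_inner,
                seed=np.random.SeedSequence([seed, i, j]),
                sim_sigma=sim_sigma,
            )
            probs[:, i, j] = sp.as_array()
    return ChangeProbabilityTable(
        axis07=axis,
        axis10=axis,
        probs=probs,
        bin_width=bin_width,
        seed=seed,
        meta={
            "n_outer": n_outer,
            "n_inner": n_inner,
            "sim_sigma": bm.model_se if sim_sigma is None else sim_sigma,
            "biomass_model": {"slope": bm.slope, "intercept": bm.intercept, "sigma": bm.sigma},
            "speckle_model": {"alpha": sm.alpha, "beta": sm.beta},
            "definition": {"T": defn.woodland_threshold, "r": defn.loss_ratio},
        },
    )


def classify_rasters(
    img07: Raster,
    img10: Raster,
    table: ChangeProbabilityTable,
    interpolate: bool = False,
) -> dict[str, Raster]:
    """Per-pixel state probabilities for a co-registered backscatter pair.

    Returns five probability rasters keyed by :data:`CLASSES`; nodata in
    either year propagates to all five outputs.
    """
    if img07.shape != img10.shape:
        raise ValueError("images are not co-registered (shape mismatch)")
    if img07.pixel_size != img10.pixel_size:
        raise ValueError("images are not co-registered (pixel size mismatch)")
    valid = img07.valid & img10.valid
    g07 = img07.data[valid]
    g10 = img10.data[valid]
    if interpolate:
        p = table.lookup_bilinear(g07, g10)
    else:
        p, oor = table.lookup(g07, g10)
        if oor.any():
            import logging

            logging.getLogger(__name__).warning(
                "classify_rasters: %d pixels outside the lookup-table range (edge cell used)",
                int(oor.sum()),
            )
    out: dict[str, Raster] = {}
    for c, name in enumerate(CLASSES):
        grid = np.full(img07.shape, np.nan)
        grid[valid] = p[c]
        out[name] = img07.copy_with(grid, year=None)
    return out
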