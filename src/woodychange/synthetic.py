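"""Synthetic landscapes with known truth for end-to-end validation.

The generator builds a two-date carbon-density world first (truth), then
observes it through the forward model the pipeline assumes: mean
backscatter from the inverted biomass regression, one gamma speckle draw
per pixel per year.  Default intensities mirror the study system: a
gamma-shaped AGC background with mean 24 MgC/ha, degradation removing
20-50% of initial stock, deforestation leaving residual biomass below the
10 MgC/ha threshold, and growth increments with median 1.3 and SD
0.9 MgC/ha/yr over a 3-year window.  Change classes are laid out as
contiguous patches (a quantile slicing of a smoothed noise field), giving
exact class fractions up to rounding while still exercising the spatial
assumptions of the speckle filter.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .biomass import BiomassModel, ChangeDefinition, invert_agc, SATURATION_AGC
from .raster import Raster
from .speckle import SpeckleModel, gamma_params_for_mean

__all__ = [
    "SyntheticScenario",
    "SyntheticTruth",
    "generate_truth",
    "simulate_observations",
    "sample_plot_records",
    "moisture_proxy",
    "write_fixture",
    "derive_label",
    "LABELS",
]

log = logging.getLogger(__name__)

#: Truth label order.  'stable' marks unchanged pixels (exact ties), which
#: the five-state probabilistic classifier assigns to no change class.
LABELS = ("nonwooded", "deforested", "degraded", "gain", "minor_loss", "stable")


@dataclass
class SyntheticScenario:
    shape: tuple[int, int] = (300, 300)
    pixel_size: float = 25.0
    # Class fractions of all pixels; the remainder is stable wooded land.
    # Defaults echo the study region: gains on about half the wooded area,
    # degradation on ~17% and deforestation on ~8% of it.
    frac_nonwooded: float = 0.15
    frac_deforested: float = 0.08
    frac_degraded: float = 0.17
    frac_gain: float = 0.48
    frac_minor_loss: float = 0.12
    # AGC background: gamma-shaped, mean 24 MgC/ha.
    agc_shape: float = 3.0
    agc_scale: float = 8.0
    # Change intensities.
    degradation_ratio: tuple[float, float] = (0.5, 0.8)
    minor_loss_ratio: tuple[float, float] = (0.82, 0.98)
    growth_median: float = 1.3      # MgC/ha/yr
    growth_sd: float = 0.9          # MgC/ha/yr
    years: float = 3.0
    blob_sigma: float = 3.0         # patch smoothness (pixels)
    seed: int = 0
    # Per-class placement knobs (defaults echo observed intensities; the
    # separated() preset pushes classes away from the decision boundaries).
    nonwooded_agc_max: float = 8.0
    defor_agc07_mean: float = 14.0
    defor_agc07_sd: float = 4.0
    defor_agc07_min: float = 10.5
    defor_residual_frac: float = 0.95   # residual AGC cap as fraction of min(T, r*B07)
    degraded_agc07_min: float | None = None
    gain_agc07_range: tuple[float, float] | None = None
    gain_increment_range: tuple[float, float] | None = None  # total MgC/ha if set

    @classmethod
    def separated(cls, **overrides) -> "SyntheticScenario":
        """A validation scenario whose classes sit well clear of the
        woodland-threshold and loss-ratio decision boundaries.

        Minor losses are omitted: the (r, 1) ratio band is narrower than
        the observation noise, so that class cannot be separated at all.
        """
        kv = dict(
            frac_nonwooded=0.15,
            frac_deforested=0.20,
            frac_degraded=0.20,
            frac_gain=0.45,
            frac_minor_loss=0.0,
            degradation_ratio=(0.45, 0.55),
            nonwooded_agc_max=3.0,
            defor_agc07_mean=30.0,
            defor_agc07_sd=4.0,
            defor_agc07_min=25.0,
            defor_residual_frac=0.35,
            degraded_agc07_min=40.0,
            gain_agc07_range=(18.0, 32.0),
            gain_increment_range=(20.0, 30.0),
        )
        kv.update(overrides)
        return cls(**kv)

    def fractions(self) -> dict[str, float]:
        f = {
            "nonwooded": self.frac_nonwooded,
            "deforested": self.frac_deforested,
            "degraded": self.frac_degraded,
            "gain": self.frac_gain,
            "minor_loss": self.frac_minor_loss,
        }
        f["stable"] = 1.0 - sum(f.values())
        return f

    def validate(self) -> None:
        f = self.fractions()
        if any(v < -1e-12 for v in f.values()):
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        lo, hi = self.degradation_ratio
        if not 0 < lo < hi <= 0.8:
            raise ValueError("degradation ratios must lie in (0, 0.8]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticScenario":
        kv = json.loads(Path(path).read_text())
        for key in ("shape", "degradation_ratio", "minor_loss_ratio",
                    "gain_agc07_range", "gain_increment_range"):
            if kv.get(key) is not None:
                kv[key] = tuple(kv[key])
        return cls(**kv)


@dataclass
class SyntheticTruth:
    agc07: Raster
    agc10: Raster
    labels: np.ndarray                     # int index into LABELS
    scenario: SyntheticScenario
    class_areas_ha: dict[str, float] = field(default_factory=dict)
    class_carbon_change_mgc: dict[str, float] = field(default_factory=dict)

    def label_names(self) -> np.ndarray:
        return np.asarray(LABELS)[self.labels]


def derive_label(b07: np.ndarray, b10: np.ndarray, defn: ChangeDefinition) -> np.ndarray:
    """Truth label from a noise-free AGC pair — the classifier's own rules."""
    b07 = np.asarray(b07, dtype=float)
    b10 = np.asarray(b10, dtype=float)
    T, r = defn.woodland_threshold, defn.loss_ratio
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(b07 > 0, b10 / np.where(b07 > 0, b07, 1.0), np.inf)
    out = np.full(b07.shape, LABELS.index("stable"), dtype=int)
    wooded = b07 >= T
    out[~wooded] = LABELS.index("nonwooded")
    out[wooded & (b10 < T) & (ratio < r)] = LABELS.index("deforested")
    out[wooded & (b10 >= T) & (ratio < r)] = LABELS.index("degraded")
    out[wooded & (b10 > b07)] = LABELS.index("gain")
    out[wooded & (b07 > b10) & (ratio >= r)] = LABELS.index("minor_loss")
    return out


def _truncated(draw, lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n`` values from ``draw(size)`` restricted to [lo, hi]."""
    out = np.empty(n)
    have = 0
    while have < n:
        cand = draw(max(2 * (n - have), 16), rng)
        cand = cand[(cand >= lo) & (cand <= hi)]
        take = min(len(cand), n - have)
        out[have : have + take] = cand[:take]
        have += take
    return out


def _exact_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n pixels to classes."""
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def generate_truth(
    scenario: SyntheticScenario, defn: ChangeDefinition = ChangeDefinition()
) -> SyntheticTruth:
    """Build the noise-free two-date AGC world and its per-pixel class labels.

    Every pixel's label is re-derivable from (AGC07, AGC10) and the change
    definition, exactly; class counts match the requested fractions up to
    rounding.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    nrows, ncols = scenario.shape
    n = nrows * ncols
    T = defn.woodland_threshold

    # Contiguous patches: rank a smoothed noise field and slice by quantile.
    fld = gaussian_filter(rng.normal(size=(nrows, ncols)), scenario.blob_sigma)
    order = np.argsort(fld.ravel(), kind="stable")
    counts = _exact_counts(scenario.fractions(), n)
    labels_flat = np.empty(n, dtype=int)
    pos = 0
    # Shuffle class band order so no class is always in the field's low end.
    band_order = list(LABELS)
    rng.shuffle(band_order)
    slices: dict[str, np.ndarray] = {}
    for name in band_order:
        cnt = counts[name]
        idx = order[pos : pos + cnt]
        labels_flat[idx] = LABELS.index(name)
        slices[name] = idx
        pos += cnt

    b07 = np.empty(n)
    b10 = np.empty(n)

    def background(size: int, r: np.random.Generator) -> np.ndarray:
        return r.gamma(scenario.agc_shape, scenario.agc_scale, size)

    # Non-wooded: low AGC well under the threshold, essentially unchanged.
    idx = slices["nonwooded"]
    b07[idx] = rng.uniform(0.0, min(scenario.nonwooded_agc_max, 0.95 * T), len(idx))
    b10[idx] = b07[idx]

    # Deforested: end state below threshold with more than the ratio loss;
    # cleared land may keep residual trees.
    idx = slices["deforested"]
    v = _truncated(
        lambda s, r: r.normal(scenario.defor_agc07_mean, scenario.defor_agc07_sd, s),
        max(scenario.defor_agc07_min, T + 0.5),
        40.0,
        len(idx),
        rng,
    )
    b07[idx] = v
    cap = np.minimum(T, defn.loss_ratio * v) * scenario.defor_residual_frac
    b10[idx] = rng.uniform(0.0, 1.0, len(idx)) * cap

    # Degraded: higher-biomass woodland losing 20-50% but staying wooded.
    idx = slices["degraded"]
    deg_min = (
        scenario.degraded_agc07_min
        if scenario.degraded_agc07_min is not None
        else T / scenario.degradation_ratio[0] + 4.0
    )
    v = _truncated(lambda s, r: r.normal(29.0, 10.0, s), deg_min,
                   SATURATION_AGC - 5.0, len(idx), rng)
    b07[idx] = v
    lo, hi = scenario.degradation_ratio
    b10[idx] = v * rng.uniform(lo, hi, len(idx))

    # Gain: wooded background plus a lognormal annual increment (or a fixed
    # total-increment range if the scenario sets one).
    idx = slices["gain"]
    g07_lo, g07_hi = scenario.gain_agc07_range or (T + 0.5, SATURATION_AGC - 1.0)
    v = _truncated(lambda s, r: background(s, r), g07_lo, g07_hi, len(idx), rng)
    if scenario.gain_increment_range is not None:
        g_lo, g_hi = scenario.gain_increment_range
        inc_total = rng.uniform(g_lo, g_hi, len(idx))
        v = np.minimum(v, SATURATION_AGC - g_hi - 1.0)
    else:
        mu = np.log(scenario.growth_median)
        cv2 = (scenario.growth_sd / scenario.growth_median) ** 2
        sigma = np.sqrt(np.log((1 + np.sqrt(1 + 4 * cv2)) / 2))
        inc_total = scenario.years * rng.lognormal(mu, sigma, len(idx))
    b07[idx] = v
    b10[idx] = np.minimum(v + inc_total, SATURATION_AGC)

    # Minor loss: wooded background losing at most (1 - r) of its stock.
    idx = slices["minor_loss"]
    v = _truncated(lambda s, r: background(s, r), T + 0.5, SATURATION_AGC, len(idx), rng)
    b07[idx] = v
    lo, hi = scenario.minor_loss_ratio
    b10[idx] = v * rng.uniform(lo, hi, len(idx))

    # Stable wooded: unchanged.
    idx = slices["stable"]
    v = _truncated(lambda s, r: background(s, r), T + 0.5, SATURATION_AGC, len(idx), rng)
    b07[idx] = v
    b10[idx] = v

    derived = derive_label(b07, b10, defn)
    if not np.array_equal(derived, labels_flat):
        bad = int(np.sum(derived != labels_flat))
        raise AssertionError(f"{bad} generated pixels violate their own class rules")

    agc07 = Raster(b07.reshape(nrows, ncols), pixel_size=scenario.pixel_size, year=2007)
    agc10 = Raster(b10.reshape(nrows, ncols), pixel_size=scenario.pixel_size, year=2010)
    px = agc07.pixel_area_ha
    areas = {name: float(counts[name]) * px for name in LABELS}
    dcarbon = {
        name: float(np.sum(b10[slices[name]] - b07[slices[name]])) * px for name in LABELS
    }
    return SyntheticTruth(
        agc07=agc07,
        agc10=agc10,
        labels=labels_flat.reshape(nrows, ncols),
        scenario=scenario,
        class_areas_ha=areas,
        class_carbon_change_mgc=dcarbon,
    )


def simulate_observations(
    truth: SyntheticTruth,
    bm: BiomassModel,
    sm: SpeckleModel,
    seed: int | None = None,
) -> tuple[Raster, Raster]:
    """Observe the truth through the forward model: one speckle draw per
    pixel and year, independent between years."""
    seed = truth.scenario.seed + 1 if seed is None else seed
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(2)]
    out = []
    for raster, rng in zip((truth.agc07, truth.agc10), streams):
        agc = raster.data
        if np.any(agc > SATURATION_AGC):
            warnings.warn("AGC above the backscatter saturation ceiling; clamping")
            agc = np.clip(agc, None, SATURATION_AGC)
        mean_g = invert_agc(agc, bm)
        k, theta = gamma_params_for_mean(sm, mean_g)
        draws = np.where(k > 0, rng.gamma(np.maximum(k, 1e-12), theta), 0.0)
        out.append(raster.copy_with(draws))
    return out[0], out[1]


def sample_plot_records(
    truth: SyntheticTruth,
    bm: BiomassModel,
    sm: SpeckleModel,
    n_plots: int = 137,
    plot_pixels: int = 10,
    field_sigma: float = 8.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot-like calibration records sampled from the truth.

    Each plot's backscatter is the arithmetic mean of ``plot_pixels``
    speckle draws at the pixel's expected backscatter (a ~0.6 ha footprint
    on a 25 m grid); field AGC carries normal error with SD
    ``field_sigma``, the stand-in for total calibration error.
    """
    rng = np.random.default_rng(seed)
    flat07 = truth.agc07.data.ravel()
    pick = rng.choice(len(flat07), size=n_plots, replace=False)
    agc_true = flat07[pick]
    mean_g = invert_agc(agc_true, bm)
    k, theta = gamma_params_for_mean(sm, mean_g)
    draws = rng.gamma(np.maximum(k, 1e-12)[:, None], theta[:, None], (n_plots, plot_pixels))
    g0 = np.where(k > 0, draws.mean(axis=1), 0.0)
    agc_field = np.clip(agc_true + rng.normal(0.0, field_sigma, n_plots), 0.0, None)
    return pd.DataFrame(
        {
            "plot_id": [f"SP{i:04d}" for i in range(n_plots)],
            "agc_mgc_ha": agc_field,
            "gamma0_linear": g0,
            "area_ha": plot_pixels * truth.agc07.pixel_area_ha,
            "country": "synthetic",
        }
    )


def moisture_proxy(shape: tuple[int, int], seed: int = 0, smooth: float = 10.0) -> Raster:
    """A unitless, smooth moisture-difference proxy field in roughly [-1, 1]."""
    rng = np.random.default_rng(seed)
    fld = gaussian_filter(rng.normal(size=shape), smooth)
    fld /= max(np.abs(fld).max(), 1e-12)
    return Raster(fld)


def write_fixture(
    scenario: SyntheticScenario,
    outdir: str | Path,
    bm: BiomassModel | None = None,
    sm: SpeckleModel | None = None,
    defn: ChangeDefinition = ChangeDefinition(),
) -> dict[str, Path]:
    """Write a self-describing bundle: two-date imagery, truth, plots, moisture.

    Returns the paths written, keyed by role.
    """
    bm = bm or BiomassModel.published()
    sm = sm or SpeckleModel.published()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(scenario, defn)
    img07, img10 = simulate_observations(truth, bm, sm)
    plots = sample_plot_records(truth, bm, sm, seed=scenario.seed + 2)
    moist = moisture_proxy(scenario.shape, seed=scenario.seed + 3)

    paths = {
        "scenario": outdir / "scenario.json",
        "img07": outdir / "gamma0_2007.asc",
        "img10": outdir / "gamma0_2010.asc",
        "truth07": outdir / "truth_agc_2007.asc",
        "truth10": outdir / "truth_agc_2010.asc",
        "labels": outdir / "truth_labels.asc",
        "truth_summary": outdir / "truth_summary.csv",
        "plots": outdir / "plots.csv",
        "moisture": outdir / "moisture_diff.asc",
    }
    scenario.to_json(paths["scenario"])
    img07.write_ascii(paths["img07"])
    img10.write_ascii(paths["img10"])
    truth.agc07.write_ascii(paths["truth07"])
    truth.agc10.write_ascii(paths["truth10"])
    Raster(truth.labels.astype(float), pixel_size=scenario.pixel_size).write_ascii(paths["labels"])
    rows = [
        {
            "class": name,
            "area_ha": truth.class_areas_ha[name],
            "carbon_change_mgc": truth.class_carbon_change_mgc[name],
        }
        for name in LABELS
    ]
    pd.DataFrame(rows).to_csv(paths["truth_summary"], index=False)
    plots.to_csv(paths["plots"], index=False)
    moist.write_ascii(paths["moisture"])
    log.info("synthetic fixture written to %s", outdir)
    return paths
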