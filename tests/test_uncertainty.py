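"""Cross-validation replication and CI propagation."""

import numpy as np
import pandas as pd
import pytest

from woodychange import (
    SyntheticScenario,
    UncertaintyConfig,
    cv_replicate_models,
    generate_truth,
    propagate_to_summaries,
    simulate_observations,
)
from woodychange.uncertainty import sample_tiles

SMALL_CFG = UncertaintyConfig(
    n_replicates=20,
    n_tiles=3,
    tile_pixels=16,
    lut_n_outer=200,
    lut_n_inner=8,
    lut_bin_width=0.01,
    seed=5,
)


def noiseless_plots(n=24):
    g = np.linspace(0.02, 0.1, n)
    return pd.DataFrame({"agc_mgc_ha": 715.67 * g - 5.97, "gamma0_linear": g})


def noisy_plots(rng, n=137, sigma=8.5):
    g = rng.uniform(0.015, 0.11, n)
    agc = np.clip(715.67 * g - 5.97 + rng.normal(0, sigma, n), 0, None)
    return pd.DataFrame({"agc_mgc_ha": agc, "gamma0_linear": g})


@pytest.fixture(scope="module")
def small_world(bm, sm, defn):
    truth = generate_truth(SyntheticScenario.separated(shape=(50, 50), seed=31), defn)
    img07, img10 = simulate_observations(truth, bm, sm, seed=32)
    return truth, img07, img10


class TestReplicates:
    def test_noiseless_plots_give_identical_models(self):
        reps = cv_replicate_models(noiseless_plots(), n_replicates=10, seed=1)
        slopes = {round(m.slope, 9) for m in reps}
        assert slopes == {round(715.67, 9)}
        assert all(abs(m.bias) < 1e-9 for m in reps)

    def test_slope_distribution_centred_on_truth(self, rng):
        plots = noisy_plots(rng)
        reps = cv_replicate_models(plots, n_replicates=100, seed=2)
        slopes = np.array([m.slope for m in reps])
        assert abs(np.median(slopes) - 715.67) < 3 * slopes.std()

    def test_seed_determinism(self, rng):
        plots = noisy_plots(rng)
        a = cv_replicate_models(plots, n_replicates=5, seed=7)
        b = cv_replicate_models(plots, n_replicates=5, seed=7)
        assert [(m.slope, m.bias) for m in a] == [(m.slope, m.bias) for m in b]

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError):
            cv_replicate_models(noiseless_plots(4), n_replicates=3)


class TestTiles:
    def test_tiles_inside_extent(self):
        tiles = sample_tiles((60, 80), 10, 16, seed=3)
        for rs, cs in tiles:
            assert 0 <= rs.start and rs.stop <= 60
            assert 0 <= cs.start and cs.stop <= 80
            assert rs.stop - rs.start == 16

    def test_oversized_tile_rejected(self):
        with pytest.raises(ValueError):
            sample_tiles((10, 10), 2, 16)


class TestPropagation:
    def test_zero_noise_gives_zero_width_cis(self, sm, defn, small_world, bm):
        _, img07, img10 = small_world
        reps = cv_replicate_models(noiseless_plots(), n_replicates=4, seed=1)
        cfg = UncertaintyConfig(
            n_replicates=4, n_tiles=2, tile_pixels=12,
            lut_n_outer=150, lut_n_inner=6, lut_bin_width=0.012, seed=9,
        )
        # point model = the same noiseless fit, so point == every replicate
        ci = propagate_to_summaries(reps, img07, img10, sm, defn, cfg, point_model=reps[0])
        assert np.allclose(ci["lo"], ci["hi"])
        assert np.allclose(ci["lo"], ci["point"])

    def test_cis_bracket_point_estimates(self, rng, sm, defn, small_world, bm):
        _, img07, img10 = small_world
        reps = cv_replicate_models(noisy_plots(rng), n_replicates=SMALL_CFG.n_replicates, seed=4)
        ci = propagate_to_summaries(reps, img07, img10, sm, defn, SMALL_CFG, point_model=bm)
        assert np.all(ci["lo"] <= ci["point"] + 1e-12)
        assert np.all(ci["point"] <= ci["hi"] + 1e-12)
        assert (ci["hi"] - ci["lo"]).max() > 0  # noisy calibration -> real spread

    def test_deterministic_under_master_seed(self, rng, sm, defn, small_world, bm):
        _, img07, img10 = small_world
        plots = noisy_plots(rng)
        reps = cv_replicate_models(plots, n_replicates=6, seed=11)
        cfg = UncertaintyConfig(
            n_replicates=6, n_tiles=2, tile_pixels=12,
            lut_n_outer=150, lut_n_inner=6, lut_bin_width=0.012, seed=21,
        )
        a = propagate_to_summaries(reps, img07, img10, sm, defn, cfg, point_model=bm)
        b = propagate_to_summaries(reps, img07, img10, sm, defn, cfg, point_model=bm)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_width_stable_in_replicate_count(self, rng, sm, defn, small_world, bm):
        # Quadrupling the replicate count must not move the interval much.
        _, img07, img10 = small_world
        plots = noisy_plots(rng)
        cfg = UncertaintyConfig(
            n_replicates=2, n_tiles=2, tile_pixels=12,
            lut_n_outer=150, lut_n_inner=6, lut_bin_width=0.012, seed=17,
        )
        few = cv_replicate_models(plots, n_replicates=200, seed=3)
        many = cv_replicate_models(plots, n_replicates=800, seed=3)
        ci_few = propagate_to_summaries(few, img07, img10, sm, defn, cfg, point_model=bm)
        ci_many = propagate_to_summaries(many, img07, img10, sm, defn, cfg, point_model=bm)
        row_f = ci_few.set_index("quantity").loc["wooded_area_ha"]
        row_m = ci_many.set_index("quantity").loc["wooded_area_ha"]
        w_f = row_f["hi"] - row_f["lo"]
        w_m = row_m["hi"] - row_m["lo"]
        assert w_f > 0 and w_m > 0
        assert abs(w_f - w_m) / w_m < 0.3
        # intervals overlap
        assert row_f["lo"] < row_m["hi"] and row_m["lo"] < row_f["hi"]

    def test_coverage_over_independent_worlds(self, bm, sm, defn):
        # Across >= 20 independent synthetic worlds the 95% CI for wooded
        # area should contain the true (tile-restricted) wooded area in a
        # clear majority of worlds (loose desk-scale coverage check).
        from woodychange.synthetic import sample_plot_records

        cfg = UncertaintyConfig(
            n_replicates=24, n_tiles=3, tile_pixels=14,
            lut_n_outer=200, lut_n_inner=8, lut_bin_width=0.01, seed=2,
        )
        hits = 0
        n_worlds = 20
        for w in range(n_worlds):
            truth = generate_truth(
                SyntheticScenario.separated(shape=(42, 42), seed=1000 + w), defn
            )
            img07, img10 = simulate_observations(truth, bm, sm, seed=2000 + w)
            plots = sample_plot_records(truth, bm, sm, n_plots=60, seed=3000 + w)
            reps = cv_replicate_models(plots, cfg.n_replicates, seed=4000 + w)
            ci = propagate_to_summaries(reps, img07, img10, sm, defn, cfg, point_model=bm)
            row = ci.set_index("quantity").loc["wooded_area_ha"]
            tiles = sample_tiles(img07.shape, cfg.n_tiles, cfg.tile_pixels, seed=cfg.seed)
            true_wooded = sum(
                (truth.agc07.data[t] >= defn.woodland_threshold).sum() for t in tiles
            ) * truth.agc07.pixel_area_ha
            if row["lo"] <= true_wooded <= row["hi"]:
                hits += 1
        assert hits >= 0.8 * n_worlds

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            UncertaintyConfig(n_replicates=1)
        with pytest.raises(ValueError):
            UncertaintyConfig(percentiles=(97.5, 2.5))
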