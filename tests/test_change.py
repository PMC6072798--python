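"""Probabilistic change classification and the lookup table."""

import numpy as np
import pytest

from woodychange import (
    CLASSES,
    ChangeProbabilityTable,
    Raster,
    build_lookup_table,
    classify_rasters,
    invert_agc,
    state_probabilities,
)

# Desk-scale simulation sizes for unit tests (acceptance runs the full sizes).
N_OUTER, N_INNER = 2000, 50


def probs_for(bm, sm, defn, agc07, agc10, seed=1, **kw):
    return state_probabilities(
        invert_agc(agc07, bm), invert_agc(agc10, bm), bm, sm, defn,
        n_outer=N_OUTER, n_inner=N_INNER, seed=seed, **kw,
    )


class TestStateProbabilities:
    def test_partition_sums_to_one(self, bm, sm, defn):
        for agc07, agc10 in [(25, 16), (24, 28), (70, 0), (5, 5), (12, 11)]:
            sp = probs_for(bm, sm, defn, agc07, agc10)
            assert sp.total == pytest.approx(1.0, abs=2 / np.sqrt(N_OUTER * N_INNER))
            assert sp.p_tie == pytest.approx(0.0, abs=1e-6)

    def test_large_loss_is_deforestation_or_nonwooded(self, bm, sm, defn):
        sp = probs_for(bm, sm, defn, 70, 0)
        assert sp.p_deforested + sp.p_nonwooded == pytest.approx(1.0, abs=0.01)
        assert sp.p_deforested > 0.9

    def test_low_biomass_is_nonwooded(self, bm, sm, defn):
        sp = probs_for(bm, sm, defn, 1, 1)
        assert sp.p_nonwooded > 0.95

    def test_seed_determinism(self, bm, sm, defn):
        a = probs_for(bm, sm, defn, 25, 16, seed=42)
        b = probs_for(bm, sm, defn, 25, 16, seed=42)
        assert a == b

    def test_product_rule_close_to_joint_away_from_thresholds(self, bm, sm, defn):
        joint = probs_for(bm, sm, defn, 40, 25)
        prod = probs_for(bm, sm, defn, 40, 25, product_rule=True)
        assert prod.p_degraded == pytest.approx(joint.p_degraded, abs=0.03)

    def test_invalid_inputs_rejected(self, bm, sm, defn):
        with pytest.raises(ValueError):
            state_probabilities(-0.01, 0.02, bm, sm, defn)
        with pytest.raises(ValueError):
            state_probabilities(0.02, 0.02, bm, sm, defn, n_outer=0)
        with pytest.raises(ValueError):
            state_probabilities(0.02, 0.02, bm, sm, defn, sim_sigma=-1.0)


@pytest.fixture(scope="module")
def small_table(bm, sm, defn):
    return build_lookup_table(
        bm, sm, defn,
        gamma_range=(0.01, 0.08), bin_width=0.005,
        n_outer=500, n_inner=20, seed=11,
    )


class TestLookupTable:
    def test_cell_reproduces_direct_call(self, bm, sm, defn, small_table):
        i, j = 3, 1
        sp = state_probabilities(
            small_table.axis07[i], small_table.axis10[j], bm, sm, defn,
            n_outer=500, n_inner=20, seed=small_table.cell_seed(i, j),
        )
        np.testing.assert_array_equal(small_table.probs[:, i, j], sp.as_array())

    def test_partition_in_every_cell(self, small_table):
        total = small_table.probs.sum(axis=0)
        mc_se = 3 / np.sqrt(500 * 20)
        assert np.all(np.abs(total - 1.0) < max(3 * mc_se, 0.05))

    def test_loss_probability_monotone_along_row(self, bm, sm, defn, small_table):
        # For a 2007 value well above the threshold, the chance of a >20%
        # loss cannot grow as the 2010 backscatter rises.
        i = len(small_table.axis07) - 1  # highest gamma07 (AGC ~ 50)
        p_loss = small_table.probs[0, i, :] + small_table.probs[1, i, :]
        diffs = np.diff(p_loss)
        assert np.all(diffs < 0.05)  # non-increasing within MC noise
        assert p_loss[0] > p_loss[-1]

    def test_diagonal_splits_evenly(self, bm, sm, defn):
        # Identical marginal distributions on both dates: gains take half
        # the mass, losses of any kind the other half.
        g = invert_agc(40.0, bm)
        sp = state_probabilities(g, g, bm, sm, defn, n_outer=N_OUTER, n_inner=N_INNER, seed=3)
        losses = sp.p_deforested + sp.p_degraded + sp.p_minor_loss
        assert sp.p_gain == pytest.approx(0.5, abs=0.05)
        assert losses == pytest.approx(0.5, abs=0.05)

    def test_axes_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ChangeProbabilityTable(
                axis07=np.array([0.1, 0.1]),
                axis10=np.array([0.1, 0.2]),
                probs=np.zeros((5, 2, 2)),
                bin_width=0.1,
            )

    def test_save_load_roundtrip(self, tmp_path, small_table):
        p = tmp_path / "table.json"
        small_table.save(p)
        back = ChangeProbabilityTable.load(p)
        np.testing.assert_array_equal(back.probs, small_table.probs)
        np.testing.assert_array_equal(back.axis07, small_table.axis07)
        assert back.seed == small_table.seed


class TestClassifyRasters:
    def test_constant_pair_matches_table_cell(self, bm, small_table):
        g07 = float(small_table.axis07[4])
        g10 = float(small_table.axis10[2])
        img07 = Raster(np.full((6, 6), g07), year=2007)
        img10 = Raster(np.full((6, 6), g10), year=2010)
        probs = classify_rasters(img07, img10, small_table)
        for c, name in enumerate(CLASSES):
            np.testing.assert_allclose(probs[name].data, small_table.probs[c, 4, 2])

    def test_nodata_propagates_to_all_outputs(self, small_table):
        a = np.full((4, 4), 0.04)
        b = np.full((4, 4), 0.03)
        b[1, 2] = np.nan
        probs = classify_rasters(Raster(a), Raster(b), small_table)
        for name in CLASSES:
            assert np.isnan(probs[name].data[1, 2])
            assert np.isfinite(probs[name].data[0, 0])

    def test_matches_per_pixel_lookup_oracle(self, small_table, rng):
        g07 = rng.uniform(0.015, 0.075, (20, 20))
        g10 = rng.uniform(0.015, 0.075, (20, 20))
        probs = classify_rasters(Raster(g07), Raster(g10), small_table)
        # brute force: nearest bin per pixel, one at a time
        for r in range(20):
            for c in range(20):
                i = int(np.argmin(np.abs(small_table.axis07 - g07[r, c])))
                j = int(np.argmin(np.abs(small_table.axis10 - g10[r, c])))
                for k, name in enumerate(CLASSES):
                    assert probs[name].data[r, c] == small_table.probs[k, i, j]

    def test_shape_mismatch_rejected(self, small_table):
        with pytest.raises(ValueError, match="co-registered"):
            classify_rasters(Raster(np.ones((3, 3))), Raster(np.ones((4, 4))), small_table)

    def test_bilinear_interpolation_renormalises(self, small_table, rng):
        g07 = rng.uniform(0.015, 0.075, (8, 8))
        g10 = rng.uniform(0.015, 0.075, (8, 8))
        p = small_table.lookup_bilinear(g07, g10)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-9)
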