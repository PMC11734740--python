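import numpy as np
import pandas as pd
import pytest

from stagescreen import (BScoreNormalizer, PlateMeasurementSet, aggregate_bscores,
                         bscore_plate)

from _oracles import naive_bscore
from conftest import additive_plate_frame, make_wells


def as_pms(df, n_rows=8, n_cols=12):
    return PlateMeasurementSet(df, n_rows=n_rows, n_cols=n_cols)


def test_uniform_plate_is_degenerate_with_zero_scores():
    df = additive_plate_frame(row_step=0, col_step=0)
    res = bscore_plate(as_pms(df))
    assert res.degenerate
    assert res.mad_scale == 0.0
    np.testing.assert_array_equal(res.bscores[~np.isnan(res.bscores)], 0.0)


def test_spiked_well_matches_brute_force_oracle():
    df = additive_plate_frame(base=10, row_step=1, col_step=2)
    df.loc[(df["row"] == 3) & (df["col"] == 5), "value"] += 50.0
    res = bscore_plate(as_pms(df))

    mat = np.full((8, 12), np.nan)
    mat[df["row"], df["col"]] = df["value"]
    oracle_scores, oracle_scale = naive_bscore(mat.tolist())
    assert res.mad_scale == pytest.approx(oracle_scale, abs=1e-10)
    np.testing.assert_allclose(res.bscores, np.asarray(oracle_scores), atol=1e-8)
    assert res.bscores[3, 5] == np.nanmax(res.bscores)


def test_oracle_equivalence_on_random_plates():
    """B-scores match an independently coded naive polish + MAD to 1e-8."""
    rng = np.random.default_rng(99)
    for _ in range(50):
        df = additive_plate_frame(row_step=rng.uniform(-2, 2),
                                  col_step=rng.uniform(-2, 2))
        df["value"] += rng.normal(0, 3, size=len(df))
        df["value"] = df["value"].clip(0, 100)
        res = bscore_plate(as_pms(df), max_iter=2000, tol=1e-10)
        mat = np.full((8, 12), np.nan)
        mat[df["row"], df["col"]] = df["value"]
        oracle_scores, _ = naive_bscore(mat.tolist(), max_iter=2000, tol=1e-10)
        np.testing.assert_allclose(res.bscores, np.asarray(oracle_scores), atol=1e-8)


@pytest.mark.parametrize("shift", [5.0, -3.0, 45.0])
def test_whole_plate_shift_leaves_bscores_unchanged(shift):
    df = additive_plate_frame()
    df["value"] += np.random.default_rng(1).normal(0, 2, len(df))
    base = bscore_plate(as_pms(df), tol=1e-10, max_iter=2000)
    shifted = df.copy()
    shifted["value"] += shift
    res = bscore_plate(as_pms(shifted), tol=1e-10, max_iter=2000)
    np.testing.assert_allclose(res.bscores, base.bscores, atol=1e-9)


@pytest.mark.parametrize("axis", ["row", "col"])
def test_single_row_or_column_offset_absorbed(axis):
    df = additive_plate_frame()
    df["value"] += np.random.default_rng(2).normal(0, 2, len(df))
    base = bscore_plate(as_pms(df), tol=1e-10, max_iter=2000)
    bumped = df.copy()
    bumped.loc[bumped[axis] == 4, "value"] += 20.0
    res = bscore_plate(as_pms(bumped), tol=1e-10, max_iter=2000)
    np.testing.assert_allclose(res.bscores, base.bscores, atol=1e-9)


def test_positive_scaling_leaves_bscores_unchanged():
    df = additive_plate_frame()
    df["value"] += np.random.default_rng(3).normal(0, 2, len(df))
    base = bscore_plate(as_pms(df), tol=1e-10, max_iter=2000)
    scaled = df.copy()
    scaled["value"] *= 0.37
    res = bscore_plate(as_pms(scaled), tol=1e-10, max_iter=2000)
    np.testing.assert_allclose(res.bscores, base.bscores, atol=1e-9)


def test_controls_are_excluded_from_the_polish():
    """Extreme control values must not perturb sample-well B-scores."""
    df = additive_plate_frame()
    df["value"] += np.random.default_rng(4).normal(0, 2, len(df))
    base = bscore_plate(as_pms(df), tol=1e-10, max_iter=2000)

    poisoned = df.copy()
    ctrl = (poisoned["row"] == 0) & (poisoned["col"] < 4)
    poisoned.loc[ctrl, ["role", "gene", "sirna_id"]] = ["negative_control", None, "NT"]
    poisoned.loc[ctrl, "value"] = 100.0
    res = bscore_plate(as_pms(poisoned), tol=1e-10, max_iter=2000)

    sample_mask = ~ctrl.to_numpy().reshape(8, 12)
    # control wells differ (NaN in the poisoned result), samples must not react
    # beyond the small change from removing 4 wells from the medians/MAD
    diff = np.abs(res.bscores - base.bscores)[sample_mask]
    assert np.nanmedian(diff) < 0.5
    assert np.isnan(res.bscores[0, :4]).all()


def test_too_few_sample_wells_rejected():
    rows = [("p1", "b1", 1, 0, j, "sample", f"G{j}", f"s{j}", "IL6", 10.0)
            for j in range(3)]
    with pytest.raises(ValueError, match=">= 4"):
        bscore_plate(as_pms(make_wells(rows)))


def test_mixed_plate_slice_rejected():
    df = pd.concat([additive_plate_frame(plate="P1"), additive_plate_frame(plate="P2")])
    with pytest.raises(ValueError, match="plate_id"):
        bscore_plate(as_pms(df.reset_index(drop=True)))


def test_normalizer_scores_control_wells_from_decomposition():
    df = additive_plate_frame()
    ctrl = (df["row"] == 7) & (df["col"] >= 10)
    df.loc[ctrl, ["role", "gene", "sirna_id"]] = ["negative_control", None, "NT"]
    norm = BScoreNormalizer().fit(as_pms(df))
    out = norm.transform(as_pms(df))
    assert out.loc[ctrl, "bscore"].notna().all()
    # additive plate: every residual is 0, controls included
    np.testing.assert_allclose(out["bscore"], 0.0, atol=1e-6)


def test_aggregate_mean_and_missingness():
    wells = pd.DataFrame([
        # siRNA in two wells with B = 2 and 4 -> 3
        dict(batch_id="B1", gene="G1", sirna_id="s1", replicate=1, channel="IL6", bscore=2.0),
        dict(batch_id="B1", gene="G1", sirna_id="s1", replicate=1, channel="IL6", bscore=4.0),
        # single well -> identity
        dict(batch_id="B1", gene="G2", sirna_id="s2", replicate=1, channel="IL6", bscore=1.5),
        # G2 present in replicate 2, G1 absent there
        dict(batch_id="B2", gene="G2", sirna_id="s2", replicate=2, channel="IL6", bscore=2.5),
    ])
    agg = aggregate_bscores(wells)
    g1r1 = agg.query("gene == 'G1' and replicate == 1")["score"].iloc[0]
    g2r1 = agg.query("gene == 'G2' and replicate == 1")["score"].iloc[0]
    g1r2 = agg.query("gene == 'G1' and replicate == 2")["score"]
    assert g1r1 == pytest.approx(3.0)
    assert g2r1 == pytest.approx(1.5)
    assert len(g1r2) == 1 and np.isnan(g1r2.iloc[0])
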