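import numpy as np
import pandas as pd
import pytest

from lowflight import nnmodel, terrain, trackproc
from lowflight.evalsuite import prepare_xy, train_val_split
from lowflight.nnmodel import ModelConfig
from lowflight.raster import Raster, RasterError
from lowflight.riskmap import (
    aggregate_bagged,
    bagging_train,
    binarize,
    high_risk_intersect,
    joint_probability,
    predict_raster,
    threshold_at_sensitivity,
)
from lowflight.synthgen import WorldConfig, generate_world
from lowflight.terrain import FEATURE_COLUMNS, stack_features


def prob_raster(data):
    data = np.asarray(data, dtype=float)
    return Raster(data, y0=data.shape[0] * 25.0, cell=25.0)


# ---------------------------------------------------------------------------
# bagging
# ---------------------------------------------------------------------------

def test_bootstrap_resample_unique_fraction():
    """Classical bootstrap coverage: ~1 - 1/e of rows appear per resample."""
    rng = np.random.default_rng([6, 0, 0])  # the ensemble's resampling stream
    n = 10_000
    resample = rng.integers(0, n, size=n)
    unique_frac = len(np.unique(resample)) / n
    assert abs(unique_frac - (1 - np.exp(-1))) < 0.02


def test_bagging_ensemble_members(small_table):
    cfg = ModelConfig(units1=8, units2=4, dropout_rate=0.2, max_epochs=4,
                      patience=2, batch_size=256, seed=0)
    members, stats = bagging_train(small_table, cfg, B=3, seed=0)
    assert len(members) == 3
    X, _ = prepare_xy(small_table, stats)
    preds = [nnmodel.predict(m, X) for m in members]
    # members trained on different resamples genuinely differ
    assert not np.allclose(preds[0], preds[1])
    with pytest.raises(ValueError):
        bagging_train(small_table, cfg, B=1)


def test_aggregate_bagged_mean_and_percentiles(rng):
    members = [prob_raster(rng.random((4, 4))) for _ in range(30)]
    bag = aggregate_bagged(members)
    stack = np.stack([m.data for m in members])
    np.testing.assert_allclose(bag.mean.data, stack.mean(axis=0), atol=1e-12)
    # order-statistic oracle at one cell: sort the 30 values by hand
    vals = np.sort(stack[:, 2, 3])
    k = 0.025 * 29  # linear interpolation between order statistics
    lo = vals[int(k)] + (k - int(k)) * (vals[int(k) + 1] - vals[int(k)])
    assert bag.lower.data[2, 3] == pytest.approx(lo)
    assert np.all(bag.lower.data <= bag.upper.data)


def test_aggregate_identical_members():
    m = prob_raster(np.full((3, 3), 0.4))
    bag = aggregate_bagged([m, m.copy_with(m.data), m.copy_with(m.data)])
    np.testing.assert_allclose(bag.mean.data, 0.4, atol=1e-12)
    np.testing.assert_allclose(bag.lower.data, 0.4, atol=1e-12)
    np.testing.assert_allclose(bag.upper.data, 0.4, atol=1e-12)


def test_aggregate_two_members_mean():
    a = prob_raster([[0.2]])
    b = prob_raster([[0.8]])
    assert aggregate_bagged([a, b]).mean.data[0, 0] == pytest.approx(0.5)


def test_aggregate_rejects_misregistered():
    a = prob_raster(np.zeros((3, 3)))
    b = Raster(np.zeros((3, 3)), x0=10.0, y0=75.0, cell=25.0)
    with pytest.raises(RasterError):
        aggregate_bagged([a, b])


def test_bagged_mean_permutation_invariant(rng):
    members = [prob_raster(rng.random((3, 3))) for _ in range(5)]
    fwd = aggregate_bagged(members)
    rev = aggregate_bagged(members[::-1])
    np.testing.assert_array_equal(fwd.mean.data, rev.mean.data)


# ---------------------------------------------------------------------------
# raster prediction
# ---------------------------------------------------------------------------

def test_cell_prediction_matches_hand_built_row(small_world, small_table):
    env = small_world[0]
    cfg = ModelConfig(units1=8, units2=4, dropout_rate=0.0, seed=1)
    stats = terrain.fit_normalizer(small_table)
    model = nnmodel.init_network(cfg)
    model.norm_stats = stats
    pm = predict_raster(model, env, stats)
    feats, rows, cols = stack_features(env)
    k = 100
    X, _ = prepare_xy(feats.iloc[[k]].assign(label=0), stats)
    assert pm.data[rows[k], cols[k]] == pytest.approx(nnmodel.predict(model, X)[0])
    vals = pm.data[~np.isnan(pm.data)]
    assert vals.min() > 0 and vals.max() < 1


def test_constant_stack_gives_constant_map(small_table):
    n = 8
    mk = lambda v: Raster(np.full((n, n), float(v)), y0=n * 25.0, cell=25.0)
    env = terrain.EnvStack({
        "elevation": mk(1000), "landcover": mk(4), "geology": mk(2),
        "eastness": mk(0), "northness": mk(0), "slope": mk(0),
        "slope_unev": mk(0), "tpi": mk(0), "ibex": mk(0.5), "chamois": mk(0.5),
        "windspeed": mk(5),
    })
    stats = terrain.fit_normalizer(small_table)
    model = nnmodel.init_network(ModelConfig(units1=8, units2=4, seed=2))
    pm = predict_raster(model, env, stats)
    assert len(np.unique(pm.data[~np.isnan(pm.data)])) == 1


def test_ensemble_mean_map_equals_cellwise_average(small_world, small_table):
    env = small_world[0]
    stats = terrain.fit_normalizer(small_table)
    models = []
    for s in range(3):
        m = nnmodel.init_network(ModelConfig(units1=8, units2=4, seed=s))
        m.norm_stats = stats
        models.append(m)
    maps = predict_raster(models, env, stats)
    bag = aggregate_bagged(maps)
    stack = np.stack([m.data for m in maps])
    valid = ~np.isnan(stack).any(axis=0)
    direct = stack.mean(axis=0)
    np.testing.assert_allclose(bag.mean.data[valid], direct[valid], atol=1e-12)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def brute_force_threshold(labels, scores, target):
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    best = None
    for t in np.unique(scores):
        tpr = np.mean(pos >= t)
        if tpr >= target and (best is None or t > best):
            best = t
    return best


def test_threshold_worked_example():
    labels = [1, 1, 1, 1, 1, 0, 0]
    scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3]
    t, tpr = threshold_at_sensitivity(labels, scores, target=0.8)
    assert t == pytest.approx(0.6)  # 4 of 5 positives captured
    assert tpr == pytest.approx(0.8)


def test_threshold_matches_exhaustive_scan(rng):
    for _ in range(50):
        n = int(rng.integers(5, 40))
        labels = rng.integers(0, 2, n)
        if (labels == 1).sum() == 0:
            continue
        scores = np.round(rng.random(n), 2)
        target = float(rng.choice([0.5, 0.8, 0.9, 0.95]))
        t, tpr = threshold_at_sensitivity(labels, scores, target)
        assert t == pytest.approx(brute_force_threshold(labels, scores, target))
        assert tpr >= target
        # maximality: any larger candidate drops the TPR below target
        pos = scores[labels == 1]
        larger = np.unique(scores)[np.unique(scores) > t]
        if len(larger):
            assert np.mean(pos >= larger[0]) < target


def test_threshold_degenerate_target_zero(rng):
    labels = [1, 0, 1]
    scores = [0.2, 0.5, 0.9]
    t, tpr = threshold_at_sensitivity(labels, scores, target=0.0)
    assert t == 0.9  # the largest candidate; TPR >= 0 always holds
    assert tpr > 0


def test_threshold_requires_positives():
    with pytest.raises(ValueError):
        threshold_at_sensitivity([0, 0], [0.1, 0.2])


# ---------------------------------------------------------------------------
# binarize / joint / high-risk
# ---------------------------------------------------------------------------

def test_binarize_boundary_and_nodata():
    r = prob_raster([[0.5, 0.49], [np.nan, 0.9]])
    out = binarize(r, 0.5)
    assert out.data[0, 0] == 1.0  # p == threshold -> 1
    assert out.data[0, 1] == 0.0
    assert np.isnan(out.data[1, 0])
    assert not np.any((out.data == 0) & (r.data >= 0.5))
    zeros = binarize(prob_raster(np.zeros((2, 2))), 0.5)
    np.testing.assert_array_equal(zeros.data, 0.0)
    with pytest.raises(ValueError):
        binarize(r, np.inf)


def test_joint_probability_product_rules(rng):
    a = prob_raster([[0.8, 0.2], [0.5, 1.0]])
    b = prob_raster([[0.5, 0.5], [0.5, 0.5]])
    out = joint_probability(a, b)
    assert out.data[0, 0] == pytest.approx(0.4)
    assert np.all(out.data <= np.minimum(a.data, b.data) + 1e-12)
    ones = prob_raster(np.ones((2, 2)))
    np.testing.assert_array_equal(joint_probability(a, ones).data, a.data)
    with pytest.raises(ValueError):
        joint_probability(prob_raster([[1.5]]), prob_raster([[0.5]]))


def test_high_risk_extremes(rng):
    conflict = prob_raster(rng.integers(0, 5, size=(10, 10)).astype(float))
    all_fly = prob_raster(np.ones((10, 10)))
    none_fly = prob_raster(np.zeros((10, 10)))
    high, shares = high_risk_intersect(all_fly, conflict)
    np.testing.assert_array_equal(high.data, conflict.data)
    assert shares["remaining"].abs().max() == 0.0
    high0, shares0 = high_risk_intersect(none_fly, conflict)
    np.testing.assert_array_equal(high0.data, 0.0)
    pd.testing.assert_series_equal(
        shares0["remaining"], shares0["potential"], check_names=False)


def test_high_risk_accounting_on_random_rasters(rng):
    """Cell-count oracle: per level, potential = high_risk + remaining."""
    conflict = prob_raster(rng.integers(0, 5, size=(20, 20)).astype(float))
    binary = prob_raster(rng.integers(0, 2, size=(20, 20)).astype(float))
    high, shares = high_risk_intersect(binary, conflict)
    n = conflict.data.size
    for _, row in shares.iloc[:4].iterrows():
        level = row["level"]
        potential = 100 * np.sum(conflict.data == level) / n
        high_pct = 100 * np.sum((conflict.data == level) & (binary.data == 1)) / n
        assert row["potential"] == pytest.approx(potential)
        assert row["high_risk"] == pytest.approx(high_pct)
        assert row["potential"] == pytest.approx(row["high_risk"] + row["remaining"])
    # high-risk cells only where low flight is predicted
    assert not np.any((high.data > 0) & (binary.data == 0))


def test_unknown_conflict_level_rejected():
    with pytest.raises(ValueError):
        high_risk_intersect(prob_raster([[1.0]]), prob_raster([[7.0]]))


# ---------------------------------------------------------------------------
# end-to-end: more low flight means more flagged area
# ---------------------------------------------------------------------------

def test_flagged_share_increases_with_low_flight_prevalence():
    """Raising the generating intercept makes low flight more prevalent
    everywhere, so the share of the region flagged as critical must rise."""
    shares = []
    cfg0 = WorldConfig(grid_rows=70, grid_cols=70, n_birds=5, fixes_per_bird=700, seed=31)
    mcfg = ModelConfig(units1=16, units2=8, dropout_rate=0.2, max_epochs=15,
                       patience=5, batch_size=256, seed=0)
    for intercept in (-1.5, 1.0, 3.5):
        cfg = WorldConfig(**{**cfg0.__dict__, "intercept": intercept,
                             "beta": cfg0.beta.copy()})
        env, fixes, birds, _ = generate_world(cfg)
        cleaned, _ = trackproc.clean_tracks(
            fixes, birds, env["elevation"], env["undulation"], env["region_mask"],
            cfg.lat0, cfg.lon0)
        table = terrain.extract_features(cleaned, env)
        tr, va = train_val_split(len(table), seed=0)
        stats = terrain.fit_normalizer(table.loc[tr])
        Xtr, ytr = prepare_xy(table.loc[tr], stats)
        Xva, yva = prepare_xy(table.loc[va], stats)
        model = nnmodel.init_network(mcfg)
        model, _ = nnmodel.train(model, Xtr, ytr, Xva, yva, mcfg)
        X_all = np.vstack([Xtr, Xva])
        y_all = np.concatenate([ytr, yva])
        t, _ = threshold_at_sensitivity(y_all, nnmodel.predict(model, X_all), 0.95)
        pm = predict_raster(model, env, stats)
        binary = binarize(pm, t)
        region = env["region_mask"].data == 1
        flagged = np.nansum(binary.data[region] == 1) / region.sum()
        shares.append(flagged)
    assert shares[0] < shares[1] <= shares[2]
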