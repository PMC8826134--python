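import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter
from sklearn.metrics import roc_auc_score

from lowflight import nnmodel, terrain
from lowflight.evalsuite import (
    BlockGrid,
    GridSpec,
    HEADLINE_GROUPS,
    VARIABLE_GROUPS,
    auc,
    block_cv,
    enumerate_grid,
    estimate_block_size,
    grid_search,
    ice_pd,
    loo_bird_cv,
    make_blocks,
    permutation_importance,
    prepare_xy,
    train_val_split,
)
from lowflight.nnmodel import ModelConfig, init_network
from lowflight.raster import Raster
from lowflight.terrain import CONTINUOUS_VARS, EnvStack, FEATURE_COLUMNS


def brute_force_auc(labels, scores):
    """Exhaustive pairwise concordance: ties count one half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_worked_example():
    # 3 concordant of the 4 positive-negative pairs
    assert auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)


def test_auc_separated_and_all_ties():
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([1, 1], [0.2, 0.3])


def test_auc_equals_exhaustive_oracle_on_all_small_datasets(rng):
    """Rank-based AUC against brute-force pair enumeration (and sklearn as
    a second independent check) on many random datasets of <= 12 rows."""
    for _ in range(200):
        n = int(rng.integers(2, 13))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 1)  # coarse grid to force ties
        expected = brute_force_auc(labels, scores)
        assert auc(labels, scores) == pytest.approx(expected, abs=1e-12)
        assert auc(labels, scores) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def test_default_grid_enumerates_216_configurations():
    grid = GridSpec()
    configs = enumerate_grid(grid)
    assert grid.size == 216
    assert len(configs) == 216
    assert len({(c.units1, c.units2, c.dropout_rate) for c in configs}) == 216


def test_reduced_grid_single_configuration():
    grid = GridSpec((16,), (16,), (0.2,))
    assert grid.size == 1
    assert len(enumerate_grid(grid)) == 1


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(units1=16, units2=8, dropout_rate=0.2, max_epochs=8,
                       patience=3, batch_size=128, seed=0)


def test_grid_search_sort_contract_and_single_config_equivalence(small_table, tiny_cfg):
    grid = GridSpec((8, 16), (4,), (0.2,))
    results, best = grid_search(small_table, grid, tiny_cfg, seed=0)
    assert len(results) == 2
    assert results["val_auc"].iloc[0] >= results["val_auc"].iloc[1]
    assert (best.units1, best.units2) in {(8, 4), (16, 4)}

    # a one-configuration grid equals a direct training run
    one = GridSpec((16,), (4,), (0.2,))
    res_one, _ = grid_search(small_table, one, tiny_cfg, seed=0)
    tr, va = train_val_split(len(small_table), seed=0)
    stats = terrain.fit_normalizer(small_table.loc[tr])
    Xtr, ytr = prepare_xy(small_table.loc[tr], stats)
    Xva, yva = prepare_xy(small_table.loc[va], stats)
    from dataclasses import replace
    cfg = replace(tiny_cfg, units1=16, units2=4, dropout_rate=0.2)
    model = init_network(cfg)
    _, log = nnmodel.train(model, Xtr, ytr, Xva, yva, cfg)
    assert res_one["val_auc"].iloc[0] == pytest.approx(log.best_val_auc)


# ---------------------------------------------------------------------------
# leave-one-bird-out
# ---------------------------------------------------------------------------

def test_loo_bird_cv_one_model_per_bird(small_table, tiny_cfg):
    res = loo_bird_cv(small_table, tiny_cfg, n_epochs=3)
    birds = sorted(small_table["bird_id"].unique())
    assert list(res.frame["bird_id"]) == birds
    # partition contract: each fold's test size is that bird's row count
    counts = small_table.groupby("bird_id").size()
    for _, row in res.frame.iterrows():
        assert row["n_test"] == counts[row["bird_id"]]
        assert row["n_train"] == len(small_table) - counts[row["bird_id"]]


def test_loo_bird_cv_homogeneous_birds(small_table, tiny_cfg):
    """Synthetic birds share one generating process, so per-bird test AUCs
    cluster around their mean."""
    res = loo_bird_cv(small_table, tiny_cfg, n_epochs=10)
    aucs = res.frame["test_auc"].dropna()
    assert len(aucs) >= 2
    sd = max(aucs.std(), 0.01)
    assert np.all(np.abs(aucs - aucs.mean()) <= 3 * sd)


def test_loo_requires_two_birds(small_table, tiny_cfg):
    one = small_table[small_table["bird_id"] == small_table["bird_id"].iloc[0]]
    with pytest.raises(ValueError):
        loo_bird_cv(one, tiny_cfg)


# ---------------------------------------------------------------------------
# spatial blocks
# ---------------------------------------------------------------------------

def region(nrows, ncols, cell=25.0):
    return Raster(np.ones((nrows, ncols)), x0=0.0, y0=nrows * cell, cell=cell)


def test_block_tiling_count():
    # 2500 m x 2500 m region, 1000 m blocks -> ceil(2.5)^2 = 9 blocks
    mask = region(100, 100)
    blocks = make_blocks(mask, side_m=1000.0, n_folds=5, seed=0)
    assert blocks.block_raster.data.max() == 8  # ids 0..8
    folds = set(blocks.fold_of_block.values())
    assert folds == {1, 2, 3, 4, 5}
    sizes = pd.Series(list(blocks.fold_of_block.values())).value_counts()
    assert sizes.max() - sizes.min() <= 1  # balanced to within one block


def test_block_assignment_deterministic_and_inherited():
    mask = region(100, 100)
    b1 = make_blocks(mask, side_m=500.0, seed=3)
    b2 = make_blocks(mask, side_m=500.0, seed=3)
    assert b1.fold_of_block == b2.fold_of_block
    x, y = np.array([10.0, 1200.0]), np.array([2490.0, 600.0])
    f1 = b1.fold_of_points(x, y)
    blocks_of = b1.block_raster.sample(x, y).astype(int)
    assert [b1.fold_of_block[b] for b in blocks_of] == list(f1)


def test_too_few_blocks_rejected():
    with pytest.raises(ValueError):
        make_blocks(region(40, 40), side_m=1000.0, n_folds=5)


def test_block_cv_partitions_all_rows(small_world, small_table, tiny_cfg):
    env = small_world[0]
    blocks = make_blocks(env["region_mask"], side_m=500.0, n_folds=5, seed=0)
    res = block_cv(small_table, blocks, tiny_cfg, n_epochs=3)
    assert res.frame["n_test"].sum() == len(small_table)
    assert len(res.frame) == 5


# ---------------------------------------------------------------------------
# block-size recommendation
# ---------------------------------------------------------------------------

def noise_stack(rng, sigma_cells=0.0, n=120, cell=25.0):
    base = rng.standard_normal((n, n))
    if sigma_cells:
        base = gaussian_filter(base, sigma_cells, mode="reflect")
    other = base.copy()
    return EnvStack({
        "slope": Raster(base, y0=n * cell, cell=cell),
        "tpi": Raster(other, y0=n * cell, cell=cell),
    })


def test_white_noise_band_has_no_practical_range(rng):
    recommended, per_band = estimate_block_size(noise_stack(rng), n_pairs=8000, seed=0)
    assert recommended <= 2 * 25.0


def test_identical_bands_identical_ranges(rng):
    _, per_band = estimate_block_size(noise_stack(rng, sigma_cells=4), n_pairs=8000, seed=0)
    ranges = per_band.set_index("band")["range_m"]
    assert ranges["slope"] == pytest.approx(ranges["tpi"])


def test_smoothed_band_range_matches_empirical_autocorrelation(rng):
    """Oracle: the lag at which the empirical autocorrelation of the known
    smoothed field decays below 0.05, computed directly from the grid."""
    sigma_cells, cell = 5.0, 25.0
    stack = noise_stack(rng, sigma_cells=sigma_cells)
    field = stack["slope"].data
    # direct autocorrelation along rows at increasing lags
    lags = np.arange(1, 60)
    ac = []
    flat = field - field.mean()
    for L in lags:
        a, b = flat[:, :-L].ravel(), flat[:, L:].ravel()
        ac.append(np.corrcoef(a, b)[0, 1])
    ac = np.asarray(ac)
    below = np.flatnonzero(ac < 0.05)
    oracle_range = lags[below[0]] * cell
    recommended, _ = estimate_block_size(stack, n_pairs=20_000, seed=1)
    # the exponential practical range of a Gaussian-shaped variogram
    # systematically overshoots the direct decorrelation lag somewhat
    assert 0.5 * oracle_range <= recommended <= 3.0 * oracle_range


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------

def manual_model(slope_scale=2.0, bias=0.0):
    """A network computing sigmoid(scale * slope_z + bias) exactly:
    h1 = [relu(v), relu(-v)], h2 = [relu(v), relu(-v)], out = scale*(h2_1 - h2_2)."""
    cfg = ModelConfig(units1=2, units2=2, dropout_rate=0.0)
    model = init_network(cfg)
    k = FEATURE_COLUMNS.index("slope")
    W1 = np.zeros((22, 2)); W1[k, 0] = 1.0; W1[k, 1] = -1.0
    W2 = np.array([[1.0, -1.0], [-1.0, 1.0]])
    W3 = np.array([[slope_scale], [-slope_scale]])
    model.params = {"W1": W1, "b1": np.zeros(2), "W2": W2, "b2": np.zeros(2),
                    "W3": W3, "b3": np.array([bias])}
    return model


def importance_data(rng, n=800):
    X = rng.normal(size=(n, 22))
    # valid one-hot blocks so joint permutation preserves the invariant
    X[:, :14] = 0.0
    X[np.arange(n), rng.integers(0, 10, n)] = 1.0
    X[np.arange(n), 10 + rng.integers(0, 4, n)] = 1.0
    return X


def test_unused_feature_has_zero_importance(rng):
    model = manual_model()
    X = importance_data(rng)
    k = FEATURE_COLUMNS.index("slope")
    y = (rng.random(len(X)) < 1 / (1 + np.exp(-2 * X[:, k]))).astype(int)
    res = permutation_importance(model, X, y, n_reps=5, seed=0)
    tbl = res.set_index("group")["importance"]
    assert tbl["windspeed"] == 0.0  # weight exactly zero: no drop at all
    assert tbl["slope"] > 5.0


def test_full_permutation_destroys_discrimination(rng):
    model = manual_model()
    X = importance_data(rng)
    k = FEATURE_COLUMNS.index("slope")
    y = (rng.random(len(X)) < 1 / (1 + np.exp(-2 * X[:, k]))).astype(int)
    groups = {"everything": tuple(FEATURE_COLUMNS)}
    res = permutation_importance(model, X, y, groups=groups, n_reps=10, seed=1)
    auc0 = res.attrs["auc0"]
    drop = res["importance"].iloc[0]
    # permuted AUC ~ 0.5: the drop approaches 100 * (auc0 - 0.5) / auc0
    assert drop == pytest.approx(100 * (auc0 - 0.5) / auc0, abs=5.0)


def test_joint_permutation_preserves_one_hot_rows(rng):
    X = importance_data(rng, n=50)
    perm = np.random.default_rng(0).permutation(len(X))
    Xp = X.copy()
    idx = [FEATURE_COLUMNS.index(c) for c in VARIABLE_GROUPS["landcover"]]
    Xp[:, idx] = X[perm][:, idx]
    np.testing.assert_array_equal(Xp[:, :10].sum(axis=1), 1.0)


def test_importance_seed_invariance_within_mc_error(rng):
    model = manual_model()
    X = importance_data(rng)
    k = FEATURE_COLUMNS.index("slope")
    y = (rng.random(len(X)) < 1 / (1 + np.exp(-2 * X[:, k]))).astype(int)
    r1 = permutation_importance(model, X, y, n_reps=20, seed=1).set_index("group")
    r2 = permutation_importance(model, X, y, n_reps=20, seed=2).set_index("group")
    for g in r1.index:
        se = np.sqrt(r1.loc[g, "sd"] ** 2 + r2.loc[g, "sd"] ** 2) / np.sqrt(20)
        assert abs(r1.loc[g, "importance"] - r2.loc[g, "importance"]) <= 2 * max(se, 0.05)


def test_headline_grouping_covers_all_continuous_vars():
    merged = [c for cols in HEADLINE_GROUPS.values() for c in cols]
    assert set(merged) == set(FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# ICE / PD
# ---------------------------------------------------------------------------

def natural_rows(rng, n=40):
    rows = pd.DataFrame(0.0, index=range(n), columns=list(FEATURE_COLUMNS))
    rows.loc[:, "landcover_1"] = 1.0
    rows.loc[:, "geology_1"] = 1.0
    for v in CONTINUOUS_VARS:
        rows[v] = rng.normal(10.0, 3.0, n)
    return rows


def unit_stats():
    mean = pd.Series({v: 10.0 for v in CONTINUOUS_VARS})
    sd = pd.Series({v: 3.0 for v in CONTINUOUS_VARS})
    return terrain.NormStats(mean=mean, sd=sd)


def test_constant_model_gives_flat_curves(rng):
    model = manual_model(slope_scale=0.0, bias=0.3)
    curves = ice_pd(model, natural_rows(rng), "windspeed", n_grid=7, norm_stats=unit_stats())
    np.testing.assert_allclose(curves.ice, curves.ice[0, 0])
    np.testing.assert_allclose(curves.pd, curves.ice[0, 0])


def test_known_link_recovered_exactly(rng):
    """For a model that is an exact logistic in one variable, every ICE
    curve equals the PD curve equals the link evaluated on the grid."""
    model = manual_model(slope_scale=2.0, bias=-0.5)
    rows = natural_rows(rng)
    stats = unit_stats()
    curves = ice_pd(model, rows, "slope", n_grid=9, norm_stats=stats)
    z = (curves.grid - 10.0) / 3.0
    expected = 1 / (1 + np.exp(-(2.0 * z - 0.5)))
    for i in range(curves.ice.shape[0]):
        np.testing.assert_allclose(curves.ice[i], expected, atol=1e-9)
    np.testing.assert_allclose(curves.pd, expected, atol=1e-9)


def test_pd_is_exact_mean_of_ice(small_table, study_model=None):
    rng = np.random.default_rng(4)
    model = manual_model()
    curves = ice_pd(model, natural_rows(rng), "ibex", n_grid=5, norm_stats=unit_stats())
    np.testing.assert_array_equal(curves.pd, curves.ice.mean(axis=0))


def test_categorical_ice_switches_whole_group(rng):
    model = manual_model()
    curves = ice_pd(model, natural_rows(rng), "landcover", norm_stats=unit_stats())
    assert list(curves.grid) == list(range(1, 11))
    assert curves.ice.shape == (40, 10)


def test_ice_requires_grid_of_two(rng):
    with pytest.raises(ValueError):
        ice_pd(manual_model(), natural_rows(rng), "slope", n_grid=1, norm_stats=unit_stats())
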