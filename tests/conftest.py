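"""Shared fixtures: synthetic worlds at two scales.

``small_world`` is a fast world for unit-level checks; ``study_world`` is
the study-condition run (default configuration, ~50 000 generated fixes)
shared by the slower end-to-end tests, with one classifier trained once per
session.
"""

import numpy as np
import pytest

from lowflight import evalsuite, nnmodel, terrain, trackproc
from lowflight.synthgen import WorldConfig, generate_world

SMALL_CFG = WorldConfig(
    grid_rows=80, grid_cols=80, n_birds=6, fixes_per_bird=500, seed=11
)

STUDY_CFG = WorldConfig(seed=2022)  # defaults: 200x200 grid, 25 birds x 2000 fixes


@pytest.fixture(scope="session")
def small_world():
    return generate_world(SMALL_CFG)


@pytest.fixture(scope="session")
def small_env(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def small_clean(small_world):
    env, fixes, birds, _ = small_world
    return trackproc.clean_tracks(
        fixes, birds, env["elevation"], env["undulation"], env["region_mask"],
        SMALL_CFG.lat0, SMALL_CFG.lon0,
    )


@pytest.fixture(scope="session")
def small_table(small_world, small_clean):
    env = small_world[0]
    cleaned, _ = small_clean
    return terrain.extract_features(cleaned, env)


@pytest.fixture(scope="session")
def study_world():
    return generate_world(STUDY_CFG)


@pytest.fixture(scope="session")
def study_table(study_world):
    env, fixes, birds, _ = study_world
    cleaned, _ = trackproc.clean_tracks(
        fixes, birds, env["elevation"], env["undulation"], env["region_mask"],
        STUDY_CFG.lat0, STUDY_CFG.lon0,
    )
    return terrain.extract_features(cleaned, env)


@pytest.fixture(scope="session")
def study_model(study_table):
    """Default-architecture classifier trained on the study-scale table.

    Returns (model, log, norm_stats, train_mask, val_mask).
    """
    cfg = nnmodel.ModelConfig(seed=0, max_epochs=60)
    train_mask, val_mask = evalsuite.train_val_split(len(study_table), seed=0)
    stats = terrain.fit_normalizer(study_table.loc[train_mask])
    Xtr, ytr = evalsuite.prepare_xy(study_table.loc[train_mask], stats)
    Xva, yva = evalsuite.prepare_xy(study_table.loc[val_mask], stats)
    model = nnmodel.init_network(cfg)
    model.norm_stats = stats
    model, log = nnmodel.train(model, Xtr, ytr, Xva, yva, cfg)
    return model, log, stats, train_mask, val_mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
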