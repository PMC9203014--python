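"""Shared fixtures: toy bin universes and the two seed-pinned training runs.

The collaborative and distance-stratified recovery experiments are expensive
(half a minute each), so they run once per session and are shared by the
tests that inspect them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from chromecho.contact_maps import DistanceRange
from chromecho.genome_io import bin_genome
from chromecho.pipeline import RunParams, load_fixture, run_experiment
from chromecho.synthetic import make_fixture


@pytest.fixture
def toy_bins():
    # 20 bins on cA, 15 on cB
    return bin_genome({"cA": "A" * 4_000, "cB": "A" * 3_000}, width=200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "tiny"
    manifest = make_fixture("tiny", out, seed=0)
    return out, manifest


@pytest.fixture(scope="session")
def collab_run(tmp_path_factory):
    """Full collaborative-recovery experiment at seed 0."""
    out = tmp_path_factory.mktemp("fixtures") / "collab"
    make_fixture("collaborative", out, seed=0)
    params = RunParams(seed=0)
    bundle = load_fixture(out, params)
    results = run_experiment(bundle, params)
    return {"dir": out, "params": params, "bundle": bundle, "results": results}


@pytest.fixture(scope="session")
def dist_run(tmp_path_factory):
    """Distance-stratified retraining on the distance-specific fixture, seed 0."""
    from chromecho.evaluation import distance_experiment
    from chromecho.model import TrainConfig, encode_all, pretrain_encoder

    out = tmp_path_factory.mktemp("fixtures") / "dist"
    make_fixture("distance-specific", out, seed=0)
    params = RunParams(seed=0)
    bundle = load_fixture(out, params)
    cfg = params.model_config(bundle.X.shape[2], bundle.labels.n_features)
    pre_tc = TrainConfig(batch_size=params.batch_size, lr=params.pretrain_lr,
                         epochs=params.pretrain_epochs, seed=params.seed)
    encoder, _head, _ = pretrain_encoder(
        bundle.X, bundle.labels.y, bundle.split_idx["train"],
        bundle.split_idx["validation"], cfg, pre_tc)
    phi = encode_all(encoder, bundle.X)
    ranges = [DistanceRange(1_000, 5_000), DistanceRange(20_000, math.inf)]
    tc = TrainConfig(batch_size=params.batch_size, lr=params.train_lr,
                     epochs=params.train_epochs, seed=params.seed)
    tables = distance_experiment(
        bundle.graph, phi, bundle.labels.y, bundle.labels.features,
        bundle.split_idx, ranges, cfg, tc, params.k_c)
    return {"dir": out, "bundle": bundle, "tables": tables}
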