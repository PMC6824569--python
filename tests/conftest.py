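"""Shared fixtures.

The expensive end-to-end fixtures (trained desk-profile networks) are
session-scoped and shared between the training, evaluation and acceptance
tests so the whole suite stays inside a CI-friendly budget.  The desk profile
here is a grid-64 shrink of the full 512-grid configuration: 90-view x
93-channel sinograms, 8 base channels, depth 2.
"""

from __future__ import annotations

import math

import pytest

from sinoct.geometry import limit_angle, scaled_geometry, subsample_views
from sinoct.network import build_unet
from sinoct.phantoms import analytic_fan_projection, generate_random_phantom, rasterize
from sinoct.training import TrainConfig, initialize_parameters, make_training_pair, train

DESK_GRID = 64
DESK_BASE_CHANNELS = 8
DESK_DEPTH = 2
DESK_SPARSE_FACTOR = 6
DESK_LIMITED_ANGLE = math.radians(120.0)
N_TRAIN = 8
N_TEST = 6


@pytest.fixture(scope="session")
def desk_geometry():
    return scaled_geometry(DESK_GRID)


@pytest.fixture(scope="session")
def desk_train_config():
    # lr scaled up for the short desk schedule; paper-scale defaults are in
    # TrainConfig itself
    return TrainConfig(
        initial_learning_rate=2e-3,
        decay_rate=0.1,
        decay_steps=10,
        outer_iterations=15,
        seed=1,
    )


def _make_item(seed: int, geometry):
    phantom = generate_random_phantom(seed, 5, 12, DESK_GRID)
    complete = analytic_fan_projection(phantom, geometry)
    return {
        "label": f"phantom_{seed:04d}",
        "phantom": phantom,
        "phantom_image": rasterize(phantom).values,
        "complete": complete,
    }


@pytest.fixture(scope="session")
def desk_train_items(desk_geometry):
    return [_make_item(seed, desk_geometry) for seed in range(N_TRAIN)]


@pytest.fixture(scope="session")
def desk_test_items(desk_geometry):
    items = [_make_item(seed, desk_geometry) for seed in range(100, 100 + N_TEST)]
    for item in items:
        item["incomplete"] = {
            "sparse": subsample_views(item["complete"], DESK_SPARSE_FACTOR),
            "limited": limit_angle(item["complete"], DESK_LIMITED_ANGLE),
        }
    return items


def _degrade(item, case):
    if case == "sparse":
        return subsample_views(item["complete"], DESK_SPARSE_FACTOR)
    return limit_angle(item["complete"], DESK_LIMITED_ANGLE)


@pytest.fixture(scope="session")
def desk_pairs(desk_train_items, desk_geometry):
    pairs = {}
    for case in ("sparse", "limited"):
        pairs[case] = [
            make_training_pair(
                _degrade(item, case),
                item["complete"],
                desk_geometry,
                DESK_GRID,
                label=item["label"],
            )
            for item in desk_train_items
        ]
    return pairs


def _train_net(pairs, geometry, config, pooling_mode):
    net = build_unet(
        (geometry.n_views, geometry.n_channels),
        DESK_BASE_CHANNELS,
        DESK_DEPTH,
        pooling_mode,
    )
    initialize_parameters(net, seed=1)
    net, history = train(pairs, net, config)
    return net, history


@pytest.fixture(scope="session")
def trained_sparse_nets(desk_pairs, desk_geometry, desk_train_config):
    """Sparse-condition networks for all three pooling modes (ablation)."""
    nets = {}
    for mode in ("strided_conv", "max_pool", "mean_pool"):
        nets[mode], _ = _train_net(
            desk_pairs["sparse"], desk_geometry, desk_train_config, mode
        )
    return nets


@pytest.fixture(scope="session")
def trained_limited_net(desk_pairs, desk_geometry, desk_train_config):
    net, _ = _train_net(
        desk_pairs["limited"], desk_geometry, desk_train_config, "strided_conv"
    )
    return net
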