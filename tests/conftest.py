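"""Shared fixtures: phantom banks and trained tiny networks.

The heavy artifacts (20-phantom bank, trained regression and segmentation
networks) are session-scoped so the end-to-end and evaluation tests reuse a
single training run.
"""

import numpy as np
import pytest

from corsurf.phantom import (
    WM_LEFT,
    WM_RIGHT,
    PhantomParams,
    generate_phantom,
)
from corsurf.unet import (
    NetConfig,
    TrainConfig,
    build_network,
    levelset_to_target,
    normalize_intensity,
    train,
)

N_BANK = 20
N_TRAIN = 16


@pytest.fixture(scope="session")
def default_params():
    return PhantomParams()


@pytest.fixture(scope="session")
def phantom_bank(default_params):
    """Seeds 0..19 at the default study conditions (48^3 grid, 1 mm)."""
    return [generate_phantom(default_params, seed=s) for s in range(N_BANK)]


@pytest.fixture(scope="session")
def one_phantom(phantom_bank):
    return phantom_bank[1]


@pytest.fixture(scope="session")
def two_hemi_params():
    return PhantomParams(grid_shape=(96, 48, 48), n_hemispheres=2)


@pytest.fixture(scope="session")
def two_hemi_bank(two_hemi_params):
    """Seeds 100..106; [:6] are training subjects, [6] is held out."""
    return [generate_phantom(two_hemi_params, seed=100 + s) for s in range(7)]


def segmentation_target(ph):
    """Class labels: 0 background, 1 left WM, 2 right WM."""
    t = np.zeros(ph.tissue_labels.shape, dtype=np.int16)
    t[ph.tissue_labels.data == WM_LEFT] = 1
    t[ph.tissue_labels.data == WM_RIGHT] = 2
    return ph.tissue_labels.like(t)


@pytest.fixture(scope="session")
def regression_model(phantom_bank):
    """Tiny level-set regression U-Net trained on the first 16 bank phantoms."""
    dataset = [
        (
            normalize_intensity(ph.image),
            levelset_to_target(ph.white_levelset),
            ph.wm_mask("left"),
        )
        for ph in phantom_bank[:N_TRAIN]
    ]
    model = build_network(NetConfig.tiny(), seed=0)
    tc = TrainConfig(patches_per_epoch=8, max_epochs=60, convergence_window=50, seed=0)
    return train(model, dataset, tc)


@pytest.fixture(scope="session")
def segmentation_model(two_hemi_bank):
    """Tiny hemispheric WM segmentation U-Net (6 two-hemisphere phantoms)."""
    dataset = [
        (normalize_intensity(ph.image), segmentation_target(ph))
        for ph in two_hemi_bank[:6]
    ]
    model = build_network(
        NetConfig.tiny(head="segmentation", in_channels=1, out_channels=3), seed=0
    )
    tc = TrainConfig(patches_per_epoch=8, max_epochs=40, convergence_window=35, seed=0)
    return train(model, dataset, tc)
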