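import numpy as np
import pytest

from islesar import (
    MatrixSimConfig,
    ModelForm,
    PresenceAbsenceMatrix,
    SARParams,
    SARSimConfig,
    simulate_matrix,
    simulate_sar,
)

# archipelago-like three-segment truth: near-flat small-island regime,
# moderate middle slope, steep speciation-regime slope
REPTILE_LIKE_TRUTH = SARParams(
    intercepts=(0.244, 0.280, 0.031),
    slopes=(0.080, 0.297, 0.421),
    thresholds=(-0.603, 0.946),
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160705)


@pytest.fixture
def hand_matrix():
    """3x4 matrix whose NODF (700/9) was pre-computed by the pairwise
    brute-force oracle (and cross-checked against vegan::nestednodf)."""
    return PresenceAbsenceMatrix.from_cells(
        [[1, 1, 1, 1], [1, 1, 0, 0], [1, 0, 1, 0]]
    )


@pytest.fixture
def staircase_10():
    return simulate_matrix(MatrixSimConfig(10, 10, structure="perfectly_nested"))


@pytest.fixture
def checkerboard_6():
    return simulate_matrix(MatrixSimConfig(6, 6, structure="checkerboard"))


def noisy_sar(form: ModelForm, params: SARParams, n=40, noise=0.08, seed=0,
              log_range=(-2.0, 3.0)):
    return simulate_sar(
        SARSimConfig(
            n_islands=n,
            true_form=form,
            true_params=params,
            log_area_range=log_range,
            noise_sd=noise,
            seed=seed,
        )
    )
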