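"""Shared fixtures: one fixed acquisition geometry for the unit tests and the
session-scoped desk-scale corpus + trained network reused by the training,
SNR and acceptance tests (training is the expensive step, so it runs once)."""

from __future__ import annotations

import pytest

from mskrecon.sampling import make_regular_mask
from mskrecon.synthetic import (
    AcquisitionSpec,
    knee_like_phantom,
    make_training_set,
    render_phantom,
    simulate_acquisition,
    simulate_bias_field,
    simulate_sensitivities,
)
from mskrecon.varnet import train

MATRIX = (96, 96)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def sens(acq):
    return simulate_sensitivities(acq, MATRIX)


@pytest.fixture(scope="session")
def bias(acq):
    return simulate_bias_field(acq, MATRIX)


@pytest.fixture(scope="session")
def knee_image():
    return render_phantom(knee_like_phantom(MATRIX))


@pytest.fixture(scope="session")
def knee_truth(knee_image, bias):
    """The biased object the SENSE model actually sees."""
    return bias.field * knee_image


def acquire(knee_image, sens, bias, R=4, acs=16, sigma=0.0, seed=1, n_pe=96):
    pattern = make_regular_mask(n_pe, R, acs, n_ro=MATRIX[1])
    return simulate_acquisition(knee_image, sens, bias, pattern, sigma, seed)


@pytest.fixture(scope="session")
def noiseless_r4(knee_image, sens, bias):
    return acquire(knee_image, sens, bias, R=4, acs=16, sigma=0.0)


@pytest.fixture(scope="session")
def desk_corpus():
    """The study conditions: 200 synthetic 96x96 8-coil phantoms at R = 4
    with a 16-line ACS block and ~30 dB input SNR."""
    return make_training_set(200, seed=0)


@pytest.fixture(scope="session")
def trained(desk_corpus):
    """Desk-scale network (2 pre / 4 main / 1 post) trained for 20 epochs."""
    params, history = train(desk_corpus, epochs=20, seed=0)
    return params, history
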