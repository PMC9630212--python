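"""Shared fixtures: synthetic inputs and expensive shared computations."""

from __future__ import annotations

import numpy as np
import pytest

from cborient import (
    FiberFieldParams,
    MeasurementConfig,
    generate_fiber_image,
    measure_grey_image,
    oracle_spectral_anisotropy,
)
from cborient.preprocess import GreyImage


def make_grating(angle_deg: float, period: float = 8.0, n: int = 256,
                 amplitude: float = 127.5) -> GreyImage:
    """Pure sinusoidal grating; angle is the propagation direction (deg)."""
    ys, xs = np.mgrid[0:n, 0:n]
    t = np.deg2rad(angle_deg)
    phase = 2.0 * np.pi * (xs * np.cos(t) + ys * np.sin(t)) / period
    return GreyImage(pixels=127.5 + amplitude * np.sin(phase), depth="8bit")


@pytest.fixture(scope="session")
def hann_config() -> MeasurementConfig:
    return MeasurementConfig(window="hann")


@pytest.fixture(scope="session")
def kappa_sweep(hann_config):
    """Mean pipeline index and spectral-moment oracle per concentration.

    20 independent fields per κ ∈ {0, 1, 2, 4, 8}; shared between the
    isotropy/parallel-limit and monotonicity checks because it is the
    most expensive synthetic computation in the suite.
    """
    kappas = (0.0, 1.0, 2.0, 4.0, 8.0)
    n_seeds = 20
    index_means, oracle_means = [], []
    for kappa in kappas:
        idx, ora = [], []
        for seed in range(n_seeds):
            grey, _ = generate_fiber_image(
                FiberFieldParams(kappa=kappa, seed=seed)
            )
            idx.append(measure_grey_image(grey, hann_config).index)
            ora.append(oracle_spectral_anisotropy(grey))
        index_means.append(float(np.mean(idx)))
        oracle_means.append(float(np.mean(ora)))
    return {"kappas": kappas, "index_means": index_means, "oracle_means": oracle_means}
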