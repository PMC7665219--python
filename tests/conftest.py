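"""Shared fixtures: expensive simulations are solved once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lsrmm import forward, io, matrix, solver

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def spectral_from_stack(stack):
    """Descan -> assemble -> crop to scan lattice -> k-space."""
    lab = matrix.descan_to_lab(stack)
    return matrix.to_spectral(matrix.crop_to_scan_grid(matrix.assemble_matrix(lab)))


def crop_to_coarse(phase_fine: np.ndarray) -> np.ndarray:
    """Central crop of a fine-grid pupil map onto the scan-lattice k-grid."""
    n = phase_fine.shape[0]
    q = n // 4
    return phase_fine[q : n - q, q : n - q]


@pytest.fixture(scope="session")
def optics16():
    return forward.OpticsConfig.nyquist(0.9, 1.0, 16)


@pytest.fixture(scope="session")
def optics32():
    return forward.OpticsConfig.nyquist(0.9, 1.0, 32)


@pytest.fixture(scope="session")
def optics64():
    return forward.OpticsConfig.nyquist(0.9, 1.0, 64)


@pytest.fixture(scope="session")
def star_fixture():
    return io.make_fixture("siemens_star_smallgrid", seed=0)


@pytest.fixture(scope="session")
def star_solved(star_fixture):
    """Noise-free Siemens-star fixture solved by global CLASS."""
    sm = spectral_from_stack(star_fixture["stack"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = solver.run_class(sm, max_iter=100)
    return {"sm": sm, "result": result, **star_fixture}


@pytest.fixture(scope="session")
def noisy_solved():
    fx = io.make_fixture("noisy_ssmr008", seed=0)
    sm = spectral_from_stack(fx["stack"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = solver.run_class(sm, max_iter=200)
    return {"sm": sm, "result": result, **fx}


@pytest.fixture(scope="session")
def two_patch_fixture():
    return io.make_fixture("two_patch_aniso", seed=0)
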