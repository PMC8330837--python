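"""Shared fixtures: a small, fast microscope configuration and stacks.

The small bench keeps the reference optics (532 nm, 0.1 NA, 3.45 µm camera
pixels at 2x) but uses a 7x7 LED corner of the matrix and 16x16 raw images
at 2x upsampling, so a full measurement stack is 49 images of 16x16 and a
reconstruction runs in well under a second.
"""

from __future__ import annotations

import numpy as np
import pytest

import fptycho as fp


@pytest.fixture(scope="session")
def small_cfg() -> fp.SystemConfig:
    return fp.SystemConfig(led_rows=7, led_cols=7, lowres_size=16,
                           upsample_factor=2)


@pytest.fixture(scope="session")
def small_basis(small_cfg) -> fp.ZernikeBasis:
    return fp.basis_from_config(small_cfg, 10)


@pytest.fixture(scope="session")
def defocus_coeffs(small_basis) -> fp.CoeffVector:
    values = np.zeros(small_basis.n_modes)
    values[4] = -1.48          # defocus Z2^0, 50 um at 532 nm / 0.1 NA
    return fp.CoeffVector(values, list(small_basis.index_scheme))


@pytest.fixture(scope="session")
def zero_coeffs(small_basis) -> fp.CoeffVector:
    return fp.CoeffVector(np.zeros(small_basis.n_modes),
                          list(small_basis.index_scheme))


@pytest.fixture(scope="session")
def small_phantom(small_cfg) -> fp.ComplexField:
    return fp.make_phantom(small_cfg.highres_size, seed=3)


@pytest.fixture(scope="session")
def small_stack(small_cfg, defocus_coeffs, small_phantom) -> fp.MeasurementStack:
    """Noiseless defocus-aberrated stack on the small bench."""
    return fp.simulate_dataset(small_phantom, defocus_coeffs, small_cfg)


@pytest.fixture(scope="session")
def small_stack_ideal(small_cfg, zero_coeffs, small_phantom) -> fp.MeasurementStack:
    """Noiseless aberration-free stack on the small bench."""
    return fp.simulate_dataset(small_phantom, zero_coeffs, small_cfg)
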