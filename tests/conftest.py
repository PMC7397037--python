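"""Shared fixtures: small simulated images, disc masks, oracle helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from cgdist.segment import mask_from_truth
from cgdist.simulate import EquatorialSimConfig, disc_mask, simulate_equatorial


def make_disc_mask(radius_px: int, pad: int = 10) -> np.ndarray:
    """Boolean disc: pixel centres within radius of the image centre."""
    n = 2 * radius_px + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = n / 2 - 0.5
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2


@pytest.fixture
def disc_mask_200():
    return mask_from_truth(make_disc_mask(200), pixel_size=1.0)


@pytest.fixture
def small_eq_config():
    """A quick-to-render equatorial section with dense granulation."""
    return EquatorialSimConfig(
        image_size=400,
        pixel_size=0.4,
        oocyte_radius=60.0,
        n_granules=1500,
        peripheral_bias=0.3,
        granule_sigma=0.5,
        granule_amplitude=50.0,
        background=5.0,
        noise_model="gaussian",
        noise_sd=2.0,
        seed=7,
    )


@pytest.fixture
def small_eq_image(small_eq_config):
    img, truth = simulate_equatorial(small_eq_config)
    return img, truth, disc_mask(small_eq_config)


def expected_icgd_oracle(cfg: EquatorialSimConfig, partition) -> float:
    """Closed-form expectation of I_cgd under the generative model.

    Integrates the granule placement density (uniform disc / 20%-area
    annulus mixture) against the Gaussian spot profile via the Rice CDF,
    giving the exact expected pixel value at every pixel centre — no
    simulation involved — then averages over the supplied partition's
    zones.  Independent of the simulator's sampling and rendering code.
    """
    from scipy.stats import rice

    n, ps, R = cfg.image_size, cfg.pixel_size, cfg.oocyte_radius
    sig = cfg.granule_sigma
    c = n * ps / 2
    coords = (np.arange(n) + 0.5) * ps - c
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(xx, yy)
    F_R = rice.cdf(R, b=r / sig, scale=sig)
    F_in = rice.cdf(np.sqrt(0.8) * R, b=r / sig, scale=sig)
    p, N, A = cfg.peripheral_bias, cfg.n_granules, cfg.granule_amplitude
    density_um2 = (1 - p) * N / (np.pi * R**2) * F_R + p * N / (
        0.2 * np.pi * R**2
    ) * (F_R - F_in)
    e_img = cfg.background + A * 2 * np.pi * (sig / ps) ** 2 * density_um2 * ps**2
    return float(e_img[partition.peripheral].mean() / e_img[partition.central].mean())
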