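"""Replicate simulation studies: bias ordering, power, type-I error,
density recovery.

These drive the whole pipeline (simulate -> mask -> partition -> I_cgd ->
t-test, or simulate -> detect -> windows -> density) over many replicate
cohorts.  They run on scaled-down geometry (small images, moderate granule
counts) so that hundreds of replicates complete in minutes; the granule
*placement model* and every estimator are identical to the full-scale
defaults, only the frame and counts shrink.  Ground-truth disc masks are
used for the zonal studies so they measure the statistic, not the
segmenter (which has its own accuracy suite).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import derive_seed
from .segment import mask_from_truth
from .simulate import (
    EquatorialSimConfig,
    SurfaceSimConfig,
    disc_mask,
    iter_cohort,
    simulate_equatorial,
    simulate_surface,
)
from .spots import detect_spots, measure_density, place_density_windows
from .stats import compare_groups
from .zonal import compute_icgd, partition_by_area

#: Scaled-down equatorial geometry for replicate studies (~2 ms/oocyte).
STUDY_EQ = EquatorialSimConfig(
    image_size=110,
    pixel_size=0.5,
    oocyte_radius=23.0,
    n_granules=250,
    peripheral_bias=0.0,
    granule_sigma=0.6,
    granule_amplitude=40.0,
    background=4.0,
    noise_model="gaussian",
    noise_sd=1.5,
    seed=0,
)

#: Even smaller geometry for the 1000-replicate null study.
STUDY_EQ_SMALL = dataclasses.replace(
    STUDY_EQ, image_size=80, oocyte_radius=16.5, n_granules=150
)

#: Surface-field geometry for density recovery (SNR = amplitude/noise_sd =
#: 7.5).  Granule sigma sits at the small end of the real size range so
#: individual granules stay optically resolvable at the densities the
#: counting protocol reports (up to ~100 per 100 µm²).
STUDY_SURFACE = SurfaceSimConfig(
    image_size=1000,
    pixel_size=0.1,
    target_density=60.0,
    granule_sigma=0.10,
    granule_amplitude=60.0,
    background=5.0,
    noise_model="gaussian",
    noise_sd=8.0,
    seed=0,
)

#: Detection scales (µm) for the surface study, bracketing its granule sigma.
STUDY_SCALES = [0.10, 0.12, 0.15]

#: Demonstration configs, illustration only: peripheral biases solved from
#: the closed-form expected-image model so the cohort-mean I_cgd lands near
#: the 1.5 (low meiotic competence) and 2.2 (high competence) regime at the
#: full-scale default geometry.  They do not reproduce any real dataset.
DEMO_LOW_COMPETENCE = EquatorialSimConfig(peripheral_bias=0.2021)
DEMO_HIGH_COMPETENCE = EquatorialSimConfig(peripheral_bias=0.4475)


def icgd_from_config(cfg: EquatorialSimConfig) -> float:
    """Simulate one equatorial section and measure I_cgd on its true disc."""
    img, _ = simulate_equatorial(cfg)
    mask = mask_from_truth(disc_mask(cfg), cfg.pixel_size)
    part = partition_by_area(mask)
    return compute_icgd(img, part).icgd


def cohort_icgd(
    base_a: EquatorialSimConfig,
    base_b: EquatorialSimConfig,
    n_per_group: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """I_cgd values for a jittered two-group cohort, measured on true masks."""
    values: dict[str, list[float]] = {"a": [], "b": []}
    for _, group, img, truth in iter_cohort({"a": base_a, "b": base_b}, n_per_group, seed):
        cfg = EquatorialSimConfig(**truth.config)
        mask = mask_from_truth(disc_mask(cfg), cfg.pixel_size)
        part = partition_by_area(mask)
        values[group].append(compute_icgd(img, part).icgd)
    return np.asarray(values["a"]), np.asarray(values["b"])


def bias_ordering_study(
    biases: tuple[float, ...] = (0.0, 0.4, 0.8),
    n_oocytes: int = 30,
    n_replicates: int = 100,
    seed: int = 0,
    base: EquatorialSimConfig = STUDY_EQ,
) -> pd.DataFrame:
    """Mean I_cgd per peripheral bias over replicate cohorts.

    Returns one row per (bias, replicate) with the cohort-mean I_cgd.
    """
    rows = []
    for p in biases:
        cfg = dataclasses.replace(base, peripheral_bias=p)
        for rep in range(n_replicates):
            rng = np.random.default_rng(derive_seed(seed, f"order:{p}:{rep}"))
            vals = []
            for _ in range(n_oocytes):
                oc = dataclasses.replace(cfg, seed=int(rng.integers(0, 2**31)))
                vals.append(icgd_from_config(oc))
            rows.append({"bias": p, "replicate": rep, "mean_icgd": float(np.mean(vals))})
    return pd.DataFrame(rows)


def power_study(
    p_a: float = 0.2,
    p_b: float = 0.8,
    n_per_group: int = 30,
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    base: EquatorialSimConfig = STUDY_EQ,
) -> float:
    """Fraction of replicate cohorts where the bias contrast is declared
    significant (pooled t-test at ``alpha``)."""
    cfg_a = dataclasses.replace(base, peripheral_bias=p_a)
    cfg_b = dataclasses.replace(base, peripheral_bias=p_b)
    hits = 0
    for rep in range(n_replicates):
        a, b = cohort_icgd(cfg_a, cfg_b, n_per_group, derive_seed(seed, f"power:{rep}"))
        if compare_groups(a, b, alpha=alpha).significant:
            hits += 1
    return hits / n_replicates


def type1_study(
    n_per_group: int = 30,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    base: EquatorialSimConfig = STUDY_EQ_SMALL,
) -> float:
    """Empirical type-I error: equal-config groups, fraction rejected."""
    hits = 0
    for rep in range(n_replicates):
        a, b = cohort_icgd(base, base, n_per_group, derive_seed(seed, f"null:{rep}"))
        if compare_groups(a, b, alpha=alpha).significant:
            hits += 1
    return hits / n_replicates


def measure_surface_density(
    cfg: SurfaceSimConfig,
    window_um: float = 30.0,
    scales: list[float] | None = None,
    response_threshold: float = 11.0,
    window_seed: int = 0,
) -> float:
    """Detect spots on one surface field and average three window densities."""
    img, _ = simulate_surface(cfg)
    if scales is None:
        scales = STUDY_SCALES
    spotset = detect_spots(img, None, scales=scales, response_threshold=response_threshold)
    region = np.ones(img.shape, bool)
    windows = place_density_windows(
        region, img.pixel_size, window_um=window_um, n_windows=3, seed=window_seed
    )
    return measure_density(spotset, windows).oocyte_density


def density_recovery_study(
    densities: tuple[float, ...] = (20, 40, 60, 80, 100),
    n_fields: int = 50,
    seed: int = 0,
    base: SurfaceSimConfig = STUDY_SURFACE,
    window_um: float = 30.0,
    response_threshold: float = 11.0,
) -> pd.DataFrame:
    """True vs measured density over ``n_fields`` fields spanning the
    density range; one row per field with the relative error."""
    rows = []
    for k in range(n_fields):
        d = densities[k % len(densities)]
        cfg = dataclasses.replace(
            base, target_density=float(d), seed=derive_seed(seed, f"dens:{k}")
        )
        _, truth = simulate_surface(cfg)
        measured = measure_surface_density(
            cfg,
            window_um=window_um,
            response_threshold=response_threshold,
            window_seed=derive_seed(seed, f"win:{k}"),
        )
        true_d = truth.true_density_per_100um2
        rows.append(
            {
                "field": k,
                "target_density": float(d),
                "true_density": true_d,
                "measured_density": measured,
                "rel_error": abs(measured - true_d) / true_d if true_d else np.nan,
            }
        )
    return pd.DataFrame(rows)
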