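"""Synthetic confocal-section generator with exact ground truth.

Two geometries are emulated:

* **Equatorial sections** — a disc-shaped ooplasm of radius ``R`` with
  ``n_granules`` bright Gaussian spots.  A fraction ``p`` of the granules
  (the peripheral bias) is placed uniformly in the outer annulus holding
  20% of the disc area (inner radius ``sqrt(0.8) * R``); the remainder is
  uniform over the whole disc.  ``p = 0`` is the fully uniform immature
  pattern, ``p = 1`` the fully cortical mature pattern.
* **Cortical-surface fields** — a flat field with spots placed as a
  homogeneous Poisson process at a target density in granules per 100 µm²,
  emulating an optical section tangential to the apical pole.

Spots are rendered as isotropic Gaussians sampled at pixel centres
(centre-value approximation); sub-pixel spot centres are kept in the
ground truth in µm.  Granule sigma below one pixel is rejected — it would
alias.  Granules may overlap; there is no excluded-volume rule.

Ground truth records every centre, the per-granule radial fraction r/R
(equatorial), the exact count, and the realized density (surface), so
every downstream estimator can be scored against the generative model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .config import derive_seed
from .errors import GeometryError, ValidationError
from .image import ConfocalImage, write_image

PERIPHERAL_AREA_FRACTION = 0.2  # outer annulus holds 20% of the disc area
INNER_RADIUS_FRACTION = np.sqrt(1.0 - PERIPHERAL_AREA_FRACTION)  # sqrt(0.8)

NoiseModel = Literal["none", "gaussian", "poisson"]


@dataclass(frozen=True)
class EquatorialSimConfig:
    """Generative parameters for one equatorial optical section.

    ``peripheral_bias`` is the fraction of granules forced into the outer
    20%-area annulus; defaults follow realistic porcine-oocyte confocal
    geometry (120 µm oocyte, 0.2 µm pixels, granule sigma 0.25 µm for
    granules 0.2-0.6 µm in diameter).
    """

    image_size: int = 680
    oocyte_radius: float = 60.0
    pixel_size: float = 0.2
    n_granules: int = 2000
    peripheral_bias: float = 0.5
    granule_sigma: float = 0.25
    granule_amplitude: float = 60.0
    background: float = 5.0
    noise_model: NoiseModel = "gaussian"
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_common(self)
        if not 0.0 <= self.peripheral_bias <= 1.0:
            raise ValidationError(
                f"peripheral_bias must be in [0,1], got {self.peripheral_bias}"
            )
        half_um = self.image_size * self.pixel_size / 2.0
        if self.oocyte_radius + 2.0 * self.granule_sigma > half_um:
            raise GeometryError(
                f"oocyte radius {self.oocyte_radius} µm + 2 sigma margin does not "
                f"fit in a {self.image_size}x{self.image_size} px frame "
                f"({2 * half_um:.1f} µm across)"
            )


@dataclass(frozen=True)
class SurfaceSimConfig:
    """Generative parameters for one cortical-surface field.

    ``target_density`` is in granules per 100 µm²; placement is a
    homogeneous Poisson process over the field.
    """

    image_size: int = 500
    pixel_size: float = 0.2
    target_density: float = 60.0
    granule_sigma: float = 0.25
    granule_amplitude: float = 60.0
    background: float = 5.0
    noise_model: NoiseModel = "gaussian"
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_common(self)
        if self.target_density < 0:
            raise ValidationError("target_density must be >= 0")


def _validate_common(cfg) -> None:
    if cfg.image_size < 16:
        raise ValidationError("image_size must be >= 16 px")
    if cfg.pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0")
    if cfg.granule_sigma < cfg.pixel_size:
        raise ValidationError(
            f"granule_sigma {cfg.granule_sigma} µm is below one pixel "
            f"({cfg.pixel_size} µm): rendering would alias"
        )
    if cfg.noise_model not in ("none", "gaussian", "poisson"):
        raise ValidationError(f"unknown noise_model {cfg.noise_model!r}")
    if cfg.background < 0 or cfg.granule_amplitude < 0:
        raise ValidationError("background and amplitude must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact generative record for one simulated section."""

    centers_um: np.ndarray  # (n, 2) array of (x, y) in µm
    radial_fraction: np.ndarray | None  # r/R per granule (equatorial only)
    true_count: int
    true_density_per_100um2: float | None  # surface only
    config: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers_um", np.atleast_2d(np.asarray(self.centers_um, float)))


def render_spots(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    """Render Gaussian spots at (row, col) centres onto a zero canvas.

    Each spot contributes ``amplitude * exp(-d^2 / (2 sigma^2))`` evaluated
    at pixel centres, truncated at 4 sigma.
    """
    canvas = np.zeros(shape, dtype=float)
    if len(centers_px) == 0:
        return canvas
    r = int(np.ceil(4.0 * sigma_px))
    nrow, ncol = shape
    for row_c, col_c in np.atleast_2d(centers_px):
        i0, i1 = int(np.floor(row_c)) - r, int(np.floor(row_c)) + r + 1
        j0, j1 = int(np.floor(col_c)) - r, int(np.floor(col_c)) + r + 1
        i0c, i1c = max(i0, 0), min(i1, nrow)
        j0c, j1c = max(j0, 0), min(j1, ncol)
        if i0c >= i1c or j0c >= j1c:
            continue
        ii = np.arange(i0c, i1c, dtype=float)[:, None]
        jj = np.arange(j0c, j1c, dtype=float)[None, :]
        d2 = (ii - row_c) ** 2 + (jj - col_c) ** 2
        canvas[i0c:i1c, j0c:j1c] += amplitude * np.exp(-d2 / (2.0 * sigma_px**2))
    return canvas


def _apply_noise(signal: np.ndarray, cfg, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_model == "none":
        out = signal
    elif cfg.noise_model == "gaussian":
        out = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    else:  # poisson: signal is the photon mean
        out = rng.poisson(np.clip(signal, 0, None)).astype(float)
    return np.clip(out, 0.0, None)


def _um_to_px(xy_um: np.ndarray, pixel_size: float) -> np.ndarray:
    """(x, y) µm -> (row, col) px; pixel (i, j) centre sits at
    ((j + .5) ps, (i + .5) ps)."""
    xy = np.atleast_2d(xy_um)
    rows = xy[:, 1] / pixel_size - 0.5
    cols = xy[:, 0] / pixel_size - 0.5
    return np.column_stack([rows, cols])


def disc_mask(config: EquatorialSimConfig) -> np.ndarray:
    """The true ooplasm mask: pixel centres within the generative disc."""
    n, ps = config.image_size, config.pixel_size
    c_um = n * ps / 2.0
    coords = (np.arange(n) + 0.5) * ps - c_um
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    return xx**2 + yy**2 <= config.oocyte_radius**2


def simulate_equatorial(config: EquatorialSimConfig) -> tuple[ConfocalImage, GroundTruth]:
    """Simulate one equatorial section; identical config+seed reproduces
    the image bit-exactly."""
    rng = np.random.default_rng(config.seed)
    n = config.n_granules
    R = config.oocyte_radius
    n_annulus = int(round(config.peripheral_bias * n))
    n_uniform = n - n_annulus

    u_ann = rng.uniform(size=n_annulus)
    r_ann = R * np.sqrt((1.0 - PERIPHERAL_AREA_FRACTION) + PERIPHERAL_AREA_FRACTION * u_ann)
    u_uni = rng.uniform(size=n_uniform)
    r_uni = R * np.sqrt(u_uni)
    radii = np.concatenate([r_ann, r_uni])
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)

    c_um = config.image_size * config.pixel_size / 2.0
    xs = c_um + radii * np.cos(theta)
    ys = c_um + radii * np.sin(theta)
    centers_um = np.column_stack([xs, ys]) if n else np.empty((0, 2))

    signal = render_spots(
        (config.image_size, config.image_size),
        _um_to_px(centers_um, config.pixel_size) if n else np.empty((0, 2)),
        config.granule_sigma / config.pixel_size,
        config.granule_amplitude,
    )
    signal += config.background
    pixels = _apply_noise(signal, config, rng)
    image = ConfocalImage(pixels=pixels, pixel_size=config.pixel_size)
    truth = GroundTruth(
        centers_um=centers_um,
        radial_fraction=radii / R if n else np.empty(0),
        true_count=n,
        true_density_per_100um2=None,
        config=dataclasses.asdict(config),
    )
    return image, truth


def simulate_surface(config: SurfaceSimConfig) -> tuple[ConfocalImage, GroundTruth]:
    """Simulate one cortical-surface field with Poisson spot placement."""
    rng = np.random.default_rng(config.seed)
    side_um = config.image_size * config.pixel_size
    area_um2 = side_um**2
    mean_count = config.target_density * area_um2 / 100.0
    count = int(rng.poisson(mean_count))
    xs = rng.uniform(0.0, side_um, size=count)
    ys = rng.uniform(0.0, side_um, size=count)
    centers_um = np.column_stack([xs, ys]) if count else np.empty((0, 2))

    signal = render_spots(
        (config.image_size, config.image_size),
        _um_to_px(centers_um, config.pixel_size) if count else np.empty((0, 2)),
        config.granule_sigma / config.pixel_size,
        config.granule_amplitude,
    )
    signal += config.background
    pixels = _apply_noise(signal, config, rng)
    image = ConfocalImage(pixels=pixels, pixel_size=config.pixel_size)
    truth = GroundTruth(
        centers_um=centers_um,
        radial_fraction=None,
        true_count=count,
        true_density_per_100um2=count / area_um2 * 100.0,
        config=dataclasses.asdict(config),
    )
    return image, truth


def jitter_config(base, rng: np.random.Generator):
    """Per-oocyte biological variability: radius ±10%, granule count ±20%
    (equatorial) or target density ±20% (surface), fresh seed."""
    seed = int(rng.integers(0, 2**31))
    if isinstance(base, EquatorialSimConfig):
        return dataclasses.replace(
            base,
            oocyte_radius=base.oocyte_radius * rng.uniform(0.9, 1.1),
            n_granules=max(1, int(round(base.n_granules * rng.uniform(0.8, 1.2)))),
            seed=seed,
        )
    return dataclasses.replace(
        base,
        target_density=base.target_density * rng.uniform(0.8, 1.2),
        seed=seed,
    )


def iter_cohort(
    group_configs: dict[str, EquatorialSimConfig | SurfaceSimConfig],
    n_per_group: int,
    seed: int,
) -> Iterator[tuple[str, str, ConfocalImage, GroundTruth]]:
    """Yield (image_id, group, image, truth) for a jittered cohort.

    Deterministic for a given seed; used both by the on-disk cohort writer
    and by in-memory replicate studies.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    for label in sorted(group_configs):
        base = group_configs[label]
        rng = np.random.default_rng(derive_seed(seed, f"cohort:{label}"))
        for k in range(n_per_group):
            cfg = jitter_config(base, rng)
            if isinstance(cfg, EquatorialSimConfig):
                img, truth = simulate_equatorial(cfg)
            else:
                img, truth = simulate_surface(cfg)
            yield f"{label}_{k:04d}", label, img, truth


def simulate_cohort(
    group_configs: dict[str, EquatorialSimConfig | SurfaceSimConfig],
    n_per_group: int,
    seed: int,
    out_dir: str | Path,
    write_truth_masks: bool = True,
) -> pd.DataFrame:
    """Write a cohort dataset: one TIFF per oocyte, a ground-truth CSV and
    a manifest mapping file -> group -> truth.  For equatorial cohorts the
    generative disc is also written as a 0/255 mask TIFF (``mask_path``
    column) so measurements can be made on the true ooplasm as well as on
    the segmented one.  Refuses to overwrite an existing manifest."""
    from .image import write_mask  # local import avoids cycle at module load

    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists():
        raise ValidationError(f"refusing to overwrite existing manifest {manifest_path}")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    manifest_rows, truth_rows = [], []
    for image_id, group, img, truth in iter_cohort(group_configs, n_per_group, seed):
        rel = f"images/{image_id}.tif"
        write_image(img, out_dir / rel)
        mask_rel = ""
        if write_truth_masks and truth.radial_fraction is not None:
            cfg = EquatorialSimConfig(**truth.config)
            mask_rel = f"masks/{image_id}_mask.tif"
            write_mask(disc_mask(cfg), out_dir / mask_rel)
        manifest_rows.append(
            {
                "image_id": image_id,
                "group": group,
                "path": rel,
                "mask_path": mask_rel,
                "pixel_size": img.pixel_size,
                "true_count": truth.true_count,
            }
        )
        equatorial = truth.radial_fraction is not None
        for i in range(truth.true_count):
            truth_rows.append(
                {
                    "image_id": image_id,
                    "group": group,
                    "x_um": truth.centers_um[i, 0],
                    "y_um": truth.centers_um[i, 1],
                    "radial_fraction": truth.radial_fraction[i] if equatorial else "",
                    "true_count": truth.true_count,
                    "true_density_per_100um2": (
                        "" if equatorial else truth.true_density_per_100um2
                    ),
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest
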