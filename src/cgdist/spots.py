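"""Granule spot detection and CG density per 100 µm².

Detection is multi-scale Laplacian-of-Gaussian: the image is filtered with
scale-normalized LoG kernels at each requested scale (sigma in µm, chosen
around the granule size range 0.2-0.6 µm diameter, sigma = diameter/2.355),
3D local maxima above a response threshold are kept, and greedy
non-maximum suppression at radius sqrt(2)*scale removes duplicate
responses.  A Gaussian spot of amplitude A detected at its own scale has
normalized response A/2, which anchors threshold choices.

Density follows the three-window protocol: three disjoint axis-aligned
windows are placed (seeded, reproducible) inside the sampling region, spot
centres are counted per window with half-open bounds (a centre on a shared
edge lands in exactly one window), and the per-oocyte density is the
unweighted mean of the three window densities in granules per 100 µm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import GeometryError, ResolutionError, ValidationError
from .image import ConfocalImage

GRANULE_DIAMETER_RANGE_UM = (0.2, 0.6)
FWHM_TO_SIGMA = 2.355


def default_scales(pixel_size: float) -> list[float]:
    """LoG sigmas (µm) spanning the granule diameter range, floored at one
    pixel so the smallest scale stays resolvable."""
    lo, hi = (d / FWHM_TO_SIGMA for d in GRANULE_DIAMETER_RANGE_UM)
    lo = max(lo, pixel_size)
    if hi < lo:
        hi = lo
    return [round(s, 4) for s in np.linspace(lo, hi, 3)]


@dataclass(frozen=True)
class SpotSet:
    """Detected spots: (row, col) centres in px, per-spot scale and response."""

    centers_px: np.ndarray  # (n, 2) float
    scales_um: np.ndarray  # (n,)
    responses: np.ndarray  # (n,)
    pixel_size: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centers_px", np.asarray(self.centers_px, float).reshape(-1, 2)
        )
        object.__setattr__(self, "scales_um", np.asarray(self.scales_um, float))
        object.__setattr__(self, "responses", np.asarray(self.responses, float))

    def __len__(self) -> int:
        return len(self.centers_px)

    @property
    def centers_um(self) -> np.ndarray:
        """(x, y) µm positions of spot centres (pixel-centre convention)."""
        rows, cols = self.centers_px[:, 0], self.centers_px[:, 1]
        return np.column_stack([(cols + 0.5) * self.pixel_size, (rows + 0.5) * self.pixel_size])


def detect_spots(
    image: ConfocalImage,
    mask: np.ndarray | None,
    scales: list[float] | None = None,
    response_threshold: float = 10.0,
) -> SpotSet:
    """Multi-scale LoG blob detection restricted to a mask.

    Parameters
    ----------
    scales
        LoG sigmas in µm, each within [0.1, 1.0] µm and at least one pixel.
    response_threshold
        Minimum scale-normalized LoG response (intensity units); a Gaussian
        spot of amplitude A peaks near A/2.

    Raises
    ------
    ResolutionError
        If a scale is below one pixel at this pixel size.
    """
    if scales is None:
        scales = default_scales(image.pixel_size)
    scales = sorted(float(s) for s in scales)
    if not scales:
        raise ValidationError("at least one detection scale is required")
    for s in scales:
        if not 0.1 <= s <= 1.0:
            raise ValidationError(f"scale {s} µm outside the granule range [0.1, 1.0] µm")
        if s < image.pixel_size:
            raise ResolutionError(
                f"scale {s} µm is below one pixel ({image.pixel_size} µm/px): "
                "the image cannot resolve it"
            )
    px = image.pixels.astype(float)
    stack = np.empty((len(scales), *px.shape))
    for k, s_um in enumerate(scales):
        s_px = s_um / image.pixel_size
        stack[k] = -(s_px**2) * ndimage.gaussian_laplace(px, s_px)

    peaks = peak_local_max(stack, threshold_abs=response_threshold, exclude_border=False)
    if len(peaks) == 0:
        return SpotSet(np.empty((0, 2)), np.empty(0), np.empty(0), image.pixel_size)
    if mask is not None:
        m = np.asarray(mask, bool)
        peaks = peaks[m[peaks[:, 1], peaks[:, 2]]]
    responses = stack[peaks[:, 0], peaks[:, 1], peaks[:, 2]]
    scale_of = np.asarray(scales)[peaks[:, 0]]
    centers = peaks[:, 1:].astype(float)

    # greedy NMS, strongest first; deterministic tie-break on position.
    # A spatial hash with cell size = the largest suppression radius keeps
    # this linear in the number of candidates.
    order = np.lexsort((centers[:, 1], centers[:, 0], -responses))
    radii = np.sqrt(2.0) * scale_of / image.pixel_size
    cell = float(radii.max())
    grid: dict[tuple[int, int], list[int]] = {}
    kept: list[int] = []
    for i in order:
        pos = centers[i]
        ci, cj = int(pos[0] // cell), int(pos[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    if np.hypot(*(pos - centers[k])) < max(radii[i], radii[k]):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(i)
            grid.setdefault((ci, cj), []).append(i)
    kept_arr = np.array(sorted(kept), int)
    return SpotSet(
        centers_px=centers[kept_arr],
        scales_um=scale_of[kept_arr],
        responses=responses[kept_arr],
        pixel_size=image.pixel_size,
    )


@dataclass(frozen=True)
class Window:
    """Axis-aligned sampling rectangle in pixel coordinates."""

    row0: int
    col0: int
    height: int
    width: int

    def area_um2(self, pixel_size: float) -> float:
        return self.height * self.width * pixel_size**2

    def contains(self, row: float, col: float) -> bool:
        """Half-open membership: top/left edges inclusive, bottom/right
        exclusive."""
        return (
            self.row0 <= row < self.row0 + self.height
            and self.col0 <= col < self.col0 + self.width
        )

    def overlaps(self, other: "Window") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )


@dataclass(frozen=True)
class WindowDensity:
    """One counting window's result."""

    area_um2: float
    count: int
    density_per_100um2: float


@dataclass(frozen=True)
class DensityMeasurement:
    """Three-window CG density for one oocyte (granules per 100 µm²)."""

    windows: list[WindowDensity]
    oocyte_density: float


def place_density_windows(
    region: np.ndarray,
    pixel_size: float,
    window_um: float | tuple[float, float] = 20.0,
    n_windows: int = 3,
    seed: int = 0,
) -> list[Window]:
    """Place disjoint axis-aligned windows fully inside a region mask.

    Deterministic for a given seed.  The region is the peripheral band for
    equatorial sections or the whole field for surface scans.

    Raises
    ------
    GeometryError
        If the requested windows cannot fit disjointly inside the region.
    """
    region = np.asarray(region, bool)
    if isinstance(window_um, (int, float)):
        window_um = (float(window_um), float(window_um))
    h = max(1, int(round(window_um[0] / pixel_size)))
    w = max(1, int(round(window_um[1] / pixel_size)))
    area = int(region.sum())
    if n_windows * h * w > area:
        raise GeometryError(
            f"{n_windows} windows of {h}x{w} px need {n_windows * h * w} px "
            f"but the region holds only {area} px"
        )
    # anchors whose full rectangle lies inside the region, via integral image
    ii = np.pad(np.cumsum(np.cumsum(region, 0), 1), ((1, 0), (1, 0)))
    nrow, ncol = region.shape
    r_max, c_max = nrow - h, ncol - w
    if r_max < 0 or c_max < 0:
        raise GeometryError("window larger than the image")
    rr = np.arange(r_max + 1)[:, None]
    cc = np.arange(c_max + 1)[None, :]
    rect_sum = ii[rr + h, cc + w] - ii[rr, cc + w] - ii[rr + h, cc] + ii[rr, cc]
    anchors = np.argwhere(rect_sum == h * w)
    if len(anchors) == 0:
        raise GeometryError("no window position lies fully inside the region")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(anchors))
    placed: list[Window] = []
    for k in order:
        cand = Window(int(anchors[k, 0]), int(anchors[k, 1]), h, w)
        if all(not cand.overlaps(p) for p in placed):
            placed.append(cand)
            if len(placed) == n_windows:
                return placed
    raise GeometryError(
        f"could not place {n_windows} disjoint windows in the region "
        f"(best: {len(placed)})"
    )


def measure_density(
    spotset: SpotSet,
    windows: list[Window],
    pixel_size: float | None = None,
) -> DensityMeasurement:
    """Count spot centres per window and average the three window densities.

    Raises
    ------
    ValidationError
        Unless exactly three pairwise non-overlapping windows are given.
    """
    if len(windows) != 3:
        raise ValidationError(f"exactly three windows are required, got {len(windows)}")
    for i in range(3):
        for j in range(i + 1, 3):
            if windows[i].overlaps(windows[j]):
                raise ValidationError(f"windows {i} and {j} overlap")
    ps = pixel_size if pixel_size is not None else spotset.pixel_size
    results = []
    for win in windows:
        count = sum(
            1 for row, col in spotset.centers_px if win.contains(row, col)
        )
        area = win.area_um2(ps)
        results.append(
            WindowDensity(area_um2=area, count=count, density_per_100um2=count / area * 100.0)
        )
    return DensityMeasurement(
        windows=results,
        oocyte_density=float(np.mean([r.density_per_100um2 for r in results])),
    )
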