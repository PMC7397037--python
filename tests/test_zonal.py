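"""Zonal partition geometry and the I_cgd statistic."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from cgdist.errors import (
    CongruenceError,
    PartitionInfeasibleError,
    UndefinedIndexError,
    ValidationError,
)
from cgdist.image import ConfocalImage
from cgdist.segment import mask_from_truth
from cgdist.simulate import disc_mask, simulate_equatorial
from cgdist.studies import STUDY_EQ, icgd_from_config
from cgdist.zonal import compute_icgd, icgd_batch, partition_by_area

from conftest import expected_icgd_oracle, make_disc_mask


def exhaustive_partition_oracle(mask: np.ndarray, target: float = 0.8):
    """Brute-force reference: try every distinct distance threshold by
    direct counting and return (best_d, best_fraction), ties toward the
    larger central region."""
    dist = ndimage.distance_transform_edt(mask)
    total = mask.sum()
    best = None
    for d in np.unique(dist[mask]):
        frac = np.count_nonzero(dist[mask] >= d) / total
        err = abs(frac - target)
        if best is None or err < best[0] - 1e-15 or (
            abs(err - best[0]) <= 1e-15 and frac > best[2]
        ):
            best = (err, float(d), frac)
    return best[1], best[2]


class TestPartitionGeometry:
    @pytest.mark.parametrize("radius", [100, 200, 400])
    def test_disc_erosion_depth_matches_continuum_and_oracle(self, radius):
        """For discs, d*/R must sit within 0.01 of the continuum value
        1 - sqrt(0.8), and the discrete threshold must equal the
        exhaustive pixel-count oracle exactly."""
        m = make_disc_mask(radius)
        part = partition_by_area(mask_from_truth(m, 1.0))
        continuum = (1 - np.sqrt(0.8))
        assert abs(part.erosion_depth_um / radius - continuum) <= 0.01
        d_oracle, frac_oracle = exhaustive_partition_oracle(m)
        assert part.erosion_depth_um == d_oracle
        assert part.achieved_central_fraction == frac_oracle

    @pytest.mark.parametrize("radius", [100, 200, 400])
    def test_zones_tile_the_mask_exactly(self, radius):
        m = make_disc_mask(radius)
        part = partition_by_area(mask_from_truth(m, 1.0))
        assert not np.any(part.central & part.peripheral)
        np.testing.assert_array_equal(part.central | part.peripheral, m)

    def test_achieved_fraction_near_target(self, disc_mask_200):
        part = partition_by_area(disc_mask_200)
        assert abs(part.achieved_central_fraction - 0.8) <= 0.02

    def test_tiny_mask_infeasible(self):
        m = np.zeros((32, 32), bool)
        m[10:20, 10:20] = True  # 100 px < 500
        with pytest.raises(PartitionInfeasibleError):
            partition_by_area(mask_from_truth(m, 1.0))

    def test_irregular_mask_tiles_exactly(self):
        # ellipse with a flattened side: non-circular but solid
        yy, xx = np.mgrid[:160, :220]
        m = ((xx - 110) / 100.0) ** 2 + ((yy - 80) / 60.0) ** 2 <= 1
        m &= yy > 25
        part = partition_by_area(mask_from_truth(m, 0.7))
        np.testing.assert_array_equal(part.central | part.peripheral, m)
        assert abs(part.achieved_central_fraction - 0.8) <= 0.02

    def test_bad_fraction_rejected(self, disc_mask_200):
        with pytest.raises(ValidationError):
            partition_by_area(disc_mask_200, central_fraction=1.2)


class TestCgdIndex:
    def test_uniform_image_gives_exactly_one(self, disc_mask_200):
        part = partition_by_area(disc_mask_200)
        img = ConfocalImage(np.full(part.central.shape, 37.0), 1.0)
        assert compute_icgd(img, part).icgd == 1.0

    def test_two_level_image_gives_exact_ratio(self, disc_mask_200):
        part = partition_by_area(disc_mask_200)
        px = np.zeros(part.central.shape)
        px[part.central] = 10.0
        px[part.peripheral] = 20.0
        assert compute_icgd(ConfocalImage(px, 1.0), part).icgd == 2.0

    def test_scale_invariance(self, disc_mask_200):
        part = partition_by_area(disc_mask_200)
        rng = np.random.default_rng(3)
        px = rng.uniform(1, 50, part.central.shape)
        base = compute_icgd(ConfocalImage(px, 1.0), part).icgd
        scaled = compute_icgd(ConfocalImage(px * 7.3, 1.0), part).icgd
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_central_mean_is_undefined(self, disc_mask_200):
        part = partition_by_area(disc_mask_200)
        px = np.zeros(part.central.shape)
        px[part.peripheral] = 5.0
        with pytest.raises(UndefinedIndexError):
            compute_icgd(ConfocalImage(px, 1.0), part)

    def test_shape_mismatch_rejected(self, disc_mask_200):
        part = partition_by_area(disc_mask_200)
        with pytest.raises(CongruenceError):
            compute_icgd(ConfocalImage(np.ones((32, 32)), 1.0), part)

    @pytest.mark.parametrize("bias", [0.0, 0.9])
    def test_mean_icgd_matches_generative_model_oracle(self, bias):
        """Over 200 noise-free replicates, the empirical mean I_cgd must sit
        within 3 SE of the closed-form expectation obtained by integrating
        the placement density against the spot profile (Rice CDF)."""
        cfg = dataclasses.replace(
            STUDY_EQ, peripheral_bias=bias, n_granules=500, noise_model="none"
        )
        part = partition_by_area(mask_from_truth(disc_mask(cfg), cfg.pixel_size))
        oracle = expected_icgd_oracle(cfg, part)
        vals = [
            icgd_from_config(dataclasses.replace(cfg, seed=s)) for s in range(200)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - oracle) < 3 * se

    def test_bias_ordering_small_scale(self):
        """Group-mean I_cgd must order with the generative peripheral bias."""
        means = []
        for p in (0.1, 0.5, 0.9):
            cfg = dataclasses.replace(STUDY_EQ, peripheral_bias=p)
            vals = [icgd_from_config(dataclasses.replace(cfg, seed=s)) for s in range(15)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestIcgdBatch:
    def _cohort(self, tmp_path, n=3):
        import pandas as pd

        from cgdist.simulate import EquatorialSimConfig, simulate_cohort

        a = EquatorialSimConfig(
            image_size=256, pixel_size=0.5, oocyte_radius=50.0, n_granules=1500,
            peripheral_bias=0.2, granule_sigma=0.6, granule_amplitude=50.0,
            background=5.0, noise_model="gaussian", noise_sd=2.0, seed=0,
        )
        b = dataclasses.replace(a, peripheral_bias=0.8)
        simulate_cohort({"low": a, "high": b}, n, seed=4, out_dir=tmp_path / "c")
        return pd.read_csv(tmp_path / "c" / "manifest.csv"), tmp_path / "c"

    def test_one_row_per_oocyte_and_group_ordering(self, tmp_path):
        manifest, base = self._cohort(tmp_path)
        table = icgd_batch(manifest, base_dir=base)  # truth masks from manifest
        assert len(table) == 6
        assert (table["status"] == "ok").all()
        means = table.groupby("group")["icgd"].mean()
        assert means["high"] > means["low"]

    def test_group_ordering_survives_segmentation(self, tmp_path):
        manifest, base = self._cohort(tmp_path)
        table = icgd_batch(manifest.drop(columns=["mask_path"]), base_dir=base)
        assert (table["status"] == "ok").all()
        means = table.groupby("group")["icgd"].mean()
        assert means["high"] > means["low"]

    def test_unreadable_image_fails_row_not_batch(self, tmp_path):
        manifest, base = self._cohort(tmp_path)
        manifest.loc[0, "path"] = "images/does_not_exist.tif"
        table = icgd_batch(manifest, base_dir=base)
        assert (table["status"] == "failed").sum() == 1
        assert (table["status"] == "ok").sum() == 5

    def test_empty_manifest_is_an_error(self):
        import pandas as pd

        with pytest.raises(ValidationError, match="empty"):
            icgd_batch(pd.DataFrame())
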