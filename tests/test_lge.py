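"""Remote-referenced SD thresholding: exactness against a per-voxel
oracle, conservation, invariances, transmural extent."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrquant.lge import (
    InfarctSegmenter,
    LGEStudy,
    classify_transmurality,
    partition_infarct,
    pct_infarct_of_lv,
    remote_stats,
    transmural_extent,
)
from cmrquant.synthetic import (
    PhantomConfig,
    default_infarct_masks,
    generate_lge_phantom,
)


def _study_from_image(image, remote_box=((0, 4), (0, 4)), voxel_ml=0.1):
    image = np.asarray(image, dtype=float)[None]
    myo = np.ones_like(image, bool)
    remote = np.zeros_like(image, bool)
    (r0, r1), (c0, c1) = remote_box
    remote[0, r0:r1, c0:c1] = True
    return LGEStudy(
        image=image, myo_mask=myo, remote_mask=remote, voxel_volume_ml=voxel_ml
    )


def _oracle_partition(image, myo, mu, sd, k_total=2.0, k_core=3.0):
    """Exhaustive per-voxel classification, no vectorization."""
    total = np.zeros_like(myo)
    core = np.zeros_like(myo)
    peri = np.zeros_like(myo)
    t_tot, t_core = mu + k_total * sd, mu + k_core * sd
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            if not myo[r, c]:
                continue
            v = image[r, c]
            if v > t_core:
                core[r, c] = total[r, c] = True
            elif v > t_tot:
                peri[r, c] = total[r, c] = True
    return total, core, peri


class TestRemoteStats:
    def test_constant_remote(self):
        img = np.full((8, 8), 50.0)
        mu, sd = remote_stats(_study_from_image(img), 0)
        assert (mu, sd) == (50.0, 0.0)

    def test_two_point_remote_sd(self):
        img = np.zeros((8, 8))
        img[0, 0], img[0, 1] = 40.0, 60.0
        study = _study_from_image(img, remote_box=((0, 1), (0, 2)))
        with pytest.warns(UserWarning, match="unreliable"):
            mu, sd = remote_stats(study, 0)
        assert mu == 50.0
        assert sd == pytest.approx(np.sqrt(200.0))

    def test_matches_brute_force_on_random_region(self, rng):
        img = rng.normal(100, 15, (10, 10))
        study = _study_from_image(img)
        mu, sd = remote_stats(study, 0)
        vals = [img[r, c] for r in range(4) for c in range(4)]
        assert mu == pytest.approx(np.mean(vals), abs=1e-12)
        assert sd == pytest.approx(np.std(vals, ddof=1), abs=1e-12)

    def test_empty_remote_raises(self):
        study = _study_from_image(np.zeros((8, 8)))
        study.remote_mask[:] = False
        with pytest.raises(ValueError, match="empty"):
            remote_stats(study, 0)


class TestPartition:
    def test_threshold_arithmetic_on_three_voxels(self):
        # remote mean 100, sample SD exactly 10 -> thresholds 120 / 130;
        # 115 excluded, 125 peri, 135 core
        img = np.full((8, 8), 100.0)
        x = 10.0 * np.sqrt(7.0 / 8.0)  # 8 voxels at 100 +/- x: SD(ddof=1)=10
        img[0:2, 0:4] = [[100 - x, 100 + x] * 2] * 2
        img[5, 0], img[5, 1], img[5, 2] = 115.0, 125.0, 135.0
        study = _study_from_image(img, remote_box=((0, 2), (0, 4)))
        mu, sd = remote_stats(study, 0)
        assert (mu, sd) == pytest.approx((100.0, 10.0))
        part = partition_infarct(study)
        assert not part.total_mask[0, 5, 0]  # 115 < 120
        assert part.peri_mask[0, 5, 1] and not part.core_mask[0, 5, 1]
        assert part.core_mask[0, 5, 2]
        assert int(part.total_mask.sum()) == 2

    def test_planted_phantom_percentages(self):
        cfg = PhantomConfig(seed=2)
        core, peri = default_infarct_masks(cfg, 40, 60)
        study, _ = generate_lge_phantom(cfg, core, peri)
        part = partition_infarct(study)
        assert part.pct_core_of_total == pytest.approx(40.0)
        assert part.pct_peri_of_total == pytest.approx(60.0)
        assert part.pct_core_of_total + part.pct_peri_of_total == pytest.approx(100.0)

    def test_no_voxel_above_threshold_gives_empty_partition(self):
        img = np.full((8, 8), 100.0)
        study = _study_from_image(img)
        part = partition_infarct(study)
        assert part.mde_total_g == 0.0
        assert pct_infarct_of_lv(part, 100.0) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_random_slices(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(100, 20, (32, 32))
        myo = rng.random((32, 32)) < 0.6
        myo[0:6, 0:6] = True
        study = LGEStudy(
            image=img[None], myo_mask=myo[None],
            remote_mask=(np.zeros_like(myo) | (np.arange(32)[:, None] < 6)
                         & (np.arange(32)[None, :] < 6))[None] & myo[None],
            voxel_volume_ml=0.1,
        )
        mu, sd = remote_stats(study, 0)
        part = partition_infarct(study)
        total, core, peri = _oracle_partition(img, myo, mu, sd)
        np.testing.assert_array_equal(part.total_mask[0], total)
        np.testing.assert_array_equal(part.core_mask[0], core)
        np.testing.assert_array_equal(part.peri_mask[0], peri)
        # conservation
        assert (part.core_mask | part.peri_mask).sum() == part.total_mask.sum()
        assert not np.any(part.core_mask & part.peri_mask)

    def test_mass_arithmetic(self):
        img = np.full((8, 8), 100.0)
        img[5, 0:3] = 200.0
        study = _study_from_image(img, voxel_ml=2.0)
        part = partition_infarct(study)
        # 3 voxels x 2 mL x 1.05 g/mL
        assert part.mde_total_g == pytest.approx(3 * 2.0 * 1.05)

    def test_pct_of_lv(self):
        img = np.full((8, 8), 100.0)
        img[5, 0:3] = 200.0
        study = _study_from_image(img, voxel_ml=2.0)
        part = partition_infarct(study)
        assert pct_infarct_of_lv(part, 63.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            pct_infarct_of_lv(part, 0.0)

    @given(shift=st.floats(-500, 500, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_intensity_shift_invariance(self, shift):
        rng = np.random.default_rng(7)
        img = rng.normal(100, 20, (16, 16))
        base = partition_infarct(_study_from_image(img))
        shifted = partition_infarct(_study_from_image(img + shift))
        np.testing.assert_array_equal(base.total_mask, shifted.total_mask)
        np.testing.assert_array_equal(base.core_mask, shifted.core_mask)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        img = rng.normal(100, 20, (16, 16))
        study = _study_from_image(img)
        part23 = partition_infarct(study)
        seg3 = InfarctSegmenter(k_total=3.0, k_core=4.0).fit(study)
        labels3 = seg3.predict(study)
        total_at_3 = (labels3 > 0).sum()
        assert total_at_3 <= part23.total_mask.sum()
        # core at 3 SD equals a total computed with a 3 SD threshold
        assert part23.core_mask.sum() == total_at_3

    def test_misordered_multipliers_rejected(self):
        study = _study_from_image(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            InfarctSegmenter(k_total=3.0, k_core=2.0).fit(study)


class TestTransmurality:
    def test_class_boundaries_closed_on_left(self):
        assert classify_transmurality(0.49) == "<50%"
        assert classify_transmurality(0.50) == "50-75%"
        assert classify_transmurality(0.75) == "50-75%"
        assert classify_transmurality(0.76) == ">75%"

    def test_full_wall_infarct_is_high_class(self):
        rows = cols = 32
        from cmrquant.synthetic import _annulus
        myo2d, _ = _annulus((rows, cols), 8.0, 13.4)
        myo = np.broadcast_to(myo2d, (1, rows, cols)).copy()
        center = (rows - 1) / 2.0
        rr, cc = np.mgrid[0:rows, 0:cols]
        ang = np.degrees(np.arctan2(-(rr - center), cc - center)) % 360
        wedge = myo2d & (ang >= 180) & (ang < 240)
        img = np.full((1, rows, cols), 100.0)
        img[0][wedge] = 200.0
        remote = (myo2d & (ang >= 45) & (ang < 135))[None]
        study = LGEStudy(img, myo, remote, voxel_volume_ml=0.1)
        part = partition_infarct(study)
        ext = transmural_extent(part, study)
        assert ext["study_class"] == ">75%"

    def test_no_infarct_gives_low_class_everywhere(self):
        from cmrquant.synthetic import _annulus
        rows = cols = 32
        myo2d, _ = _annulus((rows, cols), 8.0, 13.4)
        myo = myo2d[None]
        img = np.full((1, rows, cols), 100.0)
        remote = myo.copy()
        study = LGEStudy(img, myo, remote, voxel_volume_ml=0.1)
        part = partition_infarct(study)
        ext = transmural_extent(part, study)
        assert ext["study_class"] == "<50%"
        assert all(v["transmurality"] == 0.0 for v in ext["sectors"].values())

    def test_mid_wall_infarct_hits_middle_class(self):
        # enhancement spanning ~60% of the wall depth in one wedge lands
        # in the middle class and does not leak into the high class
        from cmrquant.synthetic import _annulus
        rows = cols = 64
        r_in, r_out = 16.0, 28.0
        myo2d, _ = _annulus((rows, cols), r_in, r_out)
        myo = myo2d[None]
        center = (rows - 1) / 2.0
        rr, cc = np.mgrid[0:rows, 0:cols]
        rad = np.hypot(rr - center, cc - center)
        ang = np.degrees(np.arctan2(-(rr - center), cc - center)) % 360
        wedge = myo2d & (ang >= 180) & (ang < 240) & (
            rad < r_in + 0.6 * (r_out - r_in)
        )
        img = np.full((1, rows, cols), 100.0)
        img[0][wedge] = 200.0
        remote = (myo2d & (ang >= 45) & (ang < 135))[None]
        study = LGEStudy(img, myo, remote, voxel_volume_ml=0.1)
        part = partition_infarct(study)
        ext = transmural_extent(part, study, n_sectors=6)
        assert ext["study_class"] == "50-75%"
        frac = ext["sectors"][3]["transmurality"]
        assert 0.5 <= frac <= 0.75
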