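"""Entropy thresholding, segmentation, size filtering and colocalization."""

import numpy as np
import pytest

from cardiocal.cluster_quant import (
    ClusterRecord,
    ContactRegion,
    FluorescenceImage,
    ThresholdError,
    contact_summary,
    costes_pearson,
    filter_by_size,
    kapur_threshold,
    renyi_entropy_threshold,
    renyi_threshold_intensity,
    segment_clusters,
    size_distribution,
)

PX = 0.1581


def _kapur_brute_force(hist):
    """Independent exhaustive maximization of Kapur's two-class entropy.

    Returns (best threshold, criterion value at every candidate).
    """
    p = np.asarray(hist, dtype=float)
    p = p / p.sum()
    crit = np.full(p.size - 1, -np.inf)
    for t in range(p.size - 1):
        p1 = p[: t + 1].sum()
        p2 = 1.0 - p1
        if p1 <= 0 or p2 <= 0:
            continue
        b = p[: t + 1][p[: t + 1] > 0] / p1
        f = p[t + 1 :][p[t + 1 :] > 0] / p2
        crit[t] = -np.sum(b * np.log(b)) - np.sum(f * np.log(f))
    return int(np.argmax(crit)), crit


class TestThreshold:
    def test_kapur_matches_exhaustive_oracle_on_random_histograms(self):
        """The package threshold attains the exhaustive-search maximum of
        Kapur's criterion and partitions the same histogram mass.  (Runs of
        empty bins create exact criterion ties, so thresholds are compared
        through the criterion and the class masses, not the raw index.)"""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 100:
            hist = rng.integers(0, 60, size=256).astype(float)
            hist[rng.integers(0, 256, size=rng.integers(50, 250))] = 0.0
            if np.count_nonzero(hist) < 2:
                continue
            t_pkg = kapur_threshold(hist)
            t_ref, crit = _kapur_brute_force(hist)
            assert crit[t_pkg] == pytest.approx(crit[t_ref], abs=1e-9)
            cum = np.cumsum(hist)
            assert cum[t_pkg] == cum[t_ref]
            checked += 1

    def test_two_delta_masses_threshold_between_modes(self):
        hist = np.zeros(256)
        hist[10] = 500
        hist[200] = 100
        t = renyi_entropy_threshold(hist)
        assert 10 <= t < 200

    def test_single_occupied_bin_rejected(self):
        hist = np.zeros(256)
        hist[42] = 1000
        with pytest.raises(ThresholdError):
            renyi_entropy_threshold(hist)
        with pytest.raises(ThresholdError):
            kapur_threshold(hist)

    def test_intensity_threshold_shift_invariant(self):
        rng = np.random.default_rng(3)
        img = rng.normal(50, 5, (64, 64))
        img[20:28, 20:28] = 200.0
        img = np.clip(img, 0, None)
        t0 = renyi_threshold_intensity(FluorescenceImage(img))
        t1 = renyi_threshold_intensity(FluorescenceImage(img + 100.0))
        assert t1 - t0 == pytest.approx(100.0, abs=1e-6)


class TestSegmentation:
    def _region(self, shape):
        return ContactRegion(mask=np.ones(shape, dtype=bool))

    def test_disjoint_spots_counted(self):
        img = np.zeros((40, 80))
        for i in range(7):
            img[10:13, 5 + 10 * i : 8 + 10 * i] = 100.0
        recs = segment_clusters(
            FluorescenceImage(img), self._region(img.shape), threshold=50.0
        )
        assert len(recs) == 7
        assert all(r.pixel_count == 9 for r in recs)

    def test_all_below_threshold_empty(self):
        img = np.full((20, 20), 10.0)
        recs = segment_clusters(
            FluorescenceImage(img), self._region(img.shape), threshold=50.0
        )
        assert recs == []

    def test_diagonal_touch_is_one_cluster_under_8_connectivity(self):
        img = np.zeros((10, 10))
        img[2, 2] = img[3, 3] = 100.0
        recs = segment_clusters(
            FluorescenceImage(img), self._region(img.shape), threshold=50.0
        )
        assert len(recs) == 1
        recs4 = segment_clusters(
            FluorescenceImage(img), self._region(img.shape), threshold=50.0,
            connectivity=1,
        )
        assert len(recs4) == 2

    def test_pixel_counts_partition_foreground(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 100, (50, 50))
        region = ContactRegion(mask=rng.uniform(size=(50, 50)) > 0.3)
        thr = 60.0
        recs = segment_clusters(FluorescenceImage(img), region, thr)
        assert sum(r.pixel_count for r in recs) == int(
            np.sum((img > thr) & region.mask)
        )

    def test_empty_region_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            segment_clusters(
                FluorescenceImage(img),
                ContactRegion(mask=np.zeros((10, 10), dtype=bool)),
                threshold=1.0,
            )


class TestSizeFilter:
    def _cluster(self, n_px):
        return ClusterRecord(
            area=n_px * PX**2, pixel_count=n_px, centroid=(0.0, 0.0),
            mean_intensity=100.0,
        )

    def test_default_bounds_keep_2_to_40_pixels(self):
        clusters = [self._cluster(n) for n in (1, 2, 40, 41)]
        kept = filter_by_size(clusters)
        assert [c.pixel_count for c in kept] == [2, 40]

    def test_boundary_cluster_at_min_area_retained(self):
        # 2 px at the default pixel size is the 0.05 µm² lower bound
        assert filter_by_size([self._cluster(2)]) != []

    def test_empty_input_empty_output(self):
        assert filter_by_size([]) == []

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_size([], min_area=1.0, max_area=0.05)


class TestSummary:
    def test_density_is_count_over_area(self):
        region = ContactRegion(mask=np.ones((10, 20), dtype=bool), pixel_size=PX)
        clusters = [
            ClusterRecord(area=0.1, pixel_count=4, centroid=(0, 0),
                          mean_intensity=1.0)
            for _ in range(10)
        ]
        s = contact_summary(clusters, region)
        assert s.density_per_um2 == pytest.approx(10.0 / region.area)

    def test_single_cluster_mean_is_its_area(self):
        region = ContactRegion(mask=np.ones((10, 10), dtype=bool))
        c = ClusterRecord(area=0.33, pixel_count=13, centroid=(0, 0),
                          mean_intensity=1.0, cell_id=5)
        s = contact_summary([c], region)
        assert s.mean_area_um2 == pytest.approx(0.33)
        assert s.per_cell_mean_area == {5: pytest.approx(0.33)}


class TestSizeDistribution:
    def test_identical_groups_have_zero_statistic(self):
        a = np.array([0.1, 0.2, 0.3, 0.5, 0.8] * 10)
        _, _, _, chi2, p = size_distribution(a, a.copy())
        assert chi2 == 0.0
        assert p == 1.0

    def test_two_by_two_hand_computed_statistic(self):
        # table (10,0 / 0,10): chi-square without continuity correction = 20
        a = np.full(10, 0.2)
        b = np.full(10, 0.8)
        edges = np.array([0.05, 0.5, 1.0])
        _, _, _, chi2, _ = size_distribution(a, b, edges)
        assert chi2 == pytest.approx(20.0)

    def test_shifted_lognormals_detected_with_power(self):
        """Groups of 500 drawn from shifted log-normal laws differ at
        p < 0.05 in at least 90% of seeded runs."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = np.exp(rng.normal(-1.36, 0.55, 500))
            b = np.exp(rng.normal(-1.12, 0.55, 500))
            sel_a = a[(a >= 0.05) & (a <= 1.0)]
            sel_b = b[(b >= 0.05) & (b <= 1.0)]
            _, _, _, _, p = size_distribution(sel_a, sel_b)
            hits += p < 0.05
        assert hits >= 18

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            size_distribution(np.array([0.2]), np.array([0.21]),
                              np.array([0.05, 0.5, 1.0]))


class TestCostes:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 100, (64, 64))
        return base

    def test_identical_channels_give_unity_pearson(self):
        img = self._pair()
        res = costes_pearson(
            FluorescenceImage(img), FluorescenceImage(img.copy()),
            np.ones_like(img, dtype=bool),
        )
        assert res.pearson_above_threshold == pytest.approx(1.0)
        assert not res.anti_correlated

    def test_independent_noise_centred_on_zero(self):
        """Null simulation: mean above-threshold Pearson of independent
        images stays within ±0.1 of zero over 10 seeds."""
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.uniform(0, 100, (48, 48))
            b = rng.uniform(0, 100, (48, 48))
            res = costes_pearson(
                FluorescenceImage(a), FluorescenceImage(b),
                np.ones_like(a, dtype=bool),
            )
            if np.isfinite(res.pearson_above_threshold):
                vals.append(res.pearson_above_threshold)
            else:
                vals.append(res.pearson_overall)
        assert abs(np.mean(vals)) < 0.1

    def test_anti_correlation_flagged(self):
        img = self._pair(3)
        inv = img.max() - img
        res = costes_pearson(
            FluorescenceImage(img), FluorescenceImage(inv),
            np.ones_like(img, dtype=bool),
        )
        assert res.anti_correlated
        assert res.slope < 0

    def test_zero_variance_rejected(self):
        img = self._pair(1)
        flat = np.full_like(img, 5.0)
        with pytest.raises(ValueError):
            costes_pearson(
                FluorescenceImage(img), FluorescenceImage(flat),
                np.ones_like(img, dtype=bool),
            )
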