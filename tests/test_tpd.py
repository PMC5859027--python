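import numpy as np
import pytest

from perfcov.normal_limits import NormalLimits
from perfcov.polarmap import CoverageMask, build_segment_model, normalize_map, whole_heart_mask
from perfcov.tpd import (
    build_three_slice_mask,
    compute_three_slice_tpd,
    compute_tpd,
    score_patient,
    segment_extents,
)
from .conftest import make_map


def oracle_tpd(values, mean, mad, threshold, weights, include):
    """Independent per-pixel summation of the TPD definition."""
    num = den = 0.0
    R, A = values.shape
    for r in range(R):
        for a in range(A):
            if not include[r, a]:
                continue
            den += weights[r, a]
            dev = max(0.0, (mean[r, a] - values[r, a]) / mad[r, a])
            if dev >= threshold:
                s = min(1.0, max(0.0, (mean[r, a] - values[r, a]) / mean[r, a]))
                num += weights[r, a] * s
    return 100.0 * num / den


def flat_limits(shape, mean=100.0, mad=5.0):
    return NormalLimits(
        gender="male", mean=np.full(shape, mean), mad=np.full(shape, mad)
    )


@pytest.fixture(scope="module")
def limits(model):
    return flat_limits((model.R, model.A))


class TestComputeTpd:
    def test_zero_uptake_map_scores_100(self, model, limits):
        zero = make_map(np.zeros((model.R, model.A)), normalized=True)
        tpd = compute_tpd(zero, limits, whole_heart_mask(model), model)
        assert tpd == pytest.approx(100.0)

    def test_map_at_limits_mean_scores_0(self, model, limits):
        at_mean = make_map(limits.mean.copy(), normalized=True)
        assert compute_tpd(at_mean, limits, whole_heart_mask(model), model) == 0.0

    def test_single_abnormal_pixel_weighted_quarter_percent(self):
        # one abnormal pixel of severity 0.5 and weight 1 in total weight 200
        model = build_segment_model(R=8, A=24, zone_fractions=(1 / 8, 2 / 8, 2 / 8, 3 / 8),
                                    weight_offset=0.0)
        lim = flat_limits((8, 24), mean=100.0, mad=5.0)
        values = np.full((8, 24), 100.0)
        values[0, 0] = 50.0  # deficit 50 = 10 MAD, severity 0.5, ring-0 weight 1
        pmap = make_map(values, normalized=True)
        w = model.area_weight
        mask = np.zeros((8, 24), dtype=bool)
        # pick mask pixels totalling weight 200: ring0 pixel (w=1) + others
        mask[0, 0] = True
        acc = 1.0
        for r in range(1, 8):
            for a in range(24):
                if acc < 200.0 and acc + w[r, a] <= 200.0:
                    mask[r, a] = True
                    acc += w[r, a]
        assert acc == 200.0
        tpd = compute_tpd(pmap, lim, CoverageMask(mask), model)
        assert tpd == pytest.approx(100.0 * (1.0 * 0.5) / 200.0)
        assert tpd == pytest.approx(0.25)

    def test_matches_brute_force_oracle_on_random_maps(self, model, rng):
        mean = rng.uniform(60, 120, (model.R, model.A))
        mad = rng.uniform(1.0, 9.0, (model.R, model.A))
        lim = NormalLimits(gender="male", mean=mean, mad=mad)
        for _ in range(5):
            values = rng.uniform(0, 140, (model.R, model.A))
            pmap = make_map(values, normalized=True)
            got = compute_tpd(pmap, lim, whole_heart_mask(model), model)
            want = oracle_tpd(
                values, mean, mad, lim.threshold_mad,
                model.area_weight, np.ones(values.shape, bool),
            )
            assert got == pytest.approx(want)

    def test_empty_mask_rejected(self, model, limits):
        zero = make_map(np.zeros((model.R, model.A)), normalized=True)
        with pytest.raises(ValueError, match="empty"):
            compute_tpd(zero, limits, CoverageMask(np.zeros((model.R, model.A), bool)), model)

    def test_gender_mismatch_rejected(self, model, limits):
        pmap = make_map(limits.mean, gender="female", normalized=True)
        with pytest.raises(ValueError, match="gender"):
            compute_tpd(pmap, limits, whole_heart_mask(model), model)

    def test_range_bounds(self, model, limits, rng):
        for _ in range(10):
            values = rng.uniform(0, 200, (model.R, model.A))
            tpd = compute_tpd(make_map(values, normalized=True), limits,
                              whole_heart_mask(model), model)
            assert 0.0 <= tpd <= 100.0

    def test_monotone_in_pixel_deficit(self, model, limits, rng):
        values = rng.uniform(40, 120, (model.R, model.A))
        base = compute_tpd(make_map(values, normalized=True), limits,
                           whole_heart_mask(model), model)
        for _ in range(20):
            r = rng.integers(model.R)
            a = rng.integers(model.A)
            lowered = values.copy()
            lowered[r, a] *= rng.uniform(0.0, 0.9)
            tpd = compute_tpd(make_map(lowered, normalized=True), limits,
                              whole_heart_mask(model), model)
            assert tpd >= base - 1e-12

    def test_scale_invariance_through_normalization(self, model, male_limits, rng):
        values = rng.uniform(10, 100, (model.R, model.A))
        values[5:9, 3:9] *= 0.4  # plant a defect
        t1 = compute_tpd(normalize_map(make_map(values)), male_limits,
                         whole_heart_mask(model), model)
        t2 = compute_tpd(normalize_map(make_map(values * 7.3)), male_limits,
                         whole_heart_mask(model), model)
        assert t1 == pytest.approx(t2)
        assert t1 > 0


class TestThreeSliceMask:
    def test_default_model_selects_center_rings(self, model):
        mask = build_three_slice_mask(model)
        selected = sorted(np.where(mask.include.any(axis=1))[0])

        def oracle_rings(start, stop):
            lo = (start + stop - 1) // 2
            return [lo, lo + 1]

        want = []
        for zone in ("apical", "mid", "basal"):
            want += oracle_rings(*model.zone_bounds[zone])
        assert selected == sorted(want)
        # local index 3 and 4 of each 7-ring zone
        for zone in ("apical", "mid", "basal"):
            start, _ = model.zone_bounds[zone]
            assert start + 3 in selected and start + 4 in selected

    def test_never_includes_apex_cap(self, model):
        mask = build_three_slice_mask(model)
        for r in model.zone_rings("apex_cap"):
            assert not mask.include[r].any()

    def test_pixel_count_is_6A(self, model):
        assert build_three_slice_mask(model).n_pixels == 6 * model.A

    def test_two_ring_zones_fully_selected(self):
        m = build_segment_model(R=8, A=24, zone_fractions=(2 / 8, 2 / 8, 2 / 8, 2 / 8))
        mask = build_three_slice_mask(m)
        for zone in ("apical", "mid", "basal"):
            start, stop = m.zone_bounds[zone]
            assert mask.include[start:stop].all()


class TestThreeSliceTpd:
    def test_uniform_defect_same_under_both_coverages(self, model, limits):
        s = 0.5  # deficit of 10 MAD everywhere, well past the threshold
        values = limits.mean * (1 - s)
        pmap = make_map(values, normalized=True)
        wh = compute_tpd(pmap, limits, whole_heart_mask(model), model)
        ts = compute_three_slice_tpd(pmap, limits, model)
        assert wh == pytest.approx(100 * s)
        assert ts == pytest.approx(100 * s)

    def test_apex_cap_defect_invisible_to_three_slice(self, model, limits):
        values = limits.mean.copy()
        values[model.segment_of == 17] = 0.0
        pmap = make_map(values, normalized=True)
        wh = compute_tpd(pmap, limits, whole_heart_mask(model), model)
        ts = compute_three_slice_tpd(pmap, limits, model)
        assert ts == 0.0
        assert wh > 0.0

    def test_equals_restriction_oracle(self, model, rng):
        mean = rng.uniform(60, 120, (model.R, model.A))
        mad = rng.uniform(1.0, 9.0, (model.R, model.A))
        lim = NormalLimits(gender="male", mean=mean, mad=mad)
        values = rng.uniform(0, 140, (model.R, model.A))
        pmap = make_map(values, normalized=True)
        mask = build_three_slice_mask(model)
        got = compute_three_slice_tpd(pmap, lim, model)
        want = oracle_tpd(values, mean, mad, lim.threshold_mad,
                          model.area_weight, mask.include)
        assert got == pytest.approx(want)

    def test_whole_denominator_option(self, model, limits):
        values = limits.mean * 0.3
        pmap = make_map(values, normalized=True)
        masked = compute_three_slice_tpd(pmap, limits, model, denominator="masked")
        whole = compute_three_slice_tpd(pmap, limits, model, denominator="whole")
        w = model.area_weight
        frac = w[build_three_slice_mask(model).include].sum() / w.sum()
        assert whole == pytest.approx(masked * frac)
        with pytest.raises(ValueError):
            compute_three_slice_tpd(pmap, limits, model, denominator="nope")

    def test_restriction_consistency(self, model, rng):
        # whole-heart TPD is the area-weighted average of mask and complement
        mean = rng.uniform(60, 120, (model.R, model.A))
        lim = NormalLimits(gender="male", mean=mean, mad=np.full(mean.shape, 4.0))
        values = rng.uniform(0, 140, (model.R, model.A))
        pmap = make_map(values, normalized=True)
        mask = build_three_slice_mask(model)
        comp = CoverageMask(~mask.include)
        w = model.area_weight
        wm, wc = w[mask.include].sum(), w[comp.include].sum()
        wh = compute_tpd(pmap, lim, whole_heart_mask(model), model)
        tm = compute_tpd(pmap, lim, mask, model)
        tc = compute_tpd(pmap, lim, comp, model)
        assert wh == pytest.approx((wm * tm + wc * tc) / (wm + wc))


class TestSegmentExtents:
    def test_defect_free_map_all_zero(self, model, limits):
        extents = segment_extents(make_map(limits.mean, normalized=True), limits, model)
        assert set(extents) == set(range(1, 18))
        assert all(v == 0.0 for v in extents.values())

    def test_whole_apex_cap_abnormal(self, model, limits):
        values = limits.mean.copy()
        values[model.segment_of == 17] = 0.0
        extents = segment_extents(make_map(values, normalized=True), limits, model)
        assert extents[17] == pytest.approx(100.0)
        assert all(extents[s] == 0.0 for s in range(1, 17))

    def test_half_of_segment13_by_sector_count(self, small_model):
        # small model: apical segments span 6 sectors; zero out 3 full columns
        lim = flat_limits((small_model.R, small_model.A))
        seg13 = small_model.segment_mask(13)
        sectors = np.unique(np.where(seg13)[1])
        assert len(sectors) == 6
        values = lim.mean.copy()
        values[np.ix_(range(small_model.R), sectors[:3])] *= np.where(
            seg13[np.ix_(range(small_model.R), sectors[:3])], 0.0, 1.0
        )
        extents = segment_extents(make_map(values, normalized=True), lim, small_model)
        # ring weights cancel: full columns of the segment are abnormal
        assert extents[13] == pytest.approx(50.0)

    def test_counting_oracle_on_random_map(self, model, rng):
        mean = np.full((model.R, model.A), 100.0)
        lim = NormalLimits(gender="male", mean=mean, mad=np.full(mean.shape, 5.0))
        values = rng.uniform(50, 130, (model.R, model.A))
        extents = segment_extents(make_map(values, normalized=True), lim, model)
        abnormal = (mean - values) / 5.0 >= 3.0
        w = model.area_weight
        for seg in range(1, 18):
            m = model.segment_of == seg
            want = 100.0 * w[m & abnormal].sum() / w[m].sum()
            assert extents[seg] == pytest.approx(want)


class TestScorePatient:
    def test_defect_free_result_fields(self, model, limits):
        res = score_patient(make_map(limits.mean, normalized=True), limits, model)
        assert res.whole_heart_tpd == 0.0
        assert res.three_slice_tpd == 0.0
        assert res.abnormal_area_percent == 0.0
        assert all(res.per_segment_extent[s] == 0.0 for s in range(1, 18))
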