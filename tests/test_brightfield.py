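"""Phansalkar thresholding, particle analysis and the top-100 statistic."""

import numpy as np
import pandas as pd
import pytest
from skimage import draw

from colonoidquant.brightfield import (
    ParticleRecord,
    ThresholdParams,
    WellSummary,
    analyze_particles,
    phansalkar_threshold,
    summarize_condition,
    topk_mean_area,
)
from colonoidquant.design import Condition, SampleKey


def phansalkar_oracle(image: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Direct-definition Phansalkar mask via mirror-padded sliding
    windows; shares no code with the implementation's filter path."""
    x = image.astype(np.float64) / 255.0
    r = params.radius
    padded = np.pad(x, r, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (2 * r + 1, 2 * r + 1))
    m = windows.mean(axis=(2, 3))
    s = windows.std(axis=(2, 3))
    t = m * (1 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1))
    return x < t if params.polarity == "dark_objects" else x > t


class TestPhansalkar:
    def test_constant_image_closed_form(self):
        # m = 0.5, s = 0 -> t = 0.5·(1 + 2e^-5 - 0.25) ≈ 0.38174
        img = np.full((32, 32), 128, dtype=np.uint8)  # 128/255 ≈ 0.502
        params = ThresholdParams(radius=5, polarity="bright_objects")
        mask = phansalkar_threshold(img, params)
        m = 128 / 255
        t = m * (1 + 2 * np.exp(-10 * m) - 0.25)
        assert t == pytest.approx(0.3832, abs=1e-3)
        assert mask.all()  # value > t everywhere
        assert not phansalkar_threshold(img, ThresholdParams(radius=5)).any()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        params = ThresholdParams(radius=5)
        np.testing.assert_array_equal(phansalkar_threshold(img, params), phansalkar_oracle(img, params))

    def test_step_edge_polarity(self):
        img = np.full((40, 40), 200, dtype=np.uint8)
        img[:, 20:] = 40
        params = ThresholdParams(radius=4)
        mask = phansalkar_threshold(img, params)
        oracle = phansalkar_oracle(img, params)
        np.testing.assert_array_equal(mask, oracle)
        # away from the transition band, only the dark side is foreground
        assert mask[:, 30:].all()
        assert not mask[:, :12].any()

    def test_requires_8bit(self):
        with pytest.raises(ValueError, match="8-bit"):
            phansalkar_threshold(np.zeros((8, 8), dtype=np.uint16), ThresholdParams(radius=2))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ThresholdParams(radius=0)
        with pytest.raises(ValueError):
            ThresholdParams(polarity="sideways")


class TestAnalyzeParticles:
    def test_edge_particle_excluded(self):
        mask = np.zeros((80, 80), dtype=bool)
        for center in [(20, 20), (20, 60), (78, 40)]:  # third overlaps border
            rr, cc = draw.disk(center, 8, shape=mask.shape)
            mask[rr, cc] = True
        records = analyze_particles(mask, calibration=1.0)
        assert len(records) == 2

    def test_holes_filled(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = draw.disk((20, 20), 10, shape=mask.shape)
        mask[rr, cc] = True
        filled_area = mask.sum()
        hole_rr, hole_cc = draw.disk((20, 20), 4, shape=mask.shape)
        mask[hole_rr, hole_cc] = False  # annulus
        records = analyze_particles(mask, calibration=1.0)
        assert len(records) == 1
        assert records[0].area_px == filled_area

    def test_all_zero_mask(self):
        assert analyze_particles(np.zeros((10, 10), dtype=bool), calibration=1.0) == []

    def test_min_size_in_area_units(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = draw.disk((15, 15), 2, shape=mask.shape)  # ~12 px
        mask[rr, cc] = True
        rr, cc = draw.disk((40, 40), 6, shape=mask.shape)  # ~113 px
        mask[rr, cc] = True
        # calibration 2 µm/px: areas ~48 µm² and ~450 µm²; threshold 100 µm²
        records = analyze_particles(mask, calibration=2.0, min_size=100.0)
        assert len(records) == 1
        # same geometry interpreted as an equivalent-diameter filter
        records = analyze_particles(mask, calibration=2.0, min_size=10.0, min_size_unit="diameter")
        assert len(records) == 1

    def test_roi_restricts_particles(self):
        mask = np.zeros((60, 60), dtype=bool)
        for center in [(15, 15), (45, 45)]:
            rr, cc = draw.disk(center, 5, shape=mask.shape)
            mask[rr, cc] = True
        roi = [(0, 0), (0, 30), (30, 30), (30, 0)]  # only the first disk
        records = analyze_particles(mask, calibration=1.0, roi=roi)
        assert len(records) == 1
        assert records[0].centroid == pytest.approx((15, 15), abs=0.5)

    def test_degenerate_roi_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        with pytest.raises(ValueError):
            analyze_particles(mask, calibration=1.0, roi=[(0, 0), (0, 1)])


def _particle(i, area):
    return ParticleRecord(
        id=i, area_px=int(area), area_um2=float(area), centroid=(0.0, 0.0),
        touches_edge=False, solidity=1.0,
    )


class TestTopK:
    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        areas = rng.uniform(10, 5000, size=150)
        particles = [_particle(i, a) for i, a in enumerate(areas)]
        summary = topk_mean_area(particles, k=100)
        oracle = float(np.mean(np.sort(areas)[::-1][:100]))
        assert summary.mean_top_k_area == pytest.approx(oracle, rel=0, abs=1e-9)
        assert not summary.truncated

    def test_exactly_k_particles_plain_mean(self):
        particles = [_particle(i, 10 * (i + 1)) for i in range(5)]
        summary = topk_mean_area(particles, k=5)
        assert summary.mean_top_k_area == pytest.approx(30.0)

    def test_fewer_than_k_truncates(self):
        particles = [_particle(i, 100.0) for i in range(10)]
        summary = topk_mean_area(particles, k=100)
        assert summary.truncated and summary.top_k == 10

    def test_monotone_in_added_large_particle(self):
        particles = [_particle(i, 50.0) for i in range(20)]
        base = topk_mean_area(particles, k=10).mean_top_k_area
        grown = topk_mean_area(particles + [_particle(99, 500.0)], k=10).mean_top_k_area
        assert grown >= base

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            topk_mean_area([], k=100)


class TestSummarizeCondition:
    @staticmethod
    def _summary(mean, donor="HC1", oxygen="2%", cond=Condition.DMSO, well=1, calib=2.0):
        return WellSummary(
            n_particles=120, top_k=100, mean_top_k_area=mean, truncated=False,
            calibration=calib,
            key=SampleKey(donor=donor, oxygen=oxygen, condition=cond, well=well),
        )

    def test_two_wells_average(self):
        out = summarize_condition([self._summary(100.0, well=1), self._summary(200.0, well=2)])
        assert len(out) == 1
        assert out.mean_top_k_area.iloc[0] == pytest.approx(150.0)

    def test_three_donor_grid_matches_hand_oracle(self):
        rng = np.random.default_rng(4)
        summaries, expected = [], {}
        for donor in ("HC1", "HC2", "UC1"):
            for cond in (Condition.DMSO, Condition.TOFA):
                means = rng.uniform(500, 3000, size=3)
                expected[(donor, "2%", cond.label)] = means.mean()
                summaries += [
                    self._summary(m, donor=donor, cond=cond, well=w + 1)
                    for w, m in enumerate(means)
                ]
        out = summarize_condition(summaries)
        for (donor, oxygen, cond), mean in expected.items():
            row = out[(out.donor == donor) & (out.condition == cond)]
            assert row.mean_top_k_area.iloc[0] == pytest.approx(mean)

    def test_mixed_calibration_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            summarize_condition([self._summary(100.0, well=1), self._summary(100.0, well=2, calib=1.0)])


class TestPipelineRecovery:
    def test_counts_and_areas_recovered(self, brightfield_scene):
        image, truth = brightfield_scene
        mask = phansalkar_threshold(image, ThresholdParams(radius=15))
        records = analyze_particles(mask, calibration=image.calibration, min_size=10.0)
        planted = truth.objects[~truth.objects.touches_edge]
        assert len(records) == len(planted)
        rec = pd.DataFrame(
            {"row": [p.centroid[0] for p in records], "col": [p.centroid[1] for p in records],
             "area_px": [p.area_px for p in records]}
        )
        for _, obj in planted.iterrows():
            dist = np.hypot(rec.row - obj.row, rec.col - obj.col)
            match = rec.loc[dist.idxmin()]
            rel_err = abs(match.area_px - obj.area_px) / obj.area_px
            if obj.equiv_diam_px >= 10:
                assert rel_err <= 0.05
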