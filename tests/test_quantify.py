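"""qPCR calibration, absolute quantification and ratio estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodui.quantify import (
    DilutionSeries,
    StandardCurve,
    fit_standard_curve,
    ngs_ratio,
    quantify_sample,
    ratio_with_ci,
)
from mitodui.simulate import QpcrSimConfig, simulate_qpcr_dataset


def perfect_series(slope=-3.3219, icq=37.0, target="F_cox1", decades=(0, 2, 4, 6)):
    pts = [(10.0**d, [icq + slope * d] * 3) for d in decades]
    return DilutionSeries(target, pts)


class TestStandardCurve:
    def test_perfect_doubling(self):
        curve = fit_standard_curve(perfect_series())
        assert curve.slope == pytest.approx(-3.3219, abs=1e-6)
        assert curve.intercept_cq == pytest.approx(37.0, abs=1e-6)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.qc_pass

    def test_low_efficiency_fails_qc(self):
        curve = fit_standard_curve(perfect_series(slope=-3.6))
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-6)
        assert not curve.qc_pass

    def test_noisy_series_recovers_slope(self):
        rng = np.random.default_rng(0)
        slopes = []
        for i in range(20):
            pts = [
                (10.0**d, list(37.0 - 3.3219 * d + rng.normal(0, 0.1, 3)))
                for d in range(1, 8)
            ]
            slopes.append(fit_standard_curve(DilutionSeries("t", pts)).slope)
        assert np.mean(slopes) == pytest.approx(-3.3219, abs=0.05)

    def test_positive_slope_rejected(self):
        pts = [(10.0**d, [20.0 + d] * 2) for d in range(4)]
        with pytest.raises(ValueError, match="slope"):
            fit_standard_curve(DilutionSeries("t", pts))

    def test_narrow_range_rejected(self):
        pts = [(c, [30.0] * 2) for c in (100.0, 150.0, 200.0)]
        with pytest.raises(ValueError, match="decade"):
            fit_standard_curve(DilutionSeries("t", pts))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            DilutionSeries("t", [(10.0, [30.0]), (100.0, [27.0])])

    def test_efficiency_invariant_under_copy_scaling(self):
        base = fit_standard_curve(perfect_series())
        scaled = fit_standard_curve(
            DilutionSeries(
                "t", [(c * 50, cqs) for c, cqs in perfect_series().points]
            )
        )
        assert scaled.slope == pytest.approx(base.slope, abs=1e-9)
        assert scaled.efficiency == pytest.approx(base.efficiency, abs=1e-9)
        assert scaled.intercept_cq != pytest.approx(base.intercept_cq)


class TestQuantifySample:
    @pytest.fixture
    def curve(self):
        return StandardCurve("F_cox1", -3.3219, 37.0, 1.0)

    def test_one_copy_at_intercept(self, curve):
        q = quantify_sample([37.0], curve)
        assert q.copies == pytest.approx(1.0)

    def test_hundred_copies(self, curve):
        q = quantify_sample([30.3562], curve)
        assert q.copies == pytest.approx(100.0, rel=1e-4)

    def test_zero_spread_zero_width(self, curve):
        q = quantify_sample([30.3562] * 3, curve)
        assert q.ci_low == q.ci_high == pytest.approx(q.copies)

    def test_ci_brackets_estimate(self, curve):
        q = quantify_sample([30.2, 30.4, 30.5], curve)
        assert q.ci_low <= q.copies <= q.ci_high
        assert q.ci_low < q.ci_high

    def test_below_detection_flag(self, curve):
        assert quantify_sample([36.0] * 3, curve).below_detection
        assert not quantify_sample([30.0] * 3, curve).below_detection

    def test_empty_errors(self, curve):
        with pytest.raises(ValueError):
            quantify_sample([], curve)

@settings(deadline=None, max_examples=40)
@given(copies=st.floats(min_value=1.0, max_value=1e9))
def test_noiseless_round_trip(copies):
    curve = StandardCurve("F_cox1", -3.3219, 37.0, 1.0)
    cq = curve.cq_from_copies(copies)
    q = quantify_sample([cq], curve, detection_cutoff=1e9)
    assert q.copies == pytest.approx(copies, rel=1e-9)


class TestRatio:
    @pytest.fixture
    def curves(self):
        return (
            StandardCurve("M_nad1", -3.3219, 37.5, 1.0),
            StandardCurve("F_cox1", -3.3219, 37.0, 1.0),
        )

    def test_equal_copies_ratio_one(self, curves):
        cm, cf = curves
        qm = quantify_sample([cm.cq_from_copies(500.0)] * 3, cm, sample_id="s")
        qf = quantify_sample([cf.cq_from_copies(500.0)] * 3, cf, sample_id="s")
        est = ratio_with_ci(qm, qf)
        assert est.ratio == pytest.approx(1.0)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_self_ratio_ci_contains_one(self, curves):
        cm, _ = curves
        rng = np.random.default_rng(1)
        cqs = list(cm.cq_from_copies(800.0) + rng.normal(0, 0.05, 3))
        q = quantify_sample(cqs, cm, sample_id="s")
        est = ratio_with_ci(q, q)
        assert est.ratio == pytest.approx(1.0)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_below_detection_numerator_bounded(self, curves):
        cm, cf = curves
        qm = quantify_sample([36.5] * 3, cm, sample_id="s")
        qf = quantify_sample([25.0] * 3, cf, sample_id="s")
        est = ratio_with_ci(qm, qf)
        assert est.below_detection
        assert est.ci_low == 0.0

    def test_below_detection_denominator_undefined(self, curves):
        cm, cf = curves
        qm = quantify_sample([25.0] * 3, cm, sample_id="s")
        qf = quantify_sample([36.5] * 3, cf, sample_id="s")
        est = ratio_with_ci(qm, qf)
        assert est.below_detection and math.isnan(est.ratio)

    def test_coverage_near_nominal(self, curves):
        cm, cf = curves
        rng = np.random.default_rng(2)
        true_ratio, hits, N = 10.0, 0, 300
        for _ in range(N):
            cqm = cm.cq_from_copies(5000.0) + rng.normal(0, 0.05, 3)
            cqf = cf.cq_from_copies(500.0) + rng.normal(0, 0.05, 3)
            est = ratio_with_ci(
                quantify_sample(list(cqm), cm, sample_id="s"),
                quantify_sample(list(cqf), cf, sample_id="s"),
            )
            hits += est.ci_low <= true_ratio <= est.ci_high
        assert 0.90 <= hits / N <= 0.99


class TestNgsRatio:
    def test_reads_proportional_to_length(self):
        est = ngs_ratio(2400, 1800, 24_000, 18_000, seed=0)
        assert est.ratio == pytest.approx(1.0)

    def test_hand_computed(self):
        est = ngs_ratio(200, 100, 24_000, 18_000, seed=0)
        assert est.ratio == pytest.approx((200 / 24_000) / (100 / 18_000))
        assert est.ratio == pytest.approx(1.5)

    def test_zero_f_reads_bounded(self):
        est = ngs_ratio(100, 0, 24_000, 18_000, seed=0)
        assert est.below_detection and math.isinf(est.ratio)

    def test_no_reads_errors(self):
        with pytest.raises(ValueError):
            ngs_ratio(0, 0, 24_000, 18_000)

    def test_ci_brackets_point(self):
        est = ngs_ratio(31_000, 1000, 24_347, 18_113, seed=3)
        assert est.ci_low < est.ratio < est.ci_high
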