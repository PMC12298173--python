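"""RTD functions, moments, regime classification and the image pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulab.rtd import (
    ConcentrationSeries,
    FlowRegime,
    NoTracerError,
    analyze_series,
    classify_flow_regime,
    cumulative_function,
    density_function,
    dimensionless_curves,
    dimensionless_variance,
    image_to_rtd,
    mean_residence_time,
    times_from_collection_window,
    variance,
)


def exponential_series(tau=30.0, dt=0.01, span=50):
    t = np.arange(dt / 2, span * tau, dt)
    return ConcentrationSeries(t, np.exp(-t / tau) / tau, np.full_like(t, dt))


class TestTimeGrid:
    def test_uniform_window(self):
        t, dt = times_from_collection_window(0, 200, 200)
        np.testing.assert_allclose(dt, 1.0)
        np.testing.assert_allclose(t, np.arange(200) + 0.5)

    def test_single_bin(self):
        t, dt = times_from_collection_window(0, 200, 1)
        assert t[0] == pytest.approx(100.0)
        assert dt[0] == pytest.approx(200.0)

    def test_offset_window(self):
        t, dt = times_from_collection_window(30, 230, 100)
        assert dt[0] == pytest.approx(2.0)
        assert t[0] == pytest.approx(31.0)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            times_from_collection_window(10, 10, 5)


class TestDensityAndCumulative:
    def test_symmetric_pulse(self):
        cs = ConcentrationSeries([0.5, 1.5, 2.5, 3.5], [0, 2, 2, 0], 1.0)
        e = density_function(cs)
        np.testing.assert_allclose(e, [0, 0.5, 0.5, 0])
        np.testing.assert_allclose(cumulative_function(e, cs.dt), [0, 0.5, 1, 1])

    def test_uniform_concentration_gives_flat_density(self):
        cs = ConcentrationSeries(np.arange(10) + 0.5, np.full(10, 3.0), 1.0)
        np.testing.assert_allclose(density_function(cs), 0.1)

    def test_unequal_bin_widths(self):
        cs = ConcentrationSeries([1.0, 2.5], [1.0, 3.0], [2.0, 1.0])
        e = density_function(cs)
        np.testing.assert_allclose(e, [0.2, 0.6])
        np.testing.assert_allclose(cumulative_function(e, cs.dt), [0.4, 1.0])

    def test_all_zero_concentration_raises(self):
        with pytest.raises(NoTracerError):
            ConcentrationSeries([0.5, 1.5], [0.0, 0.0], 1.0)


class TestMoments:
    def test_dirac_pulse(self):
        cs = ConcentrationSeries([9.5, 10.0, 10.5], [0, 5.0, 0], 0.5)
        res = analyze_series(cs)
        assert res.moments.t_m == pytest.approx(10.0)
        assert res.moments.sigma2 == pytest.approx(0.0)
        assert res.regime.label is FlowRegime.PLUG_FLOW

    def test_symmetric_density_mean(self):
        t = np.arange(100) + 0.5
        c = np.exp(-0.5 * ((t - 50) / 5) ** 2)
        res = analyze_series(ConcentrationSeries(t, c, 1.0))
        assert res.moments.t_m == pytest.approx(50.0, abs=1e-6)

    def test_two_point_distribution_by_hand(self):
        cs = ConcentrationSeries([0.0, 2.0], [1.0, 1.0], 1.0)
        e = density_function(cs)
        t_m = mean_residence_time(cs.t, e, cs.dt)
        s2 = variance(cs.t, e, cs.dt, t_m)
        assert t_m == pytest.approx(1.0)
        assert s2 == pytest.approx(1.0)

    def test_exponential_closed_forms(self):
        cs = exponential_series(tau=30.0)
        res = analyze_series(cs)
        assert res.moments.t_m == pytest.approx(30.0, abs=0.1)
        assert res.moments.sigma2 == pytest.approx(900.0, abs=5.0)
        # F at one mean residence time: 1 - 1/e
        i = np.searchsorted(res.functions.theta, 1.0)
        assert res.functions.f_theta[i] == pytest.approx(1 - np.exp(-1), abs=1e-3)


class TestDimensionless:
    @pytest.mark.parametrize(
        "t_m, sigma2, expected",
        [
            (113, 7939, 0.62),   # tracer-dosage study, 1.00 mg
            (127, 9392, 0.58),   # throughput study, 40% opening
            (84, 3327, 0.47),    # 60% opening
            (73, 2022, 0.38),    # 80% opening
            (102, 5746, 0.55),   # screw-speed study, 250 r/min
        ],
    )
    def test_published_moment_pairs(self, t_m, sigma2, expected):
        assert round(dimensionless_variance(t_m, sigma2), 2) == expected

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            dimensionless_variance(0.0, 1.0)

    def test_theta_scaling(self):
        theta, f_theta = dimensionless_curves([50.0, 100.0, 200.0],
                                              [0.2, 0.5, 1.0], 100.0)
        np.testing.assert_allclose(theta, [0.5, 1.0, 2.0])
        np.testing.assert_allclose(f_theta, [0.2, 0.5, 1.0])


class TestRegime:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.0, FlowRegime.PLUG_FLOW),
            (0.03, FlowRegime.PLUG_FLOW),
            (0.58, FlowRegime.INTERMEDIATE),
            (0.97, FlowRegime.MIXED_FLOW),
            (1.0, FlowRegime.MIXED_FLOW),
        ],
    )
    def test_thresholds(self, value, label):
        assert classify_flow_regime(value).label is label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_flow_regime(-0.1)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    n=st.integers(5, 60),
    k=st.floats(1e-3, 1e3),
    seed=st.integers(0, 2**16),
)
def test_normalization_and_scale_invariance(n, k, seed):
    """E integrates to 1, F ends at 1, and every moment is invariant
    under rescaling of the concentration proxy."""
    rng = np.random.default_rng(seed)
    t = np.cumsum(rng.uniform(0.5, 2.0, n))
    dt = rng.uniform(0.5, 2.0, n)
    c = rng.uniform(0, 1, n)
    c[rng.integers(n)] += 1.0  # guarantee tracer mass
    base = analyze_series(ConcentrationSeries(t, c, dt))
    scaled = analyze_series(ConcentrationSeries(t, k * c, dt))
    assert np.sum(base.functions.e * dt) == pytest.approx(1.0, abs=1e-9)
    assert base.functions.f[-1] == pytest.approx(1.0, abs=1e-9)
    assert scaled.moments.t_m == pytest.approx(base.moments.t_m, rel=1e-9)
    assert scaled.moments.sigma2 == pytest.approx(base.moments.sigma2, rel=1e-9)
    assert scaled.moments.sigma_theta2 == pytest.approx(base.moments.sigma_theta2,
                                                        rel=1e-9)


def test_moment_consistency_dimensionless_route():
    cs = exponential_series(tau=20.0, dt=0.05, span=40)
    res = analyze_series(cs)
    e, dt, t_m = res.functions.e, cs.dt, res.moments.t_m
    theta = cs.t / t_m
    direct = float(np.sum((theta - 1.0) ** 2 * e * dt * t_m**2)) / t_m**2
    assert res.moments.sigma_theta2 == pytest.approx(direct, abs=1e-9)


class TestImagePipeline:
    def test_round_trip_recovers_truth(self, tanks3_images):
        fx = tanks3_images
        res = image_to_rtd(fx["sample"], fx["blank"], fx["spec"].region(),
                           fx["truth"]["t0"], fx["truth"]["t1"])
        assert res.moments.t_m == pytest.approx(100.0, rel=0.02)
        assert res.moments.sigma_theta2 == pytest.approx(1 / 3, abs=0.02)
        assert res.regime.label is FlowRegime.INTERMEDIATE

    def test_identical_images_raise_no_tracer(self, tanks3_images):
        fx = tanks3_images
        with pytest.raises(NoTracerError):
            image_to_rtd(fx["blank"], fx["blank"], fx["spec"].region(), 0, 400)

    def test_plug_flow_band_image(self, tanks3_images):
        """A narrow dark band around one height reads as plug flow."""
        spec = tanks3_images["spec"]
        blank = tanks3_images["blank"]
        sample = blank.copy()
        region = spec.region()
        # paint 10 of 200 grids dark at mid-height
        rows = slice(500, 550)
        sample[rows, region.col_start:region.col_stop] = 40
        res = image_to_rtd(sample, blank, region, 0, 400)
        assert res.moments.sigma_theta2 < 0.05
        assert res.regime.label is FlowRegime.PLUG_FLOW

    def test_calibrated_concentration_mode(self, tanks3_images):
        fx = tanks3_images
        res = image_to_rtd(fx["sample"], fx["blank"], fx["spec"].region(),
                           0, 400, calibration=fx["cal"])
        # same normalized curve as the darkness-signal route
        assert res.moments.t_m == pytest.approx(100.0, rel=0.02)
        assert res.moments.sigma_theta2 == pytest.approx(1 / 3, abs=0.02)
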