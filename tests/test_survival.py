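import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marsalt import (
    FitError,
    InvalidParameterError,
    OutOfRangeError,
    SurvivalAnchor,
    default_anchors,
    fit_weibull,
    interpolant_curve,
    surviving_fraction,
    weibull_curve,
)
from marsalt.survival import read_anchors_csv, write_anchors_csv


class TestDefaultAnchors:
    def test_values(self):
        anchors = default_anchors()
        assert [(a.time, a.surviving_fraction) for a in anchors] == [
            (60.0, 0.50),
            (3600.0, 0.03),
            (86400.0, 0.005),
        ]

    def test_sorted_and_non_increasing(self):
        anchors = default_anchors()
        times = [a.time for a in anchors]
        fracs = [a.surviving_fraction for a in anchors]
        assert times == sorted(times)
        assert fracs == sorted(fracs, reverse=True)


class TestInterpolant:
    def test_exact_at_anchors(self, anchor_curve):
        for a in default_anchors():
            assert surviving_fraction(anchor_curve, a.time) == pytest.approx(
                a.surviving_fraction, rel=1e-14
            )

    def test_log_log_geometric_midpoint(self, anchor_curve):
        """At the geometric mean of two anchor times, log-log linearity
        forces the geometric mean of their fractions: sqrt(0.5*0.03)."""
        t_mid = math.sqrt(60.0 * 3600.0)
        expected = math.sqrt(0.50 * 0.03)  # ~0.1225
        assert surviving_fraction(anchor_curve, t_mid) == pytest.approx(
            expected, rel=1e-12
        )

    def test_out_of_range_raises_without_extrapolation(self, anchor_curve):
        with pytest.raises(OutOfRangeError):
            surviving_fraction(anchor_curve, 10.0)
        with pytest.raises(OutOfRangeError):
            surviving_fraction(anchor_curve, 1e6)

    def test_extrapolation_extends_terminal_power_law(self):
        curve = interpolant_curve(allow_extrapolation=True)
        # beyond the last anchor the local slope continues, so S keeps
        # decreasing below the final anchor value
        assert surviving_fraction(curve, 2 * 86400.0) < 0.005
        assert surviving_fraction(curve, 30.0) > 0.50

    def test_nonpositive_time_rejected(self, anchor_curve):
        with pytest.raises(InvalidParameterError):
            surviving_fraction(anchor_curve, 0.0)

    def test_unsorted_anchors_rejected(self):
        with pytest.raises(InvalidParameterError):
            interpolant_curve([SurvivalAnchor(100.0, 0.5), SurvivalAnchor(10.0, 0.9)])

    def test_increasing_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            interpolant_curve([SurvivalAnchor(10.0, 0.5), SurvivalAnchor(100.0, 0.9)])


class TestWeibull:
    def test_scale_parameter_gives_exp_minus_one(self):
        curve = weibull_curve(0.6, 120.0)
        assert surviving_fraction(curve, 120.0) == pytest.approx(math.exp(-1), rel=1e-14)

    def test_halving_time_lengthens_when_shape_below_one(self):
        """With k < 1, each successive halving of the survivors takes
        longer than the previous one (sub-exponential inactivation)."""
        curve = weibull_curve(0.3, 100.0)
        # times at which S = 1/2, 1/4, 1/8 ... : t_m = lambda*(m*ln2)^(1/k)
        t = [100.0 * (m * math.log(2)) ** (1 / 0.3) for m in range(1, 6)]
        gaps = np.diff(t)
        assert np.all(np.diff(gaps) > 0)
        for m, tm in enumerate(t, start=1):
            assert surviving_fraction(curve, tm) == pytest.approx(0.5**m, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            weibull_curve(-0.5, 100.0)
        with pytest.raises(InvalidParameterError):
            weibull_curve(0.5, 0.0)


class TestFitWeibull:
    def test_noiseless_self_consistency(self):
        """Fitting exact Weibull samples recovers the parameters."""
        k_true, lam_true = 0.6, 120.0
        curve = weibull_curve(k_true, lam_true)
        times = np.geomspace(5.0, 5000.0, 10)
        data = [(t, float(surviving_fraction(curve, t))) for t in times]
        k, lam = fit_weibull(data)
        assert k == pytest.approx(k_true, rel=1e-2)
        assert lam == pytest.approx(lam_true, rel=1e-2)

    def test_default_anchors_give_sub_exponential_shape(self):
        """The three digitized anchors fit to k ~ 0.285 < 1, lambda ~ 134 s
        (frozen from an independent hand regression of log(-log S) on log t)."""
        pts = [(a.time, a.surviving_fraction) for a in default_anchors()]
        k, lam = fit_weibull(pts)
        assert k < 1.0
        assert k == pytest.approx(0.28514, rel=1e-3)
        assert lam == pytest.approx(133.74, rel=1e-3)

    def test_matches_independent_regression(self):
        """Cross-check the fit against scipy's linregress on the same
        linearisation."""
        from scipy.stats import linregress

        pts = [(a.time, a.surviving_fraction) for a in default_anchors()]
        k, lam = fit_weibull(pts)
        x = np.log([t for t, _ in pts])
        y = np.log(-np.log([s for _, s in pts]))
        res = linregress(x, y)
        assert k == pytest.approx(res.slope, rel=1e-12)
        assert lam == pytest.approx(math.exp(-res.intercept / res.slope), rel=1e-12)

    @pytest.mark.parametrize(
        "data",
        [
            [(60.0, 0.5)],                      # single point
            [(60.0, 0.5), (60.0, 0.3)],         # degenerate times
            [(60.0, 0.5), (120.0, 1.0)],        # fraction not in (0,1)
            [(60.0, 0.5), (-1.0, 0.3)],         # nonpositive time
        ],
    )
    def test_degenerate_inputs_raise(self, data):
        with pytest.raises(FitError):
            fit_weibull(data)


@settings(max_examples=100, derandomize=True)
@given(
    k=st.floats(min_value=0.05, max_value=5.0),
    lam=st.floats(min_value=1.0, max_value=1e6),
    t1=st.floats(min_value=1e-3, max_value=1e9),
    t2=st.floats(min_value=1e-3, max_value=1e9),
)
def test_weibull_fraction_non_increasing(k, lam, t1, t2):
    curve = weibull_curve(k, lam)
    lo, hi = sorted((t1, t2))
    assert surviving_fraction(curve, lo) >= surviving_fraction(curve, hi)


@settings(max_examples=100, derandomize=True)
@given(data=st.data())
def test_interpolant_fraction_non_increasing(data):
    """Monotone anchors force a monotone interpolant everywhere."""
    n = data.draw(st.integers(min_value=2, max_value=6))
    times = sorted(
        data.draw(
            st.lists(
                st.floats(min_value=1.0, max_value=1e6),
                min_size=n, max_size=n, unique=True,
            )
        )
    )
    fracs = sorted(
        data.draw(
            st.lists(
                st.floats(min_value=1e-6, max_value=1.0),
                min_size=n, max_size=n,
            )
        ),
        reverse=True,
    )
    curve = interpolant_curve(
        [SurvivalAnchor(t, f) for t, f in zip(times, fracs)]
    )
    t_eval = np.linspace(times[0], times[-1], 50)
    s = surviving_fraction(curve, t_eval)
    assert np.all(np.diff(s) <= 1e-12)


def test_anchor_csv_roundtrip(tmp_path):
    path = tmp_path / "anchors.csv"
    write_anchors_csv(default_anchors(), path)
    back = read_anchors_csv(path)
    assert back == default_anchors()
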