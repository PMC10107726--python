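"""Initial-rate fitting, unit conversion, control subtraction, heat map."""

import numpy as np
import pandas as pd
import pytest

from iredmine.kinetics import (
    EPSILON_NADPH,
    AbsorbanceTrace,
    build_heatmap,
    fit_initial_rate,
    plate_rates,
    rate_for_trace,
    slope_to_rate,
    subtract_controls,
    traces_from_frame,
)
from iredmine.synth import gen_plate, gen_trace


def _trace(times, a340, **kw):
    base = dict(well="A1", enzyme="e", substrate="s", cofactor="NADPH",
                pH=7.0, replicate=1)
    base.update(kw)
    return AbsorbanceTrace(times=np.asarray(times), a340=np.asarray(a340), **base)


class TestFitInitialRate:
    def test_constant_trace_gives_zero_slope(self):
        t = np.arange(0, 30, 1.0)
        slope, r2, _ = fit_initial_rate(_trace(t, np.full_like(t, 0.9)))
        assert slope == pytest.approx(0.0)
        assert r2 == 1.0

    def test_exact_line_recovered(self):
        t = np.arange(0, 30, 0.5)
        slope, r2, _ = fit_initial_rate(_trace(t, 1.0 - 0.00622 * t))
        assert slope == pytest.approx(-0.00622)
        assert r2 == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            _trace([0, 1, 2, 3], [1, 1, 1, 1])

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _trace([0, 1, 1, 2, 3], [1, 1, 1, 1, 1])

    def test_window_avoids_plateau(self):
        # depletion at 0.1 mM/min exhausts 0.2 mM cofactor at 2 min
        trace = gen_trace(0.1, noise_sd=0.0, seed=0)
        result = rate_for_trace(trace)
        assert result.rate == pytest.approx(0.1, rel=1e-6)

    def test_recovery_unbiased_with_noise(self):
        """Mean recovered rate within 5% of truth over 100 noisy traces."""
        rates = [
            rate_for_trace(gen_trace(0.02, noise_sd=0.002, seed=s)).rate
            for s in range(100)
        ]
        assert np.mean(rates) == pytest.approx(0.02, rel=0.05)


class TestSlopeToRate:
    @pytest.mark.parametrize(
        "slope,expected",
        [(-0.00622, 0.001), (-0.0622, 0.01), (0.0, 0.0)],
    )
    def test_conversion(self, slope, expected):
        assert slope_to_rate(slope, 6220.0, 1.0) == pytest.approx(expected)

    def test_linear_in_slope_inverse_in_epsilon_and_path(self):
        base = slope_to_rate(-0.01, 6220.0, 1.0)
        assert slope_to_rate(-0.02, 6220.0, 1.0) == pytest.approx(2 * base)
        assert slope_to_rate(-0.01, 12440.0, 1.0) == pytest.approx(base / 2)
        assert slope_to_rate(-0.01, 6220.0, 0.5) == pytest.approx(2 * base)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            slope_to_rate(-0.01, 0.0, 1.0)
        with pytest.raises(ValueError):
            slope_to_rate(-0.01, 6220.0, -1.0)


def _rate_result(enzyme, rate, substrate="s", cofactor="NADPH", pH=7.0):
    from iredmine.kinetics import RateResult

    return RateResult(
        enzyme=enzyme, substrate=substrate, cofactor=cofactor, pH=pH,
        slope=-rate * EPSILON_NADPH / 1000.0, rate=rate,
        fit_window=(0, 4), r2=1.0, path_length=1.0,
    )


class TestSubtractControls:
    def test_mean_minus_control_mean(self):
        nets = subtract_controls(
            [_rate_result("e", 0.5)],
            [_rate_result("ctl", 0.1), _rate_result("ctl2", 0.1)],
        )
        assert nets[0].net_rate == pytest.approx(0.4)
        assert not nets[0].below_background

    def test_below_background_floors_at_zero(self):
        nets = subtract_controls(
            [_rate_result("e", 0.05)], [_rate_result("ctl", 0.08)]
        )
        assert nets[0].net_rate == 0.0
        assert nets[0].below_background
        assert nets[0].raw_net == pytest.approx(-0.03)

    def test_missing_control_names_condition(self):
        with pytest.raises(ValueError, match="substrate=s"):
            subtract_controls([_rate_result("e", 0.5)], [])

    def test_replicates_averaged_after_fitting(self):
        nets = subtract_controls(
            [_rate_result("e", 0.4), _rate_result("e", 0.6)],
            [_rate_result("ctl", 0.1)],
        )
        assert nets[0].n_replicates == 2
        assert nets[0].net_rate == pytest.approx(0.4)


class TestHeatmap:
    def test_dense_matrix_no_missing(self):
        nets = [
            _rate_result(e, 0.1, substrate=s, cofactor=c, pH=p)
            for e in ("e1", "e2")
            for s in ("s1", "s2", "s3")
            for c in ("NADPH", "NADH")
            for p in (7.0, 9.0)
        ]
        for n in nets:
            object.__setattr__(n, "net_rate", n.rate)
        hm = build_heatmap(nets)
        assert hm.shape == (2, 12)
        assert not hm.isna().any().any()

    def test_absent_condition_is_missing_not_zero(self):
        nets = [_rate_result("e1", 0.1), _rate_result("e2", 0.2, substrate="s2")]
        for n in nets:
            object.__setattr__(n, "net_rate", n.rate)
        hm = build_heatmap(nets)
        assert hm.isna().sum().sum() == 2

    def test_duplicate_condition_rejected(self):
        nets = [_rate_result("e", 0.1), _rate_result("e", 0.2)]
        with pytest.raises(ValueError, match="duplicate"):
            build_heatmap(nets)

    def test_row_sums_conserve_net_rates(self):
        truth = {
            ("enzA", "MP", "NADPH", 7.0): 0.02,
            ("enzA", "MP", "NADH", 7.0): 0.005,
            ("enzB", "MP", "NADPH", 7.0): 0.05,
        }
        df, _ = gen_plate(truth, seed=8)
        nets, hm = plate_rates(df)
        for enzyme in hm.index:
            expected = sum(n.net_rate for n in nets if n.enzyme == enzyme)
            assert hm.loc[enzyme].sum() == pytest.approx(expected)


class TestEndToEnd:
    def test_plate_recovery_within_noise(self):
        truth = {
            ("enzA", "MP", "NADPH", 7.0): 0.02,
            ("enzB", "MP", "NADPH", 7.0): 0.1,
            ("enzC", "MP", "NADPH", 7.0): 0.0,
        }
        df, _ = gen_plate(truth, noise_sd=0.002, n_replicates=2, seed=5)
        nets, _ = plate_rates(df)
        by_enzyme = {n.enzyme: n for n in nets}
        assert by_enzyme["enzA"].net_rate == pytest.approx(0.02, abs=0.003)
        assert by_enzyme["enzB"].net_rate == pytest.approx(0.1, abs=0.01)
        assert by_enzyme["enzC"].net_rate == pytest.approx(0.0, abs=0.003)

    def test_deterministic_outputs(self):
        truth = {("enzA", "MP", "NADPH", 7.0): 0.02}
        df1, _ = gen_plate(truth, seed=3)
        df2, _ = gen_plate(truth, seed=3)
        pd.testing.assert_frame_equal(df1, df2)
        nets1, hm1 = plate_rates(df1)
        nets2, hm2 = plate_rates(df2)
        assert [n.net_rate for n in nets1] == [n.net_rate for n in nets2]
        pd.testing.assert_frame_equal(hm1, hm2)
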