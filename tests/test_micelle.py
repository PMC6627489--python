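"""CMC break-point fitting and micelle geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfbind import (
    InvalidInputError,
    InvalidShapeError,
    NoBreakError,
    TensiometryCurve,
    TensiometrySpec,
    aggregation_number,
    fit_cmc_breakpoint,
    micelle_geometry,
    simulate_tensiometry,
    sphere_volume,
)
from surfbind.datasets import (
    MICELLE_RH_PM6,
    MICELLE_VMON_PM6,
    REPORTED_NAGG_PM6,
    REPORTED_VMIC_PM6,
    SYSTEMS,
)


class TestSphereVolume:
    @pytest.mark.parametrize(
        "r, expected, tol", [(2.4, 57.9, 0.05), (1.8, 24.43, 0.005), (0.0, 0.0, 1e-15)]
    )
    def test_reference_radii(self, r, expected, tol):
        assert sphere_volume(r) == pytest.approx(expected, abs=tol)

    @settings(derandomize=True, max_examples=50)
    @given(r=st.floats(1e-3, 1e3))
    def test_cubic_scaling(self, r):
        assert sphere_volume(2 * r) == pytest.approx(8 * sphere_volume(r), rel=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(InvalidInputError):
            sphere_volume(-1.0)


class TestAggregationNumber:
    @pytest.mark.parametrize(
        "v_mic, v_mon, expected", [(57.90, 1.61, 36), (24.43, 1.35, 18), (1.0, 1.0, 1)]
    )
    def test_reference_values(self, v_mic, v_mon, expected):
        assert aggregation_number(v_mic, v_mon) == expected

    def test_rounds_half_away_from_zero(self):
        assert aggregation_number(2.5, 1.0) == 3
        assert aggregation_number(0.2, 1.0) == 1  # floor at one monomer

    def test_all_reference_systems_reproduce(self):
        """PM6 radii and monomer volumes give the reported V_mic and N_agg."""
        for system in SYSTEMS:
            geom = micelle_geometry(
                system, MICELLE_RH_PM6[system], MICELLE_VMON_PM6[system], "PM6"
            )
            reported = REPORTED_VMIC_PM6[system]
            decimals = len(str(reported).rsplit(".", 1)[1])
            assert round(geom.v_mic, decimals) == reported
            assert geom.n_agg == REPORTED_NAGG_PM6[system]


class TestCmcBreakpoint:
    @pytest.mark.parametrize("cmc_true", [0.045, 0.017, 0.033])
    def test_noiseless_round_trip(self, cmc_true):
        curve = simulate_tensiometry(TensiometrySpec(cmc_true=cmc_true))
        res = fit_cmc_breakpoint(curve)
        assert res.cmc == pytest.approx(cmc_true, rel=1e-4)
        assert res.gamma_cmc == pytest.approx(28.4, abs=1e-3)
        assert res.slope_pre < res.slope_post <= 1e-3
        assert curve.conc[0] < res.cmc < curve.conc[-1]

    def test_single_line_has_no_break(self):
        c = np.geomspace(0.003, 0.12, 10)
        g = 60.0 - 10.0 * np.log10(c / 0.003)
        with pytest.raises(NoBreakError):
            fit_cmc_breakpoint(TensiometryCurve("line", tuple(c), tuple(g)))

    def test_flat_curve_has_no_break(self):
        c = np.geomspace(0.003, 0.12, 8)
        with pytest.raises(NoBreakError):
            fit_cmc_breakpoint(TensiometryCurve("flat", tuple(c), (30.0,) * 8))

    def test_ascending_curve_is_invalid_shape(self):
        c = np.geomspace(0.003, 0.12, 10)
        g = 30.0 + 10.0 * np.log10(c / 0.003)
        with pytest.raises(InvalidShapeError):
            fit_cmc_breakpoint(TensiometryCurve("asc", tuple(c), tuple(g)))

    def test_noisy_recovery_median_within_10pct(self):
        """100 seeded sigma=0.3 curves: median CMC within 10% of 0.045 mM."""
        recovered = [
            fit_cmc_breakpoint(
                simulate_tensiometry(TensiometrySpec(noise_sd=0.3, seed=1000 + i))
            ).cmc
            for i in range(100)
        ]
        assert abs(np.median(recovered) - 0.045) / 0.045 < 0.10

    def test_bootstrap_ci_is_seeded_and_ordered(self):
        curve = simulate_tensiometry(TensiometrySpec(noise_sd=0.3, seed=7))
        a = fit_cmc_breakpoint(curve, n_boot=50, seed=3)
        b = fit_cmc_breakpoint(curve, n_boot=50, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low < a.ci_high

    def test_bootstrap_coverage_at_least_85pct(self):
        """95% residual-bootstrap CIs cover the true CMC in >= 85/100 runs."""
        hits = 0
        for i in range(100):
            curve = simulate_tensiometry(TensiometrySpec(noise_sd=0.3, seed=1000 + i))
            res = fit_cmc_breakpoint(curve, n_boot=199, seed=i)
            hits += res.ci_low <= 0.045 <= res.ci_high
        assert hits >= 85


class TestCurveInvariants:
    def test_requires_six_points(self):
        with pytest.raises(InvalidInputError):
            TensiometryCurve("x", (0.01, 0.02, 0.04, 0.08, 0.1), (50.0,) * 5)

    def test_rejects_non_increasing_concentration(self):
        c = (0.01, 0.02, 0.02, 0.04, 0.08, 0.1)
        with pytest.raises(InvalidInputError):
            TensiometryCurve("x", c, (50.0,) * 6)
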