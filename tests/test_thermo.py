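"""Van't Hoff regression, Gibbs energies and force classification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from surfbind import (
    ForceClass,
    InsufficientDataError,
    InvalidInputError,
    TemperatureSeries,
    ThermoSpec,
    classify_binding_forces,
    fit_vant_hoff,
    gibbs_from_enthalpy_entropy,
    gibbs_from_k,
    simulate_temperature_series,
)

TEMPS = (298.0, 303.0, 310.0)


class TestVantHoff:
    def test_cu_surfactin_system(self):
        """The Cu complex K_SV triple gives dH -51.30, dS -98.23/-98.24."""
        res = fit_vant_hoff(
            TemperatureSeries("Cu", TEMPS, (7.292e3, 5.102e3, 3.267e3))
        )
        assert res.delta_h == pytest.approx(-51.30, abs=0.05)
        assert res.delta_s == pytest.approx(-98.24, abs=0.05)
        assert res.force_class is ForceClass.HBOND_VDW

    def test_exact_two_point_line(self):
        # ln K = -1000/T + 10 -> slope -1000, intercept 10
        k = tuple(math.exp(-1000.0 / t + 10.0) for t in (298.0, 310.0))
        res = fit_vant_hoff(TemperatureSeries("line", (298.0, 310.0), k))
        assert res.delta_h == pytest.approx(8.314, rel=1e-9)
        assert res.delta_s == pytest.approx(83.14, rel=1e-9)
        assert res.r_squared == 1.0
        assert res.sd == 0.0

    def test_delta_g_consistency_invariant(self):
        res = fit_vant_hoff(
            TemperatureSeries("Cu", TEMPS, (7.292e3, 5.102e3, 3.267e3))
        )
        for t, g in res.delta_g_by_temperature.items():
            assert g == pytest.approx(
                gibbs_from_enthalpy_entropy(res.delta_h, res.delta_s, t), abs=1e-9
            )
            assert g < 0  # binding is spontaneous at every temperature
        # dG rises with T when dS < 0
        gs = [res.delta_g_by_temperature[t] for t in sorted(res.delta_g_by_temperature)]
        assert gs == sorted(gs)

    @settings(derandomize=True, max_examples=50)
    @given(
        dh=st.floats(-100, 100),
        ds=st.floats(-200, 200).filter(lambda v: abs(v) > 1e-6),
    )
    def test_generator_round_trip(self, dh, ds):
        series = simulate_temperature_series(
            ThermoSpec(delta_h_true=dh, delta_s_true=ds, temperatures=TEMPS)
        )
        res = fit_vant_hoff(series)
        assert res.delta_h == pytest.approx(dh, rel=1e-9, abs=1e-9)
        assert res.delta_s == pytest.approx(ds, rel=1e-9, abs=1e-9)

    def test_single_temperature_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            TemperatureSeries("x", (298.0, 298.0), (1e3, 1e3))

    def test_non_positive_k_is_invalid(self):
        with pytest.raises(InvalidInputError):
            TemperatureSeries("x", TEMPS, (1e3, -1.0, 1e3))


class TestGibbs:
    @pytest.mark.parametrize(
        "dh, ds, t, expected",
        [
            (-51.30, -98.23, 310.0, -20.85),
            (-49.07, -91.10, 303.0, -21.47),
            (0.0, 0.0, 298.0, 0.0),
        ],
    )
    def test_from_enthalpy_entropy(self, dh, ds, t, expected):
        assert gibbs_from_enthalpy_entropy(dh, ds, t) == pytest.approx(
            expected, abs=0.005
        )

    @pytest.mark.parametrize(
        "k, t, expected, tol",
        [(7292.0, 298.0, -22.03, 0.05), (1.0, 298.0, 0.0, 1e-12), (6696.0, 298.0, -21.84, 0.05)],
    )
    def test_from_k(self, k, t, expected, tol):
        assert gibbs_from_k(k, t) == pytest.approx(expected, abs=tol)

    def test_two_routes_agree_on_the_fitted_line(self):
        """-RT ln K equals dH - T dS when K lies exactly on the fit."""
        series = simulate_temperature_series(
            ThermoSpec(delta_h_true=-51.30, delta_s_true=-98.23, temperatures=TEMPS)
        )
        for t, k in zip(series.temperatures, series.k_values):
            assert gibbs_from_k(k, t) == pytest.approx(
                gibbs_from_enthalpy_entropy(-51.30, -98.23, t), abs=1e-9
            )


class TestForceClassification:
    @pytest.mark.parametrize(
        "dh, ds, expected",
        [
            (-51.30, -98.23, ForceClass.HBOND_VDW),
            (5.0, 20.0, ForceClass.HYDROPHOBIC),
            (-5.0, 20.0, ForceClass.ELECTROSTATIC),
            (0.0, 20.0, ForceClass.INDETERMINATE),
            (-5.0, 0.0, ForceClass.INDETERMINATE),
        ],
    )
    def test_ross_subramanian_rules(self, dh, ds, expected):
        assert classify_binding_forces(dh, ds) is expected
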