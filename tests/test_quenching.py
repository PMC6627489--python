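"""Inner-filter correction, Stern-Volmer and binding-isotherm regressions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfbind import (
    InsufficientDataError,
    InvalidInputError,
    Mechanism,
    TitrationSeries,
    TitrationSpec,
    classify_mechanism,
    correct_inner_filter,
    correct_series,
    fit_binding_isotherm,
    fit_stern_volmer,
    simulate_titration,
)

CONC = (0.0, 2e-5, 4e-5, 6e-5, 8e-5, 10e-5, 12e-5)


def series_from_model(ksv, conc=CONC, f0=1000.0, **kw):
    q = np.asarray(conc)
    return TitrationSeries(
        label="model", temperature=298.0, quencher_conc=conc,
        intensity_obs=tuple(f0 / (1 + ksv * q)), **kw,
    )


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f_obs, a_ex, a_em, expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 0.1, 0.1, 100 * 10**0.1),
            (250.0, 0.05, 0.03, 250 * 10**0.04),
        ],
    )
    def test_point_correction(self, f_obs, a_ex, a_em, expected):
        assert correct_inner_filter(f_obs, a_ex, a_em) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        f=st.floats(1e-3, 1e6),
        ax=st.floats(0, 2),
        ae=st.floats(0, 2),
        bump=st.floats(1e-6, 1),
    )
    def test_identity_at_zero_and_monotone(self, f, ax, ae, bump):
        base = correct_inner_filter(f, ax, ae)
        assert correct_inner_filter(f, 0.0, 0.0) == f
        assert correct_inner_filter(f, ax + bump, ae) > base
        assert correct_inner_filter(f, ax, ae + bump) > base

    @pytest.mark.parametrize(
        "f, ax, ae", [(-1.0, 0.0, 0.0), (0.0, 0.1, 0.1), (10.0, -0.1, 0.0), (10.0, 0.0, -0.2)]
    )
    def test_invalid_inputs_name_the_index(self, f, ax, ae):
        with pytest.raises(InvalidInputError, match="index 0"):
            correct_inner_filter(f, ax, ae)

    def test_series_correction_returns_new_series(self):
        s = simulate_titration(TitrationSpec(ksv_true=7000, inner_filter_slope=1000))
        corrected = correct_series(s)
        assert corrected is not s
        assert s.has_absorbances()  # input untouched
        assert not corrected.has_absorbances()
        # forward attenuation and correction cancel exactly
        ideal = simulate_titration(TitrationSpec(ksv_true=7000))
        assert corrected.intensity_obs == pytest.approx(ideal.intensity_obs, rel=1e-12)


class TestTitrationSeriesInvariants:
    def test_requires_zero_quencher_first(self):
        with pytest.raises(InvalidInputError):
            TitrationSeries("x", 298.0, (1e-5, 2e-5, 3e-5), (10.0, 9.0, 8.0))

    def test_rejects_non_increasing_concentrations(self):
        with pytest.raises(InvalidInputError):
            TitrationSeries("x", 298.0, (0.0, 2e-5, 2e-5), (10.0, 9.0, 8.0))

    def test_rejects_non_positive_intensity(self):
        with pytest.raises(InvalidInputError, match="index 2"):
            TitrationSeries("x", 298.0, (0.0, 1e-5, 2e-5), (10.0, 9.0, 0.0))

    def test_rejects_mismatched_absorbances(self):
        with pytest.raises(InvalidInputError):
            TitrationSeries(
                "x", 298.0, (0.0, 1e-5, 2e-5), (10.0, 9.0, 8.0), abs_ex=(0.0, 0.1),
                abs_em=(0.0, 0.1, 0.2),
            )


class TestSternVolmer:
    @pytest.mark.parametrize("fix_intercept", [False, True])
    @pytest.mark.parametrize("ksv", [5000.0, 6.696e3, 7.292e3])
    def test_noiseless_round_trip(self, ksv, fix_intercept):
        fit = fit_stern_volmer(series_from_model(ksv), fix_intercept=fix_intercept)
        assert fit.ksv == pytest.approx(ksv, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.sd == pytest.approx(0.0, abs=1e-6)

    def test_kq_is_exactly_ksv_over_tau0(self):
        s = series_from_model(7.292e3, tau0=5e-9)
        fit = fit_stern_volmer(s)
        assert fit.kq == fit.ksv / 5e-9  # bitwise

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_stern_volmer(
                TitrationSeries("x", 298.0, (0.0, 1e-5), (10.0, 9.0))
            )

    def test_non_quenching_slope_warns_indeterminate(self):
        q = np.asarray(CONC)
        s = TitrationSeries(
            "anti", 298.0, CONC, tuple(1000.0 * (1 + 100 * q))  # rising F
        )
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_stern_volmer(s)
        assert fit.mechanism is Mechanism.INDETERMINATE

    def test_noisy_recovery_mean_within_2pct(self):
        """200 seeded 1%-noise titrations: mean K_SV within 2% of truth."""
        vals = [
            fit_stern_volmer(
                simulate_titration(
                    TitrationSpec(ksv_true=7e3, noise_rel=0.01, seed=seed)
                )
            ).ksv
            for seed in range(200)
        ]
        assert abs(np.mean(vals) - 7e3) / 7e3 < 0.02
        sd = float(np.std(vals, ddof=1))
        assert np.isfinite(sd) and sd > 0


class TestMechanism:
    def test_static_call_with_decreasing_trend(self):
        trend = {298.0: 7.292e3, 303.0: 5.102e3, 310.0: 3.267e3}
        assert classify_mechanism(1.458e12, trend) is Mechanism.STATIC

    def test_dynamic_call_with_increasing_trend(self):
        trend = {298.0: 1e3, 303.0: 2e3, 310.0: 3e3}
        assert classify_mechanism(1e9, trend) is Mechanism.DYNAMIC

    def test_rate_criterion_alone(self):
        assert classify_mechanism(3e10) is Mechanism.STATIC

    def test_conflicting_evidence_is_indeterminate(self):
        rising = {298.0: 1e3, 303.0: 2e3, 310.0: 3e3}
        assert classify_mechanism(1e12, rising) is Mechanism.INDETERMINATE
        falling = {298.0: 3e3, 303.0: 2e3, 310.0: 1e3}
        assert classify_mechanism(1e9, falling) is Mechanism.INDETERMINATE

    def test_rejects_non_positive_rate(self):
        with pytest.raises(InvalidInputError):
            classify_mechanism(0.0)


class TestBindingIsotherm:
    @pytest.mark.parametrize("kb, n", [(1e4, 1.0), (1.315e4, 1.07), (0.746e4, 0.99)])
    def test_noiseless_round_trip(self, kb, n):
        s = simulate_titration(TitrationSpec(kb_true=kb, n_true=n))
        fit = fit_binding_isotherm(s)
        assert fit.kb == pytest.approx(kb, rel=1e-3)
        assert fit.n_sites == pytest.approx(n, rel=1e-3)
        assert fit.n_points_used == len(CONC) - 1
        assert fit.excluded_indices == ()

    def test_point_with_f_above_f0_is_excluded(self):
        q = np.asarray(CONC)
        f = 1000.0 / (1 + 1e4 * q)
        f[-1] = 1001.0  # noise pushed the last point above F0
        s = TitrationSeries("noisy", 298.0, CONC, tuple(f))
        fit = fit_binding_isotherm(s)
        assert fit.n_points_used == len(CONC) - 2
        assert fit.excluded_indices == (len(CONC) - 1,)

    def test_too_few_usable_points_lists_exclusions(self):
        q = (0.0, 1e-5, 2e-5, 3e-5)
        s = TitrationSeries("hopeless", 298.0, q, (10.0, 11.0, 12.0, 9.0))
        with pytest.raises(InsufficientDataError, match=r"\[1, 2\]"):
            fit_binding_isotherm(s)
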