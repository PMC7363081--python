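"""Life-table reduction and fitting: summaries, onset rule, normalization,
linear and nonlinear least squares."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from helpers import brute_force_onset
from ovimodel import (
    FemaleRecord,
    detect_onset,
    fit_linear,
    fit_nonlinear,
    normalize_ages,
    summarize,
)
from ovimodel.agedist import (
    Weibull2Params,
    Weibull3Params,
    survival_prop,
    weibull2_cdf,
    weibull3_cdf,
)
from ovimodel.lifetable import assign_onsets
from ovimodel.thermal import (
    AgingParams,
    Briere2Params,
    FecundityParams,
    OdrmParams,
    aging_rate,
    fecundity,
    ovi_rate,
    preovi_rate,
)


class TestSummarize:
    def test_two_record_means(self):
        recs = [
            make_record(longevity=10, rid="a"),
            make_record(longevity=20, rid="b"),
        ]
        row = summarize(recs).iloc[0]
        assert row["longevity_mean"] == 15
        assert row["longevity_median"] == 15
        assert row["n"] == 2

    def test_single_record_flags_se(self):
        row = summarize([make_record(longevity=10)]).iloc[0]
        assert row["longevity_mean"] == 10
        assert np.isnan(row["longevity_se"])

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_fecundity_is_mean_of_lifetime_totals(self):
        recs = [
            make_record(eggs=[0, 10, 30], rid="a"),
            make_record(eggs=[0, 0, 20], rid="b"),
        ]
        assert summarize(recs).iloc[0]["fecundity_mean"] == 30.0


class TestDetectOnset:
    @pytest.mark.parametrize(
        "eggs, expected",
        [
            ([0, 0, 0, 0], None),
            ([0, 0, 6, 8, 4], 3),
            ([0, 7, 0, 0, 0, 0, 0, 0, 0], None),
            ([0, 7, 0, 0, 0, 0, 0, 0, 1], 2),  # laying resumes on day 9
            ([6], None),  # no follow-up possible
            ([0, 4, 4, 9, 2], 4),  # threshold is strict: > 5
        ],
    )
    def test_rule(self, eggs, expected):
        assert detect_onset(eggs) == expected

    @given(
        eggs=st.lists(st.integers(0, 12), min_size=0, max_size=25),
        threshold=st.integers(0, 8),
        window=st.integers(1, 10),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_scan(self, eggs, threshold, window):
        assert detect_onset(eggs, threshold, window) == brute_force_onset(
            eggs, threshold, window
        )

    def test_assign_onsets_sets_apop_and_aop(self):
        rec = make_record(eggs=[0, 0, 6, 8, 0, 3], longevity=8)
        (out,) = assign_onsets([rec])
        assert out.apop == 3
        assert out.aop == 6 - 3 + 1


class TestNormalizeAges:
    def test_survival_ages_divide_by_mean_longevity(self):
        recs = [
            make_record(longevity=10, rid="a"),
            make_record(longevity=20, rid="b"),
        ]
        pts = normalize_ages(recs, "survival")
        ages = pts["physio_age"].to_numpy()
        assert ages[9] == pytest.approx(10 / 15)
        assert ages[19] == pytest.approx(20 / 15)
        # proportions non-increasing within the temperature
        assert np.all(np.diff(pts["proportion"]) <= 0 + 1e-15)

    def test_completion_empirical_cdf(self):
        recs = [
            make_record(rid=f"r{d}", longevity=30, apop=d, aop=5, eggs=np.zeros(30))
            for d in (4, 5, 6)
        ]
        pts = normalize_ages(recs, "completion")
        np.testing.assert_allclose(pts["physio_age"], [0.8, 1.0, 1.2])
        np.testing.assert_allclose(pts["proportion"], [1 / 3, 2 / 3, 1.0])

    def test_missing_reference_mean_is_error(self):
        recs = [make_record(longevity=10)]
        with pytest.raises(ValueError):
            normalize_ages(recs, "survival", reference={23.5: 0.0})


class TestFitLinear:
    def test_exact_line(self):
        p, r = fit_linear([1, 2, 3], [2, 4, 6])
        assert p.slope_a == pytest.approx(2.0)
        assert p.intercept_b == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_region_filter_and_minimum_points(self):
        with pytest.raises(ValueError):
            fit_linear([1, 2, 3, 4], [1, 2, 3, 4], region=(3, 4))

    def test_aop_regression_from_published_means(self, ovi_table):
        """Reciprocal mean oviposition periods over 18.8-32.0 °C give the
        published line 0.0014·T − 0.0175."""
        T = ovi_table["temperature_C"].to_numpy()
        rate = 1.0 / ovi_table["aop_mean"].to_numpy()
        p, r = fit_linear(T, rate, region=(18.8, 32.0))
        assert round(p.slope_a, 4) == 0.0014
        assert round(p.intercept_b, 4) == -0.0175


class TestFitNonlinear:
    """Noise-free samples of each model recover the generating values."""

    def _assert_recovers(self, kind, x, y, truth, fields, rel=1e-6):
        res = fit_nonlinear(kind, x, y)
        assert res.converged
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        for f in fields:
            assert getattr(res.params, f) == pytest.approx(
                getattr(truth, f), rel=rel, abs=1e-8
            ), f"{kind}.{f}"

    def test_aging(self):
        truth = AgingParams(r0=0.0096, T_H=51.4995, c=4.8952)
        T = np.array([13.5, 16.7, 18.8, 23.5, 28.1, 32.0, 34.9])
        self._assert_recovers(
            "aging", T, aging_rate(truth, T), truth, ("r0", "T_H", "c"), rel=1e-5
        )

    def test_fecundity(self):
        truth = FecundityParams(alpha_f=19.3991, T_L=16.3221, T_H=35.2481)
        T = np.linspace(17.0, 35.0, 8)
        self._assert_recovers(
            "fecundity", T, fecundity(truth, T), truth, ("alpha_f", "T_L", "T_H")
        )

    def test_briere2(self):
        truth = Briere2Params(alpha_p=2.8177e-4, T_L=13.3204, T_H=35.1973, m=4.4668)
        T = np.linspace(15.0, 35.0, 9)
        self._assert_recovers(
            "pdrm", T, preovi_rate(truth, T), truth,
            ("alpha_p", "T_L", "T_H", "m"), rel=1e-4,
        )

    def test_odrm_exact_linear_solve(self):
        truth = OdrmParams(a=0.0393, b=1.99645e-17, c=-12.7215, d=871175.0)
        T = np.array([16.7, 18.8, 23.5, 28.1, 32.0, 34.9])
        res = fit_nonlinear("odrm", T, ovi_rate(truth, T))
        np.testing.assert_allclose(
            ovi_rate(res.params, T), ovi_rate(truth, T), rtol=1e-9
        )

    def test_survival_weibull(self):
        truth = Weibull2Params(alpha=1.0921, beta=2.9417)
        x = np.linspace(0.05, 2.0, 30)
        self._assert_recovers(
            "survival", x, survival_prop(truth, x), truth, ("alpha", "beta")
        )

    def test_oorm_weibull(self):
        truth = Weibull2Params(alpha=0.2401, beta=1.0459)
        x = np.linspace(0.02, 1.5, 30)
        self._assert_recovers(
            "oorm", x, weibull2_cdf(truth, x), truth, ("alpha", "beta")
        )

    def test_orm_weibull3(self):
        truth = Weibull3Params(gamma=0.1020, eta=0.2495, beta=1.2024)
        x = np.linspace(0.0, 1.5, 40)
        self._assert_recovers(
            "orm", x, weibull3_cdf(truth, x), truth, ("gamma", "eta", "beta"),
            rel=1e-5,
        )

    def test_needs_more_points_than_parameters(self):
        with pytest.raises(ValueError):
            fit_nonlinear("aging", [20.0, 25.0, 30.0], [0.01, 0.02, 0.03])
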