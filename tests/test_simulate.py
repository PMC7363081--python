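"""Oviposition simulators: onset arithmetic, conservation, cohort ledger."""

import numpy as np
import pytest

from helpers import running_sum_ages
from ovimodel import (
    ParameterSet,
    accumulate_physio_age,
    compare_observed,
    egg_surface,
    lifetime_eggs,
    simulate_current_om,
    simulate_two_phase_om,
)
from ovimodel.agedist import Weibull2Params, Weibull3Params, weibull3_cdf
from ovimodel.thermal import (
    AgingParams,
    Briere2Params,
    FecundityParams,
    OdrmParams,
    fecundity,
)


class TestAccumulatePhysioAge:
    def test_constant_rate(self):
        px = accumulate_physio_age(lambda T: np.full(T.shape, 0.1), np.full(5, 25.0))
        np.testing.assert_allclose(px, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_empty_series(self):
        assert accumulate_physio_age(lambda T: T, []).size == 0

    def test_matches_running_sum_oracle(self):
        rng = np.random.default_rng(5)
        T = rng.uniform(10, 35, 50)
        rate = lambda t: 0.001 * t  # arbitrary rate model
        np.testing.assert_allclose(
            accumulate_physio_age(rate, T), running_sum_ages(rate(T))
        )


class TestCurrentModel:
    def test_no_eggs_below_fecundity_limit(self, params):
        sim = simulate_current_om(params, np.full(200, 13.0))
        assert sim["daily_eggs"].sum() == 0.0

    def test_first_egg_day_from_onset_arithmetic(self, params):
        """At 23.5 °C the aging clock crosses the oviposition onset age
        gamma = 0.1020 on day 8 = ceil(0.1020 / A(23.5))."""
        sim = simulate_current_om(params, np.full(300, 23.5))
        first = int(sim.loc[sim["daily_eggs"] > 0, "day"].iloc[0])
        assert first == 8

    def test_lifetime_bounded_by_fecundity(self, params):
        sim = simulate_current_om(params, np.full(300, 23.5))
        assert lifetime_eggs(sim) <= fecundity(params.fecundity, 23.5)

    def test_requires_nonempty_series(self, params):
        with pytest.raises(ValueError):
            simulate_current_om(params, [])


class TestTwoPhaseModel:
    def test_no_eggs_below_fecundity_limit(self, params):
        sim = simulate_two_phase_om(params, np.full(200, 13.0))
        assert sim["daily_eggs"].sum() == 0.0

    def test_first_egg_day_follows_completion(self, params):
        """At 32 °C the pre-oviposition clock crosses gamma = 0.4852 on
        day 3; the cohort enters oviposition the following day."""
        sim = simulate_two_phase_om(params, np.full(300, 32.0))
        first = int(sim.loc[sim["daily_eggs"] > 0, "day"].iloc[0])
        assert first == 4

    def test_cohort_ledger_conserves_fractions(self, params):
        sim, ledger = simulate_two_phase_om(
            params, np.full(300, 23.5), return_ledger=True
        )
        fractions = np.array([c.fraction for c in ledger])
        assert np.all(fractions >= 0)
        total = fractions.sum()
        assert total <= 1.0 + 1e-12
        # entering fractions add up to the completion CDF at the final
        # pre-oviposition age (cohorts entering past the run excluded)
        final_px = sim["preovi_px"].iloc[-2]  # last possible completion day
        assert total == pytest.approx(
            weibull3_cdf(params.pcdm, final_px), rel=1e-9
        )

    def test_delayed_onset_versus_current_model_at_cool_temperature(self, params):
        series = np.full(300, 16.7)
        cur = simulate_current_om(params, series)
        two = simulate_two_phase_om(params, series)
        first_cur = int(cur.loc[cur["daily_eggs"] > 0, "day"].iloc[0])
        first_two = int(two.loc[two["daily_eggs"] > 0, "day"].iloc[0])
        assert first_cur == 10
        assert first_two == 17
        assert first_two > first_cur


def _random_params(rng):
    """Parameter draw: published values perturbed component-wise."""
    f = lambda v, lo=0.7, hi=1.3: v * rng.uniform(lo, hi)
    return ParameterSet(
        aging_female=AgingParams(r0=f(0.0096), T_H=f(51.5, 0.9, 1.1), c=f(4.9)),
        survival_female=Weibull2Params(alpha=f(1.09), beta=f(2.94)),
        fecundity=FecundityParams(alpha_f=f(19.4), T_L=f(16.3, 0.9, 1.0), T_H=f(35.2, 1.0, 1.1)),
        orm=Weibull3Params(gamma=f(0.102), eta=f(0.2495), beta=f(1.2)),
        pdrm=Briere2Params(alpha_p=f(2.8e-4), T_L=f(13.3, 0.9, 1.0), T_H=f(35.2, 1.0, 1.1), m=f(4.47)),
        pcdm=Weibull3Params(gamma=f(0.485), eta=f(0.453), beta=f(2.31)),
        odrm=OdrmParams(a=f(0.0393), b=f(2e-17), c=f(-12.7), d=f(871175.0)),
        oorm=Weibull2Params(alpha=f(0.2401), beta=f(1.046)),
    )


@pytest.mark.parametrize("model_seed", range(8))
def test_conservation_and_monotonicity_on_random_draws(model_seed):
    """For perturbed parameter sets and fluctuating series: eggs stay
    non-negative, cumulative eggs non-decreasing, survival non-increasing,
    lifetime eggs bounded by the best fecundity on the series, and the
    oviposition-rate-model increments sum below one."""
    rng = np.random.default_rng(1000 + model_seed)
    p = _random_params(rng)
    T = rng.uniform(8.0, 40.0, 250)
    for sim_fn in (simulate_current_om, simulate_two_phase_om):
        sim = sim_fn(p, T)
        assert np.all(sim["daily_eggs"] >= -1e-12)
        assert np.all(np.diff(sim["cum_eggs"]) >= -1e-12)
        assert np.all(np.diff(sim["survival"]) <= 1e-15)
        cap = fecundity(p.fecundity, T).max()
        assert lifetime_eggs(sim) <= cap + 1e-9
    # one-phase model: ORM increments over the whole run sum below one
    sim = simulate_current_om(p, T)
    delta = np.diff(
        np.concatenate([[0.0], weibull3_cdf(p.orm, sim["aging_px"].to_numpy())])
    )
    assert delta.sum() <= 1.0 + 1e-12
    # two-phase model: completion fractions over the run sum below one
    sim = simulate_two_phase_om(p, T)
    assert sim["completed_frac"].sum() <= 1.0 + 1e-12


class TestEggSurface:
    def test_cold_columns_are_zero(self, params):
        surf = egg_surface(params, "two_phase", t_grid=[12.0, 14.0, 16.0], horizon=150)
        assert surf["daily_eggs"].sum() == 0.0

    def test_models_share_temperature_support(self, params):
        grid = np.arange(15.0, 21.0)
        support = {}
        for model in ("current", "two_phase"):
            surf = egg_surface(params, model, t_grid=grid, horizon=250)
            totals = surf.groupby("temperature_C")["daily_eggs"].sum()
            support[model] = set(totals[totals > 0].index)
        assert support["current"] == support["two_phase"]
        assert min(support["current"]) == 17.0


class TestCompareObserved:
    def test_identical_series(self, params):
        sim = simulate_two_phase_om(params, np.full(120, 23.5))
        assert compare_observed(sim, sim["daily_eggs"].to_numpy()) == pytest.approx(1.0)

    def test_scale_free(self, params):
        sim = simulate_two_phase_om(params, np.full(120, 23.5))
        assert compare_observed(
            sim, 2.0 * sim["daily_eggs"].to_numpy()
        ) == pytest.approx(1.0)

    def test_constant_series_is_error(self):
        with pytest.raises(ValueError):
            compare_observed(np.zeros(10), np.zeros(10))

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            compare_observed([1.0, 2.0], [1.0, 2.0])
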