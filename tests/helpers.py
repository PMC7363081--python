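"""Independent oracles used by the test suite.

Everything here is deliberately written against the model equations
directly — plain loops and per-individual sampling — never by calling
the aggregate simulators it is used to check.
"""

import numpy as np

from ovimodel.agedist import survival_prop, weibull2_cdf, weibull3_cdf
from ovimodel.thermal import aging_rate, fecundity, ovi_rate, preovi_rate


def brute_force_onset(eggs, threshold=5.0, window=7):
    """Reference onset rule, nested loops."""
    eggs = list(eggs)
    for d in range(len(eggs)):
        if eggs[d] > threshold:
            for later in range(d + 1, min(d + 1 + window, len(eggs))):
                if eggs[later] > 0:
                    return d + 1
    return None


def running_sum_ages(rates):
    """Physiological age by explicit per-day accumulation."""
    out, total = [], 0.0
    for r in rates:
        total += r
        out.append(total)
    return np.array(out)


def monte_carlo_two_phase_eggs(params, temperature, n_females, horizon, rng):
    """Individual-based two-phase simulation at constant temperature.

    Each female samples her pre-oviposition completion day from the
    completion distribution increments and her death day from the
    survival curve; she enters oviposition the day after completing and
    lays the deterministic oviposition-phase increments of her capacity
    while alive.  Returns mean lifetime eggs per female.
    """
    days = np.arange(1, horizon + 1)
    S = survival_prop(
        params.survival_female, days * aging_rate(params.aging_female, temperature)
    )
    Cp = weibull3_cdf(
        params.pcdm, days * preovi_rate(params.pdrm, temperature)
    )
    F = fecundity(params.fecundity, temperature)
    do = ovi_rate(params.odrm, temperature)

    u = rng.random(n_females)
    v = rng.random(n_females)
    completion = np.searchsorted(Cp, u) + 1  # horizon+1 = never completes
    last_alive = np.searchsorted(-S, -v, side="left")  # days with S > v
    entry = completion + 1
    ovi_days = np.maximum(last_alive - entry + 1, 0)
    ovi_days = np.where(completion > horizon, 0, ovi_days)
    eggs = F * weibull2_cdf(params.oorm, ovi_days * do)
    return float(np.where(ovi_days > 0, eggs, 0.0).mean())
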