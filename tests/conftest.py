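import numpy as np
import pytest

import remipk as rp


@pytest.fixture(scope="session")
def typical():
    return rp.ADULT_TYPICAL


@pytest.fixture(scope="session")
def omega():
    return rp.ADULT_OMEGA


@pytest.fixture(scope="session")
def residual():
    return rp.ADULT_RESIDUAL


@pytest.fixture(scope="session")
def typical_63kg4():
    """Typical parameters scaled to the 63.4-kg median adult."""
    return rp.allometric_scale(rp.ADULT_TYPICAL, 63.4)


def random_params(rng):
    """A random but physiologically shaped parameter set (log-uniform)."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return rp.PKParameters(
        CL=lu(0.1, 3.0), V1=lu(0.5, 10.0), V2=lu(2.0, 40.0),
        Q2=lu(0.1, 3.0), V3=lu(5.0, 80.0), Q3=lu(0.02, 1.0),
    )


def random_events(rng, max_events=3):
    events = []
    for _ in range(int(rng.integers(1, max_events + 1))):
        events.append(
            rp.DoseEvent(
                start=float(rng.uniform(0, 60)),
                duration=float(rng.uniform(0.5, 120)),
                amount=float(rng.uniform(1, 300)),
            )
        )
    return events


def ode_oracle(params, events, times):
    """Independent adaptive-ODE solution of the compartmental system (ng/mL)."""
    from scipy.integrate import solve_ivp

    k = params.micro_rates()
    K = np.array(
        [
            [-(k["k10"] + k["k12"] + k["k13"]), k["k21"], k["k31"]],
            [k["k12"], -k["k21"], 0.0],
            [k["k13"], 0.0, -k["k31"]],
        ]
    )

    def rhs(t, A):
        rate = sum(ev.rate for ev in events if ev.start <= t < ev.end)
        return K @ A + np.array([rate, 0.0, 0.0])

    cuts = sorted({0.0, float(times[-1])} | {ev.start for ev in events} | {ev.end for ev in events})
    cuts = [c for c in cuts if c <= times[-1]] + [float(times[-1])]
    cuts = sorted(set(cuts))
    A = np.zeros(3)
    out = np.empty(len(times))
    times = np.asarray(times, dtype=float)
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        sel = (times > lo) & (times <= hi)
        sol = solve_ivp(
            rhs, (lo, hi), A, t_eval=np.unique(np.concatenate([times[sel], [hi]])),
            rtol=1e-11, atol=1e-13, method="LSODA",
        )
        interp = {t: y for t, y in zip(sol.t, sol.y[0])}
        for i in np.flatnonzero(sel):
            out[i] = interp[times[i]]
        A = sol.y[:, -1]
    out[times == 0.0] = 0.0
    return out / params.V1 * 1000.0
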