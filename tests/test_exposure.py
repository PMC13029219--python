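"""Exposure metrics, summaries, target window, AFE and ratio tables."""

import numpy as np
import pytest

import remipk as rp
from remipk.exposure import (
    ExposureMetrics,
    ExposureSummary,
    afe,
    build_target_window,
    compute_metrics,
    ratio_table,
    summarize,
)
from remipk.population import OmegaMatrix, VirtualSubject
from remipk.regimen import Regimen, resolve_events
from remipk.simulate import run_mc


def _typical_profile(typical, reg, weight=63.4):
    sub = VirtualSubject(id=1, age=30, weight=weight)
    mc = run_mc(typical, OmegaMatrix.zero(), [sub], reg, seed=1)
    return mc.profiles[0], mc.params[0], mc.events_list[0]


class TestComputeMetrics:
    def test_zero_dose_all_zero(self, typical):
        prof = rp.solve_concentrations(typical, [], np.linspace(0, 100, 50))
        m = compute_metrics(prof, typical, [])
        assert (m.cmax, m.c2h, m.auc_inf) == (0.0, 0.0, 0.0)

    def test_analytic_auc_vs_trapezoid(self, typical):
        prof, params, events = _typical_profile(typical, Regimen(0.3, 1.0, ((1.0, 2.0),)))
        m = compute_metrics(prof, params, events)
        trap = np.trapezoid(prof.concentrations, prof.times) / 60.0
        lam_z = params.CL / (params.V1 + params.V2 + params.V3)
        tail = prof.concentrations[-1] / lam_z / 60.0
        assert m.auc_inf == pytest.approx(trap + tail, rel=5e-3)

    def test_c2h_read_at_end_of_maintenance(self, typical):
        reg = Regimen(0.3, 1.0, ((1.0, 2.0),))
        prof, params, events = _typical_profile(typical, reg)
        m = compute_metrics(prof, params, events)
        idx = np.searchsorted(prof.times, 121.0)
        assert prof.times[idx] == 121.0  # event boundary is on the grid
        assert m.c2h == pytest.approx(prof.concentrations[idx], rel=1e-9)

    def test_c2h_fraction_of_css_increases_with_elimination_rate(self, typical):
        """For a pure constant-rate infusion the approach to steady state is
        faster when elimination is faster."""
        slow = typical
        fast = rp.PKParameters(CL=2 * typical.CL, V1=typical.V1, V2=typical.V2,
                               Q2=typical.Q2, V3=typical.V3, Q3=typical.Q3)
        reg = Regimen(0.0, 1.0, ((1.0, 2.0),))
        fracs = []
        for p in (slow, fast):
            prof, params, events = _typical_profile(p, reg)
            m = compute_metrics(prof, params, events)
            css = events[0].rate / params.CL * 1000  # ng/mL
            fracs.append(m.c2h / css)
        assert 0 < fracs[0] < fracs[1] < 1

    def test_grid_not_covering_readout_rejected(self, typical):
        reg = Regimen(0.3, 1.0, ((1.0, 2.0),))
        events = resolve_events(reg, 63.0)
        prof = rp.solve_concentrations(typical, events, np.linspace(0, 60, 61))
        with pytest.raises(ValueError, match="readout"):
            compute_metrics(prof, typical, events)


class TestSummarize:
    def test_single_subject_quantiles_collapse(self):
        m = ExposureMetrics(100.0, 50.0, 200.0)
        s = summarize([m])
        assert s.median["cmax"] == s.lower["cmax"] == s.upper["cmax"] == 100.0

    def test_quantile_ordering_on_random_data(self):
        rng = np.random.default_rng(0)
        ms = [ExposureMetrics(*np.exp(rng.normal(size=3))) for _ in range(97)]
        s = summarize(ms)
        for met in ("cmax", "c2h", "auc_inf"):
            assert s.lower[met] <= s.median[met] <= s.upper[met]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


def _printed_adult_summaries():
    """Published adult exposure summaries for the two reference regimens."""
    low = ExposureSummary(
        median={"cmax": 4990, "c2h": 946, "auc_inf": 2320},
        lower={"cmax": 4100, "c2h": 749, "auc_inf": 1810},
        upper={"cmax": 5860, "c2h": 1190, "auc_inf": 2980},
        n=1000,
    )
    high = ExposureSummary(
        median={"cmax": 4990, "c2h": 2810, "auc_inf": 6360},
        lower={"cmax": 4100, "c2h": 2230, "auc_inf": 4970},
        upper={"cmax": 5860, "c2h": 3520, "auc_inf": 8170},
        n=1000,
    )
    return low, high


class TestTargetWindow:
    def test_window_from_printed_summaries(self):
        low, high = _printed_adult_summaries()
        win = build_target_window(low, high)
        assert win.lower["auc_inf"] == 1810 and win.upper["auc_inf"] == 8170
        assert win.lower["cmax"] == 4100 and win.upper["cmax"] == 5860
        # window contains the corresponding medians
        for met in ("cmax", "c2h", "auc_inf"):
            assert win.contains(met, low.median[met])
            assert win.contains(met, high.median[met])

    def test_identical_summaries(self):
        low, _ = _printed_adult_summaries()
        win = build_target_window(low, low)
        assert win.lower == low.lower and win.upper == low.upper

    def test_mismatched_metrics_rejected(self):
        low, high = _printed_adult_summaries()
        bad = ExposureSummary(
            median={"cmax": 1.0}, lower={"cmax": 0.5}, upper={"cmax": 2.0}, n=1
        )
        with pytest.raises(ValueError):
            build_target_window(low, bad)


class TestAfe:
    def test_published_fold_errors(self):
        assert afe(174, 137) == pytest.approx(1.27, abs=0.005)
        assert afe(1660, 2020) == pytest.approx(0.82, abs=0.005)

    def test_identity_and_scale_invariance(self):
        assert afe(3.3, 3.3) == 1.0
        assert afe(7 * 2.0, 7 * 4.0) == afe(2.0, 4.0)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            afe(1.0, 0.0)


class TestRatioTable:
    def test_self_ratio_is_one(self):
        low, _ = _printed_adult_summaries()
        assert all(v == 1.0 for v in ratio_table(low, low).values())

    def test_cross_model_ratio(self):
        a = ExposureSummary({"cmax": 4260, "c2h": 1, "auc_inf": 1},
                            {"cmax": 1, "c2h": 1, "auc_inf": 1},
                            {"cmax": 9999, "c2h": 1, "auc_inf": 1}, 1)
        b = ExposureSummary({"cmax": 4175, "c2h": 1, "auc_inf": 1},
                            {"cmax": 1, "c2h": 1, "auc_inf": 1},
                            {"cmax": 9999, "c2h": 1, "auc_inf": 1}, 1)
        assert ratio_table(a, b)["cmax"] == pytest.approx(1.02, abs=0.005)

    def test_reciprocal(self):
        low, high = _printed_adult_summaries()
        r = ratio_table(low, high)
        rinv = ratio_table(high, low)
        for met in r:
            assert r[met] * rinv[met] == pytest.approx(1.0, rel=1e-12)
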