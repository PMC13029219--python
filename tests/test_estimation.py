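"""Mixed-effects estimation: objective, fitting, screening, bootstrap, pcVPC."""

import math

import numpy as np
import pandas as pd
import pytest

import remipk as rp
from remipk.dataset import PKDataset
from remipk.estimation import (
    ThreeCompartmentPopModel,
    _predict_log_batch,
    screen_covariates,
    stepwise_select,
)
from remipk.covariates import CovariateEffect
from remipk.population import OmegaMatrix, ResidualSpec
from remipk.study import StudyArm, StudyDesign, design_ia, generate_dataset
from remipk.regimen import Regimen

TRUE_SIGMA2 = 0.0162


def small_design(n_per_arm=5):
    """A compact rich design for fast estimation tests: four dose arms,
    eight samples through 4 h."""
    arms = [
        StudyArm(f"{d:g} mg/kg", n_per_arm, Regimen(d, 1.0))
        for d in (0.05, 0.1, 0.2, 0.3)
    ]
    return StudyDesign(name="small", arms=arms, schedule=(0.0, 1, 3, 8, 20, 45, 90, 150, 240))


@pytest.fixture(scope="module")
def small_iiv_cl_fit():
    """Dataset with IIV on CL only, plus its maximum-likelihood fit."""
    omega = OmegaMatrix.diagonal({"CL": 0.04})
    ds = generate_dataset(
        small_design(5), rp.ADULT_TYPICAL, omega, ResidualSpec(TRUE_SIGMA2), seed=31
    )
    m = ThreeCompartmentPopModel(ds, iiv=("CL",))
    res = m.fit()
    return m, res


def test_batched_predictor_matches_public_solver(typical):
    """The estimation fast path and the public solver are the same model."""
    from remipk.estimation import _Design

    events = [rp.DoseEvent(0.0, 1.0, 19.0), rp.DoseEvent(1.0, 120.0, 126.0)]
    times = np.array([0.5, 1.0, 30.0, 121.0, 300.0])
    design = _Design(events, times)
    p = typical.as_array()
    for use_numba in (False, True):
        got = _predict_log_batch(p[None, :], design, use_numba=use_numba)[0]
        want = np.log(rp.solve_concentrations(typical, events, times).concentrations)
        np.testing.assert_allclose(got, want, rtol=1e-10)


def test_zero_iiv_objective_is_nls_deviance(typical):
    """With no random effects the OFV reduces to the fixed-effects
    least-squares deviance on the log scale."""
    ds = generate_dataset(
        small_design(3), typical, OmegaMatrix.zero(), ResidualSpec(TRUE_SIGMA2), seed=32
    )
    m = ThreeCompartmentPopModel(ds, iiv=())
    x = m.pack(typical, {}, TRUE_SIGMA2)
    got = m.ofv(x)
    # independent computation through the public solver
    dev = 0.0
    for s in ds.subjects():
        pred = rp.solve_concentrations(
            rp.allometric_scale(typical, s.weight), s.events, s.obs_times
        ).concentrations
        r = np.log(s.obs_conc) - np.log(pred)
        dev += (r @ r) / TRUE_SIGMA2 + len(r) * math.log(2 * math.pi * TRUE_SIGMA2)
    assert got == pytest.approx(dev, rel=1e-9)


def test_noise_free_residuals_vanish_at_truth(typical):
    ds = generate_dataset(small_design(2), typical, OmegaMatrix.zero(), ResidualSpec(0.0), seed=33)
    sub = ds.subjects()[0]
    pred = rp.solve_concentrations(
        rp.allometric_scale(typical, sub.weight), sub.events, sub.obs_times
    ).concentrations
    rss = np.sum((np.log(sub.obs_conc) - np.log(pred)) ** 2)
    assert rss < 1e-18


def test_ofv_prefers_truth_over_doubled_clearance(typical, omega, residual):
    """On a synthetic single-ascending-dose study the OFV at the generating
    parameters beats the OFV with CL doubled."""
    ds = generate_dataset(design_ia(), typical, omega, residual, seed=34, n_scale=1.59)
    assert ds.n_subjects >= 100
    m = ThreeCompartmentPopModel(ds)
    x_true = m.pack(typical, {k: omega.variances[k] for k in m.iiv}, TRUE_SIGMA2)
    x_double = x_true.copy()
    x_double[0] += math.log(2)
    assert m.ofv(x_true) < m.ofv(x_double)


def test_near_deterministic_limit_recovers_fixed_effects(typical):
    """Zero IIV and tiny noise: fixed effects recovered within 1%."""
    ds = generate_dataset(
        small_design(4), typical, OmegaMatrix.zero(), ResidualSpec(1e-6), seed=35
    )
    m = ThreeCompartmentPopModel(ds, iiv=())
    res = m.fit()
    np.testing.assert_allclose(res.params.as_array(), typical.as_array(), rtol=0.01)


def test_refit_from_optimum_is_stationary(small_iiv_cl_fit):
    m, res = small_iiv_cl_fit
    res2 = m.fit(start=res.x)
    assert abs(res2.ofv - res.ofv) < 0.01


def test_fit_recovers_small_iiv_model(small_iiv_cl_fit):
    m, res = small_iiv_cl_fit
    assert res.converged
    np.testing.assert_allclose(res.params.as_array(), rp.ADULT_TYPICAL.as_array(), rtol=0.15)
    assert res.omega2["CL"] == pytest.approx(0.04, rel=0.6)
    assert res.sigma2 == pytest.approx(TRUE_SIGMA2, rel=0.5)
    assert res.ofv <= m.ofv(m.pack(rp.ADULT_TYPICAL, {"CL": 0.04}, TRUE_SIGMA2)) + 1e-6


def test_summary_and_serialisation(small_iiv_cl_fit):
    _, res = small_iiv_cl_fit
    text = res.summary()
    assert "CL" in text and "OFV" in text
    d = res.to_dict()
    assert set(d["estimates"]) == set(rp.compartments.PARAM_NAMES)


@pytest.fixture(scope="module")
def fit_with_covariates(typical):
    """EB etas at the generating parameters, with extra covariate columns:
    one built from eta_CL, one pure noise, one constant, one exact copy."""
    omega = OmegaMatrix.diagonal({"CL": 0.09})
    ds = generate_dataset(
        small_design(25), typical, omega, ResidualSpec(TRUE_SIGMA2), seed=36
    )
    m0 = ThreeCompartmentPopModel(ds, iiv=("CL",))
    res0 = m0.fit(
        start=m0.pack(typical, {"CL": 0.09}, TRUE_SIGMA2),
        free=np.zeros(m0.k_params, dtype=bool),
    )
    eta = res0.eta_frame().set_index("ID")["eta_CL"]
    rng = np.random.default_rng(37)
    df = ds.df.copy()
    df["XSTRONG"] = df["ID"].map(eta) * 2.0 + rng.normal(0, 0.05, len(df))[0]
    df["XNULL"] = df["ID"].map({i: v for i, v in zip(eta.index, rng.normal(size=len(eta)))})
    df["XCONST"] = 1.0
    df["XCOPY"] = df["XSTRONG"]
    m = ThreeCompartmentPopModel(PKDataset(df), iiv=("CL",))
    res = m.fit(
        start=m.pack(typical, {"CL": 0.09}, TRUE_SIGMA2),
        free=np.zeros(m.k_params, dtype=bool),
    )
    return res


class TestScreening:
    def test_informative_covariate_eligible(self, fit_with_covariates):
        out = screen_covariates(fit_with_covariates, ["XSTRONG", "XNULL", "XCONST", "XCOPY"])
        assert "XSTRONG" in out["eligible"] or "XCOPY" in out["eligible"]
        assert out["correlations"]["XSTRONG"] >= 0.3

    def test_null_covariate_not_eligible(self, fit_with_covariates):
        out = screen_covariates(fit_with_covariates, ["XNULL"])
        assert out["correlations"]["XNULL"] < 0.3

    def test_constant_excluded_and_copy_collinear(self, fit_with_covariates):
        out = screen_covariates(fit_with_covariates, ["XSTRONG", "XCOPY", "XCONST"])
        assert out["notes"]["XCONST"] == "constant"
        assert sum(c in out["eligible"] for c in ("XSTRONG", "XCOPY")) == 1
        dropped = "XCOPY" if "XSTRONG" in out["eligible"] else "XSTRONG"
        assert "collinear" in out["notes"][dropped]


class TestStepwise:
    def _dataset_with_cl_covariate(self, typical, strong=True):
        """Simulate subjects whose CL carries a power effect of covariate X."""
        rng = np.random.default_rng(38)
        rows = []
        design = small_design(6)
        for sid in range(1, 25):
            w = float(rng.uniform(55, 75))
            x = float(np.exp(rng.normal(0, 0.4)))
            p = rp.allometric_scale(typical, w)
            cl = p.CL * (x ** 0.8 if strong else 1.0)
            p = rp.PKParameters(CL=cl, V1=p.V1, V2=p.V2, Q2=p.Q2, V3=p.V3, Q3=p.Q3)
            arm = design.arms[sid % 4]
            events = rp.resolve_events(arm.regimen, w)
            times = np.asarray(design.schedule[1:], dtype=float)
            conc = rp.solve_concentrations(p, events, times).concentrations
            conc = conc * np.exp(rng.normal(0, math.sqrt(TRUE_SIGMA2), conc.shape))
            rows.append(dict(ID=sid, TIME=0.0, EVID=1, AMT=events[0].amount,
                             RATE=events[0].rate, DV=np.nan, MDV=1, WT=w, X=x))
            for t, c in zip(times, conc):
                rows.append(dict(ID=sid, TIME=t, EVID=0, AMT=np.nan, RATE=np.nan,
                                 DV=c, MDV=0, WT=w, X=x))
        return PKDataset(pd.DataFrame(rows))

    def test_empty_candidates_returns_base(self, typical):
        ds = self._dataset_with_cl_covariate(typical, strong=False)
        m = ThreeCompartmentPopModel(ds, iiv=("CL",))
        base = m.fit(start=m.pack(typical, {"CL": 0.02}, TRUE_SIGMA2),
                     free=np.zeros(m.k_params, dtype=bool))
        out = stepwise_select(m, base, [])
        assert out["selected"] == []
        assert out["ofv"] == pytest.approx(out["base_ofv"])

    def test_strong_covariate_selected_null_not(self, typical):
        ds = self._dataset_with_cl_covariate(typical, strong=True)
        m = ThreeCompartmentPopModel(ds, iiv=("CL",))
        base = m.fit(start=m.pack(typical, {"CL": 0.02}, TRUE_SIGMA2),
                     free=np.zeros(m.k_params, dtype=bool))
        cands = [
            CovariateEffect("CL", "X", "power", 0.0, 1.0),
            CovariateEffect("V1", "AGE", "power", 0.0, 30.0),
        ]
        # add an uninformative AGE column
        ds.df["AGE"] = 30.0 + (ds.df["ID"] % 5)
        out = stepwise_select(m, base, cands)
        names = [c.covariate for c in out["selected"]]
        assert "X" in names and "AGE" not in names


class TestBootstrap:
    def test_requires_ten_subjects(self, typical):
        ds = generate_dataset(
            small_design(1), typical, OmegaMatrix.zero(), ResidualSpec(TRUE_SIGMA2), seed=40
        )
        m = ThreeCompartmentPopModel(ds, iiv=())
        res = m.fit(maxiter=5)
        with pytest.raises(ValueError, match="10 subjects"):
            res.bootstrap(n=2, seed=1)

    def test_medians_near_point_estimates(self, small_iiv_cl_fit):
        m, res = small_iiv_cl_fit
        out = res.bootstrap(n=12, seed=41, maxiter=60)
        assert out["n_success"] >= 10
        for n in rp.compartments.PARAM_NAMES:
            assert out["median"][n] == pytest.approx(getattr(res.params, n), rel=0.25)
            assert out["ci_lower"][n] <= out["median"][n] <= out["ci_upper"][n]

    def test_resample_is_deterministic(self, small_iiv_cl_fit):
        m, _ = small_iiv_cl_fit
        a = m.dataset.resample_subjects(np.random.default_rng(5)).df
        b = m.dataset.resample_subjects(np.random.default_rng(5)).df
        pd.testing.assert_frame_equal(a, b)


class TestPcVpc:
    def test_correction_is_noop_when_typical_predictions_equal(self, typical):
        """Single shared observation time and weight: every typical
        prediction is identical, so prediction correction changes nothing."""
        rows = []
        rng = np.random.default_rng(42)
        for sid in range(1, 13):
            rows.append(dict(ID=sid, TIME=0.0, EVID=1, AMT=18.9, RATE=18.9, DV=np.nan, MDV=1, WT=63.0))
            c = 2000 * math.exp(rng.normal(0, 0.1))
            rows.append(dict(ID=sid, TIME=10.0, EVID=0, AMT=np.nan, RATE=np.nan, DV=c, MDV=0, WT=63.0))
        ds = PKDataset(pd.DataFrame(rows))
        m = ThreeCompartmentPopModel(ds, iiv=("CL",))
        res = m.fit(start=m.pack(typical, {"CL": 0.02}, 0.01),
                    free=np.zeros(m.k_params, dtype=bool))
        table = res.pcvpc(n_sim=50, bins=1, seed=43)
        obs = ds.df.loc[ds.df.EVID == 0, "DV"]
        assert table.loc[0, "obs_p50"] == pytest.approx(np.quantile(obs, 0.5), rel=1e-9)

    def test_deterministic_under_seed(self, small_iiv_cl_fit):
        _, res = small_iiv_cl_fit
        a = res.pcvpc(n_sim=40, bins=4, seed=44)
        b = res.pcvpc(n_sim=40, bins=4, seed=44)
        pd.testing.assert_frame_equal(a, b)
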