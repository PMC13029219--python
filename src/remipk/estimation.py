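"""Nonlinear mixed-effects estimation for the three-compartment model.

The model is fitted to event-record data by maximising an approximate
marginal likelihood.  Per subject, the random-effect vector eta is
profiled to its empirical-Bayes mode by damped Gauss-Newton, and the
marginal contribution is evaluated with a Laplace approximation using the
Gauss-Newton Hessian (a FOCE-type objective).  Fixed effects, random-effect
variances and the residual variance are log-parameterised and minimised
with a quasi-Newton optimiser, so all estimates stay positive.  Only
objective-function *differences* are meaningful; absolute values depend on
the approximation.

Residual error acts on log-concentration by default, matching the
additive-on-log residual model of the simulator.

`ThreeCompartmentPopModel` / `PopPKResults` follow the familiar
model/results split: the model holds data and configuration, `fit()`
returns a results object carrying estimates, empirical-Bayes etas,
diagnostics (`summary`, `bootstrap`, `pcvpc`) and simulation hooks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .compartments import PARAM_NAMES, PKParameters, solve_amounts
from .covariates import AllometricSpec, CovariateEffect, apply_covariate_effect
from .dataset import PKDataset, SubjectRecord
from .population import OmegaMatrix, ResidualSpec
from .units import MGL_TO_NGML

__all__ = [
    "ThreeCompartmentPopModel",
    "PopPKResults",
    "fit_population",
    "objective",
    "screen_covariates",
    "stepwise_select",
    "bootstrap",
    "pcvpc",
]

_LOG_FLOOR = 1e-9  # ng/mL floor before taking logs
_PENALTY = 1e10


def _predict_log(pvec, events, times):
    """log central concentration (log ng/mL) for a raw parameter vector."""
    try:
        params = PKParameters.from_array(pvec)
    except ValueError:
        return None
    amounts = solve_amounts(params, events, times)
    conc = amounts[:, 0] / params.V1 * MGL_TO_NGML
    return np.log(np.clip(conc, _LOG_FLOOR, None))


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


class _Design:
    """Per-subject dosing design preprocessed for batched evaluation.

    The observation grid is split once into constant-rate segments; the
    batched predictor then only does (stacked) 3x3 eigendecompositions and
    elementwise exponentials, so evaluating a whole finite-difference
    Jacobian costs one batched call.  Segment data is also kept in flat
    arrays for the compiled kernel.
    """

    def __init__(self, events, times):
        from .compartments import _segments

        times = np.asarray(times, dtype=float)
        t_end = max([times[-1] if times.size else 0.0] + [ev.end for ev in events])
        self.n_times = times.size
        self.segs = []
        for lo, hi, rate in _segments(events, t_end):
            idx = np.flatnonzero((times > lo) & (times <= hi))
            self.segs.append((hi - lo, rate, idx, times[idx] - lo))
        self.dts = np.array([s[0] for s in self.segs])
        self.rates = np.array([s[1] for s in self.segs])
        self.idx = np.concatenate([s[2] for s in self.segs]) if self.segs else np.empty(0, int)
        self.taus = np.concatenate([s[3] for s in self.segs]) if self.segs else np.empty(0)
        self.seg_ptr = np.cumsum([0] + [len(s[2]) for s in self.segs]).astype(np.int64)


@_njit(cache=True)
def _log_conc_kernel(P, dts, rates, idx, taus, seg_ptr, n_times):  # pragma: no cover - numba
    m = P.shape[0]
    out = np.zeros((m, n_times))
    for r in range(m):
        CL, V1, V2, Q2, V3, Q3 = P[r, 0], P[r, 1], P[r, 2], P[r, 3], P[r, 4], P[r, 5]
        k10, k12, k21 = CL / V1, Q2 / V1, Q2 / V2
        k13, k31 = Q3 / V1, Q3 / V3
        d = np.array([1.0, np.sqrt(k21 / k12), np.sqrt(k31 / k13)])
        S = np.zeros((3, 3))
        S[0, 0] = -(k10 + k12 + k13)
        S[1, 1] = -k21
        S[2, 2] = -k31
        S[0, 1] = S[1, 0] = np.sqrt(k12 * k21)
        S[0, 2] = S[2, 0] = np.sqrt(k13 * k31)
        lam, U = np.linalg.eigh(S)
        A0 = np.zeros(3)
        y0 = np.zeros(3)
        yu = np.zeros(3)
        for s in range(dts.shape[0]):
            rate, dt = rates[s], dts[s]
            for i in range(3):
                acc = 0.0
                for j in range(3):
                    acc += U[j, i] * d[j] * A0[j]
                y0[i] = acc
                yu[i] = U[0, i] * rate  # d[0] == 1
            for tpos in range(seg_ptr[s], seg_ptr[s + 1]):
                tau = taus[tpos]
                c = 0.0
                for i in range(3):
                    e = np.exp(lam[i] * tau)
                    c += U[0, i] * (e * y0[i] + (e - 1.0) / lam[i] * yu[i])
                out[r, idx[tpos]] = c
            for i in range(3):
                e = np.exp(lam[i] * dt)
                y0[i] = e * y0[i] + (e - 1.0) / lam[i] * yu[i]
            for j in range(3):
                acc = 0.0
                for i in range(3):
                    acc += U[j, i] / d[j] * y0[i]
                A0[j] = acc
        for t in range(n_times):
            c = out[r, t] / V1 * 1000.0
            out[r, t] = np.log(max(c, 1e-9))
    return out


def _predict_log_batch(P, design: _Design, use_numba: bool | None = None):
    """log concentration (log ng/mL) for a stack of parameter vectors.

    P has shape (m, 6) in canonical order; returns (m, n_times).  All
    parameters must be strictly positive and finite (callers pass
    exp-transformed values; non-finite stacks return None).  Exact
    piecewise solution, identical in substance to
    :func:`remipk.compartments.solve_concentrations`; a compiled kernel is
    used when numba is available.
    """
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)) or np.any(P <= 0):
        return None
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba:
        return _log_conc_kernel(
            P, design.dts, design.rates, design.idx, design.taus, design.seg_ptr, design.n_times
        )
    m = P.shape[0]
    CL, V1, V2, Q2, V3, Q3 = (P[:, j] for j in range(6))
    k10, k12, k21, k13, k31 = CL / V1, Q2 / V1, Q2 / V2, Q3 / V1, Q3 / V3
    K = np.zeros((m, 3, 3))
    K[:, 0, 0] = -(k10 + k12 + k13)
    K[:, 0, 1] = k21
    K[:, 0, 2] = k31
    K[:, 1, 0] = k12
    K[:, 1, 1] = -k21
    K[:, 2, 0] = k13
    K[:, 2, 2] = -k31
    d = np.stack([np.ones(m), np.sqrt(k21 / k12), np.sqrt(k31 / k13)], axis=1)
    S = K * d[:, :, None] / d[:, None, :]
    S = 0.5 * (S + S.transpose(0, 2, 1))
    lam, U = np.linalg.eigh(S)
    W = U.transpose(0, 2, 1) * d[:, None, :]   # (m,3,3): amounts -> eigenbasis
    Winv = U / d[:, :, None]                   # eigenbasis -> amounts
    row0 = Winv[:, 0, :]                       # central-compartment read-out

    out = np.zeros((m, design.n_times))
    A0 = np.zeros((m, 3))
    for dt, rate, idx, taus in design.segs:
        y0 = np.einsum("mij,mj->mi", W, A0)
        yu = W[:, :, 0] * rate
        if idx.size:
            E = np.exp(lam[:, None, :] * taus[None, :, None])      # (m,nt,3)
            Y = E * y0[:, None, :] + (E - 1.0) / lam[:, None, :] * yu[:, None, :]
            out[:, idx] = np.einsum("mj,mtj->mt", row0, Y)
        Ee = np.exp(lam * dt)
        Ye = Ee * y0 + (Ee - 1.0) / lam * yu
        A0 = np.einsum("mij,mj->mi", Winv, Ye)
    conc = out / V1[:, None] * MGL_TO_NGML
    return np.log(np.clip(conc, _LOG_FLOOR, None))


@dataclass
class _Subject:
    """Preprocessed per-subject design."""

    rec: SubjectRecord
    log_obs: np.ndarray
    scale: np.ndarray  # allometric factors per parameter
    design: _Design = None


class ThreeCompartmentPopModel:
    """Population three-compartment model bound to an event-record dataset.

    Parameters
    ----------
    dataset : PKDataset
        Event records; observations must be positive (log-scale residual).
    iiv : sequence of parameter names
        Which structural parameters carry a log-normal random effect
        (default: all six).  The fitted omega is diagonal.
    covariate_effects : sequence of CovariateEffect
        Optional parametric covariate effects; their coefficients are
        estimated alongside the structural parameters.
    reference_weight, allometric : allometric weight scaling applied to all
        subjects before random effects (exponent 0.75 clearances, 1.0
        volumes).
    """

    def __init__(
        self,
        dataset: PKDataset,
        iiv=PARAM_NAMES,
        covariate_effects=(),
        allometric: AllometricSpec = AllometricSpec(),
        residual_scale: str = "log-concentration",
    ):
        if residual_scale != "log-concentration":
            raise NotImplementedError("only the log-concentration residual scale is fitted")
        self.dataset = dataset
        self.allometric = allometric
        self.iiv = tuple(iiv)
        self.iiv_idx = np.array([PARAM_NAMES.index(n) for n in self.iiv], dtype=int)
        self.covariate_effects = tuple(covariate_effects)
        self._subjects = []
        for rec in dataset.subjects():
            if rec.n_obs == 0:
                continue
            if np.any(rec.obs_conc <= 0):
                raise ValueError(
                    f"subject {rec.id!r} has non-positive observations; "
                    "log-scale residual requires positive concentrations"
                )
            r = rec.weight / allometric.reference_weight
            fc, fv = r**allometric.exponent_clearances, r**allometric.exponent_volumes
            scale = np.array([fc, fv, fv, fc, fv, fc])  # CL,V1,V2,Q2,V3,Q3
            self._subjects.append(
                _Subject(rec, np.log(rec.obs_conc), scale, _Design(rec.events, rec.obs_times))
            )
        if not self._subjects:
            raise ValueError("dataset contains no usable observations")
        self._eta_cache = {}

    @classmethod
    def from_csv(cls, path, **kw) -> "ThreeCompartmentPopModel":
        from .io import read_dataset

        return cls(read_dataset(path), **kw)

    @classmethod
    def from_dataframe(cls, df, **kw) -> "ThreeCompartmentPopModel":
        return cls(PKDataset(df), **kw)

    # ---- parameter vector layout: [log theta(6), log w2(q), log s2, coefs] ----

    @property
    def q(self) -> int:
        return len(self.iiv)

    @property
    def k_params(self) -> int:
        return 6 + self.q + 1 + len(self.covariate_effects)

    def pack(self, theta: PKParameters, omega2: dict, sigma2: float, coefs=()) -> np.ndarray:
        x = [math.log(getattr(theta, n)) for n in PARAM_NAMES]
        x += [math.log(max(omega2.get(n, 1e-4), 1e-8)) for n in self.iiv]
        x += [math.log(sigma2)]
        x += list(coefs)
        return np.array(x)

    def unpack(self, x):
        theta = np.exp(x[:6])
        w2 = np.exp(x[6 : 6 + self.q])
        s2 = float(np.exp(x[6 + self.q]))
        coefs = np.asarray(x[7 + self.q :], dtype=float)
        return theta, w2, s2, coefs

    def _individual_base(self, theta, coefs, sub: _Subject) -> np.ndarray:
        """Typical parameters for a subject: allometry then covariate effects."""
        p = theta * sub.scale
        for eff, c in zip(self.covariate_effects, coefs):
            j = PARAM_NAMES.index(eff.target_parameter)
            val = sub.rec.covariates.get(eff.covariate)
            if val is None:
                raise ValueError(f"covariate {eff.covariate!r} missing for subject {sub.rec.id!r}")
            p = p.copy()
            p[j] = apply_covariate_effect(p[j], replace(eff, coefficient=float(c)), val)
        return p

    # ---- inner problem: empirical-Bayes mode per subject ----

    def _subject_pred(self, base, eta_full, sub: _Subject):
        with np.errstate(all="ignore"):
            out = _predict_log_batch((base * np.exp(eta_full))[None, :], sub.design)
        if out is None:
            return None
        f = out[0]
        return f if np.all(np.isfinite(f)) else None

    def _jacobian(self, base, eta, f, sub: _Subject, h: float = 1e-5):
        """FD Jacobian of the log prediction wrt eta, one batched call."""
        q = self.q
        Eta = np.zeros((q, 6))
        Eta[:, self.iiv_idx] = eta[None, :]
        Eta[np.arange(q), self.iiv_idx] += h
        with np.errstate(all="ignore"):
            F = _predict_log_batch(base[None, :] * np.exp(Eta), sub.design)
        if F is None:
            return np.zeros((len(f), q))
        F = np.where(np.isfinite(F), F, f[None, :])
        return (F - f[None, :]).T / h

    def _eb_mode(self, base, sub: _Subject, w2, s2, eta0):
        """Damped Gauss-Newton maximisation of the conditional posterior."""
        q = self.q
        oinv = 1.0 / np.maximum(w2, 1e-12)
        eta = eta0.copy()

        def embed(e):
            full = np.zeros(6)
            full[self.iiv_idx] = e
            return full

        def g_of(e):
            f = self._subject_pred(base, embed(e), sub)
            if f is None:
                return None, None
            r = sub.log_obs - f
            return 0.5 * (r @ r) / s2 + 0.5 * np.sum(oinv * e * e), f

        g, f = g_of(eta)
        if g is None:
            eta = np.zeros(q)
            g, f = g_of(eta)
            if g is None:
                return None
        mu = 1e-8
        for _ in range(40):
            J = self._jacobian(base, eta, f, sub)
            r = sub.log_obs - f
            grad = -(J.T @ r) / s2 + oinv * eta
            if np.linalg.norm(grad) < 1e-7:
                break
            H = J.T @ J / s2 + np.diag(oinv)
            try:
                step = np.linalg.solve(H + mu * np.eye(q), -grad)
            except np.linalg.LinAlgError:
                break
            improved = False
            for _ls in range(8):
                g_new, f_new = g_of(eta + step)
                if g_new is not None and g_new < g:
                    eta = eta + step
                    g, f = g_new, f_new
                    mu = max(mu / 4, 1e-10)
                    improved = True
                    break
                step *= 0.5
                mu *= 4
            if not improved:
                break
        J = self._jacobian(base, eta, f, sub)
        return eta, f, J

    # ---- objective ----

    def ofv(self, x, update_cache: bool = True) -> float:
        """Approximate -2 log marginal likelihood at a packed parameter vector."""
        theta, w2, s2, coefs = self.unpack(x)
        total = 0.0
        no_iiv = np.all(w2 < 1e-10)
        for sub in self._subjects:
            base = self._individual_base(theta, coefs, sub)
            n = len(sub.log_obs)
            if no_iiv:
                f = self._subject_pred(base, np.zeros(6), sub)
                if f is None or not np.all(np.isfinite(f)):
                    return _PENALTY
                r = sub.log_obs - f
                total += (r @ r) / s2 + n * math.log(2 * math.pi * s2)
                continue
            eta0 = self._eta_cache.get(sub.rec.id, np.zeros(self.q))
            out = self._eb_mode(base, sub, w2, s2, eta0)
            if out is None:
                return _PENALTY
            eta, f, J = out
            if update_cache:
                self._eta_cache[sub.rec.id] = eta
            r = sub.log_obs - f
            oinv = 1.0 / w2
            H = J.T @ J / s2 + np.diag(oinv)
            sign, logdet_h = np.linalg.slogdet(H)
            if sign <= 0:
                return _PENALTY
            total += (
                (r @ r) / s2
                + n * math.log(2 * math.pi * s2)
                + np.sum(oinv * eta * eta)
                + float(np.sum(np.log(w2)))
                + logdet_h
            )
        return float(total)

    # ---- fitting ----

    def fit(
        self,
        start: np.ndarray | None = None,
        method: str = "laplace",
        maxiter: int = 200,
        gtol: float = 1e-4,
        free: np.ndarray | None = None,
    ) -> "PopPKResults":
        """Maximise the approximate marginal likelihood.

        ``start`` is a packed vector (see :meth:`pack`); by default the fit
        starts from rough physiological values.  ``free`` is an optional
        boolean mask over the packed vector restricting which entries are
        optimised (used by the stepwise covariate search); fixed entries
        keep their starting values.
        """
        if method not in ("laplace", "foce"):
            raise ValueError(f"unknown method {method!r}")
        if start is None:
            start = self.pack(
                PKParameters(CL=1.0, V1=3.0, V2=10.0, Q2=1.0, V3=20.0, Q3=0.3),
                {n: 0.05 for n in self.iiv},
                0.05,
                np.zeros(len(self.covariate_effects)),
            )
        start = np.asarray(start, dtype=float)
        if free is None:
            free = np.ones(start.size, dtype=bool)
        free = np.asarray(free, dtype=bool)
        x_fixed = start.copy()

        def fun(z):
            x = x_fixed.copy()
            x[free] = z
            return self.ofv(x)

        self._eta_cache = {}
        if not free.any():
            ofv = self.ofv(start)
            etas = {sid: e.copy() for sid, e in self._eta_cache.items()}
            return PopPKResults(self, start, ofv, True, "no free parameters", 0, etas)
        res = optimize.minimize(
            fun,
            start[free],
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-10, "eps": 1e-4},
        )
        x_opt = x_fixed.copy()
        x_opt[free] = res.x
        ofv = self.ofv(x_opt)
        etas = {sid: e.copy() for sid, e in self._eta_cache.items()}
        return PopPKResults(
            model=self,
            x=x_opt,
            ofv=ofv,
            converged=bool(res.success),
            message=str(res.message),
            n_iter=int(res.nit),
            etas=etas,
        )


class PopPKResults:
    """Estimates, variance components, OFV and diagnostics from a fit."""

    def __init__(self, model, x, ofv, converged, message, n_iter, etas):
        self.model = model
        self.x = np.asarray(x, dtype=float)
        self.ofv = float(ofv)
        self.converged = converged
        self.message = message
        self.n_iter = n_iter
        self.etas = etas
        theta, w2, s2, coefs = model.unpack(self.x)
        self.params = PKParameters.from_array(theta)
        self.omega2 = dict(zip(model.iiv, map(float, w2)))
        self.sigma2 = float(s2)
        self.coefs = dict(zip((e.covariate for e in model.covariate_effects), map(float, coefs)))
        self.bse = None

    @property
    def omega(self) -> OmegaMatrix:
        return OmegaMatrix.diagonal(self.omega2)

    @property
    def residual(self) -> ResidualSpec:
        return ResidualSpec(self.sigma2, "log-concentration")

    def eta_frame(self) -> pd.DataFrame:
        rows = []
        for sub in self.model._subjects:
            e = self.etas.get(sub.rec.id, np.zeros(self.model.q))
            row = {"ID": sub.rec.id, **{f"eta_{n}": v for n, v in zip(self.model.iiv, e)}}
            row.update(sub.rec.covariates)
            rows.append(row)
        return pd.DataFrame(rows)

    def compute_se(self, step: float = 1e-3):
        """Standard errors from a central finite-difference Hessian of the
        OFV over the packed (log-scale) parameters; expensive, opt-in."""
        k = self.x.size
        H = np.zeros((k, k))
        f0 = self.ofv

        def f(x):
            return self.model.ofv(x, update_cache=False)

        for i in range(k):
            for j in range(i, k):
                xi = self.x.copy()
                xi[i] += step
                xi[j] += step
                fpp = f(xi)
                xi = self.x.copy()
                xi[i] += step
                xi[j] -= step
                fpm = f(xi)
                xi = self.x.copy()
                xi[i] -= step
                xi[j] += step
                fmp = f(xi)
                xi = self.x.copy()
                xi[i] -= step
                xi[j] -= step
                fmm = f(xi)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step * step)
        try:
            cov = 2.0 * np.linalg.inv(H)
            self.bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            warnings.warn("Hessian not invertible; standard errors unavailable")
        return self.bse

    def summary(self) -> str:
        lines = [
            "Population three-compartment model (log-scale Laplace/FOCE-type fit)",
            f"subjects: {len(self.model._subjects)}   observations: "
            f"{sum(len(s.log_obs) for s in self.model._subjects)}",
            f"OFV: {self.ofv:.3f}   converged: {self.converged}   iterations: {self.n_iter}",
            "",
            f"{'parameter':<12}{'estimate':>12}   units",
        ]
        units = {"CL": "L/min", "V1": "L", "V2": "L", "Q2": "L/min", "V3": "L", "Q3": "L/min"}
        ref = self.model.allometric.reference_weight
        for n in PARAM_NAMES:
            lines.append(f"{n:<12}{getattr(self.params, n):>12.4g}   {units[n]}/{ref:g} kg")
        for n, v in self.omega2.items():
            lines.append(f"{'w2(' + n + ')':<12}{v:>12.4g}   (log scale)")
        lines.append(f"{'s2(resid)':<12}{self.sigma2:>12.4g}   (log-concentration)")
        for n, v in self.coefs.items():
            lines.append(f"{'coef ' + n:<12}{v:>12.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": {n: getattr(self.params, n) for n in PARAM_NAMES},
            "omega2": self.omega2,
            "sigma2": self.sigma2,
            "coefficients": self.coefs,
            "ofv": self.ofv,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    # convenience simulation from the fitted model
    def simulate(self, population, regimen, seed=None, grid=None, residual=None):
        from .simulate import run_mc

        return run_mc(self.params, self.omega, population, regimen, grid=grid, seed=seed,
                      residual=residual, allometric=self.model.allometric)

    def bootstrap(self, n: int = 1000, seed=None, maxiter: int = 100):
        return bootstrap(self.model, self, n=n, seed=seed, maxiter=maxiter)

    def pcvpc(self, n_sim: int = 1000, bins: int = 8, seed=None):
        return pcvpc(self.model, self, n_sim=n_sim, bins=bins, seed=seed)


# ---------------------------------------------------------------- functions


def fit_population(dataset: PKDataset, start=None, method: str = "laplace", **kw) -> PopPKResults:
    """Fit the population model to a dataset (module-level convenience)."""
    return ThreeCompartmentPopModel(dataset).fit(start=start, method=method, **kw)


def objective(dataset: PKDataset, x, method: str = "laplace") -> float:
    """OFV of a packed parameter vector on a dataset."""
    return ThreeCompartmentPopModel(dataset).ofv(np.asarray(x, dtype=float))


def screen_covariates(
    results: PopPKResults,
    covariates,
    eligibility: float = 0.3,
    collinearity: float = 0.8,
) -> dict:
    """Correlation screening of covariates against empirical-Bayes etas.

    A covariate is eligible when any |Pearson R| with an eta column reaches
    the eligibility threshold.  Within groups of eligible covariates whose
    pairwise |R| exceeds the collinearity threshold, only the one with the
    strongest eta correlation is kept.  Constant covariates are excluded
    with a note.
    """
    frame = results.eta_frame()
    eta_cols = [c for c in frame.columns if c.startswith("eta_")]
    notes = {}
    strength = {}
    for cov in covariates:
        if cov not in frame.columns:
            notes[cov] = "absent"
            continue
        v = frame[cov].to_numpy(dtype=float)
        if np.std(v) == 0:
            notes[cov] = "constant"
            continue
        rs = [abs(np.corrcoef(v, frame[e])[0, 1]) for e in eta_cols if np.std(frame[e]) > 0]
        strength[cov] = max(rs) if rs else 0.0
        notes[cov] = "eligible" if strength[cov] >= eligibility else "below threshold"
    eligible = [c for c in strength if notes[c] == "eligible"]
    kept = []
    for cov in sorted(eligible, key=lambda c: -strength[c]):
        coll = [
            k for k in kept
            if abs(np.corrcoef(frame[cov].astype(float), frame[k].astype(float))[0, 1])
            > collinearity
        ]
        if coll:
            notes[cov] = f"collinear with {coll[0]}"
        else:
            kept.append(cov)
    return {"eligible": kept, "correlations": strength, "notes": notes}


def stepwise_select(
    model: ThreeCompartmentPopModel,
    base_results: PopPKResults,
    candidates,
    forward_dofv: float = 3.84,
    backward_dofv: float = 10.83,
    refit: str = "coef-only",
    maxiter: int = 100,
) -> dict:
    """Greedy forward inclusion / backward elimination by OFV change.

    Forward: at each round, the candidate with the largest OFV drop above
    ``forward_dofv`` enters.  Backward: effects whose removal raises the
    OFV by less than ``backward_dofv`` are eliminated.  ``refit`` controls
    whether candidate fits re-optimise every parameter ("full") or only
    the covariate coefficients with structural and variance parameters
    held at the base estimates ("coef-only", a score-test-flavoured and
    much cheaper variant with the same asymptotic null behaviour).
    Failed candidate fits are skipped with a note.
    """
    if refit not in ("coef-only", "full"):
        raise ValueError("refit must be 'coef-only' or 'full'")

    def fit_with(effects):
        m = ThreeCompartmentPopModel(
            model.dataset, iiv=model.iiv, covariate_effects=tuple(effects),
            allometric=model.allometric,
        )
        start = np.concatenate([base_results.x[: 7 + model.q], np.zeros(len(effects))])
        if refit == "coef-only":
            free = np.zeros(start.size, dtype=bool)
            free[7 + model.q :] = True
        else:
            free = np.ones(start.size, dtype=bool)
        return m.fit(start=start, free=free, maxiter=maxiter)

    base_ofv = fit_with([]).ofv if refit == "coef-only" else base_results.ofv
    selected: list[CovariateEffect] = []
    current_ofv = base_ofv
    log = []
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            try:
                r = fit_with(selected + [cand])
            except Exception as exc:  # fit failure: skip with note
                log.append(("forward-failed", cand.covariate, str(exc)))
                continue
            drop = current_ofv - r.ofv
            log.append(("forward-tried", cand.covariate, drop))
            if drop > forward_dofv and (best is None or drop > best[1]):
                best = (cand, drop, r)
        if best is None:
            break
        selected.append(best[0])
        remaining = [c for c in remaining if c is not best[0]]
        current_ofv = best[2].ofv
        log.append(("forward-included", best[0].covariate, best[1]))
    # backward elimination
    changed = True
    while changed and selected:
        changed = False
        for cand in list(selected):
            reduced = [c for c in selected if c is not cand]
            try:
                r = fit_with(reduced)
            except Exception as exc:
                log.append(("backward-failed", cand.covariate, str(exc)))
                continue
            rise = r.ofv - current_ofv
            log.append(("backward-tried", cand.covariate, rise))
            if rise <= backward_dofv:
                selected = reduced
                current_ofv = r.ofv
                log.append(("backward-removed", cand.covariate, rise))
                changed = True
                break
    return {"selected": selected, "ofv": current_ofv, "base_ofv": base_ofv, "log": log}


def bootstrap(
    model: ThreeCompartmentPopModel,
    results: PopPKResults,
    n: int = 1000,
    seed=None,
    maxiter: int = 100,
) -> dict:
    """Nonparametric bootstrap: resample subjects, refit, summarise.

    Reports the median and 2.5/97.5 percentiles of each fixed effect over
    successful replicates; replicates whose refit fails to produce a
    finite OFV are counted and excluded.  Aborts if more than half fail.
    """
    if model.dataset.n_subjects < 10:
        raise ValueError("bootstrap needs at least 10 subjects")
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    for _ in range(n):
        ds = model.dataset.resample_subjects(rng)
        try:
            m = ThreeCompartmentPopModel(
                ds, iiv=model.iiv, covariate_effects=model.covariate_effects,
                allometric=model.allometric,
            )
            r = m.fit(start=results.x, maxiter=maxiter)
            if not math.isfinite(r.ofv) or r.ofv >= _PENALTY:
                raise RuntimeError("non-finite refit")
            draws.append(r.params.as_array())
        except Exception:
            failures += 1
            if failures > n / 2 and failures > 5:
                raise RuntimeError(f"bootstrap aborted: {failures} failures out of {n} attempted")
    arr = np.array(draws)
    med = dict(zip(PARAM_NAMES, np.median(arr, axis=0)))
    lo = dict(zip(PARAM_NAMES, np.percentile(arr, 2.5, axis=0)))
    hi = dict(zip(PARAM_NAMES, np.percentile(arr, 97.5, axis=0)))
    return {"median": med, "ci_lower": lo, "ci_upper": hi, "n_success": len(draws), "n_failed": failures}


def pcvpc(
    model: ThreeCompartmentPopModel,
    results: PopPKResults,
    n_sim: int = 1000,
    bins: int = 8,
    seed=None,
    probs=(0.05, 0.5, 0.95),
) -> pd.DataFrame:
    """Prediction-corrected visual predictive check.

    Observations and simulations are normalised by the ratio of the bin's
    median typical prediction to the record's own typical prediction
    (typical = random effects at zero for the subject's weight).  Time
    bins are quantile-based; empty bins are merged with neighbours by
    construction.  For each bin the observed percentile statistics are
    compared with the 95% interval of the same statistics over ``n_sim``
    simulated replicates of the dataset design.
    """
    rng = np.random.default_rng(seed)
    theta, w2, s2, _ = model.unpack(results.x)
    recs = model._subjects
    pred_typ, times, obs = [], [], []
    for sub in recs:
        f = _predict_log_batch((theta * sub.scale)[None, :], sub.design)[0]
        pred_typ.append(np.exp(f))
        times.append(sub.rec.obs_times)
        obs.append(np.exp(sub.log_obs))
    pred_typ = np.concatenate(pred_typ)
    times = np.concatenate(times)
    obs = np.concatenate(obs)

    edges = np.unique(np.quantile(times, np.linspace(0, 1, bins + 1)))
    if edges.size < 2:  # a single observation time collapses to one bin
        edges = np.array([times.min() - 0.5, times.max() + 0.5])
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    bin_median_typ = np.array([np.median(pred_typ[bin_idx == b]) for b in range(len(edges) - 1)])
    correction = bin_median_typ[bin_idx] / pred_typ
    pc_obs = obs * correction

    def binned_stats(values):
        return np.array(
            [np.quantile(values[bin_idx == b], probs) for b in range(len(edges) - 1)]
        )  # (nbins, 3)

    obs_stats = binned_stats(pc_obs)

    sd = math.sqrt(s2)
    sim_cols = []  # per subject: (n_sim, n_obs_i) simulated concentrations
    for sub in recs:
        Eta = np.zeros((n_sim, 6))
        Eta[:, model.iiv_idx] = rng.normal(0.0, np.sqrt(w2), size=(n_sim, model.q))
        F = _predict_log_batch((theta * sub.scale)[None, :] * np.exp(Eta), sub.design)
        sim_cols.append(np.exp(F + rng.normal(0.0, sd, size=F.shape)))
    sim_all = np.concatenate(sim_cols, axis=1) * correction[None, :]
    sim_stats = np.empty((n_sim, len(edges) - 1, len(probs)))
    for s in range(n_sim):
        sim_stats[s] = binned_stats(sim_all[s])
    lo = np.percentile(sim_stats, 2.5, axis=0)
    hi = np.percentile(sim_stats, 97.5, axis=0)

    rows = []
    for b in range(len(edges) - 1):
        row = {
            "bin": b,
            "t_lo_min": edges[b],
            "t_hi_min": edges[b + 1],
            "n_obs": int((bin_idx == b).sum()),
        }
        for j, p in enumerate(probs):
            tag = f"p{int(round(100 * p))}"
            row[f"obs_{tag}"] = obs_stats[b, j]
            row[f"sim_{tag}_lo"] = lo[b, j]
            row[f"sim_{tag}_hi"] = hi[b, j]
            row[f"covered_{tag}"] = bool(lo[b, j] <= obs_stats[b, j] <= hi[b, j])
        rows.append(row)
    return pd.DataFrame(rows)
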