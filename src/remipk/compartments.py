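"""Exact solution of the linear three-compartment mammillary model.

The model is the standard intravenous three-compartment structure with
linear (first-order) elimination from the central compartment:

    dA1/dt = -(k10 + k12 + k13) A1 + k21 A2 + k31 A3 + u(t)
    dA2/dt =  k12 A1 - k21 A2
    dA3/dt =  k13 A1 - k31 A3

with micro-rate constants k10 = CL/V1, k12 = Q2/V1, k21 = Q2/V2,
k13 = Q3/V1, k31 = Q3/V3.  Dosing input u(t) is a superposition of
zero-order infusion segments, so the system is piecewise linear with
constant forcing and admits an exact segment-wise solution.

The rate matrix of a mammillary model is similar to a symmetric matrix
under a diagonal scaling, so its eigenvalues are real and negative; the
solver exploits this via `scipy.linalg.eigh` on the symmetrised matrix,
falling back to a matrix-exponential path when an intercompartmental
clearance is zero (degenerate scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .units import MGL_TO_NGML, auc_mgmin_per_l_to_nghr_per_ml

__all__ = [
    "PKParameters",
    "DoseEvent",
    "ConcProfile",
    "solve_concentrations",
    "solve_amounts",
    "auc_inf",
    "PARAM_NAMES",
]

#: canonical parameter order used for arrays, random-effect vectors and fits
PARAM_NAMES = ("CL", "V1", "V2", "Q2", "V3", "Q3")


@dataclass(frozen=True)
class PKParameters:
    """Clearances (L/min) and volumes (L) of the three-compartment model.

    CL is systemic clearance from the central compartment (volume V1);
    Q2/V2 and Q3/V3 are the intercompartmental clearance and volume of the
    shallow and deep peripheral compartments.
    """

    CL: float
    V1: float
    V2: float
    Q2: float
    V3: float
    Q3: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"PKParameters.{name} must be strictly positive and finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PKParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def micro_rates(self) -> dict[str, float]:
        return {
            "k10": self.CL / self.V1,
            "k12": self.Q2 / self.V1,
            "k21": self.Q2 / self.V2,
            "k13": self.Q3 / self.V1,
            "k31": self.Q3 / self.V3,
        }


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order infusion of `amount` mg over `duration` min from `start`.

    A "bolus over 1 min" is duration = 1.  Events may overlap; the system is
    linear so inputs superpose.
    """

    start: float
    duration: float
    amount: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"DoseEvent.duration must be > 0, got {self.duration!r}")
        if self.amount < 0:
            raise ValueError(f"DoseEvent.amount must be >= 0, got {self.amount!r}")
        if self.start < 0:
            raise ValueError(f"DoseEvent.start must be >= 0, got {self.start!r}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/min."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class ConcProfile:
    """Central-compartment concentration (ng/mL) on a strictly increasing grid."""

    times: np.ndarray
    concentrations: np.ndarray
    subject_id: object = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be matching 1-d arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def _rate_matrix(params: PKParameters) -> np.ndarray:
    k = params.micro_rates()
    return np.array(
        [
            [-(k["k10"] + k["k12"] + k["k13"]), k["k21"], k["k31"]],
            [k["k12"], -k["k21"], 0.0],
            [k["k13"], 0.0, -k["k31"]],
        ]
    )


class _Propagator:
    """Exact propagator for one parameter set, reusable across segments."""

    def __init__(self, params: PKParameters):
        self.K = _rate_matrix(params)
        k = params.micro_rates()
        # Mammillary models are symmetrisable: D K D^-1 is symmetric with
        # D = diag(1, sqrt(k21/k12), sqrt(k31/k13)).  Requires k12, k13 > 0.
        if k["k12"] > 0 and k["k13"] > 0:
            d = np.array([1.0, math.sqrt(k["k21"] / k["k12"]), math.sqrt(k["k31"] / k["k13"])])
            S = (self.K * d[:, None]) / d[None, :]
            S = 0.5 * (S + S.T)  # clean round-off
            lam, U = np.linalg.eigh(S)
            self.lam = lam
            self.W = U.T * d[None, :]       # maps amounts -> eigenbasis (U^T D)
            self.Winv = U / d[:, None]      # maps eigenbasis -> amounts (D^-1 U)
            self.degenerate = False
        else:
            self.degenerate = True

    def states(self, A0: np.ndarray, rate: float, taus: np.ndarray) -> np.ndarray:
        """Amount vectors at elapsed times `taus` within one constant-rate segment.

        Returns array of shape (len(taus), 3).
        """
        if self.degenerate:
            return self._states_expm(A0, rate, taus)
        u = np.array([rate, 0.0, 0.0])
        y0 = self.W @ A0
        yu = self.W @ u
        E = np.exp(np.outer(taus, self.lam))          # (nt, 3)
        phi = np.where(self.lam != 0, (E - 1.0) / self.lam, taus[:, None])
        Y = E * y0[None, :] + phi * yu[None, :]
        return Y @ self.Winv.T

    def _states_expm(self, A0, rate, taus):
        # Augmented-matrix exponential: exact for constant input, no
        # invertibility assumption.  Used only when Q2 or Q3 is exactly zero.
        M = np.zeros((4, 4))
        M[:3, :3] = self.K
        M[0, 3] = rate
        out = np.empty((len(taus), 3))
        z0 = np.array([*A0, 1.0])
        for i, tau in enumerate(taus):
            out[i] = (expm(M * tau) @ z0)[:3]
        return out


def _segments(events: Sequence[DoseEvent], t_end: float):
    """Break [0, t_end] into intervals of constant total infusion rate."""
    cuts = {0.0, t_end}
    for ev in events:
        if ev.start < t_end:
            cuts.add(ev.start)
            cuts.add(min(ev.end, t_end))
    bounds = sorted(cuts)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (lo + hi)
        rate = sum(ev.rate for ev in events if ev.start <= mid < ev.end)
        yield lo, hi, rate


def solve_amounts(
    params: PKParameters, events: Sequence[DoseEvent], times
) -> np.ndarray:
    """Amounts in all three compartments (mg) at the requested times.

    `times` must be sorted and non-negative.  The solution is exact for
    piecewise-constant input: within each constant-rate segment the state is
    propagated analytically, and segment boundaries are handled continuously.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be a 1-d array")
    if t.size and (t[0] < 0 or np.any(np.diff(t) < 0)):
        raise ValueError("times must be sorted and non-negative")
    prop = _Propagator(params)
    out = np.zeros((t.size, 3))
    if t.size == 0:
        return out
    A = np.zeros(3)
    t_end = max([t[-1]] + [ev.end for ev in events], default=t[-1])
    # times exactly at 0 resolve to the initial state
    out[t == 0.0] = A
    for lo, hi, rate in _segments(events, t_end):
        mask = (t > lo) & (t <= hi)
        if mask.any():
            out[mask] = prop.states(A, rate, t[mask] - lo)
        A = prop.states(A, rate, np.array([hi - lo]))[0]
    return out


def solve_concentrations(
    params: PKParameters, events: Sequence[DoseEvent], times, subject_id=None
) -> ConcProfile:
    """Central-compartment concentration profile in ng/mL.

    Concentration is amount-in-central / V1 (mg/L), reported as ng/mL.
    Negative round-off values are clipped at zero.
    """
    amounts = solve_amounts(params, events, times)
    conc = np.clip(amounts[:, 0] / params.V1 * MGL_TO_NGML, 0.0, None)
    return ConcProfile(np.asarray(times, dtype=float), conc, subject_id)


def auc_inf(params: PKParameters, events: Sequence[DoseEvent]) -> float:
    """Analytic area under the concentration-time curve to infinity (ng*h/mL).

    For a linear model with central elimination, AUC0-inf = total dose / CL
    regardless of the infusion schedule; this is grid-free and exact.
    """
    total = sum(ev.amount for ev in events)
    return auc_mgmin_per_l_to_nghr_per_ml(total / params.CL)
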