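"""Virtual subjects and inter-individual random effects.

Subjects carry demographics (age, weight, optional height/sex/creatinine)
with derived covariates computed on demand through the covariate engine.
Random effects are mean-zero multivariate normal on the log scale with the
6x6 covariance assembled from per-parameter variances plus the (CL, V1)
and (V2, Q2) covariance blocks; individual parameters are the
allometrically scaled typical values times exp(eta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .compartments import PARAM_NAMES, PKParameters
from .covariates import AllometricSpec, allometric_scale, bmi, bsa_dubois, fces1, mdrd_egfr

__all__ = [
    "VirtualSubject",
    "OmegaMatrix",
    "ResidualSpec",
    "sample_etas",
    "individual_parameters",
    "make_adult_population",
    "make_weight_band_population",
    "make_age_cohorts",
    "AGE_COHORTS",
]


@dataclass(frozen=True)
class VirtualSubject:
    """A simulated individual: demographics plus on-demand derived covariates."""

    id: object
    age: float
    weight: float
    height: float | None = None
    sex: int = 0  # 0 = male, 1 = female
    creatinine: float | None = None

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")

    @property
    def bmi(self) -> float:
        if self.height is None:
            raise ValueError("height required for BMI")
        return bmi(self.weight, self.height)

    @property
    def bsa(self) -> float:
        if self.height is None:
            raise ValueError("height required for BSA")
        return bsa_dubois(self.weight, self.height)

    @property
    def fces1(self) -> float:
        return fces1(self.age)

    @property
    def egfr(self) -> float:
        if self.creatinine is None or self.height is None:
            raise ValueError("creatinine and height required for eGFR")
        return mdrd_egfr(self.creatinine, self.age, bool(self.sex), self.bsa)


class OmegaMatrix:
    """Covariance of the log-normal inter-individual random effects.

    Assembled as a 6x6 symmetric matrix in the canonical parameter order
    (CL, V1, V2, Q2, V3, Q3) from per-parameter variances and named
    covariance terms; entries not named are zero.
    """

    def __init__(self, variances: dict[str, float], covariances: dict[tuple, float] | None = None):
        for name, v in variances.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if v < 0:
                raise ValueError(f"variance for {name} must be >= 0")
        self.variances = {n: float(variances.get(n, 0.0)) for n in PARAM_NAMES}
        self.covariances = {tuple(k): float(v) for k, v in (covariances or {}).items()}
        m = np.zeros((6, 6))
        idx = {n: i for i, n in enumerate(PARAM_NAMES)}
        for n, v in self.variances.items():
            m[idx[n], idx[n]] = v
        for (a, b), v in self.covariances.items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
        self.matrix = m
        # both correlated blocks must be valid covariance blocks
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -1e-12:
            raise ValueError("assembled omega matrix is not positive semi-definite")

    @classmethod
    def zero(cls) -> "OmegaMatrix":
        return cls({n: 0.0 for n in PARAM_NAMES})

    @classmethod
    def diagonal(cls, variances: dict[str, float]) -> "OmegaMatrix":
        return cls(variances)

    def __repr__(self):
        return f"OmegaMatrix(variances={self.variances}, covariances={self.covariances})"


@dataclass(frozen=True)
class ResidualSpec:
    """Residual-error model: additive normal noise on the configured scale.

    On the default "log-concentration" scale the additive variance acts
    multiplicatively (proportionally) on the natural concentration scale;
    on the "concentration" scale it is additive in ng/mL and simulated
    concentrations are truncated at zero.
    """

    variance: float = 0.0
    scale: str = "log-concentration"

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("residual variance must be >= 0")
        if self.scale not in ("log-concentration", "concentration"):
            raise ValueError(f"unknown residual scale {self.scale!r}")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def sample_etas(omega: OmegaMatrix, n: int, rng, strict: bool = False) -> np.ndarray:
    """Draw n mean-zero multivariate-normal random-effect vectors (n x 6).

    Sampling goes through a Cholesky-like factorization of the assembled
    matrix; an indefinite matrix is repaired to the nearest PSD matrix with
    a warning unless ``strict``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    m = omega.matrix
    if not np.any(m):
        return np.zeros((n, 6))
    eigval, eigvec = np.linalg.eigh(m)
    if eigval.min() < -1e-10:
        if strict:
            raise ValueError("omega matrix is not positive semi-definite")
        warnings.warn("omega matrix repaired to nearest PSD", stacklevel=2)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((n, 6))
    return z @ root.T


def individual_parameters(
    typical: PKParameters,
    subject: VirtualSubject,
    etas=None,
    spec: AllometricSpec = AllometricSpec(),
) -> PKParameters:
    """Individual parameters: allometric scaling to the subject's weight,
    then elementwise multiplication by exp(eta)."""
    scaled = allometric_scale(typical, subject.weight, spec)
    if etas is None:
        return scaled
    etas = np.asarray(etas, dtype=float)
    vals = scaled.as_array() * np.exp(etas)
    return PKParameters.from_array(vals)


def _truncated_normal(rng, mean, sd, lo, hi, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def make_adult_population(n: int, seed, weight_mean: float = 63.4, weight_sd: float = 7.3):
    """Virtual adults with weight ~ Normal(mean, sd) truncated at +/-3 SD.

    Ages are uniform on 18-51 years (the adult study range); age does not
    enter the final model and is carried for covariate plumbing only.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = _truncated_normal(
        rng, weight_mean, weight_sd, weight_mean - 3 * weight_sd, weight_mean + 3 * weight_sd, n
    )
    ages = rng.uniform(18.0, 51.0, size=n)
    sexes = rng.random(n) < 0.2  # ~20% female as in the adult studies
    return [
        VirtualSubject(id=i + 1, age=float(a), weight=float(w), sex=int(s))
        for i, (a, w, s) in enumerate(zip(ages, weights, sexes))
    ]


def make_weight_band_population(n: int, w_min: float, w_max: float, seed):
    """Pediatric weight band: weights uniform on [w_min, w_max].

    The uniform-within-band choice puts the band median at the midpoint
    (20 kg for 10-30 kg, 50 kg for 30-70 kg).  Ages are assigned from the
    age-cohort table by nearest median weight; they do not enter the model.
    """
    if not (0 < w_min < w_max):
        raise ValueError("need 0 < w_min < w_max")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(w_min, w_max, size=n)
    cohorts = AGE_COHORTS
    med_w = np.array([c[3] for c in cohorts])
    mid_age = np.array([0.5 * (c[1] + c[2]) for c in cohorts])
    ages = mid_age[np.abs(weights[:, None] - med_w[None, :]).argmin(axis=1)]
    return [
        VirtualSubject(id=i + 1, age=float(a), weight=float(w))
        for i, (a, w) in enumerate(zip(ages, weights))
    ]


#: (label, age_lo, age_hi, median_weight_kg) for the seven simulation cohorts
AGE_COHORTS = (
    ("<1 y", 0.0, 1.0, 6.6),
    ("1-3 y", 1.0, 3.0, 12.2),
    ("3-6 y", 3.0, 6.0, 17.2),
    ("6-9 y", 6.0, 9.0, 24.0),
    ("9-12 y", 9.0, 12.0, 32.9),
    ("12-18 y", 12.0, 18.0, 50.3),
    (">18 y", 18.0, 51.0, 57.0),
)


def make_age_cohorts(seed=None, n_per_cohort: int = 1, weight_cv: float = 0.0):
    """The seven age cohorts used for pediatric extrapolation.

    Returns a list of (label, subjects).  By default each cohort holds one
    subject at the cohort's median weight and mid-age; optional log-normal
    weight jitter (coefficient of variation ``weight_cv``) spreads weights
    for larger cohorts.
    """
    rng = np.random.default_rng(seed)
    out = []
    sid = 0
    for label, lo, hi, med_w in AGE_COHORTS:
        subs = []
        for _ in range(n_per_cohort):
            sid += 1
            w = med_w
            if weight_cv > 0:
                w = float(med_w * np.exp(rng.normal(0.0, weight_cv)))
            subs.append(VirtualSubject(id=sid, age=0.5 * (lo + hi), weight=w))
        out.append((label, subs))
    return out
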