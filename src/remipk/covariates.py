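"""Deterministic covariate mathematics.

Allometric weight scaling of clearances and volumes, the CES1 ontogeny
function, derived covariates (BSA, BMI, MDRD eGFR), and the parametric
covariate-effect forms used during covariate screening.

Remimazolam is inactivated by carboxylesterase 1 (CES1); hepatic CES1
protein abundance matures with age following a Hill-type function that
rises from about 20% of the adult level at birth with half-maturation
near 1.1 years.  In the adult-derived population model the ontogeny
factor is negligible above ~3 years and is therefore exposed as an
optional clearance multiplier, off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .compartments import PKParameters

__all__ = [
    "AllometricSpec",
    "OntogenyParams",
    "CovariateEffect",
    "allometric_scale",
    "fces1",
    "fces1_clearance_factor",
    "mdrd_egfr",
    "bmi",
    "bsa_dubois",
    "apply_covariate_effect",
]

#: reference weight (kg) at which typical parameter values are quoted
REFERENCE_WEIGHT = 63.0

#: reference age (years) for normalising the CES1 ontogeny factor — the
#: typical adult used in model qualification
REFERENCE_AGE = 30.0


@dataclass(frozen=True)
class AllometricSpec:
    """Power-law weight scaling: exponent 0.75 for clearances, 1.0 for volumes."""

    reference_weight: float = REFERENCE_WEIGHT
    exponent_clearances: float = 0.75
    exponent_volumes: float = 1.0

    def __post_init__(self):
        if self.reference_weight <= 0:
            raise ValueError("reference_weight must be positive")


@dataclass(frozen=True)
class OntogenyParams:
    """Hill-function parameters of CES1 protein maturation with age."""

    adult_max: float = 1.0
    f_birth: float = 0.2
    age50: float = 1.10
    hill: float = 0.56

    def __post_init__(self):
        if not (0 <= self.f_birth <= self.adult_max):
            raise ValueError("need 0 <= f_birth <= adult_max")
        if self.age50 <= 0 or self.hill <= 0:
            raise ValueError("age50 and hill must be positive")


def allometric_scale(
    typical: PKParameters, weight: float, spec: AllometricSpec = AllometricSpec()
) -> PKParameters:
    """Scale typical parameters to a body weight.

    CL, Q2 and Q3 are multiplied by (weight/reference)**0.75; V1, V2 and V3
    by (weight/reference)**1.0.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight!r}")
    r = weight / spec.reference_weight
    fc = r**spec.exponent_clearances
    fv = r**spec.exponent_volumes
    return PKParameters(
        CL=typical.CL * fc,
        V1=typical.V1 * fv,
        V2=typical.V2 * fv,
        Q2=typical.Q2 * fc,
        V3=typical.V3 * fv,
        Q3=typical.Q3 * fc,
    )


def fces1(age: float, params: OntogenyParams = OntogenyParams()) -> float:
    """Fractional adult CES1 abundance at an age in years.

    F(age) = (adult_max - f_birth) * age^n / (age50^n + age^n) + f_birth,
    a Hill function equal to f_birth at birth and half-way between birth
    and adult levels at age50.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age!r}")
    if age == 0:
        return params.f_birth
    a_n = age**params.hill
    return (params.adult_max - params.f_birth) * a_n / (params.age50**params.hill + a_n) + params.f_birth


def fces1_clearance_factor(
    age: float, params: OntogenyParams = OntogenyParams(), reference_age: float = REFERENCE_AGE
) -> float:
    """CES1 ontogeny as a clearance multiplier normalised to a reference adult.

    Returns fces1(age)/fces1(reference_age); equals 1 at the reference age.
    Optional — not part of the final adult-derived model, where the factor
    was evaluated on clearance but not retained.
    """
    return fces1(age, params) / fces1(reference_age, params)


def bsa_dubois(weight: float, height: float) -> float:
    """Du Bois body surface area (m^2) from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def bmi(weight: float, height: float) -> float:
    """Body mass index (kg/m^2) from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


def mdrd_egfr(creatinine: float, age: float, female: bool, bsa: float) -> float:
    """MDRD estimated glomerular filtration rate (mL/min), BSA-adjusted.

    eGFR = 175 * (CR/88.4)^-1.234 * age^-0.179 * 0.79(if female) * BSA/1.73
    with serum creatinine CR in umol/L and BSA in m^2.
    """
    if creatinine <= 0 or age <= 0 or bsa <= 0:
        raise ValueError("creatinine, age and bsa must be positive")
    out = 175.0 * (creatinine / 88.4) ** (-1.234) * age ** (-0.179) * bsa / 1.73
    if female:
        out *= 0.79
    return out


CovariateForm = Literal["linear", "power", "exponential", "categorical-shift", "additive-factor"]


@dataclass(frozen=True)
class CovariateEffect:
    """A parametric covariate-parameter relationship.

    Continuous forms (reference value ``reference`` is the covariate median):

    - linear:       P * (1 + theta * cov / reference)
    - power:        P * (cov / reference)^theta
    - exponential:  P * exp(theta * cov)

    Categorical forms:

    - categorical-shift: P + theta[level], with theta[0] fixed at 0 for the
      reference level (``coefficient`` is a mapping level -> shift)
    - additive-factor:   P + theta * indicator, for binary covariates
    """

    target_parameter: str
    covariate: str
    form: CovariateForm
    coefficient: object = 0.0
    reference: float | None = None


def apply_covariate_effect(base: float, effect: CovariateEffect, value) -> float:
    """Evaluate one covariate effect on a base parameter value."""
    form = effect.form
    if form == "linear":
        return base * (1.0 + effect.coefficient * value / effect.reference)
    if form == "power":
        if value <= 0 or effect.reference is None or effect.reference <= 0:
            raise ValueError("power form requires positive covariate and reference")
        return base * (value / effect.reference) ** effect.coefficient
    if form == "exponential":
        return base * math.exp(effect.coefficient * value)
    if form == "categorical-shift":
        shifts = dict(effect.coefficient)
        shifts.setdefault(0, 0.0)
        if value not in shifts:
            raise ValueError(f"no coefficient for categorical level {value!r}")
        return base + shifts[value]
    if form == "additive-factor":
        if value not in (0, 1, 0.0, 1.0, False, True):
            raise ValueError("additive-factor form requires a 0/1 indicator")
        return base + effect.coefficient * float(value)
    raise ValueError(f"unknown covariate form {form!r}")
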