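"""Synthetic clinical-study generator.

Emulates the statistical structure of the two adult Phase-I studies so the
estimation layer is testable end-to-end without any data download:

* study Ia — single ascending doses, eleven groups from 0.007 to
  0.32 mg/kg given as a 1-min IV injection, arterial samples at 19 time
  points (pre-dose through 8 h);
* study Ib — 0.29 mg/kg loading over 1 min given *concurrently* with a
  1.08 mg/kg/h maintenance infusion for 2 h, samples at 26 time points.

Concentrations are simulated from the population model with log-normal
inter-individual variability and additive-on-log residual error; samples
below the assay's lower limit of quantification (0.5 ng/mL) are excluded
by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .compartments import PKParameters
from .covariates import AllometricSpec
from .dataset import PKDataset
from .population import OmegaMatrix, ResidualSpec, VirtualSubject, individual_parameters, sample_etas, _truncated_normal
from .regimen import Regimen, resolve_events
from .compartments import solve_concentrations

__all__ = [
    "StudyDesign",
    "StudyArm",
    "design_ia",
    "design_ib",
    "generate_dataset",
    "combine_datasets",
    "LLOQ_NG_ML",
]

#: assay lower limit of quantification, ng/mL
LLOQ_NG_ML = 0.5


@dataclass(frozen=True)
class StudyArm:
    label: str
    n: int
    regimen: Regimen


@dataclass(frozen=True)
class StudyDesign:
    """Arms, a shared sampling schedule (min), and the demographic generator."""

    name: str
    arms: Sequence[StudyArm]
    schedule: Sequence[float]  # includes the pre-dose sample at t = 0
    age_range: tuple = (18.0, 51.0)
    weight_mean: float = 62.8
    weight_sd: float = 7.3
    weight_bounds: tuple = (50.2, 83.8)
    female_fraction: float = 0.2

    def __post_init__(self):
        if not self.arms:
            raise ValueError("a study design needs at least one arm")
        t = np.asarray(self.schedule, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("schedule times must be non-negative and strictly increasing")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "arms": [
                {"label": a.label, "n": a.n, "regimen": a.regimen.to_dict()} for a in self.arms
            ],
            "schedule_min": list(map(float, self.schedule)),
            "age_range_y": list(self.age_range),
            "weight_mean_kg": self.weight_mean,
            "weight_sd_kg": self.weight_sd,
            "weight_bounds_kg": list(self.weight_bounds),
            "female_fraction": self.female_fraction,
        }


#: single-dose sampling schedule: pre-dose, 1-45 min, 1-8 h (19 points)
IA_SCHEDULE = (0.0, 1, 2, 3, 4, 6, 8, 10, 12, 15, 20, 30, 45, 60, 120, 180, 240, 360, 480)

IA_DOSES = (0.007, 0.01, 0.04, 0.05, 0.07, 0.11, 0.14, 0.18, 0.22, 0.25, 0.32)
IA_GROUP_SIZES = (3, 3, 3, 6, 6, 6, 6, 6, 6, 9, 9)

#: loading+maintenance schedule: pre-dose, on-infusion samples, a
#: pre-cessation sample at 119 min, and post-cessation samples to 4 h
#: after the end of the infusion (26 points)
IB_SCHEDULE = (
    0.0, 1, 2, 3, 4, 6, 10, 15, 30, 60, 90, 119, 120,
    121, 122, 123, 124, 126, 128, 130, 140, 160, 180, 210, 270, 360,
)


def design_ia() -> StudyDesign:
    """Single-ascending-dose study: 11 arms, 1-min IV injection, 63 subjects."""
    arms = [
        StudyArm(f"{d:g} mg/kg", n, Regimen(induction_dose=d, induction_duration=1.0))
        for d, n in zip(IA_DOSES, IA_GROUP_SIZES)
    ]
    return StudyDesign(name="ia", arms=arms, schedule=IA_SCHEDULE)


def design_ib() -> StudyDesign:
    """Loading + concurrent maintenance study: 0.29 mg/kg over 1 min with
    1.08 mg/kg/h for 2 h starting simultaneously; 8 subjects."""
    reg = Regimen(
        induction_dose=0.29,
        induction_duration=1.0,
        maintenance=((1.08, 2.0),),
        maintenance_start="concurrent",
    )
    return StudyDesign(name="ib", arms=[StudyArm("0.29 mg/kg + 1.08 mg/kg/h", 8, reg)], schedule=IB_SCHEDULE)


def generate_dataset(
    design: StudyDesign,
    typical: PKParameters,
    omega: OmegaMatrix,
    residual: ResidualSpec,
    seed,
    lloq: float | None = LLOQ_NG_ML,
    allometric: AllometricSpec = AllometricSpec(),
    n_scale: float = 1.0,
) -> PKDataset:
    """Simulate one dataset realisation of a study design.

    Demographics are drawn per the design spec (truncated-normal weight,
    uniform age, Bernoulli sex).  Residual error is applied on the
    configured scale; observations below ``lloq`` (and the zero pre-dose
    sample) are excluded, mirroring exclusion-style handling of
    below-quantification records.  ``n_scale`` multiplies every arm size
    (rounded up) for parameter-recovery experiments at larger n.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    n_blq = 0
    for arm in design.arms:
        n_arm = max(1, int(np.ceil(arm.n * n_scale)))
        for _ in range(n_arm):
            sid += 1
            w = float(
                _truncated_normal(
                    rng, design.weight_mean, design.weight_sd, *design.weight_bounds, 1
                )[0]
            )
            age = float(rng.uniform(*design.age_range))
            sex = int(rng.random() < design.female_fraction)
            sub = VirtualSubject(id=sid, age=age, weight=w, sex=sex)
            eta = sample_etas(omega, 1, rng)[0]
            p = individual_parameters(typical, sub, eta, allometric)
            events = resolve_events(arm.regimen, w)
            times = np.asarray(design.schedule, dtype=float)
            conc = solve_concentrations(p, events, times).concentrations
            if residual.variance > 0:
                eps = rng.normal(0.0, residual.sd, size=conc.shape)
                if residual.scale == "log-concentration":
                    conc = np.where(conc > 0, conc * np.exp(eps), 0.0)
                else:
                    conc = np.clip(conc + eps, 0.0, None)
            for ev in events:
                rows.append(
                    dict(ID=sid, TIME=ev.start, EVID=1, AMT=ev.amount, RATE=ev.rate,
                         DV=np.nan, MDV=1, WT=w, AGE=age, SEX=sex)
                )
            for t, c in zip(times, conc):
                if lloq is not None and c < lloq:
                    n_blq += 1
                    continue
                missing = c <= 0  # pre-dose / unquantifiable sample
                rows.append(
                    dict(ID=sid, TIME=float(t), EVID=0, AMT=np.nan, RATE=np.nan,
                         DV=np.nan if missing else float(c), MDV=int(missing),
                         WT=w, AGE=age, SEX=sex)
                )
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    ds = PKDataset(df)
    ds.n_below_lloq = n_blq
    return ds


def combine_datasets(*datasets: PKDataset) -> PKDataset:
    """Pool datasets (e.g. the two study realisations), renumbering subjects."""
    parts = []
    offset = 0
    for ds in datasets:
        g = ds.df.copy()
        ids = {sid: offset + j + 1 for j, sid in enumerate(g["ID"].unique())}
        g["ID"] = g["ID"].map(ids)
        offset += len(ids)
        parts.append(g)
    return PKDataset(pd.concat(parts, ignore_index=True))
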