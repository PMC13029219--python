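"""Pediatric weight-band dose recommendation against the adult target window.

A candidate regimen passes for a weight band when the simulated medians of
all three exposure metrics fall inside the adult target window (the
weakest criterion consistent with "comparable to the adult exposure
range").  The recommendation per band is the set of passing regimens; ties
for a single pick are broken by the lowest maintenance rate that covers
the window.  Band-specific maintenance ceilings apply: bands above 30 kg
keep the adult 3.0 mg/kg/h ceiling, bands at or below 30 kg may go up to
4.0 mg/kg/h.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compartments import PKParameters
from .exposure import METRIC_NAMES, TargetWindow, metrics_for, summarize
from .population import OmegaMatrix, make_weight_band_population
from .regimen import Regimen
from .simulate import run_mc

__all__ = ["RegimenVerdict", "evaluate_regimen", "recommend"]


@dataclass(frozen=True)
class RegimenVerdict:
    regimen: Regimen
    band: tuple
    medians: dict
    window_lower: dict
    window_upper: dict
    passes: dict
    policy_note: str = ""

    @property
    def overall_pass(self) -> bool:
        return all(self.passes.values())


def evaluate_regimen(
    population,
    regimen: Regimen,
    window: TargetWindow,
    typical: PKParameters,
    omega: OmegaMatrix,
    seed,
    band=None,
    cmax_lower_policy: bool = False,
) -> RegimenVerdict:
    """Simulate a band population under a regimen and test medians vs window.

    ``cmax_lower_policy`` marks a reduced induction dose carried as a
    deliberately conservative option: the Cmax lower bound is then not
    enforced (a lower peak is acceptable by policy, not exposure matching)
    and the verdict carries a note.
    """
    mc = run_mc(typical, omega, population, regimen, seed=seed)
    summ = summarize(metrics_for(mc))
    passes, note = {}, ""
    for m in METRIC_NAMES:
        lo, hi = window.lower[m], window.upper[m]
        ok = lo <= summ.median[m] <= hi
        if m == "cmax" and cmax_lower_policy and summ.median[m] < lo and summ.median[m] <= hi:
            ok = True
            note = "cmax lower bound waived for reduced induction dose (policy)"
        passes[m] = ok
    return RegimenVerdict(
        regimen, tuple(band) if band else (), dict(summ.median),
        dict(window.lower), dict(window.upper), passes, note,
    )


def _max_rate(regimen: Regimen) -> float:
    return max((r for r, _ in regimen.maintenance), default=0.0)


def recommend(
    bands,
    candidates,
    window: TargetWindow,
    typical: PKParameters,
    omega: OmegaMatrix,
    seed,
    n_per_band: int = 1000,
    caps: dict | None = None,
    reference_induction: float = 0.3,
    upper_coverage: dict | None = None,
) -> dict:
    """Evaluate a candidate grid per weight band and report the recommendation.

    Two questions are answered per band:

    1. which candidates *pass* (all metric medians inside the window); the
       selected initial regimen is the passing one with the lowest
       maintenance rate;
    2. what maintenance *ceiling* the band needs — the smallest candidate
       rate at the reference induction dose whose median C2h and AUC reach
       the upper-window coverage thresholds (``upper_coverage``, typically
       the 5th percentiles of the adult high-maintenance regimen).  Cmax is
       excluded from the ceiling rule: both adult reference regimens share
       the induction dose, so the peak is set by induction, not maintenance.

    ``caps`` maps a band tuple to its allowed ceiling (mg/kg/h); default
    4.0 for bands entirely at or below 30 kg and 3.0 otherwise; candidates
    above the cap are excluded.  Induction doses below
    ``reference_induction`` are conservative options exempted from the Cmax
    lower bound.  A band with no passing candidate is reported explicitly.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate regimen list is empty")
    caps = caps or {}
    report = {}
    for k, band in enumerate(bands):
        w_min, w_max = band
        cap = caps.get(tuple(band), 4.0 if w_max <= 30.0 else 3.0)
        pop = make_weight_band_population(n_per_band, w_min, w_max, seed=(seed, k))
        verdicts = []
        for reg in candidates:
            if _max_rate(reg) > cap:
                continue
            v = evaluate_regimen(
                pop, reg, window, typical, omega, seed=(seed, k, 1),
                band=band, cmax_lower_policy=reg.induction_dose < reference_induction,
            )
            verdicts.append(v)
        passing = [v for v in verdicts if v.overall_pass]
        selected = None
        if passing:
            selected = min(
                passing,
                key=lambda v: (_max_rate(v.regimen), v.regimen.induction_dose),
            )
        required_ceiling = None
        if upper_coverage is not None:
            for v in sorted(verdicts, key=lambda v: _max_rate(v.regimen)):
                if v.regimen.induction_dose != reference_induction:
                    continue
                if all(v.medians[m] >= upper_coverage[m] for m in ("c2h", "auc_inf")):
                    required_ceiling = _max_rate(v.regimen)
                    break
        report[tuple(band)] = {
            "cap_mg_per_kg_per_h": cap,
            "verdicts": verdicts,
            "passing": passing,
            "selected": selected,
            "required_ceiling_mg_per_kg_per_h": required_ceiling,
            "no_passing_candidate": not passing,
        }
    return report
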