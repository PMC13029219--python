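"""Exposure metrics, population summaries, and the adult target window.

The three exposure-matching metrics are Cmax (peak central concentration),
C2h (concentration at the end of the 2-hour maintenance phase) and
AUC0-inf (total area under the curve, computed analytically as
dose/CL).  Population summaries report the median with the empirical
5th/95th percentiles — the 90% interval of individual predictions.  The
adult target window spans the low-maintenance regimen's 5th percentile to
the high-maintenance regimen's 95th percentile, per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import ConcProfile, PKParameters, auc_inf

__all__ = [
    "ExposureMetrics",
    "ExposureSummary",
    "TargetWindow",
    "compute_metrics",
    "metrics_for",
    "summarize",
    "build_target_window",
    "afe",
    "ratio_table",
    "METRIC_NAMES",
]

METRIC_NAMES = ("cmax", "c2h", "auc_inf")


@dataclass(frozen=True)
class ExposureMetrics:
    """Per-subject exposure: cmax and c2h in ng/mL, auc_inf in ng*h/mL."""

    cmax: float
    c2h: float
    auc_inf: float

    def __post_init__(self):
        if min(self.cmax, self.c2h, self.auc_inf) < 0:
            raise ValueError("exposure metrics must be non-negative")


@dataclass(frozen=True)
class ExposureSummary:
    """Median and 5th/95th percentile per metric over a simulated population."""

    median: dict
    lower: dict
    upper: dict
    n: int

    def __post_init__(self):
        for m in self.median:
            if not (self.lower[m] <= self.median[m] <= self.upper[m]):
                raise ValueError(f"quantile ordering violated for {m}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(self.median),
                "median": [self.median[m] for m in self.median],
                "p5": [self.lower[m] for m in self.median],
                "p95": [self.upper[m] for m in self.median],
            }
        )


@dataclass(frozen=True)
class TargetWindow:
    """Per-metric [lower, upper] exposure window."""

    lower: dict
    upper: dict

    def __post_init__(self):
        for m in self.lower:
            if not self.lower[m] < self.upper[m]:
                raise ValueError(f"window degenerate for {m}")

    def contains(self, metric: str, value: float) -> bool:
        return self.lower[metric] <= value <= self.upper[metric]


def compute_metrics(
    profile: ConcProfile,
    params: PKParameters,
    events,
    c2h_time: float | None = None,
) -> ExposureMetrics:
    """Exposure metrics for one subject.

    Cmax is the grid maximum (the simulator injects event boundaries into
    the grid, so infusion-end peaks are exact).  C2h is read at
    ``c2h_time`` minutes (default: end of the last dose event) with linear
    interpolation on log-concentration.  AUC0-inf is analytic (dose/CL),
    exact and grid-free.
    """
    t, c = profile.times, profile.concentrations
    if len(events) == 0 or sum(ev.amount for ev in events) == 0:
        return ExposureMetrics(0.0, 0.0, 0.0)
    if c2h_time is None:
        c2h_time = max(ev.end for ev in events)
    if c2h_time > t[-1] or c2h_time < t[0]:
        raise ValueError(f"profile grid does not cover the readout time {c2h_time} min")
    logc = np.log(np.clip(c, 1e-300, None))
    c2h = float(np.exp(np.interp(c2h_time, t, logc)))
    return ExposureMetrics(float(c.max()), c2h, auc_inf(params, events))


def metrics_for(mc_result, c2h_time: float | None = None) -> list[ExposureMetrics]:
    """Per-subject metrics for a Monte-Carlo result."""
    return [
        compute_metrics(prof, p, ev, c2h_time)
        for prof, p, ev in zip(mc_result.profiles, mc_result.params, mc_result.events_list)
    ]


def summarize(metrics, probs=(0.05, 0.5, 0.95)) -> ExposureSummary:
    """Empirical quantile summary (type-7 interpolation) per metric."""
    metrics = list(metrics)
    if not metrics:
        raise ValueError("cannot summarize an empty metrics collection")
    lo_p, med_p, hi_p = sorted(probs)
    median, lower, upper = {}, {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(x, m) for x in metrics])
        lower[m], median[m], upper[m] = np.quantile(vals, [lo_p, med_p, hi_p])
    return ExposureSummary(median, lower, upper, len(metrics))


def build_target_window(low_summary: ExposureSummary, high_summary: ExposureSummary) -> TargetWindow:
    """Adult target window: low regimen's 5th pct to high regimen's 95th pct."""
    if set(low_summary.median) != set(high_summary.median):
        raise ValueError("summaries cover different metrics")
    return TargetWindow(dict(low_summary.lower), dict(high_summary.upper))


def afe(predicted: float, observed: float) -> float:
    """Average fold error: predicted / observed."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    return predicted / observed


def ratio_table(summary_a: ExposureSummary, summary_b: ExposureSummary) -> dict:
    """Elementwise ratio of medians, metric by metric (model-comparison table)."""
    if set(summary_a.median) != set(summary_b.median):
        raise ValueError("summaries cover different metrics")
    return {m: summary_a.median[m] / summary_b.median[m] for m in summary_a.median}
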