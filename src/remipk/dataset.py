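"""Event-record dataset container.

Records follow the conventional IV event-record dialect: one row per dose
or observation, identified by EVID (1 = dose, 0 = observation).  Doses
carry AMT (mg) and RATE (mg/min); observations carry DV (ng/mL) unless
MDV = 1.  WT (kg), AGE (y), SEX (0 = male, 1 = female) and optional HT
(cm) / CR (umol/L) ride along as covariates; any additional numeric
column is kept and exposed as a subject-level covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import DoseEvent

__all__ = ["PKDataset", "SubjectRecord", "DatasetError", "MANDATORY_COLUMNS"]

MANDATORY_COLUMNS = ("ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV", "WT")
OPTIONAL_COLUMNS = ("AGE", "SEX", "HT", "CR")


class DatasetError(ValueError):
    pass


@dataclass
class SubjectRecord:
    """Per-subject view: dose events, observation times and concentrations."""

    id: object
    weight: float
    events: list
    obs_times: np.ndarray
    obs_conc: np.ndarray
    covariates: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)


class PKDataset:
    """Validated event-record dataset wrapping a DataFrame.

    Validation reports offending row numbers (0-based positions in the
    frame).  Observations recorded before any dose are accepted (pre-dose
    samples); structural violations raise :class:`DatasetError`.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing mandatory column(s): {missing}")
        problems = []
        for col in ("TIME", "EVID", "WT"):
            bad = df.index[df[col].isna()].tolist()
            if bad:
                problems.append(f"{col} missing at rows {bad[:5]}")
        doses = df["EVID"] == 1
        obs = df["EVID"] == 0
        bad = df.index[doses & ~(df["AMT"] > 0)].tolist()
        if bad:
            problems.append(f"dose rows need AMT > 0: rows {bad[:5]}")
        bad = df.index[doses & df["DV"].notna()].tolist()
        if bad:
            problems.append(f"dose rows must not carry DV: rows {bad[:5]}")
        bad = df.index[doses & ~(df["RATE"] > 0)].tolist()
        if bad:
            problems.append(f"dose rows need RATE > 0: rows {bad[:5]}")
        bad = df.index[obs & (df["MDV"].fillna(0) == 0) & df["DV"].isna()].tolist()
        if bad:
            problems.append(f"observation rows need DV unless MDV=1: rows {bad[:5]}")
        for sid, g in df.groupby("ID", sort=False):
            t = g["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                problems.append(f"records not time-ordered for subject {sid!r}")
        if problems:
            raise DatasetError("; ".join(problems))
        self.df = df

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_obs(self) -> int:
        d = self.df
        return int(((d["EVID"] == 0) & (d["MDV"].fillna(0) == 0)).sum())

    def subjects(self) -> list[SubjectRecord]:
        extra = [
            c
            for c in self.df.columns
            if c not in MANDATORY_COLUMNS and pd.api.types.is_numeric_dtype(self.df[c])
        ]
        out = []
        for sid, g in self.df.groupby("ID", sort=False):
            doses = g[g["EVID"] == 1]
            events = [
                DoseEvent(start=float(r.TIME), duration=float(r.AMT / r.RATE), amount=float(r.AMT))
                for r in doses.itertuples()
            ]
            o = g[(g["EVID"] == 0) & (g["MDV"].fillna(0) == 0)]
            cov = {c: float(g[c].iloc[0]) for c in extra if pd.notna(g[c].iloc[0])}
            cov["WT"] = float(g["WT"].iloc[0])
            out.append(
                SubjectRecord(
                    id=sid,
                    weight=float(g["WT"].iloc[0]),
                    events=events,
                    obs_times=o["TIME"].to_numpy(dtype=float),
                    obs_conc=o["DV"].to_numpy(dtype=float),
                    covariates=cov,
                )
            )
        return out

    def resample_subjects(self, rng) -> "PKDataset":
        """Nonparametric bootstrap resample: subjects drawn with replacement,
        re-identified 1..n."""
        ids = self.df["ID"].unique()
        rng = np.random.default_rng(rng)
        picks = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(picks, start=1):
            g = self.df[self.df["ID"] == sid].copy()
            g["ID"] = new_id
            parts.append(g)
        return PKDataset(pd.concat(parts, ignore_index=True))

    def __repr__(self):
        return f"PKDataset(n_subjects={self.n_subjects}, n_obs={self.n_obs})"
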