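"""NONMEM-style dataset container and CSV dialect.

Rows carry ID, TIME (h), EVID (1 = dose, 0 = observation), AMT (mg),
DUR (h), DV (mg/L) and the covariate columns WT, SCR, AGE, SEX, HT, EGFR.
Missing values (DV on dose rows, AMT/DUR on observation rows) are written
as ``.``, the NONMEM convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_model import DoseEvent

__all__ = ["Subject", "PKDataset", "COLUMNS"]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "WT", "SCR", "AGE", "SEX", "HT", "EGFR"]

_NUMERIC = ["TIME", "EVID", "AMT", "DUR", "DV", "WT", "SCR", "AGE", "SEX", "HT", "EGFR"]


@dataclass
class Subject:
    """One subject's dosing history, observations and covariates."""

    id: object
    doses: list[DoseEvent]
    obs_times: np.ndarray
    obs_values: np.ndarray
    covariates: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)


class PKDataset:
    """A population PK dataset backed by a long-format DataFrame."""

    def __init__(self, df: pd.DataFrame):
        missing = {"ID", "TIME", "EVID"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing required columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    # -- IO ---------------------------------------------------------------

    @classmethod
    def read_csv(cls, path) -> "PKDataset":
        df = pd.read_csv(path, na_values=["."], comment="#",
                         float_precision="round_trip")
        for col in _NUMERIC:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col])
        return cls(df)

    def write_csv(self, path) -> None:
        out = self.df.copy()
        out.to_csv(path, index=False, na_rep=".")

    # -- access -----------------------------------------------------------

    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    def subjects(self) -> list[Subject]:
        subjects = []
        for sid, grp in self.df.groupby("ID", sort=False):
            doses = [
                DoseEvent(start_time=float(r.TIME), amount=float(r.AMT),
                          duration=float(r.DUR) if "DUR" in grp.columns and np.isfinite(r.DUR) else 0.5)
                for r in grp[grp["EVID"] == 1].itertuples()
            ]
            obs = grp[grp["EVID"] == 0]
            cov_row = grp.iloc[0]
            covariates = {
                c: float(cov_row[c])
                for c in ("WT", "SCR", "AGE", "SEX", "HT", "EGFR")
                if c in grp.columns and np.isfinite(cov_row[c])
            }
            subjects.append(
                Subject(
                    id=sid,
                    doses=doses,
                    obs_times=obs["TIME"].to_numpy(dtype=float),
                    obs_values=obs["DV"].to_numpy(dtype=float),
                    covariates=covariates,
                )
            )
        return subjects

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def drop_blq(self, loq: float) -> tuple["PKDataset", int]:
        """Drop observation rows with DV < loq; returns (dataset, n_dropped)."""
        mask = (self.df["EVID"] == 0) & (self.df["DV"] < loq)
        return PKDataset(self.df[~mask]), int(mask.sum())
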