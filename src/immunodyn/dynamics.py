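"""Rate-of-change parametrization between the two sampling time points."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .feature_extraction import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class DynamicsMatrix:
    """Patients x features matrix of rates of change (units per week)."""

    values: pd.DataFrame           # index: patient; columns: feature IDs
    meta: pd.DataFrame             # inherited per-feature metadata
    sheet: pd.DataFrame            # aligned sample sheet (patient order)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, meta: pd.DataFrame,
                 sheet: pd.DataFrame) -> "DynamicsMatrix":
        values = pd.read_csv(path, index_col=0)
        sheet = sheet.set_index("patient").loc[values.index].reset_index()
        return cls(values, meta, sheet)


def _patient_frame(fm, timepoint: str) -> pd.DataFrame:
    """Patient-indexed values from a FeatureMatrix (possibly a single
    timepoint slice) or a plain patient-indexed DataFrame."""
    df = fm.values if isinstance(fm, FeatureMatrix) else fm
    if isinstance(df.index, pd.MultiIndex):
        tps = df.index.get_level_values("timepoint").unique()
        if timepoint in tps:
            df = df.xs(timepoint, level="timepoint")
        elif len(tps) == 1:
            df = df.droplevel("timepoint")
        else:
            raise ValidationError(
                f"feature matrix lacks timepoint {timepoint!r}")
    return df


def compute_rates(fm_t1, fm_t2, sheet: pd.DataFrame) -> DynamicsMatrix:
    """rho = (value_T2 - value_T1) / (GA_T2 - GA_T1) per patient per feature.

    Patients missing either time point are dropped with a warning; missing
    feature values at either time point yield a missing (NaN) rate.
    """
    v1 = _patient_frame(fm_t1, "T1")
    v2 = _patient_frame(fm_t2, "T2")
    if list(v1.columns) != list(v2.columns):
        common = [c for c in v1.columns if c in set(v2.columns)]
        if not common:
            raise ValidationError("T1/T2 feature matrices share no columns")
        logger.warning("restricting rates to %d shared features", len(common))
        v1, v2 = v1[common], v2[common]

    sheet = sheet.copy()
    sheet["patient"] = sheet["patient"].astype(str)
    v1.index = v1.index.astype(str)
    v2.index = v2.index.astype(str)
    bad = sheet[sheet["GA_T2"] <= sheet["GA_T1"]]
    if len(bad):
        raise ValidationError(
            "GA_T2 <= GA_T1 for patient(s): "
            + ", ".join(bad["patient"].tolist()))

    patients = [p for p in sheet["patient"]
                if p in v1.index and p in v2.index]
    dropped = [p for p in sheet["patient"] if p not in patients]
    if dropped:
        logger.warning("dropping patients missing a time point: %s", dropped)
    sheet = sheet[sheet["patient"].isin(patients)].reset_index(drop=True)

    ga = sheet.set_index("patient")
    dt = (ga.loc[patients, "GA_T2"] - ga.loc[patients, "GA_T1"]).to_numpy()
    rates = (v2.loc[patients].to_numpy() - v1.loc[patients].to_numpy()) \
        / dt[:, None]
    values = pd.DataFrame(rates, index=pd.Index(patients, name="patient"),
                          columns=v1.columns)
    meta = fm_t1.meta if isinstance(fm_t1, FeatureMatrix) else pd.DataFrame(
        index=v1.columns)
    n_missing = int(np.isnan(rates).sum())
    if n_missing:
        logger.warning("%d missing rates flagged as NaN", n_missing)
    return DynamicsMatrix(values, meta.loc[list(values.columns)]
                          if len(meta) else meta, sheet)
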