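"""Immune feature derivation from labeled single-cell event tables.

Three feature categories are produced per sample (patient x timepoint):

* ``frequency`` — percentage of labeled cells falling in each subset;
* ``basal`` — mean arcsinh-transformed intensity of each functional marker
  within each subset, computed on the unstimulated (reference) condition;
* ``stim_response`` — difference of mean transformed intensities,
  stimulated minus unstimulated, per subset, marker and stimulation
  condition, with configurable exclusions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PairingError, ValidationError

logger = logging.getLogger(__name__)

#: The 21 immune cell subsets profiled by the default panel.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "B cells",
    "NK",
    "CD56hiCD16- NK",
    "CD56loCD16+ NK",
    "CD4+T",
    "CD4+Tmem",
    "CD4+Tnaive",
    "Th1",
    "Tregs",
    "CD8+T",
    "CD8+Tmem",
    "CD8+Tnaive",
    "CD8+Tbet+CD45RA-",
    "CD8+Tbet+CD45RA+",
    "TCRgd T",
    "cMC",
    "ncMC",
    "intMC",
    "M-MDSC",
    "mDC",
    "pDC",
)

#: The 11 functional (signaling) markers of the default panel.
DEFAULT_FUNCTIONAL_MARKERS: tuple[str, ...] = (
    "pSTAT1",
    "pSTAT3",
    "pSTAT5",
    "pSTAT6",
    "pNFkB",
    "pMAPKAPK2",
    "pP38",
    "prpS6",
    "pERK1/2",
    "pCREB",
    "IkB",
)

DEFAULT_CONDITIONS: tuple[str, ...] = ("unstim", "LPS+IFNa")

#: Label applied to events that belong to none of the declared subsets.
UNASSIGNED = "unassigned"

_SEP = "|"


def feature_id(category: str, cell_type: str, marker: str | None = None,
               condition: str | None = None) -> str:
    """Build the canonical feature identifier for a (category, subset, marker,
    condition) combination, e.g. ``'stim|Th1|pSTAT5|LPS+IFNa'``."""
    parts = [category, cell_type]
    if marker is not None:
        parts.append(marker)
    if condition is not None:
        parts.append(condition)
    return _SEP.join(parts)


@dataclass(frozen=True)
class PanelConfig:
    """Panel/gating configuration: subsets, markers, conditions, exclusions.

    Parameters
    ----------
    cell_types
        Ordered subset names; defaults to the 21-subset panel.
    functional_markers
        Ordered signaling marker names; defaults to the 11-marker panel.
    conditions
        All conditions, the first (or ``reference_condition``) being the
        unstimulated reference.
    exclusion_mask
        Set of ``(cell_type, marker, condition)`` triples dropped from the
        stimulation-response features.
    arcsinh_cofactor
        Cofactor of the variance-stabilizing arcsinh transform.
    min_cells
        Minimum events per subset for signaling features; below it the
        feature is reported missing (NaN) rather than computed.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    functional_markers: tuple[str, ...] = DEFAULT_FUNCTIONAL_MARKERS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    reference_condition: str | None = None
    exclusion_mask: frozenset[tuple[str, str, str]] = frozenset()
    arcsinh_cofactor: float = 5.0
    min_cells: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "functional_markers",
                           tuple(self.functional_markers))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "exclusion_mask",
                           frozenset(tuple(t) for t in self.exclusion_mask))
        if self.reference_condition is None:
            object.__setattr__(self, "reference_condition", self.conditions[0])
        self.validate()

    def validate(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ConfigurationError("arcsinh_cofactor must be > 0")
        if self.reference_condition not in self.conditions:
            raise ConfigurationError(
                f"reference_condition {self.reference_condition!r} not among "
                f"declared conditions {self.conditions}")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigurationError("duplicate cell type names")
        if len(set(self.functional_markers)) != len(self.functional_markers):
            raise ConfigurationError("duplicate marker names")
        for ct, m, cond in self.exclusion_mask:
            if ct not in self.cell_types:
                raise ConfigurationError(
                    f"exclusion_mask references unknown cell type {ct!r}")
            if m not in self.functional_markers:
                raise ConfigurationError(
                    f"exclusion_mask references unknown marker {m!r}")
            if cond not in self.conditions:
                raise ConfigurationError(
                    f"exclusion_mask references unknown condition {cond!r}")

    @property
    def stim_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions
                     if c != self.reference_condition)

    def included_stim_triples(self) -> list[tuple[str, str, str]]:
        """All (cell_type, marker, condition) stim triples not excluded."""
        return [(ct, m, cond)
                for cond in self.stim_conditions
                for ct in self.cell_types
                for m in self.functional_markers
                if (ct, m, cond) not in self.exclusion_mask]

    def feature_ids(self) -> list[str]:
        """Canonical feature column order: frequency, basal, stim-response."""
        ids = [feature_id("freq", ct) for ct in self.cell_types]
        ids += [feature_id("basal", ct, m)
                for ct in self.cell_types for m in self.functional_markers]
        ids += [feature_id("stim", ct, m, cond)
                for ct, m, cond in self.included_stim_triples()]
        return ids

    def feature_metadata(self) -> pd.DataFrame:
        rows = []
        for ct in self.cell_types:
            rows.append((feature_id("freq", ct), "frequency", ct, None, None))
        for ct in self.cell_types:
            for m in self.functional_markers:
                rows.append((feature_id("basal", ct, m), "basal", ct, m,
                             self.reference_condition))
        for ct, m, cond in self.included_stim_triples():
            rows.append((feature_id("stim", ct, m, cond), "stim_response",
                         ct, m, cond))
        meta = pd.DataFrame(rows, columns=["feature", "category", "cell_type",
                                           "marker", "condition"])
        return meta.set_index("feature")


@dataclass
class EventTable:
    """Single-cell events for one (patient, timepoint, condition).

    ``data`` holds one row per cell with a ``cell_type`` column plus one
    column per marker. ``transformed`` records whether marker columns are
    already arcsinh-transformed.
    """

    patient: str
    timepoint: str
    condition: str
    data: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if "cell_type" not in self.data.columns:
            raise ValidationError(
                f"event table {self.key} lacks a 'cell_type' column")
        if not self.transformed:
            markers = [c for c in self.data.columns if c != "cell_type"]
            if len(markers) and (self.data[markers].to_numpy() < 0).any():
                raise ValidationError(
                    f"negative raw intensities in event table {self.key}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient, self.timepoint, self.condition)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "patient", self.patient)
        out.insert(1, "timepoint", self.timepoint)
        out.insert(2, "condition", self.condition)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, transformed: bool = False) -> "EventTable":
        df = pd.read_csv(path)
        for col in ("patient", "timepoint", "condition"):
            if col not in df.columns:
                raise ValidationError(f"{path}: missing column {col!r}")
        keys = df[["patient", "timepoint", "condition"]].drop_duplicates()
        if len(keys) != 1:
            raise ValidationError(
                f"{path}: expected a single (patient, timepoint, condition)")
        patient, timepoint, condition = map(str, keys.iloc[0])
        data = df.drop(columns=["patient", "timepoint", "condition"])
        return cls(patient, timepoint, condition, data, transformed=transformed)


@dataclass
class FeatureMatrix:
    """Samples x features matrix with per-feature metadata.

    ``values`` is indexed by a (patient, timepoint) MultiIndex; ``meta`` is
    indexed by feature id with columns category / cell_type / marker /
    condition.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate feature IDs in FeatureMatrix")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(
                f"features lacking metadata: {sorted(missing)[:5]} ...")
        freq_cols = self.meta.index[self.meta["category"] == "frequency"]
        freq_cols = [c for c in freq_cols if c in self.values.columns]
        if freq_cols:
            fv = self.values[freq_cols].to_numpy(dtype=float)
            ok = np.isnan(fv) | ((fv >= 0) & (fv <= 100))
            if not ok.all():
                raise ValidationError("frequency features outside [0, 100]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def for_timepoint(self, timepoint: str) -> pd.DataFrame:
        """Patient-indexed slice of one timepoint."""
        df = self.values.xs(timepoint, level="timepoint")
        return df

    def stacked(self) -> pd.DataFrame:
        """All samples as rows (observations pooled over timepoints)."""
        return self.values

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path)
        sidecar = path.with_suffix(".meta.json")
        meta = self.meta.reset_index()
        sidecar.write_text(json.dumps(
            meta.where(pd.notna(meta), None).to_dict(orient="records"),
            indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        values = pd.read_csv(path, index_col=[0, 1])
        values.index.names = ["patient", "timepoint"]
        records = json.loads(path.with_suffix(".meta.json").read_text())
        meta = pd.DataFrame.from_records(records).set_index("feature")
        return cls(values, meta)


def arcsinh_transform(x, cofactor: float = 5.0):
    """Variance-stabilizing transform ``asinh(x / cofactor)``.

    Raises on negative input: raw mass-cytometry counts are non-negative.
    """
    if cofactor <= 0:
        raise ConfigurationError("cofactor must be > 0")
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValidationError("arcsinh_transform: negative intensity")
    out = np.arcsinh(arr / cofactor)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _transformed_markers(events: EventTable, panel: PanelConfig) -> pd.DataFrame:
    markers = [m for m in panel.functional_markers if m in events.data.columns]
    unknown = [c for c in events.data.columns
               if c not in ("cell_type", *panel.functional_markers)]
    if unknown:
        raise ConfigurationError(
            f"event table {events.key} carries markers not in panel: {unknown}")
    vals = events.data[markers]
    if events.transformed:
        return vals
    return pd.DataFrame(
        arcsinh_transform(vals.to_numpy(), panel.arcsinh_cofactor),
        columns=markers, index=vals.index)


def compute_frequencies(events: EventTable, panel: PanelConfig) -> pd.Series:
    """Per-subset percentage of all labeled live mononuclear cells."""
    total = events.n_cells
    if total == 0:
        raise ValidationError(f"zero cells in sample {events.key}")
    counts = events.data["cell_type"].value_counts()
    freqs = {feature_id("freq", ct): 100.0 * counts.get(ct, 0) / total
             for ct in panel.cell_types}
    return pd.Series(freqs, dtype=float)


def _mean_by_celltype(events: EventTable, panel: PanelConfig) -> pd.DataFrame:
    """Mean transformed intensity per (cell_type, marker); NaN below
    the ``min_cells`` threshold or for absent subsets."""
    tvals = _transformed_markers(events, panel)
    by = tvals.groupby(events.data["cell_type"].to_numpy())
    means = by.mean()
    counts = by.size()
    means = means.reindex(list(panel.cell_types))
    small = counts.reindex(list(panel.cell_types)).fillna(0) < panel.min_cells
    means[small.to_numpy()] = np.nan
    return means  # rows: cell types; cols: markers


def compute_basal_signaling(events_unstim: EventTable,
                            panel: PanelConfig) -> pd.Series:
    """Mean arcsinh-transformed intensity per (subset, marker) at rest."""
    if events_unstim.condition != panel.reference_condition:
        raise PairingError(
            f"basal features require the reference condition "
            f"{panel.reference_condition!r}, got {events_unstim.condition!r}")
    means = _mean_by_celltype(events_unstim, panel)
    out = {feature_id("basal", ct, m): means.at[ct, m]
           for ct in panel.cell_types for m in means.columns}
    return pd.Series(out, dtype=float)


def compute_stim_response(events_stim: EventTable, events_unstim: EventTable,
                          panel: PanelConfig) -> pd.Series:
    """Arcsinh-difference (stimulated minus unstimulated mean transformed
    intensity) per included (subset, marker) triple."""
    if (events_stim.patient, events_stim.timepoint) != \
            (events_unstim.patient, events_unstim.timepoint):
        raise PairingError(
            f"stim table {events_stim.key} does not pair with "
            f"unstim table {events_unstim.key}")
    cond = events_stim.condition
    m_stim = _mean_by_celltype(events_stim, panel)
    m_ref = _mean_by_celltype(events_unstim, panel)
    out = {}
    for ct, m, c in panel.included_stim_triples():
        if c != cond or m not in m_stim.columns:
            continue
        out[feature_id("stim", ct, m, c)] = m_stim.at[ct, m] - m_ref.at[ct, m]
    return pd.Series(out, dtype=float)


def extract_features(event_tables: Iterable[EventTable], panel: PanelConfig,
                     sample_sheet: pd.DataFrame) -> FeatureMatrix:
    """Assemble the full FeatureMatrix for a cohort.

    ``sample_sheet`` must carry ``patient`` plus the timepoints implied by
    the event tables; every (patient, timepoint) needs an unstimulated
    table, stimulated tables are optional per condition.
    """
    by_key: dict[tuple[str, str, str], EventTable] = {}
    for t in event_tables:
        by_key[t.key] = t
    samples = sorted({(t.patient, t.timepoint) for t in by_key.values()})
    patients = set(sample_sheet["patient"].astype(str))
    samples = [s for s in samples if s[0] in patients]

    columns = panel.feature_ids()
    rows = {}
    for patient, timepoint in samples:
        ref_key = (patient, timepoint, panel.reference_condition)
        if ref_key not in by_key:
            raise PairingError(
                f"missing unstimulated table for sample ({patient}, {timepoint})")
        unstim = by_key[ref_key]
        feats = [compute_frequencies(unstim, panel),
                 compute_basal_signaling(unstim, panel)]
        for cond in panel.stim_conditions:
            key = (patient, timepoint, cond)
            if key in by_key:
                feats.append(compute_stim_response(by_key[key], unstim, panel))
        rows[(patient, timepoint)] = pd.concat(feats)

    values = pd.DataFrame.from_dict(rows, orient="index")
    values = values.reindex(columns=[c for c in columns if c in values.columns]
                            if len(values) else columns)
    if len(values):
        values.index = pd.MultiIndex.from_tuples(values.index,
                                                 names=["patient", "timepoint"])
    else:
        values.index = pd.MultiIndex.from_arrays([[], []],
                                                 names=["patient", "timepoint"])
    meta = panel.feature_metadata().loc[list(values.columns)]
    logger.info("extracted %d features for %d samples (%d freq, %d basal, "
                "%d stim-response)", values.shape[1], values.shape[0],
                len(panel.cell_types),
                len(panel.cell_types) * len(panel.functional_markers),
                len(panel.included_stim_triples()))
    return FeatureMatrix(values, meta)


def impute_missing(values: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Mean-impute missing feature values, within group when labels given.

    Features missing everywhere (or everywhere within a group, with no
    global fallback) are filled with 0 and logged.
    """
    out = values.copy()
    if groups is not None:
        g = groups.reindex(out.index.get_level_values("patient")
                           if isinstance(out.index, pd.MultiIndex)
                           else out.index)
        for lvl in g.unique():
            mask = (g == lvl).to_numpy()
            sub = out[mask]
            out[mask] = sub.fillna(sub.mean())
    out = out.fillna(out.mean())
    still = out.columns[out.isna().any()]
    if len(still):
        logger.warning("features with no observed values filled with 0: %s",
                       list(still[:5]))
        out = out.fillna(0.0)
    return out
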