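"""Ground-truthed synthetic cohorts for end-to-end testing of the pipeline.

Two generators share one mean model:

* :func:`simulate_feature_matrix` emits sample x feature matrices directly
  (latent-factor structure + group/time trends + Gaussian noise);
* :func:`simulate_event_tables` emits single-cell event tables whose
  arcsinh-transformed marker means follow the same model, so that feature
  extraction recovers the intended values up to Monte-Carlo error.

Every random draw is routed through substreams derived deterministically
from the design's single integer seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .feature_extraction import (DEFAULT_CELL_TYPES, DEFAULT_FUNCTIONAL_MARKERS,
                                 DEFAULT_CONDITIONS, EventTable, FeatureMatrix,
                                 PanelConfig, feature_id)

logger = logging.getLogger(__name__)

_CATEGORIES = ("frequency", "basal", "stim_response")


@dataclass(frozen=True)
class PlantedEffect:
    """A feature with group-differential temporal dynamics.

    Slopes are in feature units per week of gestational age; the optional
    ``baseline_shift_case`` is a constant offset added to case samples.
    """

    cell_type: str
    category: str
    marker: str | None = None
    condition: str | None = None
    control_slope: float = 0.0
    case_slope: float = 0.0
    baseline_shift_case: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ConfigurationError(
                f"planted effect category must be one of {_CATEGORIES}, "
                f"got {self.category!r}")
        if self.category != "frequency" and self.marker is None:
            raise ConfigurationError(
                f"planted {self.category} effect needs a marker")

    def feature(self, stim_condition: str) -> str:
        if self.category == "frequency":
            return feature_id("freq", self.cell_type)
        if self.category == "basal":
            return feature_id("basal", self.cell_type, self.marker)
        cond = self.condition or stim_condition
        return feature_id("stim", self.cell_type, self.marker, cond)


@dataclass
class CohortDesign:
    """Parameters of a 2-group, 2-timepoint, 2-condition synthetic cohort."""

    n_control: int = 12
    n_case: int = 11
    ga_t1_mean_sd: tuple[float, float] = (11.0, 1.9)
    ga_t2_mean_sd: tuple[float, float] = (25.25, 4.2)
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    functional_markers: tuple[str, ...] = DEFAULT_FUNCTIONAL_MARKERS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    planted_effects: tuple[PlantedEffect, ...] = ()
    n_latent_factors: int = 0
    factor_loading_sd: float = 0.0
    noise_sd: float = 0.1
    events_per_sample: int = 5000
    seed: int = 0
    # mean-model baselines (arbitrary but plausible arcsinh-scale values)
    basal_mean: float = 2.0
    stim_response_mean: float = 0.5
    event_sd: float = 0.5
    arcsinh_cofactor: float = 5.0
    dirichlet_concentration: float = 5000.0

    def __post_init__(self) -> None:
        self.cell_types = tuple(self.cell_types)
        self.functional_markers = tuple(self.functional_markers)
        self.conditions = tuple(self.conditions)
        self.planted_effects = tuple(self.planted_effects)
        self.validate()

    def validate(self) -> None:
        if self.n_control < 2:
            raise ConfigurationError("n_control must be >= 2")
        if self.n_case < 2:
            raise ConfigurationError("n_case must be >= 2")
        if self.ga_t2_mean_sd[0] <= self.ga_t1_mean_sd[0]:
            raise ConfigurationError(
                "ga_t2_mean_sd mean must exceed ga_t1_mean_sd mean")
        if self.events_per_sample < 100:
            raise ConfigurationError("events_per_sample must be >= 100")
        if self.n_latent_factors < 0:
            raise ConfigurationError("n_latent_factors must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        stim = self.stim_conditions
        for eff in self.planted_effects:
            if eff.cell_type not in self.cell_types:
                raise ConfigurationError(
                    f"planted_effects: unknown cell type {eff.cell_type!r}")
            if eff.marker is not None and eff.marker not in self.functional_markers:
                raise ConfigurationError(
                    f"planted_effects: unknown marker {eff.marker!r}")
            if eff.condition is not None and eff.condition not in self.conditions:
                raise ConfigurationError(
                    f"planted_effects: unknown condition {eff.condition!r}")
        if not stim:
            raise ConfigurationError("design needs >= 1 stimulated condition")

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]

    @property
    def stim_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions[1:])

    @property
    def n_patients(self) -> int:
        return self.n_control + self.n_case

    def panel(self) -> PanelConfig:
        return PanelConfig(cell_types=self.cell_types,
                           functional_markers=self.functional_markers,
                           conditions=self.conditions,
                           arcsinh_cofactor=self.arcsinh_cofactor)

    def feature_ids(self) -> list[str]:
        return self.panel().feature_ids()


@dataclass
class TruthTable:
    """Ground truth recorded alongside a simulated cohort."""

    informative_features: set[str]
    true_slopes: dict[str, dict[str, float]]  # feature -> {control, case}
    community_assignment: dict[str, int]      # feature -> latent factor
    groups: dict[str, str]                    # patient -> control/case
    gestational_ages: dict[str, dict[str, float]]  # patient -> {T1, T2}
    intended_means: pd.DataFrame | None = None  # (patient, timepoint) x feature

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "informative_features": sorted(self.informative_features),
            "true_slopes": self.true_slopes,
            "community_assignment": self.community_assignment,
            "groups": self.groups,
            "gestational_ages": self.gestational_ages,
        }
        path.write_text(json.dumps(payload, indent=1))
        if self.intended_means is not None:
            self.intended_means.to_csv(path.with_suffix(".means.csv"))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        path = Path(path)
        d = json.loads(path.read_text())
        means_path = path.with_suffix(".means.csv")
        means = None
        if means_path.exists():
            means = pd.read_csv(means_path, index_col=[0, 1])
            means.index.names = ["patient", "timepoint"]
        return cls(informative_features=set(d["informative_features"]),
                   true_slopes=d["true_slopes"],
                   community_assignment={k: int(v) for k, v in
                                         d["community_assignment"].items()},
                   groups=d["groups"],
                   gestational_ages=d["gestational_ages"],
                   intended_means=means)


# ---------------------------------------------------------------------------
# internals

def _rng(design: CohortDesign, *stream: int) -> np.random.Generator:
    return np.random.default_rng([design.seed & 0x7FFFFFFF, *stream])


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal(mean, sd) truncated to [lo, hi] by resampling."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _sample_sheet(design: CohortDesign) -> pd.DataFrame:
    rng = _rng(design, 0)
    patients = ([f"C{i + 1:02d}" for i in range(design.n_control)]
                + [f"P{i + 1:02d}" for i in range(design.n_case)])
    groups = ["control"] * design.n_control + ["case"] * design.n_case
    ga1 = _truncated_normal(rng, *design.ga_t1_mean_sd, 8.0, 16.0,
                            design.n_patients)
    ga2 = _truncated_normal(rng, *design.ga_t2_mean_sd, 18.0, 34.0,
                            design.n_patients)
    ga2 = np.maximum(ga2, ga1 + 2.0)  # guarantee GA_T2 > GA_T1
    case = np.asarray([g == "case" for g in groups])
    bmi = rng.normal(26.0, 4.0, design.n_patients) + 2.0 * case
    sheet = pd.DataFrame({
        "patient": patients,
        "group": groups,
        "GA_T1": np.round(ga1, 2),
        "GA_T2": np.round(ga2, 2),
        "BMI": np.round(np.clip(bmi, 16, 55), 1),
        "autoimmune": (rng.random(design.n_patients) < np.where(case, .25, .02)).astype(int),
        "chronic_hypertension": (rng.random(design.n_patients) < np.where(case, .2, .02)).astype(int),
        "type2_diabetes": (rng.random(design.n_patients) < np.where(case, .2, .02)).astype(int),
        "gestational_diabetes": (rng.random(design.n_patients) < .08).astype(int),
    })
    return sheet


def _base_values(design: CohortDesign, features: list[str]) -> np.ndarray:
    base = np.empty(len(features))
    n_ct = len(design.cell_types)
    for j, f in enumerate(features):
        kind = f.split("|", 1)[0]
        if kind == "freq":
            base[j] = 100.0 / n_ct
        elif kind == "basal":
            base[j] = design.basal_mean
        else:
            base[j] = design.stim_response_mean
    return base


def _slopes(design: CohortDesign, features: list[str]):
    idx = {f: j for j, f in enumerate(features)}
    ctrl = np.zeros(len(features))
    case = np.zeros(len(features))
    shift = np.zeros(len(features))
    stim0 = design.stim_conditions[0]
    informative = set()
    for eff in design.planted_effects:
        f = eff.feature(stim0)
        j = idx[f]
        ctrl[j] = eff.control_slope
        case[j] = eff.case_slope
        shift[j] = eff.baseline_shift_case
        if eff.control_slope != eff.case_slope:
            informative.add(f)
    return ctrl, case, shift, informative


def _factor_model(design: CohortDesign, features: list[str]):
    """Per-feature factor index and loading; factor scores per patient."""
    p = len(features)
    if design.n_latent_factors <= 0:
        return np.zeros(p, dtype=int) - 1, np.zeros(p), np.zeros(
            (design.n_patients, 1))
    rng = _rng(design, 1)
    assign = np.arange(p) % design.n_latent_factors
    loadings = rng.normal(0.0, design.factor_loading_sd, size=p)
    scores = rng.normal(0.0, 1.0,
                        size=(design.n_patients, design.n_latent_factors))
    return assign, loadings, scores


def _intended_means(design: CohortDesign, sheet: pd.DataFrame,
                    features: list[str]):
    """Noise-free feature means per (patient, timepoint): base + factor
    contribution + group trend (+ case offset)."""
    base = _base_values(design, features)
    ctrl_s, case_s, shift, informative = _slopes(design, features)
    assign, loadings, scores = _factor_model(design, features)
    ga_ref = design.ga_t1_mean_sd[0]
    rows = {}
    for i, row in sheet.reset_index(drop=True).iterrows():
        is_case = row["group"] == "case"
        slopes = case_s if is_case else ctrl_s
        factor = np.where(assign >= 0, loadings * scores[i, assign], 0.0)
        for tp, ga in (("T1", row["GA_T1"]), ("T2", row["GA_T2"])):
            mu = base + factor + slopes * (ga - ga_ref)
            if is_case:
                mu = mu + shift
            rows[(row["patient"], tp)] = mu
    means = pd.DataFrame.from_dict(rows, orient="index")
    means.columns = features
    means.index = pd.MultiIndex.from_tuples(means.index,
                                            names=["patient", "timepoint"])
    freq_cols = [j for j, f in enumerate(features) if f.startswith("freq|")]
    vals = means.to_numpy()
    vals[:, freq_cols] = np.clip(vals[:, freq_cols], 0.0, 100.0)
    means.iloc[:, :] = vals
    return means, informative, assign


def _truth(design: CohortDesign, sheet: pd.DataFrame, features: list[str],
           informative: set[str], assign: np.ndarray,
           intended: pd.DataFrame | None) -> TruthTable:
    ctrl_s, case_s, _, _ = _slopes(design, features)
    return TruthTable(
        informative_features=informative,
        true_slopes={f: {"control": float(ctrl_s[j]), "case": float(case_s[j])}
                     for j, f in enumerate(features)
                     if ctrl_s[j] != 0 or case_s[j] != 0},
        community_assignment={f: int(assign[j])
                              for j, f in enumerate(features)},
        groups=dict(zip(sheet["patient"], sheet["group"])),
        gestational_ages={r["patient"]: {"T1": float(r["GA_T1"]),
                                         "T2": float(r["GA_T2"])}
                          for _, r in sheet.iterrows()},
        intended_means=intended)


# ---------------------------------------------------------------------------
# public generators

def simulate_feature_matrix(design: CohortDesign
                            ) -> tuple[FeatureMatrix, FeatureMatrix,
                                       pd.DataFrame, TruthTable]:
    """Simulate feature matrices at T1 and T2 directly.

    Each value is the intended mean (latent-factor contribution plus
    group/time trend) plus ``Normal(0, noise_sd)`` noise. Deterministic for
    a fixed seed.
    """
    design.validate()
    sheet = _sample_sheet(design)
    features = design.feature_ids()
    means, informative, assign = _intended_means(design, sheet, features)
    rng = _rng(design, 2)
    noise = rng.normal(0.0, design.noise_sd, size=means.shape) \
        if design.noise_sd > 0 else 0.0
    values = means + noise
    freq_cols = [f for f in features if f.startswith("freq|")]
    values[freq_cols] = values[freq_cols].clip(0.0, 100.0)
    meta = design.panel().feature_metadata()
    truth = _truth(design, sheet, features, informative, assign, means)
    fm_t1 = FeatureMatrix(values.xs("T1", level="timepoint", drop_level=False),
                          meta)
    fm_t2 = FeatureMatrix(values.xs("T2", level="timepoint", drop_level=False),
                          meta)
    return fm_t1, fm_t2, sheet, truth


def simulate_event_tables(design: CohortDesign
                          ) -> tuple[list[EventTable], pd.DataFrame, TruthTable]:
    """Simulate single-cell event tables per (patient, timepoint, condition).

    Cell-type counts follow a Dirichlet-multinomial around the intended
    frequency vector; marker intensities are drawn so arcsinh-transformed
    values are Normal(intended mean, event_sd) on the transformed scale
    (raw = cofactor * sinh(t), negatives clipped to zero).
    """
    design.validate()
    sheet = _sample_sheet(design)
    features = design.feature_ids()
    means, informative, assign = _intended_means(design, sheet, features)
    panel = design.panel()
    markers = list(design.functional_markers)
    cts = list(design.cell_types)
    n_ev = design.events_per_sample
    if n_ev < 20 * len(cts):
        logger.warning("events_per_sample=%d is small for %d subsets; rare "
                       "subsets may be absent from some samples", n_ev, len(cts))

    tables: list[EventTable] = []
    intended_rows = {}
    patient_index = {p: i for i, p in enumerate(sheet["patient"])}
    for _, row in sheet.iterrows():
        patient = row["patient"]
        pi = patient_index[patient]
        for ti, tp in enumerate(("T1", "T2")):
            mu_row = means.loc[(patient, tp)]
            target = np.array([mu_row[feature_id("freq", ct)]
                               for ct in cts]) / 100.0
            target = np.clip(target, 1e-9, None)
            target = target / target.sum()
            rng_p = _rng(design, 3, pi, ti)
            props = rng_p.dirichlet(target * design.dirichlet_concentration)
            adjusted = mu_row.copy()
            for k, ct in enumerate(cts):
                adjusted[feature_id("freq", ct)] = 100.0 * props[k]
            intended_rows[(patient, tp)] = adjusted
            for ci, cond in enumerate(design.conditions):
                rng_s = _rng(design, 3, pi, ti, ci + 1)
                counts = rng_s.multinomial(n_ev, props)
                cols = {"cell_type": np.repeat(cts, counts)}
                for m in markers:
                    t = np.empty(n_ev)
                    pos = 0
                    for k, ct in enumerate(cts):
                        mu = mu_row[feature_id("basal", ct, m)]
                        if cond != design.reference_condition:
                            mu = mu + mu_row[feature_id("stim", ct, m, cond)]
                        t[pos:pos + counts[k]] = rng_s.normal(
                            mu, design.event_sd, size=counts[k])
                        pos += counts[k]
                    cols[m] = np.maximum(
                        design.arcsinh_cofactor * np.sinh(t), 0.0)
                tables.append(EventTable(patient, tp, cond,
                                         pd.DataFrame(cols)))
    intended = pd.DataFrame.from_dict(intended_rows, orient="index")
    intended.index = pd.MultiIndex.from_tuples(intended.index,
                                               names=["patient", "timepoint"])
    truth = _truth(design, sheet, features, informative, assign, intended)
    return tables, sheet, truth


def planted_cohort_design(n_planted: int = 8, delta_over_noise: float = 3.0,
                          noise_sd: float = 0.1, seed: int = 0,
                          **kwargs) -> CohortDesign:
    """Convenience design with ``n_planted`` group-differential stim-response
    features whose slope gap equals ``delta_over_noise`` times the implied
    per-patient rate noise SD (``noise_sd * sqrt(2) / mean GA gap``)."""
    base = CohortDesign(seed=seed, noise_sd=noise_sd, **kwargs)
    dt = base.ga_t2_mean_sd[0] - base.ga_t1_mean_sd[0]
    rate_noise_sd = noise_sd * np.sqrt(2.0) / dt
    delta = delta_over_noise * rate_noise_sd
    stim0 = base.stim_conditions[0]
    combos = [(ct, m) for ct in base.cell_types
              for m in base.functional_markers]
    if n_planted > len(combos):
        raise ConfigurationError("more planted effects than (subset, marker) "
                                 "combinations")
    picks = np.linspace(0, len(combos) - 1, n_planted).astype(int)
    effects = []
    for i, k in enumerate(picks):
        ct, m = combos[k]
        sign = 1.0 if i % 2 == 0 else -1.0
        effects.append(PlantedEffect(cell_type=ct, marker=m, condition=stim0,
                                     category="stim_response",
                                     control_slope=sign * delta / 2.0,
                                     case_slope=-sign * delta / 2.0))
    return CohortDesign(seed=seed, noise_sd=noise_sd,
                        planted_effects=tuple(effects), **kwargs)
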