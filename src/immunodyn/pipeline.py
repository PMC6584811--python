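"""End-to-end orchestration: simulate/load -> extract -> rates -> fit ->
reduce -> network -> univariate, with one seed, structured logging, and a
manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation_network import (build_network, detect_communities,
                                  layout_network)
from .dynamics import compute_rates
from .errors import ConfigurationError, ImmunodynError
from .feature_extraction import (EventTable, FeatureMatrix, PanelConfig,
                                 extract_features)
from .model_reduction import reduce_model
from .predictive_model import repeated_holdout
from .synthetic_data import (CohortDesign, PlantedEffect, TruthTable,
                             planted_cohort_design, simulate_event_tables,
                             simulate_feature_matrix)
from .univariate_stats import (cohort_summary, compare_features,
                               confounder_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run (YAML-loadable)."""

    seed: int
    output_dir: str = "runs/out"
    simulate: dict[str, Any] | None = None     # CohortDesign kwargs (+ n_planted)
    inputs: dict[str, str] | None = None       # events_dir / sample_sheet / ...
    panel: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)
    flags: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigurationError("config must set an integer 'seed'")
        return cls(**raw)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'simulate' or 'inputs' must be configured")
        if self.inputs is not None:
            sheet = self.inputs.get("sample_sheet")
            if not sheet:
                raise ConfigurationError("inputs.sample_sheet is required")
            if not Path(sheet).exists():
                raise ConfigurationError(
                    f"sample sheet not found: {sheet}")
            events_dir = self.inputs.get("events_dir")
            if not events_dir or not Path(events_dir).is_dir():
                raise ConfigurationError(
                    f"inputs.events_dir missing or not a directory: {events_dir}")

    def canonical_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ImmunodynError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise ImmunodynError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _build_design(cfg: RunConfig) -> CohortDesign:
    kwargs = dict(cfg.simulate or {})
    kwargs.setdefault("seed", cfg.seed)
    n_planted = kwargs.pop("n_planted", None)
    effects = kwargs.pop("planted_effects", None)
    if effects:
        kwargs["planted_effects"] = tuple(
            PlantedEffect(**e) for e in effects)
    if n_planted:
        return planted_cohort_design(n_planted=n_planted, **kwargs)
    return CohortDesign(**kwargs)


def _load_events(cfg: RunConfig) -> tuple[list[EventTable], pd.DataFrame]:
    sheet = pd.read_csv(cfg.inputs["sample_sheet"])
    transformed = bool(cfg.inputs.get("transformed", False))
    tables = [EventTable.from_csv(p, transformed=transformed)
              for p in sorted(Path(cfg.inputs["events_dir"]).glob("*.csv"))]
    if not tables:
        raise ConfigurationError(
            f"no event CSVs in {cfg.inputs['events_dir']}")
    return tables, sheet


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write all artifacts under ``config.output_dir``.

    Returns a name -> path map of the written artifacts. Any stage failure
    raises with the stage name; artifacts written so far are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save(name: str, path: Path) -> Path:
        artifacts[name] = path
        return path

    # --- stage: data -------------------------------------------------------
    truth: TruthTable | None = None
    if config.simulate is not None:
        design = _stage("simulate")(_build_design)(config)
        if bool(config.flags.get("event_level", False)):
            tables, sheet, truth = _stage("simulate")(simulate_event_tables)(design)
            panel = PanelConfig(cell_types=design.cell_types,
                                functional_markers=design.functional_markers,
                                conditions=design.conditions,
                                arcsinh_cofactor=design.arcsinh_cofactor,
                                **config.panel)
            fm = _stage("extract")(extract_features)(tables, panel, sheet)
            fm_t1 = FeatureMatrix(fm.values.xs("T1", level="timepoint",
                                               drop_level=False), fm.meta)
            fm_t2 = FeatureMatrix(fm.values.xs("T2", level="timepoint",
                                               drop_level=False), fm.meta)
        else:
            fm_t1, fm_t2, sheet, truth = _stage("simulate")(
                simulate_feature_matrix)(design)
        truth.to_json(save("truth", out / "truth.json"))
    else:
        tables, sheet = _stage("load")(_load_events)(config)
        panel = PanelConfig(**config.panel)
        fm = _stage("extract")(extract_features)(tables, panel, sheet)
        fm_t1 = FeatureMatrix(fm.values.xs("T1", level="timepoint",
                                           drop_level=False), fm.meta)
        fm_t2 = FeatureMatrix(fm.values.xs("T2", level="timepoint",
                                           drop_level=False), fm.meta)

    sheet.to_csv(save("sample_sheet", out / "sample_sheet.csv"), index=False)
    fm_t1.to_csv(save("features_t1", out / "features_t1.csv"))
    fm_t2.to_csv(save("features_t2", out / "features_t2.csv"))

    # --- stage: rates ------------------------------------------------------
    D = _stage("rates")(compute_rates)(fm_t1, fm_t2, sheet)
    D.to_csv(save("rates", out / "rates.csv"))

    # --- stage: fit --------------------------------------------------------
    mp = dict(config.model)
    result = _stage("fit")(repeated_holdout)(
        D, n_test=int(mp.get("n_test", 3)),
        n_iterations=int(mp.get("n_iterations", 100)),
        seed=int(mp.get("seed", config.seed)),
        n_folds=int(mp.get("n_folds", 5)),
        n_lambdas=int(mp.get("n_lambdas", 100)),
        min_ratio=float(mp.get("lambda_min_ratio", 0.01)))
    result.to_json(save("model_result", out / "model_result.json"))
    result.final_predictions.rename("prediction").to_frame().assign(
        label=result.labels.astype(int)).to_csv(
        save("predictions", out / "predictions.csv"))

    # --- stage: reduce -----------------------------------------------------
    profile = _stage("reduce")(reduce_model)(
        result, continuous=bool(config.flags.get("continuous_breakpoint",
                                                 False)))
    profile.to_csv(save("selection_profile", out / "selection_profile.csv"))

    # --- stage: network ----------------------------------------------------
    threshold = float(config.network.get("threshold", 1e-12))
    per_tp = bool(config.network.get("per_timepoint", False))
    stacked = fm_t1.values.copy() if per_tp else pd.concat(
        [fm_t1.values, fm_t2.values])
    net = _stage("network")(build_network)(stacked, threshold=threshold,
                                           min_obs=int(config.network.get(
                                               "min_obs", 10)))
    _stage("network")(detect_communities)(net, seed=config.seed)
    _stage("network")(layout_network)(net, seed=config.seed)
    net.edges_to_csv(save("network_edges", out / "network_edges.csv"))
    net.to_graphml(save("network_graphml", out / "network.graphml"))
    net.communities.rename("community").to_csv(
        save("communities", out / "communities.csv"))
    net.layout.to_csv(save("layout", out / "layout.csv"))

    # --- stage: stats ------------------------------------------------------
    labels = result.labels
    rates_for_stats = D.values.loc[:, profile.top_features] \
        if profile.top_features else D.values.iloc[:, :0]
    uni = _stage("stats")(compare_features)(
        rates_for_stats, labels,
        bh_correction=bool(config.flags.get("bh_correction", False)))
    uni.to_csv(save("univariate", out / "univariate.csv"))
    conf = None
    if set(("BMI", "autoimmune", "chronic_hypertension",
            "type2_diabetes")) <= set(sheet.columns):
        conf = _stage("stats")(confounder_table)(rates_for_stats, D.sheet)
        conf.to_csv(save("confounders", out / "confounders.csv"))
    demo = _stage("stats")(cohort_summary)(sheet)
    demo.to_csv(save("cohort_summary", out / "cohort_summary.csv"))

    # --- report + manifest -------------------------------------------------
    report = _render_report(config, result, profile, net, uni, conf)
    save("report", out / "report.md").write_text(report)
    manifest = {
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "package": {"immunodyn": __version__},
        "libraries": _library_versions(),
        "artifacts": {k: str(v.name) for k, v in artifacts.items()},
    }
    save("manifest", out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return artifacts


def _library_versions() -> dict[str, str]:
    import igraph
    import scipy
    import sklearn
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "igraph": igraph.__version__}


def _render_report(config, result, profile, net, uni, conf) -> str:
    sizes = net.community_sizes()
    lines = [
        "# immunodyn run report",
        "",
        f"- seed: {config.seed}",
        f"- patients: {len(result.patients)} "
        f"({int(result.labels.sum())} case / "
        f"{int(len(result.labels) - result.labels.sum())} control)",
        f"- features: {len(result.feature_names)}",
        "",
        "## Predictive model",
        f"- iterations: {result.n_iterations_total} "
        f"({result.n_iterations} requested)",
        f"- ensemble AUC: {result.auc:.3f}",
        f"- group-difference p-value: {result.p_value:.4g}",
        f"- significant at 0.05: {'yes' if result.p_value < 0.05 else 'NO'}",
        "",
        "## Model reduction",
        f"- breakpoint index: {profile.breakpoint_index}"
        + ("" if profile.abrupt else " (no abrupt shift)"),
        "- top features:",
    ]
    for f in profile.top_features:
        row = profile.table.loc[f]
        auc = row.get("auc")
        auc_s = f", AUC {auc:.2f}" if pd.notna(auc) else ""
        lines.append(f"  - {f} (freq {row['frequency']:.2f}{auc_s})")
    lines += [
        "",
        "## Correlation network",
        f"- nodes: {len(net.nodes)}, edges: {len(net.edges)}",
        f"- communities: {len(sizes)} (modularity {net.modularity:.3f})",
        f"- community sizes: {sizes.to_dict()}",
        "",
        "## Univariate tests (top features)",
    ]
    for f, row in uni.iterrows():
        lines.append(f"  - {f}: {row['test']} p={row['p_value']:.3g}, "
                     f"AUC={row['auc']:.2f}")
    if conf is not None and len(conf):
        lines += ["", "## Confounder regression (top features)"]
        for f, row in conf.iterrows():
            lines.append(f"  - {f}: status p={row['status_p']:.3g}")
    lines.append("")
    return "\n".join(lines)
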