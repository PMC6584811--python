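"""Stability-based model reduction.

Features are ranked by the frequency with which they received a nonzero
coefficient across repeated-holdout iterations; the ranking is cut at the
index where a two-segment least-squares fit of the descending frequency
curve best explains an abrupt shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .predictive_model import ModelResult
from .univariate_stats import roc_auc

logger = logging.getLogger(__name__)


def selection_frequencies(result: ModelResult) -> pd.Series:
    """Fraction of iterations in which each feature had beta != 0."""
    if not result.iterations:
        raise ValidationError("ModelResult holds no iterations")
    freq = result.support_matrix.mean(axis=0)
    return pd.Series(freq, index=result.feature_names, name="frequency")


class Breakpoint(NamedTuple):
    index: int          # size of the leading segment (1-based cut)
    abrupt: bool        # False when no split improves on a single line
    sse_split: float
    sse_single: float


def _segment_sse(y: np.ndarray) -> float:
    """SSE of an OLS line fit to (1..m, y)."""
    m = len(y)
    if m <= 2:
        return 0.0
    x = np.arange(m, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = (xc ** 2).sum()
    slope = (xc * yc).sum() / denom
    resid = yc - slope * xc
    return float((resid ** 2).sum())


def piecewise_breakpoint(sorted_frequencies, min_segment: int = 2) -> Breakpoint:
    """Index k in [2, n-2] minimizing the summed SSE of two independent
    least-squares lines over the leading k and trailing n-k points.

    The input must be sorted in descending order; ties go to the smallest
    k. A relative SSE improvement below 1e-12 flags "no abrupt shift".
    """
    y = np.asarray(sorted_frequencies, dtype=float)
    n = len(y)
    if n < 2 * min_segment:
        raise ValidationError(f"sequence of length {n} too short for a "
                              f"two-segment fit (need >= {2 * min_segment})")
    if np.any(np.diff(y) > 1e-12):
        raise ValidationError("sequence must be sorted in descending order")
    sse_single = _segment_sse(y)
    best_k, best_sse = min_segment, np.inf
    for k in range(min_segment, n - min_segment + 1):
        sse = _segment_sse(y[:k]) + _segment_sse(y[k:])
        if sse < best_sse - 1e-15:
            best_k, best_sse = k, sse
    improvement = (sse_single - best_sse) / max(sse_single, 1e-300)
    abrupt = improvement >= 1e-12
    if not abrupt:
        logger.info("no abrupt shift detected (relative improvement %.2e)",
                    improvement)
    return Breakpoint(best_k, abrupt, float(best_sse), float(sse_single))


def piecewise_breakpoint_continuous(sorted_frequencies,
                                    min_segment: int = 2) -> Breakpoint:
    """Variant constraining the two segments to meet at the breakpoint."""
    y = np.asarray(sorted_frequencies, dtype=float)
    n = len(y)
    if n < 2 * min_segment:
        raise ValidationError("sequence too short")
    x = np.arange(n, dtype=float)
    sse_single = _segment_sse(y)
    best_k, best_sse = min_segment, np.inf
    for k in range(min_segment, n - min_segment + 1):
        # basis: 1, x, hinge max(x - (k-1), 0)
        X = np.column_stack([np.ones(n), x, np.maximum(x - (k - 1), 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ coef) ** 2).sum())
        if sse < best_sse - 1e-15:
            best_k, best_sse = k, sse
    improvement = (sse_single - best_sse) / max(sse_single, 1e-300)
    return Breakpoint(best_k, improvement >= 1e-12, float(best_sse),
                      float(sse_single))


@dataclass
class SelectionProfile:
    """Ranked selection frequencies with the breakpoint-defined top set."""

    table: pd.DataFrame          # feature, frequency, mean_abs_coef, rank, in_top_set, auc
    breakpoint_index: int
    abrupt: bool
    top_features: list[str]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def reduce_model(result: ModelResult, continuous: bool = False
                 ) -> SelectionProfile:
    """Rank features by selection frequency (ties: mean |beta|, then ID),
    cut at the piecewise breakpoint, and annotate per-feature univariate
    AUC of the rates when available."""
    freq = selection_frequencies(result)
    if (freq == 0).all():
        raise ValidationError("null model; nothing to reduce")
    mean_abs = pd.Series(np.abs(result.coef_matrix).mean(axis=0),
                         index=result.feature_names, name="mean_abs_coef")
    table = pd.concat([freq, mean_abs], axis=1)
    table = table.sort_values(["frequency", "mean_abs_coef"],
                              ascending=[False, False],
                              kind="mergesort")
    # stable mergesort on a pre-sorted-by-ID frame gives the lexical tiebreak
    table = table.loc[sorted(table.index)].sort_values(
        ["frequency", "mean_abs_coef"], ascending=[False, False],
        kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)

    bp_fn = piecewise_breakpoint_continuous if continuous \
        else piecewise_breakpoint
    bp = bp_fn(table["frequency"].to_numpy())
    top = list(table.index[:bp.index])
    table["in_top_set"] = table["rank"] <= bp.index

    if result.rates is not None:
        aucs = {}
        for f in top:
            vals = result.rates[f].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if len(np.unique(result.labels[ok])) == 2 and np.ptp(vals[ok]) > 0:
                aucs[f] = roc_auc(vals[ok], result.labels[ok])
        table["auc"] = pd.Series(aucs).reindex(table.index)

    table.index.name = "feature"
    return SelectionProfile(table=table, breakpoint_index=bp.index,
                            abrupt=bp.abrupt, top_features=top)
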