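"""Feature-feature Spearman correlation network with Louvain communities.

Edges connect feature pairs whose Spearman correlation is significant at a
very stringent threshold (default p < 1e-12, two-sided t approximation);
edge weight is -log10(p) clamped at 300. Communities come from multi-level
(Louvain) modularity optimization; a t-SNE embedding of the edge-derived
dissimilarities provides a purely cosmetic 2-D layout.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .feature_extraction import FeatureMatrix

logger = logging.getLogger(__name__)

MAX_NEGLOG10P = 300.0


def _snap(rho: float) -> float:
    """Clamp floating-point drift so perfect rank agreement is exact."""
    if rho > 1.0 - 1e-12:
        return 1.0
    if rho < -1.0 + 1e-12:
        return -1.0
    return rho


def _spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p via the t approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_edges(fm, threshold: float = 1e-12,
                   min_obs: int = 10) -> pd.DataFrame:
    """Significant Spearman edges between all unordered feature pairs.

    ``fm`` is a FeatureMatrix (samples pooled over time points) or plain
    DataFrame. Pairs are evaluated on pairwise-complete observations;
    constant features are skipped with a log message. Returns columns
    source, target, rho, p, weight (weight = -log10 p, clamped).
    """
    df = fm.stacked() if isinstance(fm, FeatureMatrix) else fm
    X = df.to_numpy(dtype=float)
    cols = list(df.columns)
    n, p = X.shape
    if n < min_obs:
        raise ValidationError(
            f"need >= {min_obs} observations per pair, have {n}")

    rows = []
    has_nan = np.isnan(X).any()
    if not has_nan:
        sds = X.std(axis=0)
        constant = sds == 0
        if constant.any():
            logger.info("skipping %d constant features", int(constant.sum()))
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        ranks = (ranks - ranks.mean(axis=0))
        norms = np.sqrt((ranks ** 2).sum(axis=0))
        norms[norms == 0] = np.nan
        C = (ranks.T @ ranks) / np.outer(norms, norms)
        C = np.clip(C, -1.0, 1.0)
        iu, ju = np.triu_indices(p, k=1)
        for i, j in zip(iu, ju):
            if constant[i] or constant[j]:
                continue
            rho = _snap(float(C[i, j]))
            pv = _spearman_pvalue(rho, n)
            if pv < threshold:
                rows.append((cols[i], cols[j], rho, pv,
                             min(-np.log10(max(pv, 1e-300)), MAX_NEGLOG10P)
                             if pv > 0 else MAX_NEGLOG10P))
    else:
        for i in range(p):
            for j in range(i + 1, p):
                ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
                if ok.sum() < min_obs:
                    continue
                xi, xj = X[ok, i], X[ok, j]
                if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                    continue
                rho = _snap(float(stats.spearmanr(xi, xj).statistic))
                pv = _spearman_pvalue(rho, int(ok.sum()))
                if pv < threshold:
                    rows.append((cols[i], cols[j], rho, pv,
                                 min(-np.log10(max(pv, 1e-300)),
                                     MAX_NEGLOG10P) if pv > 0
                                 else MAX_NEGLOG10P))
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p",
                                        "weight"])
    logger.info("retained %d edges at p < %g over %d features",
                len(edges), threshold, p)
    return edges


@dataclass
class CorrelationNetwork:
    """Feature nodes, significant Spearman edges, communities, layout."""

    nodes: list[str]
    edges: pd.DataFrame
    meta: pd.DataFrame | None = None
    communities: pd.Series | None = None      # node -> community index
    modularity: float | None = None
    layout: pd.DataFrame | None = None        # node -> (x, y)

    def graph(self) -> ig.Graph:
        g = ig.Graph()
        g.add_vertices(self.nodes)
        if len(self.edges):
            g.add_edges(list(zip(self.edges["source"], self.edges["target"])))
            g.es["weight"] = self.edges["weight"].tolist()
            g.es["rho"] = self.edges["rho"].tolist()
            g.es["p"] = self.edges["p"].tolist()
        return g

    def community_sizes(self) -> pd.Series:
        if self.communities is None:
            raise ValidationError("communities not computed yet")
        return self.communities.value_counts().sort_index()

    def to_graphml(self, path: str | Path) -> None:
        g = self.graph()
        if self.communities is not None:
            g.vs["community"] = [int(self.communities[v]) for v in self.nodes]
        if self.layout is not None:
            g.vs["x"] = [float(self.layout.at[v, "x"]) for v in self.nodes]
            g.vs["y"] = [float(self.layout.at[v, "y"]) for v in self.nodes]
        g.write_graphml(str(path))

    def edges_to_csv(self, path: str | Path) -> None:
        self.edges.to_csv(path, index=False)


def build_network(fm, threshold: float = 1e-12,
                  min_obs: int = 10) -> CorrelationNetwork:
    df = fm.stacked() if isinstance(fm, FeatureMatrix) else fm
    edges = spearman_edges(df, threshold=threshold, min_obs=min_obs)
    meta = fm.meta if isinstance(fm, FeatureMatrix) else None
    return CorrelationNetwork(nodes=list(df.columns), edges=edges, meta=meta)


def detect_communities(net: CorrelationNetwork, seed: int = 0,
                       restarts: int = 10) -> pd.Series:
    """Louvain multi-level modularity optimization on -log10(p) weights;
    best partition over ``restarts`` seeded runs. Isolated nodes each get
    their own community."""
    g = net.graph()
    if g.ecount() == 0:
        logger.warning("empty edge set; every node is its own community")
        labels = pd.Series(range(len(net.nodes)), index=net.nodes,
                           name="community")
        net.communities, net.modularity = labels, 0.0
        return labels
    best, best_q = None, -np.inf
    for r in range(max(1, restarts)):
        ig.set_random_number_generator(random.Random(seed + r))
        part = g.community_multilevel(weights="weight")
        q = g.modularity(part.membership, weights="weight")
        if q > best_q:
            best, best_q = part.membership, q
    labels = pd.Series(best, index=net.nodes, name="community")
    net.communities, net.modularity = labels, float(best_q)
    logger.info("found %d communities (modularity %.3f)",
                labels.nunique(), best_q)
    return labels


def layout_network(net: CorrelationNetwork, seed: int = 0,
                   perplexity: float | None = None) -> pd.DataFrame:
    """Cosmetic 2-D t-SNE embedding of edge-derived dissimilarities
    (1/(1+weight) for connected pairs, 1.0 otherwise)."""
    n = len(net.nodes)
    if n < 3:
        logger.warning("fewer than 3 nodes; trivial layout")
        coords = pd.DataFrame({"x": np.arange(n, dtype=float),
                               "y": np.zeros(n)}, index=net.nodes)
        net.layout = coords
        return coords
    from sklearn.manifold import TSNE

    idx = {v: i for i, v in enumerate(net.nodes)}
    D = np.ones((n, n))
    np.fill_diagonal(D, 0.0)
    for _, e in net.edges.iterrows():
        i, j = idx[e["source"]], idx[e["target"]]
        D[i, j] = D[j, i] = 1.0 / (1.0 + e["weight"])
    # tiny symmetric jitter: exact distance ties destabilize t-SNE
    rng = np.random.default_rng(seed)
    jit = rng.uniform(0.0, 1e-3 * D.max(), size=D.shape)
    D = D + (jit + jit.T) / 2.0
    np.fill_diagonal(D, 0.0)
    perplexity = perplexity or min(30.0, max(2.0, (n - 2) / 3.0))
    ts = TSNE(n_components=2, metric="precomputed", init="random",
              random_state=seed, perplexity=perplexity)
    xy = ts.fit_transform(D)
    coords = pd.DataFrame(xy, columns=["x", "y"], index=net.nodes)
    net.layout = coords
    return coords
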