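"""Co-activation networks from posterior region-intensity samples.

Regions co-activate when their per-iteration mean intensities correlate
across retained MCMC states.  Correlations are thresholded by a
max-statistic permutation test (family-wise error control), turned into
weighted graphs with edge distance 2 - r, and summarized by betweenness
centrality, grouped global efficiency, and a force-directed layout.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np

from .intensity import IntensityMatrix

log = logging.getLogger("metafoci")


def coactivation_matrix(matrix: IntensityMatrix | np.ndarray) -> np.ndarray:
    """R x R Pearson correlations of region intensities across iterations.

    Constant columns have undefined correlations: their rows/columns are
    NaN (warned), diagonal forced to 1.
    """
    m = matrix.values if isinstance(matrix, IntensityMatrix) else np.asarray(matrix)
    if m.shape[0] < 3:
        raise ValueError("need at least 3 iterations for correlations")
    sd = m.std(axis=0)
    const = sd == 0
    if const.any():
        log.warning("%d constant region columns: correlations undefined", const.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m, rowvar=False)
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def permutation_threshold(
    matrix: IntensityMatrix | np.ndarray,
    n_perm: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> float:
    """Max-statistic permutation threshold r* for the correlation matrix.

    Each replicate permutes the rows of every column independently
    (destroying all cross-region dependence while preserving marginals),
    records the maximum off-diagonal correlation, and r* is the given
    percentile (default 95th over 1000 replicates) of those maxima —
    controlling matrix-wise false positives at the matching FWER.
    """
    m = matrix.values if isinstance(matrix, IntensityMatrix) else np.asarray(matrix)
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    t, r = m.shape
    rng = np.random.default_rng(seed)
    mask_off = ~np.eye(r, dtype=bool)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        order = np.argsort(rng.random((t, r)), axis=0)
        perm = np.take_along_axis(m, order, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(perm, rowvar=False)
        maxima[p] = np.nanmax(c[mask_off])
    return float(np.percentile(maxima, percentile))


def apply_common_threshold(matrices: dict, thresholds: dict) -> tuple:
    """Threshold all categories' matrices at the most stringent threshold.

    The maximum of the per-category thresholds is applied everywhere so
    graphs stay comparable; sub-threshold entries are zeroed (no edge).
    Returns (thresholded matrices, common threshold).
    """
    common = max(thresholds[c] for c in matrices)
    out = {}
    for c, m in matrices.items():
        thr = np.array(m, dtype=float, copy=True)
        off = ~np.eye(thr.shape[0], dtype=bool)
        keep = np.zeros_like(thr, dtype=bool)
        keep[off] = thr[off] > common
        thr[off & ~keep] = 0.0
        out[c] = thr
    return out, float(common)


def coactivation_graph(
    corr: np.ndarray,
    names: list,
    groups: dict | None = None,
    threshold: float | None = None,
    absolute: bool = False,
) -> nx.Graph:
    """Weighted graph with supra-threshold correlations as edges.

    Edge attributes: ``weight`` = r and ``distance`` = 2 - r (in (1, 3)
    for r in (-1, 1)).  By default only positive supra-threshold
    correlations become edges; ``absolute=True`` admits |r| > threshold.
    """
    corr = np.asarray(corr, dtype=float)
    g = nx.Graph()
    for i, name in enumerate(names):
        g.add_node(name, group=(groups or {}).get(name, "all"))
    thr = -np.inf if threshold is None else threshold
    for i, j in itertools.combinations(range(len(names)), 2):
        r = corr[i, j]
        if not np.isfinite(r):
            continue
        val = abs(r) if absolute else r
        if val > thr:
            g.add_edge(names[i], names[j], weight=float(r), distance=float(2.0 - r))
    return g


def betweenness(graph: nx.Graph) -> dict:
    """Weighted-shortest-path betweenness centrality per node.

    Distances are the 2 - r edge attribute; values normalized by
    (N-1)(N-2)/2 (the networkx convention for undirected graphs).
    """
    return nx.betweenness_centrality(graph, weight="distance", normalized=True)


def connectors(bc: dict, percentile: float = 90.0) -> list:
    """Nodes above the given betweenness percentile ('connector' regions)."""
    vals = np.array(list(bc.values()))
    cut = np.percentile(vals, percentile)
    return sorted(n for n, v in bc.items() if v > cut)


def global_efficiency(graph: nx.Graph, group_a, group_b) -> float:
    """Average inverse shortest-path length between two node groups.

    Path lengths use the 2 - r edge distances over significant edges
    only; unreachable pairs contribute 0.  Within-group (group_a is
    group_b) averages over unordered pairs; between groups over all
    cross pairs.  Because every edge distance exceeds 1, the value lies
    in [0, 1]: 0 for disjoint systems, 1 when every pair is directly
    connected at r = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("node groups must be nonempty")
    same = set(group_a) == set(group_b)
    if same:
        pairs = list(itertools.combinations(sorted(group_a), 2))
    else:
        pairs = [(a, b) for a in group_a for b in group_b if a != b]
    if not pairs:
        return float("nan")
    lengths = {}
    for a in {p[0] for p in pairs}:
        lengths[a] = nx.single_source_dijkstra_path_length(graph, a, weight="distance")
    inv = [1.0 / lengths[a][b] if b in lengths[a] and lengths[a][b] > 0 else 0.0
           for a, b in pairs]
    return float(np.mean(inv))


def efficiency_table(graph: nx.Graph) -> "pd.DataFrame":
    """Group x group global-efficiency matrix (diagonal = within-group)."""
    import pandas as pd

    members = {}
    for n, d in graph.nodes(data=True):
        members.setdefault(d.get("group", "all"), []).append(n)
    names = sorted(members)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b and len(members[a]) < 2:
                continue
            val = global_efficiency(graph, members[a], members[b])
            out.loc[a, b] = out.loc[b, a] = val
    return out


def fr_layout(graph: nx.Graph, seed: int = 0, iterations: int = 100) -> dict:
    """Fruchterman–Reingold force-directed 2-D layout (seeded).

    Attractive forces follow the correlation edge weights.  A single
    node sits at the origin.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("layout needs at least one node")
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): np.zeros(2)}
    pos = nx.spring_layout(graph, seed=seed, weight="weight", iterations=iterations)
    return {n: np.asarray(p, dtype=float) for n, p in pos.items()}
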