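"""Sample-proportionality networks and shared-OTU connectivity metrics.

Samples whose CLR profiles are nearly proportional (symmetric phi statistic
below a threshold, 0.15 by default) are linked with edge weight ``1 - phi``;
the resulting weighted undirected graph is summarized by Louvain modularity
and the mean local clustering coefficient.  Connectivity is additionally
quantified as the proportion of OTUs shared among samples within a water
layer (horizontal) or within a site's vertical profile (vertical).
"""

from __future__ import annotations

import dataclasses
import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import OtuTable, SampleFrame


def phi_matrix(clr_matrix: pd.DataFrame, symmetric: bool = True) -> pd.DataFrame:
    """Proportionality statistic between all sample pairs of a CLR matrix.

    The symmetric variant is ``phi_s(x, y) = var(x - y) / var(x + y)`` with
    variances taken across OTUs; 0 means perfectly proportional samples.  The
    asymmetric Lovell variant ``var(x - y) / var(x)`` is available with
    ``symmetric=False`` (then the matrix is not symmetric).  Pairs whose
    denominator is zero are undefined and returned as NaN.
    """
    x = clr_matrix.to_numpy()
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = np.var(x[i] - x[j])
            den = np.var(x[i] + x[j]) if symmetric else np.var(x[i])
            out[i, j] = num / den if den > 0 else np.nan
    return pd.DataFrame(out, index=clr_matrix.index, columns=clr_matrix.index)


def build_network(
    phi: pd.DataFrame,
    meta: SampleFrame | None = None,
    threshold: float = 0.15,
) -> nx.Graph:
    """Undirected sample network: edge iff phi < threshold, weight ``1 - phi``.

    Isolated samples remain as nodes.  NaN phi values (undefined pairs) never
    produce an edge.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    ids = list(phi.index)
    for s in ids:
        attrs = {}
        if meta is not None and s in meta.meta.index:
            row = meta.meta.loc[s]
            attrs = {
                "site": str(row["site"]),
                "layer": str(row["layer"]),
                "depth": float(row["depth"]),
            }
        g.add_node(s, **attrs)
    vals = phi.to_numpy()
    for a, b in itertools.combinations(range(len(ids)), 2):
        v = vals[a, b]
        if np.isfinite(v) and v < threshold:
            g.add_edge(ids[a], ids[b], phi=float(v), weight=float(1.0 - v))
    return g


@dataclasses.dataclass
class ModularityResult:
    q: float | None  # None when the network has no edges
    partition: dict[str, int]
    seed: int


def modularity(network: nx.Graph, seed: int = 0, resolution: float = 1.0) -> ModularityResult:
    """Weighted Newman modularity of the best Louvain partition.

    Deterministic for a given seed.  An edgeless network has no defined
    modularity; ``q`` is None and every node sits in its own community.
    """
    if network.number_of_edges() == 0:
        part = {n: i for i, n in enumerate(sorted(network.nodes))}
        return ModularityResult(q=None, partition=part, seed=seed)
    comms = nx.community.louvain_communities(
        network, weight="weight", resolution=resolution, seed=seed
    )
    q = nx.community.modularity(network, comms, weight="weight", resolution=resolution)
    part = {}
    for i, c in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in c:
            part[node] = i
    return ModularityResult(q=float(q), partition=part, seed=seed)


def mean_clustering_coefficient(network: nx.Graph) -> float:
    """Unweighted local clustering coefficient averaged over all nodes.

    Nodes of degree < 2 contribute 0 (the common graph-tool convention); an
    empty graph returns 0.
    """
    if network.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(network, count_zeros=True))


# ---------------------------------------------------------------------------
# shared-OTU connectivity

SHARING_MODES = ("at_least_2", "all", "mean_pairwise_jaccard")


def _shared_fraction(presence: np.ndarray, mode: str) -> float:
    """Sharing percentage for one group's samples × OTUs presence block."""
    occ = presence.sum(axis=0)
    union = occ >= 1
    if union.sum() == 0:
        return float("nan")
    if mode == "at_least_2":
        return 100.0 * (occ >= 2).sum() / union.sum()
    if mode == "all":
        return 100.0 * (occ == presence.shape[0]).sum() / union.sum()
    if mode == "mean_pairwise_jaccard":
        n = presence.shape[0]
        vals = []
        for a, b in itertools.combinations(range(n), 2):
            u = np.logical_or(presence[a], presence[b]).sum()
            i = np.logical_and(presence[a], presence[b]).sum()
            vals.append(i / u if u else np.nan)
        return 100.0 * float(np.nanmean(vals))
    raise ValueError(f"unknown sharing mode {mode!r}")


def shared_otu_horizontal(
    table: OtuTable,
    groups: pd.Series,
    modes: tuple[str, ...] = SHARING_MODES,
) -> pd.DataFrame:
    """Percentage of OTUs shared among samples within each water layer.

    Modes: ``at_least_2`` (OTUs present in ≥2 of the layer's samples over
    OTUs present in ≥1; the default headline number), ``all`` (strict
    intersection over union), ``mean_pairwise_jaccard``.  Layers with a
    single sample are skipped (recorded as NaN rows).
    """
    groups = groups.reindex(table.sample_ids)
    pres = table.presence().to_numpy()
    rows = []
    for layer in pd.unique(groups.dropna()):
        idx = np.flatnonzero((groups == layer).to_numpy())
        row: dict = {"group": layer, "n_samples": len(idx)}
        if len(idx) < 2:
            row.update({m: float("nan") for m in modes})
        else:
            block = pres[idx]
            row.update({m: _shared_fraction(block, m) for m in modes})
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def shared_otu_vertical(
    table: OtuTable,
    meta: SampleFrame,
    depth_window: tuple[float | None, float | None] = (None, None),
    modes: tuple[str, ...] = SHARING_MODES,
) -> pd.DataFrame:
    """Percentage of OTUs shared between samples of each site's vertical profile.

    ``depth_window = (lo, hi)`` keeps samples with lo ≤ depth ≤ hi (inclusive
    bounds; None leaves a side open), e.g. ``(None, 1000)`` for "at and above
    1,000 m" or ``(2000, None)`` for "at and below 2,000 m".
    """
    meta = meta.aligned_to(table)
    depth = meta.meta["depth"]
    lo, hi = depth_window
    keep = pd.Series(True, index=depth.index)
    if lo is not None:
        keep &= depth >= lo
    if hi is not None:
        keep &= depth <= hi
    sites = meta.meta["site"]
    pres = table.presence().to_numpy()
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    for site in pd.unique(sites):
        members = [s for s in table.sample_ids if sites[s] == site and keep[s]]
        row: dict = {"group": site, "n_samples": len(members)}
        if len(members) < 2:
            row.update({m: float("nan") for m in modes})
        else:
            block = pres[[pos[s] for s in members]]
            row.update({m: _shared_fraction(block, m) for m in modes})
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
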