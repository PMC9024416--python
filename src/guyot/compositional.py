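"""Compositional beta diversity: zero replacement, CLR, Aitchison distance,
hierarchical clustering gated by SIMPROF.

Count data are compositions: only relative information is meaningful, so the
analysis path is count-zero-multiplicative replacement of zeros → centered
log-ratio (CLR) transform → Euclidean distance between CLR rows (the Aitchison
distance) → agglomerative clustering, with group structure validated by the
similarity-profile (SIMPROF) permutation test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.stats.composition import clr as _skbio_clr

from .data_io import OtuTable, ValidationError


class GroupingError(ValueError):
    pass


def replace_zeros(
    table: OtuTable | pd.DataFrame, delta_frac: float = 0.65
) -> pd.DataFrame:
    """Count-zero-multiplicative replacement.

    Each zero in a sample becomes ``delta = delta_frac / total`` on the
    proportion scale (65% of the detection limit ``1/total`` by default); the
    non-zero proportions are multiplicatively shrunk by ``1 - n_zeros*delta``
    so each row remains a composition summing to one.  All outputs are
    strictly positive proportions.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    x = counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("negative entries")
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError("all-zero row")
    props = x / totals[:, None]
    zeros = props == 0
    delta = (delta_frac / totals)[:, None]  # per-sample pseudo-proportion
    adj = 1.0 - zeros.sum(axis=1)[:, None] * delta
    out = np.where(zeros, delta, props * adj)
    if np.any(out <= 0):
        raise ValidationError(
            "zero replacement produced non-positive values; too many zeros for delta"
        )
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def clr_transform(positive: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform: ln(x_ij / geometric mean of row i).

    Rows of the result sum to zero; the transform is invariant to per-row
    scaling, so proportions and raw positive counts give the same answer.
    """
    x = positive.to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("CLR requires strictly positive entries; replace zeros first")
    return pd.DataFrame(_skbio_clr(x), index=positive.index, columns=positive.columns)


def aitchison_distance(clr_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between CLR rows, labeled by sample id."""
    d = squareform(pdist(clr_matrix.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=clr_matrix.index, columns=clr_matrix.index)


# ---------------------------------------------------------------------------
# SIMPROF


@dataclasses.dataclass
class SimprofResult:
    pi: float
    p_value: float
    n_perm: int
    warning: str | None = None


def simprof(
    clr_group: pd.DataFrame,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SimprofResult:
    """Similarity-profile permutation test for structure within one group.

    The observed profile is the sorted vector of pairwise Aitchison distances
    among the group's samples.  Null profiles come from independently
    permuting each OTU column across the group's samples (destroying any
    sample-level structure while preserving each OTU's marginal
    distribution).  The statistic is ``pi = sum |profile - mean null
    profile|``; the p-value is the fraction of permuted pi at least as large
    as the observed pi.  Following Clarke's original scheme, one set of
    ``n_perm`` permutations builds the mean profile and an independent second
    set supplies the null pi distribution, so no profile is compared against
    a mean containing itself (which would bias the test anticonservative).
    """
    n = clr_group.shape[0]
    if n == 2:
        # profile has a single distance; no structure is testable
        return SimprofResult(pi=0.0, p_value=1.0, n_perm=0, warning="group of 2")
    if n < 2:
        raise GroupingError("SIMPROF needs at least 2 samples")
    warning = None
    if n_perm < 100:
        warning = f"n_perm={n_perm} < 100; p-value resolution is poor"

    rng = np.random.default_rng(seed)
    x = clr_group.to_numpy()
    obs = np.sort(pdist(x))

    def null_profile():
        xp = np.empty_like(x)
        for j in range(x.shape[1]):
            xp[:, j] = x[rng.permutation(n), j]
        return np.sort(pdist(xp))

    mean_null = np.mean([null_profile() for _ in range(n_perm)], axis=0)
    pi_obs = float(np.abs(obs - mean_null).sum())
    pi_perm = np.array(
        [np.abs(null_profile() - mean_null).sum() for _ in range(n_perm)]
    )
    p = float(np.mean(pi_perm >= pi_obs))
    return SimprofResult(pi=pi_obs, p_value=p, n_perm=n_perm, warning=warning)


# ---------------------------------------------------------------------------
# clustering


@dataclasses.dataclass
class ClusterResult:
    linkage_matrix: np.ndarray  # scipy hierarchy format
    sample_ids: list[str]
    groups: pd.Series  # flat SIMPROF-gated group label per sample
    simprof_tests: list[dict]  # node id, n, pi, p, split?


def _node_leaves(node) -> list[int]:
    return node.pre_order(lambda leaf: leaf.id)


def cluster_samples(
    dist: pd.DataFrame,
    clr_matrix: pd.DataFrame | None = None,
    linkage: str = "ward",
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering of samples with SIMPROF-gated flat groups.

    The dendrogram is cut top-down: starting at the root, each node's sample
    set is tested with SIMPROF; a significant profile (p < alpha) splits the
    node and recurses into its children, otherwise the node's samples form one
    flat group.  Without a CLR matrix no SIMPROF gating is possible and every
    sample ends in a single group only if the root test cannot run.
    """
    ids = list(dist.index)
    if len(ids) < 2:
        raise GroupingError("need at least 2 samples to cluster")
    condensed = squareform(dist.to_numpy(), checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    root, _ = hierarchy.to_tree(z, rd=True)

    labels = pd.Series(index=pd.Index(ids), dtype=object)
    tests: list[dict] = []
    counter = {"next": 1}
    rng = np.random.default_rng(seed)

    def assign(node) -> None:
        leaves = _node_leaves(node)
        members = [ids[i] for i in leaves]
        if node.is_leaf() or len(members) < 3 or clr_matrix is None:
            _flat(node, members)
            return
        res = simprof(
            clr_matrix.loc[members],
            n_perm=n_perm,
            alpha=alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        split = res.p_value < alpha
        tests.append(
            {
                "node": int(node.id),
                "n": len(members),
                "pi": res.pi,
                "p_value": res.p_value,
                "split": bool(split),
            }
        )
        if split:
            assign(node.get_left())
            assign(node.get_right())
        else:
            _flat(node, members)

    def _flat(node, members: list[str]) -> None:
        g = f"G{counter['next']:02d}"
        counter["next"] += 1
        labels.loc[members] = g

    assign(root)
    return ClusterResult(linkage_matrix=z, sample_ids=ids, groups=labels, simprof_tests=tests)
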