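"""Null-model partitioning of community assembly into selection, dispersal,
and drift.

Two complementary null models classify every pair of communities:

* the phylogenetic stage compares the observed abundance-weighted beta mean
  nearest taxon distance (betaMNTD) against a tip-shuffling null; its z-score
  (betaNTI) beyond ±2 indicates selection — heterogeneous (variable) when
  communities are more phylogenetically distinct than chance (betaNTI > 2),
  homogeneous when less (betaNTI < −2);
* pairs without a selection signal go to the taxonomic stage: the Raup–Crick
  statistic (beta_RC) compares the observed shared-OTU count against a
  richness-preserving, occupancy-weighted null; beta_RC > 0.95 indicates
  dispersal limitation (plus drift), beta_RC < −0.95 homogeneous dispersal,
  and |beta_RC| ≤ 0.95 drift alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_io import CoverageError, OtuTable, PhyloTree, ValidationError

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogeneous_dispersal",
    "drift",
)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def beta_mntd_pair(
    abund_a: pd.Series, abund_b: pd.Series, d: pd.DataFrame
) -> float:
    """Abundance-weighted beta mean nearest taxon distance for one pair.

    ``0.5 * [ sum_i f_iA * min_{j in B} d_ij + sum_j f_jB * min_{i in A} d_ij ]``
    where f is the within-sample relative abundance and the minimum runs over
    OTUs present in the other sample (a shared OTU finds itself at distance
    zero).  Reference implementation; :func:`beta_mntd_matrix` is the
    vectorized all-pairs version.
    """
    a = abund_a[abund_a > 0]
    b = abund_b[abund_b > 0]
    if a.empty or b.empty:
        raise ValidationError("both samples need at least one OTU present")
    missing = (set(a.index) | set(b.index)) - set(d.index)
    if missing:
        raise CoverageError(f"OTUs missing from distance matrix: {sorted(missing)[:10]}")
    fa = a / a.sum()
    fb = b / b.sum()
    d_ab = d.loc[list(a.index), list(b.index)].to_numpy()
    term_a = float(np.dot(fa.to_numpy(), d_ab.min(axis=1)))
    term_b = float(np.dot(fb.to_numpy(), d_ab.min(axis=0)))
    return 0.5 * (term_a + term_b)


def _bmntd_all_pairs(freq: np.ndarray, pres: np.ndarray, d: np.ndarray) -> np.ndarray:
    """All-pairs betaMNTD.

    ``M[b, i] = min over OTUs j present in sample b of d[i, j]`` makes the
    pair sum a single matrix product: ``G = freq @ M.T`` has
    ``G[a, b] = sum_i f_ia * min_{j in b} d_ij``, and betaMNTD = (G + G.T)/2.
    """
    n_samples, n_otus = freq.shape
    m = np.empty((n_samples, n_otus))
    for b in range(n_samples):
        m[b] = d[:, pres[b]].min(axis=1)
    g = freq @ m.T
    return 0.5 * (g + g.T)


@dataclasses.dataclass
class BntiResult:
    bnti: pd.DataFrame  # symmetric, NaN where undefined
    bmntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    n_null: int
    seed: int


def bnti(
    table: OtuTable,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
) -> BntiResult:
    """betaNTI matrix: z-score of observed betaMNTD against a taxa-shuffle null.

    The null randomizes the association between OTU identities and tips by
    permuting the labels of the patristic matrix; one shuffle per replicate is
    shared across all sample pairs.  Pairs with zero null standard deviation
    (degenerate trees) are NaN.
    """
    table = table.drop_empty_otus()
    d_df = tree.patristic_matrix(table.otu_ids)
    d = d_df.to_numpy()
    freq = table.relative_abundance().to_numpy()
    pres = freq > 0

    obs = _bmntd_all_pairs(freq, pres, d)

    rng = np.random.default_rng(seed)
    n_samples = table.n_samples
    acc = np.zeros((n_samples, n_samples))
    acc2 = np.zeros((n_samples, n_samples))
    n_otus = table.n_otus
    for _ in range(n_null):
        perm = rng.permutation(n_otus)
        # relabeling tips on d == permuting the OTU axis of the communities
        null = _bmntd_all_pairs(freq[:, perm], pres[:, perm], d)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = acc2 / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / sd, np.nan)
    np.fill_diagonal(z, 0.0)

    ids = table.sample_ids
    wrap = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return BntiResult(
        bnti=wrap(z),
        bmntd_obs=wrap(obs),
        null_mean=wrap(mean),
        null_sd=wrap(sd),
        n_null=n_null,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Raup–Crick


def _weighted_subset(rng, keys_shape, weights, sizes):
    """Null presence matrix: per sample, a weighted draw without replacement.

    Efraimidis–Spirakis exponential race: the ``n`` smallest ``Exp(1)/w``
    keys are a weighted sample without replacement, matching sequential
    probability-proportional-to-weight draws.
    """
    n_samples, n_otus = keys_shape
    keys = rng.exponential(size=keys_shape) / weights[None, :]
    order = np.argsort(keys, axis=1)
    pres = np.zeros(keys_shape, dtype=bool)
    for s in range(n_samples):
        pres[s, order[s, : sizes[s]]] = True
    return pres


@dataclasses.dataclass
class RaupCrickResult:
    brc: pd.DataFrame  # symmetric in [-1, 1]
    shared_obs: pd.DataFrame
    n_null: int
    seed: int
    weighting: str


def raup_crick(
    table: OtuTable,
    n_null: int = 9999,
    seed: int = 0,
    weighting: str = "occupancy",
) -> RaupCrickResult:
    """Raup–Crick beta_RC matrix from occurrence (presence/absence) data.

    For a pair with richnesses ``n_A`` and ``n_B``, each null replicate draws
    ``n_A`` and ``n_B`` OTUs from the regional pool without replacement with
    probability proportional to occupancy frequency across all samples
    (``weighting="occupancy"``; ``"equal"`` and ``"abundance"`` are options)
    and counts the shared OTUs.  With ``p = [#(SS_null > SS_obs) +
    0.5·#(SS_null = SS_obs)] / n_null``, ``beta_RC = 2(p − 0.5)`` lies in
    [−1, 1]; positive values mean the pair shares fewer OTUs than the null
    expects.
    """
    table = table.drop_empty_otus()
    pres = table.presence().to_numpy()
    n_samples, n_pool = pres.shape
    sizes = pres.sum(axis=1)
    if np.any(sizes > n_pool):
        raise ValidationError("sample richness exceeds pool size")

    if weighting == "occupancy":
        w = pres.sum(axis=0).astype(float)
    elif weighting == "equal":
        w = np.ones(n_pool)
    elif weighting == "abundance":
        w = table.counts.to_numpy().sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if np.any(w <= 0):
        raise ValidationError("pool OTUs with zero weight")

    ss_obs = (pres.astype(np.int64) @ pres.T.astype(np.int64)).astype(np.int64)

    rng = np.random.default_rng(seed)
    gt = np.zeros((n_samples, n_samples), dtype=np.int64)
    eq = np.zeros((n_samples, n_samples), dtype=np.int64)
    for _ in range(n_null):
        null = _weighted_subset(rng, (n_samples, n_pool), w, sizes)
        ss_null = null.astype(np.int64) @ null.T.astype(np.int64)
        gt += ss_null > ss_obs
        eq += ss_null == ss_obs
    p = (gt + 0.5 * eq) / n_null
    brc = 2.0 * (p - 0.5)
    brc = 0.5 * (brc + brc.T)  # numerical symmetrization (null draws are shared)
    np.fill_diagonal(brc, 0.0)

    ids = table.sample_ids
    return RaupCrickResult(
        brc=pd.DataFrame(brc, index=ids, columns=ids),
        shared_obs=pd.DataFrame(ss_obs, index=ids, columns=ids),
        n_null=n_null,
        seed=seed,
        weighting=weighting,
    )


# ---------------------------------------------------------------------------
# process partition


@dataclasses.dataclass
class ProcessPartition:
    pairs: pd.DataFrame  # sample_a, sample_b, bnti, brc, process
    fractions: dict[str, float]
    n_pairs: int
    n_excluded: int  # pairs with undefined betaNTI

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "process": list(self.fractions),
                "fraction": list(self.fractions.values()),
            }
        ).set_index("process")


def classify_pair(bnti_value: float, brc_value: float | None) -> str:
    """Two-stage threshold rule mapping (betaNTI, beta_RC) to a process."""
    if np.isnan(bnti_value):
        raise ValueError("undefined betaNTI")
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if brc_value is None or np.isnan(brc_value):
        raise ValueError("beta_RC required when |betaNTI| <= 2")
    if brc_value > 0.95:
        return "dispersal_limitation"
    if brc_value < -0.95:
        return "homogeneous_dispersal"
    return "drift"


def partition_processes(
    bnti_matrix: pd.DataFrame, brc_matrix: pd.DataFrame
) -> ProcessPartition:
    """Classify every sample pair and summarize process fractions.

    beta_RC is consulted only for pairs with |betaNTI| ≤ 2 (the two-stage
    framework); pairs with undefined betaNTI are excluded and counted.
    """
    ids = list(bnti_matrix.index)
    if list(brc_matrix.index) != ids:
        brc_matrix = brc_matrix.loc[ids, ids]
    rows = []
    excluded = 0
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            z = float(bnti_matrix.loc[a, b])
            r = float(brc_matrix.loc[a, b])
            if np.isnan(z):
                excluded += 1
                continue
            proc = classify_pair(z, r)
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "bnti": z,
                    "brc": r if abs(z) <= 2 else float("nan"),
                    "process": proc,
                }
            )
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "bnti", "brc", "process"])
    n = len(pairs)
    fractions = {p: (float((pairs["process"] == p).sum()) / n if n else 0.0) for p in PROCESSES}
    return ProcessPartition(pairs=pairs, fractions=fractions, n_pairs=n, n_excluded=excluded)
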