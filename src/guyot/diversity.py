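"""Alpha diversity: depth normalization, rarefaction, richness, group tests.

Counts are normalized by subsampling each sample without replacement down to
the smallest sample size, richness is the number of OTUs observed after
normalization, and differences between depth layers are tested by one-way
ANOVA with Fisher's LSD letters when normality and homoscedasticity hold, or
the Kruskal–Wallis rank sum test otherwise.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data_io import OtuTable, ValidationError


class GroupingError(ValueError):
    """Group structure unusable for a between-group test."""


def normalize_to_min_depth(table: OtuTable, seed: int) -> OtuTable:
    """Subsample every sample, without replacement, to the minimum sample total.

    One multivariate-hypergeometric draw per sample (not an average over
    draws); the seed makes the draw reproducible.
    """
    counts = table.counts.to_numpy()
    depth = int(counts.sum(axis=1).min())
    if depth <= 0:
        raise ValidationError("cannot normalize: a sample has zero total")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns))


def rarefaction_curve(counts: np.ndarray | pd.Series, depths: np.ndarray) -> np.ndarray:
    """Analytic expected OTU richness of one sample at each subsampling depth.

    Uses the hypergeometric closed form
    ``E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n))`` evaluated in log space.
    """
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    total = int(x.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if np.any(depths < 0) or np.any(depths > total):
        raise ValueError(f"depths must lie in [0, {total}]")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = np.empty(len(depths), dtype=float)
    for k, n in enumerate(depths):
        rest = total - x  # reads not in OTU i
        prob_absent = np.where(
            rest >= n,
            np.exp(log_choose(rest, n) - log_choose(total, n)),
            0.0,
        )
        expected[k] = float(np.sum(1.0 - prob_absent))
    return expected


def observed_richness(table: OtuTable) -> pd.Series:
    return (table.counts > 0).sum(axis=1).rename("observed_richness")


# ---------------------------------------------------------------------------
# between-group testing


@dataclasses.dataclass
class GroupTestReport:
    """Which test branch ran and what it found."""

    branch: str  # "anova" | "kruskal" | "degenerate"
    statistic: float
    p_value: float
    shapiro_p: dict[str, float]
    bartlett_p: float
    letters: dict[str, str] | None  # LSD letters, only when ANOVA ran and p<0.05
    pairwise_p: dict[tuple[str, str], float] | None


@dataclasses.dataclass
class RichnessResult:
    table: pd.DataFrame  # sample_id, depth_layer, observed_richness, normalized_depth
    report: GroupTestReport


def _lsd_pairwise(values: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Fisher's LSD: pairwise t tests with the pooled within-group mean square.

    No multiplicity correction — that is what the LSD procedure is.
    """
    groups = list(values)
    ns = {g: len(values[g]) for g in groups}
    means = {g: float(np.mean(values[g])) for g in groups}
    n_total = sum(ns.values())
    k = len(groups)
    sse = sum(float(np.sum((values[g] - means[g]) ** 2)) for g in groups)
    df_err = n_total - k
    mse = sse / df_err
    out = {}
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            out[(a, b)] = 1.0 if means[a] == means[b] else 0.0
            continue
        t = (means[a] - means[b]) / se
        out[(a, b)] = float(2 * stats.t.sf(abs(t), df_err))
    return out


def _letter_display(
    groups: list[str],
    means: dict[str, float],
    pairwise_p: dict[tuple[str, str], float],
    alpha: float,
) -> dict[str, str]:
    """Compact letter display: same letter ⇔ pairwise p ≥ alpha.

    Insert-and-absorb over groups sorted by decreasing mean, the usual
    agricultural-statistics presentation ("a", "b", "ab", ...).
    """

    def sig(a: str, b: str) -> bool:
        p = pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))
        return p < alpha

    ordered = sorted(groups, key=lambda g: -means[g])
    # letter groups: maximal sets of mutually non-significant groups
    letter_sets: list[list[str]] = []
    for g in ordered:
        placed = False
        for s in letter_sets:
            if all(not sig(g, h) for h in s):
                s.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    # absorb sets fully contained in another
    keep = []
    for i, s in enumerate(letter_sets):
        if not any(set(s) < set(t) for j, t in enumerate(letter_sets) if j != i):
            keep.append(s)
    # dedupe identical sets
    uniq: list[list[str]] = []
    for s in keep:
        if set(s) not in [set(u) for u in uniq]:
            uniq.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = {g: "" for g in groups}
    for letter, s in zip(alphabet, uniq):
        for g in s:
            labels[g] += letter
    return {g: "".join(sorted(labels[g])) for g in groups}


def richness_by_group(
    table: OtuTable,
    groups: pd.Series,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
) -> RichnessResult:
    """Observed richness per sample plus a between-layer significance test.

    Shapiro–Wilk per group and Bartlett across groups gate (at ``gate_alpha``)
    the choice between one-way ANOVA (with Fisher's LSD letters when the ANOVA
    is significant at ``alpha``) and the Kruskal–Wallis rank sum test.
    """
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        raise GroupingError("every sample needs a group label")
    rich = observed_richness(table)
    by = {g: rich[groups == g].to_numpy(dtype=float) for g in groups.unique()}
    if len(by) < 2:
        raise GroupingError("need at least 2 groups")
    small = [g for g, v in by.items() if len(v) < 2]
    if small:
        raise GroupingError(f"groups with fewer than 2 samples: {small}")

    depth = int(table.sample_totals().min())
    out_table = pd.DataFrame(
        {
            "depth_layer": groups,
            "observed_richness": rich,
            "normalized_depth": depth,
        }
    )

    # degenerate: no variance anywhere
    pooled = rich.to_numpy(dtype=float)
    if np.ptp(pooled) == 0 or all(np.ptp(v) == 0 for v in by.values()):
        report = GroupTestReport(
            branch="degenerate",
            statistic=float("nan"),
            p_value=float("nan"),
            shapiro_p={},
            bartlett_p=float("nan"),
            letters=None,
            pairwise_p=None,
        )
        return RichnessResult(out_table, report)

    shapiro_p = {}
    normal = True
    for g, v in by.items():
        if np.ptp(v) == 0:
            shapiro_p[g] = float("nan")  # constant group: Shapiro undefined
            normal = False
            continue
        shapiro_p[g] = float(stats.shapiro(v).pvalue)
        normal &= shapiro_p[g] >= gate_alpha
    try:
        bartlett_p = float(stats.bartlett(*by.values()).pvalue)
    except ValueError:
        bartlett_p = float("nan")
    homosced = np.isfinite(bartlett_p) and bartlett_p >= gate_alpha

    if normal and homosced:
        f, p = stats.f_oneway(*by.values())
        letters = None
        pairwise = None
        if p < alpha:
            pairwise = _lsd_pairwise(by)
            means = {g: float(np.mean(v)) for g, v in by.items()}
            letters = _letter_display(list(by), means, pairwise, alpha)
        report = GroupTestReport(
            branch="anova",
            statistic=float(f),
            p_value=float(p),
            shapiro_p=shapiro_p,
            bartlett_p=bartlett_p,
            letters=letters,
            pairwise_p=pairwise,
        )
    else:
        h, p = stats.kruskal(*by.values())
        report = GroupTestReport(
            branch="kruskal",
            statistic=float(h),
            p_value=float(p),
            shapiro_p=shapiro_p,
            bartlett_p=bartlett_p,
            letters=None,
            pairwise_p=None,
        )
    return RichnessResult(out_table, report)
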