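"""Environmental drivers of community composition via (db)RDA on CLR data.

Because the Aitchison distance is the Euclidean distance between CLR rows,
distance-based redundancy analysis on Aitchison distances is identical to
ordinary RDA of the CLR matrix on the (log-transformed, standardized)
environmental design — so the fit is a least-squares projection, R² the
constrained share of total variance, adjusted R² the Ezekiel correction, and
significance comes from permutation tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd


class CollinearityWarning(UserWarning):
    pass


@dataclasses.dataclass
class RdaResult:
    selected_factors: list[str]
    r2: float
    r2_adjusted: float
    axis_p: list[float]
    model_p: float
    permutations: int
    n_samples: int
    n_dropped: int  # samples dropped for missing env data
    log_offsets: dict[str, float]
    dropped_collinear: list[str]
    eigenvalues: np.ndarray | None = None


def _log_standardize(
    env: pd.DataFrame, standardize: bool = True
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Natural-log transform each factor, offsetting non-positive columns.

    The offset is half the smallest positive observed value of the factor
    (0 when all values are positive); recorded per factor.
    """
    out = {}
    offsets = {}
    for col in env.columns:
        x = env[col].to_numpy(dtype=float)
        offset = 0.0
        if np.nanmin(x) <= 0:
            positive = x[x > 0]
            offset = float(positive.min() / 2.0) if positive.size else 1.0
        offsets[col] = offset
        lx = np.log(x + offset)
        if standardize:
            sd = np.nanstd(lx, ddof=1)
            lx = (lx - np.nanmean(lx)) / sd if sd > 0 else lx - np.nanmean(lx)
        out[col] = lx
    return pd.DataFrame(out, index=env.index), offsets


def _drop_collinear(x: pd.DataFrame, cond_threshold: float = 1e8) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop factors until the design's condition number is sane."""
    dropped = []
    cols = list(x.columns)
    while len(cols) > 1:
        mat = x[cols].to_numpy()
        cond = np.linalg.cond(mat)
        if cond < cond_threshold:
            break
        # drop the factor most explained by the others
        worst, worst_r2 = None, -1.0
        for c in cols:
            others = [o for o in cols if o != c]
            a = x[others].to_numpy()
            b = x[c].to_numpy()
            coef, *_ = np.linalg.lstsq(a, b, rcond=None)
            resid = b - a @ coef
            tot = np.sum((b - b.mean()) ** 2)
            r2 = 1 - np.sum(resid**2) / tot if tot > 0 else 1.0
            if r2 > worst_r2:
                worst, worst_r2 = c, r2
        cols.remove(worst)
        dropped.append(worst)
        warnings.warn(f"dropping collinear factor {worst!r}", CollinearityWarning)
    return x[cols], dropped


def _fit_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """R² of the least-squares projection of y (centered) on x, plus eigenvalues."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    ss_fit = float(np.sum(fitted**2))
    ss_tot = float(np.sum(y**2))
    # eigenvalues of the constrained axes (for per-axis tests)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = (s**2)[: x.shape[1]]
    return (ss_fit / ss_tot if ss_tot > 0 else 0.0), eig


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel correction: ``1 − (1 − R²)(n − 1)/(n − p − 1)``."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_fit(
    clr_matrix: pd.DataFrame,
    env: pd.DataFrame,
    factors: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> RdaResult:
    """RDA of a CLR community matrix on log-transformed environmental factors.

    Samples with missing values in the requested factors are dropped (the
    count is reported, the rest of the pipeline is untouched).  Global and
    per-axis p-values come from permuting sample rows of the design.
    """
    factors = list(factors) if factors is not None else list(env.columns)
    env = env.loc[clr_matrix.index, factors]
    complete = env.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    env = env.loc[complete]
    y_df = clr_matrix.loc[env.index]

    n = env.shape[0]
    if n <= len(factors) + 1:
        raise ValueError(
            f"need more samples ({n}) than factors + 1 ({len(factors) + 1})"
        )

    x_df, offsets = _log_standardize(env, standardize=standardize)
    x_df, dropped_coll = _drop_collinear(x_df)
    x = x_df.to_numpy()
    x = x - x.mean(axis=0)
    y = y_df.to_numpy()
    y = y - y.mean(axis=0)

    r2, eig = _fit_r2(y, x)
    p_eff = x.shape[1]
    r2a = adjusted_r2(r2, n, p_eff)

    rng = np.random.default_rng(seed)
    ge_model = 0
    ge_axis = np.zeros(p_eff, dtype=int)
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        r2p, eigp = _fit_r2(y, xp)
        ge_model += r2p >= r2
        k = min(len(eigp), p_eff)
        ge_axis[:k] += eigp[:k] >= eig[:k]
    model_p = (ge_model + 1) / (n_perm + 1)
    axis_p = [(g + 1) / (n_perm + 1) for g in ge_axis]

    return RdaResult(
        selected_factors=list(x_df.columns),
        r2=float(r2),
        r2_adjusted=float(r2a),
        axis_p=axis_p,
        model_p=float(model_p),
        permutations=n_perm,
        n_samples=n,
        n_dropped=n_dropped,
        log_offsets=offsets,
        dropped_collinear=dropped_coll,
        eigenvalues=eig,
    )


@dataclasses.dataclass
class ForwardSelectionResult:
    selected_factors: list[str]  # in admission order
    admission_p: list[float]
    cumulative_r2_adjusted: list[float]
    global_r2_adjusted: float
    final: RdaResult | None  # RDA on the selected set; None when nothing selected
    global_fit: RdaResult


def forward_select(
    clr_matrix: pd.DataFrame,
    env: pd.DataFrame,
    factors: list[str] | None = None,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> ForwardSelectionResult:
    """Greedy forward selection of environmental factors for RDA.

    At each step the candidate maximizing adjusted R² is admitted only if (i)
    its marginal permutation p-value is below ``alpha`` and (ii) the
    cumulative adjusted R² does not exceed the all-factors adjusted R² — the
    double stopping rule that guards against overfitting the selection.
    """
    factors = list(factors) if factors is not None else list(env.columns)
    env_c = env.loc[clr_matrix.index, factors]
    complete = env_c.notna().all(axis=1)
    env_c = env_c.loc[complete]
    y_df = clr_matrix.loc[env_c.index]
    n = env_c.shape[0]

    global_fit = rda_fit(
        y_df, env_c, factors, n_perm=n_perm, seed=seed, standardize=standardize
    )
    target_r2a = global_fit.r2_adjusted

    x_all, _ = _log_standardize(env_c, standardize=standardize)
    x_all = x_all - x_all.mean(axis=0)
    y = y_df.to_numpy()
    y = y - y.mean(axis=0)

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    admission_p: list[float] = []
    cum_r2a: list[float] = []
    remaining = [f for f in factors if f in x_all.columns]

    while remaining:
        best, best_r2a, best_r2 = None, -np.inf, 0.0
        for cand in remaining:
            cols = selected + [cand]
            x = x_all[cols].to_numpy()
            if np.linalg.matrix_rank(x) < len(cols):
                continue  # collinear with current set
            r2, _ = _fit_r2(y, x)
            r2a = adjusted_r2(r2, n, len(cols))
            if r2a > best_r2a:
                best, best_r2a, best_r2 = cand, r2a, r2
        if best is None:
            break
        # marginal permutation test of the candidate given the current set
        cols = selected + [best]
        x = x_all[cols].to_numpy()
        r2_with = best_r2
        if selected:
            x_base = x_all[selected].to_numpy()
            r2_base, _ = _fit_r2(y, x_base)
        else:
            x_base = None
            r2_base = 0.0
        stat = r2_with - r2_base
        ge = 0
        xc = x_all[[best]].to_numpy()
        for _ in range(n_perm):
            xp = np.column_stack(
                [x_base, xc[rng.permutation(n)]]
            ) if x_base is not None else xc[rng.permutation(n)]
            r2p, _ = _fit_r2(y, xp)
            ge += (r2p - r2_base) >= stat
        p = (ge + 1) / (n_perm + 1)
        if p >= alpha or best_r2a > target_r2a:
            break
        selected.append(best)
        admission_p.append(float(p))
        cum_r2a.append(float(best_r2a))
        remaining.remove(best)

    final = (
        rda_fit(y_df, env_c, selected, n_perm=n_perm, seed=seed, standardize=standardize)
        if selected
        else None
    )
    return ForwardSelectionResult(
        selected_factors=selected,
        admission_p=admission_p,
        cumulative_r2_adjusted=cum_r2a,
        global_r2_adjusted=float(target_r2a),
        final=final,
        global_fit=global_fit,
    )
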