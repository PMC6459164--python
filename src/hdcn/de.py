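"""Permutation-calibrated differential expression with p-value combination.

Three test statistics (Welch t, Wilcoxon rank-sum, median difference) are
each calibrated by label permutation; the three p-values are combined with
Fisher's method (chi-square, 6 df). A gene is called differentially
expressed when the raw-scale fold-change exceeds 1.25 in either direction
and the combined p-value is below 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hdcn._log import get_logger
from hdcn._log import derive_seed
from hdcn.containers import ExpressionMatrix

log = get_logger("hdcn.de")

STATISTICS = ("t", "rank_sum", "median_diff")
FC_THRESHOLD = 1.25
P_THRESHOLD = 0.01
N_PERM = 1000


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    denom = np.sqrt(v1 / x.size + v2 / y.size)
    if denom == 0:
        return 0.0
    return float((x.mean() - y.mean()) / denom)


def _statistic_obs(x: np.ndarray, y: np.ndarray, statistic: str) -> float:
    if statistic == "t":
        return _welch_t(x, y)
    if statistic == "rank_sum":
        n1, n = x.size, x.size + y.size
        ranks = stats.rankdata(np.concatenate([x, y]))
        # centered rank-sum: deviation of W from its null expectation
        return float(ranks[:n1].sum() - n1 * (n + 1) / 2.0)
    if statistic == "median_diff":
        return float(np.median(x) - np.median(y))
    raise ValueError(f"unknown statistic {statistic!r}")


def _statistic_perm(
    pooled: np.ndarray, idx: np.ndarray, n1: int, statistic: str
) -> np.ndarray:
    """Statistic for each permutation row of ``idx`` (n_perm x n)."""
    g1 = pooled[idx[:, :n1]]
    g2 = pooled[idx[:, n1:]]
    if statistic == "t":
        v1 = g1.var(axis=1, ddof=1)
        v2 = g2.var(axis=1, ddof=1)
        denom = np.sqrt(v1 / g1.shape[1] + v2 / g2.shape[1])
        diff = g1.mean(axis=1) - g2.mean(axis=1)
        return np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)
    if statistic == "rank_sum":
        n = pooled.size
        ranks = stats.rankdata(pooled)
        return ranks[idx[:, :n1]].sum(axis=1) - n1 * (n + 1) / 2.0
    if statistic == "median_diff":
        return np.median(g1, axis=1) - np.median(g2, axis=1)
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_pvalue(
    x,
    y,
    statistic: str,
    n_perm: int = N_PERM,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value with the add-one estimator.

    p = (1 + #{|s_perm| >= |s_obs|}) / (1 + n_perm) over ``n_perm`` random
    label permutations. The rank-sum statistic is centered at its null
    expectation so that two-sidedness via |s| is meaningful.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        log.warning("all values identical in both groups; p = 1")
        return 1.0
    s_obs = abs(_statistic_obs(x, y, statistic))
    rng = np.random.default_rng(seed)
    idx = rng.random((n_perm, pooled.size)).argsort(axis=1)
    s_perm = np.abs(_statistic_perm(pooled, idx, x.size, statistic))
    return float((1 + int((s_perm >= s_obs).sum())) / (1 + n_perm))


def combine_pvalues(
    p_t: float, p_wilcoxon: float, p_median: float, n_perm: int = N_PERM
) -> float:
    """Fisher's method: X = -2 sum(ln p), upper chi-square tail with 6 df.

    A zero input (impossible under the add-one permutation estimator but
    tolerated) is clamped to 1/(1+n_perm) with a warning.
    """
    ps = []
    for p in (p_t, p_wilcoxon, p_median):
        if not 0 <= p <= 1:
            raise ValueError(f"p-value out of range: {p}")
        if p == 0:
            log.warning("p = 0 clamped to 1/(1+%d)", n_perm)
            p = 1.0 / (1 + n_perm)
        ps.append(p)
    x = -2.0 * float(np.sum(np.log(ps)))
    return float(stats.chi2.sf(x, df=6))


def call_degs(
    purified_matrix: ExpressionMatrix,
    reference_matrix: ExpressionMatrix,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    n_perm: int = N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene DEG table over a purified mixed matrix and a reference matrix.

    Fold-change is computed on raw-scale group means with a +1 pseudocount
    and reported as log2. Each gene's permutation stream is seeded by a
    stable hash of (master seed, gene id), so results do not depend on gene
    order. The same permutation draws are shared by the three statistics.
    """
    genes = list(purified_matrix.gene_ids)
    if genes != list(reference_matrix.gene_ids):
        raise ValueError("purified and reference matrices must share gene ids")
    mixed = purified_matrix.values.loc[
        :, purified_matrix.mixed_samples or purified_matrix.sample_ids
    ].to_numpy(dtype=float)
    ref = reference_matrix.values.loc[
        :, reference_matrix.reference_samples or reference_matrix.sample_ids
    ].to_numpy(dtype=float)
    n1 = mixed.shape[1]
    log2fc = np.log2((mixed.mean(axis=1) + 1.0) / (ref.mean(axis=1) + 1.0))
    fc_cut = np.log2(fc_threshold)

    rows = []
    for i, gene in enumerate(genes):
        x, y = mixed[i], ref[i]
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            p_vals = {s: 1.0 for s in STATISTICS}
        else:
            rng = np.random.default_rng(derive_seed(seed, "deg", gene))
            idx = rng.random((n_perm, pooled.size)).argsort(axis=1)
            p_vals = {}
            for s in STATISTICS:
                s_obs = abs(_statistic_obs(x, y, s))
                s_perm = np.abs(_statistic_perm(pooled, idx, n1, s))
                p_vals[s] = (1 + int((s_perm >= s_obs).sum())) / (1 + n_perm)
        p_comb = combine_pvalues(
            p_vals["t"], p_vals["rank_sum"], p_vals["median_diff"], n_perm=n_perm
        )
        if p_comb < p_threshold and log2fc[i] > fc_cut:
            call = "up"
        elif p_comb < p_threshold and log2fc[i] < -fc_cut:
            call = "down"
        else:
            call = "none"
        rows.append(
            {
                "gene_id": gene,
                "log2_fc": log2fc[i],
                "p_t": p_vals["t"],
                "p_wilcoxon": p_vals["rank_sum"],
                "p_median": p_vals["median_diff"],
                "p_combined": p_comb,
                "call": call,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def overlap_summary(
    up: set, down: set, reference_list: set
) -> pd.DataFrame:
    """Overlap of called up/down gene sets with an external reference list.

    Percent = 100 * n_overlap / n_called rounded to one decimal; an empty
    direction reports NaN (undefined), not 0.
    """
    reference = set(reference_list)
    rows = []
    for direction, called in (("up", set(up)), ("down", set(down))):
        n_called = len(called)
        n_overlap = len(called & reference)
        percent = round(100.0 * n_overlap / n_called, 1) if n_called else float("nan")
        rows.append(
            {
                "direction": direction,
                "n_called": n_called,
                "n_overlap": n_overlap,
                "percent": percent,
            }
        )
    return pd.DataFrame(rows).set_index("direction")


def hypergeometric_overrep(
    k_overlap: int, n_set_a: int, n_set_b: int, n_universe: int
) -> float:
    """Upper-tail hypergeometric overlap p-value P(X >= k)."""
    if not (
        0 <= k_overlap <= min(n_set_a, n_set_b)
        and max(n_set_a, n_set_b) <= n_universe
    ):
        raise ValueError(
            f"inconsistent counts: k={k_overlap}, A={n_set_a}, "
            f"B={n_set_b}, N={n_universe}"
        )
    return float(stats.hypergeom.sf(k_overlap - 1, n_universe, n_set_a, n_set_b))


__all__ = [
    "permutation_pvalue",
    "combine_pvalues",
    "call_degs",
    "overlap_summary",
    "hypergeometric_overrep",
    "STATISTICS",
]
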