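"""V-J clonotype repertoire diversity.

The processing order is fixed: collapse identical junction reads, select
the top-K unique sequences per sample, keep in-frame junctions only, count
(V, J) combinations, then compute Shannon alpha diversity per sample and
pairwise Sorensen beta diversity with the Baselga turnover/nestedness
partition; group contrasts use two-sided label-permutation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hdcn._log import get_logger
from hdcn.containers import ClonotypeTable

log = get_logger("hdcn.repertoire")

TOP_K = 10000
STOP_CODONS = ("TAA", "TAG", "TGA")


def collapse_reads(table: ClonotypeTable) -> ClonotypeTable:
    """Merge identical junction sequences within each sample, summing counts."""
    df = table.records
    collapsed = (
        df.groupby(["sample_id", "junction_nt"], as_index=False, sort=True)
        .agg(
            v_gene=("v_gene", "first"),
            j_gene=("j_gene", "first"),
            count=("count", "sum"),
        )
    )
    return ClonotypeTable(collapsed[list(ClonotypeTable.COLUMNS)])


def select_top_k(collapsed: ClonotypeTable, k: int = TOP_K) -> ClonotypeTable:
    """Keep the K most abundant unique sequences per sample.

    Ties in count are broken lexicographically by junction sequence so the
    selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = collapsed.records.sort_values(
        ["sample_id", "count", "junction_nt"],
        ascending=[True, False, True],
        kind="stable",
    )
    kept = df.groupby("sample_id", sort=True).head(k).reset_index(drop=True)
    return ClonotypeTable(kept)


def _in_frame(junction: str) -> bool:
    if len(junction) % 3 != 0:
        return False
    for i in range(0, len(junction), 3):
        if junction[i : i + 3] in STOP_CODONS:
            return False
    return True


def filter_in_frame(table: ClonotypeTable) -> ClonotypeTable:
    """Keep junctions of length divisible by 3 with no frame-0 stop codon.

    Sequences containing N are dropped (count logged), since their frame
    cannot be translated unambiguously.
    """
    df = table.records
    has_n = df["junction_nt"].str.contains("N")
    if has_n.any():
        log.info("dropped %d junction(s) containing N", int(has_n.sum()))
    keep = ~has_n & df["junction_nt"].map(_in_frame)
    return ClonotypeTable(df[keep].reset_index(drop=True))


def vj_matrix(table: ClonotypeTable) -> pd.DataFrame:
    """Samples x (V, J) combination count matrix (column index: v_gene, j_gene)."""
    df = table.records
    mat = df.pivot_table(
        index="sample_id",
        columns=["v_gene", "j_gene"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    return mat.astype(np.int64)


def alpha_diversity(vj: pd.DataFrame) -> pd.Series:
    """Shannon index H = -sum p ln p per sample (natural log)."""
    totals = vj.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    p = vj.div(totals, axis=0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return pd.Series(terms.sum(axis=1), index=vj.index, name="shannon")


def beta_diversity(vj: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise presence/absence Sorensen dissimilarity and its partition.

    For samples i, j with a shared combinations and b, c unique to each:
    total (Sorensen) = (b+c)/(2a+b+c); turnover (Simpson) =
    min(b,c)/(a+min(b,c)); nestedness = total - turnover.
    """
    if vj.shape[0] < 2:
        raise ValueError("beta diversity requires at least 2 samples")
    presence = (vj > 0).to_numpy()
    if not presence.any(axis=1).all():
        bad = vj.index[~presence.any(axis=1)][0]
        raise ValueError(f"sample {bad!r} has no combinations")
    n = presence.shape[0]
    shared = presence.astype(int) @ presence.astype(int).T
    richness = presence.sum(axis=1)
    out = {
        key: np.zeros((n, n)) for key in ("total", "turnover", "nestedness")
    }
    for i in range(n):
        for j in range(i + 1, n):
            a = shared[i, j]
            b = richness[i] - a
            c = richness[j] - a
            sor = (b + c) / (2 * a + b + c)
            sim = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else 0.0
            for key, val in (
                ("total", sor),
                ("turnover", sim),
                ("nestedness", sor - sim),
            ):
                out[key][i, j] = out[key][j, i] = val
    return {
        key: pd.DataFrame(val, index=vj.index, columns=vj.index)
        for key, val in out.items()
    }


def _within_group_mean(diss: np.ndarray, members: np.ndarray) -> float:
    sub = diss[np.ix_(members, members)]
    m = members.sum()
    if m < 2:
        return 0.0
    return float(sub.sum() / (m * (m - 1)))


def group_permutation_test(
    data,
    labels: pd.Series,
    mode: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided label-permutation p-value for a two-group diversity contrast.

    mode="alpha_mean_diff": ``data`` is a per-sample Series; statistic is
    the difference of group means. mode="beta_within_group_mean_diff":
    ``data`` is a square dissimilarity DataFrame; statistic is the
    difference of mean within-group pairwise dissimilarities.
    """
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if mode == "alpha_mean_diff":
        values = pd.Series(data).loc[labels.index].to_numpy(dtype=float)

        def stat(mask: np.ndarray) -> float:
            return float(values[mask].mean() - values[~mask].mean())

    elif mode == "beta_within_group_mean_diff":
        diss = data.loc[labels.index, labels.index].to_numpy(dtype=float)

        def stat(mask: np.ndarray) -> float:
            return _within_group_mean(diss, mask) - _within_group_mean(diss, ~mask)

    else:
        raise ValueError(f"unknown mode {mode!r}")

    mask_obs = (labels == groups[0]).to_numpy()
    s_obs = abs(stat(mask_obs))
    rng = np.random.default_rng(seed)
    n_hits = 0
    mask = mask_obs.copy()
    for _ in range(n_perm):
        rng.shuffle(mask)
        if abs(stat(mask)) >= s_obs:
            n_hits += 1
    return (1 + n_hits) / (1 + n_perm)


__all__ = [
    "collapse_reads",
    "select_top_k",
    "filter_in_frame",
    "vj_matrix",
    "alpha_diversity",
    "beta_diversity",
    "group_permutation_test",
    "TOP_K",
    "STOP_CODONS",
]
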