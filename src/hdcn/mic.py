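"""Maximal information coefficient (MIC) and differential co-expression calls.

MIC measures the strength of any functional or near-functional association
between two variables: mutual information is maximized over axis-aligned
grids whose total cell count is bounded by ``n**alpha_exponent`` and
normalized by ``log2(min(rows, cols))``, so MIC lies in [0, 1] and reaches 1
for noiseless functional relationships. A gene pair whose MIC differs
between the two conditions by more than a threshold (default 0.4) is called
a differentially co-expressed gene pair (DCGP).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from hdcn import _mine
from hdcn._log import get_logger
from hdcn.containers import MIXED, REFERENCE, ExpressionMatrix

log = get_logger("hdcn.mic")

DELTA_MIC_THRESHOLD = 0.4


def mic(x, y, alpha_exponent: float = 0.6, clump_factor: int = 15) -> float:
    """Maximal information coefficient of two equal-length samples.

    Parameters
    ----------
    x, y
        Paired observations; no missing values.
    alpha_exponent
        Grid budget exponent: grids of a x b cells are searched for
        ``a * b <= max(4, n**alpha_exponent)``. The floor of 4 keeps the
        smallest informative (2 x 2) grid admissible at any n.
    clump_factor
        Cap on DP cut candidates, ``clump_factor * a`` superclumps.

    Returns 0 with a warning if either variable is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite with no missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant input to mic(); returning 0")
        return 0.0

    budget = max(4.0, float(n) ** alpha_exponent)
    best = 0.0
    for u, v in ((x, y), (y, x)):
        # columns on u, rows on v
        order_u = np.argsort(u, kind="stable")
        u_sorted = u[order_u]
        block_ends = np.flatnonzero(np.diff(u_sorted) != 0) + 1
        block_ends = np.append(block_ends, n).astype(np.int64)
        order_v = np.argsort(v, kind="stable")
        b_max = int(budget // 2)
        for b in range(2, b_max + 1):
            amax = int(budget // b)
            if amax < 2:
                break
            rows_sorted, n_rows = _mine.equipartition(v[order_v], b)
            if n_rows < 2:
                continue
            rows_of_point = np.empty(n, dtype=np.int64)
            rows_of_point[order_v] = rows_sorted
            rows_in_u_order = rows_of_point[order_u]
            info = _mine.optimize_axis(
                rows_in_u_order, block_ends, n_rows, amax, clump_factor * amax
            )
            for a in range(2, amax + 1):
                val = info[a] / math.log2(min(a, b))
                if val > best:
                    best = val
    return float(min(1.0, best))


def mic_matrix(
    matrix: ExpressionMatrix,
    pairs,
    alpha_exponent: float = 0.6,
    clump_factor: int = 15,
) -> pd.DataFrame:
    """MIC per unordered gene pair, computed within each condition separately.

    Returns a DataFrame with columns gene_a, gene_b, mic_mixed,
    mic_reference, self_pair. Self-pairs get MIC 1 by definition and are
    flagged (they are excluded from DCGP calling).
    """
    matrix.require_two_groups()
    genes = set(matrix.gene_ids)
    uniq: list[tuple[str, str]] = []
    seen = set()
    missing = set()
    for a, b in pairs:
        if a not in genes:
            missing.add(a)
        if b not in genes:
            missing.add(b)
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            uniq.append(key)
    if missing:
        raise ValueError(f"pairs reference genes absent from matrix: {sorted(missing)}")

    cond_values = {
        MIXED: matrix.values[matrix.mixed_samples],
        REFERENCE: matrix.values[matrix.reference_samples],
    }
    rows = []
    for a, b in uniq:
        rec = {"gene_a": a, "gene_b": b, "self_pair": a == b}
        for cond, sub in cond_values.items():
            if a == b:
                xa = sub.loc[a].to_numpy()
                val = 1.0 if not np.all(xa == xa[0]) else 0.0
            else:
                val = mic(
                    sub.loc[a].to_numpy(),
                    sub.loc[b].to_numpy(),
                    alpha_exponent=alpha_exponent,
                    clump_factor=clump_factor,
                )
            rec[f"mic_{cond}"] = val
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "mic_mixed", "mic_reference", "self_pair"]
    )


def call_dcgps(
    mic_pairs: pd.DataFrame, delta_threshold: float = DELTA_MIC_THRESHOLD
) -> pd.DataFrame:
    """Call differentially co-expressed gene pairs from per-condition MICs.

    delta = mic_mixed - mic_reference; call "up" if delta > threshold
    (co-expression stronger in the mixed/disease condition), "down" if
    delta < -threshold, else "none". Self-pairs are always "none".
    """
    out = mic_pairs.copy()
    out["delta"] = out["mic_mixed"] - out["mic_reference"]
    call = np.where(
        out["delta"] > delta_threshold,
        "up",
        np.where(out["delta"] < -delta_threshold, "down", "none"),
    )
    if "self_pair" in out.columns:
        call = np.where(out["self_pair"], "none", call)
    out["call"] = call
    return out


__all__ = ["mic", "mic_matrix", "call_dcgps", "DELTA_MIC_THRESHOLD"]
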