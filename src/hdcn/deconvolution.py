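"""Two-component expression deconvolution.

Each mixed (disease) sample is modeled on the raw FPKM scale as

    Y_ig = pi_i * R_ig + (1 - pi_i) * T_ig,

where R_ig is an (unobserved) draw from the reference law of gene g, pi_i is
the per-sample contamination proportion, and T_ig is the purified disease
component. The reference law's raw-scale moments (m_g, v_g) are estimated
from the reference samples; the purified component shares the gene's
log-scale dispersion, so its raw variance is tied to its mean through the
gene's squared coefficient of variation (v_T = v_g * (m_T/m_g)^2). Single
log-normal components are approximated by moment matching when evaluating
likelihoods.

Estimation proceeds in three steps:

1. *Relative contamination.* Across genes, a mixed sample's deviation from
   the cohort mean expression is proportional to the deviation of its pi
   from the cohort mean pi, with the (reference - purified) mean profile as
   the regressor. A weighted errors-in-variables regression over
   clear-signal genes yields each sample's relative contamination.
2. *Contamination level.* The one remaining scalar (the cohort mean pi) is
   chosen by a 1-D profile likelihood: candidate levels imply a purified
   mean profile and, through the constant-CV tie, all variances.
3. *Refinement.* Per-sample weighted least squares against the fitted
   purified profile, then a guarded alternating refinement (purified-mean
   updates accepted only when they increase the likelihood; exact grid
   maximization over pi per sample) whose objective is non-decreasing by
   construction. A per-sample boundary likelihood-ratio test shrinks pi to
   exactly 0 unless the evidence for contamination is decisive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hdcn._log import get_logger
from hdcn.containers import ExpressionMatrix

log = get_logger("hdcn.deconvolution")

EPSILON = 0.01  # floor for purified raw-scale values
SIGMA_FLOOR = 0.05
PI_MAX = 0.95
#: minimum log-likelihood gain (nats) over pi = 0 to call a sample contaminated
LRT_NULL_GAIN = 5.0


@dataclass
class DeconvolutionResult:
    pi_hat: pd.Series  # per mixed sample, in [0, PI_MAX]
    purified: ExpressionMatrix
    reference_params: pd.DataFrame  # index genes; mu, sigma (log2), mean_raw, var_raw
    converged: bool
    n_iter: int
    objective_path: list


def filter_variable_genes(
    matrix: ExpressionMatrix, cv_threshold: float = 0.5
) -> list[str]:
    """Genes whose coefficient of variation (sample sd / mean, raw scale,
    across all samples) strictly exceeds ``cv_threshold``.

    Genes with zero mean are excluded. An empty result is permitted (warned).
    """
    if cv_threshold <= 0:
        raise ValueError("cv_threshold must be positive")
    arr = matrix.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(arr.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    keep = np.nan_to_num(cv, nan=-1.0) > cv_threshold
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    if not genes:
        log.warning("CV filter at %.3g removed every gene", cv_threshold)
    return genes


def fit_reference(matrix: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Reference-law parameters per gene from the reference samples.

    mu and sigma are the sample mean and sd of log2(value + 1) (sigma
    floored at 0.05); mean_raw and var_raw are the raw-scale moments used
    by the likelihood. n_ref is carried along for the sampling-error
    correction of the reference mean.
    """
    ref_samples = matrix.reference_samples
    if len(ref_samples) < 3:
        raise ValueError(
            f"need at least 3 reference samples, got {len(ref_samples)}"
        )
    raw = matrix.values.loc[genes, ref_samples].to_numpy(dtype=float)
    logv = np.log2(raw + 1.0)
    return pd.DataFrame(
        {
            "mu": logv.mean(axis=1),
            "sigma": np.maximum(logv.std(axis=1, ddof=1), SIGMA_FLOOR),
            "mean_raw": raw.mean(axis=1),
            "var_raw": raw.var(axis=1, ddof=1),
            "n_ref": len(ref_samples),
        },
        index=genes,
    )


def _fw_loglik(lw: np.ndarray, E: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Log-density of log-observations under a moment-matched log-normal.

    ``lw`` is ln(Y+1); ``E``/``V`` are the raw-scale mean and variance of
    Y + 1's distribution minus the +1 shift handled by the caller.
    """
    V = np.maximum(V, 1e-12)
    E = np.maximum(E, 1e-6)
    s2 = np.log1p(V / E**2)
    mu = np.log(E) - s2 / 2.0
    return -0.5 * (lw - mu) ** 2 / s2 - 0.5 * np.log(s2)


def estimate_proportions(
    matrix: ExpressionMatrix,
    genes: list[str],
    reference_params: pd.DataFrame,
    grid_step: float = 0.01,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> DeconvolutionResult:
    """Estimate per-sample contamination proportions (see module docstring)."""
    matrix.require_two_groups()
    mixed = matrix.mixed_samples
    Y = matrix.values.loc[genes, mixed].to_numpy(dtype=float)
    G, S = Y.shape
    mR = reference_params.loc[genes, "mean_raw"].to_numpy()
    vR = reference_params.loc[genes, "var_raw"].to_numpy()
    n_ref = int(reference_params["n_ref"].iloc[0])
    vR_eff = vR * (1.0 + 1.0 / n_ref)  # reference-mean sampling error
    cv2 = vR_eff / np.maximum(mR, 1e-6) ** 2
    lw = np.log(Y + 1.0)
    Ybar = Y.mean(axis=1)
    vY = Y.var(axis=1, ddof=1) if S > 1 else np.zeros(G)

    # step 1: relative contamination by errors-in-variables regression
    D = Ybar - mR
    seD2 = vY / max(S, 1) + vR / n_ref
    w0 = 1.0 / np.maximum(vY, 1e-8)
    sel = D**2 > 4.0 * seD2
    if sel.sum() < 5:
        sel = np.ones(G, dtype=bool)
    denom = max(np.sum((w0 * D**2)[sel]) - np.sum((w0 * seD2)[sel]), 1e-12)
    b = ((Y - Ybar[:, None])[sel] * (w0 * D)[sel][:, None]).sum(axis=0) / denom

    # step 2: profile likelihood over the cohort contamination level
    level_grid = np.arange(0.0, 0.80 + grid_step / 2, grid_step)
    best = None
    for pibar in level_grid:
        pi_c = np.clip(pibar - b * (1.0 - pibar), 0.0, PI_MAX)
        mT = np.maximum((Ybar - pibar * mR) / (1.0 - pibar), 1e-3)
        vT = cv2 * mT**2
        E = pi_c[None, :] * mR[:, None] + (1 - pi_c[None, :]) * mT[:, None] + 1.0
        V = (
            pi_c[None, :] ** 2 * vR_eff[:, None]
            + (1 - pi_c[None, :]) ** 2 * vT[:, None]
        )
        ll = _fw_loglik(lw, E, V).sum()
        if not np.isfinite(ll):
            raise ValueError(
                f"non-finite deconvolution likelihood at level {pibar:.2f}"
            )
        if best is None or ll > best[0]:
            best = (ll, pi_c)
    pi = best[1]

    # step 3a: per-sample WLS refinement against the fitted purified profile
    for _ in range(2):
        mT = np.maximum(
            ((Y - pi[None, :] * mR[:, None]) / (1.0 - pi[None, :])).mean(axis=1),
            1e-3,
        )
        vT = cv2 * mT**2
        X = mR - mT
        Vg = pi.mean() ** 2 * vR_eff + (1 - pi.mean()) ** 2 * vT
        ww = 1.0 / np.maximum(Vg, 1e-8)
        den = float((ww * X * X).sum())
        if den > 1e-10:
            pi = np.clip(
                ((Y - mT[:, None]) * (ww * X)[:, None]).sum(axis=0) / den,
                0.0,
                PI_MAX,
            )

    # step 3b: guarded alternating refinement (monotone objective)
    pi_grid = np.arange(0.0, PI_MAX + grid_step / 2, grid_step)
    pi_grid = pi_grid[pi_grid <= PI_MAX]
    mT = np.maximum(
        ((Y - pi[None, :] * mR[:, None]) / (1.0 - pi[None, :])).mean(axis=1), 1e-3
    )
    objective_path: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mT_new = np.maximum(
            ((Y - pi[None, :] * mR[:, None]) / (1.0 - pi[None, :])).mean(axis=1),
            1e-3,
        )
        E_old = pi[None, :] * mR[:, None] + (1 - pi[None, :]) * mT[:, None] + 1.0
        V_old = (
            pi[None, :] ** 2 * vR_eff[:, None]
            + (1 - pi[None, :]) ** 2 * (cv2 * mT**2)[:, None]
        )
        E_new = pi[None, :] * mR[:, None] + (1 - pi[None, :]) * mT_new[:, None] + 1.0
        V_new = (
            pi[None, :] ** 2 * vR_eff[:, None]
            + (1 - pi[None, :]) ** 2 * (cv2 * mT_new**2)[:, None]
        )
        improves = (
            _fw_loglik(lw, E_new, V_new).sum(axis=1)
            > _fw_loglik(lw, E_old, V_old).sum(axis=1)
        )
        mT = np.where(improves, mT_new, mT)
        vT = cv2 * mT**2
        E = (
            pi_grid[None, :, None] * mR[:, None, None]
            + (1 - pi_grid[None, :, None]) * mT[:, None, None]
            + 1.0
        )
        V = (
            pi_grid[None, :, None] ** 2 * vR_eff[:, None, None]
            + (1 - pi_grid[None, :, None]) ** 2 * vT[:, None, None]
        )
        ll = _fw_loglik(lw[:, None, :], E, V).sum(axis=0)  # (grid, sample)
        new_pi = pi_grid[np.argmax(ll, axis=0)]
        objective_path.append(float(ll.max(axis=0).sum()))
        delta = float(np.mean(np.abs(new_pi - pi)))
        pi = new_pi
        # boundary test: contamination must be decisively supported
        gain = ll.max(axis=0) - ll[0]
        pi = np.where(gain < LRT_NULL_GAIN, 0.0, pi)
        if delta < tol:
            converged = True
            break

    purified = ExpressionMatrix(
        pd.DataFrame(_purify(Y, pi, mR), index=genes, columns=mixed),
        {s: matrix.groups[s] for s in mixed},
    )
    return DeconvolutionResult(
        pi_hat=pd.Series(pi, index=mixed, name="pi_hat"),
        purified=purified,
        reference_params=reference_params.loc[genes],
        converged=converged,
        n_iter=n_iter,
        objective_path=objective_path,
    )


def _purify(Y: np.ndarray, pi: np.ndarray, ref_mean: np.ndarray) -> np.ndarray:
    """Raw-scale purified component T = max(eps, (Y - pi*m_R) / (1 - pi))."""
    T = (Y - pi[None, :] * ref_mean[:, None]) / (1.0 - pi[None, :])
    return np.maximum(T, EPSILON)


def deconvolve(matrix: ExpressionMatrix, result: DeconvolutionResult) -> ExpressionMatrix:
    """Materialize the purified mixed-condition matrix from estimated pi.

    Values falling below the floor (observed value smaller than the
    estimated contamination) are clamped at epsilon and counted in the log.
    """
    genes = list(result.reference_params.index)
    mixed = list(result.pi_hat.index)
    Y = matrix.values.loc[genes, mixed].to_numpy(dtype=float)
    mR = result.reference_params["mean_raw"].to_numpy()
    T = _purify(Y, result.pi_hat.to_numpy(), mR)
    n_clamped = int((T == EPSILON).sum())
    if n_clamped:
        log.info("%d purified values clamped at epsilon=%.3g", n_clamped, EPSILON)
    return ExpressionMatrix(
        pd.DataFrame(T, index=genes, columns=mixed),
        {s: matrix.groups[s] for s in mixed},
    )


__all__ = [
    "DeconvolutionResult",
    "filter_variable_genes",
    "fit_reference",
    "estimate_proportions",
    "deconvolve",
    "EPSILON",
    "PI_MAX",
    "SIGMA_FLOOR",
    "LRT_NULL_GAIN",
]
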