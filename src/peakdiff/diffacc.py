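"""Negative-binomial differential accessibility testing.

A simplified count-based differential pipeline over a reference peak
set: median-of-ratios size factors, per-peak method-of-moments
dispersion estimates shrunk toward a fitted mean-dispersion trend, and
a per-peak NB log-linear Wald test of a two-level condition factor.

The model for peak i in sample j is

    y_ij ~ NB(mu_ij, alpha_i),   Var = mu + alpha * mu^2
    log mu_ij = log s_j + b0_i + b1_i * x_j

with x_j = 1 for the target condition, s_j the size factor, and b1 the
natural-log fold change (reported on the log2 scale).  Fitting is
Fisher scoring with the dispersion held fixed; the standard error comes
from the expected information, and the p-value is two-sided normal on
the Wald statistic.  Nominal p-values are used for peak selection (no
multiple-testing correction by default; a Benjamini-Hochberg option is
available).

This is deliberately not a re-implementation of DESeq2's full
machinery (no Cox-Reid adjustment, LFC shrinkage, outlier or
independent filtering); the downstream peak logic needs only
(log2FoldChange, p) at nominal thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet

__all__ = [
    "DifferentialCallSettings",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "select_differential",
]

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
_BETA_MAX = 30.0  # natural-log bound on coefficients for degenerate groups


@dataclass(frozen=True)
class DifferentialCallSettings:
    """Selection thresholds: nominal alpha and required fold-change sign."""

    alpha: float = 0.1
    direction: Literal["enriched-in-target", "enriched-in-reference", "both"] = (
        "enriched-in-target"
    )
    adjust: bool = False  # Benjamini-Hochberg on request; nominal p by default

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    factor_j = median over peaks of count_ij / geometric-mean_i, taken
    over peaks whose geometric mean is nonzero (all-sample-nonzero
    peaks).
    """
    y = np.asarray(counts, dtype=float)
    ok = (y > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no peak has nonzero counts in all samples; cannot normalize")
    logy = np.log(y[ok])
    loggeo = logy.mean(axis=1, keepdims=True)
    return np.exp(np.median(logy - loggeo, axis=0))


def _moments_dispersion(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak MoM dispersion and df weight from one condition's
    normalized counts (columns = replicates)."""
    n = z.shape[1]
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(m > 0, (v - m) / np.square(m), 0.0)
    return np.maximum(a, 0.0), np.full(z.shape[0], float(n - 1))


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    sfactors: np.ndarray,
    condition_labels: Sequence[str] | np.ndarray,
    *,
    prior_df: float = 100.0,
    floor: float = DISPERSION_FLOOR,
) -> np.ndarray:
    """Per-peak NB dispersions: within-condition method-of-moments,
    shrunk toward a fitted mean-dispersion trend.

    The raw estimate alpha_hat = max(0, (s^2 - m) / m^2) is computed on
    normalized counts within each condition with >= 2 replicates and
    averaged with (n_c - 1) weights.  A trend a0 + a1/mu is least-squares
    fitted over peaks and the final value is the weighted average of raw
    and trend with raw weight df / (df + prior_df).  With 2-3 replicate
    designs the per-peak moment estimate is essentially sampling noise
    (2-4 df), and a noisy plug-in dispersion inflates the Wald test's
    type-I error, so the default prior is strong (100 df: the trend,
    fitted over thousands of peaks, dominates) — lower ``prior_df`` for
    data whose dispersion genuinely varies between peaks.  Values are
    floored at ``floor``.
    """
    y = np.asarray(counts, dtype=float)
    z = y / np.asarray(sfactors, dtype=float)[None, :]
    labels = np.asarray(condition_labels)
    P = y.shape[0]

    a_num = np.zeros(P)
    df = np.zeros(P)
    for lab in np.unique(labels):
        cols = labels == lab
        if cols.sum() >= 2:
            a_c, w_c = _moments_dispersion(z[:, cols])
            a_num += a_c * w_c
            df += w_c
    if (df == 0).all():
        warnings.warn(
            "single replicate per condition everywhere; "
            "falling back to dispersion pooled across all samples",
            stacklevel=2,
        )
        a_raw, df = _moments_dispersion(z)
    else:
        a_raw = np.where(df > 0, a_num / np.maximum(df, 1.0), 0.0)

    mu = z.mean(axis=1)
    use = mu > 0
    if use.sum() >= 10:
        # least squares for alpha ~ a0 + a1/mu, coefficients clipped >= 0
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(X, a_raw[use], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:
        a0, a1 = float(np.mean(a_raw[use])) if use.any() else 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), a0)

    w_raw = df / (df + prior_df)
    alpha = w_raw * a_raw + (1.0 - w_raw) * trend
    return np.maximum(alpha, floor)


def nb_wald_test(
    counts: pd.DataFrame,
    condition_labels: Sequence[str] | np.ndarray,
    sfactors: np.ndarray,
    dispersions: np.ndarray,
    *,
    target: str = "target",
    max_iter: int = 60,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Per-peak NB Wald test of target vs reference condition.

    Returns a DataFrame indexed by peak id with columns ``baseMean``
    (mean of normalized counts over all samples), ``log2FoldChange``,
    ``lfcSE``, ``stat`` and ``pvalue``.  All-zero peaks get baseMean 0
    and missing (NaN) statistics.
    """
    y = counts.to_numpy(dtype=float)
    labels = np.asarray(condition_labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("nb_wald_test requires exactly two conditions")
    if target not in labels:
        raise ValueError(f"target condition {target!r} not among labels")
    x = (labels == target).astype(float)  # (S,)
    s = np.asarray(sfactors, dtype=float)
    alpha = np.asarray(dispersions, dtype=float)[:, None]

    z = y / s[None, :]
    base_mean = z.mean(axis=1)
    nonzero = y.sum(axis=1) > 0

    # initialize at per-condition normalized means
    eps = 1e-8
    m_ref = np.maximum(z[:, x == 0].mean(axis=1), eps)
    m_tgt = np.maximum(z[:, x == 1].mean(axis=1), eps)
    b0 = np.log(m_ref)
    b1 = np.log(m_tgt) - b0

    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :]
        mu = s[None, :] * np.exp(np.clip(eta, -_BETA_MAX, _BETA_MAX))
        denom = 1.0 + alpha * mu
        r = (y - mu) / denom
        w = mu / denom
        U0 = r.sum(axis=1)
        U1 = (r * x[None, :]).sum(axis=1)
        I00 = w.sum(axis=1)
        I01 = (w * x[None, :]).sum(axis=1)
        I11 = (w * np.square(x)[None, :]).sum(axis=1)
        det = np.maximum(I00 * I11 - I01 * I01, 1e-300)
        d0 = (I11 * U0 - I01 * U1) / det
        d1 = (I00 * U1 - I01 * U0) / det
        d0 = np.clip(d0, -5, 5)
        d1 = np.clip(d1, -5, 5)
        b0 = np.clip(b0 + d0, -_BETA_MAX, _BETA_MAX)
        b1 = np.clip(b1 + d1, -_BETA_MAX, _BETA_MAX)
        if max(np.abs(d0[nonzero]).max(initial=0.0),
               np.abs(d1[nonzero]).max(initial=0.0)) < tol:
            break

    # expected-information standard error of b1
    eta = b0[:, None] + b1[:, None] * x[None, :]
    mu = s[None, :] * np.exp(np.clip(eta, -_BETA_MAX, _BETA_MAX))
    w = mu / (1.0 + alpha * mu)
    I00 = w.sum(axis=1)
    I01 = (w * x[None, :]).sum(axis=1)
    I11 = (w * np.square(x)[None, :]).sum(axis=1)
    det = np.maximum(I00 * I11 - I01 * I01, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(I00 / det)

    lfc = b1 / LN2
    lfc_se = se_b1 / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = b1 / se_b1
    pval = 2.0 * stats.norm.sf(np.abs(stat))

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": np.where(nonzero, lfc, 0.0),
            "lfcSE": np.where(nonzero, lfc_se, np.nan),
            "stat": np.where(nonzero, stat, np.nan),
            "pvalue": np.where(nonzero, pval, np.nan),
        },
        index=counts.index,
    )
    out.index.name = "peak_id"
    return out


def select_differential(
    results: pd.DataFrame,
    settings: DifferentialCallSettings,
    peaks: PeakSet | None = None,
) -> PeakSet | list[str]:
    """Peaks passing the nominal p threshold with the requested
    fold-change sign.  Returns a PeakSet when coordinates are supplied
    (matched by peak id), otherwise the list of selected peak ids."""
    p = results["pvalue"].to_numpy()
    if settings.adjust:
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(p)
        p = p.copy()
        p[finite] = multipletests(p[finite], method="fdr_bh")[1]
    lfc = results["log2FoldChange"].to_numpy()
    keep = np.isfinite(p) & (p < settings.alpha)
    if settings.direction == "enriched-in-target":
        keep &= lfc > 0
    elif settings.direction == "enriched-in-reference":
        keep &= lfc < 0
    ids = [str(i) for i in results.index[keep]]
    if peaks is None:
        return ids
    wanted = set(ids)
    return PeakSet(
        [iv for iv in peaks if iv.id in wanted],
        label=f"differential_p<{settings.alpha}",
    )
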