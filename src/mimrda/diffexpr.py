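"""Two-group differential expression with an empirical-Bayes moderated t.

The engine reproduces the classic microarray-style moderated t-statistic:
per-feature pooled two-group variances are shrunk toward a common prior
variance ``s0^2`` with prior degrees of freedom ``d0``, both estimated by
method-of-moments on the log sample variances. The moderated statistic

    t_g = log_fc_g / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g)

is referred to a t distribution on ``d0 + df_g`` degrees of freedom
(standard normal in the ``d0 = +inf`` limit). Raw p-values are adjusted by
Benjamini-Hochberg, and features with adjusted p below alpha form the DE set.

Only the two-group (tumor vs normal) design is supported; ``log_fc`` is
mean(tumor) - mean(normal) in log2 units.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_formats import (
    DegenerateDataError,
    ExpressionMatrix,
    InsufficientReplicationError,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger("mimrda")


@dataclass(frozen=True)
class PriorEstimate:
    """Empirical-Bayes prior: ``d0`` degrees of freedom, ``s0_sq`` variance.

    ``d0`` may be ``math.inf`` when the observed spread of log variances does
    not exceed what pure sampling noise would produce.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError(f"d0 must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValidationError(f"s0_sq must be > 0, got {self.s0_sq}")


def fit_two_group(expr: ExpressionMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Per-feature two-group summary: log_fc, pooled variance, residual df.

    Returns a DataFrame indexed by feature_id with columns ``log_fc``
    (mean tumor - mean normal), ``s2`` (pooled within-group variance on
    ``df_resid = n1 + n2 - 2`` degrees of freedom) and ``df_resid``.
    """
    tumor = [s for s in meta.samples_in("tumor") if s in expr.data.columns]
    normal = [s for s in meta.samples_in("normal") if s in expr.data.columns]
    n1, n2 = len(tumor), len(normal)
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per group, got tumor={n1}, normal={n2}")
    xt = expr.data[tumor].to_numpy()
    xn = expr.data[normal].to_numpy()
    log_fc = xt.mean(axis=1) - xn.mean(axis=1)
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((xn - xn.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    return pd.DataFrame(
        {"log_fc": log_fc, "s2": s2, "df_resid": df_resid},
        index=pd.Index(expr.feature_ids, name="feature_id"),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e12
    # trigamma(x) ~ 1/x**2 (x->0), ~ 1/x (x->inf): bracket is always valid
    return optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi,
                           xtol=1e-12, rtol=1e-14)


def estimate_prior(s2: np.ndarray, df_resid: np.ndarray) -> PriorEstimate:
    """Method-of-moments fit of the variance prior on log sample variances.

    Under the scaled-F model s2_g ~ s0^2 F(df_g, d0),

        e_g = log s2_g - digamma(df_g/2) + log(df_g/2)

    has mean ``log s0^2 - digamma(d0/2) + log(d0/2)`` and variance
    ``trigamma(df_g/2) + trigamma(d0/2)``; matching the sample mean and
    variance of e yields (d0, s0_sq). If the excess variance is nonpositive,
    d0 = +inf and s0_sq is the bias-corrected geometric mean of s2.

    Zero variances are excluded from moment matching (their count is logged).
    """
    s2 = np.asarray(s2, dtype=float)
    df_resid = np.broadcast_to(np.asarray(df_resid, dtype=float), s2.shape)
    ok = (s2 > 0) & (df_resid >= 1)
    n_zero = int((s2 <= 0).sum())
    if n_zero:
        logger.info("estimate_prior: excluding %d zero variances", n_zero)
    if not ok.any():
        raise DegenerateDataError("all variances are zero")
    if ok.sum() < 10:
        raise ValidationError(
            f"need >=10 features with positive variance, got {int(ok.sum())}")
    s2u, dfu = s2[ok], df_resid[ok]
    e = np.log(s2u) - special.digamma(dfu / 2) + np.log(dfu / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, dfu / 2).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2) - math.log(d0 / 2))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return PriorEstimate(d0=d0, s0_sq=s0_sq)


def moderated_t(fits: pd.DataFrame, prior: PriorEstimate | None,
                n1: int, n2: int) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values for two-group fits.

    ``prior=None`` (or d0 = 0 via config) gives the ordinary pooled two-sample
    t-test; ``d0 = +inf`` gives the normal-limit z-test against s0^2.

    Returns the input columns plus ``t_mod``, ``df_total``, ``p_raw`` and
    ``p_adj`` (Benjamini-Hochberg).
    """
    d0 = 0.0 if prior is None else prior.d0
    s0_sq = 0.0 if prior is None else prior.s0_sq
    log_fc = fits["log_fc"].to_numpy(dtype=float)
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df_resid"].to_numpy(dtype=float)
    c_se = math.sqrt(1.0 / n1 + 1.0 / n2)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / (np.sqrt(s2_post) * c_se)
    zero_fc = log_fc == 0
    t_mod[zero_fc] = 0.0
    degenerate = (s2_post == 0) & ~zero_fc
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero moderated variance "
            "and nonzero log_fc: exact separation, p_raw set to 0",
            RuntimeWarning, stacklevel=2)

    if math.isinf(d0):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw[zero_fc] = 1.0
    p_raw[degenerate] = 0.0

    out = fits.copy()
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p_raw"] = p_raw
    out["p_adj"] = bh_adjust(p_raw)
    return out


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1 and mapped back to the input order.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(stepped[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def select_de(fits: pd.DataFrame, alpha: float = 0.01) -> set[str]:
    """Features with BH-adjusted p below alpha — the DE set."""
    return set(fits.index[fits["p_adj"] < alpha])


def run_de(expr: ExpressionMatrix, meta: SampleMetadata,
           alpha: float = 0.01, ordinary_t: bool = False) -> pd.DataFrame:
    """Full DE pass: fit, prior, moderated t, BH, DE call.

    Returns a DataFrame with log_fc, s2, df_resid, t_mod, df_total, p_raw,
    p_adj and a boolean ``is_de`` column.
    """
    fits = fit_two_group(expr, meta)
    n1 = len([s for s in meta.samples_in("tumor") if s in expr.data.columns])
    n2 = len([s for s in meta.samples_in("normal") if s in expr.data.columns])
    prior = None
    if not ordinary_t:
        prior = estimate_prior(fits["s2"].to_numpy(), fits["df_resid"].to_numpy())
        logger.info("%s prior: d0=%.4g s0_sq=%.4g", expr.feature_kind,
                    prior.d0, prior.s0_sq)
    result = moderated_t(fits, prior, n1, n2)
    result["is_de"] = result["p_adj"] < alpha
    logger.info("%s DE at alpha=%g: %d / %d features", expr.feature_kind,
                alpha, int(result["is_de"].sum()), len(result))
    return result
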