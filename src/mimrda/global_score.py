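"""Fisher's-product combination of P_NDE and P_miRNA into the global P_G.

A miRNA is interesting when its own expression shifts AND its validated
targets are over-represented among the DE mRNAs. The two evidence streams
are combined through the product c = P_NDE * P_miRNA; because the product of
two independent Uniform(0,1) p-values has CDF

    P(U1 U2 <= c) = c (1 - ln c),

the global probability is P_G = c(1 - ln c), itself a p-value under the
joint null. P_G is Benjamini-Hochberg adjusted across miRNAs (once — the
component p-values enter raw) and miRNAs are ranked by ascending P_G.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust
from .io_formats import ValidationError

logger = logging.getLogger("mimrda")


def fisher_combine(p_nde, p_mirna):
    """Combine two p-values: c = p_nde * p_mirna, P_G = c(1 - ln c).

    Accepts scalars or arrays; the product is formed in log space so that
    extremely small components do not underflow before the correction term
    is applied. c = 0 maps to P_G = 0 (with a warning).
    """
    p1 = np.asarray(p_nde, dtype=float)
    p2 = np.asarray(p_mirna, dtype=float)
    scalar = p1.ndim == 0 and p2.ndim == 0
    p1, p2 = np.atleast_1d(p1), np.atleast_1d(p2)
    if ((p1 < 0) | (p1 > 1)).any() or ((p2 < 0) | (p2 > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.zeros(np.broadcast_shapes(p1.shape, p2.shape), dtype=float)
    zero = (p1 == 0) | (p2 == 0)
    if zero.any():
        warnings.warn("zero p-value in Fisher combination: P_G set to 0",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore"):
        log_c = np.where(zero, -np.inf, np.log(p1) + np.log(p2))
    nz = ~zero
    # c*(1 - ln c) = exp(log c + log1p(-log c)); log c <= 0 keeps the
    # argument of log1p nonnegative
    out[nz] = np.exp(log_c[nz] + np.log1p(-log_c[nz]))
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def score_all(mirna_fits: pd.DataFrame, ora: pd.DataFrame,
              prefilter_de_mirnas: bool = False,
              alpha_mirna: float = 0.01) -> pd.DataFrame:
    """Join miRNA DE results with ORA results into a ranked score table.

    ``mirna_fits`` is the moderated-t result for measured miRNAs (indexed by
    feature_id, with p_raw and log_fc); ``ora`` the ORA table indexed by
    mirna_id. Every measured miRNA is scored: those absent from the
    interaction table get p_nde = 1 and a ``no_interactions`` flag. p_mirna
    is the RAW moderated-t p-value; FDR control is applied once, to P_G.

    ``prefilter_de_mirnas=True`` restricts scoring to miRNAs whose DE
    BH-adjusted p-value is below ``alpha_mirna``.
    """
    fits = mirna_fits
    if prefilter_de_mirnas:
        fits = fits[fits["p_adj"] < alpha_mirna]
    if len(fits) == 0:
        raise ValidationError("no miRNAs to score after joining/prefiltering")

    table = pd.DataFrame({
        "mirna_id": fits.index,
        "p_mirna": fits["p_raw"].to_numpy(),
        "log_fc": fits["log_fc"].to_numpy(),
    }).set_index("mirna_id")
    joined = table.join(ora[["m", "x", "p_nde", "flags"]], how="left")
    absent = joined["p_nde"].isna()
    joined.loc[absent, ["m", "x"]] = 0
    joined.loc[absent, "p_nde"] = 1.0
    joined.loc[absent, "flags"] = "no_interactions"
    joined[["m", "x"]] = joined[["m", "x"]].astype(int)

    joined["c"] = joined["p_nde"].to_numpy() * joined["p_mirna"].to_numpy()
    joined["p_g"] = fisher_combine(joined["p_nde"].to_numpy(),
                                   joined["p_mirna"].to_numpy())
    joined["p_g_fdr"] = bh_adjust(joined["p_g"].to_numpy())
    return rank_mirnas(joined)


def rank_mirnas(scores: pd.DataFrame) -> pd.DataFrame:
    """Order by ascending p_g; ties by p_nde, then p_mirna, then mirna_id.

    Assigns a dense ``rank`` column 1..n and returns the table in rank order
    with mirna_id as a regular column.
    """
    out = scores.reset_index()
    out = out.sort_values(
        ["p_g", "p_nde", "p_mirna", "mirna_id"],
        kind="mergesort",  # stable, so the lexicographic fallback holds
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
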