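"""Hypergeometric over-representation of miRNA target sets among DE mRNAs.

For each miRNA i with ``m`` validated targets inside a universe of ``M``
mRNAs, of which ``k`` are differentially expressed, the probability of seeing
``x`` or more DE targets by chance is the hypergeometric upper tail

    P_NDE(i) = sum_{j >= x} C(m, j) C(M - m, k - j) / C(M, k).

The universe is, by default, the intersection of the interaction table's
mRNAs with the measured mRNAs, so the sampling model matches the genes the
DE test actually saw; ``interaction_table`` mode uses every mRNA in the
table. ``N``, the dataset-wide DE_mRNA count, is carried as reported
metadata only — it does not enter the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import InteractionTable, ValidationError

logger = logging.getLogger("mimrda")

UNIVERSE_MODES = ("interaction_table", "measured_intersection")


@dataclass(frozen=True)
class Universe:
    """The mRNA background set of size M over which ORA is defined."""

    mrna_ids: frozenset[str]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in UNIVERSE_MODES:
            raise ValidationError(f"unknown universe mode {self.mode!r}")
        if not self.mrna_ids:
            raise ValidationError("universe is empty")

    def __len__(self) -> int:
        return len(self.mrna_ids)


def build_universe(interactions: InteractionTable, measured_mrnas: set[str],
                   mode: str = "measured_intersection") -> Universe:
    """Construct the ORA universe from the interaction table.

    ``measured_intersection`` (default): targeted mRNAs that are also
    measured in the expression matrix. ``interaction_table``: every mRNA in
    the table, matching a literal all-of-the-database background.
    """
    if not len(interactions):
        raise ValidationError("interaction table is empty")
    table_mrnas = interactions.mrnas
    if mode == "measured_intersection":
        ids = table_mrnas & set(measured_mrnas)
    elif mode == "interaction_table":
        ids = table_mrnas
    else:
        raise ValidationError(f"unknown universe mode {mode!r}")
    if not ids:
        raise ValidationError(
            "universe is empty (no overlap between targeted and measured mRNAs)")
    logger.info("universe (%s): M=%d", mode, len(ids))
    return Universe(mrna_ids=frozenset(ids), mode=mode)


def hypergeom_sf(M: int, k: int, m: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts DE genes in a size-m target set when k of the M universe genes
    are DE. ``x = 0`` returns exactly 1.
    """
    M, k, m, x = int(M), int(k), int(m), int(x)
    if m > M or k > M:
        raise ValidationError(f"m={m} and k={k} must not exceed M={M}")
    if x < 0 or x > min(m, k):
        raise ValidationError(f"x={x} outside [0, min(m={m}, k={k})]")
    if x == 0:
        return 1.0
    # scipy's sf is P(X > x-1) = P(X >= x)
    return float(stats.hypergeom.sf(x - 1, M, m, k))


def run_ora(interactions: InteractionTable, de_mrnas: set[str],
            universe: Universe, n_total_de: int | None = None,
            min_targets: int = 1) -> pd.DataFrame:
    """ORA over every miRNA in the interaction table.

    Returns a DataFrame indexed by mirna_id (sorted) with columns
    m, x, k, M, N, p_nde and flags. miRNAs whose universe-restricted target
    set is smaller than ``min_targets`` (including m = 0) get p_nde = 1 and a
    ``no_targets``/``below_min_targets`` flag rather than being dropped, so
    every miRNA can still receive a global score.
    """
    if not len(interactions):
        raise ValidationError("interaction table is empty")
    uni = set(universe.mrna_ids)
    M = len(uni)
    de_in_universe = set(de_mrnas) & uni
    k = len(de_in_universe)
    N = len(de_mrnas) if n_total_de is None else int(n_total_de)
    logger.info("ORA: M=%d k=%d N=%d", M, k, N)

    rows = []
    for mirna_id, targets in sorted(interactions.target_map().items()):
        t_in_uni = targets & uni
        m = len(t_in_uni)
        x = len(t_in_uni & de_in_universe)
        if m == 0:
            rows.append((mirna_id, 0, 0, k, M, N, 1.0, "no_targets"))
        elif m < min_targets:
            rows.append((mirna_id, m, x, k, M, N, 1.0, "below_min_targets"))
        else:
            rows.append((mirna_id, m, x, k, M, N, hypergeom_sf(M, k, m, x), ""))
    out = pd.DataFrame(
        rows, columns=["mirna_id", "m", "x", "k", "M", "N", "p_nde", "flags"],
    ).set_index("mirna_id")
    return out
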