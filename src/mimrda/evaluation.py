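"""Verification machinery for ranked miRNA lists.

Four procedures, mirroring how a claimed disease-miRNA ranking is typically
checked:

* **label overlap** — percentage of the top-k ranked miRNAs found in a
  curated disease-association label set;
* **ranking comparison** — labeled-miRNA counts in the top-n of the combined
  P_G ranking vs its two components (P_miRNA alone, P_NDE alone);
* **survival verification** — per-miRNA median split of expression into
  high/low groups, Kaplan-Meier curves, log-rank test and an O/E-based
  hazard ratio;
* **random-forest simulation** — stratified 5-fold cross-validated AUC of a
  random-forest classifier restricted to the top-k miRNAs, compared against
  random size-k feature sets by a rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io_formats import (
    DegenerateDataError,
    ExpressionMatrix,
    LabelSet,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger("mimrda")


@dataclass(frozen=True)
class SurvivalResult:
    """Median-split survival verdict for one miRNA."""

    mirna_id: str
    hr: float            # hazard ratio, high- vs low-expression group
    logrank_chi2: float
    logrank_p: float
    n_high: int
    n_low: int


@dataclass(frozen=True)
class AUCComparison:
    """Rank-sum comparison of per-repetition AUCs, top-k vs random-k."""

    auc_top: np.ndarray
    auc_random: np.ndarray
    p_value: float
    n_reps: int
    k: int


# ---------------------------------------------------------------------------
# label-overlap evaluation

def topk_overlap_percentage(ranked_mirnas: list[str], labels: LabelSet,
                            k: int) -> float:
    """100 * |top-k of the ranking ∩ labels| / k."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(ranked_mirnas):
        raise ValidationError(f"k={k} exceeds ranking length {len(ranked_mirnas)}")
    top = set(ranked_mirnas[:k])
    return 100.0 * len(top & labels.mirna_ids) / k


def compare_rankings(scores_pg: list[str], scores_pmirna: list[str],
                     scores_pnde: list[str], labels: LabelSet,
                     n: int = 100) -> dict[str, int]:
    """Labeled-miRNA count in the top-n of each of the three rankings.

    The three rankings must cover the same miRNA set; the more labeled
    (known disease-associated) miRNAs a method places in its top-n, the
    better it performs.
    """
    sets = [set(scores_pg), set(scores_pmirna), set(scores_pnde)]
    if not (sets[0] == sets[1] == sets[2]):
        raise ValidationError("the three rankings must cover the same miRNAs")
    n = min(n, len(scores_pg))
    return {
        "p_g": len(set(scores_pg[:n]) & labels.mirna_ids),
        "p_mirna": len(set(scores_pmirna[:n]) & labels.mirna_ids),
        "p_nde": len(set(scores_pnde[:n]) & labels.mirna_ids),
    }


# ---------------------------------------------------------------------------
# survival verification

def median_split(values: pd.Series) -> pd.Series:
    """Label samples 'high' (value > median) or 'low' (value <= median)."""
    if len(values) < 4:
        raise ValidationError("median split needs >=4 samples")
    if values.nunique() == 1:
        raise DegenerateDataError("all expression values identical; no split")
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)


def km_curve(times, events) -> pd.Series:
    """Kaplan-Meier product-limit survival estimate S(t).

    Returns a Series of survival probabilities indexed by time (step
    function; censored subjects shrink the risk set without a step).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    sf.index.name = "time"
    return sf


def logrank_test(times_high, events_high, times_low, events_low,
                 ) -> tuple[float, float, float]:
    """Two-group log-rank test with an O/E hazard-ratio estimate.

    Returns (chi2, p, hr) where hr = (O_h/E_h) / (O_l/E_l) with observed and
    expected event counts accumulated over the shared event times; tied
    event times use the standard hypergeometric variance term.
    """
    t1 = np.asarray(times_high, dtype=float)
    e1 = np.asarray(events_high, dtype=bool)
    t2 = np.asarray(times_low, dtype=float)
    e2 = np.asarray(events_low, dtype=bool)
    if t1.size == 0 or t2.size == 0:
        raise ValidationError("both groups must be nonempty")
    if not (e1.any() or e2.any()):
        raise DegenerateDataError("no events observed; log-rank undefined")

    event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    O1 = E1 = O2 = E2 = V = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        d1 = float(((t1 == t) & e1).sum())
        d2 = float(((t2 == t) & e2).sum())
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        O1 += d1
        O2 += d2
        E1 += d * n1 / n
        E2 += d * n2 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    if O1 == 0 or O2 == 0 or E1 == 0 or E2 == 0:
        hr = np.inf if (O1 > 0 and O2 == 0) else (0.0 if O1 == 0 and O2 > 0
                                                  else 1.0)
    else:
        hr = (O1 / E1) / (O2 / E2)
    return chi2, p, hr


def survival_for_mirna(mirna_id: str, mirna_expr: ExpressionMatrix,
                       meta: SampleMetadata) -> SurvivalResult:
    """Median-split KM verification of one miRNA against overall survival."""
    if not meta.has_survival:
        raise ValidationError("metadata carries no survival information")
    samples = [s for s in meta.sample_ids if s in mirna_expr.data.columns]
    values = mirna_expr.data.loc[mirna_id, samples]
    split = median_split(values)
    tab = meta.table.loc[samples]
    high_idx = split.index[split == "high"]
    low_idx = split.index[split == "low"]
    chi2, p, hr = logrank_test(
        tab.loc[high_idx, "time"], tab.loc[high_idx, "event"],
        tab.loc[low_idx, "time"], tab.loc[low_idx, "event"])
    return SurvivalResult(mirna_id=mirna_id, hr=hr, logrank_chi2=chi2,
                          logrank_p=p, n_high=len(high_idx),
                          n_low=len(low_idx))


def survival_table(mirna_ids: list[str], mirna_expr: ExpressionMatrix,
                   meta: SampleMetadata) -> pd.DataFrame:
    """Survival verification for a list of miRNAs, as a DataFrame."""
    rows = [survival_for_mirna(m, mirna_expr, meta) for m in mirna_ids]
    return pd.DataFrame(
        [(r.mirna_id, r.hr, r.logrank_chi2, r.logrank_p, r.n_high, r.n_low)
         for r in rows],
        columns=["mirna_id", "hr", "logrank_chi2", "logrank_p",
                 "n_high", "n_low"],
    )


# ---------------------------------------------------------------------------
# random-forest simulation test

def rf_evaluate(mirna_expr: ExpressionMatrix, meta: SampleMetadata,
                feature_ids: list[str], folds: int = 5, n_reps: int = 200,
                seed: int = 0, n_estimators: int = 100) -> np.ndarray:
    """Cross-validated AUCs of a random forest restricted to feature_ids.

    Per repetition: a fresh stratified ``folds``-fold split (4:1 train:test
    at the default 5 folds), out-of-fold class probabilities from a random
    forest, one pooled AUC. Returns the array of ``n_reps`` AUCs; fully
    deterministic given the seed.
    """
    missing = [f for f in feature_ids if f not in mirna_expr.data.index]
    if missing:
        raise ValidationError(f"features not measured: {missing[:5]}")
    samples = [s for s in meta.sample_ids if s in mirna_expr.data.columns]
    X = mirna_expr.data.loc[feature_ids, samples].to_numpy().T
    y = (meta.table.loc[samples, "group"] == "tumor").to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"smallest class has {counts.min()} samples < {folds} folds")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_reps)
    for rep in range(n_reps):
        rs = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        prob = np.empty(len(y))
        for train, test in skf.split(X, y):
            clf = RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=rs)
            clf.fit(X[train], y[train])
            prob[test] = clf.predict_proba(X[test])[:, 1]
        aucs[rep] = roc_auc_score(y, prob)
    return aucs


def compare_auc(auc_top: np.ndarray, auc_random: np.ndarray,
                k: int = 0) -> AUCComparison:
    """Two-sided rank-sum comparison of two AUC samples."""
    auc_top = np.asarray(auc_top, dtype=float)
    auc_random = np.asarray(auc_random, dtype=float)
    if auc_top.shape != auc_random.shape:
        raise ValidationError("AUC lists must have equal length")
    if np.array_equal(auc_top, auc_random):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(auc_top, auc_random,
                                     alternative="two-sided").pvalue)
    return AUCComparison(auc_top=auc_top, auc_random=auc_random,
                         p_value=p, n_reps=len(auc_top), k=k)
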