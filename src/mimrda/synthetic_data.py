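"""Seeded generators emulating the data the ranking method consumes.

Three ingredients are simulated so every pipeline stage is testable without
external downloads:

* **expression** — log2-scale matrices with Normal(8, 2) per-feature baseline
  means, Normal(0, sigma) noise, and a planted fraction of DE features that
  gain ``effect_size`` in tumor samples;
* **interactions** — a bipartite miRNA->mRNA network with negative-binomial
  target-set sizes (mimicking the long-tailed degree distribution of curated
  target databases), optionally rewired so that designated "disease" miRNAs
  have a fraction ``enrichment_rho`` of their targets inside the planted DE
  mRNA set, degrees preserved;
* **survival** — exponential event times with a group-dependent hazard ratio
  and independent uniform censoring calibrated to a requested censoring rate.

Expression and network enrichment are planted independently: the simulator
does not model miRNA->mRNA repression coupling. Every generator is a pure
function of its parameters and an integer seed; a single master seed fans
out to per-component seeds through fixed offsets (see ``simulate_dataset``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import (
    ExpressionMatrix,
    InteractionTable,
    SampleMetadata,
    ValidationError,
)

_SEED_MOD = 2**31

# Offsets for fanning a master seed out to independent component streams.
SEED_OFFSETS = {
    "mrna_expression": 1,
    "mirna_expression": 2,
    "interactions": 3,
    "planting": 4,
    "survival": 5,
}


def subseed(seed: int, component: str) -> int:
    """Per-component seed derived from the master seed by a fixed offset."""
    return (int(seed) * 1_000_003 + SEED_OFFSETS[component]) % _SEED_MOD


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generators.

    ``disease_mirnas`` are the miRNAs that are both differentially expressed
    and have target sets enriched in the planted DE mRNAs — the entities the
    ranking method is supposed to surface. Always a subset of ``de_mirnas``.
    """

    de_mrnas: frozenset[str]
    de_mirnas: frozenset[str]
    disease_mirnas: frozenset[str]
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.disease_mirnas <= self.de_mirnas:
            raise ValidationError("disease miRNAs must be a subset of DE miRNAs")


@dataclass(frozen=True)
class SyntheticParams:
    """Desk-scale preset emulating a TCGA-like tumor/normal study.

    Sized so the full pipeline runs in seconds while leaving power headroom:
    2,000 mRNAs and 300 miRNAs over 30+30 samples, 10% DE features with a
    1.5 log2-unit shift over unit noise, mean target-set size 40, and 20
    disease miRNAs with 40% of their targets rewired into the DE mRNA set.
    """

    n_mrna: int = 2000
    n_mirna: int = 300
    n_tumor: int = 30
    n_normal: int = 30
    de_fraction: float = 0.1
    effect_size: float = 1.5
    sigma: float = 1.0
    mean_degree: float = 40.0
    degree_dispersion: float = 0.3
    n_disease_mirnas: int = 20
    enrichment_rho: float = 0.4


PRESET = SyntheticParams()


def simulate_expression(n_features: int, n_tumor: int, n_normal: int,
                        de_fraction: float, effect_size: float, sigma: float,
                        seed: int, feature_kind: str = "mRNA",
                        prefix: str | None = None,
                        ) -> tuple[ExpressionMatrix, SampleMetadata, frozenset[str]]:
    """Log2-scale expression with a planted DE fraction.

    Baseline per-feature means ~ Normal(8, 2); i.i.d. Normal(0, sigma) noise;
    the first round(de_fraction * n_features) features (after a seeded
    shuffle of identities the planted set is still deterministic) receive
    +effect_size in tumor samples. Returns the matrix, the tumor/normal
    metadata and the planted DE feature set.
    """
    if n_tumor < 2 or n_normal < 2:
        raise ValidationError("need >=2 samples per group")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValidationError("de_fraction must lie in [0, 1]")
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    rng = np.random.default_rng(seed)
    prefix = prefix or ("mir" if feature_kind == "miRNA" else "gene")
    features = [f"{prefix}{i:05d}" for i in range(n_features)]
    samples = [f"T{i:03d}" for i in range(n_tumor)] + \
              [f"N{i:03d}" for i in range(n_normal)]
    baseline = rng.normal(8.0, 2.0, size=n_features)
    values = baseline[:, None] + rng.normal(0.0, sigma, size=(n_features,
                                                              n_tumor + n_normal))
    n_de = int(round(de_fraction * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    values[np.ix_(de_idx, np.arange(n_tumor))] += effect_size
    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=features, columns=samples),
        feature_kind=feature_kind,
    )
    meta = SampleMetadata(table=pd.DataFrame(
        {"group": ["tumor"] * n_tumor + ["normal"] * n_normal},
        index=pd.Index(samples, name="sample_id"),
    ))
    return expr, meta, frozenset(features[i] for i in de_idx)


def _draw_degrees(rng: np.random.Generator, n: int, mean_degree: float,
                  dispersion: float, n_mrna: int) -> np.ndarray:
    """Negative-binomial degrees (var = mu + dispersion*mu^2); dispersion 0
    gives the degenerate constant round(mean_degree)."""
    if dispersion == 0:
        deg = np.full(n, int(round(mean_degree)))
    else:
        # NB with mean mu and size r = 1/dispersion
        r = 1.0 / dispersion
        p = r / (r + mean_degree)
        deg = rng.negative_binomial(r, p, size=n)
    return np.clip(deg, 1, n_mrna)


def simulate_interactions(n_mirna: int, n_mrna: int, mean_degree: float,
                          degree_dispersion: float, seed: int,
                          mirna_ids: list[str] | None = None,
                          mrna_ids: list[str] | None = None) -> InteractionTable:
    """Bipartite validated-target network with long-tailed degrees.

    Each miRNA's target-set size is drawn from a negative binomial around
    ``mean_degree`` (zero dispersion: exactly round(mean_degree)); targets
    are sampled uniformly without replacement, so there are no duplicate
    pairs.
    """
    if n_mirna < 1 or n_mrna < 1:
        raise ValidationError("need at least one miRNA and one mRNA")
    if mean_degree > n_mrna:
        raise ValidationError(
            f"mean_degree {mean_degree} exceeds number of mRNAs {n_mrna}")
    rng = np.random.default_rng(seed)
    mirna_ids = mirna_ids or [f"mir{i:05d}" for i in range(n_mirna)]
    mrna_ids = mrna_ids or [f"gene{i:05d}" for i in range(n_mrna)]
    mrna_arr = np.asarray(mrna_ids, dtype=object)
    degrees = _draw_degrees(rng, n_mirna, mean_degree, degree_dispersion, n_mrna)
    pairs = set()
    for mirna, deg in zip(mirna_ids, degrees):
        targets = rng.choice(n_mrna, size=int(deg), replace=False)
        pairs.update((mirna, mrna_arr[t]) for t in targets)
    return InteractionTable(pairs=frozenset(pairs))


def plant_disease_mirnas(interactions: InteractionTable, de_mrnas: set[str],
                         disease_mirnas: set[str], enrichment_rho: float,
                         seed: int, mrna_pool: set[str] | None = None,
                         ) -> InteractionTable:
    """Rewire disease miRNAs so ~rho of their targets are DE mRNAs.

    For each disease miRNA with degree m, round(rho*m) targets are forced
    into ``de_mrnas`` (existing DE targets kept, extra ones sampled without
    replacement); an equal number of non-DE targets is dropped so every
    miRNA keeps its degree. Other miRNAs are untouched. rho = 0 returns the
    table unchanged.
    """
    if not 0.0 <= enrichment_rho <= 1.0:
        raise ValidationError("enrichment_rho must lie in [0, 1]")
    if enrichment_rho == 0 or not disease_mirnas:
        return interactions
    rng = np.random.default_rng(seed)
    de_sorted = sorted(de_mrnas)
    target_map = interactions.target_map()
    pairs = set(interactions.pairs)
    for mirna in sorted(disease_mirnas):
        targets = target_map.get(mirna, set())
        m = len(targets)
        want_de = int(round(enrichment_rho * m))
        if want_de > len(de_mrnas):
            raise ValidationError(
                f"{mirna}: needs {want_de} DE targets but only "
                f"{len(de_mrnas)} DE mRNAs exist")
        have_de = targets & de_mrnas
        n_add = want_de - len(have_de)
        if n_add <= 0:
            continue
        candidates = [g for g in de_sorted if g not in targets]
        if n_add > len(candidates):
            raise ValidationError(
                f"{mirna}: cannot reach rho={enrichment_rho} without duplicates")
        added = rng.choice(len(candidates), size=n_add, replace=False)
        non_de = sorted(targets - de_mrnas)
        dropped = rng.choice(len(non_de), size=n_add, replace=False)
        for a, d in zip(added, dropped):
            pairs.add((mirna, candidates[a]))
            pairs.discard((mirna, non_de[d]))
    return InteractionTable(pairs=frozenset(pairs))


def simulate_survival(n: int, hr: float, median_low_group: float,
                      censor_rate: float, seed: int,
                      sample_ids: list[str] | None = None,
                      groups: list[str] | None = None) -> SampleMetadata:
    """Exponential survival with a hazard ratio between two groups.

    The "low" half has hazard ln2 / median_low_group; the "high" half has
    hazard hr times that. Censoring times are Uniform(0, tau) with tau
    solved numerically so the expected censored fraction matches
    ``censor_rate`` (0 disables censoring). ``groups`` entries, if supplied,
    must be "high"/"low"; by default the first half is high.

    Group labels are stored in a ``split`` column; a ``group`` column of
    all-"tumor" is included so the result is a valid SampleMetadata.
    """
    if hr <= 0:
        raise ValidationError("hazard ratio must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must lie in [0, 1)")
    if median_low_group <= 0:
        raise ValidationError("median_low_group must be positive")
    rng = np.random.default_rng(seed)
    sample_ids = sample_ids or [f"S{i:04d}" for i in range(n)]
    if groups is None:
        groups = ["high"] * (n // 2) + ["low"] * (n - n // 2)
    if len(groups) != n or set(groups) - {"high", "low"}:
        raise ValidationError("groups must be n 'high'/'low' labels")
    lam_low = math.log(2.0) / median_low_group
    lam = np.where(np.asarray(groups) == "high", hr * lam_low, lam_low)
    times = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        lam_bar = np.mean(lam)

        def censored_frac(tau: float) -> float:
            # P(T > C), C ~ U(0, tau), averaged over the two hazards
            lams = np.array([hr * lam_low, lam_low])
            w = np.array([np.mean(np.asarray(groups) == "high"),
                          np.mean(np.asarray(groups) == "low")])
            return float(np.sum(w * (1 - np.exp(-lams * tau)) / (lams * tau)))

        hi = 1.0 / lam_bar
        while censored_frac(hi) > censor_rate:
            hi *= 2.0
        tau = optimize.brentq(lambda t: censored_frac(t) - censor_rate,
                              1e-9 / lam_bar, hi)
        cens = rng.uniform(0.0, tau, size=n)
        event = times <= cens
        obs = np.minimum(times, cens)
    else:
        event = np.ones(n, dtype=bool)
        obs = times
    return SampleMetadata(table=pd.DataFrame(
        {"group": "tumor", "split": groups, "time": obs, "event": event},
        index=pd.Index(sample_ids, name="sample_id"),
    ))


def simulate_dataset(params: SyntheticParams = PRESET, seed: int = 0,
                     ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                SampleMetadata, InteractionTable, SyntheticTruth]:
    """Generate a full coherent study: mRNA + miRNA expression, metadata,
    interaction network with planted disease miRNAs, and the truth record.

    The disease miRNAs are a seeded subset of the planted DE miRNAs whose
    target sets are then rewired toward the planted DE mRNAs.
    """
    p = params
    mrna_expr, meta, de_mrnas = simulate_expression(
        p.n_mrna, p.n_tumor, p.n_normal, p.de_fraction, p.effect_size,
        p.sigma, subseed(seed, "mrna_expression"), feature_kind="mRNA")
    mirna_expr, _, de_mirnas = simulate_expression(
        p.n_mirna, p.n_tumor, p.n_normal, p.de_fraction, p.effect_size,
        p.sigma, subseed(seed, "mirna_expression"), feature_kind="miRNA")
    if p.n_disease_mirnas > len(de_mirnas):
        raise ValidationError(
            f"n_disease_mirnas={p.n_disease_mirnas} exceeds planted DE "
            f"miRNAs ({len(de_mirnas)})")
    rng = np.random.default_rng(subseed(seed, "planting"))
    de_list = sorted(de_mirnas)
    disease = frozenset(
        de_list[i] for i in rng.choice(len(de_list), size=p.n_disease_mirnas,
                                       replace=False))
    interactions = simulate_interactions(
        p.n_mirna, p.n_mrna, p.mean_degree, p.degree_dispersion,
        subseed(seed, "interactions"),
        mirna_ids=mirna_expr.feature_ids, mrna_ids=mrna_expr.feature_ids)
    interactions = plant_disease_mirnas(
        interactions, set(de_mrnas), set(disease), p.enrichment_rho,
        subseed(seed, "planting"))
    truth = SyntheticTruth(de_mrnas=de_mrnas, de_mirnas=de_mirnas,
                           disease_mirnas=disease, seed=seed,
                           params=asdict(p))
    return mrna_expr, mirna_expr, meta, interactions, truth
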