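# Methods

## The ranking model

A miRNA is a plausible disease driver when two weakly coupled observations
coincide: its own abundance shifts between tumor and normal tissue, and the
mRNAs it is known to repress are themselves over-represented among the
differentially expressed (DE) mRNAs. `mimrda` scores each of these with a
p-value and combines them.

### Differential expression (P_miRNA, and the DE mRNA call)

Both expression matrices are assumed to be on the log2 scale (a
`--log2-transform` flag applies log2(x+1) for raw counts; normalization
beyond that is the user's responsibility). Only the two-group tumor/normal
design is supported — no covariates, pairing, or precision weights.

Per feature g the two-group fit gives logFC_g = mean(tumor) − mean(normal),
the pooled within-group variance s²_g on df = n₁+n₂−2 degrees of freedom.
An inverse-chi-square prior on the true variances (parameters d₀, s₀²) is
estimated by method of moments on e_g = log s²_g − ψ(df/2) + log(df/2):
the excess of var(e) over the sampling term ψ′(df/2) identifies d₀ via the
inverse trigamma (solved by bisection to 1e-12), and mean(e) then
identifies s₀². If the observed spread does not exceed sampling noise, d₀
is +∞ and the moderated test becomes a z-test against s₀². Features with
s² = 0 are excluded from moment matching but still scored. The moderated
statistic uses s̃² = (d₀s₀² + df·s²)/(d₀+df) on d₀+df total degrees of
freedom. Setting d₀ = 0 (the `ordinary_t` config flag) reproduces the
classical pooled t-test exactly, which the tests exploit as an oracle; the
full procedure is cross-checked against the R limma package on a small
fixture.

DE mRNAs and DE miRNAs are features with Benjamini-Hochberg adjusted
p < 0.01 (defaults `alpha_mrna`, `alpha_mirna`). BH is implemented as the
literal step-up adj_(i) = min_{j≥i} p_(j)·m/j so that it agrees bit-for-bit
with an independent brute-force implementation.

Degenerate cases: logFC = 0 gives t = 0, p = 1 regardless of variance;
s̃² = 0 with logFC ≠ 0 is exact separation and yields p = 0 with a runtime
warning.

### Target-set over-representation (P_NDE)

The universe defaults to `measured_intersection` — mRNAs that appear in the
interaction table *and* in the mRNA expression matrix — so the
hypergeometric sampling model is defined over genes the DE test could
actually have called. `interaction_table` mode (all mRNAs in the table) is
available for a literal database-wide background. With universe size M,
k DE genes in the universe, m targets of miRNA i in the universe and x DE
targets, P_NDE is the hypergeometric upper tail at x; x = 0 returns exactly
1. x counts distinct genes (duplicate interaction records collapse on
read). miRNAs with no targets in the universe are not dropped: they receive
P_NDE = 1 and a `no_targets` flag so that every measured miRNA still gets a
global score. The dataset-wide DE mRNA count N is reported alongside but
does not enter the statistic — the universe-restricted k is the draw count.

### Combination, FDR and ranking (P_G)

c = P_NDE·P_miRNA with P_miRNA taken **raw** (unadjusted); multiplicity is
controlled once, at the P_G level, to avoid double-adjustment. Since
−ln U₁U₂ of two independent uniforms is Gamma(2,1),
P(U₁U₂ ≤ c) = c(1 − ln c); P_G is computed as
exp(log c + log1p(−log c)) so subnormal products do not underflow
prematurely, c = 0 maps to P_G = 0 with a warning. P_G is monotone
increasing in c, so improving either component can never worsen a rank.
Ranking is ascending P_G with deterministic tie-breaks (P_NDE, then
P_miRNA, then lexicographic ID). All measured miRNAs are scored by default;
`prefilter_de_mirnas` optionally restricts to DE miRNAs first — both
readings of the workflow are supported because top-k evaluation needs
scores for many miRNAs.

## Synthetic studies

The generators emulate the statistical structure the method assumes, not
real sequencing noise:

* **Expression** — per-feature baselines ~ Normal(8, 2) on the log2 scale,
  i.i.d. Normal(0, σ) noise, planted DE features gaining `effect_size` in
  tumor. No count-level (negative binomial / library size) effects.
* **Network** — per-miRNA target-set sizes ~ negative binomial
  (var = μ + φμ²; φ = 0 degenerates to a constant degree), targets sampled
  without replacement — a long-tailed degree distribution like curated
  target databases at reduced scale.
* **Planting** — a seeded subset of the DE miRNAs is designated "disease";
  each has round(ρ·m) of its m targets rewired into the DE mRNA set,
  degrees preserved, other miRNAs untouched. Expression and enrichment are
  planted independently: the simulator does not model miRNA→mRNA
  repression, so recovery results demonstrate the statistic's behavior
  under its own model, not biological realism.
* **Survival** — exponential event times with hazard ratio `hr` between
  expression-defined groups, Uniform(0, τ) censoring with τ solved
  numerically to hit the requested censoring fraction.

Preset (the default study conditions): 2,000 mRNAs, 300 miRNAs, 30+30
samples, 10% DE fraction, effect 1.5 log2 units over σ = 1 noise, mean
degree 40 (dispersion 0.3), 20 disease miRNAs, ρ = 0.4 — large enough for
clear power, small enough that a full pipeline run takes well under a
second. One master seed fans out to per-component seeds through fixed
offsets (`subseed`), so components can be regenerated independently; every
generator is a pure function of parameters and seed.

## Verification procedures

* **Label overlap** — 100·|top-k ∩ labels|/k for a curated label set
  (labels are never used in scoring).
* **Ranking comparison** — labeled-miRNA counts in the top-n of the P_G,
  P_miRNA-only and P_NDE-only rankings over the same miRNA set.
* **Survival** — per miRNA, samples are median-split on expression (ties
  at the median go to the low group, a deterministic convention); the
  two groups are compared by the standard log-rank test with the
  hypergeometric variance term for ties, and the hazard ratio is the O/E
  estimator (O_h/E_h)/(O_l/E_l) from the same table — chosen over a Cox
  fit so the HR is paired with the log-rank p without a second model. The
  KM curve itself is delegated to lifelines; the hand-rolled log-rank is
  cross-checked against lifelines in the tests.
* **Random-forest test** — per repetition, stratified 5-fold
  cross-validation (a 4:1 train:test ratio per fold) of a random forest
  restricted to a feature set; one pooled out-of-fold AUC per repetition;
  top-k sets are compared with random size-k sets by a two-sided rank-sum
  test. Under a permutation null, fresh label permutations must be drawn
  per repetition — reusing one permutation pins the AUC to that
  permutation's accidental association.

## Sizes, tolerances and numerical choices

* Exhaustive-enumeration agreement of the hypergeometric tail is checked
  for all (M ≤ 12, k, m, x) at 1e-12 (the enumeration, not scipy, is the
  oracle).
* The Fisher law is checked against Monte-Carlo P(U₁U₂ ≤ c) at
  c ∈ {1e-4, 1e-2, 0.1, 0.5} within 3 Monte-Carlo SE (10⁷ pairs in the
  test suite, 2×10⁶ in the acceptance script).
* Prior recovery simulates the full hierarchical draw
  s² = s₀²·(χ²_df/df)/(χ²_d₀/d₀) (i.e. s₀²·F(df, d₀)) with d₀ = 4,
  s₀² = 0.25, df = 8, 10,000 features; the moment estimator is consistent
  under this model at any df.
* Null calibration pools 200 preset-scale replicates (60,000 p-values)
  with effect 0 and ρ = 0; P_miRNA must reject at 5% within the binomial
  99% band, while P_NDE and P_G — conservative by construction under this
  null (discrete tail; near-empty DE mRNA set forces P_NDE → 1) — must not
  exceed the band's upper edge.
* Recovery uses 100 replicates (rank-improvement) and 20 seeds (top-40
  capture); hazard-ratio coverage uses 500 replicates at n = 300.
* The RF comparison runs 200 repetitions per arm with 30-tree forests —
  on 60-sample, ≤20-feature problems the AUC separation is insensitive to
  forest size, and the small forest keeps the full comparison tractable;
  the acceptance script reports the same quantities at 60 repetitions.

## Known limitations

* Identifiers are opaque strings; no -5p/-3p or precursor/mature
  harmonization is attempted, so expression and interaction tables must
  share a naming convention.
* Two-group designs only; no batch correction, voom weights or count
  models.
* The O/E hazard-ratio estimator is mildly attenuated for strong effects
  relative to a Cox estimate; the coverage simulations account for this.
* The synthetic generators omit expression–network coupling and count
  noise, so passing recovery tests demonstrate correctness of the
  statistics, not performance on real TCGA-scale data.
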