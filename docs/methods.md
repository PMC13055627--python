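# Methods

## Scope and data model

The package analyzes a completely randomized block field trial of humic-acid
(HA) amendment on saline-alkali soil: four treatment arms (control CK at
0 Mg ha⁻¹ and HA3 / HA7.5 / HA15 at 3, 7.5 and 15 Mg ha⁻¹), three replicate
blocks, soil measured at two depth strata ("0-20cm", "20-40cm") and plant
traits carried on a "plant" pseudo-layer. The atomic record is one value for
one plot × indicator × layer; tables travel as long-format CSV so joins
across layers and indicators stay unambiguous. Depth layers are opaque
labels, never parsed intervals — the design only ever uses two fixed strata.

Each indicator carries a declared scoring direction. The defaults encode the
saline-alkali convention: reductions in pH, EC and the salinity ions (Na⁺,
Cl⁻, SO₄²⁻, HCO₃⁻) are improvements (*less is better*); nutrient pools
(TN, TP, TK, AHN, AP, AK), SOM and every plant trait are *more is better*.
K⁺, Ca²⁺ and Mg²⁺ are plant-available base cations and default to more-is-
better, but they are plain registry entries a user config can flip. Ion
units are conventional placeholders marked "(unverified)": source material
reports ion responses only in normalized form.

## Linear scores and the area index

For one indicator observed across a comparison set of groups,

- more is better: SL = x / max(x)
- less is better: SL = min(x) / x,  defined for strictly positive values.

Both give the best group a score of exactly 1 and map into (0, 1]. The
min/max ratio forms are the standard linear-scoring reading; they are an
explicit modeling assumption of this package.

A group's n scores are placed at angles 2πi/n and summarized by area:

- `squared_term` (default): 0.5 · Σ SLᵢ² · sin(2π/n). Each term is the area
  of an isoceles triangle with two sides SLᵢ; the sum is invariant under any
  permutation of indicators.
- `adjacent_product`: 0.5 · Σ SLᵢ·SL₍ᵢ₊₁ mod n₎ · sin(2π/n), the exact
  shoelace area of the radar polygon. It depends on indicator order, which
  is therefore a serialized property of the registry, stable across groups.

The squared form is the index definition this package defaults to; the
polygon form is offered behind a flag because the squared form is plausibly
a typesetting of it, and the two cannot be distinguished from the index
definition alone. Both variants are bounded by 0.5·n·sin(2π/n) (all-ones
polygon), are monotone in every score, and are invariant under cyclic
rotation of the indicator order.

Scores are computed within the comparison set shown in one radar chart: at
`treatment_mean` level the set is the four treatment means within a layer;
at `plot` level it is all twelve plots within a layer, which yields one
index per plot and so supports ANOVA and regression on the index itself.
Which level the original analysis used is not stated; both are provided and
reported side by side.

The separate *relative response* transform (r_t = mean_t / mean_control,
rescaled so the maximum is 1) reproduces the 0–1 normalization radar charts
display; it is presentation, not input to the index.

## Treatment comparison

One-way fixed-effects ANOVA is computed from sums of squares, either from
raw plot values or directly from (n, mean, sd) summaries — SSB = Σ n_g
(m_g − m)², SSW = Σ (n_g−1) sd_g² — making printed agronomic tables (means
± SD, n = 3) directly reanalyzable. The two routes are algebraically
identical and are tested against each other to 1e-10, and against an
independent ANOVA implementation. Sample SD uses the n−1 denominator
throughout. If SSW is exactly zero with unequal means, the p-value is
reported at a floor of 1e-300 and flagged rather than as a hard zero.

Post-hoc comparison is Tukey's HSD from the pooled within-group mean
square, using the studentized-range distribution (Tukey–Kramer SE for
unequal n; the design here is balanced at n = 3). The compact letter
display uses insert-and-absorb: start from one column holding all groups,
split a column for each significant pair it contains, absorb columns
subsumed by others, then assign letters in descending order of the best
member's mean, so 'a' always marks the top group. Significant pairs are
processed in sorted order, making the display deterministic. The post-hoc
family (Tukey vs LSD vs Duncan) is not stated by the source analysis; Tukey
reproduces all three published letter patterns and is the default.

Regression of yield on the indices is ordinary least squares with Pearson
r, the two-sided t-test of r, and the standard confidence band for the mean
response (narrowest at x̄). p-values below 0.001 format as "<0.001" in
reports while staying exact internally.

No multiple-testing correction is applied across indicators, no block term
is fitted, and no nonparametric fallback is triggered by a normality
pre-check — matching the analysis the package reproduces. A Shapiro–Wilk
check can be run by the user with scipy directly; the pipeline does not
gate on it.

## Mantel test and predictor ranking

The Mantel test correlates the strict upper triangles of two distance
matrices and builds its null by jointly permuting rows and columns of the
second matrix (B = 999 by default), with the one-sided (positive
association) add-one p-value (1 + #{r_perm ≥ r_obs}) / (1 + B); ties count
as ≥ with a 1e-12 tolerance. The generator is seeded explicitly, so every
p-value is reproducible. Permutations are vectorized; under independent
inputs the rejection rate at α = 0.05 calibrates to 5% by construction of
the add-one rule with B = 999.

Predictor ranking fits a random-forest regressor and reports impurity
importances, with significance from refitting on a permuted response
(B = 99 by default): p = (1 + #{null ≥ observed}) / (1 + B), per feature.
This mirrors the rfPermute-style usage common in soil microbiome papers.
Importances are returned in descending order; all randomness (forest
seeds and response permutations) derives from the single call seed.

## Community summaries

Counts aggregate to a rank by summing taxa sharing the rank label, with
unannotated taxa pooled as "Unclassified" (totals conserved exactly).
Relative abundance divides by sample totals; top-k pooling keeps the k taxa
of largest mean relative abundance and pools the rest into "Others",
breaking ties at the cut lexicographically. Shannon entropy uses the
natural log (the dominant convention in the ecology stack); Chao1 uses
S_obs + F1²/(2F2), switching to the bias-corrected S_obs + F1(F1−1)/(2(F2+1))
when no doubletons exist. Alpha diversity is computed on raw counts by
default — the reproduced analysis mentions no rarefaction — with an
optional seeded rarefaction for equal-depth comparisons. Bray–Curtis
dissimilarity d = 1 − 2Σmin(a,b)/(Σa+Σb) feeds the Mantel stage; NMDS
ordination is deliberately not implemented (the exported distance matrix
is consumable by any ordination tool).

## Synthetic trial generator

The generator defines the study conditions the tests run under. Plot
values are drawn as control_mean × treatment multiplier × (1 + ε), ε ~
N(0, CV), truncated at zero; community counts are Dirichlet-compound
multinomial (concentration 200, depth 10 000 per sample) with
treatment-specific multiplicative enrichment applied to base proportions
before renormalization. One pseudo-random stream seeded from the config
drives all draws in a fixed order, so identical configs are bit-identical.
Optional additive Gaussian block intercepts exist but default to off — the
reproduced analysis is one-way, not a block model.

Calibration of the default configuration:

- Control soil means follow the published 0–40 cm baseline table (pH
  8.16/8.25, SOM 1.13/0.36 g kg⁻¹, …). EC and the water-soluble ions have
  no published baseline; their control means (e.g. EC 1.80 / 1.40 dS m⁻¹)
  are this package's choice of plausible values for a moderately-to-
  severely saline fluvo-aquic soil.
- Treatment multipliers sit inside the published response ranges (AP
  +41–53%, AK +22–45%, SOM +15–20%, EC −8–27%, Cl⁻ −3–45%, SO₄²⁻ −7–34%,
  pH −0.05–0.17 units, root and nutrient traits +3–43%). Yield and
  yield-component means equal the published treatment means exactly
  (yield 2.72 / 2.81 / 3.04 / 3.08 Mg ha⁻¹).
- Plot-level CVs are not published anywhere; the defaults — 0.06 for soil
  chemistry, 0.10 for ions, 0.08 for plant traits, 0.02 for yield, 0.01
  for pH — are documented guesses fixed once at realistic field-trial
  noise levels.
- Community enrichment encodes the published focal-phylum responses:
  Acidobacteriota +13% / +28% under HA7.5 / HA15 and Ascomycota +13% /
  +10% / +10% under HA3 / HA7.5 / HA15, on a 12-phylum base composition
  typical of agricultural soil.

What the generator does *not* emulate: spatial field structure, weather
and season effects, indicator–indicator correlation beyond the shared
treatment effect, compositional interactions among ions, or taxa below
phylum level. Passing tests therefore demonstrate that the pipeline
recovers effects of the configured magnitude under well-behaved
multiplicative Gaussian noise — not that real trials satisfy those
assumptions.

## Numerical choices and degenerate inputs

- Scores outside [0,1] by more than 1e-12, polygons with n < 3, constant
  regressors/responses, all-zero count vectors, zero-total samples and
  asymmetric distance matrices are rejected with typed errors rather than
  propagated as NaN.
- The adjacent-product area is verified against a brute-force shoelace
  oracle to 1e-12; Bray–Curtis against a per-pair loop to 1e-12; Shannon
  and Chao1 against scikit-bio; Tukey significance patterns against
  statsmodels on reconstructed raw data.
- CLD ties and top-k ties have deterministic documented tie-breaks (sorted
  pair processing; lexicographic by name).
- All Monte-Carlo checks use fixed seed ranges. Problem sizes: 1000
  replicates for ANOVA type-I calibration and multiplier recovery, 500
  seeds × 999 permutations for Mantel calibration, 50 end-to-end runs for
  the index-ordering check, 100 fixtures for oracle-equivalence checks —
  sizes at which the binomial/Monte-Carlo error is a fraction of the
  tolerance being asserted.

## Known limitations

- The exact linear-score transform of the original analysis is defined in
  supplementary material not available here; the min/max ratio forms are
  the standard reading and all index values depend on that assumption.
- Published field percentages that depend on unpublished plot-level raw
  data (index gains, yield–index correlation coefficients) cannot be
  reproduced numerically; the pipeline reproduces their direction and
  detectability under calibrated synthetic conditions, and reproduces
  exactly those published numbers that are computable from printed
  summaries (ANOVA row, letter patterns, yield-increase range).
- Summary-statistics ANOVA/Tukey inherit the rounding of printed means and
  SDs; the reproduced p-values agree with printed ones to that rounding.
- The permutation-importance p-values are marginal, not family-corrected,
  and with 12 plots the forest ranking is informative only for strong
  effects.
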