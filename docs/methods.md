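# Methods

This note records the models, unit conventions, numerical choices and
assumptions behind `ecostoich`, and what the synthetic-data generator
does and does not emulate.

## Ecoenzymatic stoichiometry

Enzyme pools follow the supply-minus-consumption convention: the carbon
pool sums β-glucosidase, cellulase and xylanase and subtracts
dehydrogenase (the one assayed enzyme that consumes reduced carbon);
nitrogen sums urease and protease; phosphorus is acid phosphatase alone,
chosen over the alkaline isoform because field soil pH sits near the acid
phosphatase assay optimum. β-glucosidase and cellulase are kept as
separate terms even though they overlap as a family — their assays
(p-nitrophenyl substrate vs. dinitrosalicylic acid reduction) probe
different steps of cellulose breakdown.

The vector angle is `degrees(atan2(y, x))` with `x = CE/(CE+PE)` and
`y = CE/(CE+NE)`, measured from the x-axis; with positive pools it lies
strictly inside (0°, 90°) and exceeds 45° exactly when the phosphorus
pool exceeds the nitrogen pool. A non-positive carbon pool (dehydrogenase
exceeding supply) is retained as a value but the vector, ratios and
limitation call are reported undefined rather than clamped — inventing a
floor would silently change the stoichiometry. The angle threshold (45°)
is fixed by the 1:1:1 null; the vector-length cutoff separating "weak"
from "strong" limitation defaults to 0.5, the magnitude reported for
strongly P-limited cultivated drylands, and is configurable.

Group summaries exist in two aggregation orders. `of_means` averages the
nine activities first and derives pools/ratios/vector from the means;
`per_replicate` derives everything per sample and averages afterwards.
They differ for every nonlinear quantity (Jensen gap), and published
tables often mix the two conventions; the package defaults to
`per_replicate` and always reports which mode produced a summary.

## Soil chemistry

TOC uses the conventional Van Bemmelen divisor 1.724. Molar conversions
use atomic masses 12.011 (C), 14.007 (N), 30.974 (P); carbon enters in
g kg⁻¹, nitrogen and phosphorus in mg kg⁻¹, all emerging as µmol per g
of soil. Fertility indices are plain sums and quotients: SB = Ca+Mg+K+Na,
CEC = SB+PA, V% = 100·SB/CEC, m% = 100·Al/(SB+Al); V% and the potential
acidity share of CEC are exactly complementary, which the tests assert.
Qualitative flags use strict inequalities (OM-rich > 30 g kg⁻¹, high TOC
> 20, adequate P > 10 mg kg⁻¹, high saturation V% > 90, slightly acidic
6.5 < pH ≤ 7). Derived columns in input files are never trusted; they
are always recomputed from the measured ones.

## Enumeration estimators

The MPN estimator is the maximum-likelihood solution under independent
Poisson inoculation: a tube receiving inoculum *v* of a suspension with
density λ turns positive with probability 1 − e^(−λv). The score
equation is solved by bracketed Brent root-finding (the score is strictly
decreasing in λ); published lookup tables are not used because they fix
the design, while the MLE covers any level/tube layout. All-negative
series return zero with a one-sided upper bound from the exact
all-negative probability; all-positive series have no finite MLE and
raise. The confidence interval is log-normal: SE(log₁₀ λ̂) from the
Fisher information, λ̂·10^(±z·SE). The estimator is validated against a
dense likelihood-grid oracle on every outcome of a 3×3 design and obeys
scale equivariance and monotonicity in positive tubes.

CFU, DNA-yield and microscopy estimators are unit arithmetic. The
DNA-per-cell constant is 8.14 fg. Plates beyond 300 colonies are flagged
uncountable, zero counts below-detection; both flags propagate into the
long-format comparison table, where censored rows carry NaN log₁₀ values
and are excluded from correlations by default. Microscopy scaling
constants (field/filter areas, aliquot volumes) are configuration with
documented defaults, since such constants are instrument-specific.

## Biomass and quotients

MBC = (C_fum − C_unfum)/kEC with kEC = 0.45; MBN analogous with
kEN = 0.54 — the standard fumigation–extraction efficiencies, both
configurable. Negative flushes are kept and flagged, not clamped.
Respiration assumes 2 mol NaOH neutralised per mol CO₂ trapped and
normalises to a 24 h day. qCO₂ converts respiration to mg CO₂ g⁻¹ h⁻¹
(×44.01/1000/24) and biomass to g C g⁻¹ (×12.011×10⁻⁶) before dividing;
the microbial quotient divides MBC by molar TOC. Quotients computed from
group-mean inputs differ from means of per-replicate quotients (Jensen
again); the pipeline computes per replicate and averages.

## Multivariate integration

The feature matrix holds 25 variables: ten enzyme-derived (pools, three
ratios, VL, VA, alkaline phosphatase, arylsulphatase), twelve chemical
(TOC, TN, P, four cations, CEC, pH in water, three molar ratios) and
three microbial (MR, MBC, MBN). Chemistry is measured on one pooled
sample per group and broadcast to replicates. Enumeration variables stay
out of the ordination (their group differences are weak) and enter
through Spearman correlations instead. Columns are z-scored (sample SD);
zero-variance columns — which arise when all groups share one pooled
chemistry analysis — are dropped before scaling, recorded on the result.
The drop uses a relative tolerance because a column of identical floats
can retain an O(machine-epsilon) standard deviation.

PCA is the SVD of the z-scored matrix, truncated at numerical rank, with
a deterministic sign convention (largest-magnitude loading positive per
axis). Per-component inference runs the parametric battery (Shapiro–Wilk,
Levene, one-way ANOVA, Tukey HSD) alongside the non-parametric one
(Kruskal–Wallis, Dunn with Bonferroni adjustment — the adjustment is a
package choice, as is reporting both batteries unconditionally rather
than gating on normality).

RDA projects the centred responses on the centred environmental
variables by least squares; constrained axes come from the SVD of the
fitted values, unconstrained from the residuals, and the constrained +
unconstrained variance fractions sum to one. Adjusted R² is the Ezekiel
correction. Permutation inference permutes response rows with a seeded
generator and reports (1+b)/(1+B) p-values for the global model, for each
term sequentially in column order, and for each axis tested forward
after partialling out the site scores of earlier axes. Environmental
candidates pass an iterative VIF screen (drop the highest VIF until all
are below 2; exact ties drop the lexicographically first name).

PERMANOVA works on squared Euclidean distances with the standard
among/within decomposition; p-values use the same (1+b)/(1+B) convention
under seeded label permutation, or exact enumeration over all distinct
label arrangements when requested (refused beyond 5·10⁵ arrangements).
The companion dispersion check runs a one-way ANOVA on distances to
group centroids — for the Euclidean metric the feature-space centroid
distances coincide with the principal-coordinate ones, so no explicit
PCoA is needed.

## Synthetic data

The generator emulates a field study of three agave plantings sampled
with five biological replicates in two compartments. Group means default
to the published per-species values; the one published inconsistency (a
dehydrogenase mean printed an order of magnitude above the value implied
by the published pooled carbon enzyme value and across-species mean) is
resolved in favour of the internally consistent 2.44×10⁻³. Per-species
basal respiration is back-computed from the published per-species
metabolic quotients and biomass values, since only the across-species
mean respiration is published.

Replicate dispersion is not published anywhere, so all variance
parameters are assumptions surfaced in the design object: CV 0.40 for
enzyme activities and 0.25 for respiration (no significant species
differences were reported for these at n = 5, which bounds their
dispersion from below), CV 0.10 for chemistry and biomass (clearly
separated between species), and lognormal noise with CV 0.30 for
enumeration targets. Enzymes and biomass use zero-truncated normal
noise; enumeration uses lognormal; tube outcomes and field counts are
binomial/Poisson given the drawn target, except at CV = 0 where
expected-value rounding keeps the bundle fully deterministic. Raw assay
readings are back-calculated from the per-replicate targets so the
forward pipeline recovers them exactly.

Chemistry is drawn once per group (a pooled analysis, as in the emulated
study); in the null design a *single* pooled analysis is shared by all
groups — per-group draws would act as a random group effect, breaking
sample exchangeability and invalidating the type-I-error properties the
null design exists to test.

What the generator does not emulate: spatial autocorrelation between
neighbouring plants, seasonal dynamics, taxonomic composition,
correlations between variables beyond those induced by shared group
means, or assay-specific measurement error structure. Passing tests on
this generator therefore demonstrate the correctness and statistical
calibration of the pipeline, not field-level conclusions about real
plantations.

## Problem sizes and determinism

The default study (15 samples × 25 variables) makes every stage fast;
the calibration checks use 1,000 null draws with 999 (PERMANOVA) or 199
(RDA) permutations each, and 100 seeded runs for the clustering-purity
and effect-recovery rates. All permutation tests, k-means restarts and
dataset draws consume seeds explicitly; two runs with the same
configuration produce byte-identical reports, and the report JSON
validates against the pydantic-derived schema shipped in
`docs/report.schema.json`.

## Known limitations

* The MPN confidence interval is a large-sample approximation; it is
  anti-conservative for extreme tube patterns with very few positives.
* Sequential (type-I) term tests in RDA depend on the order of the
  environmental columns, as in any sequential decomposition.
* The dispersion companion test uses a plain F-test on centroid
  distances rather than a permutation distribution.
* Group-constant chemistry broadcast to replicates understates the
  within-group variance of chemical variables in the ordinations; this
  mirrors the emulated design (pooled chemistry analyses) and is
  documented rather than corrected.
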