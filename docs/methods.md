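# Methods

This note records the statistical models implemented in `geitools`, the
numerical and design choices that were genuinely open, what the simulators
do and do not emulate, and known limitations.

## Data model

All analyses run off one of two tables. The replicate-level *expression
table* (`condition, tissue, gene, block, expression`) holds qPCR
fold-changes computed by the 2^−ΔΔCt method (target normalised to a
reference gene, then to a calibrator sample). The *summary table*
(`condition, tissue, gene, mean, sd, n`) holds sufficient statistics; SD is
always the sample SD (n − 1 denominator). For a balanced design these are
genuinely sufficient: every sum of squares below is a function of cell
means, cell SDs and n only.

`expand()` maps a summary table to pseudo-replicates by affinely rescaling
seeded standard-normal draws so each cell's sample mean and SD are matched
to machine precision. The draws are retried a few times if a rescaled value
is negative (possible when sd is large relative to the mean), but exact
moments always win over non-negativity — for n = 3 the most extreme
standardized value is (n−1)/√n ≈ 1.155 SDs, so only cells with
mean < 1.155·sd can produce negative pseudo-replicates at all. Balanced
sums of squares are invariant to which particular replicate values realise
a cell's moments, which is why this reconstruction is exact for ANOVA
purposes and not merely approximate.

The packaged dataset is the 144-cell summary (4 cold-resistance genes ×
9 tissues × 4 water temperatures, n = 3) of relative expression in
*Takifugu rubripes* after 24 h of cold stress. Its replicate count is fixed
by the error degrees of freedom of the published per-temperature ANOVA
(72 = 36 cells × 2).

## Balanced factorial SS from sufficient statistics

For a complete balanced crossing, the SS of a marginal term T is computed
by inclusion–exclusion over sub-margins of cell means (the classical
balanced-design effect decomposition), weighted by the replicate count and
the sizes of the factors not in T. The pooled within-cell error stratum is
recovered from SDs as SS = Σ (n−1)·sd² with Σ (n−1) df. Main-effect and
interaction SS over all non-empty terms add to the between-cell
(treatment) SS; this additivity and an OLS sequential-ANOVA cross-check
(statsmodels, on expanded pseudo-replicates) are asserted in the tests.

## Split-split-plot ANOVA

The blocked three-tier design (temperature on main plots, tissue on sub
plots, gene on sub-sub plots, b complete blocks) is fitted by stratum
subtraction on the (b, t, s, g) data cube:

| stratum | df | role |
|---|---|---|
| Blocks | b−1 | replication; no F reported |
| Temperature | t−1 | tested vs main-plot error |
| Main-plot error (block × temperature) | (b−1)(t−1) | |
| Tissue, Temperature × Tissue | s−1, (t−1)(s−1) | tested vs sub-plot error |
| Sub-plot error | t(b−1)(s−1) | pooled block × tissue within temperature |
| Gene and its interactions | … | tested vs sub-sub-plot error |
| Sub-sub-plot error | ts(b−1)(g−1) | residual |

Blocks enter as a pure replication factor; no block × treatment terms other
than the designated error strata are split out. p-values come from the F
upper tail and are reported at full precision (significance stars are
attached only in CLI report output). The published ANOVA of the packaged
dataset is *not* numerically reproducible from summaries — it requires
block-level raw data with six blocks that were never printed (and the
block count itself is not derivable from the described triplicate tanks) —
so this module is validated structurally (the df column for b = 6, t = 4,
s = 9, g = 4) and by simulation: under a pure-noise draw each fixed-term
test must reject at the nominal 5% rate (2000 Monte-Carlo datasets in the
acceptance suite; the rate is required to lie within ±1.5 points, about
three binomial SEs).

## AMMI

The two-way table of cell means at one temperature is decomposed into
zero-sum main effects plus an SVD of the double-centered residual.
Numerical conventions:

* **IPCA df**: Gollob's g + e − 1 − 2n. These partition the interaction df
  exactly and match the published per-axis df of the packaged dataset
  (10, 8, residual 6 for a 4 × 9 table).
* **F denominators**: the pooled within-cell error MS, for treatment terms
  and IPCA axes alike.
* **Percent of total SS** uses total = treatment + error, which is what
  the published attributions imply.
* **Sign convention**: each axis is flipped so the score of the genotype
  with the largest main effect is non-negative — removes SVD sign
  ambiguity from tests and plots.
* Two IPCA axes are reported by default (configurable up to
  min(g−1, e−1)); trailing axes are pooled into the residual row.

Expression stays on the raw fold-change scale throughout: the published SS
magnitudes only reproduce without a log transform, and the package makes no
attempt to stabilise variance (see limitations).

## GGE biplot

Default configuration: tissue (column) centering, **no** per-tissue
scaling, symmetric singular-value partitioning (both coordinate sets carry
√λ). Rationale: the published winners track raw-scale magnitudes, which
implies unscaled data, and the originating software's settings are
undocumented; the configuration that reproduces the published orderings is
pinned by the fixture tests. Scaling and SVP are exposed as estimator
parameters.

View conventions, stated explicitly because the source descriptions are
verbal:

* **Which-won-where**: convex hull of gene points (counterclockwise),
  sector boundaries are rays from the origin perpendicular to hull edges;
  a tissue's winner is the hull vertex maximising the inner product with
  the tissue vector (equivalently, the vertex of its angular sector). Ties
  break to the larger PC1 projection. Collinear gene points (second
  principal spread ≤ 1e−6 of the first) are rejected as degenerate.
* **Average-tissue axis (ATA)**: direction of the mean tissue vector. Mean
  performance = signed projection onto the ATA; instability = length of
  the perpendicular component.
* **Ideal gene**: on the ATA, at the length of the *longest gene vector*
  (the conventional ideal-genotype definition). The alternative "largest
  mean projection" radius is available (`ideal="mean_projection"`) but is
  not the default: with it the 13 °C comprehensive ordering of the
  packaged dataset contradicts the published one, while the conventional
  definition reproduces the 5, 13 and 18 °C orderings.
* Sector winners and the mean-performance ordering are inner-product
  quantities and therefore invariant to the SVP choice;
  perpendicular-distance quantities (stability, ideal distance) are not,
  which is why the configuration is part of the model's contract.

Known, deliberately-reported discrepancies of the default configuration on
the packaged data: the published 8 °C comprehensive ordering
(AFP1, HMGB1, CIRP, YB-1) is not reproduced under any
scaling × SVP × ideal-point combination tried (the package obtains
AFP1, HMGB1, YB-1, CIRP — the last two swap); at 18 °C the gonad falls in a
CIRP sector rather than the published YB-1 region (the published view
itself notes gonad sits on the region boundary), and the discrimination
ranking is muscle > kidney > skin rather than muscle > skin. The
`reproduce-paper` report lists these rather than forcing them.

## Temperature-response families

Per gene × tissue series of four mean-expression values against
temperature, three candidate families are fitted: a power law y = a·xᵇ
(log–log linear regression; r² reported in log space), a quadratic and a
cubic (raw-scale OLS). Because a cubic through four points always fits
perfectly, selection needs a parsimony rule: the smallest family whose
r² ≥ 1 − τ wins (power first, then quadratic, then cubic), with τ = 0.01 by
default. The published per-series family labels were chosen without a
stated criterion or coefficients; the scan reports its selections alongside
the published labels and flags mismatches instead of hiding them. Notably
the published "power law in all nine tissues" claim for AFP1 is not
attainable by any goodness-of-fit rule: in three tissues the AFP1 series is
non-monotone (5 °C ≈ 8 °C), capping even raw-scale nonlinear power fits
near r² ≈ 0.75.

## Simulators

`simulate_ammi` draws r replicates per cell around
μ + α_g + β_e + Σ λ_n γ_gn δ_en with i.i.d. Gaussian noise; interaction
score matrices are built by column-centering seeded Gaussian draws and QR
orthonormalisation (centering survives QR because the centered columns are
orthogonal to the ones vector), so noiseless recovery tests are exact.
`simulate_ssp` adds independent Gaussian main-plot, sub-plot and residual
strata to a fixed treatment surface. Both are deterministic per seed.

What the simulators emulate is the *statistical* structure the estimators
assume: balance, homoscedastic Gaussian errors, low-rank interaction. What
they do not emulate: the strong mean–variance coupling visible in real
qPCR fold-changes (cell SDs scale roughly with means), non-negativity,
and any mechanistic temperature dependence. Passing recovery and
calibration tests therefore validates the estimators under their own
assumptions; it does not certify behaviour under heteroscedasticity.

## Problem sizes and tolerances

Monte-Carlo checks use 2000 datasets for split-split-plot type-I-error
calibration, 400 seeds for the AMMI null-interaction F calibration and 400
for the expected-mean-square check — sizes chosen so binomial/sampling
error is a small multiple of the asserted tolerance. Moment round-trips
assert 1e−9 relative; SVD reconstructions 1e−8; SS additivity 1e−9
relative. Published-value comparisons use the precision the published
tables carry: ±0.05 percentage points for %SS attributions, 0.5% relative
for F statistics, 0.1% for raw SS.

## Limitations

* Balanced, complete designs only; no REML/unbalanced path.
* Raw-scale analysis inherits the heteroscedasticity of fold-change data;
  F-tests are exact only under the homoscedastic model being fitted.
* Gollob df are liberal for IPCA F-tests (no resampling alternative such
  as FGH1/2 is provided).
* The GGE cosine ≈ correlation reading is exact only in full-rank
  environment-focused coordinates; in the 2-PC plot it is the usual
  approximation.
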