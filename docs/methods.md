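# Methods

## Consensus binary similarity

One assessor's responses to two products are compared through the 2×2
quad *(a, b, c, d)*: co-checked, first-only, second-only, co-unchecked
attribute counts, *p = a+b+c+d*. The registry evaluates 44 binary
similarity coefficients per quad. Composition:

* 24 coefficients natively in [0, 1] (Jaccard–Tanimoto, simple matching,
  Gleason/Dice–Sørensen, Russel–Rao, Rogers–Tanimoto, Driver–Kroeber,
  Kulczynski 2, Braun–Blanquet, Simpson, Sokal–Sneath 1/2/4,
  Rogot–Goldberg, Hawkins–Dotson, Faith, Austin–Colwell,
  Consonni–Todeschini 1–4, 3W-Jaccard, Sorgenfrei, Gower–Legendre,
  Baroni-Urbani–Buser);
* 12 correlation-type coefficients on [−1, 1], rescaled by
  *(x+1)/2* (Hamann, Pearson φ, Yule Q and ω, McConnaughey, Tarwid,
  Goodman–Kruskal, Cohen, Maxwell–Pilliner, Michael,
  Consonni–Todeschini 5, Scott);
* 7 with other natural ranges — dispersion [−¼, ¼], Dennis, Fossum,
  Forbes, Mountford, Harris–Lahey, Anderberg — each rescaled by its
  documented (α, β), which for Dennis/Fossum/Forbes/Harris–Lahey depend
  on *p*;
* 1 distance coefficient (mean Manhattan *(b+c)/p*), converted via
  *S = 1/(1+D)* before rescaling.

Every entry records its formula source, its attainable range, and an
explicit 0/0 convention (co-occurrence coefficients evaluate to 0 on two
all-zero vectors; agreement coefficients whose denominator vanishes only
for identical vectors evaluate to 1; Maxwell–Pilliner's degenerate limit
is +1 for identical and −1 for complementary vectors). The quoted Dennis
range [−√p/2, √p/2] found in the literature is incorrect at the upper
end (a = 1, b = c = 0, d = p−1 gives (p−1)/√p); the registry documents
and scales by the correct attainable range [−√p/2, (p−1)/√p]. All 44
scaled outputs were verified to lie in [0, 1] and to be symmetric under
swapping the compared vectors over the exhaustive quad grid
a, b, c, d ≤ 6 plus 10⁴ random large quads; these sweeps are part of the
test suite. Three entries (Michael, Harris–Lahey, Anderberg) do not
guarantee that a vector is at least as similar to itself as to any other
vector; they are flagged `identity_dominant=False` in the registry and
excluded from the identity-dominance property test.

The consensus similarity is the unweighted arithmetic mean of the 44
scaled values. No weighting or de-duplication of numerically close
coefficients is applied: the mean is the simplest consensus, and which
coefficient best reflects the "true" similarity is unknowable a priori.
Users may pass an explicit registry subset.

## Discrimination summary

Column (assessor) means of the pairs × assessors consensus matrix are
compared to the grand mean ("consensus limit"). Classification uses
strict inequality — an assessor exactly at the limit is *poor* — so a
constant matrix yields zero good discriminators. The discrimination
index is 100× the grand mean, reported to one decimal; *lower* values
mean better panel-wide discrimination, and the index confounds panel
skill with how different the products really are, so it should only be
compared across panels testing comparably spaced product sets. The
heatmap CSV (matrix plus assessor-average and flag rows) is the
canonical artifact; the optional PNG anchors a green→red colormap at the
matrix min/max.

## Clustering

Assessors are points in pair-space (their consensus column). Ward's
minimum-variance criterion on Euclidean distances (scipy's
Lance–Williams implementation) builds the tree; cutting at k = 2 (the
default; all reference case studies selected two clusters) gives the
good/poor split, with roles assigned by cluster mean similarity. An
average-silhouette sweep over k ∈ [2, 6] is always reported so the
choice of k is inspectable; silhouette of a singleton cluster, and the
0/0 case of coincident points, count as 0. Columns are not standardized
before clustering — consensus similarities already share the [0, 1]
scale.

## Per-group statistics

**Cochran's Q** per attribute over an assessor subset:
Q = (S−1)[S·ΣC_j² − (ΣC_j)²] / [S·ΣR_i − ΣR_i²], referred to χ²(S−1).
Assessors with constant responses cancel out of both numerator and
denominator; if every assessor is constant the result is flagged
degenerate with p = 1. At S = 2 the statistic reduces to McNemar's
(without continuity correction). Attribute screening is re-run
independently within each assessor group (total/good/poor), which is why
the groups generally disagree on how many terms are significant. Alpha
defaults to 0.05 with no multiplicity correction (Bonferroni /
Benjamini–Hochberg available but off by default, matching common CATA
practice).

**Correspondence analysis** runs on the product × attribute citation
count table of the group, restricted by default to that group's
significant attributes (a flag enables all attributes). The
implementation is the standard SVD of (P − rcᵀ)/√(rcᵀ): principal
coordinates are mass-rescaled singular vectors scaled by singular
values; total inertia equals Pearson χ²/N (asserted to 1e-10 in tests),
row/column coordinates satisfy the barycentric transition formulas to
1e-9, singular values below 1e-12 are treated as null dimensions, and
all-zero rows/columns are dropped and reported. Indicator-matrix CA of
the raw binary rows is *not* used; the aggregated count table is the
canonical input, since attribute-by-product citation totals are the
quantities the product map is meant to display.

**Liking**: one-way ANOVA across products within the group, Tukey HSD at
alpha, and a compact letter display built by insert-and-absorb, with
letters assigned from `a` at the lowest mean upward. The letter-sharing
relation exactly encodes Tukey non-significance (property-tested against
the pairwise reject flags). Groups need ≥ 2 ratings; all-zero
within-product variance is an error (F undefined).

## Agreement (CATATIS)

Each assessor's product × attribute 0/1 matrix is a vector; the
assessor × assessor matrix of Frobenius cosines is a Gram matrix, and
the homogeneity index is 100·λ₁/m — 100% for identical assessors,
100/m% for pairwise-orthogonal ones. Zero-norm assessors are dropped and
reported. Only the agreement index and first-eigenvector weights are
computed; the full iterative CATATIS consensus table and its CLUSCATA
clustering are out of scope. The joint agreement/discrimination table
pairs each assessor's weight with their mean consensus similarity;
their Pearson correlation is reported (zero by convention when either
column is constant).

## Synthetic panels

The generator plants: assessor classes (good/poor by `good_fraction`,
assigned to the leading assessors — order carries no information
downstream), attribute types (discriminating with per-product check
probabilities `p_signal`, noise at constant `p_base`), and
per-(class, product) liking means. Poor discriminators respond with
`attenuation·p_signal + (1−attenuation)·product-mean`; attenuation 1
reproduces the good class, 0 removes all product dependence. All checks
are independent Bernoulli draws; liking is truncated-normal, rounded
when the scale is declared integer (the default — fractional published
means arise from averaging integer votes). Everything is reproducible
from the scenario seed.

What the generator does *not* model: attribute co-occurrence and halo
effects, serving order, satiation, individual response styles beyond the
two planted classes. Real panels also sit at higher absolute consensus
levels (published consensus limits run 0.47–0.55) than independent
Bernoulli responders, whose own response noise depresses similarity.
Passing recovery tests therefore demonstrate that the pipeline detects
the planted structure, not that real panels contain exactly two classes.

Scenario presets:

* `cricket_like` / `apple_pomace_like` / `strawberry_like` — the three
  reference study shapes (67×4×38, 60×4×34, 117×6×16) with the published
  attribute ballots, good fractions matching the published cluster
  splits, dose-response ramps (0.1→0.6) on the discriminating terms, and
  the published cluster-wise liking means on a 1–9 integer scale
  (SD 1.5, a typical consumer hedonic spread).
* `two_class_scenario` — compact 4-product scenario; each
  discriminating attribute takes the high probability (default 0.6) on
  half the products and the low (0.1) on the rest.
* `recovery_scenario` — the maximum-separation design used for
  planted-class recovery: 2 products with complementary
  near-deterministic profiles (32 signal attributes at 0.98/0.02, 4
  always-checked anchors at 0.9), poor class fully attenuated.
  A quantitative note: under independent Bernoulli responses a fully
  attenuated poor assessor still flips coins at the product-averaged
  probability, which by itself depresses their pair similarity; designs
  with ≥ 3 products therefore cap the expected good/poor consensus gap
  near 0.15 regardless of contrast. Only the two-product complementary
  design reaches a gap ≳ 0.2 (measured ≈ 0.33), and it recovers the
  planted classes essentially perfectly (Rand ≈ 1 over 100 seeds).

## Numerical conventions

* Pair rows are ordered lexicographically by sample first-appearance
  index and labeled `"X vs Y"`.
* Matrix CSVs serialize with 12 significant digits (round trips are
  faithful below 1e-9).
* Ward merge ties (measure-zero for continuous data) follow scipy's
  deterministic nearest-neighbor-chain order, so repeated runs of the
  same configuration are byte-identical.
* Hedonic scale bounds are a required user input for liking tables —
  published tables rarely state the scale, and guessing it silently
  would corrupt validation.

## Study sizes used by the reproduction script

`scripts/acceptance.py` exercises the pipeline at the three reference
shapes (one seeded draw each), 100 seeded recovery panels (30×2×36) and
100 seeded power panels (60×4×10), plus 10⁴-quad registry sweeps —
sizes at which every reported quantity is stable to the precision shown
while the whole script completes in seconds.
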