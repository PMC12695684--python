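# Methods

## The analysis in brief

The package analyses a seedling screen of 114 wild barley genotypes grown in
sand-filled tubes under two soil-moisture regimes (normal, 90–95% field
capacity; water stress, 50–55% FC). The experimental layout is an augmented
block design: per condition, five blocks of 30 tubes hold 21 unreplicated
*test* genotypes each plus the same nine replicated *check* genotypes. The
pipeline derives root-architecture traits from the primary measurements,
removes block effects using the checks, classifies each genotype into one of
nine root groups by confidence-interval thresholds on root length (depth)
and root tissue density (density), and then characterises the groups with
ANOVA/LSD, canonical discriminant analysis, trait correlations and Ward
clustering.

## Derived traits

All formulas operate on per-tube values (the mean over the five plants per
tube) in cm / g / cm³. Two switches preserve the source arithmetic exactly:

- `pi_value` defaults to 3.14, the rounded constant used in the original
  formulary; `math.pi` is available for full precision.
- `rtd_mode` defaults to `paper_multiply`: root tissue density as the
  *product* of root dry weight and root volume (units g·cm³), as printed.
  The physically conventional quotient (g/cm³) is `standard_divide`.
  Switching the mode changes only the `root_tissue_density` column.

`soil_volume` (the tube volume) is a required configuration value with no
default: it is a property of the experiment that was not reported, and the
package refuses to invent a physical constant silently. Fixtures use
1000 cm³. Note that soil volume only rescales root length density, root
specific mass and root mass density by a constant, so it affects no
classification or group statistic.

The diameter formula treats the whole fibrous root system as a single
cylinder of unit density; it is kept as printed. When root fresh weight
equals root volume numerically, `root_surface_area_density` equals
`root_area` (the cylinder identity `2√(VπL) = πDL`), which the tests use as
an internal consistency check.

## Pigments

The three-wavelength equations for 96% ethanol extracts are linear through
the origin. Outputs are in raw equation units; no dilution or per-mass
normalisation is applied because none was reported. Negative concentrations
(possible for extreme absorbance ratios) are returned as computed and
flagged in the run manifest — clamping would silently bias group means.

## Augmented-design correction

Block effects are estimated from the checks only:
`effect(c, j, t) = mean of checks in block j − grand check mean`, the
classical check-based correction for augmented randomized complete blocks.
Test genotypes have their block's effect subtracted; checks receive one
value per condition, the across-block mean of corrected observations. On
additive noise-free data (`y = genotype + block + condition`) test-genotype
contrasts are recovered exactly; adding a constant to one block changes no
contrast. The factorial check ANOVA (genotype × stress, five block
replicates) is computed from cell means — the check sub-design is balanced —
with significance stars at 5% (\*) and 1% (\*\*). Constant data are reported
as SS = 0, F = 0, p = 1 rather than NaN.

Whether the original classification used adjusted or raw means is not
stated in the source; the pipeline defaults to adjusted values
(`classification.use_adjusted: true`) with a bypass flag.

## Classification

Per condition and trait, the threshold band is the Student-t confidence
interval of the mean over the n = 114 genotype-level values:
`mean ± t(1−α/2, n−1)·sd/√n`, α = 0.05. Values strictly below the band are
superficial (resp. non-dense), strictly above are deep (dense), and the
closed middle interval is semi-deep (semi-dense). t rather than normal
quantiles is a documented choice; at n = 114 the difference is negligible
but the convention must be fixed. The band is *narrow* — about 0.19
population standard deviations half-width — which has consequences for the
synthetic-data design (below). Classification is invariant under positive
affine maps of a trait, and with a frozen band it is monotone in the value.

## Group statistics

- **One-way ANOVA** across the nine groups on genotype-level values; at the
  full design scale df = (8, 105). **LSD**:
  `t(1−α/2, df_w)·√(MS_w·(1/n_i + 1/n_j))`, strict inequality for
  significance.
- **Canonical discriminant analysis** uses the pooled within-group scatter
  convention: generalized eigenproblem `S_b v = λ S_w v`, coefficients
  scaled to unit pooled within-group score variance, at most
  `min(groups−1, p)` functions. Each eigenvalue maps to a canonical
  correlation `r = √(λ/(1+λ))` — this identity is what pins the convention
  to the published eigenvalue/correlation pairs. The structure matrix holds
  pooled within-group correlations between input variables and canonical
  scores; centroids are group means of grand-centred scores (their
  size-weighted mean is 0). A singular within scatter (the trait set
  contains exact collinearities such as root length vs. root length
  density) triggers a logged ridge `ε·tr(S_w)/p`, ε = 1e−8. Stepwise
  Wilks-lambda selection (enter 3.84 / remove 2.71, the conventional
  defaults) is available but off by default; the full-variable model is the
  default path.
- **Correlations** are Pearson r over the 114 genotype-level adjusted values
  per condition (not the 9 group means, where most published significance
  flags would be unattainable at n = 9); p from the two-sided t with n−2 df,
  flags at raw 5%/1% without multiplicity adjustment, matching the source's
  reporting. A `correlation_scope: group_means` switch exists.
- **Ward clustering** of the nine group mean-trait profiles, z-scored per
  trait so heterogeneous units contribute comparably. The Lance–Williams
  recurrence on squared Euclidean distances (heights reported as square
  roots, the Ward.D2 convention) is implemented directly with a
  deterministic tie-break — the lexicographically smallest pair of sorted
  member label tuples — making results exactly invariant to input row
  order; scipy's ward linkage is the cross-check oracle in the tests.
  Dendrograms are exported as Newick plus a merge table; `cut_tree(k)`
  labels clusters by their smallest member for stable output.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the design structure exactly (checks in every
block, tests partitioned 21 per block, 150 tubes per condition) with
additive genotype, block and condition effects and Gaussian noise, truncated
at zero by resampling. Root tissue density is controlled directly: root
volume is drawn and root dry weight set to `target/volume`, so the
paper-mode product equals the latent density value and block effects act
additively on the classified trait. Absorbances are obtained by inverting
the pigment equations from latent chlorophyll/carotenoid pools (reduced 20%
under stress), so simulated extracts always have physically consistent,
non-negative pigment concentrations.

Key defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| `depth_class_means` | 20 / 35 / 50 cm | latent root-length class means |
| `density_class_means` | 0.06 / 0.16 / 0.26 g·cm³ | latent paper-mode RTD class means |
| `noise_sd` | 5 cm | total per-observation sd around a class mean (class separation = 3×) |
| `block_sd` | 2 cm | block effect sd (density scale: × separation ratio) |
| `class_proportions` | 0.45 / 0.10 / 0.45 | latent class shares per trait |
| `trait_correlation` | 0.3 | copula correlation of depth and density propensities |
| `stress_shift` | −6 cm, −0.03 g·cm³ | additive condition effect |

`noise_sd` is split 0.8/0.6 between a persistent genotype deviation and
tube-level measurement noise (0.8² + 0.6² = 1 keeps the total). Latent
classes are assigned by *stratified* ranks of the copula propensities with
exact largest-remainder counts: the panel composition is fixed, as for a
real germplasm collection, and the noiseless limit then recovers every
class deterministically (the middle class mean coincides with the grand
mean by symmetry).

Two deliberate departures from the published population are documented
rather than hidden:

1. **Small middle class.** The CI-of-the-mean band at n = 114 captures only
   ≈ 15% of a unimodal population, so a population with the published
   occupancy (55% semi-deep) is not recoverable by this classifier — most
   of a dominant middle class necessarily falls outside the band. The
   defaults therefore concentrate genotypes at the extremes with a small
   (10%) central mass, which makes latent classes identifiable: expected
   per-trait recovery at the defaults is ≈ 0.93 by the closed-form
   calculation (band half-width 0.56·σ; middle-class capture
   P(|Z| < 0.55) ≈ 0.42; extreme-class error Φ(−2.4) ≈ 0.8%), and the
   Monte-Carlo benchmark reproduces this. Passing recovery tests therefore
   shows the pipeline recovers *separated* latent structure; it does not
   show that real, continuously varying panels contain such structure.
2. **Sparse centre cell.** With a small middle stratum per trait the joint
   semi-deep × semi-dense cell (group 5) is often empty in a simulated
   panel, unlike the published tally where it is the largest cell. Analyses
   that need all nine groups populated should use the bundled reference
   classification fixture, which the tally/stability tests do.

The recovery benchmark reports depth recovery, density recovery, their mean
(`mean_class_recovery`, the headline number), the joint both-correct
fraction, and the RMSE of recovered block effects; replicates use seeds
derived deterministically from the base seed. With coincident class means
the report flags the scenario non-identifiable; recovery then equals the
label/classifier overlap Σ_c P(latent = c)·P(classified = c) ≈ 0.40 at the
default proportions.

## Numerical choices and degenerate inputs

- CSV round-trips use 17-significant-digit formatting (exact for doubles).
- Rows with missing primary measurements are dropped with a logged warning;
  no imputation rule was reported, so none is invented.
- Zero denominators (root volume, dry weight, root length) raise a domain
  error naming the offending trait and tube rather than emitting inf.
- Constant data: ANOVA F = 0 / p = 1; zero-variance traits produce NaN
  correlations plus a warning; identical profiles merge at height 0.
- Degenerate CI (zero variance) collapses to a point band; values equal to
  a band limit are middle-class (closed interval).
- The pipeline computes all artifacts before writing any, so a failed stage
  leaves no partial output directory; the manifest contains a config hash,
  seed and machine-readable warnings, and no timestamps, so identical runs
  are byte-identical.

## Problem sizes used by the test suite

The suite exercises the full design scale (300 tubes, 114 genotypes) for
structural and pipeline tests, 50 Monte-Carlo replicates for the recovery
benchmark, 100 random instances for the discriminant/ANOVA/Ward property
checks, and small hand-checkable fixtures (n ≤ 15) for every frozen oracle
value. These sizes were chosen so each property is measured with comfortable
margin while the whole suite stays fast enough to run on every change.

## Known limitations

- The classifier is the CI-of-the-mean band as specified; it is a
  population-relative split, not an absolute phenotype threshold, so class
  labels are not comparable across panels of different size or spread.
- The factorial check ANOVA is fixed-effects on the balanced check
  sub-design; no mixed models, spatial adjustment or heritability.
- Discriminant functions are reported without MANOVA significance tests.
- The generator does not model genetic relatedness, spatial greenhouse
  gradients, or longitudinal growth.
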