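# Methods

This note documents the models implemented in `neurovuln`, the structure the
synthetic-data generator plants, the defaults and why, and the numerical
conventions that tests rely on.

## Morphometric similarity

Each subject contributes five regional features: CT (mm), SA (mm²), GM
(mm³), MC (mm⁻¹), IC (dimensionless). Features are z-scored *per feature
across regions within each subject* using the sample (n−1) standard
deviation — the convention is unobservable from published MS maps, so it is
fixed here for exact testability. The MSN edge (i, j) is the Pearson
correlation of the two regions' five-feature vectors; the diagonal is set
to NaN (an excluded sentinel, never a 1) so nodal averages cannot silently
include it. Nodal similarity is the mean off-diagonal row entry. Because
z-scored feature columns each sum to ~0, the nodal-similarity distribution
is approximately zero-centered; its structure reflects how each region's
feature direction relates to the distribution of all regions' directions.

## Group contrasts

Contrasts are ordinary least squares per response (region or edge),
vectorized over responses: `NSᵢ ~ 1 + age + sex + Xan + Yan` for
sex-chromosome dosage designs and `NSᵢ ~ 1 + age + sex + Dx` for
case–control designs. The reported statistic is the two-sided T of the
dosage (Xan or Yan) or diagnosis coefficient. Responses with zero variance
get T = 0 (a flat response carries no group effect; the check uses a
relative tolerance of 1e−24 on the column variance to absorb float
cancellation). `z_for_plot` is the T map z-scored across regions and is a
display convention only. Edge models reuse the same design matrix as
regional models. The edge-effect taxonomy is the four sign combinations of
(control mean edge weight, edge T); exact zeros are assigned to the
positive branch — a measure-zero event kept deterministic for tests. A
total-surface-area covariate is available (off by default) and an optional
interaction screen (Xan×sex, Xan×Yan) reports p-values only.

## Expression atlas

Donor-level region × gene matrices are aggregated by the elementwise median
across donors, then each gene is z-scored across regions (sample SD). Gene
ranking always operates on the full atlas; the brain-expressed filter (a
per-gene flag) applies only to the cell-class analyses and ordered-list
exports, and does not recompute z-scores. A CNV gene set is a whole
chromosome, or the genes whose annotated start *and* end both lie inside
the closed interval `[median(proximal breakpoints), median(distal
breakpoints)]` — the encompassed-gene rule; boundary behavior is a package
choice since only "encompassed" is observable. The pseudoautosomal region
(PAR) is carried as its own chromosome label.

## PLS gene ranking

The predictor block X₀ is the centered atlas (columns already z-scored; no
rescaling inside the fit), the response y₀ the centered change map. SIMPLS
(de Jong's algorithm; the cross-product matrix is deflated by an
orthonormal basis of the X-loadings, not by the weights) yields component
scores T₁ = X₀w₁ and U₁ = y₀q₁ maximizing cov(T₁, U₁). For a univariate
response, w₁ is proportional to the gene-wise covariance X₀ᵀy₀ — the
independent oracle used throughout the tests. Polarity is fixed by flipping
(w₁, q₁, T₁, U₁) jointly so corr(T₁, change map) ≥ 0. Genes are ranked by
w₁ descending (ties broken lexicographically by gene label): rank 1 — the
most positive weight, i.e. high expression where MS increases in carriers —
has centered rank −(N−1)/2. Which PLS quantity the ranking uses is
ambiguous in common usage (region-indexed scores cannot index genes); predictor weights are used here, and for a univariate
response under the polarity rule the response-projected quantities induce
the same order. Per-component response-variance fractions are reported for
k = 5 components with a flag if component 1 is not maximal.

## Median-rank permutation tests

The enrichment statistic for a gene set is the median of its members'
centered ranks (midpoint for even sets). Null distributions draw
size-matched sets without replacement from the whole list (trans) or from
one chromosome (cis), vectorized by the random-keys trick. All Monte-Carlo
p-values use the add-one estimator (1 + #extreme)/(n_perm + 1) with ties
counted as extreme, so p ≥ 1/(n_perm+1) and can never be 0; an exhaustive
mode enumerates all subsets on small lists and returns the exact fraction
(the observed subset counting itself). Test direction is declared a priori
from the CNV sign: gains are tested for high median ranks and losses for
low ones. The most-extreme-chromosome test permutes gene ranks, recomputes
every chromosome median per permutation, and reports the add-one frequency
of the joint event "the target chromosome is the most extreme in the
declared direction AND its median is at least as extreme as observed";
anchoring at the observed value makes the test sensitive to enrichment
while retaining the most-extreme framing. The omnibus p treats the stored
null samples of several CNV results as simultaneous independent
permutations and reports the add-one frequency of all conditions being
jointly as extreme as observed; this construction is one defensible reading
and is flagged in result metadata. Permuted p-values are not corrected for
multiple comparisons by default; a Bonferroni flag exists for summaries.

DS/nDS comparisons permute set labels over the union's rank positions
(equivalent to rank permutation under exchangeability, and cheaper);
the statistic is median(DS) − median(nDS), two-sided by default. Decile
analysis assigns deciles on the full ranked list and tests each decile's
DS-vs-nDS within-set proportion difference with a one-sided
(over-representation) permutation p: DS genes in a DS-*depleted* decile
cannot logically belong to the extreme DS subset, and concentration of DS
genes in one decile mechanically depletes the others, so a two-sided test
would flag depletion deciles as significant. DS^SS is the set of DS genes
lying in deciles significant at p < 0.05. Set-size sensitivity subsamples
a donor set across sizes and compares the median of subsample medians with
genome-draw null medians per size.

## Cell-class decoding

A signature's regional profile is the median z-scored expression of its
genes per region. Signatures are clustered agglomeratively (average
linkage, a configurable package default) on correlation
distance; the cluster count uses Tibshirani's gap statistic with
uniform-box references (B = 50) and the 1-SE rule, computed on row-
standardized profiles so the Euclidean dispersion is monotone in the
correlation distance. Fine classes are formed by cutting the tree into as
many clusters as there are distinct retained cell labels and naming each by
its majority label; signatures with unassignable labels (an undivided
"Neuron" set, the pericyte "Per" set) are excluded beforehand, and nesting
of fine classes within the coarse clusters is verified (flagged, not
fatal). Class maps are weighted averages of member-signature profiles with
weights ∝ 1/(d + ε), ε = 1e−6, where d is the signature's Euclidean
distance from its class centroid in a PCA space retaining ≥ 95 % variance —
the distance-to-weight transform is the package's choice; inverse
distance is the documented default. The CNV screen restricts the
ranked list to brain-expressed genes, requires a two-sided median-rank
p < 0.05 for the class set, and reports the CNV∩class genes in the extreme
5 % rank centiles.

## Spin test

Each hemisphere's cortical sheet is its own unit sphere; left-hemisphere
parcel coordinates are stored as the mirror image (−x, y, z) of their
homotopic right-hemisphere positions. A spin draws three angles uniform on
[0, 2π) and rotates both hemispheres by the same matrix in this shared
frame — algebraically identical to the familiar "flip the angle signs about
y and z for the other hemisphere" rule expressed in per-hemisphere standard
frames (conjugation by the mirror), and the form that preserves the joint
law of mirror-sampled maps. Rotated parcels are matched to original parcels
greedily without replacement, processing rotated parcels in descending
order of mean Euclidean distance to the unrotated set; distance ties break
by parcel order. Every spin is a hemisphere-preserving bijection, so a spun
map preserves its value multiset exactly. Three uniform Euler angles are
not uniform on SO(3); the conventional three-axis angle procedure is kept deliberately, and
empirically the calibration of the test is insensitive to Haar vs Euler
sampling. Two known, measured limitations: (i) parcel-level greedy matching
jitters the spun map, mildly shrinking the null and making the test
slightly anticonservative for very smooth band-limited maps (false-positive
rate ≈ 0.06 at α = 0.05 for degree-≤6 harmonic maps on 300 parcels per
hemisphere); (ii) for extremely smooth maps (degree ≤ 2) the conditional
null is materially under-dispersed. Real T-statistic maps carry substantial
parcel-level noise and sit in the well-calibrated regime.

## Subject-level coupling

Expression (subjects × genes) and nodal MS (subjects × regions) are each
z-scored per column within karyotype group to remove between-karyotype
offsets, then centered; the first component is the dominant singular
triplet of the cross-block covariance (subjects as the common dimension).
Two conventions pin the sign, since a joint flip of both weight vectors
leaves the score correlation invariant: the mean gene loading is
non-negative (dosage-sensitive assay genes share a positive burden axis),
and the blocks' standardized subject scores correlate non-negatively.
Significance permutes the expression block's subject rows (either block is
equivalent under the null; one is fixed for determinism) and compares the
first singular value. Region loadings are compared to a change map by
Pearson correlation with a one-sided spin test, plus a subject bootstrap
that refits the PLS per resample. The comparison against the *observed*
group change map shares measurement noise with the loadings (both derive
from the same subjects' MSNs) and is therefore volatile at n = 55; the
comparison against the planted map is the stable readout in synthetic
studies, and both are reported.

## The synthetic-data generator

**Geometry.** Parcels are Fibonacci lattices, one full unit sphere per
hemisphere, the left mirrored from the right — matching how template
spherical surface projections treat hemispheres, which is essential for
spin-test validity. Default 152 parcels per hemisphere (304 regions).

**Smooth maps and latent factors.** Regional profiles are random
combinations of real spherical harmonics of degree ≤ 4 (QR-orthogonalized,
standardized), giving the spatially autocorrelated regime the spin test
exists for. K = 8 latent factors by default; factor 1 is the CNV-coupled
anatomical/expression gradient.

**Expression atlas.** Background gene g: Σₖ λ_gk fₖ + 0.8·noise with
λ ~ N(0, 0.3²). CNV gene: r·f₁ + √(1−r²)·u + 0.3·noise, where u is a single
shared deviation profile — sharing u keeps the *set-mean* gradient at
population correlation r with f₁ instead of averaging deviations away
(independent deviations would drive the realized coupling of a 40-gene set
toward 1). Dosage-sensitivity structure assigns per-gene couplings: nDS and
non-extreme DS genes default to the set coupling, DS^SS genes default to
−0.9 (their gradient aligns with the change map itself, the observed
opposite-polarity phenomenon); mixed couplings lower the realized set-mean
coupling below the nominal r, which is expected and visible in the demo
output. Donors add homoscedastic Gaussian noise (sd 0.3, a free parameter:
inter-donor variance of real donor-aggregated atlases is not publicly
characterized). Cell-signature genes follow their class profile plus a
signature-level deviation (not averaged away by the set median, emulating
study-to-study variation) and per-gene noise, both at `noise_sd`. Classes
have two-level structure: three coarse profiles (oligodendrocyte; other
glia/endothelium; neuronal) with seven fine classes at mixing weight
`fine_w` = 0.45. With any fine separation above the signature noise the gap
statistic correctly reports k = 7 on synthetic data; the coarse-only regime
(`fine_w` = 0) is the configuration in which the gap criterion's selection
of the planted coarse count (3) is meaningfully testable.

**Cohort.** Baseline regional feature structure is a skewed "majority" axis
(most regions mildly aligned, a tail strongly anti-aligned — reproducing a
zero-centered but structured nodal-MS distribution) plus two orthogonal
smooth components and subject noise (sd 0.35 per feature z-unit). Ages are
uniform on [5, 25] years, sexes balanced; age and sex have small planted
feature effects so the covariates are exercised. The group effect pushes
case regions' feature vectors along the majority axis in proportion to the
planted change map (−sign × f₁), most strongly through GM and MC (effect
weights [0.15, 0.15, 0.70, 0.60, 0.25]), so gains and losses produce
mirrored expected contrasts and leave-one-feature-out analysis flags GM/MC.
The induced nodal-MS response depends on higher-order interactions between
the baseline maps and the change map that defeat closed-form control, so
the generator *enforces its planted contract*: candidate baselines are
drawn (deterministically from the seed, ≤ 20 candidates) until a 24-repeat
Monte-Carlo probe confirms the expected nodal-MS response correlates ≥ 0.5
with the planted map, keeping the best candidate otherwise. Carrier
severity is a per-subject multiplier (sd 0.6) — wide penetrance variability
that also supplies the inter-individual signal for the subject-level
coupling analysis.

**Carrier expression.** Per-subject DS-gene expression = group mean + β ×
(the subject's within-group-standardized MS projection onto the planted
change map) × gene loading + noise; defaults: 11 assay genes, three
karyotype groups (XXX/XXY/XXYY-like) among 55 carriers, noise sd 0.3.

**What passing tests do and do not show.** The generator produces Gaussian,
stationary-noise data with exactly one anatomical gradient coupled to the
CNV set, no site/scanner effects, no probe-level structure, no spatial
heteroscedasticity, and planted couplings that are linear by construction.
Calibration and recovery results therefore validate the *machinery* —
estimators, permutation nulls, polarity conventions, end-to-end plumbing —
not the biological claims, and say nothing about robustness to the
artifacts of real MRI or microarray data.

## Simulation sizes and numerical conventions

Acceptance-level simulations use 152 regions per hemisphere, 2,000-gene
atlases with 6 donors, 40-gene CNV sets at coupling 0.7, cohorts of 80+80
(group contrasts) or 55 carriers + controls (subject-level coupling), 1,000
permutations per test, and 100 seeds per recovery claim; spin calibration
uses 300 parcels per hemisphere, degree-≤6 maps, 250 spins and 200 map
pairs. These sizes were chosen so each claim is measured at tight Monte-
Carlo error on a single CPU. Other conventions: all medians of even-sized
sets are central midpoints; all z-scores use the sample (n−1) SD; all
tabular output uses "%.10g" float formatting so reruns are byte-identical;
every stage seed derives from one master seed via `SeedSequence.spawn`.

## Known limitations

- The spin test's greedy parcel matching is mildly anticonservative for
  very smooth maps (measured above); variogram-matched surrogate maps
  would be the alternative and are out of scope.
- P_RAND treats gene ranks as exchangeable; co-expressed gene sets (e.g.
  the shared-deviation CNV sets at coupling 0) have overdispersed median
  ranks relative to that null, as they do for real co-regulated sets. The
  calibration guarantee applies to the test's own null (random sets).
- The omnibus-p and most-extreme-chromosome constructions are defensible
  readings of under-specified procedures; both are flagged in metadata.
- Single-hemisphere spin geometries skip mirroring with a warning; maps
  defined only on the left hemisphere are tested that way.
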