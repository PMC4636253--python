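# Methods

## The model

Each individual carries a left and a right copy of a bilaterally paired
structure (matching symmetry: two separate mirror-image objects, not one
object with an internal midline). Every copy is digitized R times. In the
tangent space at the sample consensus, the shape of copy (i, s, r)
decomposes as

    y_isr = μ + a_i + δ·1[s = right] + b_is + e_isr

with a_i the individual effect (inter-individual variation; the inverse of
canalization), δ a fixed directional-asymmetry field, b_is the
individual×side effect (fluctuating asymmetry; the inverse of
developmental stability), and e_isr digitization error. Centroid size
follows the same ladder with scalar components. The package estimates and
tests each layer and asks whether the inter- and intra-individual layers
are buffered by a common mechanism (correlations of magnitudes; angles
between principal displacement directions).

## Superimposition

Left configurations are mirrored (x negated) once, as preprocessing; the
Procrustes fit itself is rotation-only (SVD with a determinant guard), so a
chiral shape can never be silently reflected during fitting. All
configurations are centered and scaled to unit centroid size (full
Procrustes); the consensus is re-estimated and renormalized each round.
The iteration runs to near machine precision (consensus change < 1e-13,
max 100 rounds) so that re-running GPA on aligned output reproduces the
solution to better than 1e-10 — up to the global-rotation gauge freedom
that any superimposition leaves, which tests remove with a single Kabsch
rotation before comparing.

Tangent coordinates are the deviations from the consensus with the
consensus direction projected out. Centering (2), scaling (1) and
rotation alignment (1) leave intrinsic dimension d = 2·LM − 4 (76 for the
40-point anchor scheme). Semilandmarks are treated as fixed points — no
sliding — which is what makes d = 76 the correct df multiplier here.
Procrustes distance is the plain Euclidean distance between
commonly-aligned coordinate vectors (no per-pair re-superimposition); that
choice keeps the SS bookkeeping of the ANOVA exact.

## Symmetry ANOVA

Shape SS are the classical balanced two-factor sums of squares computed
per coordinate and summed; univariate df are multiplied by d. F ratios
follow the mixed-model ladder (individual and side over the interaction;
the interaction over replicate error), the only assignment consistent with
the published tables this design reproduces. Parametric p-values use the
F distribution at those df; they are exact for isotropic Gaussian tangent
noise, and in the small-variation regime the Procrustes nonlinearity
contributes only second-order error (the type-I rate of the side test is
verified at 5% over 1000 null simulations).

The interaction-free submodels are a distance-based permutational MANOVA
(sequential SS, individual entered first; pseudo-F over the pooled
residual; p from 999 seeded permutations of raw observation rows — the
permutation count is this tool-family's convention, not an inherited
setting) for shape, verified against vegan's `adonis2` on a fixture, and a
classical additive two-way ANOVA for size. Diagnostics: Shapiro–Wilk on
replicate-stratum residuals, Brown–Forsythe Levene across sides for size,
and a dispersion-homogeneity test (distance to own side's centroid, one-way
F, permutation p) for shape.

## FA indices and antisymmetry screens

Size FA is the replicate-averaged |CS_L − CS_R|. Shape FA averages
replicates *before* taking the left–right Procrustes distance; averaging
first reduces the measurement-error contribution and mirrors the size
definition. The opposite order is available (`average_first=False`) and
recorded in the call; the average-first default is the package's choice
where either reading is defensible. No measurement-error correction is
subtracted from the indices — error is handled by the ANOVA instead.
Inter-individual scores are deviations of individual means from the sample
consensus, the only definition that yields one point per individual for
the scatterplots.

Reading the interaction stratum as FA presumes the signed asymmetries are
zero-mean and unimodal. Two screens check this: the signed R−L size
distribution (skewness, excess kurtosis, and Hartigan's dip statistic —
implemented here with the classical greatest-convex-minorant /
least-concave-majorant algorithm, since no installed library provides it;
p by Monte Carlo against the uniform null, the hardest unimodal case) and
the side overlap of PCA scores of aligned coordinates (nearest-centroid
side-classification accuracy; ~0.5 means one mixed cluster). The verdict
flags antisymmetry when excess kurtosis < −1 or the dip test rejects at
0.05.

## Variation structure and angle tests

Each ANOVA stratum yields a deviation matrix (individual means about the
grand mean; interaction contrasts; replicate residuals) whose
row-weighted squared norms reproduce the ANOVA SS exactly — an identity
the tests assert. PCAs of these matrices give the dominant displacement
fields per variance source; eigenvector signs are fixed by making the
largest-magnitude loading positive.

Angles between index-matched PCs are folded to [0°, 90°] via |cos|, making
them invariant to eigenvector sign. The null is the angle between two
independent uniform unit vectors in d = 2·LM − 4 dimensions: |cos θ|² is
Beta(½, (d−1)/2), so p = P(angle ≤ observed) comes from the regularized
incomplete beta function; a seeded Monte-Carlo twin must agree within 0.01.
The test is one-sided (smaller-than-random angle = shared structure), and
d is kept at 2·LM − 4 even though a stratum's row rank may be lower — the
null describes directions in the full shape space, not in the stratum's
span. Index-matched pairing (PC1–PC1, …) is the default; cross-pairing is
a caller-side loop.

## Correlations, SMA, allometry

The buffering battery is a frozen 12-row schema (schema-tested): question
(a) inter~intra per trait and anchor, (b) shape~size within each level,
(c) the four scores across anchors on the individuals present in both.
Pearson correlation is the default (consistent with fitting SMA trend
lines; Spearman is an option), with no multiple-testing correction across
the battery by default (Holm available). SMA slope = sign(r)·sd(y)/sd(x);
trend lines are flagged only where p ≤ 0.05.

Allometry is the multivariate regression of tangent coordinates on raw
centroid size (log CS optional; raw is the default since nothing in the
design implies a log scale), reported as 100·SS_predicted/SS_total with a
permutation p (10 000 by default). Note the finite-sample inflation of the
share: even under the null the regression captures ≈ 100/(n_obs − 1)
percent, so planted-recovery checks compare against the analytic expected
share, not the planted share alone.

## Synthetic data

The generator adds i.i.d. Gaussian displacement fields per coordinate in
the tangent space at a fixed chiral anchor-like template (8 landmarks on a
closed outline, 3–6 semilandmarks equidistant per segment; default 40
points), then rescales to the drawn centroid size, applies a random
rotation and translation so the alignment step is genuinely exercised, and
mirrors left copies so the pipeline's reflect step is exercised too. The
DA field is a fixed unit field (a normalized seeded Gaussian draw, stored
with the ground truth) scaled to `da_magnitude`. An optional per-individual
lognormal `buffering_sd` factor scales the individual and FA components
together, planting exactly the shared-buffering signal question (a) looks
for. An optional allometry field shifts shape by CS deviation.

Default variance components are back-solved from the reference study's
mean-square ladders (e.g. dorsal shape: sd_error = √MS_rep ≈ 0.0049,
sd_fa = √((MS_int − MS_rep)/R) ≈ 0.0021, sd_individual =
√((MS_ind − MS_int)/(2R)) ≈ 0.0035, per coordinate at unit centroid size;
size ladder likewise, around a mean CS of 100 in the data's opaque length
units — the digitization units are carried through unchanged). Dorsal
defaults use N = 25, ventral N = 30, both R = 2; directional asymmetry
defaults to zero (the study design's side effect was null). All SDs stay
below 0.5% of centroid size, so the small-variation linearization of the
tangent-space arithmetic holds.

What the generator does *not* emulate: non-Gaussian error, digitizer-
specific bias between replicates, spatially correlated landmark noise,
sliding-semilandmark covariance, or anisotropic individual variation.
Passing tests therefore certify the estimators and their calibration under
the stated model, not robustness to those departures; with isotropic
effects the per-stratum PC percentages are far flatter than real data's.

## Problem sizes and numerics

Tests and the acceptance script run simulations at the study's own sizes
(N = 25/30, R = 2, LM = 40), with N = 200 for variance-component recovery
(method-of-moments estimates averaged over replicate simulations, since a
single size-trait ladder at N = 200 has ~10% sampling noise), 1000 null
runs for type-I calibration, and 10⁵ draws for the Monte-Carlo angle null.
Degenerate inputs are handled explicitly: constant sizes yield an ANOVA
with F reported as not-applicable plus a warning; all-zero signed
differences give an FA-consistent verdict with a degeneracy warning;
zero-variance inputs to correlation/SMA raise. Ties in the F-ladder
tie-break order, eigenvalue ordering and permutation p-values
((1 + #{F* ≥ F})/(n_perm + 1)) are deterministic given the seed.
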