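# Methods

This note documents the statistical models and numerical conventions behind
`dartpop`, the choices made where several defensible options existed, and
what the synthetic-data experiments do and do not demonstrate.

## Data model

A panel is a genotypes × markers matrix over three states: band present (1),
band absent (0), missing.  Varieties are assumed homozygous, so one band
call per genotype per marker is the complete observation — the 0/1 vector
*is* the allele vector.  All estimators treat missing calls by
complete-case analysis at the finest level that keeps them unbiased:
per marker (band frequencies, PIC, diversity), per genotype pair (Jaccard,
AMOVA distances), or per marker pair (r²).  No imputation is performed
except in PCA (marker band-frequency imputation) and PCoA (matrix-mean
imputation of undefined distances), both logged.

## Admixture model and inference

The clustering model is the classical admixture mixture for haploid
biallelic data: genotype i has membership q_i ~ Dirichlet(α, …, α) over K
source populations; population k has band frequency p_{k,l} ~ Beta(1, 1) at
marker l; each call arises from a latent origin z_{i,l} ~ Categorical(q_i)
with x | z = k ~ Bernoulli(p_{k,l}).  Inference is Gibbs sampling of
(z, p, q) with a Metropolis random walk on α (normal proposal, sd 0.25,
reflected at 0, uniform prior on (0, 10], initial value 1).  Missing cells
contribute no likelihood and are skipped in the z update.

Design decisions:

- **Haploid Bernoulli likelihood, not a diploid dominant-genotype model.**
  This is the single largest modelling decision.  For a panel of homozygous
  inbreds the dominant masking problem (heterozygote indistinguishable from
  homozygote-present) vanishes, and the one-draw-per-genotype likelihood is
  exact.  A diploid-dominant mode is explicitly out of scope.
- **Independent Beta(1, 1) frequency priors** (no correlated-frequencies
  model, no linkage model, no prior-population flags).
- **Evidence estimate.** Every 10th post-burn-in iteration records the
  marginal data log-likelihood log Pr(X | Q, P) (latent origins summed
  out); ln Pr(X | K) is estimated as mean − variance/2 of those samples,
  the standard harmonic-style estimate reported by admixture software.
  The z-conditional likelihood was rejected: its variance is dominated by
  latent-origin churn, which makes the variance-penalised evidence — and
  hence ΔK — unstable on thinned marker sets.
- **ΔK (Evanno).** With replicate runs per K, L′(K) = L(K) − L(K−1) and
  L″(K) = L′(K+1) − L′(K) on the replicate means; ΔK = |L″(K)| / sd(L(K)),
  defined for interior K only.  A K whose replicate sd is zero gets an
  undefined ΔK and is excluded from the argmax.  ΔK cannot, by
  construction, select the smallest or largest K tested.
- **Label switching** across replicate runs is resolved by greedy matching
  of q columns against the first run (largest column overlap first);
  ln Pr(X|K) is label-invariant and untouched.  Averaged memberships are
  means over aligned runs.
- **Hard assignment** is the argmax membership, ties to the lowest group
  index; genotypes with top membership < 0.6 are flagged admixed but still
  assigned (the threshold is a reporting convention, not a filter).

## LD-based marker thinning

Markers are scanned in (chromosome, position) order; a marker is retained
iff its permutation r² test against every already-retained marker on the
same chromosome is non-significant at α = 0.05.  The scan order is a
declared convention — the retained set depends on it, so a retained-set
*size* is reproducible only up to that choice.  Each pair's permutation
stream is seeded from the master seed and the two marker column indices,
making every pair decision independent of scan history.  Note that
thinning removes preferentially the most group-differentiated markers
(structure induces LD between them), so Φ_PT on the thinned set runs lower
than on the full set; both are reported.

## Distances, ordination, outliers, association

- **Jaccard** d = (M01 + M10) / (M01 + M10 + M11) over markers scored in
  both genotypes; double absences are ignored because absence of a dominant
  band is uninformative.  Pairs with an empty denominator get a missing
  distance and a warning.
- **PCoA** is classical scaling: double-centre −½D², eigendecompose, scale
  eigenvectors by √λ.  Negative eigenvalues (non-Euclidean input) are
  dropped from both the axes and the explained-fraction denominator.
- **PCA** runs on centred, variance-unscaled 0/1 columns (scaling would
  up-weight rare bands); missing calls are imputed with the marker band
  frequency.  "Top loading" markers are the ⌈fraction × L⌉ markers with the
  largest |loading| on a chosen axis (default: top 5% on PC1, the
  group-separating axis).
- **Outlier screening** flags *isolated* genotypes: the log distance to the
  3rd-nearest neighbour on the first two axes, flagged when it exceeds the
  panel median by more than k_sd (default 4) right-tail-consistent robust
  standard deviations ((Q90 − median)/1.2816 — nearest-neighbour distances
  are right-skewed, so a symmetric MAD scale is anti-conservative).  A
  centroid-distance rule was rejected because it flags every member of a
  compact minority subpopulation once group separation is strong, which
  amputates the smaller group before clustering; isolation distinguishes a
  failed assay (far from everything) from minority-cluster membership
  (close to its peers).  Null calibration: on homogeneous Gaussian clouds
  (n = 30–200) the rule is flag-free in ≥ 96/100 seeds, while a single
  10×-spread point is flagged exactly.  The pipeline applies one exclusion
  round, not an iteration.
- **Marker–group association**: with a binary marker and a two-group split
  the general linear model reduces to a 2×2 table; it is scored by
  chi-square with continuity correction, switching to Fisher's exact test
  when any expected cell is below 5.  Benjamini–Hochberg q-values are
  reported alongside raw p-values (1,400+ simultaneous tests demand
  multiplicity control even if a raw-p workflow is traditional).

## Diversity and AMOVA

Gene diversity per marker is h = 2f(1−f) (also the PIC form used for
dominant biallelic markers); the reported H is the mean over the marker
set, per group and pooled.  No small-sample n/(n−1) correction is applied.

AMOVA uses squared Euclidean distances between 0/1 profiles — the standard
binary-data route — with missing calls handled by rescaling each pair's
mismatch count by (total markers / comparable markers).  With N genotypes
in G groups of sizes n_g:

    SS_total  = Σ_{i<j} d²_ij / N
    SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g
    σ²_w = SS_within / (N − G)
    σ²_a = (SS_among/(G−1) − σ²_w) / n₀,   n₀ = (N − Σ n_g²/N)/(G−1)
    Φ_PT = σ²_a / (σ²_a + σ²_w)

A negative σ²_a is reported raw; Φ_PT is computed from the value clamped at
zero (the convention of the standard spreadsheet implementations), with the
raw Φ retained for diagnostics.  The permutation test permutes genotype
labels among groups, compares raw Φ, and carries the +1 correction
p = (1 + #{Φ_perm ≥ Φ_obs}) / (1 + n_perm), so p is never exactly zero;
the default 999 permutations give a 0.001 resolution floor.

## LD decay

r² between two markers is the squared Pearson correlation of their 0/1
vectors over genotypes scored at both loci; under the homozygosity
assumption this equals the classical haplotype-count formula
D²/(p_A p_a p_B p_b) exactly (unit-tested to 1e-12).  Only intra-chromosomal
pairs are computed.  Per-pair significance permutes one marker's calls
(1,000 permutations by default), with the +1 correction; permutations for a
pair are seeded from the master seed and the pair's column indices.  Pairs
with fewer than 4 shared calls or a monomorphic complete-case column are
skipped and counted.

The background LD is the 95th percentile — linear interpolation between
order statistics — of r² among *unlinked* pairs, defined as same-chromosome
pairs strictly more than 50 cM apart.  The decay curve is a loess smooth of
the significant (p < 0.05) pairs' r² against distance: tricube weights,
**locally quadratic** (degree 2), span 0.5 by default (the span is a
configuration knob recorded in the run log; no installed library offers a
degree-2 loess on a user grid, so the local regression is implemented
here).  The curve is evaluated on a 0.5 cM grid from 0 to the largest pair
distance; the decay distance is the first grid point at or below the
background (grid evaluation rather than root-finding, because loess is
defined pointwise).  If the curve never reaches the background, the result
records "no intercept" together with the curve's terminal extent — a real
outcome for small or strongly structured groups whose background is as high
as the significant-pair plateau.

## Synthetic data

`simulate_panel` draws Balding–Nichols panels: ancestral band frequency
p ~ U(0.05, 0.95) per marker; group frequency ~ Beta with mean p and
variance p(1−p)·F_ST (the F-model matching the admixture prior — the
natural generative model when differentiation is specified by a single
F_ST summary); haploid
Bernoulli band calls; optional selected block overriding group frequencies
on an interval of one chromosome; independent missingness.  The default
configuration emulates a European winter-wheat variety panel: 26 + 66
genotypes, 1,400
markers over 21 chromosomes with the B > A > D genome asymmetry typical of
wheat DArT maps (48%/33%/19%), 150 cM chromosomes, a 67 cM marker desert on
4D, a 2D block at 10–30 cM with group frequencies (0.9, 0.1), and 3%
missing calls.

`simulate_ld_block` generates distance-dependent linkage with a stationary
symmetric two-state Markov walk along each chromosome: state correlation at
distance d is exp(−2θd), hence r² ≈ exp(−cd) with c = 4θ, calibrated from a
target r² at a reference distance.  It is a *testing device* for the decay
estimator, not a model of real haplotype structure.  Because its genotypes
are independent walks, the panel has no population structure, and its
unlinked-pair background coincides with the permutation significance
cutoff — so against its own background the decay curve yields the
"no intercept" outcome by construction.  Decay-recovery experiments
therefore supply a fixed elevated background (0.10, the level structured
panels show) and compare the fitted crossing with the analytic target
solving exp(−cd) + 1/n = background (the 1/n term is the sampling inflation
of r² for n genotypes).

What passing tests on these panels show: the estimators are unbiased and
calibrated under the generating model (independent markers given group,
exchangeable genotypes, uniform missingness).  What they do not show:
robustness to genotyping-error structure, marker ascertainment bias,
pedigree relatedness within groups, or real haplotype-block LD — none of
which the generator emulates.

## Problem sizes and reproducibility

All stochastic stages consume a single integer seed; stage seeds and
per-pair permutation streams are derived from it, so identical
configuration + seed reproduces every output byte for byte.  The default
MCMC length (9,999 burn-in + 9,999 iterations, 10 replicate runs, K up to
10) mirrors a full production analysis; the test-suite and acceptance-script
experiments use the package's scaled experimental design — K ∈ 1..4, 5
replicates, 400 + 400 iterations on panels of ~300–1,400 markers, and
199–999 permutations — which the recovery experiments show is sufficient
for panels of this size (ΔK argmax = 2 in 10/10 seeded runs, >99% label
agreement at 378 markers).

## Known limitations

- ΔK cannot choose K = 1; inspecting the mean log-evidence curve remains
  necessary to distinguish "no structure" from K = 2.
- The thinned-set size and membership depend on the declared scan order.
- The permutation r² test is exchangeable-null; it does not account for
  relatedness within groups.
- `pairwise_phi` re-runs the two-group AMOVA per pair; p-values are not
  adjusted for the number of pairs.
- The loess span default (0.5) is a convention; decay distances move by a
  few cM across reasonable spans, which is within the estimator's seed
  variability.
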