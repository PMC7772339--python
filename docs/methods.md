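# Methods

This note documents the models, the numerical choices and the synthetic
data generator behind `mossbiome`, and what passing the test-suite does
and does not establish about real data.

## Data model and filters

The substrate is a non-negative integer OTU × library count matrix with a
semicolon-ranked taxonomy string per OTU, plus per-library metadata
describing a nested design: system (`amb` brown-moss fens / `sph`
*Sphagnum* bogs) → area → subsite → moss plant, each plant yielding two
endophyte technical-replicate libraries and one epiphyte library, with
sediment/vascular reference libraries per subsite.

Two filters run before any statistic:

* **Taxon filter.** Case-insensitive substring matching on the lineage
  (default pattern `chloroplast`, matching the class-rank annotation of
  plastid reads) plus a domain check: an OTU whose kingdom token
  contradicts the table's amplicon domain is removed.
* **Rare-entry filter.** Every count strictly below `min_fraction`
  (default 1e-4, i.e. 0.01%) of its library size is set to zero; library
  sizes are taken *before* zeroing so the rule is reproducible from the
  raw table alone; rows left all-zero are dropped. The inequality is
  strict, so an entry at exactly 0.01% survives. Whether a survey's rare
  filter zeroes entries or removes whole OTUs is ambiguous in practice;
  both semantics are exposed (`drop_whole_otus`), entry-zeroing being the
  default because "sample-wise relative abundance" is a per-entry
  quantity.

## Diversity and group contrasts

Inverse Simpson `1/Σpᵢ²` (effective number of equally abundant OTUs,
1 ≤ D ≤ richness, equality at uniformity) and richness (positive-count
OTUs). Pairwise contrasts use

* Mann–Whitney–Wilcoxon rank-sum for diversity indices: exact null when
  both groups have ≤ 50 observations and the pooled sample has no ties,
  otherwise normal approximation with tie and continuity correction;
* pooled-SD t tests for environmental variables: one SD pooled across
  *all* groups, N − k degrees of freedom (Welch available per pair).

Both adjust with Holm by default; the adjustment is a reporting choice,
surfaced in the result object, since the field's convention (the pairwise
test helpers of the common statistical environments) defaults to Holm.
The compact letter display is built by greedy insert-and-absorb and is
validated by its defining constraints (shared letter ⇔ adjusted p ≥ α)
rather than by canonical strings, because letter assignments are not
unique.

## Correlation dendrograms

Spearman (mid-rank) or Pearson correlations between library profiles;
dissimilarity `d = 1 − r` (the minimal monotone transform — recorded in
output metadata because r-to-d conventions vary); agglomerative nesting
with Lance–Williams updates (average linkage default, i.e. UPGMA; single
and complete available). Ties in the minimum dissimilarity are broken
toward the smallest cluster-id pair so that merge order is identical
across platforms. The agglomerative coefficient is
`AC = mean_i (1 − h_first(i)/h_final)`: 0 for equidistant leaves, → 1 as
early merges become tight relative to the final join. Newick export
places each node at half its merge height, making tip-to-tip path lengths
equal cophenetic heights. The agglomeration is implemented in-package
(a generic library implementation serves as the independent oracle in the
tests) because AC and deterministic tie-breaking are part of the
contract.

## Ordination

With `P = Y/N` (N the grand total), row masses `r`, column masses `c`:

    Q = D_r^{-1/2} (P - r c') D_c^{-1/2},   total inertia = ||Q||_F² = χ²/N.

* **CA**: SVD of `Q`; eigenvalues are squared singular values; site and
  species scores are the singular vectors rescaled by `D_r^{-1/2}`,
  `D_c^{-1/2}`.
* **CCA**: constraint columns are centered by their row-mass-weighted
  means and weighted by `√r`; `Q`'s rows are projected onto their span
  (modified Gram–Schmidt basis); SVD of the fitted part gives constrained
  axes, of the remainder unconstrained axes.
* **Partial CCA**: the conditioning span is removed from both `Q` and the
  constraints first; the identity conditioned + constrained + residual =
  total then holds to machine precision and is asserted on every fit.

Collinear constraints raise an error naming the aliased columns
(tolerance 1e-9 relative); `drop_aliased=True` instead drops them, which
the pipeline uses because realistic designs are aliased by construction
(the reference fraction is determined by the reference plant labels;
subsites nest areas). Conditioning matrices always drop internal aliasing
silently — only their span matters.

**Inference.** Pseudo-F = (constrained/q)/(residual/(n − q − p_cond − 1)),
with q the constraint rank. The null permutes rows of `Q` freely when
there are no conditions and rows of the reduced-model residuals
`Q − H_Z Q` otherwise (reduced-model residual permutation is the standard
exchangeability argument for partial constrained ordination);
`p = (1 + #{F* ≥ F})/(n_perm + 1)`, so p can never fall below
`1/(n_perm+1)`; `n_perm < 19` is rejected as uselessly coarse.

**Variance partitioning** is marginal by default — each variable's share
is the constrained inertia of the partial model conditioning on all other
variables, as % of total inertia — because per-variable percentages
reported in surveys of this kind do not sum to the joint constrained
share, which is the signature of partial (marginal) effects. Sequential
(Type-I-like) partitioning is available behind `scheme="sequential"`.
Marginal shares only sum to the joint share for orthogonal designs
(asserted in the tests for a balanced equal-library-size design).

**VIF** uses the row-mass-weighted regression of each encoded column on
the others, `1/(1−R²)`, ∞ flagged for exact collinearity.

Constraint preparation drops variables missing in > 20% of samples (the
missingness regime in which field campaigns drop covariates), then drops
remaining incomplete samples complete-case; categoricals are
treatment-coded against the alphabetically first level, continuous
variables centered. Reference-level choice affects individual coefficient
columns, not the span, hence none of the reported inertias.

## Core microbiomes

`min_count = ⌊t·n⌋` converts a prevalence threshold to a sample count —
the floor is forced by the worked example 66% of 122 → 80 (ceiling would
give 81). Presence means count > 0 after the rare filter, recorded in the
result's provenance. The total core (66%) additionally requires presence
in ≥ 1 sample of every system; the stricter reading (threshold met within
each system) is available as per-system cores. Species cores use 75%.
Contributions are min–max over samples of the summed relative abundance
of core OTUs, per group. Raising the threshold can only shrink a core
(monotonicity is property-tested).

## Endophyte screen

Unit of pairing is the moss plant: the two endophyte technical replicates
are summed (replicates are technical, and direction under summation
agrees with the replicate mean on replicate-consistent data — asserted in
tests), the epiphyte library is the comparator, and the 2×2 table is
[this OTU vs all others] × [endo vs epi]. Pearson's X² without continuity
correction; the null fixes both margins. For a 2×2 table that null *is*
the central hypergeometric distribution, so the sampler draws
hypergeometric counts directly (vectorized); r×c tables fall back to
Patefield sampling. `p = (1 + #{X²* ≥ X²})/(n_rep + 1)` with n_rep = 5000
by default; a zero margin leaves X² undefined and the table is flagged
untestable with p = 1.

An OTU qualifies when it is endophyte-higher (chi-square is
direction-blind, so direction is imposed via the endo-mean vs epi
relative abundance) with p < 0.001 in at least one plant unit
(configurable), and its endo-mean relative abundance exceeds 0.5% in at
least four plant units. No multiple-testing correction is applied beyond
the stringent α, mirroring field practice; an optional BH layer can be
applied downstream by the caller from the per-unit p-values. OTUs that
cannot meet the abundance filter are skipped by default (they cannot
qualify regardless of p; `test_all=True` tests everything, used for the
null-calibration analyses). A pooled mode (one 2×2 per OTU summed over
units) is exposed because the per-unit vs pooled reading of "libraries of
the same sample" is ambiguous; per-unit is the default as the closest
literal reading.

Heatmap export is `log₂(endo-mean relabund × 100,000)` with zeros floored
at half the smallest nonzero value, rows/columns clustered by Pearson
correlation → 1 − r → average linkage.

## Synthetic study generator

Defaults: 2 systems × 2 areas × 3 subsites × 3 plants (2 endo + 1 epi
libraries each) + 2 references per subsite = 132 libraries; 2000 OTUs of
which 50 shared core, 300 per-system specific, 25 endophyte-enriched;
library sizes uniform in [5,000, 50,000].

Composition model, per sample: log-linear expected weights = background
`N(0, 1.2)` per OTU + system block structure (system-specific OTUs −∞
off-system, +1 on-system) + sparse plant-species shifts + sparse
covariate responses (pH, temperature, CH₄ slopes on standardized values)
+ `log(fold)` on planted endophyte OTUs in endophyte fractions. The
planted core is overlaid at fixed weight per OTU relative to a unit-mass
background: 0.02 in `sph`, 0.002 in `amb`, which realizes core shares of
roughly 35–60% of a *Sphagnum* community and 4–15% of an Amblystegiaceae
one — the asymmetry observed in real peatlands, where OTUs shared between
systems are among the most abundant *Sphagnum* community members.
Planted endophyte OTUs draw their baseline from the abundant tail
(`N(2.5, 0.4)` on the background log scale): an endophyte-enriched OTU
that never reaches the screen's 0.5% reporting floor would be
structurally unrecoverable and would make sensitivity targets
meaningless.

Noise is Dirichlet-multinomial: one plant-level Dirichlet latent
(concentration = dispersion × expected profile, dispersion 200 by
default) shared by *all three* libraries of a plant; the endophyte
version reweights that same latent by the enrichment fold, so at fold = 1
endophyte and epiphyte libraries are exchangeable draws — a genuine null
for the paired screen. Technical jitter is a second Dirichlet at
concentration 1e6 × latent (small, as technical replicates are);
appreciable between-fraction overdispersion would make the chi-square
screen reject everywhere on real effects that are not enrichment, which
is a property of such data the generator deliberately does not emulate
(see limitations). Covariates are generated correlated with system (pH
5.8–7.0 in `amb`, 3.3–5.0 in `sph`; CH₄ higher in `sph`), reproducing the
plant-species/environment collinearity that motivates conditioning on
spatial variables.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy misannotation, compositional zero-inflation beyond
Dirichlet-multinomial, between-fraction biological overdispersion,
archaea (a single domain label is used), and failed libraries (the real
survey lost ~20% of samples to PCR/sequencing failure). Passing the
recovery and calibration suites therefore shows the *statistics* are
implemented correctly and are calibrated under their stated assumptions —
not that those assumptions hold for any particular real dataset; in
particular the paired chi-square screen is anti-conservative on
overdispersed real pairs.

## Problem sizes and numerical tolerances

The test-suite runs the full default design (2000 × 132) for recovery
checks (20 seeds), reduced designs (250–300 OTUs) for calibration, and
≤ 12 × 10 tables for oracle equivalence; eigenvalue agreement with the
independent generalized-eigenproblem formulation is asserted at 1e-8,
inertia decomposition identities at 1e-8 relative, Monte-Carlo vs exact
conditional p-values at 3 binomial standard errors (allowing the expected
~0.3% of chance 3σ exceedances over ~1500 independent tables, hard bound
5σ). Rank decisions use a 1e-9 relative tolerance; permutation and
Monte-Carlo p-values are reported with their replicate counts and are
bounded below by 1/(n+1).

## Known limitations

* CA/CCA scores are exported in one scaling (mass-rescaled singular
  vectors); other scalings (e.g. species-conditional biplots) must be
  derived by the caller from eigenvalues + scores.
* The permutation test permutes rows of the standardized residual matrix
  with masses held fixed; for very unequal library sizes this is an
  approximation to re-deriving masses per permutation (both are in use in
  the field; the choice is recorded here).
* BIOM input requires the optional `biom-format` dependency; TSV is the
  canonical interchange format.
* The endophyte screen reports per-unit p-values uncorrected; study-wide
  error control relies on the stringent α = 0.001 and the abundance
  filter.
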