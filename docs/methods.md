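# Methods

## The association statistic

All pairwise taxon–taxon association in this package is built from the
concordance partition of sample index pairs. For abundance vectors x, y of
one taxon pair over the same n samples, each of the N = n(n−1)/2 index
pairs is classified as concordant (C), discordant (D), tied only in x (Tx),
tied only in y (Ty), or tied in both (Txy); the partition always sums to N.

The default statistic is γ = (C − D)/(C + D). With no ties this equals
Kendall's τ; with ties it is the Goodman–Kruskal gamma, which simply
ignores tied pairs. Because zero-inflated abundance profiles guarantee
ties, γ and the tie-corrected τ_b = (C − D)/√((C+D+Tx)(C+D+Ty)) genuinely
diverge on real data (γ reaches ±1 whenever the untied subset is fully
concordant/discordant; τ_b does not). Both are implemented; every output
row records the method used. A pair with C + D = 0 (e.g. one taxon absent
from every sample of a group) has no defined statistic and is excluded from
the analysis family as *degenerate*, with the exclusion logged — this is
what produces focal-taxon tables with zero partners in groups where the
taxon never occurs.

## Permutation null and FDR

No closed-form null is trusted at n = 6–8 under heavy ties, so p-values
come from permutation: y is permuted against x and the statistic
recomputed, two-sided on |statistic|.

* n ≤ 8 (`max_exact_n`, configurable): all n! permutations are enumerated.
  The comparison |stat_perm| ≥ |stat_obs| is done in exact integer
  arithmetic (|C−D|_perm · (C+D)_obs ≥ |C−D|_obs · (C+D)_perm), so no
  floating-point tolerance enters. A degenerate permutation (all pairs
  tied) counts toward the numerator, conservatively. For τ_b the two
  denominator factors are invariant under permutation of y (they depend
  only on each vector's own tie structure), so only |C−D| is compared.
* n > 8: seeded Monte Carlo with the add-one estimator
  p = (1 + #{|stat| ≥ obs})/(1 + n_permutations), n_permutations ≥ 999.
  Routing from the exact to the Monte-Carlo path is an explicit, named
  condition, never silent.

Q-values are Benjamini–Hochberg step-up (via statsmodels), computed over
exactly one network family — the pairs of one group × sample type × rank
cell — and never pooled across cells. The default significance threshold is
q ≤ 0.05, configurable (e.g. to 0.005, or to raw p) through
`NetworkConfig(alpha=..., alpha_applies_to=...)`.

## Networks

An association becomes an edge iff |γ| ≥ `tau_threshold` (default 0.70 — a
correlation-magnitude reading of a "70% edge threshold") and its q-value
(or p-value) ≤ `alpha`. Nodes are exactly the taxa incident to at least one
retained edge; isolated taxa are not nodes, which matches how group-level
node counts track connected taxa. Positive edges are co-occurrences,
negative edges co-exclusions; an empty network is a valid result.

Node "strength" on the conventional 1..9 display scale is degree linearly
rescaled to that integer range; when all degrees are equal every node maps
to 9. This mapping is a documented convention of this package (the display
scale's definition is genuinely open); the sum of incident |γ| is attached
as an auxiliary `strength_tau` attribute but does not drive the scale.

## Alpha diversity and Gram phenotype

Shannon H = −Σ p ln p (natural log by default, base 2 switchable) and the
Gini–Simpson index 1 − Σ p² (inverse form 1/Σ p² behind a flag) are
computed per sample on normalised abundances. Both choices of form follow
common microbiome convention and are labelled in the output.

Gram-phenotype composition is a local lookup: a TSV maps taxon labels to
{negative, positive, variable, unknown}; unmapped taxa resolve to unknown,
so the four abundance-weighted fractions sum to 1 per sample. Percentages
are abundance-weighted (not taxon-count-weighted) and labelled as such. A
small packaged default map covers the dominant mouse-gut phyla and genera;
users supply their own map for other systems.

## Synthetic data

The generator emulates a 12-cell murine design — groups YC/YP/AC/AP ×
sample types fecal/mucosal (n = 8) and cecal (n = 6) — with 12 genera
spanning Firmicutes, Bacteroidetes, Verrucomicrobia and Proteobacteria.

Counts are drawn by Gaussian copula: latent MVN with ρ_ij = sin(π τ_ij/2)
(the exact inversion of Kendall's τ for bivariate normals; the matrix is
validated positive definite up front), pushed through each taxon's
negative-binomial quantile at its mean and dispersion, then closed to a
multinomial draw at a per-sample NB library size (mean 20,000, size 20).
Planted absences are forced to zero before closure. Zero inflation arises
only from absences and the NB's own mass at zero — no extra Bernoulli
layer — so the planted τ stays interpretable. Each cell's random stream is
derived from (seed, group, sample_type) with fixed canonical keys, so
adding a cell never perturbs the others and equal seeds give byte-identical
tables.

Default design choices worth knowing:

* **Planted edges are disjoint pairs** (Lactobacillus–Oscillospira +0.9,
  Bacteroides–Prevotella +0.9, Ruminococcus–Sutterella −0.9). A hub taxon
  with several |τ| = 0.9 partners implies latent |ρ| ≈ 0.99 rows whose
  correlation matrix is not positive definite; hub-shaped focal tables are
  exercised through directly constructed association sets instead.
* **Signal taxa are minor and overdispersed; the background is dominant and
  stable.** The six planted-edge genera have small means (0.03–0.05) and NB
  size r = 2 (CV ≈ 0.7, the behaviour of dynamic genera such as
  Lactobacillus under supplementation); the six background genera have
  large means and r = 40 (CV ≈ 0.16, dominant stable members across inbred
  mice of one group). This matters because compositional closure divides
  every taxon by the shared community total: a noisy denominator induces
  spurious *positive* rank correlation between ratios, which adds to
  planted positives (mild attenuation, ≈ 0.88 observed for a planted 0.9)
  but partially cancels planted negatives. With the default structure a
  planted −0.9 closes to ≈ −0.80 in relative abundances; with a uniformly
  noisy community it would close to ≈ −0.56 and a strong co-exclusion could
  not be planted at all. This is the generator's concession to working with
  a 12-taxon inventory — real communities have hundreds of taxa and
  correspondingly stabler totals.
* Lactobacillus is planted absent in both control groups (YC, AC) and
  present under supplementation; Sutterella (Proteobacteria) is elevated
  3× in aging controls.

What the generator does *not* emulate: real taxon inventories and their
phylogenetic correlation, sequencing-depth artefacts beyond a single NB
library-size draw, batch effects, and the broad negative correlation field
that closure induces across hundreds of taxa. Passing planted-recovery
tests therefore shows the statistical machinery is correct and powerful
under the stated conditions, not that any particular real dataset will
yield dense networks.

## Problem sizes and power

Pipeline cells use exact n!-enumeration at the design's own n = 6–8 and
999-permutation Monte Carlo in larger synthetic experiments. Planted-edge
recovery is quantified at n = 50/group (sensitivity ≥ 0.9 and false-edge
rate ≤ 0.05 over 20 seeds at the default thresholds). At the study-scale
n = 8 the same design has markedly lower, seed-dependent sensitivity — the
smallest achievable two-sided exact p at n = 8 is 2/8! ≈ 5·10⁻⁵, but the
|γ| ≥ 0.70 cut at high sampling noise dominates — so at that n only the
ordering sensitivity(n = 8) ≤ sensitivity(n = 50) is asserted, seed for
seed. End-to-end determinism is checked byte-for-byte on summaries and
manifests of repeated runs.

## Numerical and procedural choices

* Exact-p comparisons in integer arithmetic (above); nothing is clamped.
* BH q-values: statsmodels `fdr_bh`; empty family → empty output.
* Rank collapse pools taxa unclassified at the target rank into an explicit
  `unclassified` taxon so per-sample totals are conserved exactly; the
  pooled taxon is excluded from correlation by default (configurable).
* Taxon filtering (per analysis cell): presence in ≥ 25% of samples, then
  top-10 by mean abundance at genus level (unlimited at phylum level);
  both configurable. This is an explicit stand-in for an unstated inclusion
  rule — published genus networks of this kind have ≤ 10 nodes.
* Partner lists and edge listings are ordered lexicographically; per-pair
  and per-cell Monte-Carlo seeds derive from the root seed through
  `SeedSequence` spawn keys, keeping runs reproducible and below 2³¹.
* `to_relative` renormalises after division so row sums hit 1 within 1e-9;
  a second call errors by contract (`value_kind` is already `relative`).
* Samples with zero total abundance in a cell are dropped with a logged
  warning before normalisation.

## Known limitations

* γ's tie-ignoring behaviour inflates |association| for sparse taxa pairs
  with few untied sample pairs; τ_b is provided for exactly this concern.
* Compositional closure can induce spurious associations; no
  compositionality-aware inference (SparCC/SPIEC-EASI style) is attempted —
  out of scope by design.
* The exact permutation null conditions on the observed tie pattern of x
  and the multiset of y; it does not model between-group structure.
* BIOM support targets v1.0 JSON (dense and sparse); the HDF5-based v2.1
  format is not read.
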