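# Methods

## Scope and model

cubkit analyses synonymous codon usage in bacterial coding sequences under
the standard mutation–selection view: the usage of synonymous codons in a
gene reflects a balance between directional mutation pressure (which moves
the G+C content of all three codon positions together) and translational
selection (which favours particular codons, mostly at silent third
positions, in proportion to a gene's expression level). Every statistic in
the package is defined on codon counts under the bacterial genetic code
(NCBI translation table 11): 61 sense codons, stops {TAA, TAG, TGA}, and
59 synonymous codons once the single-codon families Met (ATG) and Trp
(TGG) are removed.

## Indices

* **Composition.** GC1/GC2/GC3 are G+C fractions at each codon position
  over sense codons; GC12 is their positional mean (GC1+GC2)/2; GC3s
  restricts the third position to codons of families with degeneracy ≥ 2.
  Third-position base counts A3/T3/G3/C3 are over all sense codons (a
  fourfold-family-only variant is easy to derive from the count tables but
  is not the default, since the reported PR2 quantities use all sense
  codons).
* **RSCU.** Observed count of a codon divided by its family's mean count;
  1 means no bias, family values sum to the family size. Families absent
  from a gene get RSCU 0 for every member.
* **CAI.** Geometric mean over a gene's synonymous codons of relative
  adaptiveness weights w = RSCU/max(family RSCU) computed on a highly
  expressed reference set. Reference selection is pluggable: a
  ribosomal-protein annotation regex, an explicit id list, or a two-pass
  iterative scheme (provisional CAI from genome-wide usage, weights rebuilt
  from the top 5%). Codons unused in the reference receive a pseudo-weight
  of 0.01 so CAI stays finite; the value is configurable.
* **ENC.** Wright's estimator. Per family with n ≥ 2 codons counted,
  homozygosity F = (nΣp² − 1)/(n − 1); F values are averaged within
  degeneracy classes and ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.
  Families with F = 0 (e.g. two codons seen once each) carry no
  information about bias and are excluded from the class mean. If the
  single 3-fold family (Ile) is uninformative, F̄₃ is interpolated as
  (F̄₂+F̄₄)/2; any other absent class is dropped and the remaining sum is
  rescaled by the represented family fraction. The result is clamped to
  [20, 61]: a finite gene with perfectly uniform usage produces a raw
  estimate slightly above 61 because F̂ under-estimates 1/k at finite n,
  and the clamp restores the theoretical ceiling.
* **CBI / FOP.** Against an optimal-codon set with at most one codon per
  family, CBI = (N_opt − N_ran)/(N_tot − N_ran) with N_ran the expected
  optimal count under uniform usage, and FOP = N_opt/N_tot; both totals
  run over families that hold an optimal codon. In the pipeline the
  optimal set is the genome's own ΔRSCU-identified set, so the dependency
  order is CAI → expression extremes → optimal codons → CBI/FOP.
* **GRAVY / AROMO.** Count-weighted mean Kyte–Doolittle hydropathy of the
  encoded residues (full −4.5..4.5 scale) and the fraction of Phe/Tyr/Trp.

All internal fractions live on [0, 1]; report writers add percent columns.

## Mutation-versus-selection diagnostics

The neutrality fit is unweighted OLS of GC12 on GC3 across genes; a
constant-GC12 input returns a flat fit (slope 0, r 0) rather than a NaN.
The ENC–GC3s expectation is ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²)
(note its maximum is 60.501 at s ≈ 0.502, not exactly at 0.5, because of
the linear term), and ENC_ratio = (ENC_exp − ENC_obs)/ENC_exp. PR2
coordinates are x = G3/(G3+C3), y = A3/(A3+T3); genes with a zero
denominator are flagged and excluded from quadrant occupancy. Because the
three stop codons end in A, G, A, removing them depletes third-position A
among sense codons, so y sits slightly below 0.5 even under perfectly
strand-symmetric generation — tests compare against the sampler's
analytic base probabilities, not against 0.5. Index correlations are
pairwise Pearson r with two-sided p, flagged at 0.05/0.01 and accompanied
by a Benjamini–Hochberg column; no correction is applied to the flags
themselves.

## Correspondence analysis

Classical CA of the genes × 59 RSCU matrix: proportions P, standardized
residuals S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, SVD, principal coordinates
for genes and codons, axis contribution σ_k²/Σσ². Axis signs are
arbitrary under SVD; axis 1 (and each retained axis) is oriented so its
correlation with the supplied per-gene GC3s is non-negative, which makes
outputs reproducible across backends. Degenerate inputs are handled
explicitly: all-zero rows are dropped and reported, a zero-inertia matrix
returns a "no variation" result, rank < 2 raises.

## Optimal codons

Expression extremes are the top/bottom floor(fraction·n) genes by CAI
(minimum 1 per set), ties broken lexicographically by gene id and
recorded. Set-level RSCU is computed on aggregated codon counts of each
set rather than averaging per-gene RSCU vectors — dataset-level usage is
stable under gene duplication and independent of gene-length mixture.
Both optimal-rule thresholds are strict (ΔRSCU > 0.08, RSCU > 1), and the
"RSCU > 1" clause is evaluated on the high-expression set's RSCU by
default (genome-wide RSCU is a switch). High-frequency codons are those
with genome-wide RSCU > 1; the two flags are deliberately independent.

## Codon-pair context

Pairs are immediately adjacent ordered codon pairs including each gene's
terminal stop (L − 1 pairs for a gene of L codons; self-pairs count).
Adjusted residuals use the Haberman form with marginal corrections; cells
with a zero marginal are undefined. The significance threshold defaults
to 3.0 (≈ p < 0.003 two-sided) and is configurable. Start/stop context
reports use raw counts for "most used" and the most negative residual for
"most avoided", in RNA codon labels. For cross-genome clustering the
residual matrices are flattened to 4096-vectors with undefined cells as 0,
compared by 1 − Pearson correlation, and merged by average linkage.

## Genome clustering

Genome RSCU profiles (59 values from genome-aggregated counts) are
clustered with squared Euclidean distance and between-groups average
linkage — the default pairing of mainstream statistics packages for this
analysis — with complete and Ward linkage available. Trees are serialised
as Newick with merge heights as branch lengths.

## Synthetic genomes

The generator is the package's test-bed: each gene draws a mutational GC
bias θ_g ~ Beta(α, β) (clipped to [0.02, 0.98] so silent sites never fix)
and an expression level e_g ~ Exponential(rate); a genome carries a
planted optimal set O (one codon per degenerate family; C-ending where
available, else G-ending, mimicking the G/C-ending preference of
thermophile genomes) and a selection strength s. Modes:

* *mutation* — codon probability ∝ product of base weights over all three
  positions (G, C each θ_g/2; A, T each (1−θ_g)/2), restricted to sense
  codons. Amino-acid usage co-varies with θ_g, so GC12 tracks GC3 and the
  neutrality slope approaches 1.
* *selection* — amino acids from a fixed background (a smoothed average
  bacterial proteome composition), synonymous codons weighted by
  exp(s·e_g·1[codon ∈ O]) times the third-base mutational weight at a
  genome-constant θ. GC12 stays flat while silent sites respond to
  selection, so the slope approaches 0 and a CAI gradient appears across
  genes — which is what gives the top/bottom-5% machinery signal.
* *mixed* — the selection sampler with per-gene θ_g.

Genes are ATG + body + one stop drawn with weights (0.6, 0.2, 0.2) for
TAA/TAG/TGA. Optionally a set of context pairs is planted: during
sequential sampling the next-codon probability is multiplied by
exp(context_strength) when (previous, next) is a planted pair, giving
genomes a pair-level signature that is independent of their single-codon
usage — the situation in which context clustering and RSCU clustering
disagree.

Presets fix the study conditions: `mutation-dominated` (θ_g ~ Beta(2,2),
s = 0), `selection-dominated` (θ = 0.5, s = 2, e ~ Exp(1)), `mixed`
(θ_g ~ Beta(5,5), s = 1) and `null-uniform` (θ = 0.5, s = 0). The default
genome size is 500 genes with lognormal lengths around 300 codons
(σ = 0.35), which keeps sampling noise well below the tolerances used in
the verification suite while the whole pipeline runs in seconds. What the
generator does **not** emulate: operon structure, strand asymmetry,
amino-acid-composition selection (GRAVY/AROMO gradients), horizontal
transfer, or any length–expression correlation. Passing tests therefore
demonstrate that the statistics recover the forces the model encodes, not
that real annotation pipelines or real genomes are free of the
confounders these features introduce.

## Numerical choices and limitations

* ENC needs at least one informative family; genes below 100 sense codons
  are flagged as short (threshold configurable) because the estimator is
  noisy there.
* CAI ignores Met, Trp and stops entirely; a gene with no synonymous
  codons raises rather than returning a default.
* Ties in CAI ranking are broken by gene id and recorded, so expression
  extremes are deterministic.
* The QC defaults (start ∈ {ATG, GTG, TTG}, terminal stop required, no
  internal stops, no ambiguous bases, ≥ 30 codons) are permissive for
  real bacterial annotations while guaranteeing clean frames; every rule
  can be toggled. Ambiguous bases discard the gene by default; a
  drop-codon mode keeps the remainder.
* The pipeline itself is deterministic — randomness exists only in the
  synthetic generator and flows from a single seed; re-running a config
  reproduces byte-identical tables.
* GRAVY is reported on the full Kyte–Doolittle scale (−4.5 to 4.5); some
  of the literature describes the index with a (−2, 2) range, which is a
  property of typical proteomes, not of the scale.
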