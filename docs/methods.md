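# Methods

This note documents the models, estimators and design choices behind
`paralogy`, and what the synthetic-data tests do and do not establish about
real transcript collections.

## Codon model and Ks estimation

The pairwise estimator uses the GY94 codon substitution model on the 61
sense codons of the universal code. The instantaneous rate from codon *i*
to *j* is zero unless they differ at exactly one position, and otherwise
proportional to `π_j · κ^[transition] · ω^[nonsynonymous]`, with π the F3×4
equilibrium frequencies (position-specific nucleotide frequencies estimated
from the aligned pair itself, pooled over both sequences — the per-alignment
convention). The matrix is scaled so one time unit equals one expected
substitution per codon, making the divergence *t* directly interpretable.
Because the chain is reversible, `P(t) = exp(Qt)` is computed through the
symmetric similarity transform `Π^{1/2} Q Π^{-1/2}` and a single
eigendecomposition per likelihood evaluation; π entries are floored at
1e-8 (then renormalized) to keep the transform well conditioned when a
nucleotide is absent at a codon position.

The likelihood `ℓ(t, κ, ω) = Σ_sites log π_x P_{x→y}(t)` is maximized by
bounded Nelder–Mead on log-transformed parameters, t ∈ [1e-6, 20],
κ ∈ [0.1, 20], ω ∈ [1e-4, 10], with five restarts (t started near
{0.05, 0.2, 0.5, 1, 2} jittered ±20%, κ = 2, ω = 0.3 jittered; restart
seeds derive from the pair id so reruns are identical). The best
log-likelihood is retained.

**Ks/Ka decomposition.** With the rate matrix scaled to unit flux, the
synonymous fraction of flux is `ρ_S = Σ_{syn pairs} π_i q_ij`. Three times
the same fraction computed at ω = 1 (`ρ_S¹`) is the proportion of
synonymous sites per codon, giving `Ks = t·ρ_S/(3·ρ_S¹)` and
`Ka = t·(1−ρ_S)/(3·(1−ρ_S¹))`. The ω = 1 site convention is adopted
(whether the original codeml runs used mutational-only site definitions is
not knowable from the source material); correctness is checked against the
counting oracle rather than asserted as bit-compatibility with codeml.
Pairs with no observed synonymous (nonsynonymous) differences are reported
with Ks (Ka) exactly 0 — the boundary MLE — rather than the bound value the
box-constrained optimizer would return.

**Counting oracle.** The NG86 estimator counts synonymous/nonsynonymous
sites per codon (normalized to 3, mutations to stops counted as
nonsynonymous) and averages pathway-ordered difference counts over all
permutations, applying the Jukes–Cantor correction and returning NaN at the
p ≥ 3/4 ceiling. It matches Biopython's independent implementation to
1e-9 on simulated pairs. Note a real methodological gap between the two
routes: with transition bias (κ = 2) NG86 understates synonymous sites and
therefore runs ~15% above the ML estimate at Ks 0.5; the two correlate at
r > 0.95 but are not interchangeable.

**Filters.** Codon alignment back-translates a global BLOSUM62 protein
alignment and removes columns with gaps, ambiguous bases or stops. Fits
require ≥ 10 retained columns. Ks > 2 is discarded as saturation-prone,
with the boundary inclusive (exactly 2.0 is kept). Ks = 0 pairs are treated
as redundant entries of one gene: each connected component of Ks = 0 edges
keeps its lexicographically smallest id.

## Age-distribution mixture

Duplication ages are modelled on (0, 2] as
`f(x) = w_e · Exp(λ) + Σ_k w_k · N(μ_k, σ_k²)`, every component truncated
to the support and renormalized, so the fitted density integrates to one on
exactly the domain the saturation filter leaves in the data. Weights are
free parameters. Fitting is EM: responsibilities in the E step; in the M
step the truncated-exponential rate by bounded 1-D search and each
truncated normal by Nelder–Mead on (μ, log σ), each accepted only if it
improves the weighted component likelihood, which preserves EM's ascent
property (asserted per fit). Five random starts (λ from the mean of the
youngest decile, normal means from a k-means sweep); convergence at
1e-6 absolute log-likelihood change, 300 iterations cap. Components that
degenerate (σ < 2e-3 or weight < 1e-4) are pruned and flagged.

**Identifiability constraint.** Component standard deviations are capped at
0.6 Ks units. A "normal" wider than that is not a discrete large-scale
event — reported polyploidy-peak variances lie well below 0.36 — and
without the cap the likelihood genuinely prefers a degenerate solution in
which one normal flattens into a background density (σ → 2), absorbing the
exponential tail and biasing the death rate upward by ~40%. With the cap,
refits of data simulated from the reference parameters recover the death
rate with ~8% sampling spread and the burst means to ~0.01 (young) and
~0.05 (old) at n = 10,000; the old burst retains a small positive bias
because a quarter of its mass is truncated at Ks = 2 and its left flank
trades off against the exponential.

**Model selection.** Candidates with 0–3 normals are compared by the
one-sample KS test against each fitted CDF. The selected model is the most
parsimonious fit the test cannot reject (p ≥ 0.05), falling back to the
highest p-value when all are rejected. A plain highest-p rule was rejected
during design: an extra component never worsens the KS statistic, so it
drifts to the maximum component count even on pure-exponential data. The
KS p-value against a parameter-estimated CDF is optimistic
(Lilliefors-type bias); a parametric-bootstrap p-value (199 replicates) is
available via `bootstrap_ks_pvalue`. BIC is logged alongside for
transparency.

## Families, node dating, power law

Families are connected components of the filtered paralog graph
(single-linkage). Within a family, the n−1 duplication events are dated by
average-linkage (UPGMA) agglomeration on the pairwise Ks matrix: each merge
emits one node whose age is the arithmetic mean of the *observed*
cross-cluster Ks values. Pairs lacking a Ks (identity below 60%, or
Ks > 2) are imputed with the family's maximum observed Ks so the dendrogram
stays connected, but imputed values steer only the merge order — they never
enter an age mean (a merge with no observed cross pair falls back to the
imputed value). On fully observed matrices this reproduces
`scipy.cluster.hierarchy.linkage(..., 'average')` heights exactly. Young
paralogs (Ks strictly below 0.4) are reclustered with the same procedure;
a family's amplification ratio is `n / (n − d_young)` with `d_young` its
count of nodes younger than the cutoff.

The family-size distribution is fitted as `f(x) = a·x^(−b)` by OLS of
log frequency on log size. The regression uses the contiguous run of
occupied size classes from the minimum size up to the first gap: isolated
frequency-1 classes in the sparse tail carry no frequency information and
only flatten the slope (including them biases b from 2.35 down to ~1.5 at
n = 2000). A discrete-power-law MLE is available behind `method="mle"`.
Under the fitted law, doubling the family size divides the expected family
count by `2^b`.

## GO enrichment

Ontologies are read from OBO (is_a and part_of edges, obsolete terms
dropped with a warning, cycles rejected); annotations from two-column TSV
or GAF 2.x, closed over ancestors at load time. A family is annotated with
a term when at least 30% of its members carry it (inclusive boundary,
computed after closure). Enrichment between two unit sets (families
counting once each, versus single-copy genes) uses the two-sided Fisher
exact test — scipy's implementation, which is the minimum-likelihood
two-sided method, verified against exhaustive hypergeometric enumeration
for all tables with margins ≤ 12. No multiple-testing correction by
default (the classic raw P < 0.01 rule); Benjamini–Hochberg is available
behind a flag. One α serves both over- and under-representation.

## Expression divergence

Profiles are per-library relative frequencies (counts per 10,000 library
ESTs); genes with fewer than 3 ESTs overall are excluded. Correlations are
computed on frequencies rather than raw counts because library depths
differ (raw-count mode exists behind a flag); Pearson r is invariant to
per-gene scaling and library reordering. The co-regulation threshold r\*
is the empirical 95th percentile of r over random unordered gene pairs,
excluding known paralogs so the null represents unrelated genes; undefined
correlations (constant profiles) are excluded symmetrically from null and
observed sets. For 14 libraries the normal-profile null puts r\* ≈ 0.46
(the analytic 14-point Pearson quantile); EST-profile nulls sit higher
because profiles are sparse and skewed. Tissue-specificity tests aggregate
the libraries into four classes (fruit, vegetative, reproductive,
vascular by default; configurable) and run a 2×2 Fisher test per class
(genes × class-vs-rest), Holm-corrected across the four classes (the
uncorrected any-class rule is available); pairs with fewer than 5 ESTs in
both genes are skipped.

## Synthetic-data generator

The generator's defaults are the study conditions used throughout the
tests:

* **Mixture truth**: death rate 1.892, exponential weight 0.45; young
  burst N(0.185, 0.08²) with weight 0.35; old burst N(1.65, 0.31) with
  weight 0.20; ages truncated to (0, 2] to mirror the saturation filter.
  The young burst's sd is a simulation choice (0.08): its width is not
  derivable from the source values, only its position; the old burst's
  variance (0.31) is the reported one.
* **Codon pairs**: ancestral sequences drawn from F3×4 equilibrium
  (uniform position profile by default — the empirical profile is not
  reported), evolved by exact per-site matrix-exponential transition
  sampling under the same GY94 class the estimator fits, with total
  divergence chosen so the model-expected Ks equals the target (Ks is
  linear in t: `t = Ks·3ρ_S¹/ρ_S`). Default κ = 2, ω = 0.2, 200 codons
  (600 nt — consistent with transcript-derived ORFs above the 300 nt
  filter).
* **Families**: sizes from a discrete power law (exponent 2.35 on
  [2, 250]); each family's n−1 ages are mixture draws placed on a random
  ultrametric tree (uniformly random merge topology at sorted ages), and
  sequences evolve down the tree so that the pairwise Ks of two genes
  equals the age of their joining node exactly. Families descend from
  independent random ancestors, so cross-family similarity is negligible.
  Singletons (31% of genes, the observed singlet share) are unrelated
  random sequences.
* **Expression**: each gene has a latent Dirichlet profile over libraries
  (concentration 0.3 — sparse, tissue-biased profiles); co-regulated pairs
  share a profile, tissue-shifted pairs get complementary tissue-class
  supports, divergent pairs draw independently (default 18% co-regulated,
  25% of the rest tissue-shifted). Counts are one multinomial draw per
  library across genes (14 libraries × 2,000 ESTs by default). Note the
  multinomial couples genes: a two-gene toy library is perfectly
  anti-correlated by construction; realistic gene counts make the coupling
  negligible.

The generator does **not** emulate EST sequencing error, chimeric or
misassembled transcripts, allelic variants masquerading as young
duplicates, partial ORFs, rate variation among sites or lineages, or
correlated duplication of whole pathways. Passing recovery tests therefore
demonstrate estimator correctness under the model class, not robustness to
those artifacts; on real data the Ks = 0 cleanup and the 300 nt/identity
filters carry that burden.

## Problem sizes and determinism

Tests and the acceptance script run at deliberately modest scales chosen as
adequate for the quantities measured: 100 simulated pairs for the ML/NG86
comparison (300 codons each), a 15-restart deeper search over 20 pairs as
the restart-stability reference, n = 10,000 ages for mixture recovery,
2,000 families for the power-law fit, 10⁵ random pairs for the expression
null. All randomness flows from explicit seeds (per-pair seeds derive from
pair ids; pipeline stages derive seeds from the master seed by stage-name
CRC), so every run is byte-reproducible.

## Known limitations

* Pairwise (two-taxon) likelihood only; no among-site rate variation, no
  branch models, no confidence intervals on Ks.
* The mixture's old-component mean is weakly identified against the
  exponential tail under truncation; expect a few percent of bias and
  seed-to-seed spread at n = 10,000 (quantified above).
* The built-in all-vs-all aligner reports a Karlin–Altschul surrogate
  e-value from the raw Smith–Waterman score; it is calibrated for ranking
  and filtering, not for cross-tool e-value comparability.
* Family dating assumes the within-family Ks matrix is approximately
  ultrametric; strong rate variation among paralogs will smear node ages.
* GO enrichment treats units (families, genes) as independent; it inherits
  the usual caveats of set-based enrichment with overlapping terms.
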