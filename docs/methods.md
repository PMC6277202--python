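# Methods

`compqc` screens phylogenomic gene sets for among-lineage amino-acid
compositional heterogeneity — the nonstationary substitution pattern
that standard time-reversible models (and even site-heterogeneous
mixtures) do not model, and that can draw similarly biased taxa
together in reconstructed trees. The package implements the screen as a
per-gene parametric-bootstrap hypothesis test, bins genes by outcome,
and assembles test-passing and test-failing supermatrices whose
downstream phylogenies can then be contrasted.

## The null-simulation test

For a gene alignment `A` with a fixed tree `T` (typically the gene's
externally inferred ML tree), the null hypothesis is that all lineages
share a single stationary composition vector. The test proceeds:

1. **Model fit.** A homogeneous LG+Γ4 model is parameterised on `T`:
   the composition vector π is the gene's pooled empirical amino-acid
   frequencies (gaps/missing excluded, plus a pseudocount of 0.5 per
   residue so no frequency is zero); branch lengths and the gamma shape
   α are then optimised by maximum likelihood with the topology fixed
   (optional — `refit=False` keeps the input lengths and refits only α).
2. **Null simulation.** `M` replicate alignments (default 1000) are
   simulated along the fitted tree under the fitted model; by default
   the observed gap/missing pattern is projected onto each replicate so
   the null distribution reflects the data's missingness (`mask_gaps`
   turns this off). Replicate `r` uses seed `base + r`, and each gene's
   base seed is `run_seed + crc32(gene name)`, so results are
   reproducible and per-gene results do not shift when genes are added
   or removed.
3. **Discrepancy statistic.** The observed and replicate alignments are
   summarised by the taxa × residue contingency chi-square
   `X² = Σ_ia (n_ia − e_ia)²/e_ia` with `e_ia = (row total i) × (pooled
   frequency of a)`. The per-taxon summed absolute distance
   `d_i = Σ_a |f_ia − f̄_a|` is computed alongside for reporting and
   z-score figures, but the chi-square drives the p-value.
4. **Tail-area p-value.** `p = (1 + #{null ≥ observed}) / (1 + M)`
   (add-one rule; never exactly zero, and the count `n_ge` is reported
   so every p-value is auditable).

Genes with fewer than 4 sequence-bearing taxa or fewer than 50 sites
are skipped rather than tested (both thresholds configurable). Genes
are binned as *failing* when `p < α` strictly (default α = 0.10); a
boundary p-value equal to α passes, the conservative direction for
keeping genes. No multiple-testing correction drives binning — the
screen deliberately operates at a raw α — though a Benjamini–Hochberg
FDR column is emitted for information.

Because the null distribution is simulated under parameters fitted to
the same data, the test inherits the usual mild conservatism of plug-in
parametric bootstraps (the fitted model adapts slightly to the observed
discrepancy); calibration measured by the acceptance checks is close to
but slightly below the nominal α. Note also that with finite `M` the
achievable p-values are `k/(M+1)`, so the exact null rejection rate at
α = 0.10 and M = 199 is 19/200 = 0.095.

## Likelihood machinery

Likelihoods use Felsenstein pruning over 20 amino-acid states with a
discrete-gamma rate mixture (category means over equal-probability
quantile intervals of Gamma(α, α), which preserves a unit expected rate
exactly; medians would not). Gap/missing characters contribute all-ones
partial likelihoods. Site patterns are compressed; per-pattern
rescaling with log accumulators prevents underflow, and results equal
unscaled arithmetic wherever the latter is representable.

Rate matrices are `Q_ij = s_ij π_j` normalised to one expected
substitution per site at stationarity; `P(t) = exp(Qt)` comes from the
symmetric eigendecomposition of `diag(√π) Q diag(1/√π)`, with tiny
negative entries clipped and rows renormalised. The LG exchangeability
matrix (Le & Gascuel 2008) is bundled as a constants module; a Poisson
(equal-rates) preset and user-supplied symmetric GTR matrices (TSV) are
also available.

Branch lengths and α are fitted by coordinate ascent: a depth-first
sweep of bounded 1-D optimisations (Brent, lengths in [1e-8, 20]) that
maintains exact outside-subtree partial likelihoods incrementally, so
each branch update is a true ascent step under all current parameter
values; then a bounded 1-D optimisation of α in [0.02, 100] (after the
first round the α search brackets the previous optimum and re-widens if
the optimum presses against the bracket). Rounds repeat until the
log-likelihood improves by less than 1e-4 or 30 rounds are reached;
there is no randomness anywhere in the optimiser. The topology is never
re-estimated: trees come from external inference, and refitting lengths
merely makes the simulation model self-consistent when the input
lengths were estimated under a different model.

## Simulation model

Forward simulation draws a gamma category and a root state per site and
evolves states down each edge with `P(rate × length)`. Nonstationary
data are produced through per-edge composition overrides (keyed by the
child node's label, optionally inherited by the whole subtree): the
rate matrix is rebuilt — and re-normalised to unit rate — from the
composition in force on each edge, so branch lengths keep their
expected-substitutions interpretation everywhere. Indels are not
modelled; missingness is copied from templates, not simulated.

## Synthetic study conditions

The generator emulates a phylogenomic orthologue set with a controlled
amount of lineage-restricted compositional bias. Defaults (the
conditions used by the validation suite and the acceptance script):

| parameter | default | rationale |
|---|---|---|
| `n_taxa` | 16 | deep-phylogeny-scale taxon sampling at testable cost |
| `n_genes` | 200 | enough genes for stable bin-level rates |
| `p_biased` | 0.5 | a majority-scale contaminated set, as composition screens encounter |
| `site_range` | (200, 400) | typical single-gene alignment lengths after masking |
| `alpha_range` | (0.5, 1.5) | common gamma shapes for proteins |
| `bias_weight` w | 0.5 | detectable but not trivial mixture toward the shifted composition |
| `biased_clade_size` | 3 | bias is clade-localised (a few related problem taxa), not i.i.d. per tip |
| `bias_stem_extension` | 0.75 | biased genes place the affected clade on an elongated stem (expected substitutions added) |
| `missing_taxon_rate` | 0.15 | patchy orthologue recovery comparable to real occupancy |

Per gene, a gene-specific composition is drawn from a Dirichlet centred
on the LG frequencies (concentration 100·π; typical total-variation
distance from LG ≈ 0.03), the length and shape from the ranges above.
A biased gene evolves one clade of `biased_clade_size` tips under
`(1−w)·π_gene + w·π_shift`, where π_shift concentrates 75% of its mass
equally on {A, G, P} — a caricature of the GC-rich-proteome effect that
drives real among-lineage composition differences. Species trees are
Yule topologies with exponential(mean 0.1) edge lengths.

A residue composition only drifts toward a new equilibrium in
proportion to the substitutions accumulated under it, and on a Yule
tree with mean edge length 0.1 a randomly drawn small clade can sit at
a few hundredths of a substitution — a gene "biased" there would carry
essentially no realized shift, and the planted bias magnitude would be
set by the branch-length lottery instead of by `w`. Biased genes
therefore place the affected clade on a stem elongated by
`bias_stem_extension` expected substitutions (split across tips when no
clade of the requested size exists), mirroring the long branches that
compositionally deviant lineages show in practice; the same elongated
tree is written as the gene's tree, so the data-generating process and
the analysis input stay consistent, and the mixing weight `w` is the
dial that controls bias strength. All randomness flows from the single
spec seed through named substreams, so any gene is regenerable in
isolation.

What the generator does **not** emulate: orthology or alignment error,
within-gene indel/gap structure (missingness removes whole taxa from
genes), site-heterogeneous composition profiles, or any attempt to
mimic particular real lineages. Passing tests therefore demonstrate
the statistical logic of the screen — calibration under the null, power
against clade-localised shifts, and correct binning — not biological
realism of any specific dataset.

## Predictive z-scores

For each binned supermatrix the pipeline writes a per-taxon z-score
table: the observed per-taxon distance statistic standardised against
plug-in predictive replicates, obtained by re-simulating every gene in
the bin under its fitted homogeneous model (with the observed gap mask)
and pooling the replicate supermatrix counts. Matrix-level summaries
(chi-square, distance mean/max, per-site residue diversity — the mean
number of distinct residues per column, all-gap columns excluded) are
standardised the same way. These are *parametric* predictive checks
from a single fitted model per gene, not posterior predictive checks
from an MCMC sample; the output header says so, and the table is
intended for Fig.-3C-style diagnostic plots rather than for comparison
with posterior-predictive z-values produced under site-heterogeneous
mixtures.

## Recoding

Dayhoff-6 recoding collapses the 20 amino acids into the standard
groups AGPST / DENQ / HKR / ILMV / FWY / C, written as digits '0'–'5'
in that order; gaps and missing symbols pass through unchanged. The
composition statistics are alphabet-generic and work on recoded
matrices unchanged. Recoded supermatrices are written for external
inference tools; the package does no inference on them.

## Numerical and design choices

- Partition coordinates are 1-based inclusive (RAxML convention);
  internal indexing is 0-based half-open and converted only at I/O.
- Ambiguity codes B/Z/J/U/O and `*`/`.` map to missing (`X`) on read;
  `?` is preserved and treated as missing. Gap (`-`) and missing are
  pooled when reporting "% gaps or missing".
- Supermatrix taxon order is lexicographic for deterministic output;
  missing Newick branch lengths default to 0.0 with a warning rather
  than erroring (published gene trees occasionally omit them).
- Statistics use raw counts without pseudocounts (they describe data);
  model-fitting frequencies add pseudocounts (they parameterise
  simulations) — the two contexts are deliberately distinct.
- Degenerate cases: a zero-spread null distribution yields a signed
  infinite z (with a warning) or 0 when observed equals the null mean;
  zero-length alignments give log-likelihood 0 with a warning; all-gap
  taxa are excluded from composition statistics and error when
  frequencies are requested for them.
- Validation problem sizes: the acceptance checks use 500 homogeneous
  genes at M = 199 replicates for calibration, 100 genes per bias level
  for power ordering, 5,000 sites for parameter recovery, and a
  200-gene mixed set for end-to-end binning; the acceptance script uses
  moderately smaller gene counts (250/60-per-level/150) chosen to keep
  a full from-scratch rerun comfortably interactive while leaving the
  binomial noise well inside the margins being checked.

## Known limitations

- The test assumes the supplied gene tree; grossly wrong trees push
  fitted lengths rather than composition, which can shift calibration.
- Plug-in predictive simulation understates parameter uncertainty
  relative to a posterior predictive check; z-scores are mildly shrunk
  toward zero and the test is slightly conservative.
- The chi-square statistic pools sites, so within-gene composition
  switching that cancels across taxa is invisible to the screen.
- No indel model: if missingness is informative about composition in
  real data, masking copies that pattern but cannot model it.
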