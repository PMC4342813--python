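# Methods

This note documents the models, conventions and numerical choices behind
`mtlineage`, and what the synthetic-data validation does and does not
establish about real data.

## Haplotype model and coordinate conventions

A haplotype is the set of differences of a sample from a 16,569-bp
reference with rCRS coordinates, restricted to a *reading frame*: a list
of inclusive 1-based np ranges.  Frames are lists (never one interval)
because the control region spans the origin of the circular molecule;
the named presets are `cr` (16024–16569, 1–576), `hvs1_2`
(16080–16193, 16194–16365, 73–300) and `hvs1` (16080–16180,
16195–16354), the ranges conventionally used when pooling published
datasets of differing extent.  Range lists are stored sorted by start;
the circular "wrap" is notational only.

Variants follow forensic notation: `73G` substitution, `309.1C` first
inserted base after np 309, `523del` deletion.  Conventions fixed here:

* **Indel placement** is 3'-most on the plus strand.  Alignment is done
  with edlib (banded Needleman–Wunsch) and indels are then right-shifted
  within their homopolymer context; the forensic community aligns to the
  rCRS without a universally stated placement rule, and one fixed
  convention is required for reproducible distances.
* **Multi-base deletions** are stored per position (`523del 524del` is
  two variants), mirroring the notation and the site-wise distance.
* **Distances** count differing sites: a variant present in only one of
  two haplotypes counts 1; two variants at the same site with
  IUPAC-incompatible states count 1 (one differing site), with
  compatible states (point heteroplasmy such as `Y` vs `T`) counting 0.
  Haplotype *identity* (for counting spectra and RMP) is exact token
  equality after masking — conservative distances, strict identity.
* **Hotspot policy**: insertions anchored at nps 16193, 309 and 573 are
  disregarded by default; the AC-repeat deletions at nps 515–524 are
  *not* masked (only the three C-stretch anchors are named by the
  source convention this follows).  The policy object makes both sets
  configurable.

## Haplogroup rules

Motif rules are data (TSV), not code, because mtDNA nomenclature is
versioned.  A rule lists required and forbidden variants; scoring counts
required variants missing after restricting to the sample's frame, a
forbidden hit disqualifies (several former P1-diagnostic transitions are
repeatedly back-mutated, so a cheap "most matches wins" rule would
misbehave), and among rules tied on (mismatches, matches) the
least-derived label wins with an `ambiguous` flag.  Preferring more
matched variants before the least-derived tie-break is deliberate: with
nested rule tables a zero-mismatch ancestor must not shadow its fully
matched descendant.

P1 membership uses the minimal pattern `[73G 263G 315.1C] 16357C`:
16357C is decisive, and each bracketed variant is evaluated only if the
sample's frame covers its np, so HVS-I-only literature data remain
classifiable.  The P1d1-within-P1 motif is configuration, never
hard-coded: it depends on the nomenclature build in use.

## Diversity statistics

For a population sample of n individuals on a common frame: the RMP is
Σ pᵢ² over haplotype frequencies; unique-haplotype proportions divide by
n (not by the number of distinct haplotypes); MPD is the mean site
difference over all C(n,2) pairs, and between-population MPD over all
n_A·n_B cross pairs, with the corrected value reduced by the mean of the
two within-population MPDs.  The "±" attached to MPD is the Tajima-style
no-recombination total variance
V = (3n(n+1)π + 2(n²+n+3)π²) / (11(n²−7n+6)); its denominator vanishes
at n = 6, so for n ≤ 6 the equivalent-purpose Tajima (1983) form
V = (n+1)π/(3(n−1)) + 2(n²+n+3)π²/(9n(n−1)) is substituted.  The
estimator lives in one function (`tajima_mpd_variance`) precisely so it
can be swapped if a dataset-scale comparison ever arbitrates between the
variants; the published values we compared against differ from the first
form by ~1–2%, consistent with rounding of the printed means.

## AMOVA, ΦST and MDS

The haplotypic AMOVA operates on squared Euclidean inter-individual
distances; with the 0/1-per-site kernel the squared distance *is* the
site-difference count, so counts enter the sums of squares directly:
SS_total = Σ_{i<j} d_ij / N and SS_within(k) = Σ_{i<j∈k} d_ij / n_k,
with σ²_w = MS_within, σ²_a = (MS_among − MS_within)/n′ and the usual
n-weighted n′ = (N − Σn_k²/N)/(P−1) for unequal sizes.
ΦST = σ²_a/(σ²_a+σ²_w); significance comes from permuting individuals
among populations (default 10,000 permutations, seed mandatory,
p = (hits+1)/(P+1)).  Pairwise ΦST matrices keep raw values alongside a
zero-floored copy — whether negative estimates should enter an MDS is a
judgement call, so both are emitted.

Classical MDS double-centers −½·J·D²·J, eigendecomposes, and scales the
top-k eigenvectors by √λ.  Axis signs are fixed by forcing the
largest-magnitude coordinate on each axis positive, making embeddings
fully deterministic; requesting more dimensions than positive
eigenvalues warns and shrinks.

## Parsimony trees and mutation annotation

Characters are multistate nucleotide states at variable sites (plus a
gap state for deletions and presence/absence states for insertion
slots), so back-mutations arise naturally rather than being forced into
binary recoding.  The supplied ancestral haplotype joins the analysis as
a taxon; topologies are enumerated exhaustively for up to 7 haplotypes
(≤10,395 unrooted topologies including the root taxon) and searched by
seeded random-addition-order stepwise insertion plus NNI hill-climbing
beyond that, keeping up to 100 equally parsimonious trees (truncation
warns).  Scores come from Fitch optimisation vectorised over characters.

Ancestral states are assigned by the standard Fitch refinement that
keeps the parent's state whenever it lies in the downpass set,
tie-breaking deterministically toward the lowest-coded state; this
yields a minimum-change labelling with changes drawn rootward.  Branch
mutations at a site occurring on more than one branch are flagged
recurrent (rendered `_underlined_` in text output); a mutation restoring
a state its lineage carried higher up is a reversion, rendered with the
conventional `@` prefix (`@16176`).  A structural invariant — editing
the root haplotype along any root-to-leaf path reproduces that leaf
exactly, reversions cancelling — is enforced by test on every returned
tree.

## ρ, σ, ML divergence, clocks

ρ is the mean mutation count from a clade's root to its sampled leaves;
the heuristic standard error uses the genealogy:
σ² = Σ_branches (nᵢ/n)²·lᵢ with nᵢ descendant leaves and lᵢ mutations on
the branch.  On a star genealogy this reduces to σ² = ρ/n, which is also
the exact sampling variance of ρ̂ under Poisson mutation — the
calibration the star-generator test verifies (σ within 25% of the
empirical SD of ρ̂, which would fail under strong topological clustering,
where σ correctly inflates).  By default ρ counts substitutions only;
indel inclusion is a flag on the caller's side (they are excluded from
the likelihood model regardless).

ML divergence fixes the parsimony topology and optimises branch lengths,
κ and the Γ shape α (4 equal-probability categories, category-mean
rates, empirical base frequencies) by L-BFGS-B on log-parameters over a
pattern-compressed Felsenstein pruning likelihood.  The ancestral
haplotype's sequence, when supplied, anchors the root as a zero-length
pendant tip.  A clade's divergence is the mean root-to-tip expected
substitutions per site × sequence length (whole-molecule scale); its
standard error comes from the numerical curvature of the likelihood
under a joint scaling of the clade's branch lengths (observed-information
approximation, nuisance parameters held at the MLE).  With κ = 1, equal
frequencies and no rate variation the two-sequence case collapses to the
Jukes–Cantor closed form, which the tests verify to 1e-6.

Clock models map whole-molecule substitutions to years: `linear`
(T = div × rate) or `corrected` via a user-supplied monotone table with
T(0) = 0 and error propagation through the local slope — the published
purifying-selection-corrected clock is mildly non-linear and its
coefficients are not restated here, so `fit_effective_rate` calibrates
an effective linear rate from published (divergence, age) pairs by
least squares through the origin; its residual report quantifies the
curvature (the per-clade effective rates implied by the published P1
table spread by ~2%, and the pair (ρ = 12.5, T = 35.3 ky) gives
2,824 years/substitution).

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of a seeded configuration (byte-identical
re-runs).  The star and coalescent clade generators place each mutation
at a fresh np (infinite sites), so the true genealogy's mutation count
equals the parsimony score and E[ρ̂] = λ exactly; homoplasy, recurrence
and reversions are exercised through the finite-sites HKY85+Γ sequence
simulator instead, keeping estimator validation separate from
model-misfit effects.  Mutation scales follow the study system this
package was built around: λ ≈ 12.5 whole-molecule substitutions per
lineage for dating clades, control-region samples of n = 324 with the
packaged 37-haplogroup frequency spectrum, and a private-variant rate of
λ ≈ 0.35 per individual in the acceptance run, chosen as −ln(0.7) so
that ~30% of individuals are singletons, the diversity regime of the
emulated reference dataset.

The ΦST target mode is calibrated analytically, not by fitting: with k
population-private fixed variants per population and Poisson(λ) private
mutations per individual, the expected AMOVA components give
ΦST = k/(k+λ), so the generator sets λ = k(1−Φ*)/Φ*.  The default
condition (k = 1, Φ* = 0.12, two populations of 40) reproduces the
target to within ±0.03 over 20 replicates.

What passing these tests shows: the estimators are implemented correctly
and are unbiased in the regimes where their assumptions hold.  What it
does not show: behaviour under features the generators omit — population
growth, admixture waves, selection, rate heterogeneity along the
molecule's real mutational spectrum (hypervariable sites), sequencing
artefacts, or phantom mutations in literature data.  The packaged
reference sequence is synthetic; analyses of real samples must supply
the real rCRS, and haplogroup calls are only as good as the supplied
rule table.

## Problem sizes and numerical choices

The default validation suite uses 1,000 random haplotypes for codec
algebra; 50 populations of n ≤ 60 for the diversity oracles; 10,000
permutations for the null AMOVA; 20 replicates for the ΦST target; 20
datasets of ≤6 haplotypes for the parsimony-vs-exhaustive check (945
topologies each including the root taxon); 200 star replicates (n = 50,
λ = 12.5) and 500 two-to-six-lineage coalescent replicates for ρ/σ; and
8-leaf 16.5-kb clades for likelihood recovery.  Optimiser settings:
L-BFGS-B, ftol 1e-12, parameters in log space, branch lengths
initialised from parsimony mutation counts; the JC limit is checked to
1e-6 and MDS embeddings to 1e-9.  Degenerate inputs fail loudly:
empty frames, empty rule tables, populations of n < 2 where pairs are
required, divergences outside a corrected clock's table, exhausted
infinite-sites pools.
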