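# Methods

## Orthogroup delineation by species overlap

An orthogroup (OG) at a taxonomic split is a maximal clade of the rooted
gene tree containing members of at least two sibling lineages of that
split; such a clade must descend from a single gene present before the
lineages diverged.  The delineation rule is a species-overlap criterion
made explicit:

* a node at least two of whose children each mix two or more split
  lineages witnesses a duplication **older** than the split and is recursed
  into;
* any other mixed node is emitted as one orthogroup.  A single-lineage
  child of an emitted node stays inside the OG (basal lineage-specific
  copies are membership, not noise), whereas single-lineage clades falling
  *between* emitted OGs are reported unassigned with a reason;
* leaves of species outside all split lineages (e.g. *A. trichopoda* at
  the monocot/dicot split) are outgroup evidence: they are pruned from the
  recursion, never trigger emission and never join an OG.

Branch supports (e.g. aLRT) are inputs carried on nodes.  By default they
are reported but not enforced: published OGs have been accepted on
moderately supported nodes, so support gating (`min_support`) is opt-in,
and a gated node is recursed into with the decision logged.  Refinement
applies the same rule to an OG's subtree at a strictly deeper split
(angiosperm → commelinid → Poaceae); names follow the hierarchical scheme
letter / digit / lowercase letter (`A`, `A7`, `A7a`), assigned in a
deterministic traversal order that is invariant to the child order of the
input Newick.

## Tandem clusters and collinearity consensus

Gene order is an integer rank over all annotated genes of a chromosome
(0-based), so the cluster rule is exact and annotation-version explicit:
two family genes join a cluster when at most `max_gap` (default 5) other
genes intervene — rank difference ≤ `max_gap` + 1, boundary inclusive —
and clustering is the transitive closure of this relation within one
(species, chromosome).  Strand plays no role in membership; scaffold-level
records participate with their scaffold id.  The gene set against which
ranks are computed is whatever the position file provides (typically all
annotated genes); this choice is deliberate and documented rather than
hidden.

The collinearity matrix lays clusters (rows) against orthogroup labels
(columns).  With automatic column ordering, consecutive within-cluster
label pairs vote for a direction between each label pair; the majority
graph is ordered by a greedy (lexicographic-tiebreak) topological sort.
Because genomically inverted loci vote against the ancestral order, the
order and the per-row reversal flags are solved jointly by a short
fixed-point iteration (order → flag rows whose reversal strictly improves
agreement → re-vote); a cyclic majority falls back to lexicographic order
with a warning.  The consensus row reports, per column, the fraction of
loci carrying the orthogroup and the majority orientation after flipping
strands of reversed rows; exact ties are `mixed`, strand-less columns
`unknown`.  The consensus is an unweighted per-gene majority vote — a
deterministic restatement of what is otherwise done by eye — and is flagged
as such in the report.

## Codon models

The substitution process runs on the 61 sense codons of the universal
code.  The rate from codon *i* to *j* is 0 if they differ at more than one
nucleotide, and otherwise π_j, multiplied by κ for transitions and by ω for
non-synonymous changes.  Frequencies π come from the data (`uniform`,
`F1x4`, `F3x4` default, `F61`).  The chain is reversible, so transition
matrices are computed from the eigendecomposition of the symmetrized
generator and cached per (κ, ω).

**Scaling.**  Matrices are scaled so branch lengths are expected
substitutions per codon: a single-partition matrix to unit rate; site
mixtures by one common mixture-average rate; branch and branch-site models
per branch partition by that partition's mixture-average rate.  The
simulator uses the identical convention, so refitting simulated data
recovers the generating parameters — the property the recovery studies
test.

**Site models.**  M8a: a proportion p₀ of sites draws ω from a
discretized Beta(p, q) (K = 10 equal-probability categories at their bin
means, computed analytically from incomplete beta functions), the rest sit
at ω_s = 1.  M8 frees ω_s ≥ 1; the LRT has df = 1.

**Branch models.**  One site class, one ω per branch partition: the null
has two ratios (outgroup "G" clade vs everything else), the alternative
adds a third for the tested foreground branch (the ancestral branch leading
to an orthogroup); df = 1, with Bonferroni correction over the m = 6
branch partitions tested reported alongside the raw p.

**Branch-site model A.**  Four site classes — 0 (ω₀ < 1 everywhere),
1 (neutral), 2a/2b (ω₂ ≥ 1 on the foreground branch, ω₀ or 1 elsewhere)
with p₂ₐ/p₂ᵦ = p₀/p₁.  The null fixes ω₂ = 1, giving df = 1, which matches
the published parameter counts (207 vs 208) of the case study; the
outgroup branches share the background regime in this test.

**Likelihood.**  Felsenstein pruning over unique site patterns with
per-node rescaling; gaps and ambiguous codons are missing data (partial
likelihood one), never deleted — column cleaning (`clean_alignment`, gap
fraction threshold) is a separate explicit step returning the map back to
original coordinates, so flagged sites are always reportable in the
original frame.  On trees of ≤ 3 leaves the engine is tested against
brute-force enumeration of all internal states; reversibility is checked
by re-rooting invariance.

**Optimization.**  Bounded L-BFGS-B on the natural scale (κ ∈ [0.05, 99],
ω ∈ [10⁻⁴, 99], constrained ω's ≥ 1; the branch-site proportions are
optimized as (p_total, f) so the simplex constraint maps to box bounds),
with 3 seed-jittered restarts by default against multimodality.  In each
nested pair the alternative is warm-started from the null fit, which also
guarantees lnL_alt ≥ lnL_null up to termination tolerance.  Branch
lengths are, by default, re-optimized under the null and held fixed for
the alternative (`branch_lengths="null"`); `"fixed"` keeps the input
lengths (used for the simulation studies, whose trees are true) and
`"joint"` does full joint optimization.  Fixing lengths across a nested
pair is a deliberate stability/speed trade-off versus full ML and is the
mode in which the reported parameter counts exclude branch lengths.

**LRT.**  2·(lnL_alt − lnL_null) against plain χ²(df) — not the 50:50
boundary mixture: the published p-values of the case study (e.g.
2Δ = 3.888 → 0.0486) match the unmixed χ²(1), and the boundary-constrained
tests are then conservative, which the type-I studies confirm.  Statistics
negative within 10⁻³ (optimizer termination noise) are clipped to zero;
anything more negative raises.  Bonferroni: p_corrected = min(1, m·p).

**BEB.**  After a significant branch-site test, the posterior that each
codon belongs to classes 2a/2b integrates over a uniform grid prior on the
mixture parameters: ω₀ and ω₂ on 10-point midpoint grids over (0, 1) and
(1, 11], and the proportions over (p₀, f) with p₁ = (1 − p₀)·f — this
parametrization reaches p₂ ≈ 0, so the prior cannot force positive-class
mass onto data without signal.  κ, π and branch lengths stay at their
estimates (the "empirical" part).  Sites with posterior > 0.95 are
flagged; grid size is configurable (smaller grids in the fast test suite).

## Synthetic data

`simulate_codon_alignment` draws root codons from π, a class per site from
the mixture proportions, and evolves states branch by branch with the
class- and partition-appropriate transition matrices; true site classes are
returned for sensitivity/specificity scoring.

`simulate_gene_family` runs a Gillespie birth–death process of gene
duplication and loss along a species tree.  Chromosomes carry a backbone of
inert genes (default 1000/chromosome, 3 chromosomes) so rank gaps are
meaningful.  Tandem duplications insert the copy within `max_tandem_offset`
(default 5) ranks of the parent, inheriting its strand with an inversion
probability (default 0.25); segmental duplications land at a random
position on a random chromosome with random strand.  A WGD copies every
chromosome and retains each duplicated family gene with the configured
retention probability — fractionation is the complement.  True orthogroup
identities are frozen at a configured species-tree node (default the root,
i.e. the sample's last common ancestor) and inherited through all later
events; the event log records every duplication, loss and WGD copy with
its branch and time.  Gene trees returned are the true trees — classifier
correctness is deliberately separated from tree-inference error, which the
generator does not model.  Under a fixed seed all outputs are
byte-identical.

What the simulations do **not** emulate: alignment error, gene-model
curation problems, gene conversion, rate variation beyond the fitted model
families, and inferred (noisy) gene trees.  Passing recovery tests
therefore validates the statistical machinery and the pipeline contracts,
not robustness to upstream annotation or alignment artefacts.

## Validation studies and problem sizes

The case study's fitted values (its ω estimates, BEB sites, member census)
depend on a 103-sequence codon alignment that is not redistributable here;
the engine is instead validated on ground-truthed simulations, with sizes
chosen for a desk-scale run:

* parameter recovery — 20 replicates, 6 taxa, 500 codons at ω = 0.2,
  κ = 2; ±25% tolerance bands;
* type-I error — 50 null replicates per test (5–6 taxa, 150–200 codons,
  K = 4 beta categories for the site test); the rejection count is checked
  against the 95% binomial band at the nominal 5% level, with
  boundary-constrained tests expected at or below nominal;
* branch-site power — 20 replicates, 300 codons, 10% of sites at ω₂ = 8 on
  a long post-duplication foreground branch; majority detection with at
  least one true site flagged by BEB;
* orthogroup/tandem recovery — simulated families with 4 ancestral genes
  (≥95% gene-level label recovery at the split used in simulation) and
  tandem-only histories (exact array recovery at `max_gap` = 5).

The LRT stage itself is checked directly against the published
log-likelihood pairs of the case study: all twelve printed p-values are
reproduced to the printed precision, within the uncertainty the 3-decimal
rounding of the published log-likelihoods leaves on the statistic.

## Degenerate inputs and tie-breaks

Empty families simulate to an empty record set (not an error); a
zero-length foreground branch collapses the branch test to its null
(statistic ≈ 0); an all-gap column is removable but an alignment whose
columns are all above the gap threshold raises; equal log-likelihoods give
statistic 0 and p = 1; consensus ties are `mixed`, never broken
arbitrarily; GFF3 rank ties break by (start, end, id).  Gene-order ranks
must be unique per (species, chromosome) and violations name the offending
gene pairs.
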