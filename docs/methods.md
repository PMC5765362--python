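# Methods

This note documents the models, conventions and numerical choices behind
`gfd`, and what the synthetic-data generator does and does not emulate.

## Data model and conventions

Internal coordinates are 0-based half-open; on-disk GFF3 is 1-based
inclusive. The CDS includes its terminal stop codon (so CDS-length
statistics count the stop), the protein excludes it. `N` is allowed in
nucleotide sequences; a codon containing `N` translates to `X`, and
ambiguity symbols (`N`, `X`) never count as matches in identity
computations. Intron placement is encoded as "intron after residue k"
(1-based); a splice junction inside codon k is assigned to residue k, so a
junction after CDS nucleotide L maps to residue ⌈L/3⌉. ORF validation is
report-only (start codon, in-frame terminal stop, length divisible by
three, no internal in-frame stop); filtering is the caller's decision,
mirroring annotation pipelines in which failures are inspected rather than
silently dropped.

## Alignment and divergence

Pairwise global alignment is Needleman–Wunsch with affine gaps as
implemented by Biopython's `PairwiseAligner`; a gap of length L costs
`gap_open + gap_extend·(L−1)`. Defaults: BLOSUM62 with −10/−0.5 for
protein; +2/−3 match/mismatch with −5/−2 for nucleotide. These replace a
progressive multiple aligner for pairwise use; externally produced
alignments can be imported and scored column-wise instead
(`pairwise_matrix(..., precomputed=...)`), which is the fidelity path when a
specific aligner's output matters.

Percent identity is, by default, matches over aligned columns in which
neither row is a gap. This choice is deliberate: family members with long
diverged termini would otherwise have their identity dominated by terminal
gap runs. `alignment_length` and `shorter_sequence_length` denominators
remain selectable. Divergence between proteins is reported primarily as the
count of differing aligned residue pairs (gap-free columns), with a percent
scale stored alongside. Quartiles use linear interpolation between order
statistics (numpy's default percentile rule), fixed here because summary
conventions differ between tools.

In per-residue change maps, a subfamily whose alignment places a gap
against a reference residue counts as changed at that position (an absent
residue is not the reference residue).

## Cluster calling and synteny

Clusters are single-linkage chains along a chromosome: consecutive family
members join one cluster when the intergenic gap (next start − previous
end) is ≤ `max_gap`, inclusive. No published numeric rule exists for
"chromosome-level clusters" of this kind — such clusters are usually
curated — so `max_gap` is an explicit, required parameter (50 kb default)
rather than a hidden constant. Orientation between species is inferred from
the Spearman rank correlation of shared anchor order (negative ⇒ inverted),
not from strand, because inversions of gene order are the observable of
interest. Genes on chromosomes without anchors are retained but classified
`outside` the anchor span.

## Gene-conversion permutation test

The statistic D pools pairs across clusters (unweighted by cluster); the
alternative — averaging per-cluster means — is a documented option left out
of the default because pooling weights each gene pair equally and keeps the
statistic defined when cluster sizes are very unequal. The test is
one-sided (within > between), matching the directional hypothesis of
conversion-driven homogenisation. Genomic positions are held fixed; gene
labels are shuffled uniformly, so cluster sizes and membership-by-position
are preserved under the null that identity is independent of position.
Singletons (genes outside multi-member clusters) shuffle too and contribute
between-cluster pairs.

When the number of distinct labelled assignments n!/∏ size_c! is at most
`exhaustive_threshold` (20 000), the null is enumerated exactly and
p = proportion of assignments with D ≥ D_obs (the observed assignment is in
the enumeration, so p ≥ 1/K). Otherwise Monte-Carlo sampling uses the
plus-one estimator p = (1 + #{D\* ≥ D_obs})/(1 + N), which is a valid
p-value and never returns zero. Comparisons use a 1e−12 slack so that
numerically identical permuted statistics count as ties. Calibration: with
a continuous statistic the plus-one rejection rule rejects at exactly
⌊α(N+1)⌋/(N+1); the test suite verifies ~0.05 empirically on 1000 null
datasets.

An instance can be structurally unable to reject: with few genes or one
multi-member cluster, min attainable p = 1/K may exceed α. Power analyses
in the tests therefore condition on instances with ≥ 2 multi-member
clusters and 1/K ≤ α; this is a property of the test, not of the
implementation.

## Phylogenetics

Only JC69 is implemented: distances d = −¾ ln(1 − 4p/3) with p computed
over gap-free, unambiguous columns (undefined at p ≥ 0.75; a capped variant
exists for use inside heuristic searches), and pruning likelihoods with
P_same = ¼ + ¾e^(−4t/3), P_diff = ¼ − ¼e^(−4t/3), uniform root
frequencies, gaps as missing data, and site-pattern compression. Richer
models are out of scope because every claim the package makes is
property-based (oracle equivalence, recovery, monotonicity), not a fit to a
specific dataset.

Neighbor joining is the Saitou–Nei Q-criterion with deterministic
tie-breaking (lexicographically smallest cluster-key pair; a cluster's key
is its smallest leaf label) and negative branch lengths clamped to zero
with a warning. On additive matrices it provably recovers the generating
tree; the suite checks topology and lengths to 1e−8 on random 5–8 leaf
trees.

Branch lengths are optimised per edge by bounded scalar minimisation
(Brent, bounds [1e−9, 20], xatol 1e−7), cycled until the lnL gain per cycle
is below 1e−6. Monophyly on unrooted trees is clan membership: some edge
bipartition separates exactly the query tips.

The monophyly comparison builds one constrained candidate by grafting
(NJ among clusters on mean inter-cluster distances, NJ within each cluster,
cluster subtrees replacing cluster tips), plus the plain NJ tree and
`n_random_starts` NNI hill-climbs started from random topologies and
restricted to trees in which ≥ 1 cluster is non-monophyletic. All
candidates get full branch-length optimisation. The constrained-class lnL
is the best over all candidates in which every cluster is monophyletic (the
grafted tree by construction; often the NJ tree as well), and
Δ = best overall − best constrained ≥ 0. Log-likelihoods within 1e−6 (the
optimiser's convergence tolerance) are ties, and ties resolve to Δ = 0;
with effectively identical within-cluster sequences, cluster-breaking
topologies can tie the constrained optimum to machine precision, and
reporting those as positive Δ would be optimiser noise, not signal.
"Random restarts" interpret the idea of guarding a likelihood comparison
against local optima with independently initialised searches; genes outside
any usable cluster join the tree as free-floating singletons.

Intron parsimony is exact unit-cost minimum-change reconstruction computed
by dynamic programming over the two states (down-costs by post-order,
out-of-subtree costs by pre-order), valid for polytomies and `?` leaves; a
node's reported state set contains every state attained in at least one
most-parsimonious reconstruction, so the root set is the exact set of
optimal ancestral gene structures. The per-species character matrix marks
an intron position present when any copy of the species carries it.

## Linear models

Simple OLS and one-way ANOVA are closed-form; F tail probabilities come
from `scipy.stats.f.sf` (regularised incomplete beta), so any standard
implementation agrees to ~1e−10. A perfect fit reports F = ∞, p = 0; a
flat fit reports F = 0, p = 1. Group standard errors use the pooled
residual variance (√(MSE/n_g)). The shipped sperm-diameter table is a
synthetic stand-in with plausible magnitudes (its filename says so);
replace it with measured values for real inference. No log transformation
is applied to copy number by default; the caller can transform inputs.

## The forward simulator

The generator emulates the statistical structure the analyses assume:
multi-copy families (singles to tens of copies per species), hyper-conserved
proteins with freer synonymous variation, tandem clusters whose members are
more similar to each other than to other clusters, lineage-specific cluster
placement, and intron presence/absence variation across lineages.

Mechanism: exact Gillespie simulation along each species-tree branch
(exponential waiting times, event chosen proportional to rate × count).
Duplication copies a gene adjacently within its cluster; translocation
moves a gene to a new locus seeding a new cluster (move, not copy — the
simplest mechanism that creates lineage-specific placement); loss removes a
gene, and a family can go extinct on a branch (recorded; the species is
emitted with zero copies). Conversion overwrites the acceptor's whole CDS
with the donor's, donor/acceptor drawn uniformly among ordered pairs within
one cluster — whole-CDS tracts are the simplest mechanism that enforces
within-cluster identity; tract-length modelling is an extension point.
Introns gain/lose positions independently per lineage and are untouched by
conversion, which lets intron profiles disagree with CDS history exactly as
independent lineage evolution would.

Substitution is site-uniform: a site and a new base are drawn, the change
is classified synonymous/nonsynonymous against the standard code, and
nonsynonymous changes are retained with probability `nonsyn_acceptance` —
purifying selection as a single knob rather than a codon model with ω.
Changes that would destroy the start codon, the terminal stop, or create an
internal stop are always rejected (lethal), so every emitted gene is a
valid ORF by construction. At `nonsyn_acceptance = 0` all extant proteins
equal the ancestor while synonymous sites keep diverging — the
hyper-conservation limit.

Defaults (per gene, or per ordered within-cluster pair for conversion, per
unit branch length): duplication 1.2, translocation 0.2, loss 0.3,
conversion 3.0, mutation 0.3/site, nonsynonymous acceptance 0.05, intron
gain 0.03 / loss 0.15, ancestral CDS 128 codons (384 nt with the stop), one
ancestral intron after residue 10, tandem spacing 500 nt, new clusters
≥ 100 kb away, on a five-species tree of total tip depth ≈ 1.5 units.
These were chosen once to produce the qualitative regime above — copy
numbers from zero (occasional extinction) to a few tens, within-species
protein divergence of a few residues, strong within-cluster homogenisation
— not calibrated to any measured rates, which are not available for this
kind of family. Coordinates are laid out deterministically (clusters in
state order, members at tandem spacing, inter-cluster gaps exactly the
translocation distance), so cluster calling with
tandem_spacing < max_gap < translocation_min_distance recovers the true
partition exactly; this is the ground-truth contract the recovery tests
exercise.

What the generator does **not** emulate: partial conversion tracts,
strand variation (all genes are emitted on +), multi-chromosome placement
(one abstract chromosome per species by default), population-level
processes (no coalescent, no polymorphism), rate variation among sites or
branches, and sequence-content realism of non-coding DNA (intergenic and
intronic filler is `N`). Tests passing on simulated data therefore show
that the statistics behave correctly under the generative model's
assumptions — homogeneous rates, whole-gene conversion, clean cluster
geometry — not that real annotations satisfy those assumptions.

## Pipeline and reproducibility

The pipeline (simulate or ingest → identity matrix → clusters → conversion
test → NJ + monophyly, per species) derives each stochastic stage's seed
from the global seed by hashing the stage name (blake2s, reduced mod 2³¹),
so stages are independently reproducible. Every output file is hashed
(sha256) into a JSON manifest; a failing stage is recorded and the rest
continue, with the run marked `completed_with_flags`. Repeated runs under
the same config are byte-identical apart from the manifest's timing fields.

Problem sizes in the test suite and acceptance script (tens of genes,
hundreds of permutation-test datasets, tens of tree-search replicates,
alignments of ~400 nt) are desk-scale choices that keep the full
statistical checks — calibration, power, recovery, monophyly fractions —
cheap enough to run routinely while leaving their conclusions unchanged at
larger sizes.

## Known limitations

- JC69 only; no rate heterogeneity, no codon models, no bootstrap support.
- The NNI hill-climb is a heuristic; the monophyly comparison bounds the
  constrained-vs-unconstrained difference by search, not by exhaustive
  enumeration (exhaustive behaviour is verified on 4-taxon instances).
- Cluster calling is one-dimensional chaining; no synteny-aware merging.
- The conversion test detects position-linked identity structure; it does
  not locate conversion tracts or identify donor/acceptor pairs.
- GFF3 ingestion expects gene/mRNA with CDS (or exon) children; exotic
  feature graphs are out of scope.
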