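# Methods

This note documents the models implemented in `pedigen`, the conventions
adopted where the standard literature leaves choices open, the synthetic
data generator's scope, and the numerical decisions that affect results.

## Pedigree model and contribution accounting

A breeding program is a directed acyclic graph of cultivars. Every
record is terminal (no recorded parents) or carries one breeding event:
a cross (two distinct parents), or a single-source derivation
(pure-line selection or mutation; an "introduction" is read as a
selection for all computations and kept only as a file-level label).
All lines are treated as homozygous and homogeneous — the standard
assumption for self-pollinated crop programs — so edges transmit whole
inbred genomes and no within-line segregation is modelled.

*Nuclear contribution* propagates weight 1 down from each cultivar:
crosses split it in half per parent, selections/mutations pass it whole,
and the weights accumulate on terminal ancestors. Conservation (shares
sum to 1) is asserted at 1e-12 in double precision and is exercised over
1,000 random simulated programs in the test suite.

*Cytoplasmic contribution* is an indicator: the maternal line (female
slot of every cross, the single source of a selection or mutation) is
followed to one terminal ancestor which contributes 1. Selection and
mutation are taken to transmit the source's cytoplasm — physically a
selected line carries its antecedent's organelles even though the
convention is usually stated only for hybridization.

*Breeding cycles* between an ancestor and a derived cultivar count
crosses, not selection or mutation steps, because a cycle is understood
here as one round of recombination; when multiple pedigree routes
connect the pair the **maximum** cross count is used, on the argument
that prominence indicators should reflect the deepest use of the
ancestor. Both choices are configurable points in the code and both are
validated against brute-force path enumeration.

## Coefficient of parentage

`cop(a, b)` is evaluated by memoized recursion: `cop(x, x) = 1`,
distinct terminal ancestors are unrelated, a cross child averages its
parents' values, and a selection or mutant line has `cop = 0.75` with
its antecedent. Propagation of the 0.75 rule beyond the immediate
antecedent is not fixed by the usual rule set; we multiply by 0.75 along
each selection edge when recursing, which reproduces the stated endpoint
exactly and decays relatedness monotonically beyond it. No inbreeding
adjustment is applied (all lines are already fully inbred by
assumption). Unknown parents become distinct anonymous terminal
ancestors, i.e. unknown relatedness is fixed at 0; this is the
conservative choice of the two conventions (0 or 1) that pedigree work
must adopt, and it is applied uniformly.

On cross-only pedigrees with inbred founders, `cop` equals the
probability that two lines carry the same founder allele at a random
locus. The test suite verifies this against a 10,000-replicate
gene-dropping simulation (agreement within three Monte-Carlo standard
errors) on ~50-cultivar programs.

## Core ancestors and families

Candidates are terminal ancestors reached through ≥ 3 breeding cycles by
at least one population member. A candidate is nominated *core* when at
least 2 of its 4 indicators (nuclear %, cytoplasmic %, derived count,
max cycles) are **strictly** above the candidate mean — ties do not
count, a literal reading of "higher than the average"; the threshold
count and comparison pool are parameters. Because the comparison pool is
ambiguous in the literature (within each geographic origin set versus
pooled), both modes are implemented; within-origin is the default.
"Major" core ancestors are ranked by derived-cultivar count, then
nuclear, then cytoplasmic contribution — the published counts do not
state a ranking rule, so this package defines one and documents it.

## SNP QC and SNP-LD blocks

QC drops sites with missing rate > 20%, heterozygous-call rate > 10% or
MAF < 1% (defaults; all thresholds are arguments). Heterozygous calls in
inbred lines are treated as call error and recoded missing before
frequencies are computed.

Blocking is greedy and left-to-right within a chromosome: a site joins
the current block only while its |D′| with *every* member site exceeds
the threshold (default 0.7). D′ is computed from haplotype counts
directly — inbred lines are effectively phased; general unphased
diploids are out of scope. Monomorphic pairs carry no LD information and
are assigned D′ = 0, which ends a block. Haplotype classes below a
frequency floor (default 0.01, mirroring the MAF filter) are merged into
one rare class when at least two fall below it. Association-scale
pipelines implement block assembly with additional details (windowing,
merge order) that are not published; this implementation is a documented
approximation, and a pre-assembled haplotype-locus matrix can be loaded
directly (`read_haplotype_matrix`) when fidelity to an external block
map is required.

## Diversity and differentiation statistics

Richness counts distinct haplotypes per locus over the chosen subset;
allele load is the total divided by the subset size. Dispersion uses
`π = n/(n−1) Σ p_i(1−p_i)` per locus with frequencies over non-missing
members, averaged **unweighted** over loci. SPA/SDA are counted per
(locus, haplotype): private to one population, or absent from exactly
one while present in all others.

CGS counts shared alleles per locus (2 or 0 for homozygous lines) over
`m` = pairwise-complete loci; missing loci shrink the denominator rather
than counting as dissimilarity. Pairs with no overlapping loci are
flagged NaN rather than guessed.

F_ST is the ratio-of-sums Weir–Cockerham estimator with components
summed over every haplotype at every locus before dividing; negative
per-locus components are retained. With fully homozygous lines the
observed heterozygosity is zero, so the within-individual gamete
component vanishes — the formula's own behaviour for inbred data, not a
Hardy–Weinberg assumption. A locus needs ≥ 2 non-missing lines per
population to contribute; an everywhere-monomorphic input raises an
error instead of returning 0. The raw estimate may be slightly negative
under no differentiation; reports clamp at 0 but keep the raw value.
The implementation is checked against a literal variance-component
transcription over an exhaustive family of ≤ 6-sample × ≤ 4-locus
instances.

The Mantel test correlates off-diagonal upper triangles (Pearson) with a
seeded permutation null and the `(count+1)/(n_perm+1)` tail correction;
the default alternative is one-sided ("greater", relationship matrices
are expected to correlate positively). PCA operates on the column-
centered one-hot haplotype encoding; missing entries are imputed at the
column mean (zero after centering); component signs are fixed by making
each component's largest-magnitude loading positive.

## Neighbor joining and group cutting

Canonical Saitou–Nei agglomeration. Determinism is pinned: Q-matrix ties
resolve to the lowest index pair, and a negative branch length is
clamped to zero with the deficit moved to its sibling edge so leaf-leaf
path lengths are preserved. On additive inputs the generating topology
and metric are recovered exactly (tested on 200 random additive trees up
to 12 taxa, and against an independent reference implementation on
random matrices).

Groups are produced by midpoint-rooting the tree and removing the k−1
longest edges greedily — internal edges before leaf edges, ties broken
by the smallest leaf name below the edge — skipping any cut that would
strand a leafless component; labels A, B, … follow decreasing group
size. Published cluster boundaries on real programs are typically drawn
by inspection; this cut is a reproducible stand-in, not a claim about
how any particular study delimited its groups. Note that near-duplicate
lines (e.g. a selection and its source) form zero-distance cherries
whose subtending edges can rival genuine between-group edges; the
planted-partition recovery test therefore uses cross-only simulated
programs.

## Trial ANOVA

`y_ijk = μ + t_i + b_j(i) + g_k + (gt)_ik + ε_ijk`, environments and
blocks fixed, genotype and G×E random. Sums of squares are Type-I on the
ordered model, computed directly from cell means — exact for balanced or
proportional designs (every genotype in every block; block counts may
differ between environments, as with 2 and 3 replications at two
stations). Variance components solve the expected mean squares:
`σ²_e = MS_err`, `σ²_ge = (MS_ge − MS_err)/r̄`,
`σ²_g = (MS_g − MS_ge)/R` with `r̄` the mean block count per environment
and `R` the observations per genotype. Negative estimates are reported
raw and clamped at zero inside `GCV = 100·σ_g/μ`. The implementation is
cross-checked against an independent least-squares ANOVA (statsmodels,
Type-I) in the tests; with unbalanced replication the direct-means
formulas coincide with Type-I sums of squares for the proportional
designs in scope.

## Synthetic data generator

The generator emulates the structure the pipeline is meant to analyse: a
three-ecoregion program (configurable up to four region labels) with
founder landraces per region, generations of mostly-local crossing
(cross-region parents with probability `migration_rate`), a fraction of
pure-line selections, and fully inbred gene-dropped genotypes. Defaults:
3 regions × 8 founders, 4 generations × 20 crosses, selection fraction
0.1, migration 0.05, divergence 0.6, 2 chromosomes × 120 SNPs in blocks
of mean length 5, within-block recombination 0.01 — a desk-scale
caricature of a regional breeding system in which ancestors are shared
within regions far more than between them.

Founder haplotypes are drawn per block from two widespread haplotypes
plus one region-private haplotype; `divergence` scales both the private
frequency (0.5·divergence) and the region-specific perturbation of the
widespread frequencies, so divergence 0 yields exchangeable regions and
divergence 1 yields strong SPA structure. Transmission is block-level:
a cross child draws each block from one parent (instant homozygosity)
with optional within-block recombination; selection copies; mutation
flips a configured site fraction. Block-level transmission and instant
homozygosity keep runtimes at desk scale; a real program's residual
heterozygosity, realistic recombination maps, selection on phenotype and
genotyping error are *not* emulated, so passing tests demonstrate
algorithmic correctness on idealized inbred data rather than robustness
to those features of real data.

All randomness flows through explicit integer seeds (no global state);
identical seeds reproduce byte-identical output files.

## Problem sizes used in validation

The validation suite runs at deliberately modest scales chosen as
sufficient for the properties being demonstrated: breeding programs of
tens of cultivars, hundreds of SNPs in tens of blocks, 10,000
gene-dropping replicates for the identity-by-descent concordance, 200
additive trees for topology recovery, 200 null Mantel runs at 999
permutations, and 100 ANOVA replicates at 200 genotypes × 2 environments
× 3 blocks. Full-program results from the literature (hundreds of
cultivars, ~28,000 blocks from ~278,000 SNPs) are not reproducible
without the underlying proprietary data; the printed arithmetic
identities that depend only on published totals are reproduced exactly
by the corresponding summary operations.

## Known limitations

* Pedigree reconstruction from markers, outbred/heterozygous parents and
  polyploidy are out of scope.
* Block assembly approximates unpublished association-pipeline
  behaviour; use an external block map for fidelity-critical work.
* EM phasing is not implemented; unphased heterozygous diploids are not
  supported by the LD machinery.
* REML mixed models are not implemented; the EMS solution is exact only
  for balanced/proportional designs.
* The NJ group cut is one reproducible convention among several
  defensible ones; group labels are stable but group boundaries near
  zero-length internal edges depend on the tie-breaking described above.
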