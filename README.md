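# pedigen

Pedigree-based germplasm accounting integrated with genomic-marker
diversity analysis for inbred crop breeding programs.

Breeding programs accumulate their genetic base over decades: every
released cultivar traces back through crosses, pure-line selections and
mutants to a set of *terminal ancestors* — landraces or lines whose own
parentage cannot be traced further. `pedigen` answers the questions a
germplasm curator or breeder asks about such a program:

* which terminal ancestors supplied the genome of each cultivar, and in
  what proportion (nuclear genetic contribution), and which single
  ancestor supplied the cytoplasm (maternal line);
* how related any two cultivars are on paper — the coefficient of
  parentage (COP, identity by descent) — versus how similar they are in
  the lab — the coefficient of genetic similarity (CGS, identity by
  state) computed from genome-wide markers;
* which ancestors are *core*: reached through three or more breeding
  cycles with at least two of four prominence indicators (nuclear
  contribution, cytoplasmic contribution, derived-cultivar count, cycle
  count) above the candidate average, and what their derived families
  look like across ecoregions;
* how genetically rich and differentiated subpopulations are:
  multi-allelic haplotype loci (SNP-LD blocks), allele numbers and
  loads, frequency dispersion π, population-private alleles (SPA/SDA),
  Weir–Cockerham F_ST, PCA, Mantel comparison of relationship matrices,
  and neighbor-joining clustering;
* how heritable measured traits are across environments: randomized
  complete-block multi-environment ANOVA with variance components and
  the genetic coefficient of variation (GCV).

A synthetic-data module simulates multi-ecoregion breeding programs with
gene-dropped, pedigree-consistent genotypes, so the entire pipeline is
testable end to end without confidential program data.

## The quantities computed

**Nuclear contribution.** A cross transmits half of each parent's genome,
selection and mutation transmit it whole, so the contribution of terminal
ancestor *A* to cultivar *C* is `Σ_paths (1/2)^(n_crosses)`; contributions
over all ancestors of a cultivar sum to 1. The cytoplasm follows the
female parent of every cross up to one terminal ancestor, which
contributes 1.

**Coefficient of parentage.** `COP(S, D) = Σ (1/2)^n` over common
parents, evaluated recursively with the breeding-program conventions: all
lines homozygous and homogeneous, distinct terminal ancestors unrelated
(COP 0), `COP(x, x) = 1`, and `COP = 0.75` between a selected or mutant
line and its antecedent.

**Marker statistics.** SNPs passing QC (missing rate ≤ 20%,
heterozygosity ≤ 10%, MAF ≥ 0.01) are grouped into SNP-LD blocks
(|D′| > 0.7 between every pair of member sites) treated as multi-allelic
loci whose alleles are haplotypes. On these loci: richness (allele
counts, allele load per cultivar), dispersion `π = n/(n−1) Σ p_i(1−p_i)`,
SPA/SDA counts, `CGS s_ij = Σ_k C_ijk / (2m)` with distance
`d_ij = 1 − s_ij`, the multi-allelic Weir–Cockerham
`F_ST = Σ_u a_u / Σ_u (a_u + b_u + c_u)`, PCA on the one-hot haplotype
encoding, and Saitou–Nei neighbor joining on `d_ij` with reproducible
group cutting.

**Trait analysis.** `y_ijk = μ + t_i + b_j(i) + g_k + (gt)_ik + ε_ijk`
with variance components from expected mean squares and
`GCV = 100·σ_g/μ`.

## Worked example

The released soybean cultivar Nannong 32 (a cross of Nannong 87-23 ×
Chuxiu) traces to seven terminal ancestors:

```python
from pedigen import (CultivarRecord, PedigreeGraph, cop,
                     cytoplasmic_ancestor, nuclear_contribution)

records = [
    CultivarRecord(id=t) for t in
    ["73-01-1", "Huaiyindasili", "Fengxiansuidaohuang", "51-83",
     "Dangshanwandousha", "Tongshantianedan", "Mamotan"]
]
def cross(cid, f, m):
    return CultivarRecord(id=cid, method="CROSS", female_or_source=f, male=m)
records += [
    cross("Chuxiu", "73-01-1", "Huaiyindasili"),
    cross("NN-mid-1", "Tongshantianedan", "Mamotan"),
    cross("NN-mid-2", "Dangshanwandousha", "NN-mid-1"),
    cross("NN-mid-3", "Fengxiansuidaohuang", "51-83"),
    cross("Nannong 87-23", "NN-mid-3", "NN-mid-2"),
    cross("Nannong 32", "Nannong 87-23", "Chuxiu"),
]
graph = PedigreeGraph(records)

for anc, w in sorted(nuclear_contribution(graph, "Nannong 32").items(),
                     key=lambda kv: -kv[1]):
    print(f"{anc:22s} {w:.4f}")
print("cytoplasm ->", cytoplasmic_ancestor(graph, "Nannong 32"))
print("Mamotan cycles =", graph.breeding_cycles("Mamotan", "Nannong 32"))
print("COP(Nannong 32, Chuxiu) =", cop(graph, "Nannong 32", "Chuxiu"))
```

prints

```
73-01-1                0.2500
Huaiyindasili          0.2500
Fengxiansuidaohuang    0.1250
51-83                  0.1250
Dangshanwandousha      0.1250
Tongshantianedan       0.0625
Mamotan                0.0625
cytoplasm -> Fengxiansuidaohuang
Mamotan cycles = 4
COP(Nannong 32, Chuxiu) = 0.5
```

Each value is the expected genome share of that founder in Nannong 32
(halving at every cross on the deepest route; they sum to 1); the
cytoplasm follows the maternal line to the landrace Fengxiansuidaohuang;
Mamotan sits four crossing cycles deep, matching its (1/2)^4 = 0.0625
share; and a cultivar relates to one of its immediate parents with
COP 0.5 when the parents are unrelated.

## Command line

```bash
pedigen simulate --seed 5 --divergence 0.8 --out run/          # synthetic program
pedigen trace     --pedigree run/pedigree.tsv --out run/trace
pedigen core      --pedigree run/pedigree.tsv --out run/core
pedigen diversity --vcf run/genotypes.vcf --regions run/regions.tsv --out run/div
pedigen cluster   --vcf run/genotypes.vcf --regions run/regions.tsv -k 3 --out run/nj
pedigen compare   --pedigree run/pedigree.tsv --vcf run/genotypes.vcf --out run/cmp
```

All reports are TSV/Newick/JSON; every run writes a `manifest.json` with
input checksums, parameters and the seed, and reruns with the same seed
are byte-identical.

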