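# Methods

## The question and the statistic

In an admixed population, each copy of a gene carries a *local ancestry*: the
continental population (here African `AFR`, European `EUR`, or Native
American `NAT`) from which that haplotype segment descends.  If mate choice
is correlated with ancestry — assortative mating — offspring carry the same
ancestry on both gene copies (*ancestry homozygosity*) more often than random
mating predicts; disassortative mating produces the opposite excess of
*ancestry heterozygosity*.

The Assortative Mating Index (AMI) measures this per gene.  Let the
locus-specific ancestry fractions among the `2n` haplotypes of the `n`
individuals with both copies assigned be `a`, `e`, `n̂` (`a + e + n̂ = 1`).
Treating these as allele frequencies of a triallelic locus, random mating
implies Hardy–Weinberg (HW) genotype frequencies `(a + e + n̂)²`, hence

    exp(hom) = (a² + e² + n̂²) · n        exp(het) = n − exp(hom)

and the AMI is the log odds ratio

    AMI = ln[ (obs_hom / exp_hom) / (obs_het / exp_het) ]

positive under assortative, negative under disassortative mating, zero under
HW.  Expected counts are real-valued (frequencies times counts, never
rounded) and enter all downstream formulas as-is.

Phenotypes are polygenic, so inference is at the level of *gene sets*: each
gene contributes a 2×2 stratum (rows observed/expected, columns hom/het) and
the strata are pooled with the Mantel–Haenszel (MH) fixed-effects estimator

    OR_MH = Σ_g (a_g d_g / N_g) / Σ_g (b_g c_g / N_g)

with the Robins–Breslow–Greenland (RBG) variance for `ln OR_MH`, a normal
two-sided p-value, and Benjamini–Hochberg q-values computed once over the
whole run's family of (phenotype × population) tests.  The implementation
was checked against an exact rational-arithmetic pooling oracle and agrees
with R's `metafor::rma.mh` to all printed digits.

### Known statistical property: the HW-based test is conservative

The "expected" row of each stratum is a deterministic function of the
observed ancestry fractions, but the RBG variance treats both rows as
sampled.  The estimated variance of the pooled log OR is therefore roughly
twice its true sampling variance, deflating |z| by about √2: at nominal
α = 0.05 the realized type-I error under simulated random mating is ≈ 0.01.
This matches the behaviour of the original analysis stack (the same MH
machinery applied to the same table construction) and is deliberately left
as-is: the test is valid (never anticonservative), and the trait-specificity
question is in any case better answered by the random-gene-set permutation
null described below, which calibrates itself empirically.  The practical
cost is some loss of power at a given nominal level.

## Handling of edge cases

* **Fixed loci** (one ancestry at frequency 1): `exp_het = 0`, the odds
  ratio is undefined; the gene is excluded with a logged reason.
* **Zero observed cells**: the Haldane–Anscombe continuity correction
  (+0.5 on all four cells) is applied for the gene-level display value and
  the value is flagged `corrected`.  MH pooling uses raw cells (zero cells
  are tolerated by the estimator); only if the pooled numerator or
  denominator vanishes entirely is the correction applied in pooling.
* **Ties/degenerate inputs**: equal-mean zero-variance samples in the
  distribution comparison return p = 1; identical AMI across populations
  gives zero cross-population variance.

## From segments to ancestry genotypes

A haplotype is assigned an ancestry at a gene iff the gene interval is fully
contained in one local-ancestry segment with certainty ≥ `min_certainty`
(default 0.99).  Genes straddling an ancestry switch, or covered only by
low-confidence calls, get no assignment on that haplotype — a conservative
rule; aggregating marker-level certainties by mean or majority vote over the
gene would assign more haplotypes at the cost of boundary noise.  Individuals
contribute to a gene's 2×2 only with both copies assigned; the same
individuals define the locus ancestry fractions, so observed and expected
refer to one cohort.

Genes callable in too few individuals are dropped by the *ancestry genotype
threshold*: with `n_g` the per-gene count of fully assigned individuals,
genes with `n_g > mean(n_g) − sd(n_g)` (sample sd) are retained.  When the
spread is degenerate (sd = 0, e.g. a uniform matrix or a single gene) the
rule becomes `n_g ≥ mean`, so uniform data are kept whole.  The per-gene
reading of the threshold (count of individuals per gene, not genes per
individual) is a deliberate choice; both readings are defensible and the
per-gene one is what the filter's purpose — dropping uninformative loci —
requires.

## Gene sets

GMT input; the category token (anthropometric / neurological / HLA, else
"other") is read from the description field.  Sets are restricted to genes
passing the threshold and must keep ≥ 2 genes.  Linkage disequilibrium
between genes would let one signal count twice, so pairs with inter-genic
SNP r² > 0.1 (from a user-supplied precomputed table) are broken greedily:
offending pairs in decreasing r², dropping the later-listed gene of any pair
still intact.  Keeping the earlier-listed gene makes pruning deterministic
in the set's gene order.  Pruning is within-set; a gene may survive in one
set and be pruned from another.

## Permutation nulls

**Random mating.**  Per gene, the observed haplotype labels of fully
assigned individuals are pooled and re-paired uniformly at random *with
replacement* into 10,000 virtual diploids; the AMI of the virtual cohort
against the same HW expectations gives the per-gene null.  Pairing with
replacement matches the HW ideal exactly, so the null is centered at zero
with Monte-Carlo spread `≈ √(1/(m·p_hom) + 1/(m·p_het))`.

**Random gene sets.**  Genome-wide ancestry assortment shifts every gene's
AMI, so a trait-specific claim must beat that background.  For each observed
set size, many random same-size gene subsets are drawn from the informative
pool, each pooled by MH; the observed pooled log OR gets a two-sided add-one
empirical p-value `(1 + #{|null| ≥ |obs|}) / (n_perms + 1)` (never zero; an
observation beyond all draws scores `1/(n+1)`).  One run seed drives both
procedures through independent `SeedSequence` substreams.

Cross-population AMI variance per phenotype (sample variance over
populations, normalized by the mean variance over phenotypes) uses the same
random-set draws: the null variance of draw *i* across populations locates
the observed variance empirically, since no analytic test for this ranking
is available.

## Ancestry drivers

For a gene set and ancestry `anc`, with `obs_g^anc` the count of individuals
homozygous for `anc` at gene g and `exp_g^anc = f_anc(g)² · n_g`,

    AH_anc = Σ_g (obs_g^anc − exp_g^anc) / exp_g^anc

sums *relative* excesses, so rare ancestries are not swamped; a companion
absolute column (`Σ obs − exp`, which decomposes the total homozygosity
excess exactly) and a per-gene mean are emitted alongside.  Terms with
`exp_g^anc = 0` are skipped and logged.  Inter-individual ancestry variation
is summarized by the coefficient of variation (sd/mean, sample sd) of
per-individual global fractions, per ancestry — scale-free, hence comparable
between a 10% and a 50% ancestry; undefined (NaN) for an absent ancestry.

## The simulator

A deliberately minimal forward model — the simplest that exhibits what the
AMI must detect:

* **Founders** are diploids homozygous for one ancestry at every gene,
  drawn from the founder mixture (an instantaneous admixture event).
* **Burn-in** (`n_burnin_generations`, default 5): random mating only.
  This creates admixed standing variation; without it, strong assortment
  from the founding event merely perpetuates single-ancestry lines and no
  admixed genomes ever form.
* **Mate choice**: monogamous pairs by sequential weighted sampling without
  replacement, pair weight `exp(−strength · d)`.  The distance `d` is the
  Euclidean distance between per-gene ancestry-dosage profiles (dosage of
  each ancestry at each gene, halved), normalized by √#genes so
  `d ∈ [0, √2]` at any gene count — over all genes (`global_ancestry`),
  over a designated trait set (`gene_subset`), or collapsed to the scalar
  genome fraction of one ancestry (`ancestry_component`).  Gene-wise
  similarity is the operative choice: matching on genome-averaged fractions
  alone couples so weakly to individual loci that no locus-level
  homozygosity excess arises at realistic strengths.  In component mode the
  scalar fraction *is* the matched trait (its variance inflation is the
  point there); its distances are ~10× smaller, so comparable assortment
  needs roughly strength 30 where profile modes need 10.
* **Reproduction**: constant population size; each pair's offspring draw
  each gene-haplotype uniformly from the parent's two copies, independently
  across genes (free recombination, no linkage map); no mutation or
  selection.  Size not divisible by the pair count is balanced by giving
  randomly chosen pairs one extra child.

Defaults (200 individuals, 500 genes, 5 + 10 generations, founder mixture
(0.2, 0.5, 0.3)) represent a desk-scale Latin-American-like history:
admixture beginning ~15 generations ago with mate choice operating
throughout.  Expected ancestry proportions are conserved across generations
(assortment changes genotype, not allele, frequencies); realized mate-pair
ancestry correlations per generation are recorded as ground truth.

What the simulator does *not* emulate: linked loci and realistic
recombination maps (segments here are per-gene, so segment-length
distributions are meaningless), marker-level ancestry-calling uncertainty
(simulated certainty is 1.0), continuous migration, population growth, or
selection.  Passing tests therefore validate the statistical machinery and
its calibration under the stated model, not robustness to LD structure or
ancestry-call error in real panels.

The standard fixture dataset writes four populations with qualitatively
distinct admixture profiles (European-heavy three-way, Native-American-heavy,
African-substantial, strongly European); one of them (`popB`) mates
assortatively restricted to a 30-gene trait set, the rest mate randomly —
an end-to-end testbed with known truth.

## Problem sizes used in validation

Oracle checks enumerate all 2×2 tables with cells 1–5 for one and two strata
(391,250 tables) and a seeded 100,000-table sample for three strata, against
exact integer arithmetic.  Calibration and power studies use 200-individual,
300–500-gene populations: 100 random 10-gene phenotypes for type-I error, 50
replicates of a 30-gene trait set at strength 10 (with 20 random null sets
each) for power/specificity, and 20 replicates of African-ancestry
assortment at strength 30 for driver recovery.  `scripts/acceptance.py`
recomputes all of these from scratch for any seed.
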