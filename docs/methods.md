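# Methods

## The filtering strategy

Affected relatives who share a causal allele inherited it from a common
ancestor, so the allele lies in a genomic region they share identical by
descent (IBD).  In *distant* relatives those regions cover only a few
percent of the genome, so intersecting exome variants with case-case IBD
sharing is a powerful first-pass filter.  The pipeline implements this
strategy over a set of extended pedigrees with per-gene IBD scores in
{0, 0.5, 1} (0.5 = one allele shared; 1 — both alleles — occurs only in
full siblings or twins when there is no inbreeding):

1. **Pair selection.** For each phenotype replicate, select every
   affected-affected pair whose genome-wide sharing (the unweighted mean
   of its per-gene scores) lies in [`lo`, `hi`] = [0.01, 0.09], the
   empirical central 95% interval of fourth- and fifth-degree relatives.
   The interval's endpoints are inclusive; pairs sharing more (closer
   relatives) or less are excluded.
2. **Gene scoring.** Score each gene by the number of *distinct* selected
   cases that appear in at least one selected pair with score > 0 at that
   gene (a case counts once however many pairs support it).  Two rules
   turn scores into a per-replicate gene list: **most cases** walks the
   case-count threshold k upward from 2 and stops at the first k where
   fewer than `gene_cap` = 100 genes (but more than zero) qualify, keeping
   all of them; **max cases** keeps only the argmax set.  Ties are always
   kept whole.
3. **Replicate aggregation.** Count, per gene, the replicates in which it
   was selected; keep genes at or above `replicate_min` (default a quarter
   of the replicates, i.e. 50 of 200).
4. **Variant filtering.** Within kept genes, keep variants with
   population MAF strictly below 0.10 and nonsynonymous annotation.  The
   MAF is the variant map's population frequency (the synthetic analog of
   a reference-panel frequency), not the in-sample frequency.
5. **Association screen.** A family-based association score test (below)
   run in every replicate where the marker is informative in at least
   `min_pedigrees` extended pedigrees; each marker's minimum p across
   replicates is recorded, and markers with min p < 0.05 form the
   candidate-variant table.

## Relatedness

The kinship coefficient φ is computed by the standard recursion
(φ = 0 between distinct founders; φ(x,x) = (1 + F_x)/2; otherwise recurse
on the individual of greater generation depth).  Expected genome sharing
is g = 2φ, and the **degree** of a relationship is defined through g
rather than through raw path meioses, so that two-common-ancestor pairs
land on the conventional bands: parent-offspring share 50% (degree 1),
avuncular/grandparental 25% (2), first cousins 12.5% (3), 6.25% (4),
3.13% (5), following g = (1/2)^m.  Relationships whose 2φ is not a power
of ½ (not produced by the generator, but accepted on input) get the
nearest-integer degree with an `exact=False` flag.

## The family-based score test

With additive coding X = minor-allele dosage, each nuclear family f
contributes U_f = Σ_affected (X − E[X | parents]) where
E[X | parents] = g_f/2 + g_m/2 under independent Mendelian transmission.
U = Σ_f U_f; the model variance is Σ_f Σ_affected Var(X | parents) and the
empirical (robust) variance — the default, appropriate when several
nuclear families come from one extended pedigree and are correlated — is
Σ_f U_f².  Z = U/√V with a two-sided normal p.  Only families with both
parents genotyped contribute; the sufficient-statistic machinery for
missing parents is out of scope because the simulated pedigrees are fully
genotyped.  Only affected offspring enter the score (a case-oriented
screen).  A family is *informative* for a marker when at least one parent
is heterozygous and at least one affected offspring is genotyped; a
*pedigree* is informative when at least one of its nuclear families is.
With V = 0 or no informative family the marker is flagged non-testable
rather than assigned a p-value.  Note the empirical variance bounds
|Z| ≤ √(number of informative families), so very rare variants in small
samples cannot reach small p-values — a real limit of the screen, not an
implementation artifact.  No multiple-testing correction is applied; the
strategy ranks by raw minimum p.

## The synthetic-data generator

The generator emulates the shape of a mini-exome family study — by
default 8 extended pedigrees totalling ~697 individuals, 24,488 SNPs in
3,205 genes, and 200 phenotype replicates over one fixed genotype set —
with every count scalable through `SimConfig`.

**Pedigrees.** Each family starts from one founding couple with a wide
sibship (≥ 6 children, all marrying new founders), giving several
lineages whose cross-lineage pairs are the fourth/fifth-degree material
the strategy feeds on; below the top, each couple's first child marries
(keeping lineages alive) and the rest marry with probability 0.35.
Spouses are always new founders, so there is no inbreeding and risk
alleles can enter in any generation.  Sibship sizes are Poisson (mean 3,
minimum 1); when a target study size is set, the last generation's
sibship sizes are steered to the budget and family structures are
rejection-sampled to within ~6% of the per-family target.  Depth is 5
generations by default (degree-1 through ≥5 pairs guaranteed).

**Genome and map.** Genes are point loci at their genetic-map midpoint —
the IBD unit of the study is the gene, and no within-gene breakpoints are
modelled — placed uniformly along 22 chromosomes with realistic genetic
lengths (~3.4 kcM total).  All SNPs of a gene sit at its midpoint; base
positions use ~1 Mb/cM and are made strictly increasing.  Population
MAFs are drawn from Beta(0.2, 7.9) truncated to [7×10⁻⁴, 0.5], which
reproduces a rare-heavy exome spectrum with ~88% of SNPs below MAF 0.1;
both shape parameters and the floor are config fields.  Function class is
nonsynonymous with probability 0.367, independent of frequency.

**Gene drop.** Founders carry two globally unique haplotype labels;
every transmission draws Poisson(L/100) crossovers placed uniformly on
the chromosome (Haldane model, no interference) and a random starting
phase, and copies the parental label at each gene midpoint.  Label
equality is therefore *exact* identity by descent, and the true per-gene
IBD score of a pair is half the size of the maximum matching between
their label pairs.  Founder haplotype alleles are Bernoulli(MAF) per SNP;
dosage is the minor-allele count, so genotypes and IBD truth are mutually
consistent.

**Phenotypes.** A liability-threshold model: liability = Σ β·dosage over
causal variants + standard normal noise, affected when liability exceeds
a threshold calibrated (by root-finding on the realized genetic values)
so the *expected* affected fraction equals `prevalence_target` (default
0.30, chosen to yield enough case-case pairs per pedigree).  Each
replicate redraws only the noise.  Causal genes are drawn from genes
carrying at least `causal_min_variants` rare nonsynonymous variants with
MAF in [`causal_maf_min`, `causal_maf_max`) and at least one carrier;
every such variant in a causal gene receives liability effect
`causal_effect` per allele.  The default effect is 1.0 SD; the scaled
study preset uses 2.5 SD with MAF in [0.02, 0.1) and ≥2 variants per
gene — a strong, recurrent allelic series.

**What the generator does not emulate.** Founder haplotypes are
exchangeable Bernoulli draws: there is no population LD, no shared recent
ancestry between founders, no sequencing error, and no ascertainment of
families through affected members.  Real exome studies in founder
populations concentrate rare causal alleles in the early generations of a
pedigree far more than exchangeable founders do, so passing tests here
speak to the correctness of the machinery and to the strategy's behavior
under a neutral founder model, not to its power on any particular real
data set.

## Numerical and testing choices

* Determinism: a single `numpy` Generator seeded from `SimConfig.seed`
  drives each study; identical config + seed reproduces every output
  byte-for-byte, and writers emit sorted, commented TSV.
* IBD matrices store doubled scores as uint8 (~30k pairs × 3.2k genes
  ≈ 96 MB at full scale); public accessors return {0, 0.5, 1}.
* Degenerate inputs: empty pair selections warn and yield empty gene
  lists rather than aborting a multi-replicate run; "most cases" raises
  with a per-k diagnostic when no threshold qualifies; zero-selected
  sensitivity cells render "—", not 0%.
* The realized-vs-expected sharing check uses a delete-one-chromosome
  jackknife for its Monte-Carlo standard error, since genes within a
  chromosome (and pairs within a pedigree) are correlated.
* Statistical tests are seeded (derandomised) and sized to run in
  seconds-to-minutes: e.g. 2,000 null datasets of 20 informative families
  for the score test's type-I calibration, 10⁵ single-locus gene drops
  per pedigree for the kinship oracle, and an 800-gene / 40-replicate
  8-pedigree study for the analysis scripts.

## Candidate sets and sensitivity

Two candidate sets are distinguished downstream of the screen: the
**flagged** set (min p < 0.05), which populates the candidate-variant
table, and the broader **tested** set (informative in ≥ `min_pedigrees`
pedigrees in ≥ 1 replicate), which the sensitivity grid scores.  TP% =
100 · true positives / selected is reported at both variant and gene
level, over a grid of scoring mode × informativeness threshold
({3, 5, 8} pedigrees at full scale).

## Known limitations

* The "max cases" rule has very low sensitivity in small designs.  In a
  two-pedigree study (~174 individuals, 500 genes, 5 causal genes) the
  per-replicate argmax is an extreme order statistic over hundreds of
  correlated gene-sharing counts; coancestry cliques among high-liability
  cases support arbitrary founder segments at about the same counts as
  the causal clusters, so the argmax rarely lands on a causal gene.
  Exploration across effect sizes (1.2–3.5 SD), prevalences (0.10–0.30),
  study sizes (60–350) and causal architectures (including variants
  planted on founding-couple haplotypes) found no two-pedigree regime
  with consistent max-cases recovery; "most cases" at the same scale
  shows a genuine ~2–3× enrichment over the 1% causal base rate.  The
  strategy's published use case — many pedigrees, hundreds of
  individuals, hundreds of phenotype replicates — is the regime where
  max-cases becomes competitive.
* The score test covers complete-parent nuclear families, a binary
  affected-only coding, and single markers; no haplotype or
  quantitative-trait extensions.
* No statistical IBD inference from genotypes: the pipeline consumes
  provided (here: simulated-truth) IBD scores.
* No X chromosome, no inbred pedigrees, no regulatory/splicing
  annotation.
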