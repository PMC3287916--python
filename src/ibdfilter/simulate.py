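"""Gene-drop synthetic-data generator emulating a mini-exome family study.

Produces every input the pipeline needs, with known planted truth:

* extended pedigrees (founders marrying in at every generation, relative
  pairs out to fifth degree, no inbreeding loops);
* a variant map — SNPs assigned to genes along chromosomes, population
  MAFs from a rare-skewed truncated Beta law, synonymous/nonsynonymous
  class labels;
* founder-labelled genotypes from a gene drop: every non-founder
  inherits one recombined haplotype from each parent, with crossovers
  Poisson at 1 per 100 cM (Haldane, no interference).  Genes are point
  loci at their cM midpoint, so founder labels are constant within a
  gene and true IBD is exact;
* the true per-gene IBD score matrix for any set of pairs;
* replicate affection-status files from a liability-threshold model
  with planted causal genes.

Default scale mirrors a mini-exome workshop data set: 8 extended
pedigrees totalling ~697 individuals, 24,488 SNPs in 3,205 genes, 200
phenotype replicates; every count scales down through :class:`SimConfig`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .evaluation import TruthSet
from .ibd import IbdMatrix
from .pedigree import FEMALE, MALE, Individual, Pedigree


def default_chromosome_map() -> tuple[tuple[str, float], ...]:
    """22 autosomes with approximate sex-averaged genetic lengths (cM)."""
    lengths = [
        286, 269, 223, 214, 204, 192, 187, 168, 166, 181, 158,
        175, 126, 119, 141, 134, 128, 117, 107, 108, 62, 74,
    ]
    return tuple((str(i + 1), float(c)) for i, c in enumerate(lengths))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data generator.

    ``pedigree_depth`` counts generations including the founding couple
    (depth 2 is a nuclear family).  ``causal_effect`` is the liability
    shift per minor allele at each causal variant, in residual-SD units.
    ``target_individuals`` (optional) steers the last generation's
    sibship sizes toward a total study size; branching above it stays
    stochastic.
    """

    n_pedigrees: int = 8
    pedigree_depth: int = 5
    mean_children: float = 3.0
    founding_children_min: int = 6
    marry_prob: float = 0.35
    target_individuals: Optional[int] = 697
    n_genes: int = 3205
    n_snps: int = 24488
    chromosome_map: tuple[tuple[str, float], ...] = field(
        default_factory=default_chromosome_map
    )
    maf_beta: tuple[float, float] = (0.2, 7.9)
    maf_min: float = 7e-4
    nonsyn_fraction: float = 8994 / 24488
    n_causal_genes: int = 5
    causal_effect: float = 1.0
    causal_maf_max: float = 0.10
    causal_maf_min: float = 0.0
    causal_min_variants: int = 1
    prevalence_target: float = 0.30
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pedigrees", "n_genes", "n_snps", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be > 0")
        if self.pedigree_depth < 2:
            raise ValueError("pedigree_depth must be >= 2 (no transmissions possible)")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.n_snps < self.n_genes:
            raise ValueError("n_snps must be >= n_genes (every gene needs a SNP)")
        if self.n_causal_genes < 0:
            raise ValueError("n_causal_genes must be >= 0")
        if not self.chromosome_map:
            raise ValueError("chromosome_map must be non-empty")

    @classmethod
    def scaled(cls, seed: int = 0, **overrides) -> "SimConfig":
        """A small study for fast runs: 2 pedigrees (~174 individuals),
        500 genes / 2,500 SNPs, 20 replicates, 5 causal genes of strong
        effect (2.5 residual-SD per allele) with a recurrent allelic
        series (>=2 rare nonsynonymous variants, MAF in [0.02, 0.1))."""
        base = dict(
            n_pedigrees=2,
            target_individuals=174,
            n_genes=500,
            n_snps=2500,
            n_replicates=20,
            n_causal_genes=5,
            causal_effect=2.5,
            causal_maf_min=0.02,
            causal_min_variants=2,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


# -- pedigree construction ---------------------------------------------


def make_pedigrees(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Pedigree:
    """Generate ``n_pedigrees`` extended families as one :class:`Pedigree`.

    Every couple's first child (the founding couple's first two) marries
    a new founder, guaranteeing two persisting lineages and hence
    relative pairs of degree 1 through >= 5 at the default depth.
    Other children marry with probability ``marry_prob``; last-generation
    children never do.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_target = (
        None
        if config.target_individuals is None
        else max(4, round(config.target_individuals / config.n_pedigrees))
    )
    individuals: list[Individual] = []
    for p in range(config.n_pedigrees):
        fam = f"PED{p + 1}"
        if per_target is None:
            members = _make_family(fam, config, rng, None)
        else:
            # rejection-sample the branching toward the configured size
            tol = max(2, round(0.06 * per_target))
            for _ in range(50):
                members = _make_family(fam, config, rng, per_target)
                if abs(len(members) - per_target) <= tol:
                    break
        individuals.extend(members)
    return Pedigree(individuals)


def _make_family(
    fam: str, cfg: SimConfig, rng: np.random.Generator, target: Optional[int]
) -> list[Individual]:
    counter = itertools.count(1)

    def founder(sex: int) -> Individual:
        return Individual(f"{fam}_{next(counter):04d}", None, None, sex, fam)

    def child(fa: str, mo: str, sex: int) -> Individual:
        return Individual(f"{fam}_{next(counter):04d}", fa, mo, sex, fam)

    f0, m0 = founder(MALE), founder(FEMALE)
    inds = [f0, m0]
    couples: list[tuple[str, str]] = [(f0.iid, m0.iid)]
    n_child_gens = cfg.pedigree_depth - 1
    for gen in range(1, n_child_gens + 1):
        last = gen == n_child_gens
        counts = _sibship_sizes(len(couples), cfg, rng, gen, last, target, len(inds))
        new_couples: list[tuple[str, str]] = []
        for ci, (fa, mo) in enumerate(couples):
            kids = []
            for _ in range(counts[ci]):
                kid = child(fa, mo, MALE if rng.integers(2) == 0 else FEMALE)
                inds.append(kid)
                kids.append(kid)
            if last:
                continue
            # all founding-couple children marry, anchoring one lineage
            # each; below, each couple's first child continues the line
            n_forced = len(kids) if gen == 1 else 1
            for j, kid in enumerate(kids):
                if j < n_forced or rng.random() < cfg.marry_prob:
                    spouse = founder(FEMALE if kid.sex == MALE else MALE)
                    inds.append(spouse)
                    pair = (kid.iid, spouse.iid) if kid.sex == MALE else (spouse.iid, kid.iid)
                    new_couples.append(pair)
        couples = new_couples
    return inds


def _sibship_sizes(
    n_couples: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    gen: int,
    last: bool,
    target: Optional[int],
    current_total: int,
) -> list[int]:
    if last and target is not None:
        remaining = max(0, target - current_total)
        base, extra = divmod(remaining, n_couples)
        sizes = [min(8, base + (1 if i < extra else 0)) for i in range(n_couples)]
        return sizes
    sizes = [max(1, int(rng.poisson(cfg.mean_children))) for _ in range(n_couples)]
    if gen == 1:
        # wide founding sibship: several lineages radiating from the top
        # couple, so distant (cross-lineage) relative pairs are plentiful
        sizes[0] = max(cfg.founding_children_min, sizes[0])
    return sizes


# -- variant map -------------------------------------------------------


def make_variant_map(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Generate the SNP-to-gene map with positions, MAFs and function class.

    Columns: snp, chrom, pos_bp, pos_cM, gene, maf, function.  Genes are
    point loci: all SNPs of a gene share its cM midpoint; bp positions
    (1 cM ~ 1 Mb) are strictly increasing within a chromosome.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = [c for c, _ in config.chromosome_map]
    lengths = np.array([L for _, L in config.chromosome_map], dtype=float)
    gene_counts = _largest_remainder(config.n_genes, lengths / lengths.sum())

    rows = []
    gene_no = 0
    for ci, chrom in enumerate(chroms):
        n_g = gene_counts[ci]
        if n_g == 0:
            continue
        pos = np.sort(rng.uniform(0.0, lengths[ci], n_g))
        for p in pos:
            gene_no += 1
            rows.append({"gene": f"G{gene_no:04d}", "chrom": chrom, "pos_cM": float(p)})
    genes = pd.DataFrame(rows)

    extra = rng.multinomial(config.n_snps - config.n_genes, np.full(len(genes), 1.0 / len(genes)))
    snps_per_gene = extra + 1

    maf = _sample_maf(config, rng, config.n_snps)
    nonsyn = rng.random(config.n_snps) < config.nonsyn_fraction

    records = []
    s = 0
    for gi, grow in genes.iterrows():
        for _ in range(snps_per_gene[gi]):
            records.append(
                {
                    "chrom": grow["chrom"],
                    "pos_cM": grow["pos_cM"],
                    "gene": grow["gene"],
                    "maf": float(maf[s]),
                    "function": "nonsynonymous" if nonsyn[s] else "synonymous",
                }
            )
            s += 1
    vmap = pd.DataFrame(records)
    # bp positions: ~1 Mb per cM plus within-gene offsets, made strictly
    # increasing per chromosome
    vmap["pos_bp"] = (vmap["pos_cM"] * 1e6).round().astype(np.int64) + 1
    for chrom in chroms:
        m = vmap["chrom"] == chrom
        if not m.any():
            continue
        bp = vmap.loc[m, "pos_bp"].to_numpy()
        bp = np.maximum.accumulate(bp + np.arange(len(bp)))
        vmap.loc[m, "pos_bp"] = bp
    # snp ids numbered within chromosome, in position order
    ids = []
    for chrom in chroms:
        n = int((vmap["chrom"] == chrom).sum())
        ids.extend(f"C{chrom}S{i + 1}" for i in range(n))
    vmap["snp"] = ids
    return vmap[["snp", "chrom", "pos_bp", "pos_cM", "gene", "maf", "function"]]


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    raw = weights * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _sample_maf(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    a, b = cfg.maf_beta
    lo = beta_dist.cdf(cfg.maf_min, a, b)
    hi = beta_dist.cdf(0.5, a, b)
    u = rng.uniform(lo, hi, n)
    return np.clip(beta_dist.ppf(u, a, b), cfg.maf_min, 0.5)


# -- gene drop ---------------------------------------------------------


@dataclass
class FounderLabelGenome:
    """Founder-allele labels per individual per gene.

    ``labels[i, h, g]`` is the integer founder-haplotype label carried by
    individual ``ids[i]`` on haplotype ``h`` (0 = paternal) at gene ``g``.
    Founder labels are globally unique (two per founder), so equality of
    labels is exactly identity by descent.
    """

    ids: list[str]
    genes: list[str]
    gene_chrom: np.ndarray
    gene_pos: np.ndarray
    labels: np.ndarray  # (n_individuals, 2, n_genes) int32
    label_owner: dict[int, tuple[str, int]]  # label -> (founder iid, haplotype)

    def __post_init__(self):
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def labels_for(self, iid: str) -> np.ndarray:
        try:
            return self.labels[self._index[iid]]
        except KeyError:
            raise KeyError(f"unknown individual id {iid!r}") from None

    def index_of(self, iid: str) -> int:
        try:
            return self._index[iid]
        except KeyError:
            raise KeyError(f"unknown individual id {iid!r}") from None


@dataclass
class GeneDropResult:
    genome: FounderLabelGenome
    dosages: pd.DataFrame  # individuals x SNPs, minor-allele counts 0/1/2


def _gene_table(variant_map: pd.DataFrame) -> pd.DataFrame:
    genes = variant_map.drop_duplicates("gene")[["gene", "chrom", "pos_cM"]]
    return genes.reset_index(drop=True)


def gene_drop(
    pedigree: Pedigree,
    variant_map: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    chromosome_lengths: Optional[dict[str, float]] = None,
) -> GeneDropResult:
    """Drop labelled founder haplotypes down the pedigree and emit dosages.

    Each transmission draws Poisson(L/100) crossovers uniformly on the
    chromosome (Haldane), a random starting phase, and copies the
    parent's label at each gene midpoint accordingly.  Founder haplotype
    alleles are drawn per SNP from its MAF; dosage is the minor-allele
    count.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    genes = _gene_table(variant_map)
    n_genes = len(genes)
    gene_pos = genes["pos_cM"].to_numpy()
    gene_chrom = genes["chrom"].to_numpy()
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: float(max(1.0, math.ceil(gene_pos[gene_chrom == c].max())))
            for c in pd.unique(gene_chrom)
        }
    # contiguous per-chromosome slices in gene order
    slices: list[tuple[slice, float, np.ndarray]] = []
    start = 0
    for c in pd.unique(gene_chrom):
        n = int((gene_chrom == c).sum())
        sl = slice(start, start + n)
        slices.append((sl, float(chromosome_lengths[c]), gene_pos[sl]))
        start += n

    ids = list(pedigree)
    idx = {iid: i for i, iid in enumerate(ids)}
    labels = np.empty((len(ids), 2, n_genes), dtype=np.int32)
    label_owner: dict[int, tuple[str, int]] = {}
    next_label = 0
    for iid in ids:
        ind = pedigree.individual(iid)
        i = idx[iid]
        if ind.is_founder:
            for h in (0, 1):
                labels[i, h, :] = next_label
                label_owner[next_label] = (iid, h)
                next_label += 1
        else:
            labels[i, 0, :] = _transmit(labels[idx[ind.father]], slices, rng)
            labels[i, 1, :] = _transmit(labels[idx[ind.mother]], slices, rng)

    genome = FounderLabelGenome(
        ids=ids,
        genes=list(genes["gene"]),
        gene_chrom=gene_chrom,
        gene_pos=gene_pos,
        labels=labels,
        label_owner=label_owner,
    )

    # founder haplotype alleles and per-individual dosages
    maf = variant_map["maf"].to_numpy()
    n_snps = len(variant_map)
    gene_index = {g: j for j, g in enumerate(genome.genes)}
    snp_gene_idx = variant_map["gene"].map(gene_index).to_numpy()
    founder_alleles = (rng.random((next_label, n_snps)) < maf[None, :]).astype(np.int8)
    col = np.arange(n_snps)
    dos = np.empty((len(ids), n_snps), dtype=np.int8)
    for i in range(len(ids)):
        a0 = founder_alleles[labels[i, 0, snp_gene_idx], col]
        a1 = founder_alleles[labels[i, 1, snp_gene_idx], col]
        dos[i] = a0 + a1
    dosages = pd.DataFrame(dos, index=pd.Index(ids, name="id"), columns=list(variant_map["snp"]))
    return GeneDropResult(genome=genome, dosages=dosages)


def _transmit(
    parent_labels: np.ndarray,
    slices: Sequence[tuple[slice, float, np.ndarray]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombined haplotype from a parent's two label tracks."""
    out = np.empty(parent_labels.shape[1], dtype=np.int32)
    for sl, length, pos in slices:
        start = int(rng.integers(2))
        n_x = int(rng.poisson(length / 100.0))
        if n_x:
            cuts = np.sort(rng.uniform(0.0, length, n_x))
            phase = (start + np.searchsorted(cuts, pos)) % 2
            out[sl] = np.where(phase == 0, parent_labels[0, sl], parent_labels[1, sl])
        else:
            out[sl] = parent_labels[start, sl]
    return out


def true_ibd_matrix(
    genome: FounderLabelGenome,
    pairs: Sequence[tuple[str, str]],
    chunk: int = 2048,
) -> IbdMatrix:
    """Exact per-gene IBD scores from founder labels.

    Per gene, the score is half the size of the maximum matching between
    the two individuals' label pairs (0, 0.5 or 1).
    """
    i1 = np.array([genome.index_of(a) for a, _ in pairs])
    i2 = np.array([genome.index_of(b) for _, b in pairs])
    n_genes = len(genome.genes)
    sx2 = np.empty((len(pairs), n_genes), dtype=np.uint8)
    L = genome.labels
    for s in range(0, len(pairs), chunk):
        e = min(s + chunk, len(pairs))
        a0 = L[i1[s:e], 0, :]
        a1 = L[i1[s:e], 1, :]
        b0 = L[i2[s:e], 0, :]
        b1 = L[i2[s:e], 1, :]
        both = ((a0 == b0) & (a1 == b1)) | ((a0 == b1) & (a1 == b0))
        one = (a0 == b0) | (a0 == b1) | (a1 == b0) | (a1 == b1)
        sx2[s:e] = one.astype(np.uint8) + both.astype(np.uint8)
    return IbdMatrix(list(pairs), genome.genes, scores_x2=sx2)


# -- phenotypes --------------------------------------------------------


@dataclass
class ReplicateSet:
    """Replicate affection-status assignments over one fixed genotype set."""

    affection: pd.DataFrame  # bool, individuals x replicates
    threshold: float
    prevalence_target: float

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.affection.columns)

    def affected_ids(self, replicate_id: str) -> frozenset:
        col = self.affection[replicate_id]
        return frozenset(col.index[col])


def simulate_phenotypes(
    dosages: pd.DataFrame,
    variant_map: pd.DataFrame,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ReplicateSet, TruthSet]:
    """Liability-threshold phenotypes with planted causal genes.

    Causal genes are drawn from genes carrying at least one rare
    (MAF < ``causal_maf_max``) nonsynonymous variant with a carrier in
    the sample; every such variant in a causal gene gets liability
    effect ``causal_effect`` per minor allele.  The affection threshold
    is calibrated so the expected affected fraction equals
    ``prevalence_target`` given the realized genetic values; each
    replicate redraws only the standard-normal noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    carriers = dosages.sum(axis=0)
    eligible = variant_map[
        (variant_map["function"] == "nonsynonymous")
        & (variant_map["maf"] < config.causal_maf_max)
        & (variant_map["maf"] >= config.causal_maf_min)
        & (variant_map["snp"].map(carriers).fillna(0) > 0)
    ]
    per_gene = eligible.groupby("gene").size()
    eligible_genes = sorted(per_gene.index[per_gene >= config.causal_min_variants])
    eligible = eligible[eligible["gene"].isin(eligible_genes)]
    n_causal = min(config.n_causal_genes, len(eligible_genes))
    if n_causal < config.n_causal_genes:
        warnings.warn(
            f"only {n_causal} of {config.n_causal_genes} requested causal genes "
            "have an eligible variant with carriers",
            stacklevel=2,
        )
    if n_causal > 0:
        causal_genes = sorted(
            rng.choice(np.array(eligible_genes, dtype=object), size=n_causal, replace=False)
        )
    else:
        causal_genes = []
    causal = eligible[eligible["gene"].isin(causal_genes)]
    causal_snps = list(causal["snp"])

    n_ind = len(dosages)
    if causal_snps and config.causal_effect != 0.0:
        g = dosages[causal_snps].to_numpy(dtype=float).sum(axis=1) * config.causal_effect
        if not g.any():
            warnings.warn("no individual carries any causal allele; power will be nil",
                          stacklevel=2)
    else:
        g = np.zeros(n_ind)

    prev = config.prevalence_target
    f = lambda t: float(np.mean(norm.sf(t - g))) - prev  # noqa: E731
    t = brentq(f, g.min() - 8.0, g.max() + 8.0)

    cols = {}
    for r in range(config.n_replicates):
        liab = g + rng.standard_normal(n_ind)
        cols[f"rep{r + 1:03d}"] = liab > t
    affection = pd.DataFrame(cols, index=dosages.index)
    replicate_set = ReplicateSet(
        affection=affection, threshold=float(t), prevalence_target=prev
    )
    truth = TruthSet(
        causal_genes=frozenset(causal_genes),
        causal_variants=frozenset(causal_snps),
        effects=tuple((s, config.causal_effect) for s in causal_snps),
    )
    return replicate_set, truth


# -- one-shot study ----------------------------------------------------


@dataclass
class SimulatedStudy:
    """Bundle of every simulated input plus the planted truth."""

    config: SimConfig
    pedigree: Pedigree
    variant_map: pd.DataFrame
    genome: FounderLabelGenome
    dosages: pd.DataFrame
    ibd: IbdMatrix  # all within-family pairs
    replicates: ReplicateSet
    truth: TruthSet


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a full study from one seed: pedigrees, map, gene drop,
    true IBD matrix over all within-family pairs, and phenotype replicates."""
    rng = np.random.default_rng(config.seed)
    ped = make_pedigrees(config, rng)
    vmap = make_variant_map(config, rng)
    lengths = {c: L for c, L in config.chromosome_map}
    drop = gene_drop(ped, vmap, rng, chromosome_lengths=lengths)
    ibd = true_ibd_matrix(drop.genome, ped.pairs())
    replicates, truth = simulate_phenotypes(drop.dosages, vmap, config, rng)
    return SimulatedStudy(
        config=config,
        pedigree=ped,
        variant_map=vmap,
        genome=drop.genome,
        dosages=drop.dosages,
        ibd=ibd,
        replicates=replicates,
        truth=truth,
    )
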