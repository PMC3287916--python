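import numpy as np
import pandas as pd
import pytest

from ibdfilter import SimConfig, make_pedigrees, make_variant_map, simulate_study
from ibdfilter.relatedness import relationship_degree
from ibdfilter.simulate import gene_drop, simulate_phenotypes, true_ibd_matrix


class TestConfig:
    def test_depth_below_two_rejected(self):
        with pytest.raises(ValueError, match="transmissions"):
            SimConfig(pedigree_depth=1)

    def test_more_genes_than_snps_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=100, n_snps=50)

    @pytest.mark.parametrize("prev", [0.0, 1.0, -0.2])
    def test_prevalence_bounds(self, prev):
        with pytest.raises(ValueError):
            SimConfig(prevalence_target=prev)


class TestMakePedigrees:
    def test_depth_two_is_nuclear_family(self):
        cfg = SimConfig(
            seed=0,
            n_pedigrees=1,
            pedigree_depth=2,
            target_individuals=4,
            n_genes=5,
            n_snps=5,
        )
        ped = make_pedigrees(cfg)
        assert len(ped.founders) == 2
        kids = [i for i in ped if not ped.individual(i).is_founder]
        assert len(kids) >= 1
        if len(kids) >= 2:
            assert relationship_degree(ped, kids[0], kids[1]).degree == 1

    def test_default_depth_has_distant_pairs(self):
        cfg = SimConfig(seed=3, n_genes=5, n_snps=5, n_pedigrees=3, target_individuals=261)
        ped = make_pedigrees(cfg)
        for fam in ped.families:
            ids = ped.members_of(fam)
            degrees = set()
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    r = relationship_degree(ped, a, b)
                    if r.degree is not None and r.exact:
                        degrees.add(r.degree)
            assert degrees & {4, 5}, f"{fam} lacks fourth/fifth-degree pairs"
            assert {1, 2, 3} <= degrees

    def test_full_scale_total_within_ten_percent(self):
        cfg = SimConfig(seed=11, n_genes=10, n_snps=10)
        ped = make_pedigrees(cfg)
        assert abs(len(ped) - 697) <= 0.10 * 697
        assert len(ped.families) == 8

    def test_no_inbreeding(self):
        # spouses are always new founders, so no couple shares an ancestor
        cfg = SimConfig(seed=2, n_pedigrees=2, n_genes=5, n_snps=5, target_individuals=174)
        ped = make_pedigrees(cfg)
        from ibdfilter.relatedness import kinship

        for (fa, mo), _ in ped.couples():
            assert kinship(ped, fa, mo) == 0.0


class TestVariantMap:
    def test_structure_small(self):
        cfg = SimConfig(seed=1, n_genes=10, n_snps=50, n_pedigrees=1)
        vmap = make_variant_map(cfg)
        assert len(vmap) == 50
        assert vmap["gene"].nunique() == 10
        assert vmap.groupby("gene").size().min() >= 1
        assert set(vmap["function"]) <= {"synonymous", "nonsynonymous"}
        assert vmap["maf"].between(cfg.maf_min, 0.5).all()
        for _, sub in vmap.groupby("chrom"):
            assert sub["pos_bp"].is_monotonic_increasing
            assert sub["pos_bp"].is_unique

    def test_full_scale_rare_fraction(self):
        vmap = make_variant_map(SimConfig(seed=4))
        rare = (vmap["maf"] < 0.1).mean()
        assert abs(rare - 21605 / 24488) < 0.01

    def test_full_scale_nonsyn_fraction(self):
        vmap = make_variant_map(SimConfig(seed=4))
        nonsyn = (vmap["function"] == "nonsynonymous").mean()
        assert abs(nonsyn - 8994 / 24488) < 0.01

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=60, n_snps=50)


class TestGeneDrop:
    def test_label_conservation(self, cousin_pedigree):
        cfg = SimConfig(seed=0, n_genes=20, n_snps=40, n_pedigrees=1)
        vmap = make_variant_map(cfg)
        rng = np.random.default_rng(0)
        drop = gene_drop(cousin_pedigree, vmap, rng)
        genome = drop.genome
        founders = [i for i in cousin_pedigree if cousin_pedigree.individual(i).is_founder]
        founder_labels = set()
        for f in founders:
            labs = genome.labels_for(f)
            assert len(np.unique(labs[0])) == 1 and len(np.unique(labs[1])) == 1
            founder_labels.update(np.unique(labs))
        assert len(founder_labels) == 2 * len(founders)
        for iid in cousin_pedigree:
            assert set(np.unique(genome.labels_for(iid))) <= founder_labels

    def test_offspring_shares_one_label_with_each_parent(self, cousin_pedigree):
        cfg = SimConfig(seed=0, n_genes=30, n_snps=30, n_pedigrees=1)
        vmap = make_variant_map(cfg)
        drop = gene_drop(cousin_pedigree, vmap, np.random.default_rng(1))
        genome = drop.genome
        child = genome.labels_for("A1")
        for parent in ("A", "SA"):
            plab = genome.labels_for(parent)
            share = (child[:, None, :] == plab[None, :, :]).any(axis=(0, 1))
            assert share.all()

    def test_zero_length_chromosome_no_crossover(self, cousin_pedigree):
        # single chromosome of length 0: each transmitted haplotype must be
        # a whole parental haplotype
        vmap = pd.DataFrame(
            {
                "snp": [f"S{i}" for i in range(10)],
                "chrom": "1",
                "pos_bp": np.arange(1, 11),
                "pos_cM": 0.0,
                "gene": [f"G{i}" for i in range(10)],
                "maf": 0.2,
                "function": "nonsynonymous",
            }
        )
        drop = gene_drop(
            cousin_pedigree, vmap, np.random.default_rng(2), chromosome_lengths={"1": 0.0}
        )
        genome = drop.genome
        for iid in cousin_pedigree:
            ind = cousin_pedigree.individual(iid)
            if ind.is_founder:
                continue
            for h, parent in ((0, ind.father), (1, ind.mother)):
                hap = genome.labels_for(iid)[h]
                plab = genome.labels_for(parent)
                assert (hap == plab[0]).all() or (hap == plab[1]).all()

    def test_first_cousin_mean_sharing_monte_carlo(self, cousin_pedigree):
        # 10,000 unlinked loci (one gene per zero-length chromosome) behave
        # as 10,000 independent cousin pairs; closed form is (1/2)**3
        n = 10_000
        vmap = pd.DataFrame(
            {
                "snp": [f"S{i}" for i in range(n)],
                "chrom": [f"c{i}" for i in range(n)],
                "pos_bp": 1,
                "pos_cM": 0.0,
                "gene": [f"G{i}" for i in range(n)],
                "maf": 0.2,
                "function": "synonymous",
            }
        )
        lengths = {f"c{i}": 0.0 for i in range(n)}
        drop = gene_drop(
            cousin_pedigree, vmap, np.random.default_rng(3), chromosome_lengths=lengths
        )
        ibd = true_ibd_matrix(drop.genome, [("A1", "B1")])
        scores = ibd.pair_scores(("A1", "B1"))
        se = scores.std(ddof=1) / np.sqrt(n)
        assert abs(scores.mean() - 0.125) <= 3 * se

    def test_dosage_matches_labels(self, small_study):
        # dosage of a parent-offspring duo at shared label equals shared allele
        dos = small_study.dosages
        assert dos.to_numpy().min() >= 0 and dos.to_numpy().max() <= 2

    def test_unknown_pair_member_errors(self, small_study):
        with pytest.raises(KeyError):
            true_ibd_matrix(small_study.genome, [("nobody", "nobody2")])


class TestTrueIbdScores:
    def test_score_semantics_forced(self, cousin_pedigree):
        cfg = SimConfig(seed=0, n_genes=25, n_snps=25, n_pedigrees=1)
        vmap = make_variant_map(cfg)
        drop = gene_drop(cousin_pedigree, vmap, np.random.default_rng(4))
        ibd = true_ibd_matrix(
            drop.genome, [("A", "A1"), ("F", "SA"), ("A1", "B1")]
        )
        # parent-offspring: exactly one shared allele everywhere
        assert (ibd.pair_scores(("A", "A1")) == 0.5).all()
        # unrelated founders: nothing shared
        assert (ibd.pair_scores(("F", "SA")) == 0.0).all()
        # first cousins: 0 or 0.5 only, never 1
        assert set(np.unique(ibd.pair_scores(("A1", "B1")))) <= {0.0, 0.5}

    def test_score_one_only_for_sibs(self, small_study):
        ped, ibd = small_study.pedigree, small_study.ibd
        parents = {
            iid: (ind.father, ind.mother)
            for iid, ind in ped.members.items()
            if not ind.is_founder
        }
        sx2 = ibd.support_x2()
        for i, (a, b) in enumerate(ibd.pairs):
            if (sx2[i] == 2).any():
                assert parents.get(a) is not None and parents[a] == parents.get(b), (
                    f"non-sib pair {(a, b)} has an IBD score of 1"
                )


class TestPhenotypes:
    def test_null_model_prevalence(self, small_study):
        cfg = SimConfig.scaled(seed=9, n_genes=100, n_snps=400, n_causal_genes=0,
                               n_replicates=30)
        study = simulate_study(cfg)
        frac = study.replicates.affection.to_numpy().mean()
        assert abs(frac - cfg.prevalence_target) < 0.05
        assert study.truth.causal_genes == frozenset()

    def test_replicate_count_and_fixed_genotypes(self, small_study):
        assert small_study.replicates.affection.shape[1] == 6
        assert list(small_study.replicates.affection.index) == list(
            small_study.dosages.index
        )

    def test_strong_effect_raises_carrier_risk_every_replicate(self, small_study):
        dos = small_study.dosages
        cv = sorted(small_study.truth.causal_variants)
        assert cv, "scaled config should plant causal variants"
        carrier = dos[cv].sum(axis=1) > 0
        aff = small_study.replicates.affection
        for rep in aff.columns:
            a = aff[rep]
            assert a[carrier].mean() > a[~carrier].mean()

    def test_causal_variants_respect_architecture(self, small_study):
        vm = small_study.variant_map.set_index("snp")
        cfg = small_study.config
        for s in small_study.truth.causal_variants:
            assert vm.loc[s, "function"] == "nonsynonymous"
            assert cfg.causal_maf_min <= vm.loc[s, "maf"] < cfg.causal_maf_max
        assert small_study.truth.causal_genes == frozenset(
            vm.loc[s, "gene"] for s in small_study.truth.causal_variants
        )


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = SimConfig.scaled(seed=13, n_genes=80, n_snps=320, n_replicates=4)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert s1.dosages.equals(s2.dosages)
        assert s1.replicates.affection.equals(s2.replicates.affection)
        assert (s1.genome.labels == s2.genome.labels).all()
        assert s1.truth == s2.truth

    def test_different_seed_differs(self):
        a = simulate_study(SimConfig.scaled(seed=1, n_genes=80, n_snps=320, n_replicates=4))
        b = simulate_study(SimConfig.scaled(seed=2, n_genes=80, n_snps=320, n_replicates=4))
        assert not a.dosages.equals(b.dosages)
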