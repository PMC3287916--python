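import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibdfilter.ibd import (
    IbdMatrix,
    aggregate_replicates,
    gene_share_counts,
    GeneShareTable,
    max_cases_genes,
    most_cases_genes,
    ReplicateGeneList,
    select_pairs,
)
from ibdfilter.pipeline import replicate_gene_lists


def matrix_from_rows(rows):
    """rows: {pair: [scores...]}"""
    pairs = list(rows)
    genes = [f"g{j}" for j in range(len(next(iter(rows.values()))))]
    return IbdMatrix(pairs, genes, scores=np.array(list(rows.values()), dtype=float))


def share_table(counts):
    return GeneShareTable(n_cases=pd.Series(counts))


class TestIbdMatrix:
    def test_score_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="0, 0.5, 1"):
            IbdMatrix([("a", "b")], ["g0"], scores=np.array([[0.3]]))

    def test_pair_order_symmetric(self):
        m = matrix_from_rows({("b", "a"): [0.5, 0.0]})
        assert m.score(("a", "b"), "g0") == 0.5
        assert m.score(("b", "a"), "g0") == 0.5

    def test_long_round_trip(self):
        m = matrix_from_rows({("a", "b"): [0.5, 0, 1], ("a", "c"): [0, 0.5, 0]})
        back = IbdMatrix.from_long(m.to_long(), genes=list(m.genes))
        for p in m.pairs:
            assert (back.pair_scores(p) == m.pair_scores(p)).all()

    def test_realized_sharing_all_zero(self):
        m = matrix_from_rows({("a", "b"): [0, 0, 0, 0]})
        assert m.realized_sharing(("a", "b")) == 0.0


class TestSelectPairs:
    def setup_method(self):
        # realized sharing: ab=0.12 (excluded high), ac=0.05 (in band),
        # ad=0.05 (in band), ae=0.0 (below band)
        self.m = matrix_from_rows(
            {
                ("a", "b"): [0.5] * 12 + [0.0] * 38,
                ("a", "c"): [0.5] * 5 + [0.0] * 45,
                ("a", "d"): [0.5] * 5 + [0.0] * 45,
                ("a", "e"): [0.0] * 50,
            }
        )

    def test_band_and_case_status(self):
        sel = select_pairs(self.m, affected={"a", "b", "c"})
        assert set(sel.pairs) == {("a", "c")}
        assert sel.distinct_cases == ("a", "c")

    def test_pair_with_unaffected_member_excluded(self):
        sel = select_pairs(self.m, affected={"a", "b", "e"})
        assert sel.pairs == ()

    def test_sharing_above_band_excluded(self):
        sel = select_pairs(self.m, affected={"a", "b"})
        assert sel.pairs == ()

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="no case-case pairs"):
            select_pairs(self.m, affected=set())

    def test_completeness_against_brute_force(self, small_study):
        ibd = small_study.ibd
        aff = small_study.replicates.affection
        rep = aff.columns[0]
        affected = set(aff.index[aff[rep]])
        sel = select_pairs(ibd, affected)
        expected = set()
        for pair in ibd.pairs:
            a, b = pair
            if a in affected and b in affected:
                s = float(ibd.pair_scores(pair).mean())
                if 0.01 <= s <= 0.09:
                    expected.add(pair)
        assert set(sel.pairs) == expected
        for p in sel.pairs:
            assert 0.01 <= ibd.realized_sharing(p) <= 0.09


class TestGeneShareCounts:
    def test_union_of_cases_over_supporting_pairs(self):
        m = matrix_from_rows(
            {
                ("a", "b"): [0.5, 0.5, 0.0],
                ("b", "c"): [0.5, 0.0, 0.0],
                ("c", "d"): [0.0, 0.0, 0.0],
            }
        )
        sel = select_pairs(m, affected={"a", "b", "c", "d"}, lo=0.0, hi=1.0)
        tab = gene_share_counts(m, sel)
        # g0 shared by pairs (a,b) and (b,c): cases {a,b,c}
        assert tab.n_cases["g0"] == 3
        # g1 shared only by (a,b)
        assert tab.n_cases["g1"] == 2
        # all-zero gene dropped from the table
        assert "g2" not in tab.n_cases.index

    def test_case_counted_once_across_many_pairs(self):
        m = matrix_from_rows(
            {("a", "b"): [0.5], ("a", "c"): [0.5], ("a", "d"): [0.5]}
        )
        sel = select_pairs(m, affected="abcd", lo=0.0, hi=1.0)
        tab = gene_share_counts(m, sel)
        assert tab.n_cases["g0"] == 4

    def test_empty_selection_rejected(self):
        m = matrix_from_rows({("a", "b"): [0.0]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_pairs(m, affected=set())
        with pytest.raises(ValueError, match="empty"):
            gene_share_counts(m, sel)

    def test_brute_force_oracle_random_matrix(self):
        rng = np.random.default_rng(42)
        ids = [f"i{k}" for k in range(8)]
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        scores = rng.choice([0, 0.5, 1.0], size=(len(pairs), 12), p=[0.7, 0.25, 0.05])
        m = IbdMatrix(pairs, [f"g{j}" for j in range(12)], scores=scores)
        sel = select_pairs(m, affected=set(ids[:6]), lo=0.0, hi=1.0)
        tab = gene_share_counts(m, sel)
        for j, gene in enumerate(m.genes):
            supporters = set()
            for p in sel.pairs:
                if m.score(p, gene) > 0:
                    supporters.update(p)
            assert tab.n_cases.get(gene, 0) == len(supporters)


class TestMostAndMaxCases:
    def test_threshold_walk_small(self):
        tab = share_table({"A": 6, "B": 5, "C": 5, "D": 3, "E": 2})
        out = most_cases_genes(tab, gene_cap=3)
        assert out.threshold_k == 6 and out.genes == {"A"}

    def test_brute_force_over_thresholds(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            counts = {
                f"G{i}": int(c)
                for i, c in enumerate(rng.integers(2, 30, size=rng.integers(3, 40)))
            }
            tab = share_table(counts)
            cap = int(rng.integers(2, 15))
            expected = None
            for k in range(2, max(counts.values()) + 1):
                n = sum(1 for c in counts.values() if c >= k)
                if 0 < n < cap:
                    expected = (k, frozenset(g for g, c in counts.items() if c >= k))
                    break
            if expected is None:
                with pytest.raises(ValueError):
                    most_cases_genes(tab, gene_cap=cap)
            else:
                out = most_cases_genes(tab, gene_cap=cap)
                assert (out.threshold_k, out.genes) == expected

    def test_single_gene_minimum_threshold(self):
        out = most_cases_genes(share_table({"A": 2}), gene_cap=100)
        assert out.threshold_k == 2 and out.genes == {"A"}

    def test_no_valid_threshold_diagnostic(self):
        counts = {f"G{i}": 5 for i in range(150)}
        with pytest.raises(ValueError, match="n_genes by k"):
            most_cases_genes(share_table(counts), gene_cap=100)

    def test_max_cases_argmax_and_ties(self):
        assert max_cases_genes(share_table({"A": 6, "B": 5})).genes == {"A"}
        tied = max_cases_genes(share_table({"A": 6, "B": 6, "C": 2}))
        assert tied.genes == {"A", "B"} and tied.threshold_k == 6

    def test_most_cases_superset_of_max_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = {
                f"G{i}": int(c)
                for i, c in enumerate(rng.integers(2, 25, size=rng.integers(2, 60)))
            }
            tab = share_table(counts)
            mx = max_cases_genes(tab)
            try:
                mc = most_cases_genes(tab, gene_cap=100)
            except ValueError:
                continue
            assert mx.genes <= mc.genes


class TestAggregateReplicates:
    def _lists(self, membership, n_rep, mode="most_cases"):
        lists = []
        for r in range(n_rep):
            genes = frozenset(g for g, reps in membership.items() if r in reps)
            lists.append(ReplicateGeneList(f"rep{r}", mode, 2, genes))
        return lists

    def test_boundary_at_replicate_min(self):
        membership = {"hi": set(range(140)), "lo": set(range(49))}
        agg = aggregate_replicates(self._lists(membership, 200), replicate_min=50)
        assert agg.kept_genes == {"hi"}
        tbl = agg.table.set_index("gene")
        assert tbl.loc["hi", "n_replicates"] == 140
        assert tbl.loc["lo", "n_replicates"] == 49 and not tbl.loc["lo", "kept"]

    def test_default_min_is_quarter_of_replicates(self):
        agg = aggregate_replicates(self._lists({"a": {0}}, 200))
        assert agg.replicate_min == 50

    def test_single_replicate_identity(self):
        lists = [ReplicateGeneList("r1", "most_cases", 3, frozenset({"x", "y"}))]
        agg = aggregate_replicates(lists, replicate_min=1)
        assert agg.kept_genes == {"x", "y"}

    def test_min_above_total_rejected(self):
        lists = [ReplicateGeneList("r1", "most_cases", 3, frozenset({"x"}))]
        with pytest.raises(ValueError):
            aggregate_replicates(lists, replicate_min=2)


class TestTableShapeInvariants:
    def test_n_genes_monotone_in_k(self, small_study):
        aff = small_study.replicates.affection
        for rep in aff.columns[:3]:
            affected = set(aff.index[aff[rep]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = select_pairs(small_study.ibd, affected)
            if not sel.pairs:
                continue
            tab = gene_share_counts(small_study.ibd, sel)
            counts = [tab.n_genes(k) for k in range(2, tab.max_count + 2)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))
            table = tab.threshold_table(small_study.variant_map)
            for col in ("total_snps", "rare_snps", "synonymous", "nonsynonymous"):
                assert table[col].is_monotonic_decreasing

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_most_cases_genes_all_meet_threshold(self, seed):
        rng = np.random.default_rng(seed)
        counts = {
            f"G{i}": int(c)
            for i, c in enumerate(rng.integers(2, 40, size=rng.integers(2, 50)))
        }
        tab = share_table(counts)
        try:
            out = most_cases_genes(tab, gene_cap=20)
        except ValueError:
            return
        assert all(counts[g] >= out.threshold_k for g in out.genes)
        assert 0 < len(out.genes) < 20


class TestPlantedSignalTracking:
    def test_clique_shared_gene_dominates_background_counts(self):
        """When one gene is shared IBD by a clique of cases while every
        other gene carries only sparse background sharing, the filtering
        chain (pair selection -> case counting -> most-cases -> replicate
        aggregation) must rank the planted gene first and keep it."""
        from collections import Counter

        rng = np.random.default_rng(77)
        ids = [f"i{k:02d}" for k in range(24)]
        clique = set(ids[:14])
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        n_genes = 60
        genes = [f"g{j:02d}" for j in range(n_genes)]
        # sparse background sharing; planted gene g00 is shared by every
        # within-clique pair
        sx2 = (rng.random((len(pairs), n_genes)) < 0.01).astype(np.uint8)
        for idx, (a, b) in enumerate(pairs):
            sx2[idx, 0] = 1 if (a in clique and b in clique) else 0
        m = IbdMatrix(pairs, genes, scores_x2=sx2)
        lists = []
        for rep in range(6):
            affected = set(rng.choice(ids, size=18, replace=False)) | clique
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = select_pairs(m, affected, lo=0.0, hi=1.0, replicate_id=f"r{rep}")
            tab = gene_share_counts(m, sel)
            assert tab.n_cases.idxmax() == "g00"
            lists.append(most_cases_genes(tab, gene_cap=10))
        agg = aggregate_replicates(lists, replicate_min=len(lists))
        assert "g00" in agg.kept_genes
        counts = Counter()
        for rl in lists:
            counts.update(rl.genes)
        assert counts["g00"] == len(lists)
        assert counts["g00"] >= max(counts.values())
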