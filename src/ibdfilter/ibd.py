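"""Per-gene IBD score matrices and the case-pair / gene-sharing filter.

The central object is the (pair x gene) matrix of IBD scores in
{0, 0.5, 1}: 0.5 means the pair shares one allele identical by descent
at that gene, 1 means both (only full siblings or twins in outbred
pedigrees).  The filtering strategy:

1. select affected-affected pairs whose genome-wide sharing (mean
   per-gene score) lies in a distant-relative band, default [0.01, 0.09];
2. score every gene by the number of *distinct* selected cases that
   appear in at least one selected pair sharing the gene IBD;
3. keep genes by "most cases" (smallest case-count threshold k >= 2 at
   which fewer than ``gene_cap`` genes qualify) or "max cases" (argmax
   gene set only);
4. aggregate the per-replicate gene lists across phenotype replicates
   and keep genes selected in at least ``replicate_min`` replicates.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

VALID_SCORES = (0.0, 0.5, 1.0)


def canonical_pair(pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


class IbdMatrix:
    """Dense (pair x gene) IBD score matrix.

    Scores are stored internally as doubled uint8 values {0, 1, 2} to
    keep full-scale matrices (~30k pairs x ~3.2k genes) small; the
    public API speaks in {0, 0.5, 1}.
    """

    def __init__(
        self,
        pairs: Sequence[tuple[str, str]],
        genes: Sequence[str],
        scores: Optional[np.ndarray] = None,
        scores_x2: Optional[np.ndarray] = None,
    ):
        self._pairs = [canonical_pair(p) for p in pairs]
        if len(set(self._pairs)) != len(self._pairs):
            raise ValueError("duplicate pairs in IBD matrix")
        self._index = {p: i for i, p in enumerate(self._pairs)}
        self._genes = np.asarray(list(genes), dtype=object)
        self._gene_index = {g: j for j, g in enumerate(self._genes)}
        if (scores is None) == (scores_x2 is None):
            raise ValueError("provide exactly one of scores / scores_x2")
        if scores is not None:
            arr = np.asarray(scores, dtype=float)
            if not np.isin(arr, VALID_SCORES).all():
                raise ValueError("IBD scores must be in {0, 0.5, 1}")
            sx2 = (arr * 2).astype(np.uint8)
        else:
            sx2 = np.asarray(scores_x2, dtype=np.uint8)
            if not np.isin(sx2, (0, 1, 2)).all():
                raise ValueError("doubled IBD scores must be in {0, 1, 2}")
        if sx2.shape != (len(self._pairs), len(self._genes)):
            raise ValueError(
                f"score shape {sx2.shape} does not match "
                f"({len(self._pairs)} pairs, {len(self._genes)} genes)"
            )
        self._sx2 = sx2

    # -- access ---------------------------------------------------------

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self._pairs)

    @property
    def genes(self) -> np.ndarray:
        return self._genes

    def __contains__(self, pair: Sequence[str]) -> bool:
        return canonical_pair(pair) in self._index

    def pair_index(self, pair: Sequence[str]) -> int:
        key = canonical_pair(pair)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"pair {key!r} not in IBD matrix") from None

    def pair_scores(self, pair: Sequence[str]) -> np.ndarray:
        return self._sx2[self.pair_index(pair)] / 2.0

    def score(self, pair: Sequence[str], gene: str) -> float:
        return float(self._sx2[self.pair_index(pair), self._gene_index[gene]]) / 2.0

    def realized_sharing(self, pair: Sequence[str]) -> float:
        """Genome fraction shared: unweighted mean of per-gene scores."""
        return float(self._sx2[self.pair_index(pair)].mean()) / 2.0

    def realized_sharing_all(self) -> np.ndarray:
        return self._sx2.mean(axis=1) / 2.0

    def support_x2(self) -> np.ndarray:
        """Internal doubled-score array (read-only view)."""
        v = self._sx2.view()
        v.flags.writeable = False
        return v

    def to_long(self) -> pd.DataFrame:
        """Long-format frame (id1, id2, gene, score), nonzero scores only."""
        rows_i, cols_j = np.nonzero(self._sx2)
        return pd.DataFrame(
            {
                "id1": [self._pairs[i][0] for i in rows_i],
                "id2": [self._pairs[i][1] for i in rows_i],
                "gene": self._genes[cols_j],
                "score": self._sx2[rows_i, cols_j] / 2.0,
            }
        )

    @classmethod
    def from_long(
        cls, frame: pd.DataFrame, genes: Optional[Sequence[str]] = None
    ) -> "IbdMatrix":
        """Build from long-format (id1, id2, gene, score); missing cells are 0."""
        pairs = sorted({canonical_pair((a, b)) for a, b in zip(frame["id1"], frame["id2"])})
        if genes is None:
            genes = sorted(frame["gene"].unique())
        pidx = {p: i for i, p in enumerate(pairs)}
        gidx = {g: j for j, g in enumerate(genes)}
        sx2 = np.zeros((len(pairs), len(genes)), dtype=np.uint8)
        for a, b, g, s in zip(frame["id1"], frame["id2"], frame["gene"], frame["score"]):
            if float(s) not in VALID_SCORES:
                raise ValueError(f"IBD score {s!r} not in {{0, 0.5, 1}}")
            sx2[pidx[canonical_pair((a, b))], gidx[g]] = int(round(float(s) * 2))
        return cls(pairs, list(genes), scores_x2=sx2)


@dataclass(frozen=True)
class PairSelection:
    """Case-case pairs in the distant-relative sharing band for one replicate."""

    replicate_id: Optional[str]
    pairs: tuple[tuple[str, str], ...]
    distinct_cases: tuple[str, ...]
    lo: float
    hi: float

    def __len__(self) -> int:
        return len(self.pairs)


def select_pairs(
    ibd: IbdMatrix,
    affected: Iterable[str],
    lo: float = 0.01,
    hi: float = 0.09,
    replicate_id: Optional[str] = None,
) -> PairSelection:
    """All affected-affected pairs with genome sharing in [lo, hi].

    Pairs sharing more than ``hi`` (e.g. close relatives) are excluded,
    as are pairs with any unaffected member.
    """
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError(f"invalid sharing bounds [{lo}, {hi}]")
    aff = set(affected)
    sharing = ibd.realized_sharing_all()
    selected: list[tuple[str, str]] = []
    for i, (a, b) in enumerate(ibd.pairs):
        if a in aff and b in aff and lo <= sharing[i] <= hi:
            selected.append((a, b))
    if not selected:
        warnings.warn(
            f"no case-case pairs with sharing in [{lo}, {hi}]"
            + (f" (replicate {replicate_id})" if replicate_id else ""),
            stacklevel=2,
        )
    cases = tuple(sorted({iid for p in selected for iid in p}))
    return PairSelection(
        replicate_id=replicate_id,
        pairs=tuple(selected),
        distinct_cases=cases,
        lo=lo,
        hi=hi,
    )


@dataclass
class GeneShareTable:
    """Per-gene count of distinct selected cases supporting the gene.

    A case supports a gene when it belongs to at least one selected pair
    whose IBD score at that gene is > 0; each case counts once however
    many supporting pairs it is in.
    """

    n_cases: pd.Series  # index: gene, values: int
    replicate_id: Optional[str] = None

    def n_genes(self, k: int) -> int:
        """Number of genes shared by at least ``k`` cases."""
        return int((self.n_cases >= k).sum())

    @property
    def max_count(self) -> int:
        return int(self.n_cases.max()) if len(self.n_cases) else 0

    def genes_at(self, k: int) -> frozenset:
        return frozenset(self.n_cases.index[self.n_cases >= k])

    def threshold_table(self, variant_map: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        """Per-threshold summary: for k = 2..max, the number of qualifying
        genes and (with a variant map) their SNP totals by rarity and
        function class."""
        rows = []
        for k in range(2, self.max_count + 1):
            genes = self.genes_at(k)
            row = {"k": k, "genes_shared": len(genes)}
            if variant_map is not None:
                sub = variant_map[variant_map["gene"].isin(genes)]
                row["total_snps"] = len(sub)
                row["rare_snps"] = int((sub["maf"] < 0.1).sum())
                row["synonymous"] = int((sub["function"] == "synonymous").sum())
                row["nonsynonymous"] = int((sub["function"] == "nonsynonymous").sum())
            rows.append(row)
        return pd.DataFrame(rows)


def gene_share_counts(ibd: IbdMatrix, selection: PairSelection) -> GeneShareTable:
    """Count, per gene, the distinct selected cases supporting it."""
    if not selection.pairs:
        raise ValueError("empty pair selection")
    sel_idx = [ibd.pair_index(p) for p in selection.pairs]
    shared = ibd.support_x2()[sel_idx] > 0  # (n_pairs, n_genes)
    cases = selection.distinct_cases
    member = np.zeros((len(cases), len(sel_idx)), dtype=bool)
    where = {c: i for i, c in enumerate(cases)}
    for j, (a, b) in enumerate(selection.pairs):
        member[where[a], j] = True
        member[where[b], j] = True
    supports = member.astype(np.int32) @ shared.astype(np.int32) > 0
    counts = supports.sum(axis=0).astype(int)
    series = pd.Series(counts, index=pd.Index(ibd.genes, name="gene"))
    series = series[series > 0]
    return GeneShareTable(n_cases=series, replicate_id=selection.replicate_id)


@dataclass(frozen=True)
class ReplicateGeneList:
    """Genes selected in one replicate under one scoring mode."""

    replicate_id: Optional[str]
    mode: str  # "most_cases" | "max_cases"
    threshold_k: Optional[int]
    genes: frozenset


def most_cases_genes(
    table: GeneShareTable, gene_cap: int = 100, replicate_id: Optional[str] = None
) -> ReplicateGeneList:
    """Select genes shared by "most cases": walk the case-count threshold
    k upward from 2 and stop at the first k where fewer than ``gene_cap``
    (but more than zero) genes qualify; all qualifying genes are kept,
    ties included."""
    if gene_cap < 1:
        raise ValueError("gene_cap must be >= 1")
    if table.max_count < 2:
        raise ValueError("no gene is shared by at least 2 cases")
    for k in range(2, table.max_count + 1):
        n = table.n_genes(k)
        if 0 < n < gene_cap:
            return ReplicateGeneList(
                replicate_id=replicate_id or table.replicate_id,
                mode="most_cases",
                threshold_k=k,
                genes=table.genes_at(k),
            )
    counts = {k: table.n_genes(k) for k in range(2, table.max_count + 1)}
    raise ValueError(
        f"no case-count threshold k yields 0 < n_genes(k) < {gene_cap}; "
        f"n_genes by k: {counts}"
    )


def max_cases_genes(
    table: GeneShareTable, replicate_id: Optional[str] = None
) -> ReplicateGeneList:
    """Select only the gene(s) shared by the maximum number of cases."""
    if table.max_count < 1:
        raise ValueError("empty gene-share table")
    k = table.max_count
    return ReplicateGeneList(
        replicate_id=replicate_id or table.replicate_id,
        mode="max_cases",
        threshold_k=k,
        genes=table.genes_at(k),
    )


@dataclass
class AggregatedGeneRanking:
    """Per-gene count of replicates in which it was selected."""

    table: pd.DataFrame  # columns: gene, n_replicates, kept
    replicate_min: int
    n_replicates_total: int

    @property
    def kept_genes(self) -> frozenset:
        return frozenset(self.table.loc[self.table["kept"], "gene"])

    @property
    def seen_genes(self) -> frozenset:
        return frozenset(self.table["gene"])


def aggregate_replicates(
    lists: Sequence[ReplicateGeneList], replicate_min: Optional[int] = None
) -> AggregatedGeneRanking:
    """Rank genes by the number of replicates in which they were selected;
    keep those at or above ``replicate_min`` (default: a quarter of the
    replicates, rounded up — the 50-of-200 rule)."""
    if not lists:
        raise ValueError("need at least one replicate gene list")
    n_rep = len(lists)
    if replicate_min is None:
        replicate_min = math.ceil(0.25 * n_rep)
    if replicate_min > n_rep:
        raise ValueError(
            f"replicate_min={replicate_min} exceeds number of replicates {n_rep}"
        )
    counter: Counter = Counter()
    for rl in lists:
        counter.update(rl.genes)
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(rows, columns=["gene", "n_replicates"])
    table["kept"] = table["n_replicates"] >= replicate_min
    return AggregatedGeneRanking(
        table=table, replicate_min=replicate_min, n_replicates_total=n_rep
    )
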