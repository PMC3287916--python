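"""Scoring the pipeline against planted truth.

With simulated data the causal genes and variants are known, so each
strategy setting (gene-scoring mode x minimum informative pedigrees) can
be scored by its true-positive fraction TP% = 100 * n_true / n_selected,
reported at both the variant and the gene level.  The funnel report
summarises how each stage narrows the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import variants as _variants
from .ibd import AggregatedGeneRanking, ReplicateGeneList


@dataclass(frozen=True)
class TruthSet:
    """Planted causal genes/variants and their liability-scale effects."""

    causal_genes: frozenset
    causal_variants: frozenset
    effects: tuple[tuple[str, float], ...]  # (variant, effect per minor allele)

    def __post_init__(self):
        genes_of = {g for g in self.causal_genes}
        if not self.causal_genes >= frozenset() or len(genes_of) != len(self.causal_genes):
            raise ValueError("invalid causal gene set")


def funnel_report(
    variant_map: pd.DataFrame,
    replicate_lists: Sequence[ReplicateGeneList],
    aggregated: AggregatedGeneRanking,
    fbat_table: Optional[pd.DataFrame] = None,
    maf_threshold: float = 0.10,
) -> pd.Series:
    """Stage-by-stage candidate counts (the IBD/FBAT summary funnel)."""
    kept = aggregated.kept_genes
    stages = _variants.candidate_variants(variant_map, kept, maf_threshold)
    seen = set()
    for rl in replicate_lists:
        seen.update(rl.genes)
    counts = {
        "total_genes": int(variant_map["gene"].nunique()),
        "genes_in_ge1_replicate": len(seen),
        "genes_kept": len(kept),
        "snps_in_kept_genes": len(stages["in_genes"]),
        "snps_after_maf": len(stages["after_maf"]),
        "snps_after_function": len(stages["after_function"]),
    }
    if fbat_table is not None:
        counts["variants_flagged"] = int(fbat_table["flagged"].sum())
    return pd.Series(counts, name="count")


def candidate_table(
    fbat_table: pd.DataFrame,
    aggregated: AggregatedGeneRanking,
    variant_map: pd.DataFrame,
) -> pd.DataFrame:
    """Per flagged variant: gene, IBD replicate count, MAF, position,
    function, and minimum FBAT p across replicates; sorted by gene then
    position.  Empty (but well-formed) when nothing was flagged."""
    cols = [
        "gene",
        "n_replicates",
        "snp",
        "maf",
        "chrom",
        "pos_bp",
        "function",
        "min_p",
    ]
    flagged = fbat_table[fbat_table["flagged"]]
    if flagged.empty:
        return pd.DataFrame(columns=cols)
    vm = variant_map.set_index("snp")
    agg = aggregated.table.set_index("gene")["n_replicates"]
    rows = []
    for snp, rec in flagged.iterrows():
        info = vm.loc[snp]
        rows.append(
            {
                "gene": info["gene"],
                "n_replicates": int(agg.get(info["gene"], 0)),
                "snp": snp,
                "maf": float(info["maf"]),
                "chrom": info["chrom"],
                "pos_bp": int(info["pos_bp"]),
                "function": info["function"],
                "min_p": float(rec["min_p"]),
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["gene", "pos_bp"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SensitivityCell:
    """One grid cell: TP count / selected count at one strategy setting."""

    ibd_mode: str
    min_pedigrees: int
    level: str  # "variant" | "gene"
    n_true_positive: int
    n_selected: int

    @property
    def tp_percent(self) -> Optional[float]:
        if self.n_selected == 0:
            return None
        return 100.0 * self.n_true_positive / self.n_selected

    def formatted(self) -> str:
        if self.n_selected == 0:
            return "—"  # undefined, not 0%
        return f"{self.n_true_positive}/{self.n_selected} ({self.tp_percent:.1f})"


def sensitivity_grid(
    candidates: Mapping[tuple[str, int], Mapping[str, frozenset]],
    truth: TruthSet,
) -> pd.DataFrame:
    """TP% grid over strategy settings.

    ``candidates`` maps (ibd_mode, min_pedigrees) to the selected
    candidate sets ``{"variants": ..., "genes": ...}`` from a full
    pipeline run at that setting.  Both variant-level and gene-level TP
    definitions are reported.
    """
    rows = []
    for (mode, min_ped), sets in sorted(candidates.items()):
        cells = {}
        for level, key, truth_set in (
            ("variant", "variants", truth.causal_variants),
            ("gene", "genes", truth.causal_genes),
        ):
            sel = frozenset(sets[key])
            cell = SensitivityCell(
                ibd_mode=mode,
                min_pedigrees=min_ped,
                level=level,
                n_true_positive=len(sel & truth_set),
                n_selected=len(sel),
            )
            cells[level] = cell
        rows.append(
            {
                "ibd_mode": mode,
                "min_pedigrees": min_ped,
                "n_selected_variants": cells["variant"].n_selected,
                "n_tp_variants": cells["variant"].n_true_positive,
                "tp_pct_variants": cells["variant"].tp_percent,
                "cell_variants": cells["variant"].formatted(),
                "n_selected_genes": cells["gene"].n_selected,
                "n_tp_genes": cells["gene"].n_true_positive,
                "tp_pct_genes": cells["gene"].tp_percent,
                "cell_genes": cells["gene"].formatted(),
            }
        )
    return pd.DataFrame(rows)
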