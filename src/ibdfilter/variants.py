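"""Variant-level filters applied within IBD-selected genes.

Candidate variants inside the kept genes are reduced by population minor
allele frequency (default: keep MAF < 0.10, strict) and by predicted
functional class (keep nonsynonymous only).  The MAF used is the
variant map's population frequency, the synthetic analog of a reference
panel frequency, not the in-sample frequency.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

FUNCTION_CLASSES = frozenset({"synonymous", "nonsynonymous"})


def _subset(variant_map: pd.DataFrame, snps: Optional[Iterable[str]]) -> pd.DataFrame:
    if snps is None:
        return variant_map
    snps = list(snps)
    known = set(variant_map["snp"])
    missing = [s for s in snps if s not in known]
    if missing:
        raise KeyError(f"SNPs not in variant map: {missing[:5]}")
    return variant_map[variant_map["snp"].isin(set(snps))]


def filter_by_maf(
    variant_map: pd.DataFrame,
    snps: Optional[Iterable[str]] = None,
    threshold: float = 0.10,
) -> list[str]:
    """Keep SNPs with MAF strictly below ``threshold`` (MAF < 0.1 by default)."""
    sub = _subset(variant_map, snps)
    return list(sub.loc[sub["maf"] < threshold, "snp"])


def filter_by_function(
    variant_map: pd.DataFrame, snps: Optional[Iterable[str]] = None
) -> list[str]:
    """Keep nonsynonymous SNPs; unknown function labels are an error."""
    sub = _subset(variant_map, snps)
    bad = set(sub["function"]) - FUNCTION_CLASSES
    if bad:
        raise ValueError(f"unknown function class(es): {sorted(bad)}")
    return list(sub.loc[sub["function"] == "nonsynonymous", "snp"])


def restrict_to_genes(variant_map: pd.DataFrame, genes: Iterable[str]) -> list[str]:
    """All SNPs whose gene is in ``genes`` (map order preserved)."""
    return list(variant_map.loc[variant_map["gene"].isin(set(genes)), "snp"])


def candidate_variants(
    variant_map: pd.DataFrame,
    genes: Iterable[str],
    maf_threshold: float = 0.10,
) -> dict[str, list[str]]:
    """Apply the full funnel within ``genes``: restriction, then MAF, then
    function.  Returns each stage's SNP list under keys ``in_genes``,
    ``after_maf``, ``after_function``."""
    in_genes = restrict_to_genes(variant_map, genes)
    after_maf = filter_by_maf(variant_map, in_genes, threshold=maf_threshold)
    after_function = filter_by_function(variant_map, after_maf)
    return {
        "in_genes": in_genes,
        "after_maf": after_maf,
        "after_function": after_function,
    }
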