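"""End-to-end orchestration: simulate -> IBD filter -> variant filter ->
association screen -> evaluation.

:func:`run_strategy` executes the post-simulation pipeline at one
setting (gene-scoring mode, minimum informative pedigrees);
:func:`run_pipeline` drives a whole run from a :class:`RunConfig`,
optionally writing every stage's tables.  Identical config + seed
reproduces outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import evaluation, fbat, io, variants
from .ibd import (
    AggregatedGeneRanking,
    IbdMatrix,
    ReplicateGeneList,
    aggregate_replicates,
    gene_share_counts,
    max_cases_genes,
    most_cases_genes,
    select_pairs,
)
from .pedigree import Pedigree
from .simulate import SimConfig, SimulatedStudy, simulate_study


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run.

    ``min_pedigrees``/``replicate_min`` default to the canonical
    fractions (3-of-8 pedigrees, a quarter of the replicates) scaled to
    the simulated study size.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    lo: float = 0.01
    hi: float = 0.09
    gene_cap: int = 100
    replicate_min: Optional[int] = None
    maf_threshold: float = 0.10
    min_pedigrees: Optional[int] = None
    alpha: float = 0.05
    empirical_variance: bool = True
    mode: str = "most_cases"

    def resolved_min_pedigrees(self) -> int:
        if self.min_pedigrees is not None:
            return self.min_pedigrees
        return max(1, math.ceil(3 / 8 * self.sim.n_pedigrees))

    def resolved_replicate_min(self) -> int:
        if self.replicate_min is not None:
            return self.replicate_min
        return math.ceil(0.25 * self.sim.n_replicates)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["sim"]["chromosome_map"] = [
            list(pair) for pair in payload["sim"]["chromosome_map"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sim = payload.pop("sim", {})
        if "chromosome_map" in sim:
            sim["chromosome_map"] = tuple(
                (str(c), float(L)) for c, L in sim["chromosome_map"]
            )
        if "maf_beta" in sim:
            sim["maf_beta"] = tuple(sim["maf_beta"])
        return cls(sim=SimConfig(**sim), **payload)


def replicate_gene_lists(
    ibd: IbdMatrix,
    affection: pd.DataFrame,
    mode: str = "most_cases",
    lo: float = 0.01,
    hi: float = 0.09,
    gene_cap: int = 100,
) -> list[ReplicateGeneList]:
    """Run pair selection + gene scoring in every replicate.

    Replicates where no pair or no qualifying threshold exists yield an
    empty gene list (with a warning) rather than aborting the run.
    """
    if mode not in ("most_cases", "max_cases"):
        raise ValueError(f"unknown mode {mode!r}")
    lists: list[ReplicateGeneList] = []
    for rep in affection.columns:
        affected = set(affection.index[affection[rep]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selection = select_pairs(ibd, affected, lo=lo, hi=hi, replicate_id=rep)
        if not selection.pairs:
            lists.append(ReplicateGeneList(rep, mode, None, frozenset()))
            continue
        table = gene_share_counts(ibd, selection)
        try:
            if mode == "most_cases":
                lists.append(most_cases_genes(table, gene_cap=gene_cap))
            else:
                lists.append(max_cases_genes(table))
        except ValueError as exc:
            warnings.warn(f"replicate {rep}: {exc}", stacklevel=2)
            lists.append(ReplicateGeneList(rep, mode, None, frozenset()))
    return lists


@dataclass
class StrategyResult:
    """Everything one (mode, min_pedigrees) setting produces."""

    mode: str
    min_pedigrees: int
    lists: list[ReplicateGeneList]
    aggregated: AggregatedGeneRanking
    snp_stages: dict[str, list[str]]
    fbat_table: pd.DataFrame

    @property
    def flagged_variants(self) -> frozenset:
        """Variants reaching p < alpha in at least one replicate."""
        t = self.fbat_table
        return frozenset(t.index[t["flagged"]])

    @property
    def tested_variants(self) -> frozenset:
        """Variants the association screen could test at all, i.e.
        informative in enough pedigrees in at least one replicate — the
        candidate set whose true-positive fraction the sensitivity grid
        scores."""
        t = self.fbat_table
        return frozenset(t.index[t["n_replicates_tested"] > 0])

    def flagged_genes(self, variant_map: pd.DataFrame) -> frozenset:
        vm = variant_map.set_index("snp")["gene"]
        return frozenset(vm[v] for v in self.flagged_variants)

    def tested_genes(self, variant_map: pd.DataFrame) -> frozenset:
        vm = variant_map.set_index("snp")["gene"]
        return frozenset(vm[v] for v in self.tested_variants)


def run_strategy(
    pedigree: Pedigree,
    ibd: IbdMatrix,
    affection: pd.DataFrame,
    variant_map: pd.DataFrame,
    dosages: pd.DataFrame,
    mode: str = "most_cases",
    min_pedigrees: int = 3,
    lo: float = 0.01,
    hi: float = 0.09,
    gene_cap: int = 100,
    replicate_min: Optional[int] = None,
    maf_threshold: float = 0.10,
    alpha: float = 0.05,
    empirical_variance: bool = True,
) -> StrategyResult:
    """IBD filter + variant filter + association screen at one setting."""
    lists = replicate_gene_lists(ibd, affection, mode, lo, hi, gene_cap)
    aggregated = aggregate_replicates(lists, replicate_min=replicate_min)
    snp_stages = variants.candidate_variants(
        variant_map, aggregated.kept_genes, maf_threshold
    )
    fbat_table = fbat.run_fbat_screen(
        pedigree,
        dosages,
        affection,
        snp_stages["after_function"],
        min_pedigrees=min_pedigrees,
        alpha=alpha,
        empirical_variance=empirical_variance,
    )
    return StrategyResult(
        mode=mode,
        min_pedigrees=min_pedigrees,
        lists=lists,
        aggregated=aggregated,
        snp_stages=snp_stages,
        fbat_table=fbat_table,
    )


@dataclass
class PipelineResult:
    config: RunConfig
    study: SimulatedStudy
    strategy: StrategyResult
    funnel: pd.Series
    candidates: pd.DataFrame
    relationship_table: pd.DataFrame


def run_pipeline(config: RunConfig, out_dir: Optional[str | Path] = None) -> PipelineResult:
    """Full run from one config: simulate, filter, test, evaluate, report."""
    from .relatedness import relationship_table  # local import to avoid cycle cost

    study = simulate_study(config.sim)
    strategy = run_strategy(
        study.pedigree,
        study.ibd,
        study.replicates.affection,
        study.variant_map,
        study.dosages,
        mode=config.mode,
        min_pedigrees=config.resolved_min_pedigrees(),
        lo=config.lo,
        hi=config.hi,
        gene_cap=config.gene_cap,
        replicate_min=config.resolved_replicate_min(),
        maf_threshold=config.maf_threshold,
        alpha=config.alpha,
        empirical_variance=config.empirical_variance,
    )
    funnel = evaluation.funnel_report(
        study.variant_map,
        strategy.lists,
        strategy.aggregated,
        strategy.fbat_table,
        maf_threshold=config.maf_threshold,
    )
    candidates = evaluation.candidate_table(
        strategy.fbat_table, strategy.aggregated, study.variant_map
    )
    rel = relationship_table(study.pedigree, study.ibd)
    result = PipelineResult(
        config=config,
        study=study,
        strategy=strategy,
        funnel=funnel,
        candidates=candidates,
        relationship_table=rel,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": result.config.sim.seed, "config": io.config_hash(result.config)}
    io.write_ped(
        result.study.pedigree,
        out_dir / "pedigree.ped",
        header=[f"{k}={v}" for k, v in sorted(meta.items())],
    )
    io.write_variant_map(result.study.variant_map, out_dir / "variant_map.tsv", meta)
    io.write_dosages(result.study.dosages, out_dir / "dosages.tsv", meta)
    io.write_phenotypes(result.study.replicates, out_dir / "phenotypes", meta)
    io.write_ibd_matrix(result.study.ibd, out_dir / "ibd_matrix.tsv", meta)
    io.write_tsv(result.relationship_table, out_dir / "relationships.tsv", meta)
    lists_frame = pd.DataFrame(
        [
            {
                "replicate": rl.replicate_id,
                "mode": rl.mode,
                "k": rl.threshold_k,
                "gene": gene,
            }
            for rl in result.strategy.lists
            for gene in sorted(rl.genes)
        ]
    )
    io.write_tsv(lists_frame, out_dir / "replicate_gene_lists.tsv", meta)
    io.write_tsv(result.strategy.aggregated.table, out_dir / "gene_ranking.tsv", meta)
    io.write_tsv(
        result.strategy.fbat_table.reset_index(), out_dir / "fbat_results.tsv", meta
    )
    io.write_tsv(
        result.funnel.rename_axis("stage").reset_index(), out_dir / "funnel.tsv", meta
    )
    io.write_tsv(result.candidates, out_dir / "candidates.tsv", meta)


def sensitivity_runs(
    study: SimulatedStudy,
    modes: Sequence[str] = ("most_cases", "max_cases"),
    min_pedigrees_grid: Sequence[int] = (3, 5, 8),
    **strategy_kwargs,
) -> pd.DataFrame:
    """Run the strategy over a (mode x min_pedigrees) grid and score each
    cell against the planted truth (variant- and gene-level TP%).

    Each cell's candidate set is the variants the association screen
    tested at that informativeness threshold (not only those reaching
    p < alpha), so sensitivity reflects the funnel the screen defines.
    """
    candidates = {}
    for mode in modes:
        for mp in min_pedigrees_grid:
            res = run_strategy(
                study.pedigree,
                study.ibd,
                study.replicates.affection,
                study.variant_map,
                study.dosages,
                mode=mode,
                min_pedigrees=mp,
                **strategy_kwargs,
            )
            candidates[(mode, mp)] = {
                "variants": res.tested_variants,
                "genes": res.tested_genes(study.variant_map),
            }
    return evaluation.sensitivity_grid(candidates, study.truth)
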