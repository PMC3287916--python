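"""Run the IBD filtering stage: select distant case-case pairs in every
phenotype replicate, score genes by case sharing under both rules
("most cases" and "max cases"), and aggregate across replicates."""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, GENE_CAP, TABLES

from ibdfilter import io
from ibdfilter.ibd import aggregate_replicates, gene_share_counts, select_pairs
from ibdfilter.pipeline import replicate_gene_lists


def main():
    ibd = io.read_ibd_matrix(DATA / "ibd_matrix.tsv")
    affection = io.read_phenotypes(DATA / "phenotypes")
    vmap = io.read_variant_map(DATA / "variant_map.tsv")

    rep1 = affection.columns[0]
    affected = set(affection.index[affection[rep1]])
    sel = select_pairs(ibd, affected, replicate_id=rep1)
    table = gene_share_counts(ibd, sel)
    thr = table.threshold_table(vmap)
    io.write_tsv(thr, TABLES / "replicate1_threshold_table.tsv")
    print(f"replicate 1: {len(affected)} cases, {len(sel)} case-case pairs "
          f"in the 1-9% band covering {len(sel.distinct_cases)} individuals")
    print(f"genes shared by >=2 cases: {table.n_genes(2)}; "
          f"maximum case count: {table.max_count}")

    for mode in ("most_cases", "max_cases"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lists = replicate_gene_lists(ibd, affection, mode=mode,
                                         gene_cap=GENE_CAP)
        agg = aggregate_replicates(lists)
        io.write_tsv(agg.table, TABLES / f"gene_ranking_{mode}.tsv")
        frame = pd.DataFrame(
            [
                {"replicate": rl.replicate_id, "mode": rl.mode,
                 "k": rl.threshold_k, "gene": g}
                for rl in lists
                for g in sorted(rl.genes)
            ]
        )
        io.write_tsv(frame, DATA / f"replicate_gene_lists_{mode}.tsv")
        print(f"{mode}: {len(agg.seen_genes)} genes selected in >=1 replicate; "
              f"{len(agg.kept_genes)} kept in >={agg.replicate_min} of "
              f"{agg.n_replicates_total} replicates")


if __name__ == "__main__":
    main()
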