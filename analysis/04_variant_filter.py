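"""Reduce the variants inside the IBD-kept genes by population frequency
(MAF < 0.1) and predicted function (nonsynonymous only)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, TABLES

from ibdfilter import io
from ibdfilter.variants import candidate_variants


def main():
    vmap = io.read_variant_map(DATA / "variant_map.tsv")
    ranking = io.read_tsv(TABLES / "gene_ranking_most_cases.tsv")
    kept = set(ranking.loc[ranking["kept"], "gene"])
    stages = candidate_variants(vmap, kept)

    funnel = pd.DataFrame(
        {
            "stage": ["snps_in_kept_genes", "after_maf", "after_function"],
            "n_snps": [len(stages["in_genes"]), len(stages["after_maf"]),
                       len(stages["after_function"])],
        }
    )
    io.write_tsv(funnel, TABLES / "variant_funnel.tsv")

    kept_snps = vmap[vmap["snp"].isin(set(stages["after_function"]))].copy()
    kept_snps["passed_maf"] = True
    kept_snps["passed_function"] = True
    io.write_tsv(kept_snps, DATA / "filtered_variants.tsv")

    print(f"{len(kept)} kept genes contain {len(stages['in_genes'])} variants")
    print(f"MAF < 0.1 keeps {len(stages['after_maf'])}; "
          f"nonsynonymous keeps {len(stages['after_function'])}")


if __name__ == "__main__":
    main()
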