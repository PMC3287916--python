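"""Simulate the mini-exome family study: pedigrees, variant map,
gene-drop genotypes, true per-gene IBD scores, and phenotype replicates
with five planted causal genes."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, SEED

from ibdfilter import io, simulate_study


def main():
    study = simulate_study(CONFIG)
    DATA.mkdir(parents=True, exist_ok=True)
    meta = {"seed": SEED, "config": io.config_hash(CONFIG)}
    io.write_ped(study.pedigree, DATA / "pedigree.ped",
                 header=[f"{k}={v}" for k, v in sorted(meta.items())])
    io.write_variant_map(study.variant_map, DATA / "variant_map.tsv", meta)
    io.write_dosages(study.dosages, DATA / "dosages.tsv", meta)
    io.write_ibd_matrix(study.ibd, DATA / "ibd_matrix.tsv", meta)
    io.write_phenotypes(study.replicates, DATA / "phenotypes", meta)
    truth = pd.DataFrame(
        sorted(study.truth.effects),
        columns=["variant", "effect"],
    )
    truth["gene"] = truth["variant"].map(study.variant_map.set_index("snp")["gene"])
    io.write_tsv(truth, DATA / "truth.tsv", meta)

    prev = study.replicates.affection.to_numpy().mean()
    print(f"simulated {len(study.pedigree)} individuals in "
          f"{len(study.pedigree.families)} pedigrees")
    print(f"{len(study.variant_map)} SNPs in "
          f"{study.variant_map['gene'].nunique()} genes; "
          f"rare fraction {float((study.variant_map['maf'] < 0.1).mean()):.3f}")
    print(f"{CONFIG.n_replicates} phenotype replicates, "
          f"mean affected fraction {prev:.3f}")
    print(f"causal genes: {', '.join(sorted(study.truth.causal_genes))} "
          f"({len(study.truth.causal_variants)} variants)")


if __name__ == "__main__":
    main()
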