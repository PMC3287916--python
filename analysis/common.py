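"""Shared configuration for the numbered analysis scripts.

The analysis study mirrors the full-scale design — eight extended
pedigrees of ~87 members each — with the exome and replicate count scaled
down (800 genes / 4,000 SNPs, 40 phenotype replicates) so the whole
sequence runs in a couple of minutes.  Bulk per-individual data lives
under scratch/ (regenerable); summary tables land in results/tables/.
"""

from pathlib import Path

from ibdfilter import SimConfig

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "analysis_data"
TABLES = ROOT / "results" / "tables"

SEED = 2026

CONFIG = SimConfig(
    seed=SEED,
    n_genes=800,
    n_snps=4000,
    n_replicates=40,
    n_causal_genes=5,
    causal_effect=2.5,
    causal_maf_min=0.02,
    causal_min_variants=2,
)

MIN_PEDIGREES = 3
GENE_CAP = 100
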