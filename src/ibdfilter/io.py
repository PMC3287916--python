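"""Readers and writers for the pipeline's tabular formats.

All bespoke tables are tab-delimited UTF-8 with LF line endings and
'#'-prefixed header comments carrying the seed and a config hash, so
identical runs produce byte-identical files.  A minimal VCFv4.2 export
(GT only) is available for the genotype dosages.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .ibd import IbdMatrix
from .pedigree import Pedigree, read_ped, write_ped  # noqa: F401  (re-export)
from .simulate import ReplicateSet


def config_hash(config) -> str:
    """Short stable digest of a config dataclass (or mapping)."""
    payload = asdict(config) if is_dataclass(config) else dict(config)
    text = yaml.safe_dump(payload, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _meta_lines(meta: Optional[Mapping[str, object]]) -> list[str]:
    if not meta:
        return []
    return [f"# {k}={meta[k]}" for k in sorted(meta)]


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    meta: Optional[Mapping[str, object]] = None,
    float_format: str = "%.6g",
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- specific tables ---------------------------------------------------


def write_variant_map(vmap: pd.DataFrame, path, meta=None) -> None:
    write_tsv(vmap, path, meta=meta)


def read_variant_map(path) -> pd.DataFrame:
    vmap = read_tsv(path, dtype={"snp": str, "chrom": str, "gene": str})
    required = {"snp", "chrom", "pos_bp", "pos_cM", "gene", "maf", "function"}
    missing = required - set(vmap.columns)
    if missing:
        raise ValueError(f"variant map missing columns: {sorted(missing)}")
    return vmap


def write_ibd_matrix(ibd: IbdMatrix, path, meta=None) -> None:
    """Long format (id1, id2, gene, score), nonzero cells only, sorted."""
    long = ibd.to_long().sort_values(["id1", "id2", "gene"], kind="stable")
    write_tsv(long, path, meta=meta)


def read_ibd_matrix(path, genes: Optional[Sequence[str]] = None) -> IbdMatrix:
    frame = read_tsv(path, dtype={"id1": str, "id2": str, "gene": str})
    return IbdMatrix.from_long(frame, genes=genes)


def write_phenotypes(replicates: ReplicateSet, outdir, meta=None) -> None:
    """One two-column TSV (id, affected 0/1) per replicate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rep in replicates.replicate_ids:
        frame = pd.DataFrame(
            {
                "id": replicates.affection.index,
                "affected": replicates.affection[rep].astype(int).to_numpy(),
            }
        )
        write_tsv(frame, outdir / f"{rep}.tsv", meta=meta)


def read_phenotypes(indir) -> pd.DataFrame:
    """Read a directory of per-replicate phenotype TSVs into a boolean
    individuals x replicates frame (replicates in filename order)."""
    indir = Path(indir)
    cols = {}
    index = None
    for path in sorted(indir.glob("*.tsv")):
        frame = read_tsv(path, dtype={"id": str})
        frame = frame.set_index("id")
        if index is None:
            index = frame.index
        cols[path.stem] = frame["affected"].astype(bool)
    if not cols:
        raise FileNotFoundError(f"no phenotype TSVs under {indir}")
    return pd.DataFrame(cols, index=index)


def write_dosages(dosages: pd.DataFrame, path, meta=None) -> None:
    frame = dosages.reset_index()
    write_tsv(frame, path, meta=meta)


def read_dosages(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype={"id": str})
    return frame.set_index("id")


def write_vcf(
    variant_map: pd.DataFrame,
    dosages: pd.DataFrame,
    path,
    meta: Optional[Mapping[str, object]] = None,
) -> None:
    """Minimal VCFv4.2 export: GT only, unphased, REF=A ALT=C placeholders."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(dosages.index)
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in _meta_lines(meta):
            fh.write("##" + line.lstrip("# ") + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for _, row in variant_map.iterrows():
            calls = "\t".join(gt[int(d)] for d in dosages[row["snp"]])
            fh.write(
                f"{row['chrom']}\t{int(row['pos_bp'])}\t{row['snp']}\tA\tC\t.\t.\t.\tGT\t{calls}\n"
            )
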