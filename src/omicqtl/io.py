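"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (GT field, one contig line per chromosome),
intervals as BED6, count matrices and summary statistics as TSV, ground
truth and scenario configuration as JSON/YAML. Everything round-trips
through plain text.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel, GwasSummary, PhenotypeSet

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_GT_DECODE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
              "1/1": 2, "1|1": 2, "./.": -1, ".|.": -1, ".": -1}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in panel.variants["chrom"].unique():
            end = int(panel.variants.loc[panel.variants["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(panel.samples["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, (_, v) in enumerate(panel.variants.iterrows()):
            gts = "\t".join(_GT_CODE[int(g)] for g in panel.dosages[:, j])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a (plain-text) VCF of hard GT calls back into a panel."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, columns = [], []
    for rec in vcf:
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        g = rec.gt_types.astype(np.int8)
        dos = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, -1)))
        columns.append(dos)
        rows.append((rec.ID, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    dosages = np.column_stack(columns).astype(np.int8)
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    d = np.ma.masked_equal(dosages, -1)
    variants["af"] = np.asarray(d.mean(axis=0) / 2.0)
    samples = pd.DataFrame({"id": sample_ids, "family": sample_ids, "role": "founder"})
    return GenotypePanel(dosages, variants, samples)


def write_bed6(intervals: pd.DataFrame, path: str | Path, score_col: str | None = None) -> None:
    """BED6: chrom, start, end, name, score, strand (0-based half-open)."""
    df = intervals.copy()
    df["score"] = df[score_col] if score_col else 0
    if "strand" not in df:
        df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return df


def write_counts(pheno: PhenotypeSet, path: str | Path) -> None:
    df = pd.DataFrame(pheno.counts, columns=pheno.sample_ids)
    df.insert(0, "element", pheno.elements["id"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


def read_gwas(path: str | Path, trait: str) -> GwasSummary:
    return GwasSummary(pd.read_csv(path, sep="\t"), trait=trait)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
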