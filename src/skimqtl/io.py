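"""Readers and writers for the package's standard formats.

Genotypes travel as VCF (parent A = REF, parent B = ALT, missing = "./.");
marker matrices, phenotypes, breakpoints and maps are plain TSV; bin
boundaries are BED (0-based half-open).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codes import A, B, HET, MISSING
from .genotypes import ParentCodedGenotypes

_GT = {int(A): "0/0", int(B): "1/1", int(HET): "0/1", int(MISSING): "./."}


def write_vcf(path, g: ParentCodedGenotypes, chrom_lengths: dict | None = None):
    """Write parent-coded calls as an uncompressed VCF (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=skimqtl\n")
        if chrom_lengths:
            for c, ln in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={int(ln)}>\n")
        else:
            for c in g.chrom_names:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.lines) + "\n")
        for j in range(g.n_snps):
            gts = "\t".join(_GT.get(int(c), "./.") for c in g.calls[:, j])
            fh.write(f"{g.chroms[j]}\t{g.pos[j]}\tsnp_{g.chroms[j]}_{g.pos[j]}"
                     f"\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> ParentCodedGenotypes:
    """Read a (possibly bgzipped) VCF into parent-coded calls.

    Uses cyvcf2: HOM_REF -> A, HOM_ALT -> B, HET -> HET, unknown -> missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    chroms, pos, calls = [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    lut = np.array([A, HET, MISSING, B], dtype=np.int8)
    for variant in vcf:
        chroms.append(variant.CHROM)
        pos.append(variant.POS)
        calls.append(lut[variant.gt_types])
    vcf.close()
    if not pos:
        raise ValueError(f"no variants in {path}")
    return ParentCodedGenotypes(lines, np.array(chroms), np.array(pos, dtype=np.int64),
                                np.stack(calls, axis=1))


def write_marker_matrix(path, mat: pd.DataFrame):
    mat.to_csv(path, sep="\t", index=False)


def read_marker_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_bed(path, bed: pd.DataFrame):
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_breakpoints(path, bset):
    bset.to_frame().to_csv(path, sep="\t", index=False)


def write_phenotypes(path, pheno: pd.DataFrame):
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "trait": str, "environment": str})
    required = {"line", "trait", "environment", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_linkage_map(path, lm):
    lm.table.to_csv(path, sep="\t", index=False)


def write_scan(path, result):
    result.table.to_csv(path, sep="\t", index=False)


def write_truth_breakpoints(path, truth):
    rows = [
        {"line": line, "chrom": chrom, "left_bp": l, "right_bp": r}
        for (line, chrom), bps in truth.breakpoints.items()
        for l, r in bps
    ]
    pd.DataFrame(rows, columns=["line", "chrom", "left_bp", "right_bp"]).to_csv(
        path, sep="\t", index=False)
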