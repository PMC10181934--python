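"""Text-format input/output: phased haploid VCF, site tables, phenotypes.

Haploid samples are written as single-allele genotypes in an uncompressed
VCF; positions are rounded to integer base pairs (deduplicated by
incrementing), with the exact fractional position kept in the INFO field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_vcf(path, haplotypes, positions, sample_names=None, chrom="1"):
    X = np.asarray(haplotypes)
    n, m = X.shape
    if sample_names is None:
        sample_names = [f"hap{i}" for i in range(n)]
    pos_int = []
    last = 0
    for p in np.asarray(positions, float):
        q = max(int(np.floor(p)) + 1, last + 1)
        pos_int.append(q)
        last = q
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=XPOS,Number=1,Type=Float,Description="Exact position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for k in range(m):
            gts = "\t".join(str(int(v)) for v in X[:, k])
            fh.write(
                f"{chrom}\t{pos_int[k]}\tsite{k}\tA\tC\t.\tPASS\t"
                f"XPOS={float(positions[k]):.6f}\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a haploid VCF written by :func:`write_vcf` (or equivalent).

    Returns (haplotypes N x M int8, positions, sample_names).  Phased
    diploid genotypes are split into two haploid rows per sample.
    """
    samples, rows, positions = None, [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            info = fields[7]
            pos = float(fields[1])
            for entry in info.split(";"):
                if entry.startswith("XPOS="):
                    pos = float(entry[5:])
            positions.append(pos)
            col = []
            for gt in fields[9:]:
                gt = gt.split(":")[0]
                for allele in gt.replace("|", "/").split("/"):
                    col.append(-1 if allele == "." else int(allele))
            rows.append(col)
    X = np.array(rows, dtype=np.int8).T
    return X, np.array(positions), samples


def write_site_table(path, positions, frequencies, extra=None):
    df = pd.DataFrame({"position": positions, "frequency": frequencies})
    if extra is not None:
        for k, v in extra.items():
            df[k] = v
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path):
    return pd.read_csv(path, sep="\t")


def write_phenotype(path, values, ids=None):
    ids = ids if ids is not None else np.arange(len(values))
    pd.DataFrame({"id": ids, "value": values}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_phenotype(path):
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "value"])
    return df["id"].to_numpy(), df["value"].to_numpy(float)


def write_dataset(dataset, prefix, chrom="1"):
    """Write a simulated dataset's full file bundle (VCF, site table,
    genetic map, demography, true-ARG tree sequence)."""
    from .arg import export_tree_sequence

    write_vcf(f"{prefix}.vcf", dataset.haplotypes, dataset.positions, chrom=chrom)
    write_site_table(f"{prefix}.sites.tsv", dataset.positions, dataset.frequencies)
    dataset.genetic_map.to_file(f"{prefix}.map", chrom=chrom)
    dataset.demography.to_file(f"{prefix}.demo")
    export_tree_sequence(dataset.true_arg, f"{prefix}.trees")
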