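"""Plain-text readers and writers for the pipeline's tabular formats.

Count tables, genotype dosages, phenotype tables and relationship
matrices are all TSV with an id header; genotypes can additionally be
written to (and read from) a minimal VCFv4.2 with GT fields, and reads
are 4-line Phred+33 FASTQ.
"""

from __future__ import annotations

import gzip

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .profiling import ReadBatch
from .synthio import GenotypeMatrix

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_relationship_matrix",
    "write_relationship_matrix",
    "read_fastq",
]


def read_count_table(path) -> pd.DataFrame:
    """TSV count table: first column sample id, header row feature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(np.int8)
    p = df.to_numpy().mean(axis=0) / 2.0
    return GenotypeMatrix(dosages=df, freqs=p)


def write_genotypes_tsv(gt: GenotypeMatrix, path) -> None:
    gt.dosages.to_csv(path, sep="\t", index_label="animal_id")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(gt: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with GT fields on synthetic contig chr1."""
    ids = gt.ids
    w = gt.dosages.to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for j, snp in enumerate(gt.dosages.columns):
            gts = "\t".join(_GT_CODE[int(d)] for d in w[:, j])
            fh.write(f"chr1\t{j + 1}\t{snp}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read GT dosages (ALT-allele count) from an uncompressed VCF."""
    ids, rows, snps = None, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ids = parts[9:]
                continue
            snps.append(parts[2])
            gt_idx = parts[8].split(":").index("GT")
            dose = []
            for field in parts[9:]:
                alleles = field.split(":")[gt_idx].replace("|", "/").split("/")
                dose.append(sum(a == "1" for a in alleles))
            rows.append(dose)
    if ids is None:
        raise ValueError("no #CHROM header line found")
    df = pd.DataFrame(
        np.array(rows, dtype=np.int8).T, index=ids, columns=snps
    )
    return GenotypeMatrix(dosages=df, freqs=df.to_numpy().mean(axis=0) / 2.0)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="animal_id")


def write_relationship_matrix(rel: RelationshipMatrix, path) -> None:
    rel.to_frame().to_csv(path, sep="\t", index_label="id")


def read_relationship_matrix(path, kind: str = "GRM") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return RelationshipMatrix(values=df.to_numpy(), ids=list(df.index), kind=kind)


def read_fastq(path, sample_id: str | None = None) -> ReadBatch:
    """Read a (optionally gzipped) FASTQ file into a ReadBatch."""
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # +
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            records.append((seq, qual))
    name = sample_id or str(path).rsplit("/", 1)[-1].split(".")[0]
    return ReadBatch(sample_id=name, records=records)
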