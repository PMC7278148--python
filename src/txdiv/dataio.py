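"""Readers, writers and validated containers for the pipeline's formats.

Genotypes are inbred accession panels: dosages are haploid {0, 1} with NaN
for missing. VCF input follows the usual diploid convention (0/0, 1/1, ./.);
heterozygous calls are treated as likely errors on an inbred panel and mapped
to missing with a counted warning. All coordinates are 1-based and windows
are closed intervals, matching VCF.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "CountTable",
    "SampleTable",
    "GeneTable",
    "Dataset",
    "load_dataset",
    "load_genotypes_vcf",
    "write_genotypes_vcf",
    "write_results",
]


@dataclass
class GenotypeTable:
    """Accession x SNP dosage matrix with SNP coordinates.

    Parameters
    ----------
    accessions : list of str
    snps : DataFrame with columns snp_id, chrom, pos (1-based), ref, alt
    dosages : float array (n_accessions, n_snps), values in {0, 1, NaN}
    """

    accessions: list
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.accessions = list(self.accessions)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accessions), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs"
            )
        ok = np.isnan(self.dosages) | (self.dosages == 0) | (self.dosages == 1)
        if not ok.all():
            raise ValueError("dosages must be 0, 1 or missing (NaN)")
        for _, sub in self.snps.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("SNP positions must be sorted within chromosome")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_freq(self, rows=None) -> np.ndarray:
        """Alt-allele frequency per SNP over `rows` (accession indices)."""
        d = self.dosages if rows is None else self.dosages[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0)

    def maf(self, rows=None) -> np.ndarray:
        """Minor-allele frequency per SNP, in [0, 0.5]."""
        p = self.allele_freq(rows)
        return np.minimum(p, 1.0 - p)

    def subset_accessions(self, rows) -> "GenotypeTable":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return GenotypeTable(
            [self.accessions[i] for i in rows],
            self.snps.reset_index(drop=True),
            self.dosages[rows].copy(),
        )


@dataclass
class CountTable:
    """Gene x sample matrix of non-negative integer read counts."""

    genes: list
    samples: list
    counts: np.ndarray

    def __post_init__(self):
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("count matrix shape mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    def subset_genes(self, keep) -> "CountTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountTable([self.genes[i] for i in keep], self.samples, self.counts[keep])


@dataclass
class SampleTable:
    """Sample -> accession mapping with replicate index and optional labels."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "accession_id", "replicate")

    def __post_init__(self):
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"sample table missing column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicated sample id {dup!r}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    @property
    def accession_of(self) -> dict:
        return dict(zip(self.table["sample_id"], self.table["accession_id"]))

    def accessions(self) -> list:
        """Unique accession ids, in first-appearance order."""
        return list(dict.fromkeys(self.table["accession_id"]))


@dataclass
class GeneTable:
    """Gene annotation: id, chromosome, TSS (1-based) and strand."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("gene_id", "chrom", "tss"):
            if col not in t.columns:
                raise ValueError(f"gene table missing column {col!r}")
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicated gene id {dup!r}")
        if (t["tss"] < 1).any():
            raise ValueError("TSS positions must be >= 1")
        if "strand" not in t.columns:
            t = t.assign(strand="+")
        self.table = t.reset_index(drop=True)


@dataclass
class Dataset:
    """Cross-validated bundle of genotypes, counts, annotation and metadata."""

    genotypes: GenotypeTable
    counts: CountTable
    genes: GeneTable
    samples: SampleTable
    warnings: dict = field(default_factory=dict)

    def __post_init__(self):
        known = set(self.samples.sample_ids)
        missing = [s for s in self.counts.samples if s not in known]
        if missing:
            raise ValueError(f"samples in counts but not in metadata: {missing}")
        acc = set(self.genotypes.accessions)
        unmapped = sorted(set(self.samples.table["accession_id"]) - acc)
        if unmapped:
            raise ValueError(f"accessions in metadata but not genotyped: {unmapped}")


def load_genotypes_vcf(path) -> tuple[GenotypeTable, dict]:
    """Read an inbred-panel VCF into haploid dosages.

    0/0 -> 0, 1/1 -> 1, ./. -> missing; heterozygous calls -> missing
    (counted); multi-allelic records skipped (counted).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accessions = list(vcf.samples)
    recs, rows = [], []
    n_het = n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types (gts012): 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=float)
        het = gt == 1
        n_het += int(het.sum())
        dos = np.where(gt == 0, 0.0, np.where(gt == 2, 1.0, np.nan))
        dos[het] = np.nan
        rid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        recs.append((rid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        rows.append(dos)
    vcf.close()
    if n_het:
        warnings.warn(f"{n_het} heterozygous calls set to missing (inbred panel)")
    snps = pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dos = np.array(rows).T if rows else np.empty((len(accessions), 0))
    gt = GenotypeTable(accessions, snps, dos)
    return gt, {"het_to_missing": n_het, "multiallelic_skipped": n_multi}


def write_genotypes_vcf(genotypes: GenotypeTable, path) -> None:
    """Write haploid dosages as homozygous diploid GT calls (VCF 4.2)."""
    chroms = list(dict.fromkeys(genotypes.snps["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=txdiv\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(cols[:7] + ["INFO", "FORMAT"] + list(map(str, genotypes.accessions))) + "\n")
        code = {0.0: "0/0", 1.0: "1/1"}
        for j, rec in enumerate(genotypes.snps.itertuples(index=False)):
            gts = [code.get(d, "./.") for d in genotypes.dosages[:, j]]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}"
                "\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_counts_tsv(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(list(df.index), list(df.columns), df.to_numpy())


def load_dataset(vcf_path, counts_path, genes_path, samples_path) -> Dataset:
    """Load and cross-validate the four input files."""
    genotypes, warn = load_genotypes_vcf(vcf_path)
    counts = _read_counts_tsv(counts_path)
    genes = GeneTable(pd.read_csv(genes_path, sep="\t"))
    samples = SampleTable(pd.read_csv(samples_path, sep="\t"))
    extra = set(counts.genes) - set(genes.table["gene_id"])
    if extra:
        raise ValueError(f"genes in counts but not annotated: {sorted(extra)[:5]}")
    return Dataset(genotypes, counts, genes, samples, warnings=warn)


def write_counts_tsv(counts: CountTable, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_results(tables: dict, out_dir, force: bool = False) -> list:
    """Write each DataFrame as ``<name>.tsv`` with 6-significant-digit floats.

    Missing values are written as ``NA``. Refuses to overwrite unless
    ``force`` is set.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        if os.path.exists(path) and not force:
            raise FileExistsError(f"{path} exists (use force=True to overwrite)")
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        paths.append(path)
    return paths
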