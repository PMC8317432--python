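"""Reading and writing the pipeline's on-disk formats.

Read counts travel as VCF 4.2 with per-sample AD (ref, alt) and DP;
per-sample "other"-allele counts (reads matching neither allele) are
recoverable as DP - ref - alt, and a per-site INFO field carries their
total.  Called genotypes are written as ploidy-4 GT strings (0/0/1/1)
plus a dosage TSV.  Simulation truth and population metadata round-trip
through TSV/CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotyping import MISSING, GenotypeMatrix
from .simulate import PopulationTable, ReadCountMatrix, SimulationTruth

__all__ = [
    "write_counts_vcf",
    "read_counts_vcf",
    "write_simulated_dataset",
    "read_population_table",
    "write_dosage_vcf",
    "write_dosage_tsv",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tetrapop
##contig=<ID=chr1>
##INFO=<ID=OTHER,Number=1,Type=Integer,Description="Total reads matching neither allele across samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth for ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth including other alleles">
"""


def write_counts_vcf(reads: ReadCountMatrix, path: str) -> None:
    """Write read counts as a biallelic VCF with AD/DP per sample."""
    n_ind, n_sites = reads.shape
    depth = reads.depth
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(reads.individual_ids)
            + "\n"
        )
        for j in range(n_sites):
            other_total = int(reads.other[:, j].sum())
            cells = [
                f"./././.:{reads.ref[i, j]},{reads.alt[i, j]}:{depth[i, j]}"
                for i in range(n_ind)
            ]
            fh.write(
                f"chr1\t{j + 1}\t{reads.site_ids[j]}\tA\tC\t.\tPASS\t"
                f"OTHER={other_total}\tGT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def read_counts_vcf(path: str) -> ReadCountMatrix:
    """Read a counts VCF (as written by :func:`write_counts_vcf`).

    Any VCF with per-sample AD (ref, alt) works; DP defaults to the AD
    sum when absent, making the "other" count zero.  Multiallelic
    records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    individual_ids = list(vcf.samples)
    refs, alts, others, site_ids = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic record at {var.CHROM}:{var.POS}")
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"record without AD at {var.CHROM}:{var.POS}")
        ad = np.maximum(ad.astype(np.int64), 0)
        dp = var.format("DP")
        total = (
            np.maximum(dp.astype(np.int64).reshape(-1), 0)
            if dp is not None
            else ad.sum(axis=1)
        )
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
        others.append(np.maximum(total - ad[:, 0] - ad[:, 1], 0))
        site_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    vcf.close()
    if not refs:
        raise ValueError(f"no records in {path}")
    return ReadCountMatrix(
        ref=np.column_stack(refs),
        alt=np.column_stack(alts),
        other=np.column_stack(others),
        individual_ids=individual_ids,
        site_ids=site_ids,
    )


def write_simulated_dataset(
    out_dir: str, truth: SimulationTruth, reads: ReadCountMatrix
) -> dict[str, str]:
    """Write a simulated dataset: counts VCF, truth TSVs, metadata CSV.

    Returns a name -> path mapping of everything written.  Dimensions
    are checked for consistency first.
    """
    if truth.dosage is None:
        raise ValueError("truth has no dosages; draw genotypes first")
    if truth.dosage.shape != reads.shape:
        raise ValueError(
            f"dosage shape {truth.dosage.shape} != read matrix shape {reads.shape}"
        )
    if truth.freq.shape[0] != reads.shape[1]:
        raise ValueError("locus count mismatch between truth and reads")
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "reads.vcf"),
        "pops": os.path.join(out_dir, "populations.csv"),
        "true_freq": os.path.join(out_dir, "true_frequencies.tsv"),
        "true_dosage": os.path.join(out_dir, "true_dosages.tsv"),
        "loci": os.path.join(out_dir, "loci.tsv"),
    }
    write_counts_vcf(reads, paths["vcf"])
    truth.pops.frame.to_csv(paths["pops"], index=False)
    pd.DataFrame(
        truth.freq, index=reads.site_ids, columns=truth.pops.locality_ids
    ).to_csv(paths["true_freq"], sep="\t", index_label="site_id")
    pd.DataFrame(
        truth.dosage, index=reads.individual_ids, columns=reads.site_ids
    ).to_csv(paths["true_dosage"], sep="\t", index_label="individual")
    pd.DataFrame(
        {
            "site_id": reads.site_ids,
            "adaptive": truth.adaptive_flags,
            "mode": truth.mode,
        }
    ).to_csv(paths["loci"], sep="\t", index=False)
    return paths


def read_population_table(path: str) -> PopulationTable:
    """Read a `locality,region,lat,lon,<covariate...>` CSV."""
    frame = pd.read_csv(path)
    fixed = ["locality", "region", "lat", "lon"]
    covs = [c for c in frame.columns if c not in fixed]
    return PopulationTable(frame, covariate_names=covs)


def _gt_string(dosage: int) -> str:
    if dosage == MISSING:
        return "./././."
    return "/".join(["0"] * (4 - dosage) + ["1"] * dosage)


def write_dosage_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write called genotypes as a VCF with ploidy-4 GT strings."""
    n_ind, n_sites = genotypes.shape
    with open(path, "w") as fh:
        fh.write(
            "##fileformat=VCFv4.2\n##source=tetrapop\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Tetraploid genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j in range(n_sites):
            cells = [_gt_string(int(genotypes.dosage[i, j])) for i in range(n_ind)]
            fh.write(
                f"chr1\t{j + 1}\t{genotypes.site_ids[j]}\tA\tC\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    genotypes.to_frame().to_csv(path, sep="\t", index_label="individual")
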