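"""File formats: VCF 4.2 and the package's TSV dialects.

All TSV files are tab-delimited, UTF-8, with a header row and ``NA`` for
missing values; genotype cells are coded 0 (hom-ref), 1 (het), 2 (hom-alt),
NA (missing). VCF is read through cyvcf2 (``0/1`` and ``1/0`` both map to
het, ``./.`` to missing); multi-allelic records are rejected and counted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CHROMOSOMES,
    FormatError,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleFrame,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "write_vcf",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_sample_frame",
    "write_sample_frame",
    "write_truth",
]

_CONTIG_LENGTHS = {
    "I": 15_072_434, "II": 15_279_421, "III": 13_783_801,
    "IV": 17_493_829, "V": 20_924_180, "X": 17_718_942,
}


def _normalize_contig(name: str) -> str:
    clean = name.removeprefix("chr").removeprefix("CHROMOSOME_").upper()
    if clean not in CHROMOSOMES:
        raise FormatError(f"cannot normalize contig name {name!r} to I..V/X")
    return clean


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV (format inferred from the
    extension when not given)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        sites_path = path.with_suffix(".sites.tsv")
        return read_genotypes_tsv(path, sites_path if sites_path.exists() else None)
    raise FormatError(f"unknown genotype format {fmt!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        write_vcf(matrix, path)
    elif fmt == "tsv":
        write_genotypes_tsv(matrix, path, path.with_suffix(".sites.tsv"))
    else:
        raise FormatError(f"unknown genotype format {fmt!r}")


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT-only records;
    the RAD locus id is carried in the ID column."""
    gt_text = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=demeseed\n")
        for c in CHROMOSOMES:
            fh.write(f"##contig=<ID={c},length={_CONTIG_LENGTHS[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        for j, site in matrix.sites.iterrows():
            calls = "\t".join(gt_text[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.rad_locus}\t{site.ref}\t"
                f"{site.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic diploid GT calls from a VCF.

    Multi-allelic records are skipped (count reported as a warning);
    non-diploid genotypes raise :class:`FormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    site_rows, call_cols = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = v.genotypes  # [allele1, allele2, phased] per sample
        col = np.empty(len(individuals), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise FormatError(
                    f"non-diploid genotype at {v.CHROM}:{v.POS} sample "
                    f"{individuals[i]}"
                )
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col[i] = MISSING
            elif a == 0 and b == 0:
                col[i] = HOM_REF
            elif a == 1 and b == 1:
                col[i] = HOM_ALT
            elif {a, b} == {0, 1}:
                col[i] = HET
            else:
                raise FormatError(f"unexpected allele index at {v.CHROM}:{v.POS}")
        site_rows.append(
            (
                _normalize_contig(v.CHROM), v.POS,
                v.ID if v.ID else f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0],
            )
        )
        call_cols.append(col)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records", stacklevel=2)
    if not site_rows:
        raise FormatError(f"no biallelic records in {path}")
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "rad_locus", "ref", "alt"])
    calls = np.column_stack(call_cols)
    return GenotypeMatrix(individuals=individuals, sites=sites, calls=calls)


def write_genotypes_tsv(
    matrix: GenotypeMatrix, path: str | Path, sites_path: str | Path | None = None
) -> None:
    cells = matrix.calls.astype(object)
    cells[matrix.calls == MISSING] = "NA"
    df = pd.DataFrame(cells, index=matrix.individuals, columns=matrix.site_labels())
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")
    if sites_path is not None:
        matrix.sites.to_csv(sites_path, sep="\t", index=False)


def read_genotypes_tsv(
    path: str | Path, sites_path: str | Path | None = None
) -> GenotypeMatrix:
    """Read the 0/1/2/NA genotype TSV. Site annotation (RAD locus,
    ref/alt) comes from the sidecar sites TSV when available; otherwise
    each site gets its own locus id and placeholder alleles."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    calls = df.replace("NA", str(MISSING)).astype(np.int8).to_numpy()
    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
    else:
        parts = [lab.split(":") for lab in df.columns]
        sites = pd.DataFrame(
            {
                "chrom": [p[0] for p in parts],
                "pos": [int(p[1]) for p in parts],
                "rad_locus": list(df.columns),
                "ref": "A",
                "alt": "T",
            }
        )
    return GenotypeMatrix(individuals=list(df.index), sites=sites, calls=calls)


def write_sample_frame(frame: SampleFrame, samples_path: str | Path,
                       individuals_path: str | Path) -> None:
    frame.samples.to_csv(samples_path, sep="\t", index=False, na_rep="NA")
    frame.individuals.to_csv(individuals_path, sep="\t", index=False, na_rep="NA")


def read_sample_frame(
    samples_path: str | Path,
    individuals_path: str | Path,
    dayfirst_dates: bool = False,
) -> SampleFrame:
    """Read the metadata TSVs. Dates are ISO 8601; ``dayfirst_dates``
    additionally accepts the DD/MM/YYYY field-notebook convention."""
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    individuals = pd.read_csv(
        individuals_path, sep="\t", dtype={"individual_id": str, "sample_id": str}
    )
    if dayfirst_dates:
        samples["date"] = pd.to_datetime(
            samples["date"], dayfirst=True
        ).dt.strftime("%Y-%m-%d")
    return SampleFrame(samples=samples, individuals=individuals)


def write_truth(truth, labels_path: str | Path, demes_path: str | Path) -> None:
    """Write simulator ground truth (per-individual labels and per-deme
    founder records) as TSV."""
    truth.labels.to_csv(labels_path, sep="\t", index=False)
    demes = pd.DataFrame(
        {
            "deme": np.arange(len(truth.founder_counts)),
            "founder_count": truth.founder_counts,
            "founder_haplotypes": [
                ",".join(map(str, hs)) for hs in truth.founder_haplotypes
            ],
        }
    )
    demes.to_csv(demes_path, sep="\t", index=False)
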