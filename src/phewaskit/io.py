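"""Readers/writers for the pipeline's interchange formats and the
synthesis-view results plot.

Interchange dialect: tab-delimited UTF-8 with a header row and ``NA`` for
missing values. Genotypes are additionally accepted as VCF (GT field,
biallelic records only) and written either way. The dosage TSV has samples
as rows and SNP ids as columns with values 0/1/2/NA; it carries no allele
metadata, so the reader fills placeholder ref/alt and codes the counted
allele as ALT.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .containers import GenotypeMatrix, ValidationError, validate_covariates, validate_diagnoses
from .phenotyping import CASE, CONTROL, EXCLUDED, PhenotypeMatrix, parse_icd9

NA = "NA"


# ---------------------------------------------------------------- TSV tables

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=NA)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, **kwargs)


def write_diagnoses(diagnoses: pd.DataFrame, path) -> None:
    write_tsv(validate_diagnoses(diagnoses), path)


def read_diagnoses(path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"sample_id": str, "icd9": str})
    return validate_diagnoses(df)


def write_covariates(covariates: pd.DataFrame, path) -> None:
    write_tsv(covariates.rename_axis("sample_id"), path, index=True)


def read_covariates(path) -> pd.DataFrame:
    df = read_tsv(path, dtype=str).set_index("sample_id")
    return validate_covariates(df)


# ------------------------------------------------------------- genotype I/O

def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.dosage,
        index=pd.Index(genotypes.samples, name="sample_id"),
        columns=genotypes.snp_ids,
    )
    # dosages are integral; render without trailing .0
    df = df.astype("Int64")
    write_tsv(df, path, index=True)


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = read_tsv(path, dtype={"sample_id": str}).set_index("sample_id")
    dosage = df.to_numpy(dtype=float)
    snps = pd.DataFrame(
        {"ref": "N", "alt": "N", "coded_allele": "ALT", "chrom": ".", "pos": 0},
        index=pd.Index(df.columns, name="snp_id"),
    )
    return GenotypeMatrix(list(df.index), snps, dosage)


_GT_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: 2.0, -1: np.nan}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal biallelic VCFv4.2 with GT genotypes."""
    meta = genotypes.snps
    has_panel = "panel" in meta.columns
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_panel:
            fh.write(
                '##INFO=<ID=PANEL,Number=1,Type=String,'
                'Description="SNP panel (assoc or background)">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, snp_id in enumerate(genotypes.snp_ids):
            row = meta.iloc[j]
            chrom = str(row.get("chrom", "1"))
            pos = int(row.get("pos", j + 1) or j + 1)
            gts = []
            for v in genotypes.dosage[:, j]:
                if np.isnan(v):
                    gts.append("./.")
                elif v == 0:
                    gts.append("0/0")
                elif v == 1:
                    gts.append("0/1")
                else:
                    gts.append("1/1")
            info = f"PANEL={row['panel']}" if has_panel else "."
            fh.write(
                f"{chrom}\t{pos}\t{snp_id}\t{row['ref']}\t{row['alt']}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT genotypes from a VCF via cyvcf2; multiallelic records are
    rejected with the offending record named."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, refs, alts, chroms, poss, cols, panels = [], [], [], [], [], [], []
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            raise ValidationError(
                f"multiallelic record at {variant.CHROM}:{variant.POS} "
                f"(record {i + 1}): ALT={variant.ALT}"
            )
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        gt = np.asarray(variant.gt_types, dtype=int)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        cols.append(dos)
        panels.append(variant.INFO.get("PANEL"))
    if not cols:
        raise ValidationError(f"no variant records in {path}")
    snps = pd.DataFrame(
        {"ref": refs, "alt": alts, "coded_allele": alts, "chrom": chroms, "pos": poss},
        index=pd.Index(ids, name="snp_id"),
    )
    if any(p is not None for p in panels):
        snps["panel"] = [p if p is not None else "assoc" for p in panels]
    return GenotypeMatrix(samples, snps, np.column_stack(cols))


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise ValidationError(f"unknown genotype format {fmt!r}")


# -------------------------------------------------------- phenotype matrix

_STATUS_TO_TOKEN = {CASE: "1", CONTROL: "0", EXCLUDED: NA}
_TOKEN_TO_STATUS = {"1": CASE, "0": CONTROL, NA: EXCLUDED}


def write_phenotype_matrix(matrix: PhenotypeMatrix, path) -> None:
    """Statuses encoded 1/0/NA for case/control/excluded."""
    tokens = np.vectorize(_STATUS_TO_TOKEN.get)(matrix.status) if matrix.codes else \
        np.empty((len(matrix.samples), 0), dtype=object)
    df = pd.DataFrame(
        tokens, index=pd.Index(matrix.samples, name="sample_id"), columns=matrix.code_strings
    )
    df.to_csv(path, sep="\t")


def read_phenotype_matrix(path) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).set_index("sample_id")
    status = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        status[:, j] = df[col].map(_TOKEN_TO_STATUS).to_numpy()
    return PhenotypeMatrix(list(df.index), [parse_icd9(c) for c in df.columns], status)


def write_code_summary(matrix: PhenotypeMatrix, path) -> None:
    """Per-code counts for retained codes plus one row per dropped code."""
    summary = matrix.counts()
    summary["retained"] = True
    summary["note"] = ""
    if len(matrix.removed):
        dropped = pd.DataFrame(
            {
                "icd9": matrix.removed["icd9"],
                "category": [parse_icd9(c).category for c in matrix.removed["icd9"]],
                "n_case": matrix.removed["n_case"],
                "n_control": np.nan,
                "n_excluded": np.nan,
                "retained": False,
                "note": matrix.removed["reason"],
            }
        )
        summary = pd.concat([summary, dropped], ignore_index=True)
    write_tsv(summary, path)


# ------------------------------------------------------------------ results

def write_results(results: pd.DataFrame, path) -> None:
    out = results.copy()
    for col in ("p", "p_bonferroni", "p_bh"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.6e}" if pd.notna(v) else np.nan)
    write_tsv(out, path)


def read_results(path) -> pd.DataFrame:
    return read_tsv(path, dtype={"snp_id": str, "icd9": str, "category": str})


# --------------------------------------------------------------------- plot

def synthesis_plot(records: pd.DataFrame, path) -> None:
    """Synthesis-view-style plot of replication records.

    One row per (SNP, category); −log10 p for the discovery (blue) and
    replication (red) datasets, triangle orientation encoding the direction
    of genetic effect (up = risk, down = protective).
    """
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.5 * max(len(records), 1))))
    if records.empty:
        warnings.warn("no replication records to plot", stacklevel=2)
        ax.set_title("no replicating associations")
    else:
        labels = []
        for i, row in records.reset_index(drop=True).iterrows():
            labels.append(f"{row['snp_id']}-{row['category']}")
            for p, direction, color in (
                (row["p_discovery"], row["direction_discovery"], "tab:blue"),
                (row["p_replication"], row["direction_replication"], "tab:red"),
            ):
                if pd.isna(p):
                    continue
                marker = "^" if direction >= 0 else "v"
                ax.scatter(-np.log10(p), i, marker=marker, color=color, s=60, zorder=3)
        ax.set_yticks(range(len(labels)), labels)
        ax.invert_yaxis()
        ax.scatter([], [], color="tab:blue", marker="^", label="discovery")
        ax.scatter([], [], color="tab:red", marker="^", label="replication")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel(r"$-\log_{10}\,p$")
    ax.set_ylabel("SNP-ICD9 code category")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
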