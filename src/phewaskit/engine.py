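"""The association sweep: every retained SNP × ICD-9 code through Firth
logistic regression.

For each pair, samples excluded for that code (1–2 instances) and samples
with a missing genotype are dropped; the model is

    logit P(case) = β₀ + β_g · dosage + sex + site + platform + PC1..PC3

with additive 0/1/2 dosage coding of the alternate allele and dummy-coded
categorical covariates (lexicographically first level as reference). Dummy
columns that become constant after per-code exclusions are dropped per fit
and logged in the result row — exactly the zero-case/zero-control cell
configuration that makes unpenalized fits blow up, and the reason the sweep
uses Firth. Non-converged fits are emitted flagged, never silently dropped.

No multiple-testing correction is applied to the primary p-values
(replication in an independent half of the cohort is the error control);
Bonferroni and Benjamini–Hochberg columns are appended for reference only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from statsmodels.stats.multitest import multipletests

from .containers import Cohort, GenotypeMatrix, ValidationError
from .firth import detect_separation, fit_firth
from .genetic_qc import compute_maf
from .phenotyping import CASE, CONTROL, PhenotypeMatrix

RESULT_COLUMNS = [
    "snp_id", "icd9", "category", "dataset", "stratum",
    "beta", "se", "or_", "ci_low", "ci_high", "p", "direction",
    "n_case", "n_control", "n_excluded", "maf",
    "converged", "separation_flag", "n_iter", "dropped_columns", "note",
    "p_bonferroni", "p_bh",
]


def build_covariate_design(
    covariates: pd.DataFrame,
    pcs: pd.DataFrame,
    categorical: tuple[str, ...] = ("sex", "site", "platform"),
    n_pcs: int = 3,
) -> pd.DataFrame:
    """Dummy-code covariates (first lexicographic level = reference) and
    append the leading principal-component scores."""
    parts = []
    for name in categorical:
        levels = sorted(covariates[name].astype(str).unique())
        for level in levels[1:]:
            parts.append(
                pd.Series(
                    (covariates[name].astype(str) == level).astype(float),
                    index=covariates.index,
                    name=f"{name}[{level}]",
                )
            )
    design = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=covariates.index)
    avail = min(n_pcs, pcs.shape[1])
    if avail < n_pcs:
        warnings.warn(f"only {avail} PCs available of {n_pcs} requested", stacklevel=2)
    pc_block = pcs.iloc[:, :avail].reindex(design.index if parts else covariates.index)
    if pc_block.isna().any().any():
        raise ValidationError("PC scores missing for some samples")
    pc_block.columns = [f"PC{i + 1}" for i in range(avail)]
    return pd.concat([design, pc_block], axis=1)


def _independent_columns(X: np.ndarray, labels: list[str], protected: int = 2):
    """Drop constant then linearly dependent columns (rank-revealing QR).

    The first ``protected`` columns (intercept, dosage) are kept in place;
    a dosage made constant by the per-pair exclusions is reported by the
    caller as a degenerate fit.
    """
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(protected, X.shape[1]):
        col = X[:, j]
        if col.max() - col.min() == 0:
            keep[j] = False
    Xk = X[:, keep]
    if Xk.shape[1] > 1:
        _, r, piv = qr(Xk, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > diag[0] * 1e-9).sum()) if diag.size else 0
        if rank < Xk.shape[1]:
            dependent = set(piv[rank:])
            idx = np.flatnonzero(keep)
            for pos in dependent:
                if idx[pos] >= protected:
                    keep[idx[pos]] = False
            Xk = X[:, keep]
    kept_labels = [l for l, k in zip(labels, keep) if k]
    dropped = [l for l, k in zip(labels, keep) if not k]
    return Xk, kept_labels, dropped


@dataclass
class PhewasInputs:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeMatrix
    covariate_design: pd.DataFrame  # sample-indexed, numeric

    def __post_init__(self) -> None:
        roster = list(self.genotypes.samples)
        if list(self.phenotypes.samples) != roster:
            raise ValidationError("genotype and phenotype sample rosters differ")
        if list(self.covariate_design.index) != roster:
            raise ValidationError("covariate design roster differs from genotypes")


def run_phewas(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates: pd.DataFrame,
    pcs: pd.DataFrame,
    dataset: str = "discovery",
    stratum: str = "all",
    n_pcs: int = 3,
    check_separation: bool = True,
    genotype_coding: str = "additive",
) -> pd.DataFrame:
    """Fit Firth regression for every (SNP, code) pair and return one result
    row per pair.

    The row count is always ``n_snps × n_codes``: pairs whose fit fails or
    degenerates are emitted with ``converged=False`` and a note. ``p`` is
    the two-sided Wald p-value of the dosage term; ``direction`` is
    sign(beta).
    """
    if genotype_coding not in ("additive", "dominant", "recessive"):
        raise ValidationError(f"unknown genotype coding {genotype_coding!r}")
    roster = list(genotypes.samples)
    covariates = covariates.loc[roster] if set(covariates.index) >= set(roster) else None
    if covariates is None:
        raise ValidationError("covariate table does not cover the genotype roster")
    pcs = pcs.reindex(roster)
    if pcs.isna().any().any():
        raise ValidationError("PC scores missing for samples in the roster")
    design = build_covariate_design(covariates, pcs, n_pcs=n_pcs)
    inputs = PhewasInputs(genotypes, phenotypes, design)

    cov_mat = design.to_numpy(dtype=float)
    cov_labels = list(design.columns)
    maf = compute_maf(genotypes)
    status = phenotypes.status
    rows = []
    for ci, code in enumerate(phenotypes.codes):
        st = status[:, ci]
        code_mask = st != -1  # drop per-code excluded samples
        for si, snp_id in enumerate(genotypes.snp_ids):
            g = genotypes.dosage[:, si]
            mask = code_mask & ~np.isnan(g)
            y = (st[mask] == CASE).astype(float)
            dose = g[mask]
            if genotype_coding == "dominant":
                dose = (dose >= 1).astype(float)
            elif genotype_coding == "recessive":
                dose = (dose == 2).astype(float)
            n_case = int(y.sum())
            n_control = int(mask.sum() - y.sum())
            n_excluded = int((~code_mask).sum())
            base = {
                "snp_id": snp_id,
                "icd9": code.code,
                "category": code.category,
                "dataset": dataset,
                "stratum": stratum,
                "n_case": n_case,
                "n_control": n_control,
                "n_excluded": n_excluded,
                "maf": float(maf.iloc[si]),
            }
            X = np.column_stack([np.ones(mask.sum()), dose, cov_mat[mask]])
            labels = ["intercept", "dosage", *cov_labels]
            if n_case == 0 or n_control == 0:
                rows.append({**base, "beta": np.nan, "se": np.nan, "or_": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "direction": 0, "converged": False,
                             "separation_flag": "complete", "n_iter": 0,
                             "dropped_columns": "", "note": "single-class outcome"})
                continue
            X, kept, dropped = _independent_columns(X, labels)
            if dose.max() - dose.min() == 0:
                rows.append({**base, "beta": np.nan, "se": np.nan, "or_": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "direction": 0, "converged": False,
                             "separation_flag": "none", "n_iter": 0,
                             "dropped_columns": ";".join(dropped),
                             "note": "monomorphic genotype after exclusions"})
                continue
            fit = fit_firth(X, y, columns=kept)
            summ = fit.wald_summary("dosage")
            flag = "none"
            if check_separation:
                flag = detect_separation(X, y)
            rows.append({**base, "beta": summ["beta"], "se": summ["se"],
                         "or_": summ["or"], "ci_low": summ["ci_low"],
                         "ci_high": summ["ci_high"], "p": summ["p"],
                         "direction": int(np.sign(summ["beta"])),
                         "converged": fit.converged, "separation_flag": flag,
                         "n_iter": fit.n_iter, "dropped_columns": ";".join(dropped),
                         "note": fit.message})
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    results = pd.DataFrame(rows)
    ok = results["p"].notna()
    results["p_bonferroni"] = np.nan
    results["p_bh"] = np.nan
    if ok.any():
        results.loc[ok, "p_bonferroni"] = np.minimum(results.loc[ok, "p"] * ok.sum(), 1.0)
        results.loc[ok, "p_bh"] = multipletests(results.loc[ok, "p"], method="fdr_bh")[1]
    return results.loc[:, RESULT_COLUMNS].sort_values(["snp_id", "icd9"]).reset_index(drop=True)


def stratify_by_ancestry(
    cohort: Cohort, group_labels: list[str] | None = None
) -> dict[str, Cohort]:
    """Split a cohort into per-ancestry-group sub-cohorts.

    MAF and code-prevalence floors must be re-applied within each group
    before fitting (group-specific allele frequencies can push a SNP below
    the floor in one group only); :func:`run_group_phewas` in the pipeline
    does this.
    """
    ancestry = cohort.covariates["ancestry"].astype(str)
    available = sorted(ancestry.unique())
    if group_labels is None:
        group_labels = available
    unknown = [g for g in group_labels if g not in available]
    if unknown:
        raise ValidationError(f"unknown ancestry group label(s): {unknown}")
    out = {}
    for group in group_labels:
        ids = list(ancestry.index[ancestry == group])
        if not ids:
            warnings.warn(f"ancestry group {group} is empty", stacklevel=2)
        out[group] = cohort.subset(ids) if ids else None
    return {g: c for g, c in out.items() if c is not None}
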