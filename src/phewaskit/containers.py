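"""In-memory containers shared across the pipeline.

The pipeline moves three tables between stages:

* :class:`GenotypeMatrix` — samples × SNPs additive dosages (0/1/2, NaN for
  missing) plus per-SNP allele metadata;
* a *diagnosis table* — a long-form :class:`pandas.DataFrame` with columns
  ``sample_id``, ``icd9``, ``n_instances`` (the raw EHR-shaped input);
* a *covariate table* — a :class:`pandas.DataFrame` indexed by sample id with
  columns ``sex``, ``site``, ``platform``, ``ancestry``.

:class:`Cohort` bundles the three together with the simulation ground truth
when the data came from the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAGNOSIS_COLUMNS = ("sample_id", "icd9", "n_instances")
COVARIATE_COLUMNS = ("sex", "site", "platform", "ancestry")


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


@dataclass
class GenotypeMatrix:
    """Samples × SNPs additive dosage matrix.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers (length n).
    snps
        Per-SNP metadata, indexed by SNP id, with columns ``ref``, ``alt`` and
        ``coded_allele`` (the allele counted by the dosage; by convention the
        alternate allele).
    dosage
        ``(n, m)`` float array with entries in {0, 1, 2} and NaN for missing.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample identifiers must be unique")
        if self.snps.index.has_duplicates:
            raise ValidationError("SNP identifiers must be unique")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][:5]
            raise ValidationError(f"dosages must be 0/1/2/NaN; saw {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def sample_indexer(self) -> pd.Index:
        return pd.Index(self.samples)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_indexer().get_indexer(list(sample_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0][:5]
            raise KeyError(f"unknown sample ids: {missing}")
        return GenotypeMatrix(list(sample_ids), self.snps.copy(), self.dosage[idx])

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = self.snps.index.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0][:5]
            raise KeyError(f"unknown SNP ids: {missing}")
        return GenotypeMatrix(self.samples, self.snps.iloc[idx].copy(), self.dosage[:, idx])

    def panel(self, name: str) -> "GenotypeMatrix":
        """Subset to one SNP panel (e.g. 'assoc' vs 'background'); if the
        metadata carries no ``panel`` column, the whole matrix is that panel."""
        if "panel" not in self.snps.columns:
            return self
        keep = (self.snps["panel"] == name).to_numpy()
        return GenotypeMatrix(self.samples, self.snps.loc[keep].copy(), self.dosage[:, keep])

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return np.isnan(self.dosage).mean(axis=1)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.snps.copy(), self.dosage.copy())


def validate_diagnoses(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a long-form diagnosis table.

    Duplicate ``(sample_id, icd9)`` rows are an error: real extracts must be
    pre-aggregated explicitly rather than silently summed.
    """
    missing = [c for c in DIAGNOSIS_COLUMNS if c not in diagnoses.columns]
    if missing:
        raise ValidationError(f"diagnosis table missing columns {missing}")
    out = diagnoses.loc[:, list(DIAGNOSIS_COLUMNS)].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["icd9"] = out["icd9"].astype(str).str.strip()
    counts = pd.to_numeric(out["n_instances"], errors="raise")
    if (counts < 0).any():
        raise ValidationError("instance counts must be non-negative")
    if (counts != counts.round()).any():
        raise ValidationError("instance counts must be integers")
    out["n_instances"] = counts.astype(int)
    dup = out.duplicated(subset=["sample_id", "icd9"])
    if dup.any():
        first = out.loc[dup, ["sample_id", "icd9"]].iloc[0]
        raise ValidationError(
            f"duplicate (sample, code) row: ({first['sample_id']}, {first['icd9']}); "
            "aggregate instance counts before loading"
        )
    return out


def validate_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns {missing}")
    if covariates.index.has_duplicates:
        raise ValidationError("covariate table has duplicate sample ids")
    out = covariates.copy()
    out.index = out.index.astype(str)
    return out


@dataclass
class Cohort:
    """A complete cohort: genotypes, diagnoses, covariates and (optionally)
    the generator's ground truth.

    ``truth`` holds two DataFrames when the cohort is synthetic:
    ``effects`` (snp_id, icd9, log_or) and ``relatives``
    (sample_a, sample_b, relationship, expected_kinship).
    """

    genotypes: GenotypeMatrix
    diagnoses: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diagnoses = validate_diagnoses(self.diagnoses)
        self.covariates = validate_covariates(self.covariates)
        roster = set(self.genotypes.samples)
        if set(self.covariates.index) != roster:
            raise ValidationError("covariate sample ids do not match genotype roster")
        stray = set(self.diagnoses["sample_id"]) - roster
        if stray:
            raise ValidationError(f"diagnosis sample ids not in roster: {sorted(stray)[:5]}")

    @property
    def samples(self) -> list[str]:
        return self.genotypes.samples

    def subset(self, sample_ids) -> "Cohort":
        sample_ids = [str(s) for s in sample_ids]
        keep = set(sample_ids)
        return Cohort(
            genotypes=self.genotypes.subset_samples(sample_ids),
            diagnoses=self.diagnoses[self.diagnoses["sample_id"].isin(keep)].reset_index(drop=True),
            covariates=self.covariates.loc[sample_ids],
            truth=self.truth,
        )
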