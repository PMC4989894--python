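"""ICD-9 instance-count phenotyping.

Case/control assignment per code follows the three-instance rule: a sample is
a *case* for a code if it has ≥3 recorded instances, a *control* if it has
none, and *excluded* (neither) with 1–2 instances — too much evidence to be a
clean control, too little to be a confident case. Codes carried by too few
cases are dropped before association testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ValidationError, validate_diagnoses

CASE, CONTROL, EXCLUDED = 1, 0, -1

_ICD9_RE = re.compile(r"^[VE]?\d{1,4}(?:\.\d{0,2})?$")


@dataclass(frozen=True)
class ICD9Code:
    """An ICD-9 diagnosis code and its 3-digit category.

    The category is the portion before the decimal point ("405.11" → "405",
    "E880.1" → "E880"); codes without a dot are their own category.
    """

    code: str
    category: str

    def __str__(self) -> str:
        return self.code


def parse_icd9(code: str) -> ICD9Code:
    """Parse and normalize an ICD-9 code string.

    Whitespace is stripped; leading zeros are preserved ("008.45" stays
    "008.45"). Malformed strings raise :class:`ValidationError` naming the
    offending value.
    """
    if not isinstance(code, str) or not code.strip():
        raise ValidationError(f"empty or non-string ICD-9 code: {code!r}")
    norm = code.strip()
    body = norm[1:] if norm[:1] in ("V", "E") else norm
    head = body.split(".", 1)[0]
    if not _ICD9_RE.match(norm) or not (2 <= len(norm.split(".", 1)[0]) <= 4) or not head:
        raise ValidationError(f"malformed ICD-9 code: {code!r}")
    return ICD9Code(code=norm, category=norm.split(".", 1)[0])


def assign_case_control(n_instances: int) -> int:
    """Map an instance count to ternary status: ≥3 → case, 0 → control,
    1–2 → excluded."""
    if n_instances < 0:
        raise ValidationError(f"negative instance count: {n_instances}")
    if n_instances >= 3:
        return CASE
    if n_instances == 0:
        return CONTROL
    return EXCLUDED


@dataclass
class PhenotypeMatrix:
    """Samples × ICD-9 codes ternary status matrix.

    ``status`` is an ``(n_samples, n_codes)`` int8 array with values
    ``CASE`` (1), ``CONTROL`` (0), ``EXCLUDED`` (-1). ``removed`` logs codes
    dropped by the prevalence filter.
    """

    samples: list[str]
    codes: list[ICD9Code]
    status: np.ndarray
    min_case_count: int | None = None
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["icd9", "n_case", "reason"])
    )

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.shape != (len(self.samples), len(self.codes)):
            raise ValidationError("status shape does not match samples x codes")

    @property
    def code_strings(self) -> list[str]:
        return [c.code for c in self.codes]

    def column(self, code: str) -> np.ndarray:
        return self.status[:, self.code_strings.index(code)]

    def counts(self) -> pd.DataFrame:
        """Per-code (n_case, n_control, n_excluded); rows always sum to
        n_samples."""
        s = self.status
        return pd.DataFrame(
            {
                "icd9": self.code_strings,
                "category": [c.category for c in self.codes],
                "n_case": (s == CASE).sum(axis=0),
                "n_control": (s == CONTROL).sum(axis=0),
                "n_excluded": (s == EXCLUDED).sum(axis=0),
            }
        )

    def subset_samples(self, sample_ids) -> "PhenotypeMatrix":
        idx = pd.Index(self.samples).get_indexer(list(sample_ids))
        if (idx < 0).any():
            raise KeyError("unknown sample ids in phenotype subset")
        return PhenotypeMatrix(
            list(sample_ids), list(self.codes), self.status[idx], self.min_case_count
        )


def build_phenotype_matrix(diagnoses: pd.DataFrame, samples) -> PhenotypeMatrix:
    """Pivot a long diagnosis table into a ternary status matrix.

    Samples absent from the table for a code have count 0 and become
    controls; the matrix covers the full roster × every observed code.
    Duplicate (sample, code) rows and diagnosis samples outside the roster
    are errors.
    """
    samples = [str(s) for s in samples]
    diagnoses = validate_diagnoses(diagnoses)
    stray = set(diagnoses["sample_id"]) - set(samples)
    if stray:
        raise ValidationError(f"diagnosis sample ids not in roster: {sorted(stray)[:5]}")
    codes = [parse_icd9(c) for c in sorted(diagnoses["icd9"].unique())]
    status = np.full((len(samples), len(codes)), CONTROL, dtype=np.int8)
    if codes:
        row = pd.Index(samples).get_indexer(diagnoses["sample_id"])
        col = pd.Index([c.code for c in codes]).get_indexer(diagnoses["icd9"])
        statuses = diagnoses["n_instances"].map(assign_case_control).to_numpy(dtype=np.int8)
        status[row, col] = statuses
    return PhenotypeMatrix(samples, codes, status)


def filter_low_prevalence(
    matrix: PhenotypeMatrix, min_individuals: int = 10, count: str = "cases"
) -> PhenotypeMatrix:
    """Drop codes present in fewer than ``min_individuals`` individuals.

    ``count="cases"`` (default) interprets "present in" as the number of
    cases (≥3 instances); ``count="carriers"`` counts any sample with ≥1
    instance instead. Dropped codes and their counts are recorded in
    ``removed``.
    """
    if min_individuals < 1:
        raise ValidationError("min_individuals must be ≥ 1")
    if count not in ("cases", "carriers"):
        raise ValidationError(f"count must be 'cases' or 'carriers', got {count!r}")
    s = matrix.status
    if count == "cases":
        present = (s == CASE).sum(axis=0)
    else:
        present = ((s == CASE) | (s == EXCLUDED)).sum(axis=0)
    keep = present >= min_individuals
    removed = pd.DataFrame(
        {
            "icd9": [c.code for c, k in zip(matrix.codes, keep) if not k],
            "n_case": (s == CASE).sum(axis=0)[~keep],
            "reason": f"present in fewer than {min_individuals} individuals ({count})",
        }
    )
    return PhenotypeMatrix(
        samples=list(matrix.samples),
        codes=[c for c, k in zip(matrix.codes, keep) if k],
        status=s[:, keep],
        min_case_count=min_individuals,
        removed=removed,
    )
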