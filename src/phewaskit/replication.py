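"""Two-level replication matching and pleiotropy flagging.

A discovery association replicates when the same SNP shows p < α with the
same direction of genetic effect in the held-out replication half, either
for the *exact* ICD-9 code or for the broader 3-digit *category* (any
sub-code within the category may carry the signal in either dataset; the
minimum-p sub-code represents the category). Replication across independent
halves, rather than a Bonferroni correction, is the error control: the
chance that a null pair passes both halves with concordant direction is
about α²/2.

A SNP whose passing records span two or more distinct categories is a
pleiotropy candidate — one variant associated with multiple phenotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ValidationError

REPLICATION_COLUMNS = [
    "snp_id", "match_level", "icd9_discovery", "icd9_replication", "category",
    "beta_discovery", "p_discovery", "direction_discovery",
    "beta_replication", "p_replication", "direction_replication",
    "converged_discovery", "converged_replication", "passes",
]


def _prepare(results: pd.DataFrame, which: str) -> pd.DataFrame:
    required = {"snp_id", "icd9", "category", "beta", "p", "direction", "converged"}
    missing = required - set(results.columns)
    if missing:
        raise ValidationError(f"{which} results missing columns {sorted(missing)}")
    return results.copy()


def _check_alleles(disc: pd.DataFrame, repl: pd.DataFrame) -> None:
    if "coded_allele" in disc.columns and "coded_allele" in repl.columns:
        d = disc.drop_duplicates("snp_id").set_index("snp_id")["coded_allele"]
        r = repl.drop_duplicates("snp_id").set_index("snp_id")["coded_allele"]
        shared = d.index.intersection(r.index)
        bad = shared[(d.loc[shared] != r.loc[shared])]
        if len(bad):
            raise ValidationError(
                f"allele coding differs between datasets for SNP(s) {list(bad[:5])}"
            )


def match_replication(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.01,
    level: str = "exact",
) -> pd.DataFrame:
    """Pair discovery and replication results and flag passes.

    ``level='exact'`` pairs on (snp, full code); ``level='category'`` pairs
    on (snp, 3-digit category), representing each side by its minimum-p
    sub-code. A pair passes when both p-values are < ``alpha``, the effect
    directions agree, and both fits converged.
    """
    if level not in ("exact", "category"):
        raise ValidationError(f"level must be 'exact' or 'category', got {level!r}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    disc = _prepare(discovery, "discovery")
    repl = _prepare(replication, "replication")
    _check_alleles(disc, repl)

    key = ["snp_id", "icd9"] if level == "exact" else ["snp_id", "category"]
    if level == "category":
        # representative sub-code per (snp, category): the minimum-p result
        disc = disc.sort_values("p", kind="stable").drop_duplicates(key)
        repl = repl.sort_values("p", kind="stable").drop_duplicates(key)
    merged = disc.merge(repl, on=key, how="inner", suffixes=("_discovery", "_replication"))
    if merged.empty:
        return pd.DataFrame(columns=REPLICATION_COLUMNS)
    if level == "exact":
        merged["icd9_discovery"] = merged["icd9"]
        merged["icd9_replication"] = merged["icd9"]
        merged["category"] = merged["category_discovery"]
    merged["match_level"] = level
    merged["passes"] = (
        (merged["p_discovery"] < alpha)
        & (merged["p_replication"] < alpha)
        & (merged["direction_discovery"] == merged["direction_replication"])
        & (merged["direction_discovery"] != 0)
        & merged["converged_discovery"].astype(bool)
        & merged["converged_replication"].astype(bool)
    )
    out = merged.loc[:, REPLICATION_COLUMNS].sort_values(
        ["snp_id", "category", "icd9_discovery"]
    )
    return out.reset_index(drop=True)


def flag_pleiotropy(records: pd.DataFrame) -> pd.DataFrame:
    """SNPs whose passing replication records span ≥2 distinct 3-digit
    categories, with the sorted category list."""
    if records.empty or not records["passes"].any():
        return pd.DataFrame(columns=["snp_id", "n_categories", "categories"])
    passing = records[records["passes"]]
    grouped = passing.groupby("snp_id")["category"].agg(lambda s: sorted(set(s)))
    flagged = grouped[grouped.map(len) >= 2]
    return pd.DataFrame(
        {
            "snp_id": flagged.index,
            "n_categories": flagged.map(len).to_numpy(),
            "categories": flagged.map(lambda c: ",".join(c)).to_numpy(),
        }
    ).reset_index(drop=True)
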