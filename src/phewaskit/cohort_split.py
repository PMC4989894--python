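"""Stratified discovery/replication splitting.

Samples are partitioned into strata by the joint levels of the chosen
covariates (sex, site, platform, ancestry by default) and allocated to the
discovery half proportionately within each stratum, so both halves mirror
the cohort's demographic and technical composition. Relatedness pruning runs
*after* the split, separately per half (see :mod:`phewaskit.genetic_qc`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError

DEFAULT_STRATA = ("sex", "site", "platform", "ancestry")


@dataclass
class SplitResult:
    discovery: list[str]
    replication: list[str]
    allocation: pd.DataFrame  # per-stratum sizes and discovery counts


def _n_discovery(m: int, proportion: float) -> int:
    """Round-to-nearest with .5 ties broken toward discovery (round half up)."""
    return int(math.floor(m * proportion + 0.5))


def stratified_split(
    samples,
    covariates: pd.DataFrame,
    strata_keys=DEFAULT_STRATA,
    proportion: float = 0.5,
    seed: int = 0,
) -> SplitResult:
    """Split a cohort into discovery/replication by proportional allocation
    within strata.

    Within each stratum of size ``m``, exactly ``round(m * proportion)``
    samples (ties toward discovery) are chosen uniformly at random for the
    discovery half. The two outputs are disjoint and cover every sample.
    Singleton strata go to discovery and are noted in the allocation table.
    """
    samples = [str(s) for s in samples]
    if not samples:
        raise ValidationError("cannot split an empty cohort")
    if not (0.0 < proportion < 1.0):
        raise ValidationError(f"proportion must be in (0,1), got {proportion}")
    unknown = [k for k in strata_keys if k not in covariates.columns]
    if unknown:
        raise ValidationError(f"unknown covariate name(s) in strata keys: {unknown}")
    cov = covariates.loc[samples, list(strata_keys)].astype(str)
    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    replication: list[str] = []
    rows = []
    for key, group in cov.groupby(list(strata_keys), sort=True):
        members = sorted(group.index)
        m = len(members)
        n_d = _n_discovery(m, proportion)
        picked = rng.choice(m, size=n_d, replace=False)
        mask = np.zeros(m, dtype=bool)
        mask[picked] = True
        discovery.extend(s for s, d in zip(members, mask) if d)
        replication.extend(s for s, d in zip(members, mask) if not d)
        rows.append((*key, m, n_d, m - n_d, m == 1))
    allocation = pd.DataFrame(
        rows, columns=[*strata_keys, "n_total", "n_discovery", "n_replication", "singleton"]
    )
    return SplitResult(discovery=discovery, replication=replication, allocation=allocation)
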