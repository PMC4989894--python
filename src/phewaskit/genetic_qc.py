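"""Genetic quality control: MAF filtering, method-of-moments kinship, and
genotype PCA.

Kinship follows the classic PLINK moment estimator: per pair, the observed
counts of identity-by-state (IBS) 0/1/2 across SNPs are combined with the
allele-frequency-dependent probabilities of IBS given the identity-by-descent
(IBD) state to solve for P(IBD=0), P(IBD=1), P(IBD=2); the kinship
coefficient is then ``khat = ½ P(IBD=2) + ¼ P(IBD=1)``. Expected values for
duplicates (monozygotic twins), full siblings and unrelated pairs are 0.5,
0.25 and 0. The estimator assumes a homogeneous population at the supplied
allele frequencies and needs a few thousand SNPs to be informative; with a
small panel the sampling noise of ``khat`` swamps the 0.125 pruning
threshold.

PCA standardizes each SNP column by its allele frequency (center ``2p̂``,
scale ``sqrt(2 p̂ (1-p̂))``), imputes missing entries to 0 after
standardization, and takes the top-k left singular vectors — the usual
population-structure covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ValidationError

KINSHIP_MIN_SNPS = 100


def compute_maf(genotypes: GenotypeMatrix) -> pd.Series:
    """Per-SNP minor allele frequency.

    ``f`` is the coded (alt) allele frequency over non-missing genotypes;
    MAF = min(f, 1-f). SNPs with every genotype missing get NaN.
    """
    d = genotypes.dosage
    n_valid = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nansum(d, axis=0) / (2.0 * n_valid)
    maf = np.minimum(f, 1.0 - f)
    maf[n_valid == 0] = np.nan
    return pd.Series(maf, index=genotypes.snps.index, name="maf")


def alt_allele_frequency(genotypes: GenotypeMatrix) -> pd.Series:
    d = genotypes.dosage
    n_valid = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nansum(d, axis=0) / (2.0 * n_valid)
    f[n_valid == 0] = np.nan
    return pd.Series(f, index=genotypes.snps.index, name="alt_freq")


def filter_maf(
    genotypes: GenotypeMatrix, threshold: float = 0.005
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove SNPs with MAF strictly below ``threshold`` (or undefined).

    Returns the filtered matrix and a removal log (snp_id, maf).
    """
    if not (0.0 <= threshold <= 0.5):
        raise ValidationError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    maf = compute_maf(genotypes)
    keep = (maf >= threshold).fillna(False).to_numpy()
    removed = pd.DataFrame(
        {"snp_id": maf.index[~keep], "maf": maf.to_numpy()[~keep]}
    ).reset_index(drop=True)
    kept = GenotypeMatrix(
        genotypes.samples, genotypes.snps.loc[keep].copy(), genotypes.dosage[:, keep]
    )
    return kept, removed


@dataclass
class KinshipMatrix:
    """Pairwise IBS counts and moment kinship estimates.

    All arrays are symmetric ``(n, n)``; the diagonal khat is 0.5 by
    convention and never used for pruning. Pairs with zero jointly
    non-missing SNPs have NaN khat and are listed in ``undefined_pairs``.
    """

    samples: list[str]
    ibs0: np.ndarray
    ibs1: np.ndarray
    ibs2: np.ndarray
    khat: np.ndarray
    missingness: np.ndarray  # per-sample missing fraction, used for prune ties
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def pairs_above(self, threshold: float) -> pd.DataFrame:
        iu = np.triu_indices(len(self.samples), k=1)
        mask = self.khat[iu] > threshold
        ids = np.asarray(self.samples, dtype=object)
        return pd.DataFrame(
            {
                "sample_a": ids[iu[0][mask]],
                "sample_b": ids[iu[1][mask]],
                "khat": self.khat[iu][mask],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.samples), k=1)
        ids = np.asarray(self.samples, dtype=object)
        return pd.DataFrame(
            {
                "sample_a": ids[iu[0]],
                "sample_b": ids[iu[1]],
                "ibs0": self.ibs0[iu].astype(int),
                "ibs1": self.ibs1[iu].astype(int),
                "ibs2": self.ibs2[iu].astype(int),
                "khat": self.khat[iu],
            }
        )


def mom_kinship(genotypes: GenotypeMatrix, allele_freqs: pd.Series | None = None) -> KinshipMatrix:
    """PLINK-style method-of-moments IBD estimation for every sample pair.

    Per SNP with coded-allele frequency p (q = 1-p), the probabilities of the
    observed IBS class given the latent IBD state are::

        P(IBS=0|IBD=0) = 2 p² q²           P(IBS=1|IBD=1) = 2 p q
        P(IBS=1|IBD=0) = 4 p³ q + 4 p q³   P(IBS=2|IBD=1) = p³ + q³ + p q
        P(IBS=2|IBD=0) = p⁴ + q⁴ + 4 p² q² P(IBS=2|IBD=2) = 1

    Summing these over the jointly non-missing SNPs of a pair gives expected
    IBS counts per IBD state; the moment equations are solved sequentially
    for P(IBD=0), P(IBD=1), P(IBD=2), the solution is truncated to the
    probability simplex, and ``khat = ½ P2 + ¼ P1`` is clamped to [0, 0.5].
    """
    n, m = genotypes.n_samples, genotypes.n_snps
    if m < KINSHIP_MIN_SNPS:
        warnings.warn(
            f"kinship estimated from only {m} SNPs (<{KINSHIP_MIN_SNPS}); "
            "estimates will be noisy",
            stacklevel=2,
        )
    if allele_freqs is None:
        p = alt_allele_frequency(genotypes).to_numpy()
    else:
        p = allele_freqs.reindex(genotypes.snps.index).to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValidationError("allele frequency undefined for some SNPs")
    q = 1.0 - p
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd1 = 2 * p * q
    e2_ibd1 = p**3 + q**3 + p * q

    d = genotypes.dosage
    valid = (~np.isnan(d)).astype(float)
    a0 = np.nan_to_num((d == 0).astype(float))
    a1 = np.nan_to_num((d == 1).astype(float))
    a2 = np.nan_to_num((d == 2).astype(float))

    ibs0 = a0 @ a2.T + a2 @ a0.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    n_valid = valid @ valid.T
    ibs1 = n_valid - ibs0 - ibs2

    def pair_expect(e: np.ndarray) -> np.ndarray:
        return (valid * e) @ valid.T

    E0_0, E1_0, E2_0 = pair_expect(e0_ibd0), pair_expect(e1_ibd0), pair_expect(e2_ibd0)
    E1_1, E2_1 = pair_expect(e1_ibd1), pair_expect(e2_ibd1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = ibs0 / E0_0
        p1 = (ibs1 - p0 * E1_0) / E1_1
        p2 = (ibs2 - p0 * E2_0 - p1 * E2_1) / n_valid
    # truncate to the probability simplex
    p0, p1, p2 = (np.clip(x, 0.0, 1.0) for x in (p0, p1, p2))
    total = p0 + p1 + p2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = p1 / total, p2 / total
    khat = np.clip(0.5 * p2 + 0.25 * p1, 0.0, 0.5)
    khat[n_valid == 0] = np.nan
    np.fill_diagonal(khat, 0.5)

    iu = np.triu_indices(n, k=1)
    undef = np.isnan(khat[iu])
    ids = np.asarray(genotypes.samples, dtype=object)
    undefined_pairs = list(zip(ids[iu[0][undef]], ids[iu[1][undef]]))
    return KinshipMatrix(
        samples=list(genotypes.samples),
        ibs0=ibs0,
        ibs1=ibs1,
        ibs2=ibs2,
        khat=khat,
        missingness=genotypes.missing_fraction_per_sample(),
        undefined_pairs=undefined_pairs,
    )


def prune_related(kinship: KinshipMatrix, threshold: float = 0.125) -> tuple[list[str], list[str]]:
    """Greedy relatedness pruning: while any pair exceeds the threshold,
    remove the member with more above-threshold partners (ties broken by
    larger missingness, then lexicographically larger id).

    Returns (kept ids, removed ids); the kept set contains no pair with
    ``khat > threshold``.
    """
    n = len(kinship.samples)
    adj = np.triu(np.nan_to_num(kinship.khat, nan=0.0) > threshold, k=1)
    adj = adj | adj.T
    alive = np.ones(n, dtype=bool)
    removed: list[str] = []
    ids = kinship.samples
    while True:
        degree = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        degree[~alive] = 0
        if degree.max(initial=0) == 0:
            break
        top = degree == degree.max()
        cand = np.flatnonzero(top)
        miss = kinship.missingness[cand]
        cand = cand[miss == miss.max()]
        victim = max(cand, key=lambda i: ids[i])
        alive[victim] = False
        removed.append(ids[victim])
    kept = [s for s, a in zip(ids, alive) if a]
    return kept, removed


@dataclass
class PCResult:
    """Top-k genotype principal components.

    ``scores`` (samples × k) are the per-sample coordinates used as ancestry
    covariates; ``loadings`` (SNPs × k) are orthonormal; ``eigenvalues`` are
    the nonincreasing eigenvalues of the standardized sample covariance.
    """

    samples: list[str]
    snp_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=pd.Index(self.samples, name="sample_id"), columns=cols)


def genotype_pca(genotypes: GenotypeMatrix, k: int = 3) -> PCResult:
    """Principal components of allele-frequency-standardized genotypes.

    Each SNP column is centered by ``2 p̂`` and scaled by
    ``sqrt(2 p̂ (1 - p̂))`` with ``p̂`` the sample alt-allele frequency;
    missing entries are set to 0 (the post-standardization mean).
    Monomorphic SNPs carry no information and are dropped. If ``k`` exceeds
    the matrix rank, it is reduced with a warning. Each component's sign is
    fixed so its largest-magnitude loading is positive.
    """
    d = genotypes.dosage
    p = alt_allele_frequency(genotypes).to_numpy()
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = np.isfinite(scale) & (scale > 0)
    if not poly.any():
        raise ValidationError("no polymorphic SNPs available for PCA")
    z = (d[:, poly] - 2.0 * p[poly]) / scale[poly]
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        warnings.warn(f"requested {k} PCs but rank is {rank}; returning {rank}", stacklevel=2)
        k = rank
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-magnitude loading positive per component
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    loadings = (vt * flip[:, None]).T
    eigenvalues = s**2 / max(z.shape[1], 1)
    snp_ids = [sid for sid, keep in zip(genotypes.snp_ids, poly) if keep]
    return PCResult(
        samples=list(genotypes.samples),
        snp_ids=snp_ids,
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
    )
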