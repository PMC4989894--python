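"""MAF computation/filtering, moment kinship on simulated relatives, greedy
pruning, and population-structure PCA."""

import numpy as np
import pandas as pd
import pytest

from phewaskit.containers import GenotypeMatrix, ValidationError
from phewaskit.genetic_qc import (
    KinshipMatrix,
    compute_maf,
    filter_maf,
    genotype_pca,
    mom_kinship,
    prune_related,
)
from phewaskit.simulate import SimulationConfig, SnpSpec, CodeSpec, simulate_cohort


def _geno(dosage, samples=None):
    dosage = np.asarray(dosage, dtype=float)
    samples = samples or [f"S{i}" for i in range(dosage.shape[0])]
    snps = pd.DataFrame(
        {"ref": "A", "alt": "T", "coded_allele": "T"},
        index=pd.Index([f"snp{j}" for j in range(dosage.shape[1])], name="snp_id"),
    )
    return GenotypeMatrix(samples, snps, dosage)


@pytest.mark.parametrize(
    "column,expected",
    [
        ([0, 0, 1, 2], 0.375),
        ([2, 2, 2, 1], 0.125),  # folded: alt frequency 7/8
        ([0, 0, 0, 0], 0.0),
        ([0, np.nan, 1, 2], 0.5),  # missing excluded from both sides
    ],
)
def test_compute_maf(column, expected):
    g = _geno(np.array(column, dtype=float)[:, None])
    assert compute_maf(g).iloc[0] == pytest.approx(expected)


def test_all_missing_snp_flagged():
    g = _geno(np.full((3, 1), np.nan))
    assert np.isnan(compute_maf(g).iloc[0])
    filtered, removed = filter_maf(g, 0.005)
    assert filtered.n_snps == 0
    assert removed["snp_id"].tolist() == ["snp0"]


def test_filter_maf_boundary():
    """'Below 0.005' removes 0.004 and keeps exactly 0.005."""
    n = 1000
    col_low = np.r_[np.ones(8), np.zeros(n - 8)]  # f = 8/2000 = 0.004
    col_edge = np.r_[np.ones(10), np.zeros(n - 10)]  # f = 10/2000 = 0.005
    g = _geno(np.column_stack([col_low, col_edge]))
    kept, removed = filter_maf(g, 0.005)
    assert kept.snp_ids == ["snp1"]
    assert removed["snp_id"].tolist() == ["snp0"]
    identity, removed0 = filter_maf(g, 0.0)
    assert identity.n_snps == 2 and removed0.empty


def test_filter_maf_idempotent(small_cohort):
    once, _ = filter_maf(small_cohort.genotypes, 0.05)
    twice, removed = filter_maf(once, 0.05)
    assert twice.snp_ids == once.snp_ids
    assert removed.empty


@pytest.fixture(scope="module")
def kinship_cohort():
    """30 samples x 5000 SNPs with one duplicate and one sibling pair."""
    config = SimulationConfig(
        n_samples=30,
        snp_specs=[SnpSpec("rs0", 0.3)],
        code_specs=[CodeSpec("272.1", 0.1)],
        n_background_snps=5000,
        background_maf_range=(0.05, 0.5),
        related_pairs=[("duplicate", 1), ("full_sib", 1)],
        seed=99,
    )
    return simulate_cohort(config)


def test_moment_kinship_recovers_relationships(kinship_cohort):
    geno = kinship_cohort.genotypes.panel("background")
    kin = mom_kinship(geno)
    truth = kinship_cohort.truth["relatives"].set_index("relationship")
    idx = pd.Index(geno.samples)

    def khat(a, b):
        return kin.khat[idx.get_loc(a), idx.get_loc(b)]

    dup = truth.loc["duplicate"]
    sib = truth.loc["full_sib"]
    assert khat(dup["sample_a"], dup["sample_b"]) == pytest.approx(0.5, abs=0.02)
    assert khat(sib["sample_a"], sib["sample_b"]) == pytest.approx(0.25, abs=0.03)
    related = {frozenset((r["sample_a"], r["sample_b"])) for _, r in
               kinship_cohort.truth["relatives"].iterrows()}
    iu = np.triu_indices(geno.n_samples, k=1)
    for i, j in zip(*iu):
        if frozenset((geno.samples[i], geno.samples[j])) not in related:
            assert kin.khat[i, j] < 0.05
    # symmetry and simplex truncation
    np.testing.assert_allclose(kin.khat, kin.khat.T)
    assert np.nanmax(kin.khat) <= 0.5 and np.nanmin(kin.khat) >= 0.0


def test_kinship_warns_on_tiny_panel():
    g = _geno(np.random.default_rng(1).binomial(2, 0.3, size=(5, 20)).astype(float))
    with pytest.warns(UserWarning, match="noisy"):
        mom_kinship(g)


def _kin_from_matrix(samples, khat, missingness=None):
    n = len(samples)
    z = np.zeros((n, n))
    return KinshipMatrix(
        samples=samples,
        ibs0=z,
        ibs1=z,
        ibs2=z,
        khat=np.asarray(khat, dtype=float),
        missingness=np.zeros(n) if missingness is None else np.asarray(missingness, float),
    )


def test_prune_removes_one_member_per_pair():
    khat = np.array([[0.5, 0.45, 0.0], [0.45, 0.5, 0.0], [0.0, 0.0, 0.5]])
    kept, removed = prune_related(_kin_from_matrix(["A", "B", "C"], khat))
    assert len(removed) == 1 and removed[0] in {"A", "B"}
    assert "C" in kept


def test_prune_triangle_degree_greedy():
    """A-B and B-C above threshold, A-C below: only B (degree 2) removed."""
    khat = np.array([[0.5, 0.2, 0.05], [0.2, 0.5, 0.2], [0.05, 0.2, 0.5]])
    kept, removed = prune_related(_kin_from_matrix(["A", "B", "C"], khat))
    assert removed == ["B"]
    assert kept == ["A", "C"]


def test_prune_identity_and_certification(kinship_cohort):
    none_above = _kin_from_matrix(["A", "B"], np.array([[0.5, 0.1], [0.1, 0.5]]))
    kept, removed = prune_related(none_above)
    assert kept == ["A", "B"] and removed == []

    kin = mom_kinship(kinship_cohort.genotypes.panel("background"))
    kept, removed = prune_related(kin, 0.125)
    assert len(removed) == 2  # one per related pair
    idx = {s: i for i, s in enumerate(kin.samples)}
    survivors = [idx[s] for s in kept]
    sub = kin.khat[np.ix_(survivors, survivors)]
    np.fill_diagonal(sub, 0.0)
    assert np.nanmax(sub) <= 0.125


def _two_pop_genotypes(rng, n_per=500, m=200, diff_sd=0.1):
    """Two subpopulations whose per-SNP allele frequencies differ by
    delta ~ N(0, diff_sd^2), applied symmetrically about a low-frequency
    base drawn U(0.05, 0.2)."""
    base = rng.uniform(0.05, 0.2, size=m)
    delta = rng.normal(0, diff_sd, size=m)
    pa = np.clip(base - delta / 2, 0.005, 0.995)
    pb = np.clip(base + delta / 2, 0.005, 0.995)
    d = np.vstack(
        [rng.binomial(2, pa, size=(n_per, m)), rng.binomial(2, pb, size=(n_per, m))]
    ).astype(float)
    return _geno(d), np.r_[np.zeros(n_per), np.ones(n_per)]


def test_pca_separates_two_populations(rng):
    g, labels = _two_pop_genotypes(rng)
    pcs = genotype_pca(g, k=3)
    pc1 = pcs.scores[:, 0]
    between = abs(pc1[labels == 0].mean() - pc1[labels == 1].mean())
    within = max(pc1[labels == 0].std(), pc1[labels == 1].std())
    assert between > 5 * within
    # orthonormal loadings, zero-mean scores, sorted eigenvalues
    np.testing.assert_allclose(pcs.loadings.T @ pcs.loadings, np.eye(3), atol=1e-8)
    np.testing.assert_allclose(pcs.scores.mean(axis=0), 0.0, atol=1e-8)
    assert (np.diff(pcs.eigenvalues) <= 1e-12).all()


def test_pca_homogeneous_population_no_dominant_axis(rng):
    d = rng.binomial(2, rng.uniform(0.2, 0.4, size=50), size=(500, 50)).astype(float)
    pcs = genotype_pca(_geno(d), k=2)
    assert pcs.eigenvalues[0] / pcs.eigenvalues[1] < 2


def test_pca_equivariant_under_sample_permutation(rng):
    g, _ = _two_pop_genotypes(rng, n_per=50, m=60)
    pcs = genotype_pca(g, k=2)
    perm = rng.permutation(g.n_samples)
    gp = GenotypeMatrix([g.samples[i] for i in perm], g.snps.copy(), g.dosage[perm])
    pcs_p = genotype_pca(gp, k=2)
    np.testing.assert_allclose(pcs_p.scores, pcs.scores[perm], atol=1e-8)


def test_pca_reduces_k_beyond_rank(rng):
    d = rng.binomial(2, 0.3, size=(6, 3)).astype(float)
    with pytest.warns(UserWarning, match="rank"):
        pcs = genotype_pca(_geno(d), k=5)
    assert pcs.scores.shape[1] <= 3


def test_maf_threshold_validation(small_cohort):
    with pytest.raises(ValidationError, match="threshold"):
        filter_maf(small_cohort.genotypes, 0.7)
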