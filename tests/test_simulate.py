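"""Generator contracts: HWE genotype frequencies, the latent disease model,
instance-count noise modes, relatives, determinism, and config validation."""

import numpy as np
import pytest

from conftest import small_config
from phewaskit.containers import ValidationError
from phewaskit.firth import fit_standard_logistic
from phewaskit.simulate import (
    CodeSpec,
    SimulationConfig,
    SnpSpec,
    inject_relatives,
    simulate_cohort,
    simulate_covariates,
    simulate_diagnoses,
    simulate_genotypes,
)


def _config(**overrides):
    return small_config(**overrides)


def test_hwe_genotype_frequencies():
    """maf=0.2 gives genotype frequencies (0.64, 0.32, 0.04) at large n."""
    cfg = SimulationConfig(
        n_samples=50000,
        snp_specs=[SnpSpec("rs0", 0.2)],
        code_specs=[CodeSpec("272.1", 0.1)],
        seed=5,
    )
    g = simulate_genotypes(cfg, simulate_covariates(cfg)).dosage[:, 0]
    n = g.size
    for dose, expected in ((0, 0.64), (1, 0.32), (2, 0.04)):
        frac = (g == dose).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se + 1e-12


def test_symmetric_maf_half():
    cfg = SimulationConfig(
        n_samples=100000,
        snp_specs=[SnpSpec("rs0", 0.5)],
        code_specs=[CodeSpec("272.1", 0.1)],
        seed=6,
    )
    g = simulate_genotypes(cfg, simulate_covariates(cfg)).dosage[:, 0]
    freq = g.mean() / 2
    se = np.sqrt(0.25 / (2 * g.size))
    assert abs(freq - 0.5) < 3 * se


def test_determinism_under_seed():
    c1 = simulate_cohort(_config())
    c2 = simulate_cohort(_config())
    np.testing.assert_array_equal(c1.genotypes.dosage, c2.genotypes.dosage)
    assert c1.diagnoses.equals(c2.diagnoses)
    assert c1.covariates.equals(c2.covariates)
    c3 = simulate_cohort(_config(seed=8))
    assert not np.array_equal(c1.genotypes.dosage, c3.genotypes.dosage)


def test_adding_snps_does_not_perturb_other_streams():
    """Per-label stream forking: extra SNPs leave existing genotype columns
    and diagnosis draws untouched."""
    base = simulate_cohort(_config(related_pairs=[]))
    more = simulate_cohort(
        _config(
            related_pairs=[],
            snp_specs=[SnpSpec(f"rs{i}", 0.2) for i in range(6)],
        )
    )
    for snp in ("rs0", "rs1", "rs2", "rs3"):
        np.testing.assert_array_equal(
            base.genotypes.subset_snps([snp]).dosage,
            more.genotypes.subset_snps([snp]).dosage,
        )
    assert base.diagnoses.equals(more.diagnoses)


def test_duplicate_pair_identical_and_zero_pairs_identity():
    cfg = _config(related_pairs=[("duplicate", 1)])
    cov = simulate_covariates(cfg)
    geno = simulate_genotypes(cfg, cov)
    out, truth = inject_relatives(geno, cfg.related_pairs, cfg, cov)
    a, b = truth.iloc[0][["sample_a", "sample_b"]]
    ia, ib = out.samples.index(a), out.samples.index(b)
    np.testing.assert_array_equal(out.dosage[ia], out.dosage[ib])

    same, truth0 = inject_relatives(geno, [], cfg, cov)
    np.testing.assert_array_equal(same.dosage, geno.dosage)
    assert truth0.empty


def test_too_many_pairs_rejected():
    cfg = _config()
    cov = simulate_covariates(cfg)
    geno = simulate_genotypes(cfg, cov)
    with pytest.raises(ValidationError, match="pairs"):
        inject_relatives(geno, [("duplicate", 1000)], cfg, cov)


def test_noise_free_counts_are_zero_or_at_least_three():
    cohort = simulate_cohort(_config(epsilon_undercount=0.0, delta_ruleout=0.0))
    counts = cohort.diagnoses["n_instances"]
    assert ((counts == 0) | (counts >= 3)).all()


def test_null_prevalence_with_undercount():
    """Null code at prevalence 0.1 with undercount epsilon: the fraction of
    samples reaching >=3 instances is 0.1*(1-eps)."""
    eps = 0.1
    cfg = SimulationConfig(
        n_samples=20000,
        snp_specs=[SnpSpec("rs0", 0.2)],
        code_specs=[CodeSpec("272.1", 0.1)],
        epsilon_undercount=eps,
        seed=17,
    )
    cov = simulate_covariates(cfg)
    geno = simulate_genotypes(cfg, cov)
    diag, _ = simulate_diagnoses(geno, cov, cfg)
    n_case = (diag["n_instances"] >= 3).sum()
    expected = 0.1 * (1 - eps)
    se = np.sqrt(expected * (1 - expected) / cfg.n_samples)
    assert abs(n_case / cfg.n_samples - expected) < 3 * se


def test_planted_effect_recovered_on_latent_disease():
    """OR=2 planted on (rs0, 272.1): logistic fit on the latent disease
    indicator recovers log 2."""
    cfg = _config(n_samples=20000, related_pairs=[], seed=23)
    cohort = simulate_cohort(cfg)
    d = cohort.truth["latent"]["272.1"].to_numpy(dtype=float)
    g = cohort.genotypes.subset_snps(["rs0"]).dosage[:, 0]
    fit = fit_standard_logistic(np.column_stack([np.ones(g.size), g]), d, tol=1e-8)
    assert fit.converged
    # simulation error ~ SE of the estimate
    assert fit.beta[1] == pytest.approx(np.log(2.0), abs=4 * fit.se[1])


def test_config_validation_errors():
    with pytest.raises(ValidationError, match="MAF"):
        SimulationConfig(
            n_samples=10,
            snp_specs=[SnpSpec("rs0", 0.6)],
            code_specs=[CodeSpec("272.1", 0.1)],
        )
    with pytest.raises(ValidationError, match="unknown SNP"):
        SimulationConfig(
            n_samples=10,
            snp_specs=[SnpSpec("rs0", 0.2)],
            code_specs=[CodeSpec("272.1", 0.1, effects=[("rsX", 2.0)])],
        )
    with pytest.raises(ValidationError, match="odds ratio"):
        SimulationConfig(
            n_samples=10,
            snp_specs=[SnpSpec("rs0", 0.2)],
            code_specs=[CodeSpec("272.1", 0.1, effects=[("rs0", -1.0)])],
        )
    with pytest.raises(ValidationError, match="epsilon"):
        SimulationConfig(
            n_samples=10,
            snp_specs=[SnpSpec("rs0", 0.2)],
            code_specs=[CodeSpec("272.1", 0.1)],
            epsilon_undercount=1.5,
        )


def test_config_yaml_roundtrip(tmp_path):
    raw = """
n_samples: 50
seed: 3
snp_specs:
  - {snp_id: rs1, maf: 0.3}
  - {snp_id: rs2, maf: {EA: 0.2, AA: 0.4}}
code_specs:
  - {icd9: "272.1", baseline_prevalence: 0.1, effects: [[rs1, 2.0]]}
ancestry_groups: {EA: 0.7, AA: 0.3}
related_pairs: [[duplicate, 1]]
"""
    path = tmp_path / "sim.yaml"
    path.write_text(raw)
    cfg = SimulationConfig.from_yaml(path)
    assert cfg.n_samples == 50
    assert cfg.snp_specs[1].maf_for("AA") == 0.4
    assert cfg.code_specs[0].effects == [("rs1", 2.0)]
    cohort = simulate_cohort(cfg)
    assert cohort.genotypes.n_samples == 50


def test_cohort_roster_consistency(small_cohort):
    roster = set(small_cohort.samples)
    assert set(small_cohort.covariates.index) == roster
    assert set(small_cohort.diagnoses["sample_id"]) <= roster
    vals = small_cohort.genotypes.dosage
    vals = vals[~np.isnan(vals)]
    assert np.isin(vals, (0.0, 1.0, 2.0)).all()
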