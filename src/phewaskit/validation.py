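"""Self-validation benchmarks.

Each function runs one documented check of the pipeline on synthetic or
closed-form inputs at its standard problem size and returns the measured
quantities; the test suite asserts tolerances on them and
``scripts/acceptance.py`` reports them. The study conditions (sample sizes,
allele frequencies, prevalences, effect sizes) are fixed here; only the seed
varies.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import kstest

from .cohort_split import stratified_split
from .containers import GenotypeMatrix
from .engine import run_phewas
from .firth import fit_firth, penalized_loglik
from .genetic_qc import genotype_pca, mom_kinship
from .phenotyping import build_phenotype_matrix, filter_low_prevalence
from .pipeline import PipelineConfig, run_pipeline
from .replication import match_replication
from .simulate import CodeSpec, SimulationConfig, SnpSpec, simulate_cohort


def firth_intercept_benchmark(n_max: int = 50) -> dict:
    """Max |pi_hat - (k+1/2)/(n+1)| over intercept-only fits for all
    k in {0..n}, n in {1..n_max}."""
    worst = 0.0
    count = 0
    for n in range(1, n_max + 1):
        X = np.ones((n, 1))
        for k in range(n + 1):
            y = np.r_[np.ones(k), np.zeros(n - k)]
            fit = fit_firth(X, y, tol=1e-10)
            worst = max(worst, abs(expit(fit.beta[0]) - (k + 0.5) / (n + 1)))
            count += 1
    return {"max_abs_error": worst, "n_fits": count}


def firth_2x2_benchmark(n_tables: int = 20, seed: int = 0) -> dict:
    """Max |slope - add-half log OR| over random saturated 2x2 tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = rng.integers(1, 40, size=4)
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = fit_firth(np.column_stack([np.ones(x.size), x]), y, tol=1e-10)
        expected = np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
        worst = max(worst, abs(fit.beta[1] - expected))
    return {"max_abs_error": worst, "n_tables": n_tables}


def _grid_maximize(X, y, k, points=13, rounds=7, half_width=6.0):
    centers = np.zeros(k)
    width = 2 * half_width
    best = centers
    for _ in range(rounds):
        axes = [np.linspace(c - width / 2, c + width / 2, points) for c in centers]
        best_val = -np.inf
        for beta in itertools.product(*axes):
            val = penalized_loglik(X, y, np.array(beta))
            if val > best_val:
                best_val, best = val, np.array(beta)
        centers = best
        width = width / (points - 1) * 2.5
    return best


def grid_oracle_benchmark(n_datasets: int = 5, seed: int = 0) -> dict:
    """Max per-coefficient gap between the Newton solution and dense grid
    maximization of the penalized likelihood on small random datasets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(12, 31))
        k = int(rng.integers(1, 3))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_firth(X, y, tol=1e-10)
        oracle = _grid_maximize(X, y, k + 1)
        worst = max(worst, float(np.max(np.abs(fit.beta - oracle))))
    return {"max_gap": worst, "n_datasets": n_datasets}


def _null_sweep_config(n: int, n_snps: int, n_codes: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_samples=n,
        snp_specs=[SnpSpec(f"rs{i:02d}", 0.2) for i in range(n_snps)],
        code_specs=[CodeSpec(f"{400 + j // 5}.{j % 5}", 0.1) for j in range(n_codes)],
        sites={"siteA": 0.5, "siteB": 0.3, "siteC": 0.2},
        platforms={"chip1": 0.6, "chip2": 0.4},
        ancestry_groups={"EA": 0.8, "AA": 0.2},
        n_background_snps=200,
        background_structure_sd=0.05,
        epsilon_undercount=0.03,
        delta_ruleout=0.02,
        seed=seed,
    )


def null_type1_benchmark(
    n: int = 2000, n_snps: int = 10, n_codes: int = 100, alpha: float = 0.01, seed: int = 0
) -> dict:
    """Type-I error of the full covariate-adjusted sweep on an all-null
    cohort: rejection rate at ``alpha`` over n_snps x n_codes fits, plus the
    Kolmogorov-Smirnov p-value for uniformity of the null p-values."""
    cohort = simulate_cohort(_null_sweep_config(n, n_snps, n_codes, seed))
    matrix = filter_low_prevalence(
        build_phenotype_matrix(cohort.diagnoses, cohort.samples), 10
    )
    pcs = genotype_pca(cohort.genotypes.panel("background"), 3).scores_frame()
    results = run_phewas(
        cohort.genotypes.panel("assoc"),
        matrix,
        cohort.covariates,
        pcs,
        check_separation=False,
    )
    ok = results["converged"] & results["p"].notna()
    pvals = results.loc[ok, "p"].to_numpy()
    ks = kstest(pvals, "uniform")
    return {
        "rejection_rate": float((pvals < alpha).mean()),
        "ks_pvalue": float(ks.pvalue),
        "n_fits": int(ok.sum()),
        "n_samples": n,
    }


def effect_recovery_benchmark(
    n: int = 4000,
    n_replicates: int = 200,
    odds_ratio: float = 1.5,
    maf: float = 0.2,
    prevalence: float = 0.1,
    seed: int = 0,
) -> dict:
    """Bias and Wald-CI coverage of the Firth dosage estimate under a
    planted log-additive effect, over independent replicate cohorts."""
    beta_true = np.log(odds_ratio)
    betas, covered = [], 0
    for r in range(n_replicates):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 7001, r])
        g = rng.binomial(2, maf, size=n).astype(float)
        eta = logit(prevalence) + beta_true * (g - g.mean())
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = fit_firth(np.column_stack([np.ones(n), g]), y)
        summ = fit.wald_summary("x1")
        betas.append(summ["beta"])
        if np.log(summ["ci_low"]) <= beta_true <= np.log(summ["ci_high"]):
            covered += 1
    mean_beta = float(np.mean(betas))
    return {
        "mean_beta": mean_beta,
        "true_beta": float(beta_true),
        "relative_bias": float(mean_beta / beta_true - 1.0),
        "ci_coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "n_samples": n,
    }


def kinship_benchmark(n_snps: int = 5000, n_samples: int = 30, seed: int = 0) -> dict:
    """Moment-kinship estimates for a duplicate pair, a Mendelian full-sib
    pair, and the worst unrelated pair, at ``n_snps`` SNPs."""
    config = SimulationConfig(
        n_samples=n_samples,
        snp_specs=[SnpSpec("rs0", 0.3)],
        code_specs=[CodeSpec("272.1", 0.1)],
        n_background_snps=n_snps,
        background_maf_range=(0.05, 0.5),
        related_pairs=[("duplicate", 1), ("full_sib", 1)],
        seed=seed,
    )
    cohort = simulate_cohort(config)
    geno = cohort.genotypes.panel("background")
    kin = mom_kinship(geno)
    idx = pd.Index(geno.samples)
    truth = cohort.truth["relatives"].set_index("relationship")
    dup = truth.loc["duplicate"]
    sib = truth.loc["full_sib"]
    related = {
        frozenset((r["sample_a"], r["sample_b"]))
        for _, r in cohort.truth["relatives"].iterrows()
    }
    iu = np.triu_indices(geno.n_samples, k=1)
    unrelated = [
        kin.khat[i, j]
        for i, j in zip(*iu)
        if frozenset((geno.samples[i], geno.samples[j])) not in related
    ]
    return {
        "duplicate_khat": float(kin.khat[idx.get_loc(dup["sample_a"]), idx.get_loc(dup["sample_b"])]),
        "full_sib_khat": float(kin.khat[idx.get_loc(sib["sample_a"]), idx.get_loc(sib["sample_b"])]),
        "max_unrelated_khat": float(np.max(unrelated)),
        "n_snps": n_snps,
    }


def pca_separation_benchmark(
    n_per_group: int = 500, n_snps: int = 200, diff_sd: float = 0.1, seed: int = 0
) -> dict:
    """PC1 group-mean separation (in units of within-group SD) for two
    subpopulations whose per-SNP allele frequencies differ by
    delta ~ N(0, diff_sd^2) applied symmetrically about a base frequency
    drawn U(0.05, 0.2)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 8001])
    base = rng.uniform(0.05, 0.2, size=n_snps)
    delta = rng.normal(0, diff_sd, size=n_snps)
    pa = np.clip(base - delta / 2, 0.005, 0.995)
    pb = np.clip(base + delta / 2, 0.005, 0.995)
    d = np.vstack(
        [
            rng.binomial(2, pa, size=(n_per_group, n_snps)),
            rng.binomial(2, pb, size=(n_per_group, n_snps)),
        ]
    ).astype(float)
    snps = pd.DataFrame(
        {"ref": "A", "alt": "T", "coded_allele": "T"},
        index=pd.Index([f"s{j}" for j in range(n_snps)], name="snp_id"),
    )
    geno = GenotypeMatrix([f"S{i}" for i in range(2 * n_per_group)], snps, d)
    pc1 = genotype_pca(geno, 3).scores[:, 0]
    labels = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    between = abs(pc1[labels == 0].mean() - pc1[labels == 1].mean())
    within = max(pc1[labels == 0].std(), pc1[labels == 1].std())
    return {"separation_ratio": float(between / within), "n_snps": n_snps}


def split_balance_benchmark(n_configs: int = 100, seed: int = 0) -> dict:
    """Per-stratum |n_discovery - n_replication| and the partition property
    across random stratification configurations at proportion 0.5."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 9001])
    max_imbalance = 0
    partitions_ok = True
    for _ in range(n_configs):
        n_strata = int(rng.integers(1, 8))
        sizes = rng.integers(1, 60, size=n_strata)
        site = np.repeat([f"st{j}" for j in range(n_strata)], sizes)
        ids = [f"S{i}" for i in range(site.size)]
        cov = pd.DataFrame(
            {"sex": "F", "site": site, "platform": "p", "ancestry": "EA"},
            index=pd.Index(ids, name="sample_id"),
        )
        res = stratified_split(ids, cov, proportion=0.5, seed=int(rng.integers(2**31)))
        imb = (res.allocation["n_discovery"] - res.allocation["n_replication"]).abs().max()
        max_imbalance = max(max_imbalance, int(imb))
        disc, repl = set(res.discovery), set(res.replication)
        partitions_ok &= disc.isdisjoint(repl) and (disc | repl == set(ids))
    return {"max_imbalance": max_imbalance, "partitions_ok": bool(partitions_ok), "n_configs": n_configs}


PLANTED_EFFECTS = [("rs00", "272.1", 2.0), ("rs01", "401.1", 2.0), ("rs02", "733.0", 2.0)]


def end_to_end_config(n_samples: int = 10000, seed: int = 0) -> SimulationConfig:
    """The end-to-end study cohort: 20 association SNPs, 100 hierarchical
    ICD-9 codes across 40 categories, three planted replicable effects
    (OR 2.0 at prevalence 0.15) on distinct (SNP, category) pairs, site
    confounding on one null code, and both instance-count noise modes."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 6001])
    snps = [
        SnpSpec(f"rs{i:02d}", 0.25 if i < 3 else float(rng.uniform(0.1, 0.4)))
        for i in range(20)
    ]
    planted = {code: (snp, or_) for snp, code, or_ in PLANTED_EFFECTS}
    # 97 null codes over 37 categories disjoint from the planted ones
    categories = [str(c) for c in range(500, 537)]
    codes = list(planted)
    sub_counter = {}
    for j in range(97):
        cat = categories[j % len(categories)]
        sub = sub_counter.get(cat, 0)
        sub_counter[cat] = sub + 1
        codes.append(f"{cat}.{sub}")
    code_specs = []
    for code in codes:
        if code in planted:
            snp, or_ = planted[code]
            code_specs.append(CodeSpec(code, 0.15, effects=[(snp, or_)]))
        else:
            code_specs.append(CodeSpec(code, float(rng.uniform(0.03, 0.2))))
    return SimulationConfig(
        n_samples=n_samples,
        snp_specs=snps,
        code_specs=code_specs,
        sites={"siteA": 0.5, "siteB": 0.3, "siteC": 0.2},
        platforms={"chip1": 0.6, "chip2": 0.4},
        ancestry_groups={"EA": 0.8, "AA": 0.2},
        site_code_multipliers={("siteB", codes[10]): 2.0},
        n_background_snps=300,
        background_structure_sd=0.05,
        epsilon_undercount=0.03,
        delta_ruleout=0.02,
        seed=seed,
    )


def end_to_end_benchmark(out_dir, n_samples: int = 10000, seed: int = 0) -> dict:
    """Run the full pipeline on the end-to-end cohort and compare the
    category-level replication passes against the planted truth.

    Kinship pruning is off: the cohort carries no related pairs and the
    20-SNP association panel is far below the panel size the moment
    estimator needs (see the kinship benchmark, which runs at 5000 SNPs).
    """
    cohort = simulate_cohort(end_to_end_config(n_samples, seed))
    config = PipelineConfig(
        genotypes="-",
        diagnoses="-",
        covariates="-",
        out_dir=str(out_dir),
        kinship_enabled=False,
        check_separation=False,
        seed=seed,
    )
    out = run_pipeline(config, cohort=cohort)
    records = pd.read_csv(out / "replication_category.tsv", sep="\t")
    passing = {
        (r.snp_id, str(r.category)) for r in records[records["passes"]].itertuples()
    }
    planted_pairs = {(snp, code.split(".")[0]) for snp, code, _ in PLANTED_EFFECTS}
    n_candidates = len(records)
    exact = pd.read_csv(out / "replication_exact.tsv", sep="\t")
    exact_pass = {
        (r.snp_id, str(r.category)) for r in exact[exact["passes"]].itertuples()
    }
    return {
        "planted_recovered": len(passing & planted_pairs),
        "n_planted": len(planted_pairs),
        "false_passes": len(passing - planted_pairs),
        "n_category_pairs": n_candidates,
        "exact_passes_subset_of_category": exact_pass <= passing,
        "n_samples": n_samples,
    }
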