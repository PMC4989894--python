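"""Synthetic cohort generator.

Generates genotype, diagnosis and covariate tables with the statistical
structure the downstream analysis assumes:

* biallelic SNPs in Hardy–Weinberg equilibrium at configurable per-ancestry
  minor allele frequencies;
* ICD-9 instance counts produced by a latent logistic disease model with
  additive genotype effects, optional sex effect and per-site prevalence
  multipliers (confounding);
* case-inflated counts (``3 + Poisson``) so the ≥3-instance case rule is
  meaningful, plus two error modes that populate the 1–2-instance exclusion
  band — undercounted true cases (``epsilon_undercount``) and rule-out codes
  on non-diseased samples (``delta_ruleout``);
* related sample pairs (duplicates and Mendelian full siblings) for the
  kinship QC stage to find.

Randomness is derived from a single seed; each sub-generator forks its own
stream from a fixed label, so e.g. adding SNPs does not perturb the diagnosis
draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .containers import Cohort, GenotypeMatrix, ValidationError


def _rng(seed: int, label: str) -> np.random.Generator:
    """Fork a reproducible stream from (seed, label)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass
class SnpSpec:
    """One biallelic SNP. ``maf`` is either a single frequency in (0, 0.5]
    or a mapping ancestry-group → frequency."""

    snp_id: str
    maf: float | dict

    def maf_for(self, group: str) -> float:
        if isinstance(self.maf, dict):
            if group not in self.maf:
                raise ValidationError(f"SNP {self.snp_id}: no MAF for ancestry group {group!r}")
            return float(self.maf[group])
        return float(self.maf)

    def all_mafs(self) -> list[float]:
        if isinstance(self.maf, dict):
            return [float(v) for v in self.maf.values()]
        return [float(self.maf)]


@dataclass
class CodeSpec:
    """One ICD-9 code with its baseline prevalence and planted SNP effects
    (odds ratios per coded allele)."""

    icd9: str
    baseline_prevalence: float
    effects: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class SimulationConfig:
    n_samples: int
    snp_specs: list[SnpSpec]
    code_specs: list[CodeSpec]
    sites: dict = field(default_factory=lambda: {"site1": 1.0})
    platforms: dict = field(default_factory=lambda: {"chip1": 1.0})
    ancestry_groups: dict = field(default_factory=lambda: {"EA": 1.0})
    site_code_multipliers: dict = field(default_factory=dict)  # (site, icd9) -> odds mult
    ancestry_maf_shift: dict = field(default_factory=dict)  # (group, snp_id) -> additive shift
    n_background_snps: int = 0
    background_maf_range: tuple = (0.05, 0.45)
    background_structure_sd: float = 0.0
    epsilon_undercount: float = 0.0
    delta_ruleout: float = 0.0
    instance_mean: float = 4.0
    sex_effect: float = 0.0  # log-OR of male sex on every code
    missing_rate: float = 0.0
    related_pairs: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be positive")
        if not self.code_specs:
            raise ValidationError("code_specs must be non-empty")
        snp_ids = {s.snp_id for s in self.snp_specs}
        if len(snp_ids) != len(self.snp_specs):
            raise ValidationError("duplicate snp_id in snp_specs")
        for s in self.snp_specs:
            for m in s.all_mafs():
                if not (0.0 < m <= 0.5):
                    raise ValidationError(f"SNP {s.snp_id}: MAF {m} outside (0, 0.5]")
        for c in self.code_specs:
            if not (0.0 < c.baseline_prevalence < 1.0):
                raise ValidationError(
                    f"code {c.icd9}: prevalence {c.baseline_prevalence} outside (0,1)"
                )
            for snp_id, or_ in c.effects:
                if snp_id not in snp_ids:
                    raise ValidationError(f"code {c.icd9}: effect on unknown SNP {snp_id!r}")
                if or_ <= 0:
                    raise ValidationError(f"code {c.icd9}: odds ratio {or_} must be positive")
        for frac, name in (
            (self.epsilon_undercount, "epsilon_undercount"),
            (self.delta_ruleout, "delta_ruleout"),
            (self.missing_rate, "missing_rate"),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {frac}")
        if self.instance_mean < 0:
            raise ValidationError("instance_mean must be non-negative")
        if self.n_background_snps < 0 or self.background_structure_sd < 0:
            raise ValidationError("background SNP settings must be non-negative")
        lo, hi = self.background_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"background_maf_range {self.background_maf_range} outside (0, 0.5]")
        for kind, count in self.related_pairs:
            if kind not in ("duplicate", "full_sib"):
                raise ValidationError(f"unknown related pair type {kind!r}")
            if count < 0:
                raise ValidationError("related pair count must be non-negative")
        for weights, name in (
            (self.sites, "sites"),
            (self.platforms, "platforms"),
            (self.ancestry_groups, "ancestry_groups"),
        ):
            if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ValidationError(f"{name} must map levels to non-negative weights summing > 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        snps = [SnpSpec(str(d["snp_id"]), d["maf"]) for d in raw.pop("snp_specs", [])]
        codes = [
            CodeSpec(
                str(d["icd9"]),
                float(d["baseline_prevalence"]),
                [(str(s), float(o)) for s, o in d.get("effects", [])],
            )
            for d in raw.pop("code_specs", [])
        ]
        site_mult = {
            (str(s), str(c)): float(m)
            for s, c, m in raw.pop("site_code_multipliers", [])
        }
        maf_shift = {
            (str(g), str(s)): float(v) for g, s, v in raw.pop("ancestry_maf_shift", [])
        }
        pairs = [(str(k), int(n)) for k, n in raw.pop("related_pairs", [])]
        return cls(
            snp_specs=snps,
            code_specs=codes,
            site_code_multipliers=site_mult,
            ancestry_maf_shift=maf_shift,
            related_pairs=pairs,
            **raw,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} does not contain a mapping")
        try:
            return cls.from_dict(raw)
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed simulation config {path}: {exc}") from exc


def _sample_categorical(rng: np.random.Generator, weights: dict, n: int) -> np.ndarray:
    levels = sorted(weights)
    p = np.array([weights[k] for k in levels], dtype=float)
    return rng.choice(np.array(levels, dtype=object), size=n, p=p / p.sum())


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "covariates")
    n = config.n_samples
    sample_ids = [f"S{i:06d}" for i in range(n)]
    return pd.DataFrame(
        {
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "site": _sample_categorical(rng, config.sites, n),
            "platform": _sample_categorical(rng, config.platforms, n),
            "ancestry": _sample_categorical(rng, config.ancestry_groups, n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _background_freqs(config: SimulationConfig, groups: list[str]) -> pd.DataFrame:
    """Per-ancestry allele frequencies for the background QC panel.

    Each background SNP draws a base frequency uniformly from
    ``background_maf_range``; per-group frequencies add an independent
    N(0, background_structure_sd) deviation (population differentiation for
    PCA to find), clipped to (0.01, 0.5]."""
    rng = _rng(config.seed, "background-freqs")
    base = rng.uniform(*config.background_maf_range, size=config.n_background_snps)
    freqs = {}
    for group in groups:
        shift = (
            rng.normal(0.0, config.background_structure_sd, size=base.size)
            if config.background_structure_sd > 0
            else 0.0
        )
        freqs[group] = np.clip(base + shift, 0.01, 0.5)
    ids = [f"bg{i:05d}" for i in range(config.n_background_snps)]
    return pd.DataFrame(freqs, index=pd.Index(ids, name="snp_id"))


def allele_freq_table(config: SimulationConfig, groups: list[str]) -> pd.DataFrame:
    """True coded-allele frequency per SNP (rows) and ancestry group
    (columns), association panel first, then background panel."""
    rows = {}
    for spec in config.snp_specs:
        rows[spec.snp_id] = {
            g: spec.maf_for(g) + config.ancestry_maf_shift.get((g, spec.snp_id), 0.0)
            for g in groups
        }
    assoc = pd.DataFrame.from_dict(rows, orient="index").reindex(
        [s.snp_id for s in config.snp_specs]
    )
    for snp_id, row in assoc.iterrows():
        for g, p in row.items():
            if not (0.0 < p <= 0.5):
                raise ValidationError(
                    f"SNP {snp_id}: shifted MAF {p} for group {g} outside (0, 0.5]"
                )
    if config.n_background_snps == 0:
        return assoc
    return pd.concat([assoc, _background_freqs(config, groups)])


def simulate_genotypes(config: SimulationConfig, covariates: pd.DataFrame) -> GenotypeMatrix:
    """Draw genotypes under HWE: dosage ~ Binomial(2, maf) per SNP within
    each ancestry group (so per-group genotype frequencies are q², 2pq, p²).

    Two panels are generated: the association panel from ``snp_specs`` and,
    when ``n_background_snps > 0``, a background panel used downstream for
    kinship estimation and PCA (mimicking the genome-wide backbone that QC
    runs on, as opposed to the handful of candidate variants being tested).
    The SNP metadata column ``panel`` distinguishes them.
    """
    n = config.n_samples
    ancestry = covariates["ancestry"].to_numpy()
    groups = sorted(set(ancestry))
    freqs = allele_freq_table(config, groups)
    m = len(freqs)
    dosage = np.zeros((n, m), dtype=float)
    for j, (snp_id, row) in enumerate(freqs.iterrows()):
        rng = _rng(config.seed, f"genotype:{snp_id}")
        for group in groups:
            mask = ancestry == group
            dosage[mask, j] = rng.binomial(2, row[group], size=int(mask.sum()))
        if config.missing_rate > 0:
            miss = rng.random(n) < config.missing_rate
            dosage[miss, j] = np.nan
    n_assoc = len(config.snp_specs)
    snps = pd.DataFrame(
        {
            "ref": "A",
            "alt": "T",
            "coded_allele": "T",
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "panel": ["assoc"] * n_assoc + ["background"] * (m - n_assoc),
        },
        index=freqs.index.copy(),
    )
    return GenotypeMatrix(list(covariates.index), snps, dosage)


def inject_relatives(
    genotypes: GenotypeMatrix,
    related_pairs: list[tuple[str, int]],
    config: SimulationConfig,
    covariates: pd.DataFrame,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Overwrite sample rows to create related pairs.

    Duplicates copy a genotype vector verbatim. Full siblings are drawn by
    Mendelian transmission from two fresh HWE parents (one allele from each
    parent per SNP), using the pair's ancestry-group allele frequencies.

    Returns the modified matrix and a truth table
    (sample_a, sample_b, relationship, expected_kinship).
    """
    records = []
    total = sum(n for _, n in related_pairs)
    if 2 * total > genotypes.n_samples:
        raise ValidationError(
            f"{total} related pairs need {2 * total} samples; only {genotypes.n_samples} available"
        )
    if total == 0:
        return genotypes, pd.DataFrame(
            columns=["sample_a", "sample_b", "relationship", "expected_kinship"]
        )
    out = genotypes.copy()
    rng = _rng(config.seed, "relatives")
    # pair off the tail of the roster: deterministic and never overlapping
    cursor = out.n_samples - 1
    ancestry = covariates["ancestry"]
    groups = sorted(ancestry.unique())
    freqs = allele_freq_table(config, groups).reindex(genotypes.snps.index)
    for kind, count in related_pairs:
        for _ in range(count):
            i, j = cursor - 1, cursor
            cursor -= 2
            a, b = out.samples[i], out.samples[j]
            if kind == "duplicate":
                out.dosage[j] = out.dosage[i]
                expected = 0.5
            else:  # full_sib
                group = str(ancestry.iloc[i])
                p = freqs[group].to_numpy()
                mother = rng.binomial(2, p)
                father = rng.binomial(2, p)
                for child in (i, j):
                    from_mother = rng.random(p.size) < mother / 2.0
                    from_father = rng.random(p.size) < father / 2.0
                    out.dosage[child] = from_mother.astype(float) + from_father
                expected = 0.25
            records.append((a, b, kind, expected))
    truth = pd.DataFrame(records, columns=["sample_a", "sample_b", "relationship", "expected_kinship"])
    return out, truth


def simulate_diagnoses(
    genotypes: GenotypeMatrix, covariates: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ICD-9 instance counts from the latent logistic disease model.

    For each sample i and code j the disease indicator is
    ``D_ij ~ Bernoulli(expit(alpha_j + sum_k beta_jk (g_ik - mean g_k) + ...))``
    with ``alpha_j = logit(baseline_prevalence)``; genotype and sex
    contributions are centered so the marginal prevalence stays at baseline.
    Counts: diseased samples get ``3 + Poisson(instance_mean)`` instances,
    except a fraction ``epsilon_undercount`` get 1–2 (undercoded true cases);
    non-diseased get 0, except a fraction ``delta_ruleout`` get 1–2
    (rule-out/billing noise). Samples with count 0 simply have no row.

    Returns the long diagnosis table and the latent disease indicator matrix
    (samples × codes DataFrame, used by test oracles).
    """
    n = config.n_samples
    site = covariates["site"].to_numpy()
    male = (covariates["sex"].to_numpy() == "M").astype(float)
    snp_index = {s: k for k, s in enumerate(genotypes.snp_ids)}
    rows: list[tuple[str, str, int]] = []
    latent = {}
    samples = np.asarray(genotypes.samples, dtype=object)
    for spec in config.code_specs:
        rng = _rng(config.seed, f"diagnosis:{spec.icd9}")
        eta = np.full(n, logit(spec.baseline_prevalence))
        for snp_id, or_ in spec.effects:
            g = genotypes.dosage[:, snp_index[snp_id]]
            g = np.where(np.isnan(g), np.nanmean(g), g)
            eta += np.log(or_) * (g - g.mean())
        if config.sex_effect:
            eta += config.sex_effect * (male - male.mean())
        for (mult_site, code), mult in config.site_code_multipliers.items():
            if code == spec.icd9:
                eta[site == mult_site] += np.log(mult)
        disease = rng.random(n) < expit(eta)
        latent[spec.icd9] = disease.astype(int)

        counts = np.zeros(n, dtype=int)
        d = disease
        counts[d] = 3 + rng.poisson(config.instance_mean, size=int(d.sum()))
        if config.epsilon_undercount > 0 and d.any():
            under = d & (rng.random(n) < config.epsilon_undercount)
            counts[under] = rng.integers(1, 3, size=int(under.sum()))
        if config.delta_ruleout > 0:
            ruleout = ~d & (rng.random(n) < config.delta_ruleout)
            counts[ruleout] = rng.integers(1, 3, size=int(ruleout.sum()))
        nz = counts > 0
        rows.extend(zip(samples[nz], [spec.icd9] * int(nz.sum()), counts[nz]))
    diagnoses = pd.DataFrame(rows, columns=["sample_id", "icd9", "n_instances"])
    latent_df = pd.DataFrame(latent, index=genotypes.samples)
    return diagnoses, latent_df


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generator: covariates → genotypes → relatives → diagnoses."""
    covariates = simulate_covariates(config)
    genotypes = simulate_genotypes(config, covariates)
    genotypes, relatives = inject_relatives(genotypes, config.related_pairs, config, covariates)
    diagnoses, latent = simulate_diagnoses(genotypes, covariates, config)
    effects = pd.DataFrame(
        [
            (snp_id, spec.icd9, float(np.log(or_)))
            for spec in config.code_specs
            for snp_id, or_ in spec.effects
        ],
        columns=["snp_id", "icd9", "log_or"],
    )
    return Cohort(
        genotypes=genotypes,
        diagnoses=diagnoses,
        covariates=covariates,
        truth={"effects": effects, "relatives": relatives, "latent": latent},
    )
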