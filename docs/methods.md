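# Methods

This note documents the statistical procedures phewaskit implements, the
generative model behind its synthetic cohorts, the defaults and why they
were chosen, and what the validation suite does and does not establish.

## Phenotyping

Case/control status per ICD-9 code is a function of the instance count
alone: ≥3 instances → case, 0 → control, 1–2 → excluded from that code's
analysis. Samples with exactly one instance are excluded rather than
treated as controls, because control status requires absence of the code;
a single mention is weak but non-zero evidence of disease (rule-outs,
billing noise). Codes are hierarchical: the 3-digit category is the
substring before the decimal point, which handles V- and E-codes uniformly
("V70.0" → "V70"); a code without a decimal is its own category.

The prevalence floor drops codes with fewer than `code_min_individuals`
(default 10) cases. "Present in fewer than 10 individuals" could also be
read as counting any sample with ≥1 instance; that interpretation is
available via `count="carriers"`, with cases as the default since the
analysis is powered by cases.

Duplicate `(sample, code)` input rows are rejected, not summed: the
generator never emits them, and real extracts should be aggregated
explicitly so that double-counting is a visible decision.

## Discovery/replication split

Samples are partitioned into strata by the joint levels of sex, site,
platform and ancestry and allocated to the discovery half within each
stratum at the configured proportion (default 0.5), rounding half up so odd
strata put the extra sample in discovery; singleton strata go to discovery
and are flagged in the allocation table. Membership within a stratum is a
seeded uniform draw over the lexicographically sorted member list, so
stratum counts (and memberships, given the seed) are invariant to input
order. Relatedness pruning runs after the split, separately per half: known
within-site relationships make pre-split pruning drop more samples than
necessary.

## Genetic QC

**MAF.** Coded-allele frequency over non-missing genotypes, folded to
`min(f, 1−f)`; SNPs strictly below the threshold (default 0.005) are
removed and logged. The boundary is kept: MAF exactly at threshold passes.

**Kinship.** PLINK-style method of moments. For each pair the observed
IBS 0/1/2 counts over jointly non-missing SNPs are equated to their
expectations given the IBD-state probabilities, using the standard
allele-frequency-dependent IBS|IBD table (large-sample version, without
PLINK's finite-sample correction factors); the solved `(P0, P1, P2)` is
truncated to the probability simplex, and `khat = ½P2 + ¼P1` is clamped to
[0, 0.5]. Expected values: 0.5 duplicates/MZ twins, 0.25 full siblings,
0.125 second degree, 0 unrelated. The estimator assumes allele frequencies
estimated from (or supplied for) a comparable cohort, and it needs
thousands of SNPs: at 5 000 SNPs the sampling SD for unrelated pairs is
well below the 0.125 pruning threshold (validated in the benchmark), while
a panel of a few dozen candidate SNPs gives estimates too noisy to prune
on — hence the pipeline estimates kinship on the *background* panel when
the genotype input distinguishes panels, and `kinship_enabled: false` is
the documented setting for association-panel-only inputs.

**Pruning.** Greedy: while any pair exceeds the threshold (default
kinship > 0.125, i.e. up to second-degree relatives removed), remove the
member with the most above-threshold partners, breaking ties by higher
missingness and then by lexicographically larger id. This removes exactly
one member of an isolated pair and only the hub of a path/star, and the
output is certified by re-checking that no surviving pair exceeds the
threshold.

**PCA.** Each SNP column is centered by `2p̂` and scaled by
`sqrt(2p̂(1−p̂))` (the allele-frequency standardization used for genotype
PCA), missing entries are imputed to 0 after standardization, and the top-k
(default 3) left singular vectors give the per-sample scores used as
ancestry covariates. Components are sign-fixed so the largest-magnitude
loading is positive, making results reproducible across eigensolvers. Like
kinship, PCA belongs on the background panel: principal components computed
from the association panel itself are linear combinations of the tested
dosages, and conditioning on them distorts the per-SNP null (this is
observable as type-I inflation and is why the pipeline separates the two
panels).

## Firth regression

The penalized likelihood `l*(β) = l(β) + ½ log det(XᵀWX)` is maximized by
Newton iteration on the modified score

```
U*_j = Σ_i (y_i − π_i + h_i(½ − π_i)) x_ij
```

with `h_i` the leverages of `W^{1/2}X(XᵀWX)^{-1}XᵀW^{1/2}`, starting from
β = 0, with up to five step-halvings per iteration so the penalized
likelihood never decreases. Convergence requires both `max|U*| < tol` and
`max|Δβ| < tol` (default tol 1e-6, max 25 iterations). Standard errors come
from the inverse Fisher information at the optimum; p-values are two-sided
Wald, and odds-ratio CIs are `exp(β ± z·se)`. Wald inference was chosen as
the default because the sweep reports symmetric OR CIs; penalized-LRT
profiling is a possible extension but not implemented. Non-convergence and
singular-information conditions are reported on the returned fit object
(never raised), so a sweep can record and continue.

Two closed forms anchor correctness and are asserted in the tests: the
intercept-only estimate is `π̂ = (k+½)/(n+1)`, and the saturated 2×2 slope
equals the add-½-to-every-cell log odds ratio. A coarse-to-fine grid
maximizer of `l*` — independent of the Newton path — agrees with the solver
to 1e-4 per coefficient on random small datasets. At extreme tiny-sample
corners (n ≤ 2 with all-identical outcomes) the Newton iteration can stall
just short of the score tolerance and reports `converged=False`; the
returned estimate is still accurate to ~1e-9 in π̂.

The standard (unpenalized) fit shares the machinery with the penalty off.
Monotone likelihood is flagged when any coefficient exceeds 15 on the
standardized-column scale while the Newton step has not vanished — on
separated data the raw score decays as β diverges, so the step, not the
score, is the right "still optimizing" signal. Separation itself is
classified exactly by linear programming: quasi-complete separation exists
iff some direction d ≠ 0 has `d'x_i ≥ 0` for all cases and `≤ 0` for all
controls (maximize the total margin subject to those constraints and a box
on d); if every margin can be made strictly positive the separation is
complete.

## Association sweep

For each SNP × code pair: drop the code's excluded samples and samples with
missing genotype; regress case status on intercept, additive dosage
(dominant/recessive behind a flag), sex, site and platform dummies
(lexicographically first level as reference) and the first three PCs.
Dummy columns that are constant after the per-pair exclusions — the
zero-case/zero-control cells that break unpenalized fits — are dropped per
fit and recorded in the result row; remaining collinearity is resolved by
rank-revealing QR, protecting the intercept and dosage columns. Every pair
yields a result row (monomorphic-genotype and single-class pairs are
emitted flagged), so the output row count is always #SNPs × #codes. No
multiple-testing correction is applied to the primary p-values —
replication is the error control — but Bonferroni and Benjamini–Hochberg
columns are emitted for reference. Ancestry-stratified sweeps re-apply the
MAF and prevalence floors within each group, since a SNP common in one
group may be below the floor in another.

## Replication and pleiotropy

Exact-level matching pairs results on (SNP, full code); category-level
matching pairs on (SNP, 3-digit category), representing each side by its
minimum-p sub-code — the hierarchy means the same underlying condition may
be coded 272.1 in one half and 272.4 in the other. A pair passes when both
p-values are strictly below α (default 0.01), directions agree, and both
fits converged. Under the null a pair passes both halves with concordant
direction with probability ≈ α²/2, which is the quantitative sense in which
split-sample replication substitutes for Bonferroni. One caveat of the
min-p representative: if a category contained opposite-signed sub-code
signals, an exact-level pass could in principle lack a category-level
counterpart; with direction-consistent effects (the realistic case) exact
passes are a subset of category passes, and the end-to-end test asserts
this on its output. SNPs whose passing records span ≥2 categories are
flagged as pleiotropy candidates.

## Synthetic cohorts

The generator produces the minimal structure the analysis consumes:

* **Genotypes**: `dosage ~ Binomial(2, p)` per SNP within each ancestry
  group (exact HWE), with per-group frequencies from the config; an
  optional *background panel* of `n_background_snps` draws base
  frequencies U(`background_maf_range`) with per-group
  N(0, `background_structure_sd`²) deviations, providing the genome-wide
  backbone for kinship and PCA.
* **Disease**: latent `D_ij ~ Bernoulli(expit(α_j + Σ_k β_jk g_ik + …))`
  with `α_j = logit(baseline_prevalence)`; genotype and sex contributions
  are centered at their cohort means so the marginal prevalence stays at
  baseline, and per-site odds multipliers inject confounding.
* **Instance counts**: diseased samples get `3 + Poisson(instance_mean)`
  instances (default mean 4 extra), except a fraction `epsilon_undercount`
  get 1–2 (undercoded true cases); non-diseased get 0 except a fraction
  `delta_ruleout` with 1–2 (rule-out noise). Both error modes land in the
  exclusion band, which is what makes the ≥3 rule consequential. Counts are
  generated directly rather than via per-visit event streams — the analysis
  only consumes counts.
* **Relatives**: duplicates copy a genotype row; full siblings are drawn by
  Mendelian transmission from two fresh HWE parents.
* **Determinism**: one global seed, forked per sub-generator by fixed
  string labels (CRC of the label mixed into the bit generator seed), so
  adding SNPs or codes does not perturb other draws.

Default noise levels in the validation cohorts (ε = 0.03, δ = 0.02) are
plausible EHR coding-error magnitudes; sample sizes in the benchmarks
(n = 2000 for calibration, 4000 for recovery, 10 000 for the end-to-end
study with 20 SNPs and 100 codes) are chosen so each check has the power
its tolerance implies while remaining desk-scale.

What the generator does *not* model: longitudinal visit structure,
code co-occurrence realism, LD between SNPs, sex-specific codes, and
ICD-10. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes — log-additive effects, independent SNPs,
stratification by discrete ancestry groups — not that it is robust to every
failure mode of real EHR data.

## Validation benchmarks

`phewaskit.validation` fixes the study conditions and exposes one function
per check; `tests/test_acceptance.py` asserts the tolerances and
`scripts/acceptance.py` reports the raw values. The two-population PCA
benchmark draws base allele frequencies U(0.05, 0.2) and applies the
N(0, 0.1²) between-population difference symmetrically (±δ/2) — the
ancestry-informative-marker regime; with mid-range base frequencies the
optimal-axis separation `sqrt(m·E[Δ²_std])` itself falls below the 5×
criterion, so this is a property of the generative design, not of the PCA
implementation. The end-to-end benchmark disables kinship pruning because
its cohort carries no related pairs and only the 20-SNP association panel
plus a 300-SNP background panel — far below the panel size where the
moment estimator's noise clears the 0.125 threshold (kinship has its own
benchmark at 5 000 SNPs).

## Known limitations

* Wald inference only; no penalized-LRT or score tests.
* Kinship is the classic moment estimator; no KING-robust or GRM variant,
  and no LD pruning before estimation.
* PCA has no Tracy–Widom eigenvalue significance and no projection of new
  samples onto reference components.
* The sweep treats codes independently; no cross-phenotype joint models,
  interactions, or survival outcomes.
* VCF support covers biallelic GT records; BGEN/PLINK-bed would be an
  extension.
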