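"""End-to-end pipeline orchestration.

Stage order mirrors the analysis design: stratified discovery/replication
split → per-half genetic QC (MAF filter, optional kinship pruning, PCA) →
per-half phenotyping → per-half Firth association sweep (all samples, plus
optional ancestry strata) → two-level replication matching → synthesis plot.
Every stage writes its artifacts plus a provenance record (inputs,
parameters, seed, row counts) to the output directory; a failure aborts with
the stage name and keeps the partial provenance.

Kinship pruning is on by default but should be disabled
(``kinship_enabled: false``) when the genotype input carries only a small
association panel: the moment estimator needs thousands of SNPs before its
sampling noise falls safely below the 0.125 threshold.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .cohort_split import DEFAULT_STRATA, stratified_split
from .containers import Cohort, GenotypeMatrix, ValidationError
from .engine import run_phewas, stratify_by_ancestry
from .genetic_qc import filter_maf, genotype_pca, mom_kinship, prune_related
from .phenotyping import build_phenotype_matrix, filter_low_prevalence
from .replication import flag_pleiotropy, match_replication

logger = logging.getLogger("phewaskit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genotypes: str
    diagnoses: str
    covariates: str
    out_dir: str
    genotype_format: str | None = None
    strata_keys: tuple = DEFAULT_STRATA
    split_proportion: float = 0.5
    maf_threshold: float = 0.005
    kinship_enabled: bool = True
    kinship_threshold: float = 0.125
    n_pcs: int = 3
    case_min_instances: int = 3  # informational: the ≥3 rule is fixed
    code_min_individuals: int = 10
    prevalence_count: str = "cases"
    alpha: float = 0.01
    ancestry_strata: tuple = ()  # e.g. ("EA", "AA"); empty = all-samples only
    check_separation: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("genotypes", "diagnoses", "covariates"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ValidationError(f"{name} file does not exist: {path}")
        if not (0.0 < self.split_proportion < 1.0):
            raise ValidationError("split_proportion must be in (0,1)")
        if not (0.0 <= self.maf_threshold <= 0.5):
            raise ValidationError("maf_threshold must be in [0, 0.5]")
        if not (0.0 < self.kinship_threshold <= 0.5):
            raise ValidationError("kinship_threshold must be in (0, 0.5]")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0,1)")
        if self.n_pcs < 0 or self.code_min_individuals < 1:
            raise ValidationError("n_pcs must be ≥0 and code_min_individuals ≥1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for tup in ("strata_keys", "ancestry_strata"):
            if tup in raw and raw[tup] is not None:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)


class _Provenance:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.path = out_dir / "provenance.json"
        self.record = {"config": asdict(config), "stages": []}

    def stage(self, name: str, **info) -> None:
        self.record["stages"].append({"stage": name, "time": time.time(), **info})
        self.flush()

    def flush(self) -> None:
        self.path.write_text(json.dumps(self.record, indent=2, default=str))


def _qc_half(
    genotypes: GenotypeMatrix, config: PipelineConfig, name: str, prov: _Provenance
):
    """Per-half QC. Kinship and PCA run on the background SNP panel when the
    input carries one (the genome-wide backbone); the association panel only
    gets the MAF filter. Without a panel annotation, all SNPs serve both
    roles."""
    assoc = genotypes.panel("assoc")
    background = genotypes.panel("background")
    filtered, removed_snps = filter_maf(assoc, config.maf_threshold)
    qc_panel = background if background.n_snps > 0 else filtered
    removed_samples: list[str] = []
    kinship_frame = None
    if config.kinship_enabled:
        kin = mom_kinship(qc_panel)
        kept, removed_samples = prune_related(kin, config.kinship_threshold)
        kinship_frame = kin.to_frame()
        filtered = filtered.subset_samples(kept)
        qc_panel = qc_panel.subset_samples(kept)
    pcs = genotype_pca(qc_panel, k=config.n_pcs) if config.n_pcs > 0 else None
    prov.stage(
        f"qc:{name}",
        n_snps_removed_maf=len(removed_snps),
        n_samples_removed_kinship=len(removed_samples),
        n_samples=filtered.n_samples,
        n_snps=filtered.n_snps,
        n_qc_panel_snps=qc_panel.n_snps,
    )
    return filtered, removed_snps, removed_samples, kinship_frame, pcs


def _sweep_half(
    cohort: Cohort, config: PipelineConfig, dataset: str, out: Path, prov: _Provenance
) -> pd.DataFrame:
    genotypes, removed_snps, removed_samples, kinship_frame, pcs = _qc_half(
        cohort.genotypes, config, dataset, prov
    )
    roster = genotypes.samples
    if kinship_frame is not None:
        pio.write_tsv(kinship_frame, out / f"kinship_{dataset}.tsv")
        (out / f"removed_related_{dataset}.txt").write_text("\n".join(removed_samples) + "\n")
    pio.write_tsv(removed_snps, out / f"removed_snps_{dataset}.tsv")
    pcs_frame = pcs.scores_frame() if pcs is not None else pd.DataFrame(index=pd.Index(roster))
    pio.write_tsv(pcs_frame.reset_index(), out / f"pcs_{dataset}.tsv")

    diagnoses = cohort.diagnoses[cohort.diagnoses["sample_id"].isin(set(roster))]
    matrix = build_phenotype_matrix(diagnoses, roster)
    matrix = filter_low_prevalence(matrix, config.code_min_individuals, config.prevalence_count)
    pio.write_phenotype_matrix(matrix, out / f"phenotypes_{dataset}.tsv")
    pio.write_code_summary(matrix, out / f"code_summary_{dataset}.tsv")
    prov.stage(
        f"phenotype:{dataset}",
        n_codes_retained=len(matrix.codes),
        n_codes_removed=len(matrix.removed),
    )

    covariates = cohort.covariates.loc[roster]
    results = run_phewas(
        genotypes,
        matrix,
        covariates,
        pcs_frame,
        dataset=dataset,
        stratum="all",
        n_pcs=config.n_pcs,
        check_separation=config.check_separation,
    )
    frames = [results]
    for group in config.ancestry_strata:
        sub_ids = [s for s in roster if covariates.loc[s, "ancestry"] == group]
        if len(sub_ids) < 2:
            logger.warning("ancestry stratum %s too small in %s; skipped", group, dataset)
            continue
        sub_geno = genotypes.subset_samples(sub_ids)
        sub_geno, _ = filter_maf(sub_geno, config.maf_threshold)
        if sub_geno.n_snps == 0:
            continue
        sub_matrix = build_phenotype_matrix(
            diagnoses[diagnoses["sample_id"].isin(set(sub_ids))], sub_ids
        )
        sub_matrix = filter_low_prevalence(
            sub_matrix, config.code_min_individuals, config.prevalence_count
        )
        sub_pcs = pcs_frame.loc[sub_ids]
        frames.append(
            run_phewas(
                sub_geno,
                sub_matrix,
                covariates.loc[sub_ids],
                sub_pcs,
                dataset=dataset,
                stratum=group,
                n_pcs=config.n_pcs,
                check_separation=config.check_separation,
            )
        )
    results = pd.concat(frames, ignore_index=True)
    pio.write_results(results, out / f"results_{dataset}.tsv")
    prov.stage(f"phewas:{dataset}", n_results=len(results))
    return results


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    ``cohort`` may be supplied in memory; otherwise the configured input
    files are read. Reruns with the same config and inputs are byte-identical.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        config.validate()
    prov = _Provenance(out, config)
    stage = "load"
    try:
        if cohort is None:
            genotypes = pio.read_genotypes(config.genotypes, config.genotype_format)
            diagnoses = pio.read_diagnoses(config.diagnoses)
            covariates = pio.read_covariates(config.covariates)
            cohort = Cohort(genotypes, diagnoses, covariates)
        prov.stage("load", n_samples=cohort.genotypes.n_samples, n_snps=cohort.genotypes.n_snps,
                   n_diagnosis_rows=len(cohort.diagnoses), seed=config.seed)

        stage = "split"
        split = stratified_split(
            cohort.samples,
            cohort.covariates,
            [k for k in config.strata_keys if k in cohort.covariates.columns],
            config.split_proportion,
            config.seed,
        )
        (out / "discovery_samples.txt").write_text("\n".join(split.discovery) + "\n")
        (out / "replication_samples.txt").write_text("\n".join(split.replication) + "\n")
        pio.write_tsv(split.allocation, out / "split_allocation.tsv")
        prov.stage("split", n_discovery=len(split.discovery), n_replication=len(split.replication))

        halves = {}
        for dataset, ids in (("discovery", split.discovery), ("replication", split.replication)):
            stage = f"sweep:{dataset}"
            halves[dataset] = _sweep_half(cohort.subset(ids), config, dataset, out, prov)

        stage = "replication"
        all_disc = halves["discovery"][halves["discovery"]["stratum"] == "all"]
        all_repl = halves["replication"][halves["replication"]["stratum"] == "all"]
        for level in ("exact", "category"):
            records = match_replication(all_disc, all_repl, config.alpha, level)
            pio.write_tsv(records, out / f"replication_{level}.tsv")
            if level == "category":
                passing = records[records["passes"]]
                pio.write_tsv(flag_pleiotropy(records), out / "pleiotropy.tsv")
                pio.synthesis_plot(passing.reset_index(drop=True), out / "synthesis_plot.png")
            prov.stage(
                f"replication:{level}",
                n_candidates=len(records),
                n_passing=int(records["passes"].sum()) if len(records) else 0,
            )
    except Exception as exc:
        prov.stage("error", failed_stage=stage, error=str(exc))
        raise StageError(stage, exc) from exc
    return out
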