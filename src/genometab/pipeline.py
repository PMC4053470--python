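"""End-to-end orchestration: simulate -> spectra -> chemometrics -> genassoc -> integrate."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chemometrics, genassoc, integrate, io, simulate
from .config import RunConfig
from .errors import GenometabError, ValidationError

log = logging.getLogger("genometab")


@dataclass
class StageRecord:
    name: str
    n_in: int = 0
    n_retained: int = 0
    n_excluded: int = 0
    exclusions: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)


@dataclass
class RunReport:
    version: str
    config: dict
    seeds: dict
    stages: list

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (StageRecord,)):
                return o.__dict__
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(self.__dict__, default=default, indent=2)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ["simulate", "spectra", "chemometrics", "genassoc", "integrate"]
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: RunConfig) -> tuple[RunReport, dict]:
    """Execute the configured stages in order.

    Returns the run report and a dict of in-memory artifacts ('pheno',
    'geno', 'features', 'plsda', 'assoc', 'integrate'). A failure in any
    stage is re-raised annotated with the stage name.
    """
    seeds = _stage_seeds(config.seed)
    report = RunReport(version=__version__, config=vars(config).copy(), seeds=seeds, stages=[])
    artifacts: dict = {}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def run_stage(name, enabled, fn):
        if not enabled:
            log.info("stage %s: skipped", name)
            return
        record = StageRecord(name=name)
        try:
            fn(record)
        except GenometabError as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc
        report.stages.append(record)
        log.info("stage %s: %d in, %d retained", name, record.n_in, record.n_retained)

    # ---- simulate -------------------------------------------------------
    def stage_simulate(rec: StageRecord):
        eff = simulate.EffectSpec(target_prevalence=config.target_prevalence)
        cohort = simulate.gen_cohort(
            config.n_subjects,
            seed=seeds["simulate"],
            effect_spec=eff,
            missing_rate=config.genotype_missing_rate,
            spectra_noise_sd=config.spectra_noise_sd,
            make_spectra=config.run_spectra,
        )
        artifacts.update(cohort)
        rec.n_in = rec.n_retained = config.n_subjects
        rec.outputs["prevalence"] = float(cohort["pheno"]["malb"].mean())
        if out_dir:
            io.write_phenotypes(cohort["pheno"], out_dir / "phenotypes.csv")
            io.write_genotypes_tsv(cohort["geno"], out_dir / "genotypes.tsv")
            io.write_ped_map(cohort["geno"], out_dir / "genotypes.ped", out_dir / "genotypes.map")
            cohort["levels"].to_csv(out_dir / "metabolite_levels_true.csv")
            if config.run_spectra and "spectra" in cohort:
                io.write_spectra(cohort["spectra"], out_dir / "spectra")

    def load_inputs(rec: StageRecord):
        if config.input_dir is None:
            raise ValidationError("simulate disabled but no input_dir given")
        in_dir = Path(config.input_dir)
        pheno, rejected = io.read_phenotypes(in_dir / "phenotypes.csv")
        artifacts["pheno"] = pheno
        artifacts["geno"] = io.read_genotypes_tsv(in_dir / "genotypes.tsv")
        rec.n_in = len(pheno) + len(rejected)
        rec.n_retained = len(pheno)
        rec.n_excluded = len(rejected)
        rec.exclusions = rejected.get("reject_reason", pd.Series(dtype=str)).tolist()
        manifest = in_dir / "spectra" / "manifest.csv"
        if manifest.exists():
            artifacts["spectra"] = io.read_spectra(manifest)
        levels_path = in_dir / "metabolite_levels.csv"
        if levels_path.exists():
            artifacts["levels"] = pd.read_csv(levels_path, index_col=0)

    run_stage("simulate", True, stage_simulate if config.run_simulate else load_inputs)

    # ---- spectra --------------------------------------------------------
    def stage_spectra(rec: StageRecord):
        from .spectra import quantify_metabolites

        specs = artifacts.get("spectra")
        if specs is None:
            raise ValidationError("no spectra available; enable simulate or provide inputs")
        rec.n_in = rec.n_retained = len(specs)
        features = quantify_metabolites(
            specs, width=config.bin_width, window=(config.window_lo, config.window_hi)
        )
        features.index = artifacts["pheno"].index[: len(features)]
        artifacts["features"] = features
        if out_dir:
            features.to_csv(out_dir / "metabolite_levels.csv")

    run_stage("spectra", config.run_spectra, stage_spectra)
    if "features" not in artifacts and "levels" in artifacts:
        artifacts["features"] = artifacts["levels"]

    # ---- chemometrics ---------------------------------------------------
    def stage_chemometrics(rec: StageRecord):
        features = artifacts["features"]
        y = artifacts["pheno"]["malb"].to_numpy(dtype=float)
        rec.n_in = rec.n_retained = len(features)
        plan = chemometrics.CvPlan(
            n_folds=config.cv_folds, n_repeats=config.cv_repeats, seed=seeds["chemometrics"]
        )
        X = features.to_numpy(dtype=float)
        k, results = chemometrics.select_components(X, y, plan, k_max=config.max_components)
        cv = results[k]
        model = chemometrics.fit_plsda(X, y, k)
        model.q2, model.rmscv = cv.q2, cv.rmscv
        artifacts["plsda"] = {"model": model, "cv": cv, "k": k}
        rec.outputs.update({"k": k, "q2": cv.q2, "q2_press": cv.q2_press, "rmscv": cv.rmscv})
        if out_dir:
            summary = {
                "k": k,
                "q2": cv.q2,
                "q2_press": cv.q2_press,
                "rmscv": cv.rmscv,
                "per_repeat_q2": cv.per_repeat_q2.tolist(),
                "per_repeat_rmscv": cv.per_repeat_rmscv.tolist(),
            }
            (out_dir / "plsda_summary.json").write_text(json.dumps(summary, indent=2))
            chemometrics.rank_features(model, list(features.columns)).to_csv(
                out_dir / "plsda_vip.tsv", sep="\t", index=False
            )

    run_stage("chemometrics", config.run_chemometrics, stage_chemometrics)

    # ---- genassoc -------------------------------------------------------
    def stage_genassoc(rec: StageRecord):
        geno = artifacts["geno"]
        pheno = artifacts["pheno"]
        rec.n_in = len(geno.snp_ids)
        filtered, qc = genassoc.qc_filter(
            geno, min_call_rate=config.min_call_rate, hwe_alpha=config.hwe_alpha
        )
        rec.n_retained = len(filtered.snp_ids)
        rec.n_excluded = rec.n_in - rec.n_retained
        rec.exclusions = [
            f"{snp}: {qc.loc[snp, 'fail_reasons']}" for snp in qc.index[~qc["passed"]]
        ]
        covars = pheno[config.covariates].to_numpy(dtype=float)
        table = genassoc.associate_panel(
            pheno["log_uae"].to_numpy(dtype=float),
            pheno["malb"].to_numpy(dtype=float),
            filtered,
            covariates=covars,
            alpha=config.assoc_alpha,
        )
        artifacts["geno_qc"] = qc
        artifacts["geno_filtered"] = filtered
        artifacts["assoc"] = table
        if out_dir:
            qc.to_csv(out_dir / "snp_qc.tsv", sep="\t")
            table.to_csv(out_dir / "association.tsv", sep="\t", index=False)

    run_stage("genassoc", config.run_genassoc, stage_genassoc)

    # ---- integrate ------------------------------------------------------
    def stage_integrate(rec: StageRecord):
        features = artifacts["features"]
        pheno = artifacts["pheno"]
        geno = artifacts.get("geno_filtered", artifacts["geno"])
        malb = pheno["malb"].to_numpy(dtype=bool)
        rec.n_in = rec.n_retained = len(features)
        cohort = integrate.cohort_differences(features, malb)
        plan = chemometrics.CvPlan(
            n_folds=config.cv_folds, n_repeats=config.cv_repeats, seed=seeds["integrate"]
        )
        cohort_q2 = None
        if "plsda" in artifacts:
            cohort_q2 = artifacts["plsda"]["cv"].q2
        all_strat = []
        all_reports = []
        for snp in geno.snp_ids:
            strat = integrate.stratified_differences(
                features, malb, geno, snp, min_malb=config.min_malb_per_stratum
            )
            labels = geno.genotype_labels(snp)
            q2_by_genotype = {}
            for genotype in strat["genotype"].unique():
                in_stratum = (labels == genotype).to_numpy()
                try:
                    q2_by_genotype[genotype] = integrate.stratum_plsda(
                        features, malb, in_stratum, plan=plan, k=2
                    ).q2
                except ValidationError:
                    q2_by_genotype[genotype] = None
            reports = integrate.select_discordant(
                strat,
                cohort,
                stratum_q2=q2_by_genotype,
                cohort_q2=cohort_q2,
                criteria=integrate.DiscordanceCriteria(
                    min_nonsig_fraction=config.discordance_nonsig_fraction
                ),
            )
            all_strat.append(integrate.normalized_difference_ratio(strat, cohort))
            all_reports.append(reports)
        strat_table = pd.concat(all_strat, ignore_index=True) if all_strat else pd.DataFrame()
        report_table = pd.concat(all_reports, ignore_index=True) if all_reports else pd.DataFrame()
        artifacts["integrate"] = {
            "cohort": cohort,
            "stratified": strat_table,
            "discordance": report_table,
        }
        rec.outputs["n_selected_genotypes"] = (
            int(report_table["selected"].sum()) if len(report_table) else 0
        )
        if out_dir:
            cohort.to_csv(out_dir / "cohort_differences.tsv", sep="\t")
            if len(strat_table):
                pattern = integrate.significance_pattern(strat_table, cohort)
                pattern.to_csv(out_dir / "significance_pattern.tsv", sep="\t")
                integrate.ratio_matrix(strat_table).to_csv(
                    out_dir / "difference_ratios.tsv", sep="\t"
                )
            report_table.to_json(out_dir / "discordance_report.json", orient="records", indent=2)

    run_stage("integrate", config.run_integrate, stage_integrate)

    if out_dir:
        (out_dir / "run_report.json").write_text(report.to_json())
    return report, artifacts
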