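"""End-to-end pipeline: simulate -> score -> associate -> survive -> report.

The ``simulate`` stage writes a synthetic cohort to disk (VCF genotypes,
TSV true panel, CSV phenotypes, YAML manifest); the ``analyze`` stage
reads those files (or user-supplied ones in the same formats),
re-estimates per-SNP weights from the case/control genotypes, scores
everyone, and writes the report bundle: score CSV, association CSV,
survival CSV, binned-prevalence CSV, ROC CSV and predictive-value CSV.
Every output carries the run-config hash and seed on its first line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotypes as gio
from .genotypes import GenotypeMatrix, filter_complete, read_dosage_csv
from .panel import RiskPanel, estimate_allelic_or, load_panel, panel_from_estimates
from .risk_models import (SeparationError, assoc_table, auc_by_onset_strata,
                          compare_auc_paired, fit_logistic, fit_ordinal,
                          predictive_values, quartile_or)
from .scores import ScoreSet, assign_quartiles, binned_prevalence, compute_scores
from .simulate import SimConfig, simulate_cohort
from .survival import survival_table, table2_summary

BINARY_OUTCOMES = ["renal_disorder", "immunological_disorder", "dsdna",
                   "esrd", "la", "acl_igg", "ab2gpi_igg", "deceased"]
ORDINAL_OUTCOMES = ["sdi", "ckd_stage"]
SURVIVAL_EVENTS = ["first_sdi", "first_cve", "first_ae", "first_vte",
                   "esrd_onset", "death", "nephritis_onset", "sle_onset"]

REQUIRED_PHENOTYPE_COLUMNS = ["individual_id", "is_case"]


@dataclass
class RunConfig:
    """Pipeline run parameters; one master seed drives every stage."""

    out_dir: str
    mode: str = "full"  # simulate | analyze | full
    seed: int = 0
    genotypes_path: str | None = None
    weights_path: str | None = None
    phenotypes_path: str | None = None
    quartile_reference: str = "cases_only"  # for subphenotype/survival
    covariate_model: int = 1  # 1 = age; 2 = age + age at diagnosis
    score_bin_edges: tuple = (7, 8, 9, 10, 11)
    roc_strata_edges: tuple = (20.0, 40.0)
    pv_cutoff: float | None = None  # None -> case-GRS 75th percentile
    pv_prevalence: float = 0.11
    group_size: int = 100
    sim: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # paths are excluded so the hash identifies the analysis, not
        # where it ran
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k not in ("out_dir", "genotypes_path", "weights_path",
                                "phenotypes_path")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("score_bin_edges", "roc_strata_edges"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def _read_output_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def simulate_stage(cfg: RunConfig) -> dict:
    """Generate and write a synthetic cohort; returns in-memory objects."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
    panel, genos, status, scores, cohort = simulate_cohort(sim_cfg)
    panel.to_tsv(out / "true_panel.tsv")
    gio.write_vcf(out / "genotypes.vcf", genos, panel)
    pheno = pd.DataFrame({"individual_id": genos.individual_ids,
                          "is_case": status})
    pheno = pheno.merge(cohort.drop(columns=["is_case", "grs"]),
                        on="individual_id", how="left")
    pheno.to_csv(out / "phenotypes.csv", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        sim_dict = json.loads(json.dumps(dataclasses.asdict(sim_cfg),
                                         default=float))
        yaml.safe_dump({"seed": cfg.seed,
                        "config_sha256": cfg.config_hash(),
                        "sim_config": sim_dict}, fh)
    return {"panel": panel, "genotypes": genos, "status": status,
            "cohort": cohort}


def _load_inputs(cfg: RunConfig) -> dict:
    stage = "load"
    try:
        panel = load_panel(cfg.weights_path)
        geno_path = str(cfg.genotypes_path)
        if geno_path.endswith(".vcf"):
            genos = gio.read_vcf(geno_path, panel)
        else:
            genos = read_dosage_csv(geno_path)
        pheno = pd.read_csv(cfg.phenotypes_path)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise PipelineError(
            f"stage {stage}: phenotype table missing column(s) {missing}")
    extra = set(genos.individual_ids) ^ set(pheno["individual_id"])
    if extra:
        raise PipelineError(
            f"stage {stage}: sample ids mismatch between genotypes and "
            f"phenotypes: {sorted(extra)[:5]}")
    pheno = pheno.set_index("individual_id").loc[genos.individual_ids]
    return {"panel": panel, "genotypes": genos,
            "status": pheno["is_case"].to_numpy(bool),
            "cohort": pheno.reset_index()}


def analyze_stage(cfg: RunConfig, data: dict) -> dict:
    """Score, associate and survive; writes the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    genos, status = data["genotypes"], data["status"]
    cohort = data["cohort"]

    n0 = genos.n_individuals
    genos, n_removed = filter_complete(genos)
    if n_removed:
        keep = pd.Index(genos.individual_ids)
        pos = pd.Index(data["genotypes"].individual_ids).get_indexer(keep)
        status = status[pos]
        cohort = cohort[cohort["individual_id"].isin(keep)].reset_index(drop=True)
    log.append(f"complete-genotype filter: {n0} -> {genos.n_individuals} "
               f"({n_removed} removed)")

    # weights re-estimated from the case/control genotypes, as in the
    # discovery design
    est = estimate_allelic_or(genos, status)
    panel = panel_from_estimates(data["panel"], est)
    scores = compute_scores(genos, panel)
    combined = assign_quartiles(scores, "all")
    cases_q = assign_quartiles(scores, "cases_only", status=status)
    _write_csv(cases_q.frame().assign(combined_quartile=combined.quartile),
               out / "scores.csv", cfg)

    results = []
    try:
        results.append(quartile_or(status, combined, outcome_name="sle_status"))
    except SeparationError as exc:
        log.append(f"enrichment OR: {exc}")
    results.append(fit_logistic(status, scores.grs, outcome_name="sle_status"))

    case_mask = np.asarray(status, bool)
    case_ids = [i for i, c in zip(genos.individual_ids, case_mask) if c]
    cases = cohort.set_index("individual_id").loc[case_ids].reset_index()
    case_scores = ScoreSet(case_ids, scores.rac[case_mask],
                           scores.grs[case_mask],
                           np.asarray(cases_q.quartile)[case_mask])
    cov = pd.DataFrame({"age": cases["age_last_followup"].to_numpy(float)})
    if cfg.covariate_model == 2:
        cov["age_at_diagnosis"] = cases["age_at_diagnosis"].to_numpy(float)

    for name in BINARY_OUTCOMES:
        if name not in cases.columns:
            continue
        y = cases[name]
        ok = y.notna().to_numpy()
        yb = y[ok].astype(bool).to_numpy()
        sub = ScoreSet(list(np.array(case_ids)[ok]), case_scores.rac[ok],
                       case_scores.grs[ok], np.asarray(case_scores.quartile)[ok])
        for fitter in ("quartile", "continuous"):
            try:
                if fitter == "quartile":
                    results.append(quartile_or(yb, sub, cov[ok].reset_index(drop=True),
                                               outcome_name=name))
                else:
                    results.append(fit_logistic(yb, sub.grs,
                                                cov[ok].reset_index(drop=True),
                                                outcome_name=name))
            except (SeparationError, ValueError, np.linalg.LinAlgError) as exc:
                log.append(f"assoc {name} ({fitter}): {exc}")
    for name in ORDINAL_OUTCOMES:
        if name not in cases.columns:
            continue
        try:
            results.append(fit_ordinal(cases[name].astype(int), case_scores.grs,
                                       cov, outcome_name=name))
        except (SeparationError, ValueError) as exc:
            log.append(f"assoc {name} (ordinal): {exc}")
    _write_csv(assoc_table(results), out / "associations.csv", cfg)

    # survival: extreme case quartiles, age scale
    surv = []
    for event in SURVIVAL_EVENTS:
        try:
            surv.append(table2_summary(cases, case_scores, event))
        except (ValueError, KeyError) as exc:
            log.append(f"survival {event}: {exc}")
    _write_csv(survival_table(surv), out / "survival.csv", cfg)

    prev = binned_prevalence(combined, status, cfg.group_size)
    _write_csv(prev, out / "binned_prevalence.csv", cfg)

    rac_scores = scores.rac.astype(float)
    diff, p_cmp, roc_grs, roc_rac = compare_auc_paired(scores.grs, rac_scores,
                                                       status)
    roc_rows = [{"score": "grs", "stratum": "all", "auc": roc_grs.auc,
                 "n_cases": roc_grs.n_cases, "n_controls": roc_grs.n_controls,
                 "comparison_p": p_cmp},
                {"score": "rac", "stratum": "all", "auc": roc_rac.auc,
                 "n_cases": roc_rac.n_cases, "n_controls": roc_rac.n_controls,
                 "comparison_p": p_cmp}]
    if "age_at_diagnosis" in cohort.columns:
        onset = cohort.set_index("individual_id").loc[
            genos.individual_ids, "age_at_diagnosis"].to_numpy(float)
        for r in auc_by_onset_strata(scores.grs, status, onset,
                                     cfg.roc_strata_edges):
            roc_rows.append({"score": "grs", "stratum": r.label, "auc": r.auc,
                             "n_cases": r.n_cases, "n_controls": r.n_controls,
                             "comparison_p": np.nan})
    _write_csv(pd.DataFrame(roc_rows), out / "roc.csv", cfg)

    pv_rows = []
    if "esrd" in cases.columns:
        cutoff = (cfg.pv_cutoff if cfg.pv_cutoff is not None
                  else float(np.quantile(case_scores.grs, 0.75)))
        try:
            pv = predictive_values(case_scores.grs,
                                   cases["esrd"].astype(bool).to_numpy(),
                                   cutoff, cfg.pv_prevalence)
            pv_rows.append({"outcome": "esrd", "cutoff": pv.cutoff,
                            "sensitivity": pv.sensitivity,
                            "specificity": pv.specificity, "ppv": pv.ppv,
                            "npv": pv.npv, "positive_rate": pv.positive_rate,
                            "assumed_prevalence": pv.assumed_prevalence})
        except ValueError as exc:
            log.append(f"predictive values esrd: {exc}")
    _write_csv(pd.DataFrame(pv_rows), out / "predictive_values.csv", cfg)

    (Path(cfg.out_dir) / "run.log").write_text("\n".join(log) + "\n")
    return {"scores": scores, "associations": results, "survival": surv,
            "roc": roc_rows, "log": log}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; any stage error aborts with its name."""
    if cfg.mode not in ("simulate", "analyze", "full"):
        raise PipelineError(f"unknown mode {cfg.mode!r}")
    out = Path(cfg.out_dir)
    if cfg.mode in ("simulate", "full"):
        data = simulate_stage(cfg)
        cfg.weights_path = str(out / "true_panel.tsv")
        cfg.genotypes_path = str(out / "genotypes.vcf")
        cfg.phenotypes_path = str(out / "phenotypes.csv")
        if cfg.mode == "simulate":
            return data
    data = _load_inputs(cfg)
    return analyze_stage(cfg, data)
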