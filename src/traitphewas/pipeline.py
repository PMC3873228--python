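"""End-to-end study orchestration and report accounting.

``run_study`` drives the whole analysis: cohort assembly, trait
grouping, treatment-start detection, post-treatment restriction, the
ICD scan under both aggregation schemes, the lab scan under both
discretization algorithms, event-free survival, and the efficacy 2x2.
Every stage writes a tab-separated table into the report directory, and
the run log echoes each resolved setting so a report is reproducible
from its own directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, labs as labs_mod, survival as surv_mod
from .cohort import Cohort, TraitCuts, prepare_study_population, TREATMENT_KEYWORDS
from .stats import Contingency2x2, FisherResult, fisher_exact, logistic_fit
from .terminology import (
    Terminology,
    build_block_groups,
    build_mapped_groups,
    data_path,
    load_hierarchy,
)

logger = logging.getLogger("traitphewas")

__all__ = ["StudyConfig", "run_study", "efficacy_compare", "load_config"]


@dataclass
class StudyConfig:
    """Resolved study settings; every threshold and window lives here."""

    cohort_dir: str
    out_dir: str
    seed: int = 0
    cut_low: float = 8.5
    cut_high: float = 15.0
    q: float = 0.2
    min_cases: int = 5
    min_occurrences_per_patient: int = 1
    min_cases_unit: str = "patients"
    estimator: str = "woolf_logistic"
    efficacy_estimator: str = "fisher_exact"
    splits: tuple[str, ...] = ("very_high_vs_rest", "low_vs_rest")
    schemes: tuple[str, ...] = ("icd10_block", "icd9cm_phewas")
    hierarchy_file: str | None = None
    thresholds_file: str | None = None
    lab_tests: tuple[str, ...] | None = None
    survival_test: str = "hemoglobin"
    survival_direction: str = "low"
    washout_days: int = 7
    horizon_days: int = 360
    keywords: tuple[str, ...] = TREATMENT_KEYWORDS
    write_plots: bool = False

    @property
    def cuts(self) -> TraitCuts:
        return TraitCuts(self.cut_low, self.cut_high)


def load_config(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("splits", "schemes", "lab_tests", "keywords"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return StudyConfig(**raw)


def _terminologies(config: StudyConfig) -> dict[str, Terminology]:
    out = {}
    if "icd10_block" in config.schemes:
        out["icd10_block"] = build_block_groups(
            load_hierarchy(config.hierarchy_file)
        )
    if "icd9cm_phewas" in config.schemes:
        nz = pd.read_csv(data_path("icd10_to_icd9_toy.tsv"), sep="\t", dtype=str)
        defs = pd.read_csv(data_path("phewas9_defs_toy.tsv"), sep="\t", dtype=str)
        overrides = pd.read_csv(
            data_path("mapping_overrides_toy.tsv"), sep="\t", dtype=str
        )
        excluded = pd.read_csv(
            data_path("excluded_codes_toy.tsv"), sep="\t", dtype=str
        )["icd10"]
        term, _ = build_mapped_groups(nz, defs, overrides, excluded)
        out["icd9cm_phewas"] = term
    return out


def efficacy_compare(
    flags: pd.DataFrame,
    patients: pd.DataFrame,
    exposed_group: str = "very_high",
    estimator: str = "fisher_exact",
    adjust: bool = False,
) -> dict:
    """Therapy-failure 2x2 between one trait group and the rest.

    ``flags`` carries (patient_id, failure) — failure adjudication is an
    input, not computed here. With ``adjust`` a logistic model with sex
    and age covariates is fitted alongside.
    """
    merged = flags.merge(patients, on="patient_id")
    if merged["trait_group"].nunique() < 2:
        raise ValueError("efficacy comparison needs both trait arms")
    exposed = merged["trait_group"] == exposed_group
    fail = merged["failure"].astype(bool)
    table = Contingency2x2(
        int((exposed & fail).sum()), int((exposed & ~fail).sum()),
        int((~exposed & fail).sum()), int((~exposed & ~fail).sum()),
    )
    if table.a + table.c == 0:
        return {"table": table, "p": 1.0, "estimate": None, "degenerate": True}
    fr: FisherResult = fisher_exact(table)
    if estimator == "fisher_exact":
        est, p = fr.estimate, fr.p
    else:
        from .stats import sample_or_woolf

        est, p = sample_or_woolf(table), fr.p
    out = {"table": table, "p": p, "estimate": est, "degenerate": False}
    if adjust and {"sex", "birth_year"} <= set(merged.columns):
        sub = merged.dropna(subset=["sex", "birth_year"])
        design = np.column_stack(
            [
                np.ones(len(sub)),
                (sub["trait_group"] == exposed_group).astype(float),
                (sub["sex"] == "female").astype(float),
                sub["birth_year"].astype(float) - 1960.0,
            ]
        )
        out["adjusted"] = logistic_fit(design, fail.loc[sub.index].to_numpy(float))
    return out


def run_study(config: StudyConfig) -> dict:
    """Execute every stage and write the report bundle.

    Independent stages keep running after one fails; errors are
    recorded in the run log and in the returned report dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"errors": {}}

    cohort = Cohort.read_dir(config.cohort_dir)
    study = prepare_study_population(cohort, config.cuts, config.keywords)
    study.flow.to_csv(out_dir / "flow.tsv", sep="\t", index=False)
    report["flow"] = study.flow
    report["n_patients"] = len(study.patients)
    logger.info("study population: %d patients (%d unstable assays)",
                len(study.patients), len(study.unstable))

    if len(study.patients) == 0:
        logger.warning("empty study population; no result tables emitted")
        _write_log(config, report, out_dir)
        return report

    terms = _terminologies(config)
    for scheme, term in terms.items():
        for split in config.splits:
            key = f"icd_{scheme}_{split}"
            try:
                results, thr = assoc.run_phewas(
                    study.patients, study.diagnoses, term,
                    split=split,
                    min_cases=config.min_cases,
                    estimator=config.estimator,
                    min_occurrences_per_patient=config.min_occurrences_per_patient,
                    min_cases_unit=config.min_cases_unit,
                    q=config.q,
                )
                frame = assoc.results_frame(results)
                frame.to_csv(out_dir / f"{key}.tsv", sep="\t", index=False)
                manhattan, qq = assoc.plot_tables(results, thr)
                manhattan.to_csv(out_dir / f"{key}_manhattan.tsv", sep="\t",
                                 index=False)
                qq.to_csv(out_dir / f"{key}_qq.tsv", sep="\t", index=False)
                if config.write_plots:
                    _plot_manhattan(manhattan, out_dir / f"{key}_manhattan.png")
                report[key] = {"results": results, "fdr_threshold": thr}
            except Exception as exc:  # stage isolation
                logger.exception("ICD scan %s failed", key)
                report["errors"][key] = str(exc)

    thresholds = labs_mod.load_thresholds(config.thresholds_file)
    tests = list(config.lab_tests) if config.lab_tests else sorted(
        set(study.labs["test_id"]) & set(thresholds)
    )
    for split in config.splits:
        key = f"labs_{split}"
        try:
            table = labs_mod.compare_labs(
                study.patients, study.labs, thresholds, tests,
                split=split, estimator=config.estimator,
            )
            table.to_csv(out_dir / f"{key}.tsv", sep="\t", index=False)
            report[key] = table
        except Exception as exc:
            logger.exception("lab scan %s failed", key)
            report["errors"][key] = str(exc)

    try:
        thr = thresholds[config.survival_test]
        pts = study.patients.copy()
        pts["surv_group"] = np.where(
            pts["trait_group"] == "very_high", "very_high", "other"
        )
        records = surv_mod.build_event_records(
            pts, study.labs, thr,
            direction=config.survival_direction,
            washout_days=config.washout_days,
            horizon_days=config.horizon_days,
            group_col="surv_group",
        )
        km = surv_mod.km_curve(records)
        km.to_csv(out_dir / "survival_km.tsv", sep="\t", index=False)
        stat, p = surv_mod.logrank_p(records)
        report["survival"] = {"records": records, "logrank_stat": stat,
                              "logrank_p": p}
        pd.DataFrame([{"statistic": stat, "p": p}]).to_csv(
            out_dir / "survival_logrank.tsv", sep="\t", index=False
        )
    except Exception as exc:
        logger.exception("survival stage failed")
        report["errors"]["survival"] = str(exc)

    if study.flags is not None and len(study.flags):
        try:
            eff = efficacy_compare(
                study.flags, study.patients,
                estimator=config.efficacy_estimator, adjust=True,
            )
            report["efficacy"] = eff
            est = eff["estimate"]
            pd.DataFrame(
                [{
                    "a": eff["table"].a, "b": eff["table"].b,
                    "c": eff["table"].c, "d": eff["table"].d,
                    "odds_ratio": est.point if est else np.nan,
                    "ci_low": est.ci_low if est else np.nan,
                    "ci_high": est.ci_high if est else np.nan,
                    "p": eff["p"],
                }]
            ).to_csv(out_dir / "efficacy.tsv", sep="\t", index=False)
        except Exception as exc:
            logger.exception("efficacy stage failed")
            report["errors"]["efficacy"] = str(exc)

    _write_log(config, report, out_dir)
    return report


def _write_log(config: StudyConfig, report: dict, out_dir: Path) -> None:
    resolved = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
        if not k.startswith("_") and k != "cuts"
    }
    log = {
        "config": resolved,
        "n_patients": report.get("n_patients", 0),
        "errors": report["errors"],
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))


def _plot_manhattan(manhattan: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(manhattan["position"], manhattan["neg_log10_p"],
               s=8 + 8 * manhattan["or_magnitude_class"], c="steelblue")
    ax.axhline(manhattan["dotted_line"].iloc[0], ls=":", c="grey")
    dashed = manhattan["dashed_line"].iloc[0]
    if np.isfinite(dashed):
        ax.axhline(dashed, ls="--", c="black")
    ax.set_xlabel("phenotype group")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
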