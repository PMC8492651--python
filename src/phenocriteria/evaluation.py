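"""Age-resolved sensitivity, median ages at meeting criteria, Monte-Carlo
specificity and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from phenocriteria import cohort_synthesis, control_simulation, similarity
from phenocriteria.classifier import cross_validate, feature_ratios, train
from phenocriteria.control_simulation import SimulatedIndividual
from phenocriteria.criteria import (
    MAX_AGE_MONTHS,
    CriteriaDefinition,
    ParticipantProfile,
    age_first_met,
    existing_criteria_definition,
    get_criteria,
    meets_criteria,
    proposed_criteria_definition,
    read_cohort,
)
from phenocriteria.ontology import (
    Ontology,
    information_content,
    parse_obo,
    read_annotations,
)

logger = logging.getLogger(__name__)

AGES = tuple(range(MAX_AGE_MONTHS + 1))


@dataclass(frozen=True)
class SensitivityCurve:
    """Fraction of the cohort meeting the criteria at each month 0..216."""

    ages_months: tuple
    sensitivity: tuple
    criteria_label: str
    family_history_used: bool

    def __post_init__(self) -> None:
        if len(self.ages_months) != len(self.sensitivity):
            raise ValueError("ages and sensitivity lengths differ")

    def at(self, age_months: int) -> float:
        return self.sensitivity[self.ages_months.index(age_months)]


@dataclass(frozen=True)
class SpecificityResult:
    n_controls: int
    true_negatives: int
    false_positives: int

    @property
    def specificity(self) -> float:
        return self.true_negatives / (self.true_negatives + self.false_positives)


def sensitivity_curve(
    cohort: Sequence[ParticipantProfile],
    defn: CriteriaDefinition,
    ont: Ontology,
    use_family_history: bool = True,
    use_molecular: bool = True,
) -> SensitivityCurve:
    """Monthly sensitivity from birth to 18 years.

    Features with unknown onset never count at a finite age. The curve is
    non-decreasing because features only accumulate with age.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    first_ages = [
        age_first_met(p, defn, ont, use_family_history, use_molecular) for p in cohort
    ]
    n = len(cohort)
    sens = tuple(
        sum(1 for a in first_ages if a is not None and a <= m) / n for m in AGES
    )
    return SensitivityCurve(
        ages_months=AGES,
        sensitivity=sens,
        criteria_label=defn.name,
        family_history_used=use_family_history,
    )


def median_age_at_criteria(
    cohort: Sequence[ParticipantProfile],
    defn: CriteriaDefinition,
    ont: Ontology,
    use_family_history: bool = True,
    use_molecular: bool = True,
) -> int | None:
    """Median over individuals of the age first meeting the criteria.

    Individuals who never meet count as +infinity. For even cohort sizes the
    lower of the two central order statistics is reported. Returns ``None``
    when the median is undefined because at least one central order statistic
    is infinite (i.e. half or more of the cohort never meets the criteria).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ages = sorted(
        float("inf") if a is None else a
        for a in (
            age_first_met(p, defn, ont, use_family_history, use_molecular)
            for p in cohort
        )
    )
    n = len(ages)
    upper = ages[n // 2]
    if upper == float("inf"):
        return None
    return int(ages[(n - 1) // 2])  # lower central statistic for even n


def specificity(
    controls: Sequence[SimulatedIndividual],
    defn: CriteriaDefinition,
    ont: Ontology,
) -> SpecificityResult:
    """TN / (TN + FP) over simulated controls.

    Controls have no onset data, so each is evaluated age-free ("adulthood":
    every sampled term counts), with family history and molecular diagnosis
    unavailable.
    """
    if not controls:
        raise ValueError("control set is empty")
    fp = 0
    for ind in controls:
        profile = ParticipantProfile(
            id=ind.disease_id,
            features=tuple((t, None) for t in sorted(ind.present_terms)),
        )
        if meets_criteria(
            profile, defn, ont, "any", use_family_history=False, use_molecular=False
        ):
            fp += 1
    tn = len(controls) - fp
    return SpecificityResult(
        n_controls=len(controls), true_negatives=tn, false_positives=fp
    )


# --- pipeline ----------------------------------------------------------------


DEFAULT_PIPELINE_CONFIG = {
    "k_similar": 500,
    "n_controls": 50_000,
    "seed": 0,
    "aggregation": "bma",
    "existing_variant": "methods",
    "use_family_history": True,
    "use_molecular": True,
    "exclude_diseases": ["OMIM:109400"],
    "train_classifier": False,
    "cv_folds": 10,
    "alpha": 1.0,
}


def _target_terms(ont: Ontology) -> list[str]:
    terms = existing_criteria_definition().all_terms() | proposed_criteria_definition().all_terms()
    return sorted(t for t in terms if t in ont)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute rank-diseases -> simulate-controls -> (optional) train-nbc ->
    sensitivity + specificity, writing a JSON report and curve TSV.

    *config* must name ``ontology`` and ``annotations`` paths and a cohort
    source (``cohort_file`` or ``synthetic_cohort: {n, seed, ...}``); other
    keys default from :data:`DEFAULT_PIPELINE_CONFIG`. Stage failures abort
    with a stage-named error and partial outputs are removed.
    """
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {"parameters": {k: v for k, v in cfg.items()}, "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        s = stage("load-ontology")
        ont = parse_obo(cfg["ontology"])
        table = read_annotations(cfg["annotations"], ont)
        ic = information_content(table, ont)
        report["stages"][s] = {"n_terms": len(ont), "n_diseases": len(table)}

        s = stage("rank-diseases")
        target = cfg.get("target_terms") or _target_terms(ont)
        k = min(cfg["k_similar"], len(table) - len(set(cfg["exclude_diseases"]) & set(table.annotations)))
        ranked = similarity.most_similar_diseases(
            target, table, ont, ic, k,
            exclude=cfg["exclude_diseases"], aggregation=cfg["aggregation"],
        )
        rank_path = outdir / "ranked_diseases.tsv"
        pd.DataFrame(
            [(i + 1, r.disease_id, r.score) for i, r in enumerate(ranked)],
            columns=["rank", "disease_id", "score"],
        ).to_csv(rank_path, sep="\t", index=False)
        written.append(rank_path)
        report["stages"][s] = {"k": k, "out": rank_path.name}

        s = stage("simulate-controls")
        rng = np.random.default_rng(cfg["seed"])
        controls = control_simulation.simulate_cohort(
            table, cfg["n_controls"], rng, disease_subset=[r.disease_id for r in ranked]
        )
        report["stages"][s] = {"n_controls": len(controls)}

        s = stage("load-cohort")
        if "cohort_file" in cfg:
            cohort = read_cohort(cfg["cohort_file"])
        elif "synthetic_cohort" in cfg:
            syn = dict(cfg["synthetic_cohort"] or {})
            base = cohort_synthesis.default_cohort_config(
                n_participants=syn.get("n", 48), seed=syn.get("seed", cfg["seed"])
            )
            cohort = cohort_synthesis.generate_cohort(base)
        else:
            raise ValueError("config must provide cohort_file or synthetic_cohort")
        report["stages"][s] = {"n_participants": len(cohort)}

        definitions = {
            "existing": existing_criteria_definition(cfg["existing_variant"]),
            "proposed": proposed_criteria_definition(),
        }

        if cfg["train_classifier"]:
            s = stage("train-nbc")
            vocabulary = _target_terms(ont)
            model = train(list(cohort), controls, vocabulary, ont, alpha=cfg["alpha"])
            model_path = outdir / "nbc_model.json"
            model.to_json(model_path)
            written.append(model_path)
            cv = cross_validate(
                list(cohort), controls, vocabulary, ont,
                folds=cfg["cv_folds"], alpha=cfg["alpha"],
                rng=np.random.default_rng(cfg["seed"]),
            )
            ratio_path = outdir / "feature_ratios.tsv"
            pd.DataFrame(
                [(r.term, r.p_case, r.p_control, r.log_ratio) for r in feature_ratios(model)],
                columns=["term", "p_case", "p_control", "log_ratio"],
            ).to_csv(ratio_path, sep="\t", index=False)
            written.append(ratio_path)
            report["stages"][s] = {
                "cv_mean_accuracy": cv.mean_accuracy,
                "cv_mean_sensitivity": cv.mean_sensitivity,
                "cv_mean_specificity": cv.mean_specificity,
                "model": model_path.name,
                "ratios": ratio_path.name,
            }

        s = stage("sensitivity")
        curves = {
            label: sensitivity_curve(
                cohort, defn, ont, cfg["use_family_history"], cfg["use_molecular"]
            )
            for label, defn in definitions.items()
        }
        curve_path = outdir / "sensitivity_curves.tsv"
        pd.DataFrame(
            {
                "age_months": list(AGES),
                "sensitivity_existing": list(curves["existing"].sensitivity),
                "sensitivity_proposed": list(curves["proposed"].sensitivity),
            }
        ).to_csv(curve_path, sep="\t", index=False)
        written.append(curve_path)
        report["stages"][s] = {
            "curves": curve_path.name,
            "median_age_months": {
                label: median_age_at_criteria(
                    cohort, defn, ont, cfg["use_family_history"], cfg["use_molecular"]
                )
                for label, defn in definitions.items()
            },
        }

        s = stage("specificity")
        report["stages"][s] = {}
        for label, defn in definitions.items():
            res = specificity(controls, defn, ont)
            report["stages"][s][label] = {
                "n_controls": res.n_controls,
                "true_negatives": res.true_negatives,
                "false_positives": res.false_positives,
                "specificity": res.specificity,
            }
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {s!r} failed: {exc}") from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    return report
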