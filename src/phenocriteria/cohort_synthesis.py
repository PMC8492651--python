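"""Synthetic survey-cohort generator.

Emulates a 48-participant cohort: each feature is drawn independently with
its published prevalence; non-congenital onsets come from a lognormal
parameterized by the published median (log-scale sigma 0.6 by default) and
truncated to [0, 216] months; congenital features onset at month 0.

The defaults transcribe the published per-feature prevalences and median
onset ages. Synthetic cohorts validate machinery — they do not reproduce
participant-level feature correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import norm

from phenocriteria.criteria import MAX_AGE_MONTHS, ParticipantProfile

DEFAULT_LOG_SIGMA = 0.6


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's marginal model: prevalence plus an onset distribution."""

    group_label: str
    term: str
    prevalence: float
    congenital: bool = False
    median_onset_months: float | None = None
    log_sigma: float = DEFAULT_LOG_SIGMA

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")
        if not self.congenital:
            if self.median_onset_months is None or self.median_onset_months <= 0:
                raise ValueError(
                    f"{self.group_label}: non-congenital features need a positive median onset"
                )


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int
    feature_specs: tuple
    p_family_history: float
    p_molecular_dx: float
    seed: int = 0
    # common pairwise feature correlation via a Gaussian copula; 0 = independent
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for p in (self.p_family_history, self.p_molecular_dx):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")


# prevalence, median onset (months) per feature; congenital features onset at 0
_DEFAULT_SPECS = (
    FeatureSpec("jaw keratocysts", "HP:0010603", 0.69, median_onset_months=120),
    FeatureSpec("palmar/plantar pitting", "HP:0010610", 0.69, median_onset_months=89),
    FeatureSpec("basal cell carcinoma", "HP:0002671", 0.69, median_onset_months=170),
    FeatureSpec("calcification of the falx cerebri", "HP:0005462", 0.29, median_onset_months=174),
    FeatureSpec("medulloblastoma", "HP:0002885", 0.06, median_onset_months=10),
    FeatureSpec("macrocephaly", "HP:0000256", 0.58, median_onset_months=1),
    FeatureSpec("ocular abnormality", "HP:0000518", 0.21, congenital=True),
    FeatureSpec("cleft lip/palate", "HP:0000175", 0.10, congenital=True),
    FeatureSpec("rib anomaly", "HP:0000772", 0.42, congenital=True),
    FeatureSpec("skeletal malformation", "HP:0000925", 0.46, congenital=True),
    FeatureSpec("ovarian/cardiac fibroma", "HP:0010618", 0.0, median_onset_months=60),
)


def default_cohort_config(n_participants: int = 48, seed: int = 0) -> CohortConfig:
    """The published per-feature prevalences and median onsets; first-degree
    family history at 25%, molecular diagnosis at 40%."""
    return CohortConfig(
        n_participants=n_participants,
        feature_specs=_DEFAULT_SPECS,
        p_family_history=0.25,
        p_molecular_dx=0.40,
        seed=seed,
    )


def sample_onset(spec: FeatureSpec, rng: np.random.Generator) -> int:
    """Draw an onset in months: 0 for congenital features, otherwise a
    median-parameterized lognormal rounded and truncated to [0, 216]."""
    if spec.congenital:
        return 0
    draw = math.exp(math.log(spec.median_onset_months) + spec.log_sigma * rng.standard_normal())
    return int(min(max(round(draw), 0), MAX_AGE_MONTHS))


def generate_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[ParticipantProfile]:
    """Sample a cohort: features independent Bernoulli draws, present features
    get sampled onsets, flags drawn independently. Seed-deterministic."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rho = config.correlation
    cohort = []
    for i in range(config.n_participants):
        if rho > 0.0:
            # one-factor Gaussian copula with marginal prevalences preserved
            shared = rng.standard_normal()
            z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * rng.standard_normal(
                len(config.feature_specs)
            )
            u = norm.cdf(z)
        else:
            u = rng.random(len(config.feature_specs))
        features = []
        for spec, u_j in zip(config.feature_specs, u):
            if u_j < spec.prevalence:
                features.append((spec.term, sample_onset(spec, rng)))
        cohort.append(
            ParticipantProfile(
                id=f"SYN{i:05d}",
                features=tuple(features),
                family_history_first_degree=bool(rng.random() < config.p_family_history),
                molecular_diagnosis=bool(rng.random() < config.p_molecular_dx),
            )
        )
    return cohort


# --- YAML config schema ------------------------------------------------------


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "n_participants": config.n_participants,
        "p_family_history": config.p_family_history,
        "p_molecular_dx": config.p_molecular_dx,
        "seed": config.seed,
        "correlation": config.correlation,
        "features": [
            {
                "label": s.group_label,
                "term": s.term,
                "prevalence": s.prevalence,
                "congenital": s.congenital,
                "median_onset_months": s.median_onset_months,
                "log_sigma": s.log_sigma,
            }
            for s in config.feature_specs
        ],
    }


def config_from_dict(d: dict) -> CohortConfig:
    return CohortConfig(
        n_participants=int(d["n_participants"]),
        p_family_history=float(d.get("p_family_history", 0.0)),
        p_molecular_dx=float(d.get("p_molecular_dx", 0.0)),
        seed=int(d.get("seed", 0)),
        correlation=float(d.get("correlation", 0.0)),
        feature_specs=tuple(
            FeatureSpec(
                group_label=f.get("label", f["term"]),
                term=f["term"],
                prevalence=float(f["prevalence"]),
                congenital=bool(f.get("congenital", False)),
                median_onset_months=f.get("median_onset_months"),
                log_sigma=float(f.get("log_sigma", DEFAULT_LOG_SIGMA)),
            )
            for f in d["features"]
        ),
    )


def save_config(config: CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8")


def load_config(path) -> CohortConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
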