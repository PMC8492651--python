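"""Bernoulli naive Bayes over descendant-aware binary phenotype features.

All probability arithmetic is carried out in log space. Feature extraction
is descendant-aware: a vocabulary term is "on" when the individual carries
the term or any of its ontology descendants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from phenocriteria.control_simulation import has_feature
from phenocriteria.ontology import Ontology

CLASSES = ("case", "control")


def featurize(individual, vocabulary: Sequence[str], ont: Ontology) -> np.ndarray:
    """Binary feature vector aligned to *vocabulary* (descendant-aware)."""
    if not vocabulary:
        raise ValueError("vocabulary must be nonempty")
    return np.array(
        [1 if has_feature(individual, t, ont) else 0 for t in vocabulary],
        dtype=np.int8,
    )


@dataclass(frozen=True)
class NBCModel:
    """Trained model: class log-priors and per-term Bernoulli log-probabilities.

    ``log_p_present[c]`` and ``log_p_absent[c]`` are arrays aligned to
    ``vocabulary``; smoothing keeps every probability strictly inside (0, 1).
    """

    vocabulary: tuple
    log_prior: Mapping[str, float]
    log_p_present: Mapping[str, np.ndarray]
    log_p_absent: Mapping[str, np.ndarray]
    alpha: float

    def p_present(self, cls: str, term: str) -> float:
        return float(np.exp(self.log_p_present[cls][self.vocabulary.index(term)]))

    def to_dict(self) -> dict:
        return {
            "vocabulary": list(self.vocabulary),
            "alpha": self.alpha,
            "log_prior": dict(self.log_prior),
            "log_p_present": {c: list(map(float, v)) for c, v in self.log_p_present.items()},
            "log_p_absent": {c: list(map(float, v)) for c, v in self.log_p_absent.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NBCModel":
        return cls(
            vocabulary=tuple(d["vocabulary"]),
            log_prior=dict(d["log_prior"]),
            log_p_present={c: np.asarray(v, dtype=float) for c, v in d["log_p_present"].items()},
            log_p_absent={c: np.asarray(v, dtype=float) for c, v in d["log_p_absent"].items()},
            alpha=float(d["alpha"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NBCModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FeatureRatio:
    term: str
    p_case: float
    p_control: float
    log_ratio: float


def _feature_matrix(individuals: Iterable, vocabulary: Sequence[str], ont: Ontology) -> np.ndarray:
    return np.vstack([featurize(ind, vocabulary, ont) for ind in individuals])


def train(
    cases: Sequence,
    controls: Sequence,
    vocabulary: Sequence[str],
    ont: Ontology,
    alpha: float = 1.0,
) -> NBCModel:
    """Fit Bernoulli parameters with Laplace smoothing.

    ``p(term | class) = (count_present + alpha) / (n_class + 2 * alpha)``;
    priors are the empirical class proportions.
    """
    if not cases or not controls:
        raise ValueError("both classes must be nonempty")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    vocabulary = tuple(vocabulary)
    data = {"case": cases, "control": controls}
    n_total = len(cases) + len(controls)
    log_prior, log_p_present, log_p_absent = {}, {}, {}
    for cls, members in data.items():
        x = _feature_matrix(members, vocabulary, ont)
        p = (x.sum(axis=0) + alpha) / (len(members) + 2.0 * alpha)
        log_prior[cls] = math.log(len(members) / n_total)
        log_p_present[cls] = np.log(p)
        log_p_absent[cls] = np.log1p(-p)
    return NBCModel(
        vocabulary=vocabulary,
        log_prior=log_prior,
        log_p_present=log_p_present,
        log_p_absent=log_p_absent,
        alpha=float(alpha),
    )


def predict_log_posterior(model: NBCModel, individual, ont: Ontology) -> dict:
    """Normalized log posterior per class (exp-values sum to 1)."""
    x = featurize(individual, model.vocabulary, ont)
    scores = {}
    for cls in model.log_prior:
        scores[cls] = model.log_prior[cls] + float(
            x @ model.log_p_present[cls] + (1 - x) @ model.log_p_absent[cls]
        )
    norm = logsumexp(list(scores.values()))
    return {cls: s - norm for cls, s in scores.items()}


def predict_class(model: NBCModel, individual, ont: Ontology) -> str:
    post = predict_log_posterior(model, individual, ont)
    # deterministic tie-break: class name order
    return max(sorted(post), key=lambda c: post[c])


def feature_ratios(model: NBCModel) -> list[FeatureRatio]:
    """Per-term case/control probability ratios, sorted by descending log-ratio.

    Ties break by ascending term ID so the ordering is deterministic.
    """
    out = []
    for i, term in enumerate(model.vocabulary):
        p_case = float(np.exp(model.log_p_present["case"][i]))
        p_control = float(np.exp(model.log_p_present["control"][i]))
        out.append(
            FeatureRatio(
                term=term,
                p_case=p_case,
                p_control=p_control,
                log_ratio=float(
                    model.log_p_present["case"][i] - model.log_p_present["control"][i]
                ),
            )
        )
    out.sort(key=lambda r: (-r.log_ratio, r.term))
    return out


@dataclass(frozen=True)
class CrossValidationResult:
    fold_accuracy: tuple
    fold_sensitivity: tuple
    fold_specificity: tuple

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.fold_specificity))


def _stratified_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return np.array_split(idx, folds)


def cross_validate(
    cases: Sequence,
    controls: Sequence,
    vocabulary: Sequence[str],
    ont: Ontology,
    folds: int = 10,
    alpha: float = 1.0,
    rng: np.random.Generator | None = None,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation; every record is tested exactly once.

    Class proportions are preserved per fold up to one member. Fold
    assignment is seed-deterministic via *rng*.
    """
    if len(cases) < folds or len(controls) < folds:
        raise ValueError(f"each class needs at least {folds} members")
    if rng is None:
        rng = np.random.default_rng(0)
    case_folds = _stratified_folds(len(cases), folds, rng)
    control_folds = _stratified_folds(len(controls), folds, rng)
    acc, sens, spec = [], [], []
    for f in range(folds):
        test_case_idx = set(case_folds[f].tolist())
        test_control_idx = set(control_folds[f].tolist())
        train_cases = [c for i, c in enumerate(cases) if i not in test_case_idx]
        train_controls = [c for i, c in enumerate(controls) if i not in test_control_idx]
        model = train(train_cases, train_controls, vocabulary, ont, alpha=alpha)
        tp = sum(
            predict_class(model, cases[i], ont) == "case" for i in sorted(test_case_idx)
        )
        tn = sum(
            predict_class(model, controls[i], ont) == "control"
            for i in sorted(test_control_idx)
        )
        n_case, n_control = len(test_case_idx), len(test_control_idx)
        acc.append((tp + tn) / (n_case + n_control))
        sens.append(tp / n_case)
        spec.append(tn / n_control)
    return CrossValidationResult(
        fold_accuracy=tuple(acc),
        fold_sensitivity=tuple(sens),
        fold_specificity=tuple(spec),
    )
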