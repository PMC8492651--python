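"""Monte-Carlo control individuals sampled from disease annotation profiles.

Each simulated individual belongs to one disease and carries a random
nonempty subset of that disease's annotated terms: the subset size k is
drawn uniformly from {1, ..., K} and the k terms are sampled uniformly
without replacement (``uniform-count``). A per-feature ``binomial``
inclusion model is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from phenocriteria.ontology import DiseaseAnnotationTable, Ontology

COUNT_MODELS = ("uniform-count", "binomial")


@dataclass(frozen=True)
class SimulatedIndividual:
    disease_id: str
    present_terms: frozenset


def simulate_individual(
    disease_id: str,
    table: DiseaseAnnotationTable,
    rng: np.random.Generator,
    count_model: str = "uniform-count",
    binomial_p: float = 0.5,
) -> SimulatedIndividual:
    """Sample one individual for *disease_id*; always at least one term present."""
    if disease_id not in table:
        raise KeyError(f"unknown disease {disease_id!r}")
    terms = sorted(table[disease_id])
    big_k = len(terms)
    if count_model == "uniform-count":
        k = int(rng.integers(1, big_k + 1))
    elif count_model == "binomial":
        k = int(rng.binomial(big_k, binomial_p))
        k = max(k, 1)
    else:
        raise ValueError(f"unknown count model {count_model!r}; choose from {COUNT_MODELS}")
    chosen = rng.choice(big_k, size=k, replace=False)
    return SimulatedIndividual(
        disease_id=disease_id,
        present_terms=frozenset(terms[i] for i in chosen),
    )


def simulate_cohort(
    table: DiseaseAnnotationTable,
    n: int,
    rng: np.random.Generator,
    disease_subset: Sequence[str] | None = None,
    count_model: str = "uniform-count",
    binomial_p: float = 0.5,
) -> list[SimulatedIndividual]:
    """Sample *n* individuals, each from a disease drawn uniformly from the subset.

    The subset defaults to every disease in the table. Sampling is
    reproducible: the same seeded generator and inputs give an identical
    cohort.
    """
    if disease_subset is None:
        diseases = sorted(table.annotations)
    else:
        diseases = sorted(disease_subset)
        unknown = [d for d in diseases if d not in table]
        if unknown:
            raise KeyError(f"diseases not in table: {unknown}")
    if not diseases:
        raise ValueError("disease subset is empty")
    picks = rng.integers(0, len(diseases), size=n)
    return [
        simulate_individual(diseases[i], table, rng, count_model, binomial_p)
        for i in picks
    ]


def _present_terms(individual) -> frozenset:
    # SimulatedIndividual carries present_terms; ParticipantProfile carries
    # timed features — both reduce to a term set here.
    terms = getattr(individual, "present_terms", None)
    if terms is not None:
        return frozenset(terms)
    return frozenset(t for t, _ in individual.features)


def has_feature(individual, term: str, ont: Ontology) -> bool:
    """Descendant-aware presence: true iff the individual carries *term* or any descendant."""
    return bool(_present_terms(individual) & ont.descendants(term))
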