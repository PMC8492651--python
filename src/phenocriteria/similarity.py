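"""Resnik term/profile similarity and top-k disease ranking.

Profile-level aggregation defaults to the symmetric best-match average
(BMA); ``max`` and ``mean-pairwise`` are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from phenocriteria.ontology import (
    DiseaseAnnotationTable,
    InformationContentTable,
    Ontology,
)

AGGREGATIONS = ("bma", "max", "mean-pairwise")


@dataclass(frozen=True)
class SimilarityResult:
    disease_id: str
    score: float


def resnik_term_sim(
    t1: str, t2: str, ont: Ontology, ic: InformationContentTable
) -> float:
    """IC of the most informative common ancestor (MICA) of two terms.

    Returns 0 when the terms share only the root, or when no common ancestor
    carries an IC entry.
    """
    common = ont.ancestors(t1) & ont.ancestors(t2)
    return max((ic.get(a, 0.0) for a in common), default=0.0)


def _best_match_mean(
    p1: Sequence[str], p2: Sequence[str], ont: Ontology, ic: InformationContentTable
) -> float:
    return sum(
        max(resnik_term_sim(t, u, ont, ic) for u in p2) for t in p1
    ) / len(p1)


def profile_similarity(
    p1: Iterable[str],
    p2: Iterable[str],
    ont: Ontology,
    ic: InformationContentTable,
    aggregation: str = "bma",
) -> float:
    """Similarity between two term profiles.

    ``bma``
        symmetric best-match average: each term is matched to its best
        counterpart, averaged within each direction, then the two directional
        means are averaged — symmetric by construction.
    ``max``
        maximum over all term pairs.
    ``mean-pairwise``
        mean over all term pairs.
    """
    s1 = sorted({ont.resolve(t) for t in p1})
    s2 = sorted({ont.resolve(t) for t in p2})
    if not s1 or not s2:
        raise ValueError("profiles must be nonempty")
    if aggregation == "bma":
        return 0.5 * (_best_match_mean(s1, s2, ont, ic) + _best_match_mean(s2, s1, ont, ic))
    if aggregation == "max":
        return max(resnik_term_sim(t, u, ont, ic) for t in s1 for u in s2)
    if aggregation == "mean-pairwise":
        return sum(
            resnik_term_sim(t, u, ont, ic) for t in s1 for u in s2
        ) / (len(s1) * len(s2))
    raise ValueError(f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}")


def most_similar_diseases(
    target: Iterable[str],
    table: DiseaseAnnotationTable,
    ont: Ontology,
    ic: InformationContentTable,
    k: int,
    exclude: Iterable[str] = (),
    aggregation: str = "bma",
) -> list[SimilarityResult]:
    """The *k* diseases whose annotation profiles are most similar to *target*.

    Sorted by descending score with ties broken by ascending disease ID, so
    the top-k set is deterministic under any input ordering. Diseases listed
    in *exclude* (typically the target disease itself) are not candidates.
    """
    target = list(target)
    if not target:
        raise ValueError("target profile must be nonempty")
    excluded = set(exclude)
    candidates = [d for d in table.annotations if d not in excluded]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate diseases")
    scored = [
        SimilarityResult(d, profile_similarity(target, table[d], ont, ic, aggregation))
        for d in candidates
    ]
    scored.sort(key=lambda r: (-r.score, r.disease_id))
    return scored[:k]
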