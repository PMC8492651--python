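from __future__ import annotations

import numpy as np
import pytest

from phenocriteria import datasets
from phenocriteria.ontology import (
    DiseaseAnnotationTable,
    Ontology,
    information_content,
    parse_obo,
    read_annotations,
)

TINY_OBO = """\
format-version: 1.2

[Term]
id: FX:0000001
name: root

[Term]
id: FX:0000002
name: A
is_a: FX:0000001

[Term]
id: FX:0000003
name: B
is_a: FX:0000001

[Term]
id: FX:0000004
name: C
is_a: FX:0000002
"""

TINY_ANNOTATIONS = """\
disease_id\thpo_id
D1\tFX:0000004
D2\tFX:0000002
D2\tFX:0000003
D3\tFX:0000003
"""

R, A, B, C = "FX:0000001", "FX:0000002", "FX:0000003", "FX:0000004"


@pytest.fixture(scope="session")
def tiny_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("tiny") / "tiny.obo"
    path.write_text(TINY_OBO, encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def tiny_ont(tiny_obo_path) -> Ontology:
    return parse_obo(tiny_obo_path)


@pytest.fixture(scope="session")
def tiny_table(tmp_path_factory, tiny_ont) -> DiseaseAnnotationTable:
    path = tmp_path_factory.mktemp("tiny_ann") / "tiny.tsv"
    path.write_text(TINY_ANNOTATIONS, encoding="utf-8")
    return read_annotations(path, tiny_ont)


@pytest.fixture(scope="session")
def tiny_ic(tiny_table, tiny_ont):
    return information_content(tiny_table, tiny_ont)


@pytest.fixture(scope="session")
def mini_ont() -> Ontology:
    return parse_obo(datasets.mini_obo_path())


@pytest.fixture(scope="session")
def mini_table(mini_ont) -> DiseaseAnnotationTable:
    return read_annotations(datasets.mini_annotations_path(), mini_ont)


@pytest.fixture(scope="session")
def mini_ic(mini_table, mini_ont):
    return information_content(mini_table, mini_ont)


def random_ontology(rng: np.random.Generator, n_terms: int = 20) -> Ontology:
    """A random DAG ontology: term i>0 gets 1-2 parents among earlier terms."""
    ids = [f"RX:{i + 1:07d}" for i in range(n_terms)]
    parents = {ids[0]: frozenset()}
    for i in range(1, n_terms):
        n_par = int(rng.integers(1, min(3, i + 1)))
        picks = rng.choice(i, size=n_par, replace=False)
        parents[ids[i]] = frozenset(ids[j] for j in picks)
    return Ontology(
        terms=frozenset(ids),
        parents=parents,
        names={t: t for t in ids},
        alt_map={},
    )


def random_annotations(
    rng: np.random.Generator, ont: Ontology, n_diseases: int = 6
) -> DiseaseAnnotationTable:
    terms = sorted(ont.terms)
    annotations = {}
    for d in range(n_diseases):
        k = int(rng.integers(1, 5))
        picks = rng.choice(len(terms), size=k, replace=False)
        annotations[f"DX:{d:06d}"] = frozenset(terms[i] for i in picks)
    return DiseaseAnnotationTable(annotations=annotations)


# --- independent oracles -----------------------------------------------------


def brute_force_ancestors(ont: Ontology, term: str) -> frozenset:
    """Reflexive closure by repeated single-step edge expansion to a fixed point."""
    out = {ont.resolve(term)}
    while True:
        grown = set(out)
        for t in out:
            grown |= set(ont.parents.get(t, ()))
        if grown == out:
            return frozenset(out)
        out = grown


def brute_force_ic(table: DiseaseAnnotationTable, ont: Ontology) -> dict:
    """Propagated counts computed per term by scanning every disease."""
    import math

    n = len(table)
    out = {}
    for t in sorted(ont.terms):
        count = 0
        for terms in table.annotations.values():
            if any(t in brute_force_ancestors(ont, u) for u in terms):
                count += 1
        if count:
            out[t] = -math.log(count / n) if count != n else 0.0
    return out


def brute_force_resnik(t1: str, t2: str, ont: Ontology, ic) -> float:
    common = brute_force_ancestors(ont, t1) & brute_force_ancestors(ont, t2)
    return max((ic.get(a, 0.0) for a in common), default=0.0)
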