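"""OBO ontology parsing, graph closure queries and annotation-based information content.

The ontology is a DAG of terms connected by ``is_a`` edges only. Closures are
reflexive: a term is its own ancestor and descendant, so an exact term match
satisfies any descendant-aware rule downstream.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_TERM_ID_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*):(\d+)$")


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed; message names the offending line."""


class OntologyStructureError(ValueError):
    """Raised when the is_a graph violates a structural invariant (e.g. a cycle)."""


class UnknownTermError(KeyError):
    """Raised when a term is not found in the ontology (after alt_id resolution)."""


def canonical_term_id(value: str) -> str:
    """Normalize a term identifier to ``PREFIX:NNNNNNN`` form.

    The prefix is upper-cased and the numeric part zero-padded to seven
    digits, matching the canonical HPO shape.
    """
    m = _TERM_ID_RE.match(value.strip())
    if m is None:
        raise ValueError(f"not a term identifier: {value!r}")
    prefix, num = m.groups()
    return f"{prefix.upper()}:{int(num):07d}"


@dataclass(frozen=True)
class Ontology:
    """An is_a DAG over canonical term identifiers.

    Attributes
    ----------
    terms : frozenset of str
        All non-obsolete canonical term IDs.
    parents : mapping term -> frozenset of term
        Direct ``is_a`` parents (within ``terms``).
    names : mapping term -> str
        Human-readable labels.
    alt_map : mapping term -> term
        Alternate IDs to their canonical term.
    """

    terms: frozenset
    parents: Mapping[str, frozenset]
    names: Mapping[str, str]
    alt_map: Mapping[str, str]
    _children: dict = field(default_factory=dict, repr=False, compare=False)
    _anc_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _desc_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        children: dict[str, set] = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        self._children.update({t: frozenset(c) for t, c in children.items()})

    def __contains__(self, term: str) -> bool:
        try:
            self.resolve(term)
        except UnknownTermError:
            return False
        return True

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term: str) -> str:
        """Map a (possibly alternate, possibly non-canonical) ID to its canonical term."""
        t = canonical_term_id(term)
        t = self.alt_map.get(t, t)
        if t not in self.terms:
            raise UnknownTermError(term)
        return t

    def name(self, term: str) -> str:
        return self.names.get(self.resolve(term), "")

    def roots(self) -> frozenset:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> frozenset:
        """Reflexive-transitive is_a closure of *term* (includes the term itself)."""
        t = self.resolve(term)
        cached = self._anc_cache.get(t)
        if cached is not None:
            return cached
        out = {t}
        stack = list(self.parents.get(t, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        result = frozenset(out)
        self._anc_cache[t] = result
        return result

    def descendants(self, term: str) -> frozenset:
        """Reflexive inverse closure of *term* (includes the term itself)."""
        t = self.resolve(term)
        cached = self._desc_cache.get(t)
        if cached is not None:
            return cached
        out = {t}
        stack = list(self._children.get(t, ()))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self._children.get(c, ()))
        result = frozenset(out)
        self._desc_cache[t] = result
        return result


def ancestors(ont: Ontology, term: str) -> frozenset:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ont.ancestors(term)


def descendants(ont: Ontology, term: str) -> frozenset:
    """Functional alias for :meth:`Ontology.descendants`."""
    return ont.descendants(term)


def parse_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Only ``is_a`` edges are used; obsolete terms are dropped entirely and
    their stanzas contribute nothing to ``alt_map``. ``alt_id`` tags are
    recorded so alternate IDs resolve to the canonical term.

    Raises
    ------
    OboParseError
        On a malformed stanza line (message includes the line number).
    OntologyStructureError
        If the resulting is_a graph contains a cycle.
    """
    path = Path(path)
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(f"{path}:{lineno}: malformed stanza header {raw.strip()!r}")
                in_term = line == "[Term]"
                if in_term:
                    current = {"is_a": [], "alt_id": [], "obsolete": False}
                    stanzas.append(current)
                continue
            if current is None or not in_term:
                continue  # header lines and non-Term stanzas
            if ":" not in line:
                raise OboParseError(f"{path}:{lineno}: malformed tag line {raw.strip()!r}")
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.strip()
            if tag == "id":
                current["id"] = value
            elif tag == "name":
                current["name"] = value
            elif tag == "is_a":
                current["is_a"].append(value.split()[0])
            elif tag == "alt_id":
                current["alt_id"].append(value)
            elif tag == "is_obsolete" and value.lower() == "true":
                current["obsolete"] = True

    terms: set[str] = set()
    names: dict[str, str] = {}
    raw_parents: dict[str, set] = {}
    alt_map: dict[str, str] = {}
    for st in stanzas:
        if st.get("obsolete"):
            continue
        if "id" not in st:
            raise OboParseError(f"{path}: [Term] stanza without an id tag")
        tid = canonical_term_id(st["id"])
        terms.add(tid)
        names[tid] = st.get("name", "")
        raw_parents.setdefault(tid, set()).update(canonical_term_id(p) for p in st["is_a"])
        for alt in st["alt_id"]:
            alt_map[canonical_term_id(alt)] = tid

    # keep only edges into the surviving term set (drops links to obsolete terms)
    parents = {t: frozenset(p for p in raw_parents.get(t, ()) if p in terms) for t in terms}

    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from((t, p) for t, ps in parents.items() for p in ps)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyStructureError(f"is_a graph contains a cycle: {cycle}")

    return Ontology(
        terms=frozenset(terms),
        parents=parents,
        names=names,
        alt_map=alt_map,
    )


@dataclass(frozen=True)
class DiseaseAnnotationTable:
    """Mapping from disease ID (e.g. ``OMIM:109400``) to its set of annotated terms."""

    annotations: Mapping[str, frozenset]

    def __len__(self) -> int:
        return len(self.annotations)

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.annotations

    def __getitem__(self, disease_id: str) -> frozenset:
        return self.annotations[disease_id]

    def diseases(self) -> list[str]:
        return sorted(self.annotations)


def read_annotations(path: str | Path, ont: Ontology) -> DiseaseAnnotationTable:
    """Read a ``disease_id<TAB>hpo_id`` table against a companion ontology.

    Alternate IDs are resolved to canonical terms; rows whose term is not in
    the ontology are dropped with a warning; diseases left with no valid
    terms are removed. Duplicate rows collapse under set semantics.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    # accept the HPOA column name for the disease identifier
    if "database_id" in df.columns and "disease_id" not in df.columns:
        df = df.rename(columns={"database_id": "disease_id"})
    required = {"disease_id", "hpo_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    annotations: dict[str, set] = {}
    for disease_id, hpo_id in zip(df["disease_id"], df["hpo_id"]):
        try:
            term = ont.resolve(hpo_id)
        except (UnknownTermError, ValueError):
            logger.warning("dropping annotation %s -> %s: term not in ontology", disease_id, hpo_id)
            continue
        annotations.setdefault(disease_id, set()).add(term)

    return DiseaseAnnotationTable(
        annotations={d: frozenset(ts) for d, ts in annotations.items() if ts}
    )


@dataclass(frozen=True)
class InformationContentTable:
    """Per-term information content in nats; terms with zero propagated count are absent.

    Missing terms are treated as IC 0 by similarity computations (see
    :meth:`get`), which avoids infinities for never-annotated terms.
    """

    ic: Mapping[str, float]

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __len__(self) -> int:
        return len(self.ic)

    def get(self, term: str, default: float = 0.0) -> float:
        return self.ic.get(term, default)


def information_content(table: DiseaseAnnotationTable, ont: Ontology) -> InformationContentTable:
    """Annotation-frequency information content: ``ic(t) = -ln p(t)``.

    ``p(t)`` is the fraction of diseases annotated to *t* or any descendant
    of *t* (equivalently: diseases one of whose terms has *t* as ancestor).
    """
    if len(table) == 0:
        raise ValueError("annotation table is empty")
    counts: Counter = Counter()
    for terms in table.annotations.values():
        covered: set = set()
        for t in terms:
            covered |= ont.ancestors(t)
        counts.update(covered)
    n = len(table)
    return InformationContentTable(
        ic={t: (0.0 if c == n else -math.log(c / n)) for t, c in counts.items()}
    )
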