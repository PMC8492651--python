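"""Encoding and evaluation of the existing (major/minor) and proposed
(point-based) diagnostic criteria, descendant-aware and age-aware.

Two rule variants exist for the legacy major/minor criteria because the
source material states two different decision rules:

* ``methods`` (default): diagnosis at 2 majors + 1 minor, or 1 major +
  3 minors.
* ``table`` variant: diagnosis at 1 major + molecular confirmation,
  2 majors, or 1 major + 2 minors.

Both treat a positive first-degree family history as an additional major
when family history is in use. The proposed point scheme awards 3/2/1
points per cardinal/suggestive/possible feature group, recommends testing
at >= 6 points, and treats family history as a standalone trigger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from phenocriteria.ontology import Ontology, canonical_term_id

MAX_AGE_MONTHS = 216  # 18 years
AgeSpec = int | Literal["any"]

EXISTING_RULE_VARIANTS = ("methods", "table")


@dataclass(frozen=True)
class TermGroup:
    """An "or"-group: satisfied when any member term matches descendant-aware."""

    terms: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("TermGroup needs at least one term")
        object.__setattr__(
            self, "terms", frozenset(canonical_term_id(t) for t in self.terms)
        )


def _group(label: str, *terms: str) -> TermGroup:
    return TermGroup(terms=frozenset(terms), label=label)


@dataclass(frozen=True)
class Tier:
    name: str
    groups: tuple
    weight: int


@dataclass(frozen=True)
class CriteriaDefinition:
    """Tiered term groups plus a decision rule.

    ``kind == "points"``: a profile meets criteria when the sum of tier
    weights over satisfied groups reaches ``threshold`` (family history is a
    standalone trigger when in use).

    ``kind == "major_minor"``: the first tier is "major", the second
    "minor"; the profile meets criteria when the satisfied (major, minor)
    counts dominate any pair in ``sufficient_combinations``, or — with
    molecular testing in use — the pair in ``molecular_combination``.
    Family history counts as one extra major when in use.
    """

    name: str
    kind: Literal["major_minor", "points"]
    tiers: tuple
    family_history_role: Literal["counts_as_major", "standalone_trigger"]
    sufficient_combinations: tuple = ()
    molecular_combination: tuple | None = None
    threshold: int | None = None

    def __post_init__(self) -> None:
        seen = set()
        for tier in self.tiers:
            for g in tier.groups:
                if g.terms in seen:
                    raise ValueError(f"duplicate term group {sorted(g.terms)}")
                seen.add(g.terms)
        if self.kind == "points":
            if self.threshold is None:
                raise ValueError("points-kind criteria require a threshold")
            if any(t.weight <= 0 for t in self.tiers):
                raise ValueError("points-kind tiers need positive weights")

    def all_terms(self) -> frozenset:
        return frozenset(t for tier in self.tiers for g in tier.groups for t in g.terms)

    @property
    def n_major_slots(self) -> int:
        """Major slots for major/minor criteria: coded groups plus the
        family-history slot when family history counts as a major."""
        if self.kind != "major_minor":
            raise ValueError("major slots are defined for major_minor criteria only")
        n = len(self.tiers[0].groups)
        if self.family_history_role == "counts_as_major":
            n += 1
        return n

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "family_history_role": self.family_history_role,
            "tiers": [
                {
                    "name": t.name,
                    "weight": t.weight,
                    "groups": [
                        {"label": g.label, "terms": sorted(g.terms)} for g in t.groups
                    ],
                }
                for t in self.tiers
            ],
            "sufficient_combinations": [list(c) for c in self.sufficient_combinations],
            "molecular_combination": (
                list(self.molecular_combination) if self.molecular_combination else None
            ),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CriteriaDefinition":
        return cls(
            name=d["name"],
            kind=d["kind"],
            family_history_role=d["family_history_role"],
            tiers=tuple(
                Tier(
                    name=t["name"],
                    weight=int(t["weight"]),
                    groups=tuple(
                        TermGroup(terms=frozenset(g["terms"]), label=g.get("label", ""))
                        for g in t["groups"]
                    ),
                )
                for t in d["tiers"]
            ),
            sufficient_combinations=tuple(
                tuple(c) for c in d.get("sufficient_combinations", [])
            ),
            molecular_combination=(
                tuple(d["molecular_combination"]) if d.get("molecular_combination") else None
            ),
            threshold=d.get("threshold"),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "CriteriaDefinition":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ParticipantProfile:
    """One patient: timed phenotype features plus family-history and
    molecular-diagnosis flags.

    Onset 0 encodes congenital/prenatal onset. ``None`` onset means the
    feature was reported without an age: it counts in age-free ("any")
    evaluation but is excluded at every finite age.
    """

    id: str
    features: tuple  # of (term_id, onset_months | None)
    family_history_first_degree: bool = False
    molecular_diagnosis: bool = False

    def __post_init__(self) -> None:
        feats = []
        for term, onset in self.features:
            if onset is not None and onset < 0:
                raise ValueError(f"negative onset for {term}")
            feats.append((canonical_term_id(term), onset))
        object.__setattr__(self, "features", tuple(feats))

    @property
    def present_terms(self) -> frozenset:
        return frozenset(t for t, _ in self.features)


# --- shipped criteria definitions -------------------------------------------

_EYE_GROUP = _group(
    "congenital structural eye abnormality",
    "HP:0000518", "HP:0000589", "HP:0000568", "HP:0008058",
)
_CLEFT_GROUP = _group("oral cleft", "HP:0000175", "HP:0410030")


def existing_criteria_definition(variant: str = "methods") -> CriteriaDefinition:
    """The legacy major/minor diagnostic criteria.

    *variant* selects the decision rule: ``methods`` (2 majors + 1 minor,
    or 1 major + 3 minors) or ``table`` (1 major + molecular dx, 2 majors,
    or 1 major + 2 minors). Family history counts as one major under both.
    """
    if variant not in EXISTING_RULE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {EXISTING_RULE_VARIANTS}")
    majors = Tier(
        name="major",
        weight=0,
        groups=(
            _group("jaw keratocysts", "HP:0010603"),
            _group("palmar/plantar pitting", "HP:0010610"),
            _group("calcification of the falx cerebri", "HP:0005462"),
            _group("basal cell carcinoma", "HP:0002671"),
        ),
    )
    minors = Tier(
        name="minor",
        weight=0,
        groups=(
            _group("medulloblastoma", "HP:0002885"),
            _group("macrocephaly", "HP:0000256"),
            _CLEFT_GROUP,
            _group("polydactyly", "HP:0010442"),
            _group("vertebral/rib anomaly", "HP:0000925", "HP:0000772"),
            _EYE_GROUP,
        ),
    )
    if variant == "methods":
        combos = ((2, 1), (1, 3))
    else:
        combos = ((2, 0), (1, 2))
    return CriteriaDefinition(
        name=f"existing-{variant}",
        kind="major_minor",
        tiers=(majors, minors),
        family_history_role="counts_as_major",
        sufficient_combinations=combos,
        molecular_combination=(1, 0),
    )


def proposed_criteria_definition() -> CriteriaDefinition:
    """The proposed point-based pediatric criteria (threshold 6; family
    history is a standalone trigger for molecular testing)."""
    cardinal = Tier(
        name="cardinal",
        weight=3,
        groups=(
            _group("jaw keratocysts", "HP:0010603"),
            _group("palmar/plantar pitting", "HP:0010610"),
            _group("calcification of the falx cerebri", "HP:0005462"),
            _group("basal cell carcinoma", "HP:0002671"),
            _group("rib anomaly", "HP:0000772"),
            _EYE_GROUP,
        ),
    )
    suggestive = Tier(
        name="suggestive",
        weight=2,
        groups=(
            _group("medulloblastoma", "HP:0002885"),
            _group("macrocephaly", "HP:0000256"),
            _group("vertebral anomaly", "HP:0000925"),
        ),
    )
    possible = Tier(
        name="possible",
        weight=1,
        groups=(
            _group("tall stature", "HP:0000098"),
            _group(
                "structural brain anomaly",
                "HP:0002119", "HP:0002126", "HP:0002308", "HP:0100702",
            ),
            _group("strabismus", "HP:0000486"),
            _group("natal teeth", "HP:0000695"),
            _CLEFT_GROUP,
            _group("genitourinary anomaly", "HP:0000107", "HP:0000104"),
            _group("hearing impairment", "HP:0000365"),
        ),
    )
    return CriteriaDefinition(
        name="proposed",
        kind="points",
        tiers=(cardinal, suggestive, possible),
        family_history_role="standalone_trigger",
        threshold=6,
    )


def get_criteria(name: str) -> CriteriaDefinition:
    """Look up a shipped criteria definition or load one from a JSON file."""
    if name == "existing":
        return existing_criteria_definition()
    if name in ("existing-methods", "existing-table"):
        return existing_criteria_definition(name.split("-", 1)[1])
    if name == "proposed":
        return proposed_criteria_definition()
    path = Path(name)
    if path.suffix == ".json" and path.exists():
        return CriteriaDefinition.from_json(path)
    raise ValueError(
        f"unknown criteria {name!r}: expected existing|existing-methods|"
        f"existing-table|proposed or a JSON file path"
    )


# --- evaluation --------------------------------------------------------------


def group_satisfied(
    profile: ParticipantProfile,
    g: TermGroup,
    ont: Ontology,
    at_age_months: AgeSpec = "any",
) -> bool:
    """True iff some profile feature falls under the group, subject to age.

    At a finite age only features with a known onset <= age count; at
    ``"any"`` every feature counts regardless of onset.
    """
    match_terms: set = set()
    for m in g.terms:
        match_terms |= ont.descendants(m)
    for term, onset in profile.features:
        if term not in match_terms:
            continue
        if at_age_months == "any":
            return True
        if onset is not None and onset <= at_age_months:
            return True
    return False


def _satisfied_counts(
    profile: ParticipantProfile,
    defn: CriteriaDefinition,
    ont: Ontology,
    at_age_months: AgeSpec,
) -> list[int]:
    return [
        sum(group_satisfied(profile, g, ont, at_age_months) for g in tier.groups)
        for tier in defn.tiers
    ]


def score_proposed(
    profile: ParticipantProfile,
    ont: Ontology,
    at_age_months: AgeSpec = "any",
    defn: CriteriaDefinition | None = None,
) -> int:
    """Point total under a points-kind definition (default: the proposed criteria).

    A group satisfied by several features contributes its weight once.
    """
    if defn is None:
        defn = proposed_criteria_definition()
    if defn.kind != "points":
        raise ValueError("score_proposed requires a points-kind definition")
    counts = _satisfied_counts(profile, defn, ont, at_age_months)
    return sum(c * tier.weight for c, tier in zip(counts, defn.tiers))


def meets_criteria(
    profile: ParticipantProfile,
    defn: CriteriaDefinition,
    ont: Ontology,
    at_age_months: AgeSpec = "any",
    use_family_history: bool = True,
    use_molecular: bool = True,
) -> bool:
    """Decision rule evaluated at an age (or age-free with ``"any"``)."""
    fh = use_family_history and profile.family_history_first_degree
    if defn.kind == "points":
        if fh and defn.family_history_role == "standalone_trigger":
            return True
        return score_proposed(profile, ont, at_age_months, defn) >= defn.threshold

    n_major, n_minor = _satisfied_counts(profile, defn, ont, at_age_months)
    if fh and defn.family_history_role == "counts_as_major":
        n_major += 1
    for maj, mino in defn.sufficient_combinations:
        if n_major >= maj and n_minor >= mino:
            return True
    if (
        use_molecular
        and profile.molecular_diagnosis
        and defn.molecular_combination is not None
    ):
        maj, mino = defn.molecular_combination
        if n_major >= maj and n_minor >= mino:
            return True
    return False


def _group_min_onsets(
    profile: ParticipantProfile, defn: CriteriaDefinition, ont: Ontology
) -> list[list[float]]:
    """Per tier: earliest known onset at which each group becomes satisfied
    (inf when no dated feature matches)."""
    out = []
    for tier in defn.tiers:
        tier_onsets = []
        for g in tier.groups:
            match_terms: set = set()
            for m in g.terms:
                match_terms |= ont.descendants(m)
            onsets = [
                onset
                for term, onset in profile.features
                if term in match_terms and onset is not None
            ]
            tier_onsets.append(min(onsets) if onsets else float("inf"))
        out.append(tier_onsets)
    return out


def age_first_met(
    profile: ParticipantProfile,
    defn: CriteriaDefinition,
    ont: Ontology,
    use_family_history: bool = True,
    use_molecular: bool = True,
) -> int | None:
    """Smallest month in [0, 216] at which the profile meets the criteria.

    Family history (when used) counts from month 0 — affected relatives are
    assumed diagnosed before the child's birth. Returns ``None`` when the
    criteria are never met by 18 years.

    The criteria decision only changes at feature onsets, so only those
    candidate months are examined; the result is identical to a full
    monthly scan.
    """
    fh = use_family_history and profile.family_history_first_degree
    if fh and defn.family_history_role == "standalone_trigger":
        return 0
    onsets = _group_min_onsets(profile, defn, ont)
    candidates = sorted(
        {0}
        | {int(o) for tier in onsets for o in tier if o <= MAX_AGE_MONTHS}
    )

    def meets_at(age: int) -> bool:
        counts = [sum(o <= age for o in tier) for tier in onsets]
        if defn.kind == "points":
            score = sum(c * t.weight for c, t in zip(counts, defn.tiers))
            return score >= defn.threshold
        n_major, n_minor = counts
        if fh and defn.family_history_role == "counts_as_major":
            n_major += 1
        for maj, mino in defn.sufficient_combinations:
            if n_major >= maj and n_minor >= mino:
                return True
        if (
            use_molecular
            and profile.molecular_diagnosis
            and defn.molecular_combination is not None
        ):
            maj, mino = defn.molecular_combination
            if n_major >= maj and n_minor >= mino:
                return True
        return False

    for age in candidates:
        if meets_at(age):
            return age
    return None


# --- cohort TSV dialect ------------------------------------------------------

COHORT_COLUMNS = (
    "participant_id",
    "hpo_id",
    "onset_months",
    "family_history",
    "molecular_dx",
)


def write_cohort(cohort: Sequence[ParticipantProfile], path) -> None:
    """Write profiles as one row per feature (``NA`` placeholders for
    feature-less participants)."""
    rows = []
    for p in cohort:
        if not p.features:
            rows.append(
                (p.id, "NA", "NA", int(p.family_history_first_degree), int(p.molecular_diagnosis))
            )
        for term, onset in p.features:
            rows.append(
                (
                    p.id,
                    term,
                    "NA" if onset is None else int(onset),
                    int(p.family_history_first_degree),
                    int(p.molecular_diagnosis),
                )
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> list[ParticipantProfile]:
    """Read the cohort TSV dialect back into profiles (order of first appearance)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    profiles: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        rec = profiles.setdefault(
            row.participant_id,
            {
                "features": [],
                "fh": row.family_history == "1",
                "mdx": row.molecular_dx == "1",
            },
        )
        if row.hpo_id and row.hpo_id != "NA":
            onset = None if row.onset_months in ("", "NA") else int(row.onset_months)
            rec["features"].append((row.hpo_id, onset))
    return [
        ParticipantProfile(
            id=pid,
            features=tuple(rec["features"]),
            family_history_first_degree=rec["fh"],
            molecular_diagnosis=rec["mdx"],
        )
        for pid, rec in profiles.items()
    ]
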