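"""End-to-end roster classification: the exact → fuzzy → n-gram cascade,
the colour/race override, the immigrant-ancestry index and regional
aggregation.

Each distinct surname in the roster is resolved once: exact reference
lookup first, then fuzzy matching within the distance cap, and finally
the Cavnar-Trenkle classifier, which always returns a label, so every
surname ends up classified.  Person-level outputs are the combined
category (surname ancestry unless the registered colour/race is black,
mixed or native) and the ancestry index: 0 for exclusively Iberian
surnames, 1 for exclusively non-Iberian, 0.5 for one of each, in either
order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classifiers import CTModel, ct_classify
from .labels import COLOR_CODES, COLOR_OVERRIDES, AncestryLabel
from .matching import MatchConfig, match_surnames
from .normalize import SurnamePair, split_name
from .reference import ReferenceTable

__all__ = [
    "PersonRecord",
    "LabeledPerson",
    "RegionSummary",
    "classify_roster",
    "ancestry_index",
    "combine_with_color",
    "aggregate_by_region",
    "share_with_non_iberian_surname",
    "read_roster_csv",
    "write_labeled_csv",
]


@dataclass(frozen=True)
class PersonRecord:
    """One roster row before classification."""

    person_id: str
    surnames: SurnamePair
    region: str | None = None
    color: str | None = None

    def __post_init__(self) -> None:
        if self.color is not None and self.color not in COLOR_CODES:
            raise ValueError(
                f"unknown color code {self.color!r}; valid codes: {COLOR_CODES}"
            )


@dataclass(frozen=True)
class LabeledPerson:
    """Roster row after the cascade: per-surname labels/stages, combined
    category and ancestry index."""

    person: PersonRecord
    ancestry_penultimate: AncestryLabel | None
    ancestry_last: AncestryLabel
    stage_penultimate: str | None
    stage_last: str
    category: str
    index: float

    @property
    def labels(self) -> tuple[AncestryLabel, ...]:
        if self.ancestry_penultimate is None:
            return (self.ancestry_last,)
        return (self.ancestry_penultimate, self.ancestry_last)


@dataclass(frozen=True)
class RegionSummary:
    """Per-region ancestry-index aggregate."""

    region: str
    n: int
    index_sum: float

    @property
    def rate(self) -> float:
        return self.index_sum / self.n


def ancestry_index(labels: Sequence[AncestryLabel]) -> float:
    """Immigrant-ancestry index of one individual.

    0 when every surname is Iberian, 1 when none is, 0.5 when one of two
    is, irrespective of order.  Single-surname individuals score 0 when
    Iberian and 1 otherwise.
    """
    if not labels:
        raise ValueError("at least one surname label is required")
    non_iberian = sum(1 for label in labels if label is not AncestryLabel.IBR)
    return non_iberian / len(labels)


def combine_with_color(ancestry: AncestryLabel, color: str | None) -> str:
    """Combined 8-way category: colour/race codes black, mixed and native
    override the surname label; white, yellow or absent keep it."""
    if color is None:
        return ancestry.value
    if color not in COLOR_CODES:
        raise ValueError(
            f"unknown color code {color!r}; valid codes: {COLOR_CODES}"
        )
    return COLOR_OVERRIDES.get(color, ancestry.value)


def resolve_surnames(
    surnames: Iterable[str],
    ref: ReferenceTable,
    ct: CTModel,
    cfg: MatchConfig | None = None,
) -> dict[str, tuple[AncestryLabel, str]]:
    """Run the cascade once per distinct surname.

    Returns surname -> (label, stage) with stage in {exact, fuzzy, ct}.
    """
    matches = match_surnames(set(surnames), ref, cfg)
    resolved: dict[str, tuple[AncestryLabel, str]] = {}
    for surname, result in matches.items():
        if result.stage == "unmatched":
            resolved[surname] = (ct_classify(surname, ct).label, "ct")
        else:
            resolved[surname] = (result.ancestry, result.stage)
    return resolved


def classify_roster(
    roster: Sequence[PersonRecord],
    ref: ReferenceTable,
    ct: CTModel,
    cfg: MatchConfig | None = None,
) -> tuple[list[LabeledPerson], dict[str, Counter]]:
    """Classify every roster member through the cascade.

    Returns the labeled persons plus stage counts, both over surname
    occurrences (two per two-surname person) and over distinct surnames.
    """
    if not roster:
        raise ValueError("empty roster")
    distinct = {s for p in roster for s in p.surnames.labels_input()}
    resolved = resolve_surnames(distinct, ref, ct, cfg)
    labeled: list[LabeledPerson] = []
    occurrence_stages: Counter = Counter()
    for person in roster:
        pen = person.surnames.penultimate
        last = person.surnames.last
        label_last, stage_last = resolved[last]
        occurrence_stages[stage_last] += 1
        if pen is None:
            label_pen = stage_pen = None
            labels = (label_last,)
        else:
            label_pen, stage_pen = resolved[pen]
            occurrence_stages[stage_pen] += 1
            labels = (label_pen, label_last)
        labeled.append(
            LabeledPerson(
                person=person,
                ancestry_penultimate=label_pen,
                ancestry_last=label_last,
                stage_penultimate=stage_pen,
                stage_last=stage_last,
                category=combine_with_color(label_last, person.color),
                index=ancestry_index(labels),
            )
        )
    distinct_stages = Counter(stage for _, stage in resolved.values())
    return labeled, {"occurrences": occurrence_stages, "distinct": distinct_stages}


def aggregate_by_region(
    persons: Iterable[LabeledPerson],
) -> tuple[list[RegionSummary], int]:
    """Per-region n, index sum and rate = sum/n.

    Persons without a region code are excluded and counted.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    excluded = 0
    for p in persons:
        region = p.person.region
        if region is None or region == "":
            excluded += 1
            continue
        sums[region] = sums.get(region, 0.0) + p.index
        counts[region] = counts.get(region, 0) + 1
    summaries = [
        RegionSummary(region=r, n=counts[r], index_sum=sums[r])
        for r in sorted(sums)
    ]
    return summaries, excluded


def share_with_non_iberian_surname(
    persons: Sequence[LabeledPerson],
) -> tuple[float, float]:
    """Two population shares: (any non-Iberian surname, i.e. index > 0;
    non-Iberian LAST or unique surname)."""
    if not persons:
        raise ValueError("empty roster")
    any_non_ibr = sum(1 for p in persons if p.index > 0)
    last_non_ibr = sum(
        1 for p in persons if p.ancestry_last is not AncestryLabel.IBR
    )
    return any_non_ibr / len(persons), last_non_ibr / len(persons)


# ---------------------------------------------------------------------------
# Roster I/O


@dataclass
class RosterLoad:
    """Parsed roster plus the rows excluded by normalization."""

    persons: list[PersonRecord]
    no_surname_ids: list[str] = field(default_factory=list)


def read_roster_csv(
    path: str | Path,
    first_name_lexicon=None,
) -> RosterLoad:
    """Read a roster CSV with either a full `name` column or
    `surname1`/`surname2` columns, plus optional `region` and `color`.

    Rows whose name yields no surname are excluded and reported, never
    silently dropped.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in frame.columns:
        raise ValueError("roster CSV must have an 'id' column")
    has_name = "name" in frame.columns
    if not has_name and "surname2" not in frame.columns:
        raise ValueError("roster CSV needs a 'name' or 'surname1'/'surname2' columns")
    load = RosterLoad(persons=[])
    from .normalize import normalize_token

    for row in frame.to_dict("records"):
        region = row.get("region") or None
        color = row.get("color") or None
        if has_name:
            pair = split_name(row["name"], first_name_lexicon)
        else:
            s1 = normalize_token(row.get("surname1", ""))
            s2 = normalize_token(row.get("surname2", ""))
            if not s2:
                s2, s1 = s1, ""
            pair = SurnamePair(penultimate=s1 or None, last=s2) if s2 else None
        if pair is None:
            load.no_surname_ids.append(row["id"])
            continue
        load.persons.append(
            PersonRecord(person_id=row["id"], surnames=pair,
                         region=region, color=color)
        )
    return load


def write_labeled_csv(persons: Iterable[LabeledPerson], path: str | Path) -> None:
    """Labeled roster CSV with per-surname labels, stages, category, index."""
    rows = [
        {
            "id": p.person.person_id,
            "surname1": p.person.surnames.penultimate or "",
            "surname2": p.person.surnames.last,
            "region": p.person.region or "",
            "color": p.person.color or "",
            "ancestry1": p.ancestry_penultimate.value if p.ancestry_penultimate else "",
            "ancestry2": p.ancestry_last.value,
            "stage1": p.stage_penultimate or "",
            "stage2": p.stage_last,
            "category": p.category,
            "index": p.index,
        }
        for p in persons
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
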