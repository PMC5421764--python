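"""Reference-table construction from heterogeneous surname-ancestry sources.

Historical source lists (immigrant registers, census micro-data, name
collections) disagree with each other and with themselves.  Three
conflict-resolution rules clean them into a single surname -> ancestry
reference table:

1. within each source, keep a surname only when more than a configurable
   share (default 90%, strict) of its registrations carry one ancestry;
2. drop surnames whose total count in a source falls below that source's
   configured minimum (e.g. 8 for noisy census-type micro-data);
3. across sources, identical labels merge; conflicts are won by a
   designated priority source when it carries the surname, otherwise by
   the larger summed count, with exact ties dropped.

Every dropped surname is recorded in a build log written beside the
table, so the cleaning is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .labels import AncestryLabel
from .normalize import normalize_token

__all__ = [
    "SourceRecord",
    "BuilderConfig",
    "ReferenceTable",
    "BuildLog",
    "load_source_records",
    "resolve_within_source",
    "apply_min_count_filter",
    "merge_sources",
    "build_reference_table",
]


@dataclass(frozen=True)
class SourceRecord:
    """One (surname, ancestry, source, count) row from a source list."""

    surname: str
    ancestry: AncestryLabel
    source_id: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.surname:
            raise ValueError("surname empty after normalization")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class BuilderConfig:
    """Thresholds of the three conflict-resolution rules.

    agreement_threshold
        Strict within-source majority share required to keep a surname;
        a share of exactly the threshold is dropped ("more than 90%").
    min_count_sources
        Per-source minimum total occurrences; sources absent from the map
        use 1 (no filtering).  Apply 8 to census-type sources.
    priority_source
        Source whose label wins every cross-source conflict it takes
        part in (the immigrant-museum register in the original study).
    """

    agreement_threshold: float = 0.90
    min_count_sources: dict[str, int] = field(default_factory=dict)
    priority_source: str | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.agreement_threshold <= 1.0:
            raise ValueError("agreement_threshold must be in (0.5, 1]")
        if any(m < 1 for m in self.min_count_sources.values()):
            raise ValueError("minimum counts must be >= 1")


@dataclass
class BuildLog:
    """Audit trail of the builder: every dropped surname and its reason."""

    dropped: list[dict] = field(default_factory=list)
    unmapped_rows: int = 0
    parsed_rows: int = 0

    def drop(self, surname: str, source_id: str, reason: str, **extra) -> None:
        self.dropped.append(
            {"surname": surname, "source": source_id, "reason": reason, **extra}
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "parsed_rows": self.parsed_rows,
                "unmapped_rows": self.unmapped_rows,
                "n_dropped": len(self.dropped),
                "dropped": self.dropped,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text, "utf-8")
        return text


@dataclass
class ReferenceTable:
    """Deduplicated surname -> ancestry map with provenance."""

    entries: dict[str, AncestryLabel]
    provenance: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surname: str) -> bool:
        return surname in self.entries

    def label(self, surname: str) -> AncestryLabel:
        return self.entries[surname]

    def pairs(self) -> list[tuple[str, AncestryLabel]]:
        """(surname, label) pairs in deterministic (sorted) order."""
        return sorted(self.entries.items())

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {
                "surname": list(self.entries),
                "ancestry": [v.value for v in self.entries.values()],
                "source": [self.provenance.get(s, "") for s in self.entries],
            }
        ).sort_values("surname")
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = {"surname", "ancestry"} - set(frame.columns)
        if missing:
            raise ValueError(f"reference CSV missing columns: {sorted(missing)}")
        entries, provenance = {}, {}
        for row in frame.itertuples(index=False):
            surname = normalize_token(row.surname)
            entries[surname] = AncestryLabel.parse(row.ancestry)
            if getattr(row, "source", ""):
                provenance[surname] = row.source
        return cls(entries=entries, provenance=provenance)


def load_source_records(
    path: str | Path,
    source_id: str,
    *,
    surname_col: str = "surname",
    ancestry_col: str = "ancestry",
    count_col: str | None = "count",
    alias: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    log: BuildLog | None = None,
) -> list[SourceRecord]:
    """Parse a delimited source file into normalized :class:`SourceRecord`s.

    ``alias`` maps raw ancestry strings (e.g. "Italian") onto label codes;
    rows whose ancestry cannot be mapped are dropped and counted in the
    build log.  Files whose rows all fail to parse raise rather than
    silently yielding an empty source.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path, sep=delimiter, engine="python" if delimiter is None else "c",
        dtype=str, keep_default_na=False,
    )
    missing = {surname_col, ancestry_col} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    alias = {k.strip().upper(): v for k, v in (alias or {}).items()}
    valid = {m.value for m in AncestryLabel}
    records: list[SourceRecord] = []
    log = log if log is not None else BuildLog()
    for row in frame.to_dict("records"):
        log.parsed_rows += 1
        raw_label = str(row[ancestry_col]).strip().upper()
        code = alias.get(raw_label, raw_label)
        surname = normalize_token(str(row[surname_col]))
        if code not in valid or not surname:
            log.unmapped_rows += 1
            continue
        count = 1
        if count_col and count_col in frame.columns and str(row[count_col]).strip():
            count = int(float(row[count_col]))
        records.append(
            SourceRecord(surname=surname, ancestry=AncestryLabel(code),
                         source_id=source_id, count=count)
        )
    if not records:
        raise ValueError(f"{path}: no parseable rows")
    return records


def resolve_within_source(
    records: Iterable[SourceRecord],
    cfg: BuilderConfig,
    log: BuildLog | None = None,
) -> list[SourceRecord]:
    """Rule 1: per surname, keep the majority ancestry only when its share
    of registrations strictly exceeds the agreement threshold."""
    records = list(records)
    if not records:
        return []
    sources = {r.source_id for r in records}
    if len(sources) > 1:
        raise ValueError(f"records span multiple sources: {sorted(sources)}")
    source_id = records[0].source_id
    by_surname: dict[str, dict[AncestryLabel, int]] = {}
    for r in records:
        by_surname.setdefault(r.surname, {}).setdefault(r.ancestry, 0)
        by_surname[r.surname][r.ancestry] += r.count
    kept: list[SourceRecord] = []
    for surname in sorted(by_surname):
        shares = by_surname[surname]
        total = sum(shares.values())
        best = max(shares.values())
        if best / total > cfg.agreement_threshold:
            winner = min(c for c, v in shares.items() if v == best)
            kept.append(SourceRecord(surname, winner, source_id, total))
        elif log is not None:
            log.drop(surname, source_id, "ambiguous_within_source",
                     share=round(best / total, 4))
    return kept


def apply_min_count_filter(
    records: Iterable[SourceRecord],
    cfg: BuilderConfig,
    log: BuildLog | None = None,
) -> list[SourceRecord]:
    """Rule 2: drop surnames below the source's minimum total count."""
    kept: list[SourceRecord] = []
    for r in records:
        minimum = cfg.min_count_sources.get(r.source_id, 1)
        if r.count >= minimum:
            kept.append(r)
        elif log is not None:
            log.drop(r.surname, r.source_id, "below_min_count",
                     count=r.count, minimum=minimum)
    return kept


def merge_sources(
    per_source: Iterable[Iterable[SourceRecord]],
    cfg: BuilderConfig,
    log: BuildLog | None = None,
) -> ReferenceTable:
    """Rule 3: merge resolved sources; priority label wins conflicts,
    otherwise the larger summed count; exact ties are dropped."""
    by_surname: dict[str, list[SourceRecord]] = {}
    for records in per_source:
        for r in records:
            by_surname.setdefault(r.surname, []).append(r)
    entries: dict[str, AncestryLabel] = {}
    provenance: dict[str, str] = {}
    for surname in sorted(by_surname):
        recs = by_surname[surname]
        labels = {r.ancestry for r in recs}
        if len(labels) == 1:
            entries[surname] = recs[0].ancestry
            provenance[surname] = max(
                recs, key=lambda r: (r.count, r.source_id == cfg.priority_source,
                                     r.source_id)
            ).source_id
            continue
        priority = [r for r in recs if r.source_id == cfg.priority_source]
        if priority:
            entries[surname] = priority[0].ancestry
            provenance[surname] = cfg.priority_source
            continue
        by_label: dict[AncestryLabel, int] = {}
        for r in recs:
            by_label[r.ancestry] = by_label.get(r.ancestry, 0) + r.count
        best = max(by_label.values())
        winners = [c for c, v in by_label.items() if v == best]
        if len(winners) > 1:
            if log is not None:
                log.drop(surname, "+".join(sorted({r.source_id for r in recs})),
                         "cross_source_tie",
                         labels=sorted(c.value for c in winners))
            continue
        winner = winners[0]
        entries[surname] = winner
        provenance[surname] = max(
            (r for r in recs if r.ancestry == winner),
            key=lambda r: (r.count, r.source_id),
        ).source_id
    return ReferenceTable(
        entries=entries,
        provenance=provenance,
        config={
            "agreement_threshold": cfg.agreement_threshold,
            "min_count_sources": dict(cfg.min_count_sources),
            "priority_source": cfg.priority_source,
        },
    )


def build_reference_table(
    sources: Mapping[str, Iterable[SourceRecord]],
    cfg: BuilderConfig | None = None,
) -> tuple[ReferenceTable, BuildLog]:
    """Run all three rules over already-loaded per-source record lists."""
    cfg = cfg or BuilderConfig()
    log = BuildLog()
    resolved = []
    for source_id in sorted(sources):
        records = resolve_within_source(sources[source_id], cfg, log)
        resolved.append(apply_min_count_filter(records, cfg, log))
    table = merge_sources(resolved, cfg, log)
    return table, log
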