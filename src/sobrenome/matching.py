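"""Optimal String Alignment (OSA) distance and the exact-first fuzzy matcher.

OSA — the restricted Damerau-Levenshtein distance — counts unit-cost
insertions, deletions, substitutions and adjacent transpositions, with the
restriction that no substring is edited twice.  It therefore violates the
triangle inequality (e.g. CA→AC→ABC), which is why the matcher always
verifies candidate distances rather than relying on metric pruning.

The matcher is deliberately conservative: exact hits are resolved first;
fuzzy hits require a unanimous ancestry among the nearest reference
candidates within the distance cap, otherwise the query is left unmatched.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from .labels import AncestryLabel

__all__ = ["MatchConfig", "MatchResult", "osa_distance", "match_surnames"]

Stage = Literal["exact", "fuzzy", "unmatched"]


@dataclass(frozen=True)
class MatchConfig:
    """Fuzzy-matching parameters.

    max_distance
        Distance cap d; queries farther than d from every reference
        surname stay unmatched.  d=1 is the conservative production value;
        d=0 reduces the matcher to exact dictionary lookup.
    """

    max_distance: int = 1

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one query surname against the reference."""

    query: str
    stage: Stage
    matched_to: str | None = None
    distance: int | None = None
    ancestry: AncestryLabel | None = None
    #: True when equidistant nearest candidates disagreed on ancestry.
    ambiguous: bool = False


def osa_distance(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein distance between ``a`` and ``b``.

    Standard dynamic program over the (len(a)+1) x (len(b)+1) grid with
    the adjacent-transposition case added.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            best = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and ca == b[j - 2]
                and a[i - 2] == b[j - 1]
                and prev2[j - 2] + 1 < best
            ):
                best = prev2[j - 2] + 1
            cur[j] = best
        prev2, prev = prev, cur
    return prev[lb]


def _deletion_variants(s: str, d: int) -> set[str]:
    """All strings reachable from ``s`` by deleting up to ``d`` characters."""
    out = {s}
    frontier = {s}
    for _ in range(d):
        frontier = {
            v[:i] + v[i + 1 :] for v in frontier for i in range(len(v))
        }
        out |= frontier
    return out


class _SymDeleteIndex:
    """Symmetric-deletion candidate index for distance-capped lookup.

    Two strings within OSA distance d share at least one common variant
    obtained by deleting up to d characters from each, so intersecting
    deletion neighbourhoods yields a candidate superset; every candidate
    is then verified with the exact DP.  Results are provably identical
    to exhaustive search (and checked against it in the test suite).
    """

    def __init__(self, keys: Iterable[str], d: int) -> None:
        self.d = d
        self._buckets: dict[str, list[str]] = defaultdict(list)
        for key in keys:
            for variant in _deletion_variants(key, d):
                self._buckets[variant].append(key)

    def candidates(self, query: str) -> set[str]:
        found: set[str] = set()
        for variant in _deletion_variants(query, self.d):
            found.update(self._buckets.get(variant, ()))
        return found


def _reference_entries(ref) -> Mapping[str, AncestryLabel]:
    entries = getattr(ref, "entries", ref)
    if not entries:
        raise ValueError("reference table is empty")
    return entries


def match_surnames(
    queries: Iterable[str],
    ref,
    cfg: MatchConfig | None = None,
    *,
    exhaustive: bool = False,
) -> dict[str, MatchResult]:
    """Assign reference ancestries to query surnames, exact hits first.

    Parameters
    ----------
    queries
        Normalized query surnames (duplicates collapse).
    ref
        A :class:`~sobrenome.reference.ReferenceTable` or a plain mapping
        surname -> :class:`AncestryLabel`.
    cfg
        :class:`MatchConfig`; defaults to the production cap d=1.
    exhaustive
        Scan every reference surname instead of using the deletion index
        (slow; kept for the equivalence guarantee in tests).
    """
    cfg = cfg or MatchConfig()
    entries = _reference_entries(ref)
    results: dict[str, MatchResult] = {}
    pending: list[str] = []
    for q in set(queries):
        if q in entries:
            results[q] = MatchResult(
                q, "exact", matched_to=q, distance=0, ancestry=entries[q]
            )
        else:
            pending.append(q)
    if pending and cfg.max_distance > 0:
        index = None if exhaustive else _SymDeleteIndex(entries, cfg.max_distance)
        for q in pending:
            cand = entries.keys() if exhaustive else index.candidates(q)
            best_d: int | None = None
            best: list[str] = []
            for key in cand:
                if abs(len(key) - len(q)) > cfg.max_distance:
                    continue
                d = osa_distance(q, key)
                if d > cfg.max_distance:
                    continue
                if best_d is None or d < best_d:
                    best_d, best = d, [key]
                elif d == best_d:
                    best.append(key)
            if best_d is None:
                results[q] = MatchResult(q, "unmatched")
                continue
            labels = {entries[k] for k in best}
            if len(labels) == 1:
                winner = min(best)  # deterministic representative
                results[q] = MatchResult(
                    q, "fuzzy", matched_to=winner, distance=best_d,
                    ancestry=next(iter(labels)),
                )
            else:
                results[q] = MatchResult(q, "unmatched", ambiguous=True)
    else:
        for q in pending:
            results[q] = MatchResult(q, "unmatched")
    return results


def match_report_rows(results: Mapping[str, MatchResult]) -> list[dict]:
    """Rows for the CSV matcher report: surname,stage,matched_to,distance,ancestry."""
    return [
        {
            "surname": r.query,
            "stage": r.stage,
            "matched_to": r.matched_to or "",
            "distance": "" if r.distance is None else r.distance,
            "ancestry": r.ancestry.value if r.ancestry else "",
        }
        for r in sorted(results.values(), key=lambda r: r.query)
    ]
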