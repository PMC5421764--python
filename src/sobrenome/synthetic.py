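"""Synthetic reference tables and population rosters for testing the
classification cascade without access to restricted registry data.

The generator emulates the statistical structure the method relies on:

* five ancestry classes whose surnames have distinct character
  composition — either order-1 Markov chains fitted to small stylized
  seed lists (overlapping alphabets, realistic difficulty) or disjoint
  alphabet partitions (separable by construction);
* heavy-tailed surname frequency: per-class Zipf popularity whose
  exponent is calibrated analytically so the top five surnames cover a
  target share (45% by default) of roster occurrences;
* two surnames per person, drawn independently from the class mixture;
* typographic noise: a configurable fraction of surname occurrences is
  corrupted by exactly one random OSA edit.

Ground truth (true classes, corruption flags) is retained for every
person so pipeline outputs can be scored exactly.  All randomness flows
from a single master seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .labels import AncestryLabel
from .matching import osa_distance
from .normalize import normalize_token
from .pipeline import PersonRecord
from .normalize import SurnamePair
from .reference import ReferenceTable

__all__ = [
    "GeneratorSpec",
    "MarkovNameModel",
    "load_seed_surnames",
    "generate_class_surnames",
    "build_reference",
    "generate_roster",
    "inject_typo",
    "calibrate_zipf_exponent",
    "zipf_weights",
]

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_START, _END = "^", "$"

#: Disjoint five-way alphabet partition used by the separable mode.
DISJOINT_ALPHABETS: dict[AncestryLabel, str] = {
    AncestryLabel.IBR: "ABCDE",
    AncestryLabel.ITA: "FGHIJ",
    AncestryLabel.GER: "KLMNO",
    AncestryLabel.JPN: "PQRST",
    AncestryLabel.EAS: "UVWXY",
}

#: Substream indices of the master seed.
_STREAMS = {"reference": 0, "roster": 1, "typos": 2, "regions": 3}

_DEFAULT_MIXTURE = {
    AncestryLabel.IBR: 0.881,
    AncestryLabel.ITA: 0.072,
    AncestryLabel.GER: 0.032,
    AncestryLabel.EAS: 0.008,
    AncestryLabel.JPN: 0.007,
}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic data set.

    mixture_weights default to the population ancestry shares of the
    roster being emulated (heavily Iberian); zipf_exponent=None means
    "calibrate so the top five surnames cover top5_target of roster
    occurrences"; typo_rate is the per-occurrence probability of one
    single-edit corruption.
    """

    classes: tuple[AncestryLabel, ...] = tuple(_DEFAULT_MIXTURE)
    surnames_per_class: int = 600
    roster_size: int = 10_000
    mixture_weights: dict[AncestryLabel, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    zipf_exponent: float | None = None
    top5_target: float = 0.45
    typo_rate: float = 0.10
    mode: Literal["markov", "disjoint"] = "markov"
    markov_smoothing: float = 0.1
    min_len: int = 3
    max_len: int = 12
    n_regions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture_weights[c] for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0.0 <= self.typo_rate <= 1.0:
            raise ValueError("typo_rate must lie in [0, 1]")
        if self.zipf_exponent is not None and self.zipf_exponent < 0:
            raise ValueError("Zipf exponent must be >= 0")

    def resolved_exponent(self) -> float:
        if self.zipf_exponent is not None:
            return self.zipf_exponent
        return calibrate_zipf_exponent(
            weights=[self.mixture_weights[c] for c in self.classes],
            surnames_per_class=self.surnames_per_class,
            top5_target=self.top5_target,
        )


def load_seed_surnames(label: AncestryLabel) -> list[str]:
    """Bundled stylized seed surnames that parameterize a class generator."""
    text = (
        resources.files("sobrenome.resources.seeds")
        .joinpath(f"{label.value.lower()}.txt")
        .read_text("utf-8")
    )
    return [
        tok for line in text.splitlines()
        if (tok := normalize_token(line.split("#", 1)[0]))
    ]


class MarkovNameModel:
    """Order-1 character Markov chain over A-Z with start/end states."""

    def __init__(self, samples: Sequence[str], smoothing: float = 0.1) -> None:
        states = _START + _ALPHABET
        symbols = _ALPHABET + _END
        index = {c: i for i, c in enumerate(states)}
        counts = np.full((len(states), len(symbols)), smoothing)
        for name in samples:
            prev = _START
            for ch in name:
                counts[index[prev], symbols.index(ch)] += 1
                prev = ch
            counts[index[prev], symbols.index(_END)] += 1
        self._index = index
        self._symbols = symbols
        self._probs = counts / counts.sum(axis=1, keepdims=True)

    def sample(self, rng: np.random.Generator, min_len: int, max_len: int) -> str:
        out: list[str] = []
        prev = _START
        while len(out) < max_len:
            p = self._probs[self._index[prev]].copy()
            if len(out) < min_len:
                p[-1] = 0.0  # forbid END before the minimum length
                p /= p.sum()
            sym = self._symbols[rng.choice(len(self._symbols), p=p)]
            if sym == _END:
                break
            out.append(sym)
            prev = sym
        return "".join(out)


def generate_class_surnames(
    spec: GeneratorSpec,
    label: AncestryLabel,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Seeded sampling of ``surnames_per_class`` distinct surnames."""
    if rng is None:
        rng = _substream(spec.seed, "reference")
    want = spec.surnames_per_class
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    cap = max(50 * want, 10_000)
    if spec.mode == "disjoint":
        alphabet = DISJOINT_ALPHABETS[label]
        reachable = sum(
            len(alphabet) ** L for L in range(spec.min_len, spec.max_len + 1)
        )
        if want > reachable:
            raise ValueError(
                f"could not generate {want} distinct surnames for "
                f"{label.value}: only {reachable} strings exist"
            )
        while len(out) < want and attempts < cap:
            attempts += 1
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            name = "".join(
                alphabet[i] for i in rng.integers(0, len(alphabet), size=length)
            )
            if name not in seen:
                seen.add(name)
                out.append(name)
    else:
        model = MarkovNameModel(load_seed_surnames(label), spec.markov_smoothing)
        while len(out) < want and attempts < cap:
            attempts += 1
            name = model.sample(rng, spec.min_len, spec.max_len)
            if len(name) >= spec.min_len and name not in seen:
                seen.add(name)
                out.append(name)
    if len(out) < want:
        raise ValueError(
            f"could not generate {want} distinct surnames for {label.value}"
        )
    return out


def build_reference(spec: GeneratorSpec) -> ReferenceTable:
    """Synthetic surname -> ancestry reference with known ground truth.

    Cross-class duplicates (possible in Markov mode) are assigned to the
    first generating class and dropped from later ones, keeping surnames
    unique by construction.
    """
    rng = _substream(spec.seed, "reference")
    entries: dict[str, AncestryLabel] = {}
    for label in spec.classes:
        for name in generate_class_surnames(spec, label, rng):
            entries.setdefault(name, label)
    return ReferenceTable(
        entries=entries,
        provenance={s: "synthetic" for s in entries},
        config={"generator_seed": spec.seed, "mode": spec.mode},
    )


def zipf_weights(k: int, exponent: float) -> np.ndarray:
    """Normalized Zipf probabilities over ranks 1..k."""
    ranks = np.arange(1, k + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def calibrate_zipf_exponent(
    weights: Sequence[float],
    surnames_per_class: int,
    top5_target: float = 0.45,
    tol: float = 1e-6,
) -> float:
    """Exponent s such that the five globally most frequent surnames are
    expected to cover ``top5_target`` of occurrences.

    The occurrence probability of rank-k surname in class c is
    w_c * k^(-s) / H_{K}(s); coverage of the global top five is monotone
    increasing in s, so bisection applies.
    """

    def coverage(s: float) -> float:
        probs = np.concatenate(
            [w * zipf_weights(surnames_per_class, s) for w in weights]
        )
        return float(np.sort(probs)[-5:].sum())

    lo, hi = 0.0, 10.0
    if coverage(hi) < top5_target:
        raise ValueError("top5_target unreachable even at exponent 10")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if coverage(mid) < top5_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


_EDITS = ("insert", "delete", "substitute", "transpose")


def inject_typo(surname: str, rng: np.random.Generator) -> str:
    """Apply exactly one random single edit; the result always differs
    from the input, so osa_distance(input, output) == 1."""
    if len(surname) < 2:
        raise ValueError("surname must have length >= 2")
    while True:
        edit = _EDITS[int(rng.integers(0, len(_EDITS)))]
        if edit == "insert":
            pos = int(rng.integers(0, len(surname) + 1))
            ch = _ALPHABET[int(rng.integers(0, 26))]
            return surname[:pos] + ch + surname[pos:]
        if edit == "delete":
            pos = int(rng.integers(0, len(surname)))
            return surname[:pos] + surname[pos + 1 :]
        if edit == "substitute":
            pos = int(rng.integers(0, len(surname)))
            # draw from the 25 letters differing from the current one, so
            # the result always changes and edit types stay equiprobable
            others = _ALPHABET.replace(surname[pos], "")
            ch = others[int(rng.integers(0, len(others)))]
            return surname[:pos] + ch + surname[pos + 1 :]
        swappable = [
            i for i in range(len(surname) - 1) if surname[i] != surname[i + 1]
        ]
        if not swappable:  # e.g. "AA": transposition is a no-op, resample type
            continue
        pos = swappable[int(rng.integers(0, len(swappable)))]
        return (
            surname[:pos]
            + surname[pos + 1]
            + surname[pos]
            + surname[pos + 2 :]
        )


def generate_roster(
    spec: GeneratorSpec,
    reference: ReferenceTable,
) -> tuple[list[PersonRecord], pd.DataFrame]:
    """Sample a roster of two-surname persons with Zipf-skewed popularity.

    Returns the roster plus a ground-truth frame with one row per person:
    true class and corruption flag of each surname slot, the observed
    strings, whether each observed string is (still) a reference entry,
    and the true ancestry index.
    """
    by_class: dict[AncestryLabel, list[str]] = {c: [] for c in spec.classes}
    for surname, label in reference.entries.items():
        if label in by_class:
            by_class[label].append(surname)
    for label, names in by_class.items():
        if not names:
            raise ValueError(f"reference has no surnames of class {label.value}")
        names.sort()
    exponent = spec.resolved_exponent()
    rng = _substream(spec.seed, "roster")
    typo_rng = _substream(spec.seed, "typos")
    region_rng = _substream(spec.seed, "regions")
    class_list = list(spec.classes)
    mix = np.array([spec.mixture_weights[c] for c in class_list])
    # Popularity: rank r within a class gets Zipf weight r^(-s).  The
    # generated list order is random, so ranks are arbitrary but fixed.
    class_weights = {
        c: zipf_weights(len(by_class[c]), exponent) for c in class_list
    }
    persons: list[PersonRecord] = []
    truth_rows: list[dict] = []
    n = spec.roster_size
    slot_classes = rng.choice(len(class_list), size=(n, 2), p=mix)
    regions = region_rng.integers(0, spec.n_regions, size=n)
    for i in range(n):
        observed: list[str] = []
        true_labels: list[AncestryLabel] = []
        corrupted: list[bool] = []
        for slot in range(2):
            label = class_list[slot_classes[i, slot]]
            names = by_class[label]
            name = names[int(rng.choice(len(names), p=class_weights[label]))]
            is_typo = bool(typo_rng.random() < spec.typo_rate)
            if is_typo:
                name = inject_typo(name, typo_rng)
            observed.append(name)
            true_labels.append(label)
            corrupted.append(is_typo)
        person_id = f"P{i:06d}"
        persons.append(
            PersonRecord(
                person_id=person_id,
                surnames=SurnamePair(penultimate=observed[0], last=observed[1]),
                region=f"R{int(regions[i]):02d}",
            )
        )
        truth_rows.append(
            {
                "id": person_id,
                "true1": true_labels[0].value,
                "true2": true_labels[1].value,
                "observed1": observed[0],
                "observed2": observed[1],
                "corrupted1": corrupted[0],
                "corrupted2": corrupted[1],
                "in_ref1": observed[0] in reference.entries,
                "in_ref2": observed[1] in reference.entries,
                "true_index": ancestry_index_of(true_labels),
            }
        )
    return persons, pd.DataFrame(truth_rows)


def ancestry_index_of(labels: Sequence[AncestryLabel]) -> float:
    """Ground-truth ancestry index (same rule as the pipeline's)."""
    return sum(1 for c in labels if c is not AncestryLabel.IBR) / len(labels)


def write_simulation(
    spec: GeneratorSpec, out_dir: str | Path
) -> tuple[ReferenceTable, list[PersonRecord], pd.DataFrame]:
    """Generate and write reference.csv, roster.csv and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = build_reference(spec)
    persons, truth = generate_roster(spec, reference)
    reference.to_csv(out / "reference.csv")
    pd.DataFrame(
        {
            "id": [p.person_id for p in persons],
            "surname1": [p.surnames.penultimate for p in persons],
            "surname2": [p.surnames.last for p in persons],
            "region": [p.region for p in persons],
        }
    ).to_csv(out / "roster.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return reference, persons, truth
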