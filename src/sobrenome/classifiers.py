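"""Character n-gram classifiers for surnames left unmatched by fuzzy lookup.

Two classifiers are provided, both operating on padded character n-grams
(trigrams by default):

* Cavnar-Trenkle rank-profile categorization: each ancestry class keeps a
  frequency-ranked profile of its most common n-grams (1,250 by default);
  a query surname is assigned to the class whose profile is closest under
  the out-of-place measure (sum of rank displacements, with a maximum
  penalty for n-grams absent from the profile).
* Multinomial Naive Bayes over n-gram tokens with add-alpha smoothing,
  scored as MAP in log space: argmax_y log P(y) + sum_g log P(g | y).

Both models serialize losslessly to JSON.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .labels import AncestryLabel, TIE_BREAK_ORDER

__all__ = [
    "PAD",
    "make_ngrams",
    "rank_ngrams",
    "CTModel",
    "NBModel",
    "build_ct_profiles",
    "out_of_place_distance",
    "ct_classify",
    "nb_train",
    "nb_classify",
    "grid_search_ct",
]

PAD = "_"

LabeledPairs = Iterable[tuple[str, AncestryLabel]]


def _read_maybe_path(source: str | Path) -> str:
    """Accept either a JSON string or a path to a JSON file."""
    if isinstance(source, Path):
        return source.read_text("utf-8")
    text = str(source)
    if not text.lstrip().startswith("{"):
        return Path(text).read_text("utf-8")
    return text


def make_ngrams(surname: str, n: int = 3) -> list[str]:
    """All contiguous length-``n`` windows of the padded surname, in order.

    The surname is padded with n-1 underscores on each side to preserve
    word-boundary information, so "LIMA" yields the six trigrams
    __L, _LI, LIM, IMA, MA_, A__ and a length-L surname yields L+n-1
    n-grams.
    """
    if not surname:
        raise ValueError("cannot build n-grams of an empty surname")
    if n < 1:
        raise ValueError("n must be >= 1")
    padded = PAD * (n - 1) + surname + PAD * (n - 1)
    return [padded[i : i + n] for i in range(len(padded) - n + 1)]


def rank_ngrams(ngrams: Iterable[str]) -> list[str]:
    """Rank n-grams by frequency descending, ties broken lexicographically."""
    counts = Counter(ngrams)
    return sorted(counts, key=lambda g: (-counts[g], g))


def _as_pairs(train) -> list[tuple[str, AncestryLabel]]:
    pairs = getattr(train, "pairs", None)
    return list(pairs()) if callable(pairs) else list(train)


def _tie_argbest(scores: dict[AncestryLabel, float], *, largest: bool) -> tuple[AncestryLabel, bool]:
    """Best class under the fixed tie-break order; flags whether a tie occurred."""
    best = (max if largest else min)(scores.values())
    tied = [c for c in TIE_BREAK_ORDER if c in scores and scores[c] == best]
    return tied[0], len(tied) > 1


# ---------------------------------------------------------------------------
# Cavnar-Trenkle


@dataclass
class CTModel:
    """Per-class ranked n-gram profiles plus scoring parameters."""

    n: int
    profile_size: int
    profiles: dict[AncestryLabel, list[str]]
    #: "displacement" scores |query_rank - profile_rank|; "profile_rank"
    #: scores the (1-based) profile rank alone.
    penalty_mode: Literal["displacement", "profile_rank"] = "displacement"
    _rank_maps: dict[AncestryLabel, dict[str, int]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def rank_map(self, label: AncestryLabel) -> dict[str, int]:
        if label not in self._rank_maps:
            self._rank_maps[label] = {
                g: i for i, g in enumerate(self.profiles[label])
            }
        return self._rank_maps[label]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": "cavnar-trenkle",
            "n": self.n,
            "profile_size": self.profile_size,
            "penalty_mode": self.penalty_mode,
            "profiles": {c.value: p for c, p in self.profiles.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, "utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CTModel":
        data = json.loads(_read_maybe_path(source))
        return cls(
            n=data["n"],
            profile_size=data["profile_size"],
            penalty_mode=data.get("penalty_mode", "displacement"),
            profiles={
                AncestryLabel.parse(c): list(p) for c, p in data["profiles"].items()
            },
        )


def build_ct_profiles(
    train: LabeledPairs,
    n: int = 3,
    profile_size: int = 1250,
    penalty_mode: Literal["displacement", "profile_rank"] = "displacement",
    classes: Sequence[AncestryLabel] | None = None,
) -> CTModel:
    """Pool n-gram counts per class, rank them and truncate to profile_size."""
    pairs = _as_pairs(train)
    counts: dict[AncestryLabel, Counter] = {}
    for surname, label in pairs:
        counts.setdefault(label, Counter()).update(make_ngrams(surname, n))
    required = classes if classes is not None else list(counts)
    missing = [c for c in required if c not in counts]
    if missing or not counts:
        raise ValueError(f"classes without any training surname: {missing or 'all'}")
    profiles = {
        label: sorted(ctr, key=lambda g: (-ctr[g], g))[:profile_size]
        for label, ctr in counts.items()
    }
    return CTModel(n=n, profile_size=profile_size, profiles=profiles,
                   penalty_mode=penalty_mode)


def out_of_place_distance(
    query_ranked: Sequence[str],
    profile: Sequence[str] | dict[str, int],
    profile_size: int,
    penalty_mode: Literal["displacement", "profile_rank"] = "displacement",
) -> int:
    """Out-of-place measure between a ranked query and a class profile.

    Each query n-gram at query rank i with profile rank j contributes
    |i - j| (or j+1 in profile_rank mode); n-grams absent from the profile
    contribute the maximum penalty profile_size.
    """
    rank_of = profile if isinstance(profile, dict) else {g: i for i, g in enumerate(profile)}
    total = 0
    for i, gram in enumerate(query_ranked):
        j = rank_of.get(gram)
        if j is None:
            total += profile_size
        elif penalty_mode == "displacement":
            total += abs(i - j)
        else:
            total += j + 1
    return total


@dataclass(frozen=True)
class CTPrediction:
    label: AncestryLabel
    distances: dict[AncestryLabel, int]
    tie: bool = False


def ct_classify(surname: str, model: CTModel) -> CTPrediction:
    """Assign the class whose profile has the least out-of-place distance."""
    query = rank_ngrams(make_ngrams(surname, model.n))
    distances = {
        label: out_of_place_distance(
            query, model.rank_map(label), model.profile_size, model.penalty_mode
        )
        for label in model.profiles
    }
    label, tie = _tie_argbest({c: float(d) for c, d in distances.items()}, largest=False)
    return CTPrediction(label=label, distances=distances, tie=tie)


# ---------------------------------------------------------------------------
# Naive Bayes


@dataclass
class NBModel:
    """Multinomial Naive Bayes over n-gram tokens.

    Likelihoods use add-alpha smoothing over the union vocabulary plus one
    unseen slot, so every n-gram (seen or not) has strictly positive
    probability in every class.
    """

    n: int
    alpha: float
    priors: dict[AncestryLabel, float]
    log_likelihoods: dict[AncestryLabel, dict[str, float]]
    log_unseen: dict[AncestryLabel, float]

    def __post_init__(self) -> None:
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"priors must sum to 1, got {total}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": "naive-bayes",
            "n": self.n,
            "alpha": self.alpha,
            "priors": {c.value: p for c, p in self.priors.items()},
            "log_likelihoods": {
                c.value: ll for c, ll in self.log_likelihoods.items()
            },
            "log_unseen": {c.value: v for c, v in self.log_unseen.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, "utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NBModel":
        data = json.loads(_read_maybe_path(source))
        return cls(
            n=data["n"],
            alpha=data["alpha"],
            priors={AncestryLabel.parse(c): p for c, p in data["priors"].items()},
            log_likelihoods={
                AncestryLabel.parse(c): dict(ll)
                for c, ll in data["log_likelihoods"].items()
            },
            log_unseen={
                AncestryLabel.parse(c): v for c, v in data["log_unseen"].items()
            },
        )


def nb_train(train: LabeledPairs, n: int = 3, alpha: float = 1.0) -> NBModel:
    """Fit priors (class shares of training surnames) and smoothed likelihoods."""
    if alpha <= 0:
        raise ValueError("smoothing alpha must be > 0")
    pairs = _as_pairs(train)
    if not pairs:
        raise ValueError("empty training set")
    class_counts: Counter = Counter(label for _, label in pairs)
    gram_counts: dict[AncestryLabel, Counter] = {c: Counter() for c in class_counts}
    vocab: set[str] = set()
    for surname, label in pairs:
        grams = make_ngrams(surname, n)
        gram_counts[label].update(grams)
        vocab.update(grams)
    n_train = len(pairs)
    v_plus_unseen = len(vocab) + 1
    priors = {c: class_counts[c] / n_train for c in class_counts}
    log_likelihoods: dict[AncestryLabel, dict[str, float]] = {}
    log_unseen: dict[AncestryLabel, float] = {}
    for label, ctr in gram_counts.items():
        denom = sum(ctr.values()) + alpha * v_plus_unseen
        log_likelihoods[label] = {
            g: math.log((ctr.get(g, 0) + alpha) / denom) for g in vocab
        }
        log_unseen[label] = math.log(alpha / denom)
    return NBModel(n=n, alpha=alpha, priors=priors,
                   log_likelihoods=log_likelihoods, log_unseen=log_unseen)


@dataclass(frozen=True)
class NBPrediction:
    label: AncestryLabel
    posteriors: dict[AncestryLabel, float]
    tie: bool = False


def nb_classify(surname: str, model: NBModel) -> NBPrediction:
    """MAP classification; posteriors normalized in log space."""
    grams = make_ngrams(surname, model.n)
    logps: dict[AncestryLabel, float] = {}
    for label, prior in model.priors.items():
        ll = model.log_likelihoods[label]
        unseen = model.log_unseen[label]
        logps[label] = math.log(prior) + sum(ll.get(g, unseen) for g in grams)
    m = max(logps.values())
    weights = {c: math.exp(v - m) for c, v in logps.items()}
    z = sum(weights.values())
    posteriors = {c: w / z for c, w in weights.items()}
    label, tie = _tie_argbest(logps, largest=True)
    return NBPrediction(label=label, posteriors=posteriors, tie=tie)


def grid_search_ct(
    pairs: LabeledPairs,
    n_values: Sequence[int] = (2, 3, 4),
    profile_sizes: Sequence[int] = (250, 500, 1250),
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """Pick (n, profile_size) by held-out accuracy on a seeded split.

    Returns the best configuration and the full grid of results.  Mirrors
    the accuracy search by which the production defaults (n=3, 1,250)
    were originally chosen.
    """
    from .evaluation import ConfusionMatrix, accuracy, split_train_test

    pairs = _as_pairs(pairs)
    train, test = split_train_test(pairs, test_fraction, seed)
    results = []
    for n in n_values:
        for size in profile_sizes:
            model = build_ct_profiles(train, n=n, profile_size=size)
            predicted = [ct_classify(s, model).label for s, _ in test]
            observed = [label for _, label in test]
            acc = accuracy(ConfusionMatrix.from_predictions(observed, predicted))
            results.append({"n": n, "profile_size": size, "accuracy": acc})
    best = max(results, key=lambda r: (r["accuracy"], -r["n"], -r["profile_size"]))
    return best, results
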