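"""Name normalization: case/diacritic folding, particle removal and the
separation of (possibly compound) first names from surnames.

Brazilian rosters record a full name whose leading token(s) are given
names and whose trailing tokens are up to two inherited surnames (mother's
then father's).  Connective particles (DA, DOS, VON, ...) carry no
ancestry information and are dropped.  The canonical output of this module
is a :class:`SurnamePair` — the penultimate and last surnames, folded to
the bare A-Z alphabet so that edit distances and n-grams are well defined.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

__all__ = [
    "SurnamePair",
    "normalize_token",
    "strip_particles",
    "split_name",
    "default_particles",
    "default_first_name_lexicon",
]


@dataclass(frozen=True)
class SurnamePair:
    """Penultimate and last (or unique) surname of one individual.

    ``last`` is always present for a valid name; ``penultimate`` is absent
    for single-surname individuals.  Both are uppercase A-Z strings.
    """

    penultimate: str | None
    last: str

    def labels_input(self) -> tuple[str, ...]:
        """The surname strings present, in (penultimate, last) order."""
        return (self.last,) if self.penultimate is None else (self.penultimate, self.last)


def normalize_token(raw: str) -> str:
    """Fold one token to bare uppercase A-Z.

    Diacritics are decomposed and removed (Ç→C, Ã→A, Ü→U), the result is
    uppercased and every non-alphabetic character (apostrophes, hyphens,
    digits) is dropped, so hyphenated surnames concatenate into one token.
    May return the empty string.
    """
    decomposed = unicodedata.normalize("NFKD", raw)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return "".join(c for c in stripped.upper() if "A" <= c <= "Z")


def _load_resource(name: str) -> frozenset[str]:
    text = resources.files("sobrenome.resources").joinpath(name).read_text("utf-8")
    return frozenset(
        tok for line in text.splitlines()
        if (tok := normalize_token(line.split("#", 1)[0]))
    )


def default_particles() -> frozenset[str]:
    """Bundled set of non-significant name particles."""
    return _load_resource("particles.txt")


def default_first_name_lexicon() -> frozenset[str]:
    """Bundled lexicon of common given names (normalized)."""
    return _load_resource("first_names.txt")


def strip_particles(
    tokens: Iterable[str], particle_set: frozenset[str] | set[str] | None = None
) -> list[str]:
    """Remove particle tokens (full-token matches only, never prefixes)."""
    if particle_set is None:
        particle_set = default_particles()
    return [t for t in tokens if t not in particle_set]


def split_name(
    full: str,
    first_name_lexicon: frozenset[str] | set[str] | None = None,
    particle_set: frozenset[str] | set[str] | None = None,
) -> SurnamePair | None:
    """Split a raw full name into its :class:`SurnamePair`.

    Leading tokens found in the given-name lexicon are consumed greedily,
    left to right, as the (possibly compound) first name.  A multi-token
    name always surrenders at least its first token, even when that token
    is not in the lexicon.  Particles are stripped from the remainder; the
    last two surviving tokens form the pair.

    Returns ``None`` ("no surname") when nothing survives — e.g. the whole
    name consists of known given names, or of particles.
    """
    if first_name_lexicon is None:
        first_name_lexicon = default_first_name_lexicon()
    tokens = [t for t in (normalize_token(tok) for tok in full.split()) if t]
    if not tokens:
        return None
    if len(tokens) == 1:
        token = tokens[0]
        if token in first_name_lexicon or token in (
            particle_set if particle_set is not None else default_particles()
        ):
            return None
        return SurnamePair(penultimate=None, last=token)
    # Greedy first-name consumption; the first token is a given name by
    # position even when the lexicon does not know it.
    i = 1
    while i < len(tokens) and tokens[i] in first_name_lexicon:
        i += 1
    surnames = strip_particles(tokens[i:], particle_set)
    if not surnames:
        return None
    if len(surnames) == 1:
        return SurnamePair(penultimate=None, last=surnames[0])
    return SurnamePair(penultimate=surnames[-2], last=surnames[-1])
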