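"""Ancestry labels and the fixed class orders used throughout the package.

Five surname-ancestry classes are modelled, mirroring the main immigrant
groups that arrived in Brazil after 1872: Iberian (IBR), Italian (ITA),
German (GER), Japanese (JPN) and East European (EAS).  Three further
categories (BLK, MXD, NAT) arise only from the census colour/race override
applied at the person level — they are never surname labels.
"""

from __future__ import annotations

import enum


class AncestryLabel(str, enum.Enum):
    """Closed set of surname-ancestry classes."""

    IBR = "IBR"  # Iberian (Portuguese / Spanish)
    ITA = "ITA"  # Italian
    GER = "GER"  # German
    JPN = "JPN"  # Japanese
    EAS = "EAS"  # East European

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, value: str) -> "AncestryLabel":
        """Parse a label code, rejecting anything outside the closed set."""
        try:
            return cls(value.strip().upper())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown ancestry label {value!r}; valid codes: {valid}"
            ) from None


#: Deterministic tie-break order for classifier argmin/argmax.
TIE_BREAK_ORDER: tuple[AncestryLabel, ...] = (
    AncestryLabel.IBR,
    AncestryLabel.ITA,
    AncestryLabel.GER,
    AncestryLabel.JPN,
    AncestryLabel.EAS,
)

#: Alphabetical class order used for confusion matrices and reports.
CLASS_ORDER: tuple[AncestryLabel, ...] = (
    AncestryLabel.EAS,
    AncestryLabel.GER,
    AncestryLabel.IBR,
    AncestryLabel.ITA,
    AncestryLabel.JPN,
)

#: Combined person-level categories: the five surname classes plus the
#: colour/race override categories.
COMBINED_CATEGORIES: tuple[str, ...] = (
    "IBR", "ITA", "GER", "JPN", "EAS", "BLK", "MXD", "NAT",
)

#: Valid colour/race codes (the five categories of the Brazilian census).
COLOR_CODES: tuple[str, ...] = ("white", "black", "mixed", "yellow", "native")

#: Colour codes that override the surname-derived class.
COLOR_OVERRIDES: dict[str, str] = {
    "black": "BLK",
    "mixed": "MXD",
    "native": "NAT",
}
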