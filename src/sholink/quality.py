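"""Match-quality and match-confidence scales.

Each candidate record pair is rated in four variable categories -- name,
sex, age, residence -- on the ordered scale None < Low < Medium < High,
and then given an overall confidence Weak < Fair < Strong derived from
the pattern of the four category qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class Quality(IntEnum):
    """Category-level match quality, totally ordered."""

    NONE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return _QUALITY_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Quality":
        try:
            return _QUALITY_BY_LABEL[label.strip().casefold()]
        except KeyError:
            raise ValueError(f"unknown quality label: {label!r}") from None


class Confidence(IntEnum):
    """Overall pair-level match confidence, totally ordered."""

    WEAK = 0
    FAIR = 1
    STRONG = 2

    @property
    def label(self) -> str:
        return _CONFIDENCE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Confidence":
        try:
            return _CONFIDENCE_BY_LABEL[label.strip().casefold()]
        except KeyError:
            raise ValueError(f"unknown confidence label: {label!r}") from None


_QUALITY_LABELS = {
    Quality.NONE: "None",
    Quality.LOW: "Low",
    Quality.MEDIUM: "Medium",
    Quality.HIGH: "High",
}
_QUALITY_BY_LABEL = {v.casefold(): k for k, v in _QUALITY_LABELS.items()}
_CONFIDENCE_LABELS = {
    Confidence.WEAK: "Weak",
    Confidence.FAIR: "Fair",
    Confidence.STRONG: "Strong",
}
_CONFIDENCE_BY_LABEL = {v.casefold(): k for k, v in _CONFIDENCE_LABELS.items()}

CATEGORIES = ("name", "sex", "age", "residence")


@dataclass(frozen=True)
class CategoryQualities:
    """The four category qualities of one candidate pair."""

    name: Quality
    sex: Quality
    age: Quality
    residence: Quality

    def __iter__(self):
        return iter((self.name, self.sex, self.age, self.residence))

    @property
    def high_count(self) -> int:
        return sum(q == Quality.HIGH for q in self)

    def astuple(self) -> tuple[Quality, Quality, Quality, Quality]:
        return (self.name, self.sex, self.age, self.residence)
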