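"""ICD-10 cause grouping for the four NCD categories.

Underlying causes are grouped into cardiovascular diseases (I00-I99), cancers
(C00-C97), diabetes (E10-E14) and asthma & COPD (J30-J98).  Every other
syntactically valid code — and a small set of classic ill-defined ("garbage")
codes that fall *inside* those letter ranges, such as cardiac arrest I46 and
respiratory failure J96 — maps to the garbage category and is later
redistributed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

CAUSES: tuple[str, ...] = ("cvd", "cancers", "diabetes", "asthma_copd")
GARBAGE = "garbage"
CATEGORIES: tuple[str, ...] = CAUSES + (GARBAGE,)

#: Ill-defined / unusable underlying-cause codes used by the synthetic
#: corruption step.  They take precedence over the interval lookup: I46 and
#: J96 sit inside the CVD / respiratory letter ranges but are not usable
#: underlying causes.
GARBAGE_CODES: tuple[str, ...] = ("R99", "R54", "I46", "J96", "Y34")

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")


class ICDFormatError(ValueError):
    """Raised for strings that are not syntactically valid ICD-10 codes."""


@dataclass(frozen=True)
class CauseMap:
    """Ordered ICD-10 intervals -> cause category, with a garbage carve-out.

    ``intervals`` maps a category to an inclusive (letter, lo, hi) code range.
    Lookup is total: explicit garbage codes first, then the intervals, then
    garbage for everything else.
    """

    intervals: dict[str, tuple[str, int, int]] = field(default_factory=lambda: {
        "cvd": ("I", 0, 99),
        "cancers": ("C", 0, 97),
        "diabetes": ("E", 10, 14),
        "asthma_copd": ("J", 30, 98),
    })
    garbage_codes: frozenset[str] = frozenset(GARBAGE_CODES)

    def lookup(self, code: str) -> str:
        m = _CODE_RE.match(code.strip().upper())
        if m is None:
            raise ICDFormatError(f"not a valid ICD-10 code: {code!r}")
        letter, num = m.group(1), int(m.group(2))
        root = f"{letter}{m.group(2)}"
        if root in self.garbage_codes:
            return GARBAGE
        for category, (lt, lo, hi) in self.intervals.items():
            if letter == lt and lo <= num <= hi:
                return category
        return GARBAGE


DEFAULT_CAUSE_MAP = CauseMap()


def map_causes(icd10: str, cause_map: CauseMap = DEFAULT_CAUSE_MAP) -> str:
    """Map one ICD-10 code to {cvd, cancers, diabetes, asthma_copd, garbage}."""
    return cause_map.lookup(icd10)
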