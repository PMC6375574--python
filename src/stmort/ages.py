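"""Age-band definitions shared across the pipeline.

Analyses run on 13 five-year adult age bands, 25-29 through 85+ (open-ended).
Ages below 25 are outside the study population and are dropped during
registry preparation.
"""

from __future__ import annotations

AGE_GROUPS: tuple[str, ...] = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54", "55-59",
    "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)

AGE_STARTS: tuple[int, ...] = tuple(range(25, 90, 5))

AGE_INDEX: dict[str, int] = {g: i for i, g in enumerate(AGE_GROUPS)}

N_AGE_GROUPS = len(AGE_GROUPS)

MIN_AGE = 25

SEXES: tuple[str, str] = ("male", "female")


def band_for_age(age: int) -> str | None:
    """Return the 5-year band label for a single-year age, or None if < 25."""
    if age < MIN_AGE:
        return None
    if age >= 85:
        return "85+"
    start = (age // 5) * 5
    return f"{start}-{start + 4}"
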