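"""The scripted activity label set and its FT/NFT category mapping.

Ten laboratory activities performed on the dominant wrist: four involve
repeated hand-to-face contact (face-touching, FT) and six do not (NFT).
FT is the positive class in binary recognition.
"""

from __future__ import annotations

from dataclasses import dataclass

FT = "FT"
NFT = "NFT"


@dataclass(frozen=True)
class ActivityLabel:
    """A scripted activity with its face-touching category."""

    name: str
    category: str  # "FT" or "NFT"

    @property
    def is_ft(self) -> bool:
        return self.category == FT


# Canonical order: the six NFT activities, then the four FT activities.
ACTIVITIES: tuple[ActivityLabel, ...] = (
    ActivityLabel("Using mobile phone", NFT),
    ActivityLabel("Lying flat on the back", NFT),
    ActivityLabel("Computer tasks", NFT),
    ActivityLabel("Writing", NFT),
    ActivityLabel("Leisure walk", NFT),
    ActivityLabel("Moving items from one location to another", NFT),
    ActivityLabel("Repeated face touching", FT),
    ActivityLabel("Eating and drinking", FT),
    ActivityLabel("Simulated smoking", FT),
    ActivityLabel("Adjusting eyeglass", FT),
)

ACTIVITY_NAMES: tuple[str, ...] = tuple(a.name for a in ACTIVITIES)
BY_NAME: dict[str, ActivityLabel] = {a.name: a for a in ACTIVITIES}
FT_ACTIVITIES: tuple[str, ...] = tuple(a.name for a in ACTIVITIES if a.is_ft)
NFT_ACTIVITIES: tuple[str, ...] = tuple(a.name for a in ACTIVITIES if not a.is_ft)


def category_of(activity_name: str) -> str:
    """Return "FT" or "NFT" for a known activity name.

    Raises ``KeyError`` for unknown names; ingest wraps this in a
    :class:`~facetouch.errors.LabelError`.
    """
    return BY_NAME[activity_name].category
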