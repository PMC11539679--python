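"""Activity profiles: the fixed, ordered list of annotated resuscitation activities.

A profile pins the order of the activity channels for a dataset, and that order
determines the code assigned to each activity by the periodic encoding generator
(index ``i`` -> code ``2**i - 1``).  Two profiles ship with the package:

* ``SUS`` -- six activities annotated at Stavanger University Hospital
  (baby on table, drying, stimulation, ventilation, suction, chest compression).
* ``HAYDOM`` -- seven activities annotated at Haydom Lutheran Hospital
  (unwrapped baby, stimulation, ventilation, suction, attaching dry-electrode
  ECG, wrapped baby, chest compression).

Annotation labels are free text, so each profile carries an alias table; name
matching is case-insensitive after trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

MAX_ACTIVITIES = 16


@dataclass(frozen=True)
class ActivityProfile:
    """Ordered set of activity channels for one dataset.

    Parameters
    ----------
    name
        Short label for the profile (e.g. ``"SUS"``).
    activities
        Ordered activity names; position ``i`` (1-based) fixes the code
        ``2**i - 1``.  Between 1 and 16 unique names.
    acronyms
        Short labels used on figure axes ("+"-joined for simultaneous
        activities).  Defaults to the full names.
    aliases
        Mapping of alternative spellings (lower-case) to canonical names.
    """

    name: str
    activities: tuple[str, ...]
    acronyms: tuple[str, ...] = ()
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        acts = tuple(self.activities)
        if not 1 <= len(acts) <= MAX_ACTIVITIES:
            raise ValueError(
                f"profile must have 1..{MAX_ACTIVITIES} activities, got {len(acts)}"
            )
        if len({a.lower() for a in acts}) != len(acts):
            raise ValueError("activity names must be unique (case-insensitive)")
        object.__setattr__(self, "activities", acts)
        if not self.acronyms:
            object.__setattr__(self, "acronyms", acts)
        elif len(self.acronyms) != len(acts):
            raise ValueError("acronyms must match activities in length")
        else:
            object.__setattr__(self, "acronyms", tuple(self.acronyms))
        object.__setattr__(
            self, "aliases", {k.strip().lower(): v for k, v in self.aliases.items()}
        )

    @property
    def H(self) -> int:
        """Number of activity channels."""
        return len(self.activities)

    def canonical(self, label: str) -> Optional[str]:
        """Map a free-text activity label to its canonical profile name.

        Returns ``None`` when the label matches no profile activity.
        """
        key = label.strip().lower()
        key = self.aliases.get(key, key)
        for act in self.activities:
            if act.lower() == key:
                return act
        return None

    def index(self, label: str) -> int:
        """1-based activity index of `label`; raises KeyError if unknown."""
        canon = self.canonical(label)
        if canon is None:
            raise KeyError(f"activity {label!r} not in profile {self.name!r}")
        return self.activities.index(canon) + 1

    # --- profile config files (YAML) -------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "activities": list(self.activities),
            "acronyms": list(self.acronyms),
            "aliases": dict(self.aliases),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ActivityProfile":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            name=payload["name"],
            activities=tuple(payload["activities"]),
            acronyms=tuple(payload.get("acronyms") or ()),
            aliases=dict(payload.get("aliases") or {}),
        )


SUS = ActivityProfile(
    name="SUS",
    activities=(
        "baby on table",
        "drying",
        "stimulation",
        "ventilation",
        "suction",
        "chest compression",
    ),
    acronyms=("BOT", "Dry", "Stim", "Vent", "Suc", "Chest"),
    aliases={
        "bot": "baby on table",
        "baby in table": "baby on table",
        "dry": "drying",
        "stim": "stimulation",
        "vent": "ventilation",
        "suc": "suction",
        "chest": "chest compression",
        "cc": "chest compression",
    },
)

HAYDOM = ActivityProfile(
    name="Haydom",
    activities=(
        "unwrapped baby",
        "stimulation",
        "ventilation",
        "suction",
        "attaching ecg",
        "wrapped baby",
        "chest compression",
    ),
    acronyms=("Uw", "Stim", "Vent", "Suc", "Atta", "Wrap", "Chest"),
    aliases={
        "uw": "unwrapped baby",
        "unwrapped": "unwrapped baby",
        "stim": "stimulation",
        "vent": "ventilation",
        "suc": "suction",
        "attaching dry-electrode ecg": "attaching ecg",
        "atta": "attaching ecg",
        "neobeat": "attaching ecg",
        "wrap": "wrapped baby",
        "wrapped": "wrapped baby",
        "chest": "chest compression",
        "cc": "chest compression",
    },
)

BUILTIN_PROFILES: dict[str, ActivityProfile] = {"sus": SUS, "haydom": HAYDOM}


def get_profile(name: str) -> ActivityProfile:
    """Look up a built-in profile by (case-insensitive) name."""
    try:
        return BUILTIN_PROFILES[name.strip().lower()]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; built-ins: {sorted(BUILTIN_PROFILES)}"
        ) from None
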