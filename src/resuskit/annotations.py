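"""Reading and writing annotation text files and label tables.

One annotation file describes one resuscitation episode.  Each non-empty line
holds four columns -- activity name, start, stop, duration -- with times in
milliseconds from the start of the recording.  Files are the export dialect of
the ELAN video-annotation tool: tab-delimited in the common case, but runs of
whitespace are accepted as a fallback (with the last three fields numeric and
everything before them the activity name).

The duration column is validated against ``stop - start`` (within 1 ms for
rounding in source files) but never trusted; start/stop are authoritative.

Labels and per-episode metadata (outcome, ventilation presence, time of birth)
live out-of-band in a CSV table, not inside the annotation files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .profiles import ActivityProfile

logger = logging.getLogger(__name__)

DURATION_TOLERANCE_MS = 1

#: Valid outcome codes: binary NICU-admission {0,1} or the multi-class
#: protocol {normal=1, death=2, admitted to NICU=3, stillborn=4}.
VALID_OUTCOMES = frozenset({0, 1, 2, 3, 4})
VALID_BINARY = frozenset({0, 1})


class AnnotationParseError(ValueError):
    """A line of an annotation file could not be parsed."""


class AnnotationValidationError(ValueError):
    """Parsed values violate the format's invariants (e.g. stop <= start)."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One timed activity annotation, in milliseconds from recording start."""

    activity: str
    start_ms: int
    stop_ms: int
    duration_ms: int

    def __post_init__(self) -> None:
        if self.start_ms < 0:
            raise AnnotationValidationError(
                f"start must be >= 0 ms, got {self.start_ms}"
            )
        if self.stop_ms <= self.start_ms:
            raise AnnotationValidationError(
                f"stop ({self.stop_ms}) must be greater than start ({self.start_ms})"
            )
        if abs(self.duration_ms - (self.stop_ms - self.start_ms)) > DURATION_TOLERANCE_MS:
            raise AnnotationValidationError(
                f"duration {self.duration_ms} inconsistent with "
                f"stop-start={self.stop_ms - self.start_ms}"
            )


@dataclass
class Episode:
    """One resuscitation episode: its records plus optional birth time and labels.

    ``tob_ms`` (time of birth) is on the same clock as the record times, i.e.
    milliseconds from recording start; annotation times are treated as relative
    to recording start throughout.
    """

    episode_id: str
    records: list[AnnotationRecord] = field(default_factory=list)
    tob_ms: Optional[int] = None
    labels: Optional[dict[str, int]] = None


def _parse_line(line: str, lineno: int) -> tuple[str, int, int, int]:
    fields = [f.strip() for f in line.split("\t") if f.strip() != ""]
    if len(fields) < 4:
        fields = line.split()
    if len(fields) < 4:
        raise AnnotationParseError(
            f"line {lineno}: expected >= 4 columns, got {len(fields)}: {line!r}"
        )
    activity = fields[0] if len(fields) == 4 else " ".join(fields[:-3])
    raw_times = fields[-3:]
    times = []
    for value in raw_times:
        try:
            times.append(int(round(float(value))))
        except ValueError:
            raise AnnotationParseError(
                f"line {lineno}: non-numeric time field {value!r}"
            ) from None
    return activity, times[0], times[1], times[2]


def read_annotation_file(path: str | Path, profile: ActivityProfile) -> Episode:
    """Parse one annotation file, keeping only activities in `profile`.

    Lines whose activity does not match the profile (after alias mapping,
    case-insensitively) are dropped; the number of dropped lines is logged at
    INFO level.  Raises :class:`AnnotationParseError` for malformed lines
    (naming the line number) and :class:`AnnotationValidationError` when
    ``stop <= start``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records: list[AnnotationRecord] = []
    dropped = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        activity, start_ms, stop_ms, duration_ms = _parse_line(line, lineno)
        canon = profile.canonical(activity)
        if canon is None:
            dropped += 1
            continue
        try:
            records.append(
                AnnotationRecord(canon, start_ms, stop_ms, duration_ms)
            )
        except AnnotationValidationError as exc:
            raise AnnotationValidationError(f"{path.name} line {lineno}: {exc}") from None
    if dropped:
        logger.info("%s: dropped %d line(s) with non-profile activities", path.name, dropped)
    return Episode(episode_id=path.stem, records=records)


def write_annotation_file(episode: Episode, path: str | Path) -> None:
    """Write an episode as a 4-column tab-delimited annotation file.

    Round-trips exactly: reading the file back reproduces the records
    field-for-field (order preserved).
    """
    lines = [
        f"{r.activity}\t{r.start_ms}\t{r.stop_ms}\t{r.duration_ms}"
        for r in episode.records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_labels(
    path: str | Path, protocol: Optional[str] = None
) -> dict[str, dict[str, int]]:
    """Read the per-episode label/metadata CSV.

    Expected columns: ``episode_id``, ``outcome``, ``ventilation`` and
    optionally ``tob_ms``.  Outcome codes follow the labeling protocol --
    binary NICU admission {0,1} for ``protocol="sus"`` or multi-class
    {normal=1, death=2, NICU=3, stillborn=4} for ``protocol="haydom"``; with
    no protocol given, any of {0..4} is accepted.  Ventilation presence is
    always binary.  Returns ``{episode_id: {"outcome": ..., "ventilation":
    ..., ["tob_ms": ...]}}``; an empty table yields an empty mapping.
    """
    frame = pd.read_csv(path, skipinitialspace=True, dtype={"episode_id": str})
    if frame.empty:
        return {}
    allowed = {
        None: VALID_OUTCOMES,
        "sus": VALID_BINARY,
        "haydom": frozenset({1, 2, 3, 4}),
    }[protocol.lower() if isinstance(protocol, str) else None]
    out: dict[str, dict[str, int]] = {}
    for row in frame.itertuples(index=False):
        eid = str(row.episode_id).strip()
        labels = {"outcome": int(row.outcome), "ventilation": int(row.ventilation)}
        if labels["outcome"] not in allowed:
            raise AnnotationValidationError(
                f"episode {eid!r}: outcome {labels['outcome']} outside {sorted(allowed)}"
            )
        if labels["ventilation"] not in VALID_BINARY:
            raise AnnotationValidationError(
                f"episode {eid!r}: ventilation label must be 0 or 1"
            )
        if hasattr(row, "tob_ms") and pd.notna(row.tob_ms):
            labels["tob_ms"] = int(row.tob_ms)
        out[eid] = labels
    return out


def read_dataset(
    directory: str | Path,
    profile: ActivityProfile,
    labels_csv: Optional[str | Path] = None,
    protocol: Optional[str] = None,
) -> list[Episode]:
    """Read every ``*.txt`` annotation file under `directory` (sorted by name).

    When `labels_csv` is given, outcome/ventilation labels and the time of
    birth are attached to the matching episodes.
    """
    directory = Path(directory)
    labels = read_labels(labels_csv, protocol=protocol) if labels_csv else {}
    episodes = []
    for txt in sorted(directory.glob("*.txt")):
        episode = read_annotation_file(txt, profile)
        meta = labels.get(episode.episode_id)
        if meta is not None:
            episode.tob_ms = meta.get("tob_ms")
            episode.labels = {k: v for k, v in meta.items() if k != "tob_ms"}
        episodes.append(episode)
    return episodes


def iter_records(episodes: Iterable[Episode]):
    """Yield (episode, record) pairs over a dataset."""
    for episode in episodes:
        for record in episode.records:
            yield episode, record
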