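"""Timeline and aggregated-dataset visualization.

Two views are produced:

* :class:`TimelineView` -- a single episode as per-activity lanes of merged
  intervals on a seconds-post-birth axis, with the time of birth (ToB) at
  second 0.  The per-activity onset (start of the first interval, e.g. the
  ventilation onset relative to birth) is derived alongside.
* :class:`AggregatedView` -- a whole dataset as a scatter of episodes against
  the observed activity *combinations*: each distinct nonzero fused value in
  an episode contributes one point, the y-axis enumerates the combinations
  labelled by "+"-joined activity acronyms, and color encodes the raw fused
  value (no normalization).  The category axis is built by sorting the
  distinct fused values ascending.

Both views are plain data objects (JSON-serializable) so they can be tested
headless; :func:`render` turns either into a matplotlib figure on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .annotations import Episode
from .encoding import FusedMatrix, decode_value
from .profiles import ActivityProfile


class MissingToBError(ValueError):
    """Raised when a ToB-aligned view is requested without a time of birth."""


@dataclass
class TimelineView:
    """Per-activity interval lanes for one episode, seconds after birth."""

    episode_id: str
    lanes: dict[str, list[tuple[float, float]]]
    onsets_s: dict[str, Optional[float]]
    tob_marker: float = 0.0
    horizon_s: int = 720

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "episode_id": self.episode_id,
                "lanes": self.lanes,
                "onsets_s": self.onsets_s,
                "tob_marker": self.tob_marker,
                "horizon_s": self.horizon_s,
            },
            indent=2,
        ))


@dataclass
class AggregatedView:
    """Dataset-wide scatter of episodes vs. activity-combination categories."""

    #: (episode_index, category_rank, fused_value) triples.
    points: list[tuple[int, int, int]]
    #: Category labels, ordered by ascending fused value.
    categories: list[str]
    #: Fused value behind each category (same order as `categories`).
    category_values: list[int]
    episode_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "points": self.points,
                "categories": self.categories,
                "category_values": self.category_values,
                "episode_ids": self.episode_ids,
            },
            indent=2,
        ))


def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def build_timeline(
    episode: Episode,
    profile: ActivityProfile,
    tob_ms: Optional[int] = None,
    horizon_s: int = 720,
) -> TimelineView:
    """Build the ToB-aligned timeline view of one episode.

    `tob_ms` (falling back to ``episode.tob_ms``) anchors second 0; intervals
    are clipped to ``[0, horizon_s]`` and merged per activity, lanes ordered
    by profile order.  Raises :class:`MissingToBError` when no time of birth
    is available -- encode from recording origin instead for un-anchored data.
    """
    if tob_ms is None:
        tob_ms = episode.tob_ms
    if tob_ms is None:
        raise MissingToBError(
            f"episode {episode.episode_id!r} has no time of birth; "
            "use recording-origin encoding for the non-ToB variant"
        )
    raw: dict[str, list[tuple[float, float]]] = {a: [] for a in profile.activities}
    for rec in episode.records:
        canon = profile.canonical(rec.activity)
        if canon is None:
            continue
        a = max((rec.start_ms - tob_ms) / 1000.0, 0.0)
        b = min((rec.stop_ms - tob_ms) / 1000.0, float(horizon_s))
        if b > a:
            raw[canon].append((a, b))
    lanes = {act: _merge(ivs) for act, ivs in raw.items()}
    onsets = {
        act: (ivs[0][0] if ivs else None) for act, ivs in lanes.items()
    }
    return TimelineView(
        episode_id=episode.episode_id,
        lanes=lanes,
        onsets_s=onsets,
        horizon_s=horizon_s,
    )


def combination_label(value: int, profile: ActivityProfile) -> str:
    """'+'-joined acronym label of the activity combination behind a fused value."""
    members = sorted(decode_value(int(value), profile.H))
    return "+".join(profile.acronyms[i - 1] for i in members)


def build_aggregated_view(
    fused: FusedMatrix,
    profile: ActivityProfile,
    per_second: bool = False,
) -> AggregatedView:
    """Aggregate a fused matrix into the episode-vs-combination scatter.

    By default one point is emitted per (episode, distinct nonzero fused
    value); with ``per_second=True`` every occupied second contributes a
    point (the denser variant).  Categories enumerate the distinct fused
    values observed dataset-wide, sorted ascending, labelled via
    :func:`combination_label`.
    """
    nonzero = fused.values[fused.values > 0]
    distinct = np.unique(nonzero)  # sorted ascending, O(V log V)
    rank = {int(v): r for r, v in enumerate(distinct)}
    points: list[tuple[int, int, int]] = []
    for j in range(fused.values.shape[1]):
        col = fused.values[:, j]
        values = col[col > 0] if per_second else np.unique(col[col > 0])
        for v in values:
            points.append((j, rank[int(v)], int(v)))
    return AggregatedView(
        points=points,
        categories=[combination_label(int(v), profile) for v in distinct],
        category_values=[int(v) for v in distinct],
        episode_ids=list(fused.episode_ids),
    )


_SAVEFIG_KW = {"dpi": 120, "metadata": {"Software": "resuskit"}}


def render(view: TimelineView | AggregatedView, path: str | Path) -> Path:
    """Render a view to a PNG/SVG file; deterministic for identical views."""
    path = Path(path)
    if isinstance(view, TimelineView):
        fig = _render_timeline(view)
    elif isinstance(view, AggregatedView):
        fig = _render_aggregated(view)
    else:
        raise TypeError(f"cannot render {type(view).__name__}")
    kw = dict(_SAVEFIG_KW)
    if path.suffix.lower() == ".svg":
        kw["metadata"] = {"Date": None}
    fig.savefig(path, **kw)
    plt.close(fig)
    return path


def _render_timeline(view: TimelineView):
    lanes = list(view.lanes.items())
    fig, ax = plt.subplots(figsize=(10, 0.6 * max(len(lanes), 4) + 1.2))
    for row, (activity, intervals) in enumerate(lanes):
        for a, b in intervals:
            ax.broken_barh([(a, b - a)], (row - 0.35, 0.7), color="tab:blue")
    ax.axvline(view.tob_marker, color="tab:red", lw=1.5, label="ToB")
    ax.set_yticks(range(len(lanes)))
    ax.set_yticklabels([a for a, _ in lanes])
    ax.invert_yaxis()
    ax.set_xlim(-10, view.horizon_s)
    ax.set_xlabel("time after birth (s)")
    ax.set_title(f"Resuscitation activity timeline: {view.episode_id}")
    ax.legend(loc="upper right")
    fig.tight_layout()
    return fig


def _render_aggregated(view: AggregatedView):
    n_cat = len(view.categories)
    fig, ax = plt.subplots(figsize=(10, 0.28 * max(n_cat, 8) + 1.5))
    if view.points:
        xs, ys, vs = zip(*view.points)
        sc = ax.scatter(xs, ys, c=vs, cmap="viridis", s=14, marker="s")
        fig.colorbar(sc, ax=ax, label="fused code value")
    ax.set_yticks(range(n_cat))
    ax.set_yticklabels(view.categories, fontsize=7)
    ax.set_xlabel("episode (annotation file) index")
    ax.set_title("Activities and fused activities across episodes")
    fig.tight_layout()
    return fig
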