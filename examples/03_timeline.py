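"""Render a ToB-aligned timeline of one resuscitation episode.

The time of birth anchors second 0, so the gap before the first activity
lane shows how quickly resuscitation started -- ventilation within the first
60 s ("golden minute") is the guideline target.
"""

import tempfile
from pathlib import Path

from resuskit import SUS, AnnotationRecord, Episode
from resuskit.timelines import build_timeline, render

episode = Episode(
    "example",
    records=[
        AnnotationRecord("baby on table", 5_000, 300_000, 295_000),
        AnnotationRecord("drying", 8_000, 20_000, 12_000),
        AnnotationRecord("stimulation", 20_000, 45_000, 25_000),
        AnnotationRecord("ventilation", 35_000, 95_000, 60_000),
        AnnotationRecord("ventilation", 120_000, 180_000, 60_000),
        AnnotationRecord("suction", 100_000, 115_000, 15_000),
    ],
)

view = build_timeline(episode, SUS, tob_ms=0, horizon_s=360)
for activity, intervals in view.lanes.items():
    if intervals:
        print(f"{activity:>17s}: {intervals}")
print(f"ventilation onset: {view.onsets_s['ventilation']:.0f} s post-birth")
# 35 s: inside the golden minute

out = Path(tempfile.mkdtemp()) / "timeline.png"
render(view, out)
print(f"figure written to {out}")
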