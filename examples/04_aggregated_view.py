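"""Visualize activity combinations across a whole dataset.

Fuses every episode of a synthetic Haydom-like dataset and plots one point
per (episode, observed activity combination), the y-axis enumerating the
combinations by their "+"-joined acronyms and color encoding the raw fused
value.  This single scatter summarizes which (simultaneous) activities occur
and how their usage differs across episodes.
"""

import tempfile
from pathlib import Path

from resuskit import build_dataset
from resuskit.synthetic import generate_dataset, haydom_default_config
from resuskit.timelines import build_aggregated_view, render

config = haydom_default_config(n_episodes=30, seed=1)
episodes, _, _ = generate_dataset(config)
_, fused = build_dataset(episodes, config.profile)

view = build_aggregated_view(fused, config.profile)
print(f"{len(view.points)} points over {len(view.categories)} activity combinations")
print("most common combinations:")
from collections import Counter

counts = Counter(view.categories[rank] for _, rank, _ in view.points)
for label, n in counts.most_common(8):
    print(f"  {label:>20s}: seen in {n} episodes")

out = Path(tempfile.mkdtemp()) / "aggregated.png"
render(view, out)
print(f"figure written to {out}")
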