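"""Synthetic labeled resuscitation datasets for testing every downstream stage.

Real annotation datasets of this kind are private, so this module generates
annotation files with the same structure: a handful of activity channels, each
occurring in multiple bouts of second-to-minute duration, bouts overlapping
across activities, and outcome/ventilation labels per episode.

The generative model per episode is deliberately simple and fully invertible
for tests: each outcome class carries, per activity, a presence probability, a
Poisson bout count, lognormal bout durations, and a normally distributed onset
of the first bout, with exponential gaps between consecutive bouts.  The class
signal lives in timing and presence patterns (e.g. later ventilation onset and
more chest compression for adverse outcomes), never in amplitude, because the
encoding only records presence.

Default parameters are sized to resemble published per-activity bout counts
and total durations for real Stavanger (SUS) and Haydom datasets (a few bouts
of a few seconds of stimulation per episode, fewer but longer ventilation
bouts, rare chest compression).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotations import AnnotationRecord, Episode, write_annotation_file
from .encoding import CodeMatrix, DEFAULT_N_SECONDS
from .profiles import HAYDOM, SUS, ActivityProfile

#: Outcome code -> human label under the multi-class protocol.
OUTCOME_NAMES = {1: "normal", 2: "death", 3: "nicu", 4: "stillborn"}


@dataclass(frozen=True)
class BoutSpec:
    """Per-activity bout statistics for one outcome class.

    presence_prob: probability the activity occurs at all in an episode.
    bout_count_mean: mean number of bouts (1 + Poisson(mean - 1)).
    duration_mean_s / duration_sigma: lognormal bout duration (median
    ``duration_mean_s`` seconds, log-scale sigma).
    onset_mean_s / onset_sd_s: normal first-bout onset, seconds from origin.
    gap_mean_s: mean exponential gap between consecutive bouts.
    """

    presence_prob: float = 1.0
    bout_count_mean: float = 3.0
    duration_mean_s: float = 10.0
    duration_sigma: float = 0.5
    onset_mean_s: float = 30.0
    onset_sd_s: float = 10.0
    gap_mean_s: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")
        for name in ("bout_count_mean", "duration_mean_s", "gap_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SynthConfig:
    """Configuration of a synthetic labeled dataset.

    ``class_spec`` maps outcome code -> activity name -> :class:`BoutSpec`;
    activities missing from a class's mapping are absent for that class.
    ``class_weights`` gives the sampling probability of each outcome code.
    """

    profile: ActivityProfile
    n_episodes: int = 100
    n_seconds: int = DEFAULT_N_SECONDS
    class_spec: dict[int, dict[str, BoutSpec]] = field(default_factory=dict)
    class_weights: Optional[dict[int, float]] = None
    protocol: str = "haydom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")
        if not self.class_spec:
            raise ValueError("class_spec must define at least one outcome class")
        for cls, spec in self.class_spec.items():
            for act, bout in spec.items():
                if self.profile.canonical(act) is None:
                    raise ValueError(
                        f"class {cls}: activity {act!r} not in profile "
                        f"{self.profile.name!r}"
                    )
                if bout.duration_mean_s >= self.n_seconds:
                    raise ValueError(
                        f"class {cls}/{act}: mean bout duration "
                        f"{bout.duration_mean_s}s does not fit in "
                        f"{self.n_seconds}s episodes"
                    )


def table3_fixture() -> Episode:
    """The deterministic 10-second worked-example episode.

    Four activities of the SUS profile with second-level occupancy:
    baby on table seconds 1-9, drying 1-3, stimulation 4-7, ventilation 5-9.
    Encoding it over a 10-second horizon reproduces the published worked
    example exactly (fused vector 4,4,4,8,23,23,23,16,16,0).
    """
    mk = lambda act, a, b: AnnotationRecord(act, a, b, b - a)
    return Episode(
        episode_id="table3",
        records=[
            mk("baby on table", 0, 9000),
            mk("drying", 0, 3000),
            mk("stimulation", 3000, 7000),
            mk("ventilation", 4000, 9000),
        ],
    )


def _sample_episode(
    rng: np.random.Generator,
    profile: ActivityProfile,
    spec: dict[str, BoutSpec],
    n_seconds: int,
    episode_id: str,
) -> tuple[Episode, dict[str, dict[str, int]]]:
    horizon_ms = n_seconds * 1000
    records: list[AnnotationRecord] = []
    bookkeeping: dict[str, dict[str, int]] = {}
    for activity in profile.activities:
        bout = spec.get(activity)
        if bout is None or rng.random() >= bout.presence_prob:
            continue
        n_bouts = 1 + rng.poisson(max(bout.bout_count_mean - 1.0, 0.0))
        cursor = max(rng.normal(bout.onset_mean_s, bout.onset_sd_s), 0.0) * 1000
        for _ in range(n_bouts):
            dur = rng.lognormal(np.log(bout.duration_mean_s), bout.duration_sigma)
            dur_ms = int(round(max(dur, 1.0) * 1000))
            start = int(round(cursor))
            stop = start + dur_ms
            if start >= horizon_ms:
                break
            stop = min(stop, horizon_ms)
            if stop - start >= 500:
                records.append(
                    AnnotationRecord(activity, start, stop, stop - start)
                )
            cursor = stop + rng.exponential(bout.gap_mean_s) * 1000
        made = [r for r in records if r.activity == activity]
        if made:
            bookkeeping[activity] = {
                "n_records": len(made),
                "total_duration_ms": sum(r.stop_ms - r.start_ms for r in made),
            }
    return Episode(episode_id=episode_id, records=records), bookkeeping


def generate_dataset(
    config: SynthConfig, out_dir: Optional[str | Path] = None
) -> tuple[list[Episode], pd.DataFrame, dict]:
    """Generate a labeled synthetic dataset; optionally write it to disk.

    Returns ``(episodes, labels, bookkeeping)``: the episodes (with labels
    attached), a labels DataFrame (episode_id, outcome, ventilation, tob_ms),
    and the generator's ground-truth per-episode bout bookkeeping for oracle
    tests.  With `out_dir`, one annotation ``.txt`` per episode plus
    ``labels.csv`` and ``manifest.json`` are written; identical seeds produce
    byte-identical trees.

    The ventilation label is derived from the generated records (presence of
    any ventilation bout within the horizon), so it always agrees with
    :func:`labels_from_encoding` on the encoded data.
    """
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_spec)
    if config.class_weights:
        probs = np.array([config.class_weights[c] for c in classes], dtype=float)
        probs = probs / probs.sum()
    else:
        probs = np.full(len(classes), 1.0 / len(classes))
    width = len(str(config.n_episodes))
    episodes: list[Episode] = []
    label_rows = []
    bookkeeping: dict[str, dict] = {}
    vent_name = _ventilation_name(config.profile)
    for m in range(config.n_episodes):
        outcome = int(rng.choice(classes, p=probs))
        eid = f"ep{m:0{width}d}"
        episode, book = _sample_episode(
            rng, config.profile, config.class_spec[outcome], config.n_seconds, eid
        )
        vent = int(
            any(
                r.activity == vent_name and r.start_ms < config.n_seconds * 1000
                for r in episode.records
            )
        )
        episode.tob_ms = 0
        episode.labels = {"outcome": outcome, "ventilation": vent}
        episodes.append(episode)
        label_rows.append(
            {"episode_id": eid, "outcome": outcome, "ventilation": vent, "tob_ms": 0}
        )
        bookkeeping[eid] = {"outcome": outcome, "activities": book}
    labels = pd.DataFrame(label_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ep in episodes:
            write_annotation_file(ep, out_dir / f"{ep.episode_id}.txt")
        labels.to_csv(out_dir / "labels.csv", index=False)
        manifest = {
            "profile": config.profile.name,
            "n_episodes": config.n_episodes,
            "n_seconds": config.n_seconds,
            "protocol": config.protocol,
            "seed": config.seed,
            "classes": classes,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return episodes, labels, bookkeeping


def _ventilation_name(profile: ActivityProfile) -> str:
    name = profile.canonical("ventilation")
    if name is None:
        raise ValueError(f"profile {profile.name!r} has no ventilation activity")
    return name


def labels_from_encoding(code_matrix: CodeMatrix, profile: ActivityProfile) -> int:
    """Binary ventilation-presence label read off an encoded episode.

    1 iff the ventilation row of the code matrix has any nonzero entry within
    the encoding horizon, else 0.
    """
    row = profile.index(_ventilation_name(profile)) - 1
    return int(bool(code_matrix.values[row].any()))


# ---------------------------------------------------------------------------
# Reference class specifications
# ---------------------------------------------------------------------------

def haydom_class_spec() -> dict[int, dict[str, BoutSpec]]:
    """Three-class (normal / death / NICU) bout statistics, Haydom profile.

    Healthy outcomes get early, brief ventilation (when present at all);
    adverse outcomes get delayed ventilation onset, longer bouts, and chest
    compression.  Magnitudes follow the per-activity bout counts and total
    durations reported for real datasets of this kind (several ~7 s
    stimulation bouts per episode, a few ~25 s ventilation bouts, rare chest
    compression).
    """
    return {
        1: {  # normal: quick response, little therapeutic escalation
            "unwrapped baby": BoutSpec(1.0, 1.2, 120.0, 0.4, 5.0, 3.0, 30.0),
            "stimulation": BoutSpec(0.95, 6.0, 7.0, 0.5, 15.0, 8.0, 12.0),
            "ventilation": BoutSpec(0.35, 2.0, 15.0, 0.4, 45.0, 10.0, 20.0),
            "suction": BoutSpec(0.5, 2.0, 12.0, 0.5, 60.0, 20.0, 25.0),
            "attaching ecg": BoutSpec(0.8, 1.0, 10.0, 0.3, 20.0, 8.0, 30.0),
            "wrapped baby": BoutSpec(0.9, 1.0, 90.0, 0.4, 240.0, 60.0, 60.0),
            "chest compression": BoutSpec(0.02, 1.0, 5.0, 0.4, 200.0, 60.0, 30.0),
        },
        2: {  # death: late escalation, prolonged ventilation, compressions
            "unwrapped baby": BoutSpec(1.0, 1.5, 300.0, 0.4, 5.0, 3.0, 30.0),
            "stimulation": BoutSpec(0.95, 8.0, 6.0, 0.5, 25.0, 10.0, 15.0),
            "ventilation": BoutSpec(0.95, 6.0, 45.0, 0.4, 150.0, 25.0, 15.0),
            "suction": BoutSpec(0.85, 3.0, 15.0, 0.5, 120.0, 30.0, 30.0),
            "attaching ecg": BoutSpec(0.9, 1.2, 12.0, 0.3, 40.0, 15.0, 30.0),
            "wrapped baby": BoutSpec(0.3, 1.0, 60.0, 0.4, 600.0, 60.0, 60.0),
            "chest compression": BoutSpec(0.7, 2.5, 8.0, 0.4, 300.0, 60.0, 40.0),
        },
        3: {  # NICU admission: intermediate timing and escalation
            "unwrapped baby": BoutSpec(1.0, 1.3, 200.0, 0.4, 5.0, 3.0, 30.0),
            "stimulation": BoutSpec(0.95, 7.0, 6.5, 0.5, 20.0, 8.0, 14.0),
            "ventilation": BoutSpec(0.9, 4.0, 30.0, 0.4, 85.0, 15.0, 18.0),
            "suction": BoutSpec(0.7, 2.5, 14.0, 0.5, 90.0, 25.0, 28.0),
            "attaching ecg": BoutSpec(0.85, 1.1, 11.0, 0.3, 30.0, 10.0, 30.0),
            "wrapped baby": BoutSpec(0.6, 1.0, 80.0, 0.4, 420.0, 80.0, 60.0),
            "chest compression": BoutSpec(0.15, 1.5, 6.0, 0.4, 260.0, 60.0, 35.0),
        },
    }


def sus_class_spec() -> dict[int, dict[str, BoutSpec]]:
    """Binary-outcome (0 = not admitted, 1 = NICU) bout statistics, SUS profile.

    Sparser episodes than the Haydom-like set: ventilation and stimulation
    dominate, suction is relatively rare.
    """
    return {
        0: {
            "baby on table": BoutSpec(1.0, 1.2, 180.0, 0.4, 3.0, 2.0, 40.0),
            "drying": BoutSpec(0.9, 2.0, 10.0, 0.4, 10.0, 5.0, 15.0),
            "stimulation": BoutSpec(0.9, 5.0, 7.0, 0.5, 15.0, 8.0, 12.0),
            "ventilation": BoutSpec(0.4, 3.0, 10.0, 0.4, 40.0, 10.0, 18.0),
            "suction": BoutSpec(0.25, 1.5, 15.0, 0.5, 70.0, 20.0, 25.0),
            "chest compression": BoutSpec(0.03, 1.0, 3.0, 0.4, 180.0, 50.0, 30.0),
        },
        1: {
            "baby on table": BoutSpec(1.0, 1.4, 350.0, 0.4, 3.0, 2.0, 40.0),
            "drying": BoutSpec(0.9, 2.0, 9.0, 0.4, 12.0, 5.0, 15.0),
            "stimulation": BoutSpec(0.95, 6.0, 7.0, 0.5, 20.0, 8.0, 13.0),
            "ventilation": BoutSpec(0.92, 5.0, 25.0, 0.4, 100.0, 20.0, 16.0),
            "suction": BoutSpec(0.5, 2.0, 17.0, 0.5, 100.0, 25.0, 28.0),
            "chest compression": BoutSpec(0.25, 1.5, 4.0, 0.4, 240.0, 60.0, 30.0),
        },
    }


def haydom_default_config(
    n_episodes: int = 100, n_seconds: int = DEFAULT_N_SECONDS, seed: int = 0
) -> SynthConfig:
    """Reference 3-class Haydom-like synthetic dataset configuration."""
    return SynthConfig(
        profile=HAYDOM,
        n_episodes=n_episodes,
        n_seconds=n_seconds,
        class_spec=haydom_class_spec(),
        class_weights={1: 0.5, 2: 0.2, 3: 0.3},
        protocol="haydom",
        seed=seed,
    )


def sus_default_config(
    n_episodes: int = 100, n_seconds: int = DEFAULT_N_SECONDS, seed: int = 0
) -> SynthConfig:
    """Reference binary-outcome SUS-like synthetic dataset configuration."""
    return SynthConfig(
        profile=SUS,
        n_episodes=n_episodes,
        n_seconds=n_seconds,
        class_spec=sus_class_spec(),
        class_weights={0: 0.65, 1: 0.35},
        protocol="sus",
        seed=seed,
    )
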