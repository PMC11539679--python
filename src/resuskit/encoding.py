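"""Periodic activity encoding: code generation, fusion, and exact decoding.

Each activity channel ``c_i`` (1-based index ``i`` fixed by the profile order)
is assigned the code ``G_e(i) = 2**i - 1``.  An episode becomes an ``H x N``
integer code matrix: entry ``(i, n)`` is ``G_e(i)`` when activity ``i``
overlaps second-bin ``n`` and 0 otherwise (bins are half-open
``[(n-1)*1000, n*1000)`` ms after the chosen origin).  Summing the rows fuses
the matrix into a single N-vector per episode; because the code sequence
1, 3, 7, 15, ... is superincreasing, every subset of activities sums to a
distinct value, so a fused value identifies the exact set of simultaneous
activities and can be decoded by greedy descent.

Everything in this module is exact integer arithmetic; floats appear only in
:func:`project_to_allowed`, which snaps a real-valued reconstruction back onto
the lattice of allowed (subset-sum) values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import Episode
from .profiles import MAX_ACTIVITIES, ActivityProfile

#: Default episode horizon in seconds: the first 12 minutes of resuscitation.
DEFAULT_N_SECONDS = 720

MS_PER_BIN = 1000


def generator_code(i: int) -> int:
    """Code emitted by the periodic encoding generator for activity index `i`.

    ``G_e(i) = 2**i - 1`` for 1-based ``i``; the sequence 1, 3, 7, 15, ... is
    superincreasing (each code exceeds the sum of all smaller ones), which is
    what makes fused sums uniquely decodable.
    """
    if not 1 <= i <= MAX_ACTIVITIES:
        raise ValueError(f"activity index must be in 1..{MAX_ACTIVITIES}, got {i}")
    return (1 << i) - 1


def codes(H: int) -> np.ndarray:
    """The code vector ``[G_e(1), ..., G_e(H)]`` as int64."""
    if not 1 <= H <= MAX_ACTIVITIES:
        raise ValueError(f"H must be in 1..{MAX_ACTIVITIES}, got {H}")
    return (1 << np.arange(1, H + 1, dtype=np.int64)) - 1


@dataclass
class CodeMatrix:
    """Per-episode ``H x N`` matrix of per-second activity codes."""

    values: np.ndarray  # int64, shape (H, N)
    profile: ActivityProfile
    episode_id: str

    @property
    def n_seconds(self) -> int:
        return self.values.shape[1]


@dataclass
class EpisodeTensor:
    """``H x N x M`` stack of code matrices over a dataset."""

    values: np.ndarray  # int64, shape (H, N, M)
    episode_ids: list[str]
    profile: ActivityProfile


@dataclass
class FusedMatrix:
    """``N x M`` matrix of fused per-second codes, one column per episode."""

    values: np.ndarray  # int64, shape (N, M)
    episode_ids: list[str]
    profile: ActivityProfile

    def to_csv(self, path: str | Path) -> None:
        """Seconds as rows, episodes as columns; exact integers."""
        pd.DataFrame(self.values, columns=self.episode_ids).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, profile: ActivityProfile) -> "FusedMatrix":
        frame = pd.read_csv(path)
        return cls(
            values=frame.to_numpy(dtype=np.int64),
            episode_ids=[str(c) for c in frame.columns],
            profile=profile,
        )

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path, values=self.values, episode_ids=np.array(self.episode_ids)
        )

    @classmethod
    def from_npz(cls, path: str | Path, profile: ActivityProfile) -> "FusedMatrix":
        with np.load(path, allow_pickle=False) as payload:
            return cls(
                values=payload["values"].astype(np.int64),
                episode_ids=[str(e) for e in payload["episode_ids"]],
                profile=profile,
            )


def occupancy(
    episode: Episode,
    profile: ActivityProfile,
    n_seconds: int = DEFAULT_N_SECONDS,
    origin_ms: int = 0,
) -> np.ndarray:
    """Boolean ``H x N`` activity-presence matrix on 1-second bins.

    An activity occupies bin ``n`` (1-based) when any of its records overlaps
    ``[(n-1)*1000, n*1000)`` ms after `origin_ms` -- any overlap counts, so a
    partially covered second is marked present.  Record parts before the
    origin are clipped; content beyond `n_seconds` is truncated.  Overlapping
    records of the same activity collapse to simple presence.
    """
    if n_seconds < 1:
        raise ValueError(f"n_seconds must be >= 1, got {n_seconds}")
    occ = np.zeros((profile.H, n_seconds), dtype=bool)
    horizon_ms = n_seconds * MS_PER_BIN
    for record in episode.records:
        start = record.start_ms - origin_ms
        stop = record.stop_ms - origin_ms
        start = max(start, 0)
        stop = min(stop, horizon_ms)
        if stop <= start:
            continue
        first_bin = start // MS_PER_BIN  # 0-based
        last_bin = -(-stop // MS_PER_BIN)  # ceil division, exclusive
        row = profile.index(record.activity) - 1
        occ[row, first_bin:last_bin] = True
    return occ


def encode_episode(
    episode: Episode,
    profile: ActivityProfile,
    n_seconds: int = DEFAULT_N_SECONDS,
    origin_ms: int = 0,
) -> CodeMatrix:
    """Encode one episode into its ``H x N`` code matrix.

    Row ``i`` holds ``G_e(i)`` wherever activity ``c_i`` is present (see
    :func:`occupancy`) and 0 elsewhere.  `origin_ms` defines time zero --
    the time of birth when available, else recording start.
    """
    occ = occupancy(episode, profile, n_seconds=n_seconds, origin_ms=origin_ms)
    values = occ * codes(profile.H)[:, None]
    return CodeMatrix(values=values, profile=profile, episode_id=episode.episode_id)


def fuse(code_matrix: CodeMatrix) -> np.ndarray:
    """Fuse a code matrix into an N-vector by summing over activities.

    ``x(n) = sum_i G(i, n)``; every entry is an allowed subset-sum value.
    """
    return code_matrix.values.sum(axis=0)


def build_dataset(
    episodes: list[Episode],
    profile: ActivityProfile,
    n_seconds: int = DEFAULT_N_SECONDS,
    use_tob_origin: bool = False,
) -> tuple[EpisodeTensor, FusedMatrix]:
    """Encode a dataset into its tensor and fused-matrix forms.

    Episode order is preserved and shared by both outputs.  With
    `use_tob_origin`, episodes carrying a time of birth are encoded on the
    post-birth axis; episodes without one fall back to recording origin.
    """
    if not episodes:
        raise ValueError("need at least one episode")
    mats = []
    for ep in episodes:
        origin = ep.tob_ms if (use_tob_origin and ep.tob_ms is not None) else 0
        mats.append(encode_episode(ep, profile, n_seconds=n_seconds, origin_ms=origin))
    tensor = EpisodeTensor(
        values=np.stack([m.values for m in mats], axis=2),
        episode_ids=[ep.episode_id for ep in episodes],
        profile=profile,
    )
    fused = FusedMatrix(
        values=np.stack([fuse(m) for m in mats], axis=1),
        episode_ids=tensor.episode_ids,
        profile=profile,
    )
    return tensor, fused


def allowed_values(H: int) -> np.ndarray:
    """All ``2**H`` subset sums of the activity codes, sorted ascending from 0.

    These are the only values a fused vector can take; reconstruction output
    is projected back onto this set.
    """
    sums = np.zeros(1, dtype=np.int64)
    for code in codes(H):
        sums = np.concatenate([sums, sums + code])
    out = np.unique(sums)
    assert out.size == 1 << H, "subset sums must be pairwise distinct"
    return out


def decode_value(v: int, H: int) -> frozenset[int]:
    """Recover the unique set of active (1-based) activity indices summing to `v`.

    Greedy descent over ``i = H..1`` is exact because the code sequence is
    superincreasing: ``G_e(i)`` exceeds the sum of all smaller codes, so
    ``G_e(i)`` is in the subset iff the remainder is >= ``G_e(i)``.  Raises
    ``ValueError`` for values outside the allowed set (project first).
    """
    if not 1 <= H <= MAX_ACTIVITIES:
        raise ValueError(f"H must be in 1..{MAX_ACTIVITIES}, got {H}")
    remainder = int(v)
    if remainder < 0:
        raise ValueError(f"{v} is not an allowed value for H={H}")
    members = []
    for i in range(H, 0, -1):
        code = generator_code(i)
        if remainder >= code:
            members.append(i)
            remainder -= code
    if remainder != 0:
        raise ValueError(f"{v} is not an allowed value for H={H}")
    return frozenset(members)


def project_to_allowed(v, H: int):
    """Snap real value(s) onto the nearest allowed value; ties break downward.

    Accepts a scalar or an array; returns int64 of the same shape.  Used to
    code autoencoder reconstructions back to exact activity-combination
    values.
    """
    allowed = allowed_values(H)
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("values to project must be finite")
    idx = np.searchsorted(allowed, arr)
    idx = np.clip(idx, 1, allowed.size - 1)
    lower = allowed[idx - 1]
    upper = allowed[idx]
    # tie (equidistant) resolves to the smaller allowed value
    pick_upper = (upper - arr) < (arr - lower)
    out = np.where(pick_upper, upper, lower)
    out = np.where(arr <= allowed[0], allowed[0], out)
    return out if out.ndim else np.int64(out)


def summarize_dataset(
    episodes: list[Episode], profile: ActivityProfile
) -> pd.DataFrame:
    """Per-activity annotation counts and total durations over a dataset.

    Returns one row per profile activity with columns ``n_records`` and
    ``total_duration_s`` (whole seconds, rounded), plus a ``TOTAL`` row; the
    frame's ``attrs`` carry ``n_files`` and ``total_duration_s``.
    """
    counts = {a: 0 for a in profile.activities}
    durations_ms = {a: 0 for a in profile.activities}
    for ep in episodes:
        for rec in ep.records:
            canon = profile.canonical(rec.activity)
            if canon is None:
                continue
            counts[canon] += 1
            durations_ms[canon] += rec.stop_ms - rec.start_ms
    rows = [
        {
            "activity": a,
            "n_records": counts[a],
            "total_duration_s": int(round(durations_ms[a] / 1000)),
        }
        for a in profile.activities
    ]
    rows.append(
        {
            "activity": "TOTAL",
            "n_records": sum(counts.values()),
            "total_duration_s": int(round(sum(durations_ms.values()) / 1000)),
        }
    )
    frame = pd.DataFrame(rows)
    frame.attrs["n_files"] = len(episodes)
    frame.attrs["total_duration_s"] = int(round(sum(durations_ms.values()) / 1000))
    return frame
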