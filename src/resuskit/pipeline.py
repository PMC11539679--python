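"""Experiment orchestration: NCA-alone vs. AE-NCA cluster visualization.

Two comparative experiments are supported on any encoded dataset, under the
outcome/ventilation labeling protocol:

* ``method="nca"`` -- center the fused matrix ``X`` and fit NCA directly.
* ``method="ae_nca"`` -- train the sparse autoencoder on ``X`` (seeded per
  label task), take the latent matrix ``Z``, center it, and fit NCA on ``Z``.

Each run produces a 2-D embedding CSV (episode_id, NCA1, NCA2, label), a
scatter figure colored by label, and a metrics JSON with the silhouette
score, the mean within-/between-class distance ratio, and the final NCA
objective.  Separability here is quantified by the silhouette score; the
choice of metric is this package's, made to turn a visual clustering claim
into a testable number.

Label protocol: outcome labels are binary NICU admission {0, 1} for SUS-style
datasets and multi-class {normal=1, death=2, NICU=3, stillborn=4} for
Haydom-style datasets; ventilation presence is always binary and, when no
label table provides it, is derived from the encoded ventilation row.
Seeds follow the two-seed convention: 0 for the outcome task and 42 for the
ventilation task.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score, pairwise_distances

from . import autoencoder, nca
from .annotations import Episode, read_dataset
from .encoding import DEFAULT_N_SECONDS, build_dataset, encode_episode
from .profiles import ActivityProfile, get_profile
from .synthetic import labels_from_encoding

logger = logging.getLogger(__name__)

#: Per-task training seeds (outcome -> 0, ventilation -> 42).
DEFAULT_SEEDS = {"outcome": 0, "ventilation": 42}

#: Bottleneck width per profile: 360 for the 7-activity (Haydom-style)
#: profile, 500 for the sparser 6-activity (SUS-style) profile.
DEFAULT_LATENT = {"haydom": 360, "sus": 500}

LABEL_TASKS = ("outcome", "ventilation")
METHODS = ("nca", "ae_nca")


class LabelingError(ValueError):
    """Labels required for the requested task are missing or invalid."""


@dataclass
class ExperimentConfig:
    """One NCA / AE-NCA run on one dataset and label task."""

    dataset_dir: str | Path
    profile: ActivityProfile | str
    label_task: str = "outcome"
    method: str = "ae_nca"
    ae_latent: Optional[int] = None  # default by profile (360 / 500)
    seeds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SEEDS))
    n_seconds: int = DEFAULT_N_SECONDS
    ae_epochs: int = 4000
    nca_max_iter: int = 300
    out_dir: Optional[str | Path] = None

    def __post_init__(self) -> None:
        if isinstance(self.profile, str):
            self.profile = get_profile(self.profile)
        if self.label_task not in LABEL_TASKS:
            raise ValueError(f"label_task must be one of {LABEL_TASKS}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.ae_latent is None:
            self.ae_latent = DEFAULT_LATENT.get(self.profile.name.lower(), 360)

    @property
    def seed(self) -> int:
        return self.seeds[self.label_task]


def assign_labels(
    episodes: list[Episode],
    protocol: str,
    label_task: str = "outcome",
    profile: Optional[ActivityProfile] = None,
    n_seconds: int = DEFAULT_N_SECONDS,
) -> np.ndarray:
    """Integer label vector aligned to episode order.

    For the outcome task every episode must carry an outcome label
    (validated against the protocol's range).  For the ventilation task,
    episodes lacking a label fall back to the encoded ventilation-presence
    bit, which requires `profile`.
    """
    allowed = {"sus": {0, 1}, "haydom": {1, 2, 3, 4}}[protocol.lower()]
    y = np.empty(len(episodes), dtype=int)
    for j, ep in enumerate(episodes):
        labels = ep.labels or {}
        if label_task == "outcome":
            if "outcome" not in labels:
                raise LabelingError(
                    f"episode {ep.episode_id!r} has no outcome label"
                )
            value = int(labels["outcome"])
            if value not in allowed:
                raise LabelingError(
                    f"episode {ep.episode_id!r}: outcome {value} outside "
                    f"{sorted(allowed)} for protocol {protocol!r}"
                )
        elif "ventilation" in labels:
            value = int(labels["ventilation"])
        else:
            if profile is None:
                raise LabelingError(
                    "ventilation fallback needs the activity profile"
                )
            cm = encode_episode(ep, profile, n_seconds=n_seconds)
            value = labels_from_encoding(cm, profile)
        y[j] = value
    return y


def separability_metrics(W: np.ndarray, y: np.ndarray) -> dict:
    """Cluster-separability metrics of a 2-D embedding ``W`` (d x M).

    Returns silhouette score, mean within-class / between-class distance
    ratio (smaller is better), or nulls with a reason when fewer than two
    classes are present.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        return {
            "silhouette": None,
            "within_between_ratio": None,
            "reason": "fewer than two classes; separability undefined",
        }
    pts = W.T
    dists = pairwise_distances(pts)
    same = y[:, None] == y[None, :]
    off = ~np.eye(len(y), dtype=bool)
    within = dists[same & off]
    between = dists[~same]
    return {
        "silhouette": float(silhouette_score(pts, y)),
        "within_between_ratio": float(within.mean() / between.mean())
        if within.size and between.size
        else None,
    }


def reduce_dataset(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    profile_H: int,
    ae_latent: int = 360,
    seed: int = 0,
    ae_epochs: int = 4000,
    nca_max_iter: int = 300,
) -> tuple[np.ndarray, nca.NCAModel, Optional[autoencoder.AEModel]]:
    """Run one dimensionality-reduction method on a fused matrix.

    Returns ``(W, nca_model, ae_model)`` where ``W`` is the 2 x M embedding.
    ``method="nca"`` fits NCA on the (centered) fused matrix directly;
    ``method="ae_nca"`` trains the autoencoder first and fits NCA on the
    latent matrix.
    """
    ae_model = None
    if method == "ae_nca":
        ae_model = autoencoder.train(
            X, d=ae_latent, H=profile_H, epochs=ae_epochs, seed=seed
        )
        features = autoencoder.encode(ae_model, X)
    elif method == "nca":
        features = np.asarray(X, dtype=float)
    else:
        raise ValueError(f"method must be one of {METHODS}")
    model = nca.fit(features, y, d_out=2, seed=seed, max_iter=nca_max_iter)
    return model.transform(features), model, ae_model


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment end to end from a dataset directory.

    Reads annotation files (plus ``labels.csv`` when present), encodes and
    fuses them, reduces with the configured method, and -- when ``out_dir``
    is set -- writes ``embedding.csv``, ``embedding.png`` and
    ``metrics.json``.  Returns a result dict with the embedding frame,
    metrics, and fitted models.
    """
    profile = config.profile
    dataset_dir = Path(config.dataset_dir)
    labels_csv = dataset_dir / "labels.csv"
    protocol = profile.name.lower()
    episodes = read_dataset(
        dataset_dir,
        profile,
        labels_csv=labels_csv if labels_csv.exists() else None,
        protocol=protocol if labels_csv.exists() else None,
    )
    if not episodes:
        raise FileNotFoundError(f"no annotation files under {dataset_dir}")
    _, fused = build_dataset(episodes, profile, n_seconds=config.n_seconds)
    y = assign_labels(
        episodes,
        protocol,
        label_task=config.label_task,
        profile=profile,
        n_seconds=config.n_seconds,
    )
    logger.info(
        "experiment: %s / %s on %d episodes (seed %d)",
        config.method,
        config.label_task,
        len(episodes),
        config.seed,
    )
    W, nca_model, ae_model = reduce_dataset(
        fused.values,
        y,
        method=config.method,
        profile_H=profile.H,
        ae_latent=config.ae_latent,
        seed=config.seed,
        ae_epochs=config.ae_epochs,
        nca_max_iter=config.nca_max_iter,
    )
    metrics = separability_metrics(W, y)
    metrics["nca_objective"] = nca_model.objective_trace[-1]
    metrics["nca_iterations"] = nca_model.n_iter
    if ae_model is not None:
        _, _, lossless = autoencoder.reconstruct(ae_model, fused.values)
        metrics["ae_lossless_fraction"] = lossless
        metrics["ae_final_mse"] = ae_model.loss_trace[-1]
    embedding = pd.DataFrame(
        {
            "episode_id": fused.episode_ids,
            "NCA1": W[0],
            "NCA2": W[1],
            "label": y,
        }
    )
    result = {
        "embedding": embedding,
        "metrics": metrics,
        "nca_model": nca_model,
        "ae_model": ae_model,
        "config": config,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        embedding.to_csv(out / "embedding.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
        _plot_embedding(embedding, config, out / "embedding.png")
        result["out_dir"] = out
    return result


def _plot_embedding(embedding: pd.DataFrame, config: ExperimentConfig, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, grp in embedding.groupby("label"):
        ax.scatter(grp["NCA1"], grp["NCA2"], s=18, label=str(label))
    ax.set_xlabel("NCA1")
    ax.set_ylabel("NCA2")
    ax.set_title(f"{config.method} / {config.label_task} labels")
    ax.legend(title=config.label_task)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "resuskit"})
    plt.close(fig)
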