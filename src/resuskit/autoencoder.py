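"""Shallow sparse autoencoder for redundancy reduction of fused code vectors.

The network has three fully connected layers -- input, bottleneck, output --
with the *saturated linear* transfer function ``a(u) = min(1, max(0, u))`` on
both the encoder and decoder outputs.  Because that activation clips to
[0, 1], inputs are rescaled into [0, 1] first, per feature (min-max over the
training episodes), which also equalizes the reconstruction precision the
small codes need against the large ones.

Training minimizes

    (1/M) ||X_s - X~_s||_F^2  +  l2 * (||W_e||^2 + ||W_d||^2)
                              +  sparsity_coeff * sum_i KL(rho || rho_hat_i)

where ``rho_hat_i`` is the mean activation of hidden unit ``i`` over the
batch and ``rho`` the sparsity target.  The default optimizer is full-batch
L-BFGS run for `epochs` iterations: the reconstruction must be accurate to a
fraction of a code unit on every entry for the projection step to be exact,
and a first-order method at a fixed learning rate cannot reach that within
the epoch budget on this loss surface.  Plain and momentum gradient descent
(where `lr` applies) remain available as ``optimizer="gd"`` / ``"momentum"``.

Backpropagation through the clipping activation uses a boundary-recovery
subgradient: a saturated unit gets derivative 1 when the loss gradient points
back into the linear region, so units whose pre-activation leaves [0, 1]
during training are not frozen there.

After training, reconstructions are mapped back to code units and snapped
onto the lattice of allowed subset-sum values; on data the bottleneck can
represent, this projection recovers the exact original codes (a "lossless"
compression in the sense that only redundancy is removed).  Weighting the
reconstruction error by code magnitude is exposed as a hook
(``feature_weights``) but defaults to uniform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .encoding import allowed_values, project_to_allowed

_EPS = 1e-8

OPTIMIZERS = ("lbfgs", "momentum", "gd")


@dataclass
class AEModel:
    """Trained autoencoder parameters plus training metadata.

    ``feature_min`` / ``feature_range`` hold the per-feature affine scaling
    applied before the encoder (and inverted after the decoder); ``scale``
    is the maximum allowed fused value for ``H`` activities, kept for
    reference.  ``loss_trace`` records the reconstruction MSE (scaled units,
    mean over entries) per accepted iteration.
    """

    W_e: np.ndarray  # (d, N)
    b_e: np.ndarray  # (d,)
    W_d: np.ndarray  # (N, d)
    b_d: np.ndarray  # (N,)
    d: int
    H: int
    feature_min: np.ndarray  # (N,)
    feature_range: np.ndarray  # (N,)
    seed: int
    hyperparams: dict = field(default_factory=dict)
    loss_trace: list[float] = field(default_factory=list)

    @property
    def scale(self) -> float:
        return float(allowed_values(self.H)[-1])

    @property
    def n_features(self) -> int:
        return self.W_e.shape[1]

    def _scale_in(self, X: np.ndarray) -> np.ndarray:
        denom = np.where(self.feature_range > 0, self.feature_range, 1.0)
        return (X - self.feature_min[:, None]) / denom[:, None]

    def _scale_out(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.feature_range[:, None] + self.feature_min[:, None]

    def save(self, path: str | Path) -> None:
        """Save parameters (NPZ) with a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(
            path,
            W_e=self.W_e,
            b_e=self.b_e,
            W_d=self.W_d,
            b_d=self.b_d,
            feature_min=self.feature_min,
            feature_range=self.feature_range,
        )
        meta = {
            "d": self.d,
            "H": self.H,
            "seed": self.seed,
            "hyperparams": self.hyperparams,
            "loss_trace": self.loss_trace,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AEModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path, allow_pickle=False) as arrays:
            return cls(
                W_e=arrays["W_e"],
                b_e=arrays["b_e"],
                W_d=arrays["W_d"],
                b_d=arrays["b_d"],
                feature_min=arrays["feature_min"],
                feature_range=arrays["feature_range"],
                d=int(meta["d"]),
                H=int(meta["H"]),
                seed=int(meta["seed"]),
                hyperparams=meta["hyperparams"],
                loss_trace=list(meta["loss_trace"]),
            )


def _satlin(u: np.ndarray) -> np.ndarray:
    return np.clip(u, 0.0, 1.0)


def _satlin_mask(u: np.ndarray, upstream: np.ndarray) -> np.ndarray:
    """Subgradient mask of the saturated-linear activation.

    1 in the open interval (0, 1).  At a saturated unit the boundary
    subgradient is taken as 1 exactly when the downstream gradient
    (`upstream` = dLoss/d(activation)) points back into the linear region,
    so saturated units can recover instead of freezing with derivative 0.
    """
    interior = (u > 0.0) & (u < 1.0)
    recover_low = (u <= 0.0) & (upstream < 0.0)
    recover_high = (u >= 1.0) & (upstream > 0.0)
    return interior | recover_low | recover_high


def _loss_and_grads(params, Xs, fw, l2, beta, rho, M):
    W_e, b_e, W_d, b_d = params
    Ze = W_e @ Xs + b_e[:, None]
    Hh = _satlin(Ze)
    Zd = W_d @ Hh + b_d[:, None]
    Xh = _satlin(Zd)
    E = (Xh - Xs) * fw
    mse = float(np.mean((Xh - Xs) ** 2))
    rho_hat = np.clip(Hh.mean(axis=1), _EPS, 1.0 - _EPS)
    kl = float(
        (
            rho * np.log(rho / rho_hat)
            + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))
        ).sum()
    )
    loss = (
        float((E * (Xh - Xs)).sum() / M)
        + l2 * float((W_e**2).sum() + (W_d**2).sum())
        + beta * kl
    )
    dXh = (2.0 / M) * E
    dZd = dXh * _satlin_mask(Zd, dXh)
    gW_d = dZd @ Hh.T + 2.0 * l2 * W_d
    gb_d = dZd.sum(axis=1)
    dH = W_d.T @ dZd
    if beta > 0.0:
        dkl = -rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat)
        dH = dH + beta * dkl[:, None] / M
    dZe = dH * _satlin_mask(Ze, dH)
    gW_e = dZe @ Xs.T + 2.0 * l2 * W_e
    gb_e = dZe.sum(axis=1)
    return loss, mse, (gW_e, gb_e, gW_d, gb_d)


def train(
    X: np.ndarray,
    d: int,
    H: int,
    epochs: int = 4000,
    l2: float = 1e-4,
    sparsity_coeff: float = 0.01,
    sparsity_target: float = 0.05,
    lr: float = 0.01,
    seed: int = 0,
    optimizer: str = "lbfgs",
    momentum: float = 0.95,
    feature_weights: Optional[np.ndarray] = None,
) -> AEModel:
    """Train the autoencoder on an ``N x M`` fused matrix.

    `d` is the bottleneck width (must be < N) and `H` the activity count
    (fixes the allowed-value lattice for projection).  Runs exactly `epochs`
    full-batch iterations of the chosen optimizer; `lr` and `momentum` apply
    to the gradient-descent optimizers only.  Deterministic given `seed`
    (weights initialize from a seeded Gaussian; L-BFGS itself is
    deterministic).  `feature_weights` (length N) optionally weights the
    reconstruction error per feature; default uniform.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (features x episodes) matrix")
    N, M = X.shape
    if M < 1:
        raise ValueError("need at least one episode")
    if not 0 < d < N:
        raise ValueError(f"latent size d={d} must satisfy 0 < d < N={N}")
    if not np.all(np.isfinite(X)):
        raise ValueError("input data must be finite")
    if optimizer not in OPTIMIZERS:
        raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
    feature_min = X.min(axis=1)
    feature_range = X.max(axis=1) - feature_min
    denom = np.where(feature_range > 0, feature_range, 1.0)
    Xs = (X - feature_min[:, None]) / denom[:, None]
    if feature_weights is None:
        fw = np.ones((N, 1))
    else:
        fw = np.asarray(feature_weights, dtype=float).reshape(N, 1)
        if np.any(fw < 0):
            raise ValueError("feature_weights must be non-negative")

    rng = np.random.default_rng(seed)
    W_e = rng.normal(0.0, 1.0 / np.sqrt(N), size=(d, N))
    b_e = np.full(d, 0.1)  # start all hidden units in the linear region
    W_d = rng.normal(0.0, 1.0 / np.sqrt(d), size=(N, d))
    b_d = Xs.mean(axis=1)  # start the output at the data mean
    rho = float(sparsity_target)
    beta = float(sparsity_coeff)

    loss_trace: list[float] = []
    if optimizer == "lbfgs":
        shapes = [(d, N), (d,), (N, d), (N,)]
        sizes = [int(np.prod(s)) for s in shapes]

        def unpack(v):
            out, i = [], 0
            for s, n in zip(shapes, sizes):
                out.append(v[i : i + n].reshape(s))
                i += n
            return out

        last_mse = [np.mean((Xs.mean(axis=1)[:, None] - Xs) ** 2)]

        def fun(v):
            loss, mse, grads = _loss_and_grads(unpack(v), Xs, fw, l2, beta, rho, M)
            last_mse[0] = mse
            return loss, np.concatenate([g.ravel() for g in grads])

        v = np.concatenate([W_e.ravel(), b_e, W_d.ravel(), b_d])
        # The clipping activation makes the loss flat wherever a unit is
        # saturated, so the L-BFGS line search can stall on a plateau (no
        # descent along the recovery subgradient until the unit re-enters
        # the linear region).  When that happens, spend a slice of the
        # epoch budget on momentum-GD steps, which cross plateaus, then
        # resume L-BFGS with fresh curvature memory.
        done = 0
        while done < epochs:
            result = minimize(
                fun,
                v,
                jac=True,
                method="L-BFGS-B",
                callback=lambda xk: loss_trace.append(last_mse[0]),
                options={
                    "maxiter": epochs - done,
                    "maxfun": 2 * (epochs - done) + 20,
                    "ftol": 0,
                    "gtol": 0,
                },
            )
            v = result.x
            done += max(result.nit, 1)
            if done >= epochs or result.nit >= epochs - done:
                break
            n_gd = min(50, epochs - done)
            gd_params = unpack(v)
            velocity = [np.zeros_like(p) for p in gd_params]
            for _ in range(n_gd):
                _, mse, grads = _loss_and_grads(gd_params, Xs, fw, l2, beta, rho, M)
                loss_trace.append(mse)
                for p, g, vel in zip(gd_params, grads, velocity):
                    vel *= 0.9
                    vel -= lr * g
                    p += vel
            done += n_gd
            v = np.concatenate([p.ravel() for p in gd_params])
        W_e, b_e, W_d, b_d = unpack(v)
    else:
        mom = momentum if optimizer == "momentum" else 0.0
        params = [W_e, b_e, W_d, b_d]
        velocity = [np.zeros_like(p) for p in params]
        for _ in range(epochs):
            loss, mse, grads = _loss_and_grads(params, Xs, fw, l2, beta, rho, M)
            loss_trace.append(mse)
            for p, g, v in zip(params, grads, velocity):
                v *= mom
                v -= lr * g
                p += v
        W_e, b_e, W_d, b_d = params

    return AEModel(
        W_e=np.ascontiguousarray(W_e),
        b_e=np.ascontiguousarray(b_e),
        W_d=np.ascontiguousarray(W_d),
        b_d=np.ascontiguousarray(b_d),
        d=d,
        H=H,
        feature_min=feature_min,
        feature_range=feature_range,
        seed=seed,
        hyperparams={
            "epochs": epochs,
            "l2": l2,
            "sparsity_coeff": sparsity_coeff,
            "sparsity_target": sparsity_target,
            "lr": lr,
            "optimizer": optimizer,
            "momentum": momentum,
        },
        loss_trace=loss_trace,
    )


def encode(model: AEModel, X: np.ndarray) -> np.ndarray:
    """Latent codes ``Z = a(W_e X_s + b_e)``, one column per episode.

    Entries lie in [0, 1] by the saturated-linear activation; the map is
    pointwise per episode, so duplicated columns give identical latents.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.n_features:
        raise ValueError(
            f"X has {X.shape[0]} features, model expects {model.n_features}"
        )
    return _satlin(model.W_e @ model._scale_in(X) + model.b_e[:, None])


def reconstruct(
    model: AEModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Decode, rescale to code units, and project onto allowed values.

    Returns ``(X_tilde, X_projected, lossless_fraction)``: the raw
    reconstruction, its entrywise projection onto the allowed subset-sum
    lattice, and the fraction of entries where the projection equals the
    input exactly (1.0 means the compression lost nothing).
    """
    Z = encode(model, X)
    Xh = model._scale_out(_satlin(model.W_d @ Z + model.b_d[:, None]))
    X_proj = project_to_allowed(Xh, model.H)
    lossless = float(np.mean(X_proj == np.asarray(X, dtype=np.int64)))
    return Xh, X_proj, lossless
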