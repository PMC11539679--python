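"""Neighborhood component analysis (NCA), implemented from scratch.

NCA learns a linear map ``W = A X`` (``A`` of shape ``d_out x D``) that
maximizes the expected number of points softly assigned to a neighbor of
their own class.  Each embedded point ``w_j`` picks neighbor ``w_k`` with the
softmax probability over negative squared Euclidean distances

    P_jk = exp(-||w_j - w_k||^2) / sum_{l != j} exp(-||w_j - w_l||^2),

with ``P_jj = 0``, and the objective is

    f(A) = sum_j sum_{k : y_k = y_j, k != j} P_jk,         0 <= f(A) <= M.

``f`` is maximized with nonlinear conjugate gradients (Polak-Ribiere with
restarts) and a backtracking Armijo line search, so the recorded objective
trace is non-decreasing over accepted steps.  Inputs are mean-centered
(per feature) before optimization; no variance scaling is applied.

The gradient uses the standard closed form

    df/dA = 2 A sum_j ( p_j sum_z P_jz d_jz d_jz^T - sum_{z in C_j} P_jz d_jz d_jz^T )

with ``d_jz = x_j - x_z`` and ``p_j`` the in-class probability mass of row
``j``; it is evaluated as ``2 W L X^T`` through the graph-Laplacian identity,
which costs O(M^2 d + M D d) per iteration instead of O(M^2 D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-7


@dataclass
class NCAModel:
    """Fitted NCA transformation and its optimization trace."""

    A: np.ndarray  # (d_out, D)
    feature_mean: np.ndarray  # (D,) centering applied before the map
    d_out: int
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Embed ``D x M`` data: ``W = A (X - mean)``."""
        return self.A @ (np.asarray(X, dtype=float) - self.feature_mean[:, None])


def _pairwise_sq_dists(W: np.ndarray) -> np.ndarray:
    # W: (d, M) -> (M, M) squared Euclidean distances between columns
    sq = np.sum(W * W, axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (W.T @ W)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def soft_neighbor_probabilities(W: np.ndarray) -> np.ndarray:
    """Row-stochastic soft neighbor assignment matrix ``P`` from an embedding.

    ``W`` has one column per point.  Row ``j`` holds the probabilities of
    point ``j`` selecting each other point as its neighbor; the diagonal is 0
    and each row sums to 1.  Computed with a per-row log-sum-exp shift so the
    largest within-row exponent is 0 (distances can be huge for unscaled
    data; without the shift every exponential underflows).
    """
    W = np.asarray(W, dtype=float)
    M = W.shape[1]
    if M < 2:
        raise ValueError(f"need at least 2 points, got {M}")
    d2 = _pairwise_sq_dists(W)
    neg = -d2
    np.fill_diagonal(neg, -np.inf)
    shift = neg.max(axis=1, keepdims=True)
    P = np.exp(neg - shift)
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _same_class_mask(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    mask = y[:, None] == y[None, :]
    np.fill_diagonal(mask, False)
    return mask


def objective(A: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """NCA objective ``f(A)``: expected count of correctly assigned points."""
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] != y.shape[0]:
        raise ValueError(
            f"label count {y.shape[0]} does not match point count {X.shape[1]}"
        )
    P = soft_neighbor_probabilities(A @ X)
    return float(P[_same_class_mask(y)].sum())


def _objective_and_gradient(
    A: np.ndarray, X: np.ndarray, same: np.ndarray
) -> tuple[float, np.ndarray]:
    W = A @ X
    P = soft_neighbor_probabilities(W)
    p = np.where(same, P, 0.0).sum(axis=1)  # in-class mass per row
    f = float(p.sum())
    # weight w_jz = p_j * P_jz - P_jz * [same class]; gradient = 2 A X L X^T
    Wgt = P * p[:, None] - np.where(same, P, 0.0)
    S = Wgt + Wgt.T
    L = np.diag(S.sum(axis=1)) - S
    grad = 2.0 * (W @ L) @ X.T
    return f, grad


def gradient(A: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`objective` with respect to ``A``."""
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] != y.shape[0]:
        raise ValueError(
            f"label count {y.shape[0]} does not match point count {X.shape[1]}"
        )
    return _objective_and_gradient(A, X, _same_class_mask(y))[1]


def fit(
    X: np.ndarray,
    y: np.ndarray,
    d_out: int = 2,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    init_scale: float | None = None,
) -> NCAModel:
    """Fit NCA on ``D x M`` data with integer labels ``y`` (length M).

    The data are mean-centered per feature first.  ``A`` is initialized as a
    small seeded Gaussian (std ``1/sqrt(D)`` unless `init_scale` overrides)
    and ``f`` is maximized by Polak-Ribiere conjugate gradients with
    restarts and a backtracking Armijo line search.  Deterministic given
    `seed`; stops when the relative objective change drops below `tol` or
    after `max_iter` accepted iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("input data must be finite")
    D, M = X.shape
    if M < 2:
        raise ValueError(f"need at least 2 points, got {M}")
    if y.shape[0] != M:
        raise ValueError(f"label count {y.shape[0]} != point count {M}")
    if d_out > D:
        raise ValueError(f"d_out={d_out} exceeds input dimension {D}")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    same = _same_class_mask(y)

    rng = np.random.default_rng(seed)
    scale = init_scale if init_scale is not None else 1.0 / np.sqrt(D)
    A = rng.normal(0.0, scale, size=(d_out, D))

    f, g = _objective_and_gradient(A, Xc, same)
    trace = [f]
    direction = g.copy()
    g_prev = g
    step = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        slope = float(np.sum(g * direction))
        if slope <= 0:  # not an ascent direction: restart on steepest ascent
            direction = g.copy()
            slope = float(np.sum(g * g))
            if slope <= 1e-300:
                converged = True
                break
        # backtracking Armijo line search on the ascent problem
        t = step
        accepted = False
        for _ in range(50):
            f_new, g_new = _objective_and_gradient(A + t * direction, Xc, same)
            if f_new >= f + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            if np.array_equal(direction, g):  # steepest ascent failed too
                converged = True
                break
            direction = g.copy()
            step = 1.0
            continue
        A = A + t * direction
        step = min(t * 2.0, 1e6)  # warm-start next line search
        rel = abs(f_new - f) / max(abs(f), 1e-12)
        f = f_new
        trace.append(f)
        # Polak-Ribiere update with automatic restart
        beta = float(np.sum(g_new * (g_new - g_prev)) / max(np.sum(g_prev * g_prev), 1e-300))
        beta = max(beta, 0.0)
        direction = g_new + beta * direction
        g_prev = g_new
        g = g_new
        if rel < tol:
            converged = True
            break

    return NCAModel(
        A=A,
        feature_mean=mean,
        d_out=d_out,
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )
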