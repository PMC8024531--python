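"""Multiplicative-update NMF and the joint shared-subspace factorization.

Plain NMF approximates one non-negative matrix ``A ~ U V`` under squared
Frobenius loss by alternating the classical multiplicative rules.  The
joint variant factorizes two domains at once::

    min  alpha_s ||Xs - Ws H||_F^2 + alpha_t ||Xt - Wt H||_F^2
    s.t. Ws, Wt, H >= 0,  alpha_s + alpha_t = 1

with rows-as-samples orientation: ``Xs`` is n_s x d, ``Xt`` is n_t x d,
the shared basis ``H`` is r x d over the common feature space, and
``Ws``/``Wt`` hold per-sample coefficients.  Each iteration updates the
shared basis first, then the two coefficient matrices:

    H  <- H  * (a_s Ws'Xs + a_t Wt'Xt) / (a_s Ws'Ws H + a_t Wt'Wt H + delta)
    Ws <- Ws * (Xs H') / (Ws H H' + delta)
    Wt <- Wt * (Xt H') / (Wt H H' + delta)

Every update preserves non-negativity and does not increase the objective.
With identical domains, identical initialization and alpha_s = 1/2 the
joint iteration collapses exactly to the plain NMF iteration, which is why
:func:`nmf_factorize` also updates its basis factor first by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FeatureMatrix

__all__ = [
    "FitConfig",
    "NMFResult",
    "SharedSubspaceNMF",
    "nmf_factorize",
    "joint_objective",
    "fit_shared_subspace",
    "project_shared",
]

#: Additive guard against zero denominators in the multiplicative ratios.
DENOM_GUARD = 1e-12


@dataclass
class FitConfig:
    """Hyperparameters of the (joint) factorization.

    Parameters
    ----------
    r : int
        Dimension of the shared subspace, 1 <= r <= d.
    alpha_s : float
        Source-domain weight in (0, 1); the target weight is 1 - alpha_s.
    max_iter : int
        Iteration cap.
    eps : float
        Convergence threshold on the largest entry-wise factor change.
    seed : int
        Seed for the strictly-positive uniform(0.1, 1.1) initialization.
    denom_guard : float
        Small constant added to every denominator.
    stop_rule : str
        "max" (default): stop when the maximum change across all factors
        is below eps.  "any": stop as soon as any single factor's change
        is below eps (can trigger prematurely if one factor stalls).
    """

    r: int = 10
    alpha_s: float = 0.5
    max_iter: int = 1000
    eps: float = 1e-6
    seed: int = 0
    denom_guard: float = DENOM_GUARD
    stop_rule: str = "max"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_s < 1):
            raise ValueError("alpha_s must lie strictly between 0 and 1")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.stop_rule not in ("max", "any"):
            raise ValueError("stop_rule must be 'max' or 'any'")

    @property
    def alpha_t(self) -> float:
        return 1.0 - self.alpha_s


@dataclass
class NMFResult:
    """Outcome of a plain factorization ``A ~ U V``."""

    U: np.ndarray
    V: np.ndarray
    objective_trace: np.ndarray
    iterations_run: int
    converged: bool


@dataclass
class SharedSubspaceModel:
    """Fitted joint factorization: shared basis plus per-domain coefficients."""

    H: np.ndarray
    Ws: np.ndarray
    Wt: np.ndarray
    alpha_s: float
    objective_trace: np.ndarray
    converged: bool
    iterations_run: int

    @property
    def alpha_t(self) -> float:
        return 1.0 - self.alpha_s

    @property
    def r(self) -> int:
        return self.H.shape[0]


def _check_nonneg(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError(f"{name} must be entrywise non-negative")
    if np.any(~np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def _init_positive(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    # strictly positive start: zeros are absorbing under multiplicative updates
    return rng.uniform(0.1, 1.1, size=shape)


def nmf_factorize(
    A: np.ndarray,
    r: int,
    config: FitConfig | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    update_order: str = "vu",
) -> NMFResult:
    """Factorize a non-negative matrix ``A ~ U V`` by multiplicative updates.

    ``U`` is m x r, ``V`` is r x n.  Per iteration the rules

        V <- V * (U'A) / (U'U V + delta)
        U <- U * (A V') / (U V V' + delta)

    are applied (basis factor V first by default, mirroring the joint
    algorithm; pass ``update_order="uv"`` to flip).  Iteration stops when
    the larger of the entry-wise max changes of U and V drops below
    ``config.eps``, or at ``config.max_iter``.

    Parameters
    ----------
    init : (U0, V0), optional
        Explicit strictly-positive starting factors; defaults to seeded
        uniform(0.1, 1.1) draws.
    """
    config = config or FitConfig(r=r)
    A = _check_nonneg(A, "A")
    m, n = A.shape
    if not (1 <= r <= min(m, n)):
        raise ValueError(f"r={r} out of range [1, {min(m, n)}]")
    if update_order not in ("uv", "vu"):
        raise ValueError("update_order must be 'uv' or 'vu'")
    if init is not None:
        U, V = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))
        if U.shape != (m, r) or V.shape != (r, n):
            raise ValueError("init factors have wrong shapes")
    else:
        rng = np.random.default_rng(config.seed)
        U = _init_positive(rng, (m, r))
        V = _init_positive(rng, (r, n))
    delta = config.denom_guard
    trace = [float(np.linalg.norm(A - U @ V) ** 2)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        U_prev, V_prev = U, V
        if update_order == "vu":
            V = V * (U.T @ A) / (U.T @ U @ V + delta)
            U = U * (A @ V.T) / (U @ (V @ V.T) + delta)
        else:
            U = U * (A @ V.T) / (U @ (V @ V.T) + delta)
            V = V * (U.T @ A) / (U.T @ U @ V + delta)
        trace.append(float(np.linalg.norm(A - U @ V) ** 2))
        du = float(np.max(np.abs(U - U_prev)))
        dv = float(np.max(np.abs(V - V_prev)))
        if max(du, dv) < config.eps:
            converged = True
            break
    return NMFResult(
        U=U,
        V=V,
        objective_trace=np.array(trace),
        iterations_run=it,
        converged=converged,
    )


def joint_objective(
    Xs: np.ndarray,
    Xt: np.ndarray,
    Ws: np.ndarray,
    Wt: np.ndarray,
    H: np.ndarray,
    alpha_s: float = 0.5,
) -> float:
    """Weighted two-domain reconstruction loss.

    Returns ``alpha_s ||Xs - Ws H||_F^2 + (1 - alpha_s) ||Xt - Wt H||_F^2``.
    """
    Xs, Xt = np.asarray(Xs, float), np.asarray(Xt, float)
    Ws, Wt, H = np.asarray(Ws, float), np.asarray(Wt, float), np.asarray(H, float)
    if Xs.shape != (Ws.shape[0], H.shape[1]) or Ws.shape[1] != H.shape[0]:
        raise ValueError("source shapes not conformable")
    if Xt.shape != (Wt.shape[0], H.shape[1]) or Wt.shape[1] != H.shape[0]:
        raise ValueError("target shapes not conformable")
    rs = float(np.linalg.norm(Xs - Ws @ H) ** 2)
    rt = float(np.linalg.norm(Xt - Wt @ H) ** 2)
    return alpha_s * rs + (1.0 - alpha_s) * rt


def fit_shared_subspace(
    Xs: np.ndarray | FeatureMatrix,
    Xt: np.ndarray | FeatureMatrix,
    config: FitConfig | None = None,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> SharedSubspaceModel:
    """Learn a shared non-negative basis jointly from two domains.

    Alternates, per iteration, the shared-basis update followed by the two
    coefficient updates (see module docstring) from a seeded strictly
    positive start, recording the joint objective each iteration.  Stops
    when the factor changes fall below ``config.eps`` (per its stop_rule)
    or at ``config.max_iter``.

    Parameters
    ----------
    Xs, Xt : array or FeatureMatrix
        Non-negative matrices with rows as samples sharing one feature
        space (equal column counts; sample counts may differ).
    init : (Ws0, Wt0, H0), optional
        Explicit strictly-positive starting factors.
    """
    Xs = Xs.values if isinstance(Xs, FeatureMatrix) else Xs
    Xt = Xt.values if isinstance(Xt, FeatureMatrix) else Xt
    Xs = _check_nonneg(Xs, "Xs")
    Xt = _check_nonneg(Xt, "Xt")
    ns, d = Xs.shape
    nt, dt = Xt.shape
    if d != dt:
        raise ValueError(
            f"both domains must share the feature space (d={d} vs d={dt})"
        )
    config = config or FitConfig(r=min(10, d))
    r = config.r
    if not (1 <= r <= d):
        raise ValueError(f"r={r} out of range [1, {d}]")
    a_s, a_t = config.alpha_s, config.alpha_t
    if init is not None:
        Ws, Wt, H = (np.array(m, dtype=float) for m in init)
        if Ws.shape != (ns, r) or Wt.shape != (nt, r) or H.shape != (r, d):
            raise ValueError("init factors have wrong shapes")
    else:
        rng = np.random.default_rng(config.seed)
        Ws = _init_positive(rng, (ns, r))
        Wt = _init_positive(rng, (nt, r))
        H = _init_positive(rng, (r, d))
    delta = config.denom_guard
    trace = [joint_objective(Xs, Xt, Ws, Wt, H, a_s)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        H_prev, Ws_prev, Wt_prev = H, Ws, Wt
        # parenthesized so that with identical domains and alpha_s = 1/2 the
        # update is bit-identical to the plain NMF basis rule
        H = H * (a_s * (Ws.T @ Xs) + a_t * (Wt.T @ Xt)) / (
            a_s * (Ws.T @ Ws @ H) + a_t * (Wt.T @ Wt @ H) + delta
        )
        Ws = Ws * (Xs @ H.T) / (Ws @ (H @ H.T) + delta)
        Wt = Wt * (Xt @ H.T) / (Wt @ (H @ H.T) + delta)
        trace.append(joint_objective(Xs, Xt, Ws, Wt, H, a_s))
        dh = float(np.max(np.abs(H - H_prev)))
        ds = float(np.max(np.abs(Ws - Ws_prev)))
        dt_ = float(np.max(np.abs(Wt - Wt_prev)))
        if config.stop_rule == "max":
            done = max(dh, ds, dt_) < config.eps
        else:
            done = min(dh, ds, dt_) < config.eps
        if done:
            converged = True
            break
    return SharedSubspaceModel(
        H=H,
        Ws=Ws,
        Wt=Wt,
        alpha_s=a_s,
        objective_trace=np.array(trace),
        converged=converged,
        iterations_run=it,
    )


def project_shared(H: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project samples onto the shared basis: row i of the result is H @ x_i.

    Equivalent to ``X @ H.T`` for X with samples as rows.
    """
    H = np.asarray(H, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != H.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} features but H spans {H.shape[1]}"
        )
    return X @ H.T


class SharedSubspaceNMF(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer wrapping the joint factorization.

    ``fit(X, X_target=...)`` learns the shared basis from the two domains;
    ``transform(X)`` returns the subspace coordinates ``X H'`` of any
    matrix over the same feature space.

    Parameters
    ----------
    r : int
        Subspace dimension.
    alpha_s : float
        Source-domain weight in the joint objective.
    max_iter, eps, stop_rule, random_state
        Passed through to the optimizer (see :class:`FitConfig`).

    Attributes
    ----------
    H_ : ndarray of shape (r, d)
        Shared non-negative basis.
    Ws_, Wt_ : ndarray
        Per-domain coefficient matrices.
    objective_trace_ : ndarray
        Joint objective per iteration (index 0 = at initialization).
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        r: int = 10,
        alpha_s: float = 0.5,
        max_iter: int = 1000,
        eps: float = 1e-6,
        stop_rule: str = "max",
        random_state: int = 0,
    ):
        self.r = r
        self.alpha_s = alpha_s
        self.max_iter = max_iter
        self.eps = eps
        self.stop_rule = stop_rule
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            r=self.r,
            alpha_s=self.alpha_s,
            max_iter=self.max_iter,
            eps=self.eps,
            seed=self.random_state,
            stop_rule=self.stop_rule,
        )

    def fit(self, X, y=None, *, X_target=None):
        if X_target is None:
            raise ValueError(
                "SharedSubspaceNMF needs the target domain: "
                "fit(X_source, X_target=X_target)"
            )
        model = fit_shared_subspace(X, X_target, config=self._config())
        self.H_ = model.H
        self.Ws_ = model.Ws
        self.Wt_ = model.Wt
        self.objective_trace_ = model.objective_trace
        self.n_iter_ = model.iterations_run
        self.converged_ = model.converged
        self.n_features_in_ = model.H.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "H_"):
            raise AttributeError("SharedSubspaceNMF is not fitted yet")
        return project_shared(self.H_, X)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def save_subspace_model(model: SharedSubspaceModel, directory: str | Path) -> None:
    """Serialize a fitted model: JSON manifest + delimited-text matrices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "r": model.r,
        "alpha_s": model.alpha_s,
        "shapes": {
            "H": list(model.H.shape),
            "Ws": list(model.Ws.shape),
            "Wt": list(model.Wt.shape),
        },
        "converged": bool(model.converged),
        "iterations_run": int(model.iterations_run),
        "objective_trace": [float(v) for v in model.objective_trace],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for name, mat in (("H", model.H), ("Ws", model.Ws), ("Wt", model.Wt)):
        np.savetxt(directory / f"{name}.csv", mat, delimiter=",", fmt="%.17g")


def load_subspace_model(directory: str | Path) -> SharedSubspaceModel:
    """Inverse of :func:`save_subspace_model`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    mats = {
        name: np.loadtxt(directory / f"{name}.csv", delimiter=",", ndmin=2)
        for name in ("H", "Ws", "Wt")
    }
    return SharedSubspaceModel(
        H=mats["H"],
        Ws=mats["Ws"],
        Wt=mats["Wt"],
        alpha_s=float(manifest["alpha_s"]),
        objective_trace=np.array(manifest["objective_trace"]),
        converged=bool(manifest["converged"]),
        iterations_run=int(manifest["iterations_run"]),
    )
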