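"""Linear-SEM DAG structure learning by continuous optimization.

The model is X = XW + Z: every variable is a linear combination of its
parents plus noise, with W a d x d weighted adjacency matrix (W[i, j]
weights the edge i -> j; parents index rows, children columns). Acyclicity
is enforced through the smooth constraint

    h(W) = trace(e^{W o W}) - d = 0,

which vanishes exactly when the support of W is cycle-free, so the
combinatorial DAG search becomes the constrained problem

    min_W  ||X - XW||_F^2 / (2n)   s.t.  h(W) = 0,

solved by an augmented-Lagrangian scheme: minimise
L(W, a, rho) = loss + lambda1*||W||_1 + a*h(W) + (rho/2)*h(W)^2 over W,
then update the multiplier a and escalate the penalty rho until h is
driven below tolerance. Hard-thresholding of small weights is a separate
stage (see :mod:`cohortdag.selection`), not applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from . import _solver

__all__ = ["WeightMatrix", "FitSettings", "squared_loss", "acyclicity", "notears_fit"]


@dataclass
class FitSettings:
    """Solver configuration for :func:`notears_fit`.

    lambda1
        L1 sparsity coefficient (default 0: the plain least-squares
        objective). When positive, the subproblem is solved on the smooth
        nonnegative splitting W = W+ - W-.
    h_tol
        Acyclicity tolerance: fitting stops once h(W) <= h_tol.
    rho_init, rho_max
        Initial value and cap of the quadratic penalty parameter.
    max_dual_iter
        Cap on outer (dual-update) iterations.
    scale_columns
        If true, divide each centered column by its standard deviation.
    inner_maxiter, gtol, ftol
        Inner L-BFGS iteration cap, gradient infinity-norm tolerance, and
        relative objective-change tolerance.
    """

    lambda1: float = 0.0
    h_tol: float = 1e-8
    rho_init: float = 1.0
    rho_max: float = 1e16
    max_dual_iter: int = 100
    scale_columns: bool = False
    inner_maxiter: int = 300
    gtol: float = 1e-5
    ftol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if self.h_tol <= 0:
            raise ValueError("h_tol must be > 0")
        if self.rho_max < self.rho_init:
            raise ValueError("rho_max must be >= rho_init")


@dataclass
class WeightMatrix:
    """Weighted adjacency of the learned linear SEM.

    ``W[i, j]`` is the weight of edge ``nodes[i] -> nodes[j]``; the diagonal
    is identically zero.
    """

    W: np.ndarray
    nodes: list[str]
    h: float = 0.0
    converged: bool = True
    n_dual_iter: int = 0
    loss: float = float("nan")

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        d = len(self.nodes)
        if self.W.shape != (d, d):
            raise ValueError(f"W shape {self.W.shape} does not match {d} nodes")
        if np.abs(np.diag(self.W)).max(initial=0.0) > 0:
            raise ValueError("diagonal of W must be zero")

    @property
    def d(self) -> int:
        return len(self.nodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.nodes, columns=self.nodes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "WeightMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])

    def report(self) -> dict:
        return {
            "nodes": self.nodes,
            "h": self.h,
            "loss": self.loss,
            "converged": self.converged,
            "n_dual_iter": self.n_dual_iter,
            "n_edges": int(np.count_nonzero(self.W)),
        }


def squared_loss(X: np.ndarray, W: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares loss ||X - XW||_F^2 / (2n) and its gradient in W.

    The gradient is -X'(X - XW)/n.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.ndim != 2 or W.shape != (X.shape[1], X.shape[1]):
        raise ValueError(f"shape mismatch: X {X.shape}, W {W.shape}")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    n = X.shape[0]
    R = X - X @ W
    loss = float(np.sum(R * R)) / (2.0 * n)
    grad = -(X.T @ R) / n
    return loss, grad


def acyclicity(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Smooth acyclicity measure h(W) = trace(e^{W o W}) - d and gradient.

    h >= 0 always, with h = 0 exactly when the support of W contains no
    directed cycle. The gradient is (e^{W o W})' o 2W.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    E = scipy.linalg.expm(W * W)
    h = float(np.trace(E)) - W.shape[0]
    grad = E.T * (2.0 * W)
    return h, grad


def _preprocess(X: np.ndarray, settings: FitSettings) -> np.ndarray:
    Xc = X - X.mean(axis=0, keepdims=True)
    if settings.scale_columns:
        sd = Xc.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    return Xc


def notears_fit(
    X,
    settings: FitSettings | None = None,
    nodes: list[str] | None = None,
) -> WeightMatrix:
    """Learn a weighted adjacency matrix from data by constrained optimization.

    ``X`` is an n x d data matrix (a DataFrame's columns name the nodes).
    Columns are centered internally (the linear model has no intercept).
    Returns a :class:`WeightMatrix`; if the penalty cap is reached with
    h(W) still above tolerance the best W is returned with
    ``converged=False``.
    """
    settings = settings or FitSettings()
    if isinstance(X, pd.DataFrame):
        nodes = nodes or [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if nodes is None:
        nodes = [f"x{i}" for i in range(d)]
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if d == 1:
        return WeightMatrix(np.zeros((1, 1)), nodes, h=0.0, loss=squared_loss(X - X.mean(0), np.zeros((1, 1)))[0])
    if n < 2:
        raise ValueError("need n >= 2 samples")

    Xc = _preprocess(X, settings)
    if settings.lambda1 > 0:
        W, h, n_iter = _fit_l1(Xc, settings)
    else:
        S = np.ascontiguousarray(Xc.T @ Xc)
        W, h, _, n_iter = _solver.solve_gram(
            S,
            float(n),
            np.zeros(d * d),
            settings.h_tol,
            settings.rho_init,
            settings.rho_max,
            settings.max_dual_iter,
            settings.inner_maxiter,
            settings.gtol,
            settings.ftol,
        )
    np.fill_diagonal(W, 0.0)
    loss, _ = squared_loss(Xc, W)
    return WeightMatrix(
        W, nodes, h=float(h), converged=bool(h <= settings.h_tol),
        n_dual_iter=int(n_iter), loss=loss,
    )


def _fit_l1(Xc: np.ndarray, settings: FitSettings) -> tuple[np.ndarray, float, int]:
    """Augmented-Lagrangian loop with the smooth (W+, W-) splitting.

    With lambda1 > 0 the L1 term becomes linear on the nonnegative orthant
    (||W||_1 = sum(W+ + W-)), so scipy's bound-constrained L-BFGS-B applies.
    """
    n, d = Xc.shape
    S = Xc.T @ Xc
    lam = settings.lambda1

    def objective(theta, rho, alpha):
        wp = theta[: d * d].reshape(d, d)
        wm = theta[d * d :].reshape(d, d)
        W = wp - wm
        M = np.eye(d) - W
        SM = S @ M
        loss = 0.5 / n * float(np.sum(M * SM))
        E = scipy.linalg.expm(W * W)
        h = float(np.trace(E)) - d
        f = loss + lam * float(theta.sum()) + alpha * h + 0.5 * rho * h * h
        gW = -SM / n + (alpha + rho * h) * (E.T * (2.0 * W))
        np.fill_diagonal(gW, 0.0)
        g = np.concatenate([(gW + lam).ravel(), (-gW + lam).ravel()])
        return f, g

    theta = np.zeros(2 * d * d)
    bounds = [(0.0, None)] * (2 * d * d)
    rho, alpha, h = settings.rho_init, 0.0, np.inf
    it_done = 0
    for it in range(settings.max_dual_iter):
        it_done = it + 1
        theta_new, h_new = theta, h
        while rho < settings.rho_max:
            res = scipy.optimize.minimize(
                objective, theta, args=(rho, alpha), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": settings.inner_maxiter},
            )
            theta_new = res.x
            Wn = (theta_new[: d * d] - theta_new[d * d :]).reshape(d, d)
            h_new = acyclicity(Wn)[0]
            if h_new > 0.25 * h:
                rho *= 10.0
            else:
                break
        theta, h = theta_new, h_new
        alpha += rho * h
        if h <= settings.h_tol or rho >= settings.rho_max:
            break
    W = (theta[: d * d] - theta[d * d :]).reshape(d, d)
    return W, h, it_done
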