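"""Partial least squares regression (NIPALS) with VIP and leave-one-out Q².

Single-response PLS1 of an activity endpoint on the normalized peak
matrix: one model per endpoint.  Components are extracted by NIPALS —

    w_a ∝ X_aᵀ y_a (unit norm),  t_a = X_a w_a,
    p_a = X_aᵀ t_a / t_aᵀ t_a,   q_a = y_aᵀ t_a / t_aᵀ t_a,
    X_{a+1} = X_a − t_a p_aᵀ,    y_{a+1} = y_a − q_a t_a

— giving regression coefficients b = W (PᵀW)⁻¹ q on the autoscaled
data.  Variable importance in projection is

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a ),
    SSY_a = q_a² t_aᵀ t_a,

with the usual VIP > 1 importance cut.  Model adequacy is judged by R²Y
(fitted) and Q² (leave-one-out cross-validated, scaling re-estimated in
every fold); both > 0.5 is the conventional adequacy threshold.
"""

from __future__ import annotations

import warnings
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "autoscale",
    "NIPALSPLS",
    "fit_pls",
    "loo_q2",
    "vip",
    "select_components",
]

Scale = Literal["unit_variance", "pareto", "none"]


def autoscale(X: np.ndarray, center: bool = True, scale: Scale = "unit_variance"):
    """Column-wise centering/scaling.

    Returns ``(X_scaled, means, divisors)``.  Unit-variance scaling uses
    the n-1 standard deviation; Pareto divides by its square root.
    Constant columns cannot be variance-scaled: they are left centered
    only (divisor 1) and reported via the third return value.
    """
    X = np.asarray(X, float)
    means = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - means
    if scale == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        div = np.where(sd > 0, sd, 1.0)
    elif scale == "pareto":
        sd = X.std(axis=0, ddof=1)
        div = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scale == "none":
        div = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return Xc / div, means, div


class NIPALSPLS(RegressorMixin, BaseEstimator):
    """Single-response PLS regression via NIPALS.

    Parameters
    ----------
    n_components : number of latent components A (must satisfy
        A <= min(p, n-1)).
    scale : 'unit_variance' (default), 'pareto' or 'none'; X and y are
        always column-centered.

    Attributes
    ----------
    x_weights_ : W, (p, A); each column unit norm, sign fixed so the
        largest-magnitude entry is positive.
    x_loadings_ : P, (p, A).
    y_loadings_ : q, (A,).
    x_scores_ : T, (n, A); mutually orthogonal columns.
    coef_scaled_ : b on the autoscaled data, (p,).
    coef_ : b on the raw data scale, (p,).
    intercept_ : raw-scale intercept.
    r2x_, r2y_ : cumulative fractions of X / y variance explained per
        component count.
    vip_ : variable importance in projection, (p,); Σ VIP² = p.
    """

    def __init__(self, n_components: int = 2, scale: Scale = "unit_variance"):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y have different numbers of samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in X or y")
        if np.std(y) == 0:
            raise ValueError("zero-variance response")
        A = int(self.n_components)
        if not 1 <= A <= min(p, n - 1):
            raise ValueError(f"n_components must be in [1, min(p, n-1)] = [1, {min(p, n - 1)}]")

        Xs, self.x_mean_, self.x_div_ = autoscale(X, scale=self.scale)
        ys, ym, ydiv = autoscale(y[:, None], scale=self.scale)
        self.y_mean_, self.y_div_ = float(ym[0]), float(ydiv[0])
        ys = ys.ravel()

        ssx_total = float((Xs**2).sum())
        ssy_total = float((ys**2).sum())
        Xa, ya = Xs.copy(), ys.copy()
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        T = np.zeros((n, A))
        q = np.zeros(A)
        r2x, r2y = [], []
        for a in range(A):
            w = Xa.T @ ya
            nw = np.linalg.norm(w)
            if nw == 0:
                # y residual orthogonal to X residual: no further structure
                A = a
                break
            w = w / nw
            j = int(np.argmax(np.abs(w)))
            if w[j] < 0:
                w = -w
            t = Xa @ w
            tt = float(t @ t)
            if tt == 0:
                A = a
                break
            pa = Xa.T @ t / tt
            qa = float(ya @ t / tt)
            Xa = Xa - np.outer(t, pa)
            ya = ya - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
            r2x.append(1.0 - float((Xa**2).sum()) / ssx_total if ssx_total > 0 else 0.0)
            r2y.append(1.0 - float((ya**2).sum()) / ssy_total)
        if A == 0:
            raise ValueError("no PLS component could be extracted")
        W, P, T, q = W[:, :A], P[:, :A], T[:, :A], q[:A]

        self.n_components_ = A
        self.x_weights_, self.x_loadings_, self.x_scores_, self.y_loadings_ = W, P, T, q
        self.coef_scaled_ = W @ np.linalg.solve(P.T @ W, q)
        self.coef_ = self.coef_scaled_ * self.y_div_ / self.x_div_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.r2x_ = np.asarray(r2x)
        self.r2y_ = np.asarray(r2y)
        self.vip_ = vip(self)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        return X @ self.coef_ + self.intercept_


def vip(model: NIPALSPLS) -> np.ndarray:
    """Variable importance in projection of a fitted model."""
    W, T, q = model.x_weights_, model.x_scores_, model.y_loadings_
    p = W.shape[0]
    ssy = q**2 * np.einsum("ij,ij->j", T, T)  # q_a^2 * t_a't_a
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def fit_pls(X, y, n_components: int = 2, scale: Scale = "unit_variance") -> NIPALSPLS:
    """Functional wrapper over :class:`NIPALSPLS`."""
    return NIPALSPLS(n_components=n_components, scale=scale).fit(X, y)


def loo_q2(X, y, max_components: int, scale: Scale = "unit_variance") -> np.ndarray:
    """Leave-one-out Q² for component counts 1..max_components.

    Q²(A) = 1 − PRESS(A)/SS with SS = Σ (y − ȳ)²; scaling parameters are
    re-estimated inside every fold so no information leaks from the
    held-out sample.  A fold whose fit fails contributes its training
    mean as the prediction (with a warning).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("leave-one-out Q2 needs n >= 4")
    A_max = min(max_components, X.shape[1], n - 2)  # n-2: each fold has n-1 rows
    press = np.zeros(A_max)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        for a in range(1, A_max + 1):
            try:
                m = NIPALSPLS(n_components=a, scale=scale).fit(Xtr, ytr)
                pred = float(m.predict(X[i : i + 1])[0])
            except Exception as e:  # pragma: no cover - degenerate folds
                warnings.warn(f"LOO fold {i}, A={a} failed ({e}); using fold-train mean")
                pred = float(ytr.mean())
            press[a - 1] += (y[i] - pred) ** 2
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss


def select_components(
    X,
    y,
    rule: str = "q2_gain",
    threshold: float = 0.0975,
    max_components: int | None = None,
    scale: Scale = "unit_variance",
) -> int:
    """Choose the component count A from the LOO Q² curve.

    Rules: 'max_q2' takes the argmax; 'q2_gain' keeps adding components
    while the Q² increment exceeds ``threshold`` (the conventional
    0.0975 significance limit); 'fixed' returns ``max_components``.
    A is floored at 1 — even a pure-noise response gets one component.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    cap = min(max_components or min(p, n - 2), p, n - 2)
    if rule == "fixed":
        return max(1, cap)
    q2 = loo_q2(X, y, cap, scale=scale)
    if rule == "max_q2":
        return int(np.argmax(q2)) + 1
    if rule == "q2_gain":
        a = 1
        while a < q2.size and q2[a] - q2[a - 1] > threshold:
            a += 1
        return a
    raise ValueError(f"unknown rule {rule!r}")
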