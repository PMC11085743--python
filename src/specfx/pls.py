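"""PLS1 regression (NIPALS) with VIP variable-importance screening.

Each bioactivity indicator is regressed on the common-peak area matrix with
partial least squares.  PLS handles the "wide" chemometric regime (more
peaks than batches) by extracting A latent components t_a = X w_a that
maximize covariance with the response.  Variable importance in projection,

    VIP_j = sqrt( P * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ),

weights each predictor's contribution to the components by the response
variance SS_a each component explains; the mean squared VIP is 1, so
VIP > 1 flags above-average contributors.

The literature on this screening procedure calls the model "PLS-DA" while
regressing continuous assay values; since no class labels exist, this module
implements continuous-response PLS1 regression (one model per indicator),
which is what the VIP screen actually needs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigError, FitError, ValidationError
from .fingerprint import CommonPeakMatrix
from .panel import INDICATORS, BioactivityPanel

Scaling = Literal["autoscale", "center", "none"]


@dataclass(frozen=True)
class PlsConfig:
    """PLS fitting parameters.

    n_components
        Number of latent components A (must satisfy A <= min(batches-1,
        peaks)).  Two components is a common fingerprint-model default.
    scaling
        "autoscale" (center + unit variance, the chemometric standard),
        "center" (mean only) or "none".
    max_iter / tol
        Inner-loop controls kept for interface parity; with a univariate
        response the NIPALS weight step is closed-form and never iterates.
    """

    n_components: int = 2
    scaling: Scaling = "autoscale"
    max_iter: int = 500
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.scaling not in ("autoscale", "center", "none"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")


@dataclass
class PlsModel:
    """Fitted PLS1 model (all latent quantities in the scaled space)."""

    weights: np.ndarray     # W, peaks x A, each column unit norm
    scores: np.ndarray      # T, batches x A, mutually orthogonal
    x_loadings: np.ndarray  # P, peaks x A
    y_loadings: np.ndarray  # q, A
    ss: np.ndarray          # per-component explained y-variance (scaled units)
    coef: np.ndarray        # regression coefficients on the ORIGINAL scale
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    config: PlsConfig = field(default_factory=PlsConfig)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


@dataclass
class VipResult:
    """Per-peak VIP scores for one fitted indicator model."""

    vip: np.ndarray
    peak_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.vip = np.asarray(self.vip, dtype=float)
        if np.any(self.vip < 0):
            raise ValidationError("VIP scores must be non-negative")


def _scale_xy(X: np.ndarray, y: np.ndarray, scaling: Scaling):
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scaling == "none":
        x_mean = np.zeros(X.shape[1])
        y_mean = 0.0
    x_scale = np.ones(X.shape[1])
    y_scale = 1.0
    if scaling == "autoscale":
        x_scale = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(x_scale == 0)
        if dead.size:
            raise FitError(
                f"constant predictor column(s) {dead.tolist()} cannot be autoscaled"
            )
        y_scale = float(y.std(ddof=1))
        if y_scale == 0:
            raise FitError("constant response cannot be autoscaled")
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    return Xs, ys, x_mean, x_scale, y_mean, y_scale


def fit_pls(X: np.ndarray, y: np.ndarray, config: PlsConfig = PlsConfig()) -> PlsModel:
    """Fit PLS1 by NIPALS with deflation.

    For a univariate response the weight of each component is w = X'y /
    ||X'y|| exactly, so extraction is deterministic (no random start).  X and
    y are deflated after each component.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"X has {n} rows but y has {y.size}")
    if n < 3:
        raise ValidationError("PLS needs at least 3 batches")
    A = config.n_components
    if A > min(n - 1, p):
        raise ConfigError(
            f"n_components={A} exceeds min(batches-1, peaks)={min(n - 1, p)}"
        )
    Xs, ys, x_mean, x_scale, y_mean, y_scale = _scale_xy(X, y, config.scaling)

    Xd, yd = Xs.copy(), ys.copy()
    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    q = np.empty(A)
    ss = np.empty(A)
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise FitError(
                f"component {a + 1}: response already fully deflated "
                "(reduce n_components)"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise FitError(f"component {a + 1}: degenerate score vector")
        pl = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pl)
        yd = yd - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pl, qa
        ss[a] = qa**2 * tt  # y-variance captured by component a

    # Regression vector in scaled space: B = W (P'W)^-1 q
    B = W @ np.linalg.solve(P.T @ W, q)
    coef = y_scale * B / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return PlsModel(
        weights=W, scores=T, x_loadings=P, y_loadings=q, ss=ss,
        coef=coef, intercept=intercept,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        config=config,
    )


def vip_scores(model: PlsModel) -> VipResult:
    """VIP of every predictor; satisfies sum(VIP^2) = number of predictors."""
    W, ss = model.weights, model.ss
    total = float(ss.sum())
    if total == 0:
        raise FitError("no response variance explained; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = W.shape[0]
    vip = np.sqrt(p * (wn**2 @ ss) / total)
    return VipResult(vip=vip)


def vip_screen(
    vips: dict[str, VipResult] | VipResult, threshold: float = 1.0
) -> set[tuple[str, int]]:
    """(indicator, peak) pairs with VIP strictly above the threshold."""
    if isinstance(vips, VipResult):
        vips = {"y": vips}
    hits = set()
    for ind, res in vips.items():
        ids = res.peak_ids or list(range(1, res.vip.size + 1))
        for j, v in zip(ids, res.vip):
            if v > threshold:
                hits.add((str(ind), int(j)))
    return hits


def pls_analysis(
    matrix: CommonPeakMatrix,
    panel: BioactivityPanel,
    config: PlsConfig = PlsConfig(),
) -> tuple[dict[str, PlsModel], dict[str, VipResult]]:
    """Fit one PLS1 model per indicator and compute VIP scores.

    Four separate per-indicator models (the convention in multi-indicator
    spectrum-effect studies) rather than one multi-response fit.  Raw
    indicator values are used: VIP is invariant to the sign of the response,
    so no orientation flip is needed.
    """
    if not matrix.is_complete:
        raise ValidationError("PLS requires a complete common-peak matrix")
    if list(matrix.batch_ids) != panel.batch_ids:
        raise ValidationError("matrix and panel batch ids differ (order matters)")
    models: dict[str, PlsModel] = {}
    vips: dict[str, VipResult] = {}
    for ind in INDICATORS:
        model = fit_pls(matrix.areas, panel.series(ind), config)
        models[ind] = model
        res = vip_scores(model)
        res.peak_ids = list(matrix.peak_ids)
        vips[ind] = res
    return models, vips


def loo_q2(X: np.ndarray, y: np.ndarray, config: PlsConfig = PlsConfig()) -> float:
    """Leave-one-out Q2 of a PLS1 fit (utility for choosing A, not automatic).

    Q2 = 1 - PRESS / TSS with TSS about the training means of each fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    press = 0.0
    tss = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_pls(X[keep], y[keep], config)
        press += float(model.predict(X[i][None, :])[0] - y[i]) ** 2
        tss += float(y[i] - y[keep].mean()) ** 2
    return 1.0 - press / tss
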