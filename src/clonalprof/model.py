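"""Predictor, objectives, penalties, and constrained model fitting.

The predictor is a per-site convex combination: at each of the 149
positions ``j`` the predicted amino-acid distribution is

    yhat[i, j, :] = sum_l alpha[j, l] * xstar[i, j, :, l]
                    + (1 - sum_l alpha[j, l]) * x[i, j, :]

where ``x`` is the query CF's own (single-sequence) profile, ``xstar``
stacks the p external source profiles, and the site-specific weights
``alpha`` satisfy 0 <= alpha[j, l] <= 1 and sum_l alpha[j, l] <= 1.  Undefined
(gap) positions propagate their mask and are excluded from every sum.

Two objectives are provided: a mean squared "L2 error" over profile rows,
and a Jaccard similarity between threshold-``t`` high-frequency amino-acid
sets (with a differentiable logistic surrogate used during fitting).  The
fit adds a standard lasso penalty on ``alpha`` and a fused-lasso (trend
filtering) penalty on d-th order successive differences along positions,
and minimizes by L-BFGS-B within the box with an exact penalty enforcing
the per-position sum constraint, followed by projection onto the feasible
set.  The penalized L2 problem is convex, so any local minimum is global.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .external import InputTensor
from .profiles import N_POSITIONS, ProfileTensor

_ABS_EPS = 1e-12  # smoothing of |x| ~ sqrt(x^2 + eps)
# Guard added to the surrogate's numerator and denominator so that
# positions where both high-frequency sets are (effectively) empty score 1,
# matching the exact metric's empty-set convention, while ordinary
# positions (numerator >= ~1) are perturbed by less than 1e-9.
_EMPTY_GUARD = 1e-9
_SNAP = 1e-6      # weights below this are snapped to exact zero


@dataclass
class WeightMatrix:
    """Site-specific source weights alpha, shape (149, p)."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 2 or self.alpha.shape[0] != N_POSITIONS:
            raise ValueError(f"alpha must have shape ({N_POSITIONS}, p)")

    @property
    def p(self) -> int:
        return self.alpha.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        a = self.alpha
        if np.any(a < -atol) or np.any(a > 1 + atol):
            raise ValueError("alpha entries must lie in [0, 1]")
        if np.any(a.sum(axis=1) > 1 + atol):
            raise ValueError("per-position alpha sums must be <= 1")

    @classmethod
    def zeros(cls, p: int) -> "WeightMatrix":
        return cls(np.zeros((N_POSITIONS, p)))


@dataclass
class PenaltyConfig:
    """Lasso weight ``lambda1``, fused weight ``lambda2``, differencing
    order ``d`` (penalizes d-th order discrete derivatives of each alpha
    column, favoring piecewise polynomials of order d-1)."""

    lambda1: float = 0.0
    lambda2: float = 0.0
    d: int = 1

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.d not in (1, 2, 3):
            raise ValueError("d must be in {1, 2, 3}")


@dataclass
class JaccardConfig:
    """High-frequency cutoff ``t`` and surrogate sharpness ``epsilon``."""

    t: float = 0.2
    epsilon: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.t < 1:
            raise ValueError("t must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _check_pair(y: ProfileTensor, yhat: ProfileTensor) -> None:
    if y.freqs.shape != yhat.freqs.shape:
        raise ValueError("tensor shapes disagree")
    if not np.array_equal(y.defined, yhat.defined):
        raise ValueError("defined masks disagree")


def predict(x: ProfileTensor, xstar: InputTensor, w: WeightMatrix) -> ProfileTensor:
    """Apply the per-site convex-combination predictor."""
    if len(x) != xstar.values.shape[0]:
        raise ValueError("x and xstar have different numbers of CFs")
    if w.p != xstar.p:
        raise ValueError("alpha width does not match number of sources")
    w.validate()
    yhat = _predict_raw(x.freqs, xstar.values, w.alpha)
    mask = x.defined & xstar.defined
    yhat[~mask] = 0.0
    return ProfileTensor(yhat, mask, x.cf_ids)


def _predict_raw(xf: np.ndarray, xs: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    if alpha.shape[1] == 0:
        return xf.copy()
    mixed = np.einsum("jl,ijkl->ijk", alpha, xs)
    rest = 1.0 - alpha.sum(axis=1)
    return mixed + rest[None, :, None] * xf


def l2_error(y: ProfileTensor, yhat: ProfileTensor) -> float:
    """Mean squared row error, normalized by 149 * n_cf.

    The normalizer counts all positions (the printed estimator's form) even
    though undefined cells contribute zero, so short sequences are
    down-weighted accordingly.
    """
    _check_pair(y, yhat)
    diff = (y.freqs - yhat.freqs)[y.defined]
    return float((diff ** 2).sum() / (N_POSITIONS * len(y)))


def diff_operator(v: np.ndarray, d: int) -> np.ndarray:
    """d-fold successive adjacent differences of a vector."""
    v = np.asarray(v, dtype=float)
    if d < 1:
        raise ValueError("d must be >= 1")
    if d >= v.shape[0]:
        raise ValueError("d must be smaller than the vector length")
    return np.diff(v, n=d)


def penalty(w: WeightMatrix, cfg: PenaltyConfig) -> float:
    """lambda1 * ||alpha||_1 + lambda2 * sum_l ||diff^d(alpha[:, l])||_1."""
    a = w.alpha
    lasso = np.abs(a).sum()
    fused = sum(np.abs(diff_operator(a[:, l], cfg.d)).sum() for l in range(w.p))
    return float(cfg.lambda1 * lasso + cfg.lambda2 * fused)


def _hard_sets(freqs: np.ndarray, t: float) -> np.ndarray:
    return freqs >= t


def jaccard_exact(y: ProfileTensor, yhat: ProfileTensor, t: float = 0.2) -> float:
    """Mean Jaccard similarity between threshold-t amino-acid sets.

    Per defined (CF, position) cell, the observed and predicted sets are the
    amino acids with frequency >= t; the similarity is |A & B| / |A | B|,
    with J(empty, empty) := 1.  The mean is over all defined cells.
    """
    _check_pair(y, yhat)
    if not 0 < t < 1:
        raise ValueError("t must be in (0, 1)")
    A = _hard_sets(y.freqs, t)
    B = _hard_sets(yhat.freqs, t)
    inter = (A & B).sum(axis=2).astype(float)
    union = (A | B).sum(axis=2).astype(float)
    J = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    mask = y.defined
    return float(J[mask].mean())


def smooth_membership(a: np.ndarray, cfg: JaccardConfig) -> np.ndarray:
    """Logistic set-membership smoother: 1 / (1 + exp(-eps * (a - t))).

    Equals 0.5 at a = t and tends to the hard indicator as eps grows.
    """
    return 1.0 / (1.0 + np.exp(-cfg.epsilon * (np.asarray(a) - cfg.t)))


def jaccard_smooth(y: ProfileTensor, yhat: ProfileTensor,
                   cfg: JaccardConfig) -> float:
    """Differentiable Jaccard surrogate.

    Observed memberships stay hard (0/1 at cutoff t); predicted memberships
    are smoothed logistically, and intersection/union become sums of
    elementwise min/max.  Converges to :func:`jaccard_exact` as epsilon
    grows whenever no predicted frequency sits exactly at t.
    """
    _check_pair(y, yhat)
    b = _hard_sets(y.freqs, cfg.t).astype(float)
    f = smooth_membership(yhat.freqs, cfg)
    num = np.minimum(f, b).sum(axis=2)
    den = np.maximum(f, b).sum(axis=2)
    J = (num + _EMPTY_GUARD) / (den + _EMPTY_GUARD)
    return float(J[y.defined].mean())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    maxiter: int = 2000
    gtol: float = 1e-8
    sum_penalty: float = 1e4  # exact-penalty constant for sum_l alpha <= 1


@dataclass
class FitResult:
    weights: WeightMatrix
    objective_value: float
    converged: bool
    n_iterations: int
    message: str
    diagnostics: dict = field(default_factory=dict)


def _smooth_abs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.sqrt(x * x + _ABS_EPS)
    return r, x / r


def _diff_matrix(n: int, d: int) -> np.ndarray:
    D = np.eye(n)
    for _ in range(d):
        D = D[1:] - D[:-1]
    return D


def project_feasible(alpha: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto {a: 0 <= a, a <= 1, sum a <= 1}."""
    a = np.clip(alpha, 0.0, 1.0)
    over = a.sum(axis=1) > 1.0
    for j in np.where(over)[0]:
        # projection onto the probability simplex (sum exactly 1)
        v = np.sort(alpha[j])[::-1]
        cssv = np.cumsum(v) - 1.0
        rho = np.nonzero(v * np.arange(1, len(v) + 1) > cssv)[0][-1]
        theta = cssv[rho] / (rho + 1.0)
        a[j] = np.clip(alpha[j] - theta, 0.0, None)
    return a


class _Problem:
    """Caches the data layout shared by objective and gradient evaluations."""

    def __init__(self, x: ProfileTensor, xstar: InputTensor, y: ProfileTensor,
                 pcfg: PenaltyConfig, jcfg: JaccardConfig | None,
                 objective: str, opts: FitOptions):
        mask = x.defined & xstar.defined
        if not np.array_equal(mask, y.defined):
            raise ValueError("y mask must equal the x/xstar mask")
        self.xf = x.freqs
        self.xs = xstar.values
        self.yf = y.freqs
        self.mask = mask  # (n, 149)
        self.maskf = mask[:, :, None].astype(float)
        self.n = len(x)
        self.p = xstar.p
        self.pcfg = pcfg
        self.jcfg = jcfg
        self.objective = objective
        self.opts = opts
        self.D = _diff_matrix(N_POSITIONS, pcfg.d)
        # dyhat/dalpha[j,l] at cell (i,j,k) is xs[i,j,k,l] - xf[i,j,k]
        self.dx = self.xs - self.xf[:, :, :, None]
        self.norm = N_POSITIONS * self.n
        if objective == "jaccard_smooth":
            self.bhard = (self.yf >= jcfg.t).astype(float)
            self.n_defined = int(mask.sum())

    def loss_grad(self, alpha: np.ndarray) -> tuple[float, np.ndarray]:
        yhat = _predict_raw(self.xf, self.xs, alpha) * self.maskf
        if self.objective == "l2":
            resid = (yhat - self.yf * self.maskf)
            loss = float((resid ** 2).sum() / self.norm)
            grad = 2.0 / self.norm * np.einsum("ijk,ijkl->jl", resid, self.dx)
            return loss, grad
        # smooth Jaccard (maximize => minimize negative)
        cfg = self.jcfg
        f = 1.0 / (1.0 + np.exp(-cfg.epsilon * (yhat - cfg.t)))
        b = self.bhard
        num = np.minimum(f, b).sum(axis=2) + _EMPTY_GUARD
        den = np.maximum(f, b).sum(axis=2) + _EMPTY_GUARD
        J = num / den
        loss = -float(J[self.mask].sum() / self.n_defined)
        # dJ/df = (b * den - (1-b) * num) / den^2 per amino acid
        dJdf = (b * den[:, :, None] - (1.0 - b) * num[:, :, None]) \
            / den[:, :, None] ** 2
        dfdy = cfg.epsilon * f * (1.0 - f)
        sens = -(dJdf * dfdy) * self.maskf / self.n_defined
        grad = np.einsum("ijk,ijkl->jl", sens, self.dx)
        return loss, grad

    def penalties_grad(self, alpha: np.ndarray) -> tuple[float, np.ndarray]:
        pcfg = self.pcfg
        val = 0.0
        grad = np.zeros_like(alpha)
        if pcfg.lambda1 > 0:
            r, dr = _smooth_abs(alpha)
            val += pcfg.lambda1 * r.sum()
            grad += pcfg.lambda1 * dr
        if pcfg.lambda2 > 0:
            Da = self.D @ alpha  # (149-d, p)
            r, dr = _smooth_abs(Da)
            val += pcfg.lambda2 * r.sum()
            grad += pcfg.lambda2 * (self.D.T @ dr)
        s = alpha.sum(axis=1) - 1.0
        over = s > 0
        if over.any():
            val += self.opts.sum_penalty * s[over].sum()
            grad[over] += self.opts.sum_penalty
        return val, grad

    def __call__(self, flat: np.ndarray) -> tuple[float, np.ndarray]:
        alpha = flat.reshape(N_POSITIONS, self.p)
        l, gl = self.loss_grad(alpha)
        v, gv = self.penalties_grad(alpha)
        return l + v, (gl + gv).ravel()


def fit(objective: Literal["l2", "jaccard_smooth"], x: ProfileTensor,
        xstar: InputTensor, y: ProfileTensor,
        pcfg: PenaltyConfig | None = None,
        jcfg: JaccardConfig | None = None,
        init: WeightMatrix | None = None,
        opts: FitOptions | None = None) -> FitResult:
    """Fit the site-specific weights by penalized L-BFGS-B.

    Optimization runs within the [0, 1] box; the per-position sum
    constraint is enforced by an exact linear penalty plus a final
    projection of the solution onto the feasible set.  ``init`` defaults to
    all-zero weights (the baseline model), which is always feasible.
    """
    if objective not in ("l2", "jaccard_smooth"):
        raise ValueError(f"unknown objective {objective!r}")
    pcfg = pcfg or PenaltyConfig()
    opts = opts or FitOptions()
    if objective == "jaccard_smooth":
        jcfg = jcfg or JaccardConfig()
    p = xstar.p
    if p == 0:
        return FitResult(WeightMatrix.zeros(0), 0.0, True, 0, "p=0 (baseline)")
    if init is None:
        init = WeightMatrix.zeros(p)
    init.validate()
    if init.p != p:
        raise ValueError("init width does not match number of sources")

    prob = _Problem(x, xstar, y, pcfg, jcfg, objective, opts)
    res = minimize(prob, init.alpha.ravel(), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, 1.0)] * (N_POSITIONS * p),
                   options={"maxiter": opts.maxiter, "gtol": opts.gtol,
                            "ftol": 1e-12, "maxfun": 10 * opts.maxiter})
    alpha = project_feasible(res.x.reshape(N_POSITIONS, p))
    alpha[np.abs(alpha) < _SNAP] = 0.0
    w = WeightMatrix(alpha)
    w.validate()
    final, _ = prob(alpha.ravel())
    return FitResult(w, float(final), bool(res.success), int(res.nit),
                     str(res.message),
                     diagnostics={"fun": float(res.fun),
                                  "grad_norm": float(np.abs(res.jac).max()),
                                  "nfev": int(res.nfev)})


def penalized_objective(objective: str, x: ProfileTensor, xstar: InputTensor,
                        y: ProfileTensor, w: WeightMatrix,
                        pcfg: PenaltyConfig,
                        jcfg: JaccardConfig | None = None) -> float:
    """Value of the penalized objective at given weights (loss + penalty;
    the sum-constraint exact penalty is included, so feasible points are
    unaffected)."""
    opts = FitOptions()
    prob = _Problem(x, xstar, y, pcfg, jcfg, objective, opts)
    val, _ = prob(w.alpha.ravel())
    return float(val)
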