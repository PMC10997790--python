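"""Proportional-odds logistic regression, from scratch.

Cumulative-logit model for an ordinal outcome with J levels:

    P(Y <= j | x) = logistic(zeta_j - x . beta),   j = 1..J-1

with a single slope vector shared across all cumulative splits (the
parallel-regression assumption). The likelihood is maximized by L-BFGS-B
with an analytic gradient; the cutpoints are reparameterized as
(zeta_1, log-increments) so they are strictly increasing by construction.
No penalty term is used anywhere.

Also implements the Brant (1990) test of the parallel-regression
assumption: the J-1 cumulative binary logistic regressions are fitted
separately, the joint covariance of their stacked slope estimates is
assembled from shared-observation blocks, and a Wald statistic tests
equality of the slopes across splits (omnibus df = (J-2) * p; per-variable
df = J-2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from gosepred.cohort import GOSE_LEVELS, DesignMatrix, EncodingSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PolrFit",
    "BrantResult",
    "PolrError",
    "RankDeficientError",
    "polr_negloglik",
    "polr_fit",
    "polr_fit_reduced",
    "polr_predict",
    "brant_test",
]

N_CATEGORIES = len(GOSE_LEVELS)  # 8


class PolrError(RuntimeError):
    """Model fitting failed."""


class RankDeficientError(PolrError):
    """Design matrix is rank deficient; message names the offending columns."""


@dataclass
class PolrFit:
    """Fitted proportional-odds model.

    ``observed_levels`` records which GOSE levels were present in training;
    cutpoints are defined only between adjacent observed levels, and
    prediction maps back to the full 1-8 scale with zero mass on unobserved
    levels (logged at fit time).
    """

    beta: np.ndarray
    zeta: np.ndarray
    columns: list[str]
    observed_levels: tuple[int, ...]
    n_obs: int
    loglik: float
    converged: bool
    n_iter: int = 0
    encoding_spec: EncodingSpec | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.zeta.size and not np.all(np.diff(self.zeta) > 0):
            raise PolrError("fitted zeta must be strictly increasing")

    def predict_proba(self, design: DesignMatrix | np.ndarray) -> np.ndarray:
        return polr_predict(self, design)

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(self.columns, self.beta.tolist())),
            "zeta": self.zeta.tolist(),
            "observed_levels": list(self.observed_levels),
            "n_obs": self.n_obs,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "encoding_spec": None
            if self.encoding_spec is None
            else self.encoding_spec.to_json(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PolrFit":
        spec = payload.get("encoding_spec")
        return cls(
            beta=np.array(list(payload["beta"].values()), dtype=float),
            zeta=np.array(payload["zeta"], dtype=float),
            columns=list(payload["beta"].keys()),
            observed_levels=tuple(payload["observed_levels"]),
            n_obs=int(payload["n_obs"]),
            loglik=float(payload["loglik"]),
            converged=bool(payload["converged"]),
            n_iter=int(payload.get("n_iter", 0)),
            encoding_spec=None if spec is None else EncodingSpec.from_json(spec),
        )


@dataclass
class BrantResult:
    """Brant test output: omnibus Wald statistic plus per-variable terms."""

    omnibus_stat: float
    omnibus_df: int
    omnibus_p: float
    per_variable: list[tuple[str, float, int, float]] = field(default_factory=list)
    n_splits: int = 0
    excluded_splits: list[int] = field(default_factory=list)


def _as_matrix(design: DesignMatrix | np.ndarray) -> np.ndarray:
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _compress_labels(labels: Sequence[int]) -> tuple[np.ndarray, tuple[int, ...]]:
    """Map raw GOSE labels onto 0..K-1 over the observed levels."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise PolrError("labels are empty")
    if y.min() < 1 or y.max() > N_CATEGORIES:
        raise PolrError("labels must lie in 1..8")
    observed = tuple(sorted(np.unique(y).tolist()))
    index = {lvl: k for k, lvl in enumerate(observed)}
    return np.array([index[v] for v in y]), observed


def _negloglik_grad(
    params: np.ndarray, X: np.ndarray, y0: np.ndarray, k_cats: int
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in the reparameterized space.

    params = (beta_1..beta_p, zeta_1, log d_2, ..., log d_{K-1}) with
    zeta_k = zeta_1 + sum exp(log d). y0 holds 0-based category indices.
    """
    n, p = X.shape
    t = params[p:]
    zeta = np.concatenate([[t[0]], t[0] + np.cumsum(np.exp(t[1:]))])
    eta = X @ params[:p] if p else np.zeros(n)

    # F_k = P(Y <= k+1); pad with 0 and 1 for the outer categories
    F = expit(zeta[None, :] - eta[:, None])  # (n, K-1)
    upper = np.where(y0 < k_cats - 1, F[np.arange(n), np.minimum(y0, k_cats - 2)], 1.0)
    lower = np.where(y0 > 0, F[np.arange(n), np.maximum(y0 - 1, 0)], 0.0)
    prob = upper - lower
    prob = np.clip(prob, 1e-300, None)
    nll = -float(np.sum(np.log(prob)))

    f = F * (1.0 - F)  # logistic density at each cutpoint
    f_upper = np.where(
        y0 < k_cats - 1, f[np.arange(n), np.minimum(y0, k_cats - 2)], 0.0
    )
    f_lower = np.where(y0 > 0, f[np.arange(n), np.maximum(y0 - 1, 0)], 0.0)

    # d nll / d eta_i = (f_upper - f_lower) / prob
    d_eta = (f_upper - f_lower) / prob
    grad_beta = X.T @ d_eta if p else np.empty(0)

    # d nll / d zeta_k: -(1{y=k} - 1{y=k+1}) f_k / prob  (0-based: y0=k-1, y0=k)
    grad_zeta = np.zeros(k_cats - 1)
    contrib = f / prob[:, None]
    for k in range(k_cats - 1):
        grad_zeta[k] = -(
            np.sum(contrib[y0 == k, k]) - np.sum(contrib[y0 == k + 1, k])
        )
    # chain rule to (zeta_1, log-increments)
    grad_t = np.empty(k_cats - 1)
    grad_t[0] = grad_zeta.sum()
    if k_cats > 2:
        tail = np.cumsum(grad_zeta[::-1])[::-1]
        grad_t[1:] = np.exp(t[1:]) * tail[1:]
    return nll, np.concatenate([grad_beta, grad_t])


def polr_negloglik(
    beta: np.ndarray,
    zeta: np.ndarray,
    design: DesignMatrix | np.ndarray,
    labels: Sequence[int],
) -> float:
    """Negative log-likelihood of the proportional-odds model.

    ``zeta`` must be strictly increasing; its length defines the category
    ladder (K-1 cutpoints for categories 1..K), with the outer cutpoints
    at -inf/+inf implicitly. Labels must lie in 1..K.
    """
    X = _as_matrix(design)
    zeta = np.asarray(zeta, dtype=float)
    if zeta.size and not np.all(np.diff(zeta) > 0):
        raise PolrError("zeta must be strictly increasing")
    k_cats = zeta.size + 1
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise PolrError("labels are empty")
    if y.min() < 1 or y.max() > k_cats:
        raise PolrError(f"labels must lie in 1..{k_cats} for {zeta.size} cutpoints")
    y0 = y - 1
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta if beta.size else np.zeros(X.shape[0])
    F = expit(zeta[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((len(eta), 1)), F, np.ones((len(eta), 1))])
    prob = cum[np.arange(len(eta)), y0 + 1] - cum[np.arange(len(eta)), y0]
    prob = np.clip(prob, 1e-300, None)
    return -float(np.sum(np.log(prob)))


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    if X.shape[1] == 0:
        return
    Z = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        bad = []
        # greedy scan: a column that does not raise the rank of its prefix
        for j in range(X.shape[1]):
            prefix = np.column_stack([np.ones(X.shape[0]), X[:, : j + 1]])
            if np.linalg.matrix_rank(prefix) < prefix.shape[1]:
                bad.append(columns[j] if j < len(columns) else f"col{j}")
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def polr_fit(
    design: DesignMatrix | np.ndarray,
    labels: Sequence[int],
    gtol: float = 1e-8,
    maxiter: int = 500,
    encoding_spec: EncodingSpec | None = None,
) -> PolrFit:
    """Maximum-likelihood fit of the proportional-odds model.

    Uses L-BFGS-B with the analytic gradient on (beta, zeta_1,
    log-increments); starting values are beta = 0 and cutpoints at the
    logits of the empirical cumulative proportions. No regularization.

    Raises
    ------
    RankDeficientError
        The (intercept-augmented) design is not full column rank.
    PolrError
        Fewer than two distinct labels.
    """
    X = _as_matrix(design)
    columns = (
        list(design.columns)
        if isinstance(design, DesignMatrix)
        else [f"x{j}" for j in range(X.shape[1])]
    )
    if encoding_spec is None and isinstance(design, DesignMatrix):
        encoding_spec = design.spec
    y0, observed = _compress_labels(labels)
    k_cats = len(observed)
    if k_cats < 2:
        raise PolrError("need at least 2 distinct outcome levels to fit")
    if len(y0) != X.shape[0]:
        raise PolrError("labels and design have different lengths")
    _check_rank(X, columns)
    if set(observed) != set(GOSE_LEVELS):
        logger.info(
            "polr_fit: only levels %s observed; unobserved levels get zero "
            "predicted mass",
            observed,
        )

    p = X.shape[1]
    # optimize on a centered/scaled design for conditioning; the model is
    # affine-equivariant, so estimates transform back exactly
    if p:
        mu = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = (X - mu) / scale
    else:
        mu = np.empty(0)
        scale = np.empty(0)
        Xs = X
    counts = np.bincount(y0, minlength=k_cats)
    cumprop = np.clip(np.cumsum(counts)[:-1] / len(y0), 1e-6, 1 - 1e-6)
    zeta0 = logit(cumprop)
    # enforce strict increase of starting cutpoints
    for k in range(1, zeta0.size):
        if zeta0[k] <= zeta0[k - 1]:
            zeta0[k] = zeta0[k - 1] + 1e-4
    t0 = np.concatenate([[zeta0[0]], np.log(np.diff(zeta0))]) if k_cats > 2 else zeta0[:1]
    x0 = np.concatenate([np.zeros(p), t0])

    res = optimize.minimize(
        _negloglik_grad,
        x0,
        args=(Xs, y0, k_cats),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-13, "gtol": gtol},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) and grad_norm < max(gtol * 1e4, 1e-4) * (
        1 + abs(res.fun)
    )
    # runaway standardized slopes mean the likelihood has no interior
    # maximum (complete or quasi-complete separation): flag, don't succeed
    if p and np.max(np.abs(res.x[:p])) > 10.0:
        logger.warning(
            "polr_fit: slope estimates diverged (max standardized |beta|=%.1f); "
            "likely complete separation",
            float(np.max(np.abs(res.x[:p]))),
        )
        converged = False
    if not converged:
        logger.warning(
            "polr_fit did not converge: %s (max|grad|=%.3g, possible separation)",
            res.message,
            grad_norm,
        )
    t = res.x[p:]
    zeta_s = np.concatenate([[t[0]], t[0] + np.cumsum(np.exp(t[1:]))])
    beta = res.x[:p] / scale if p else res.x[:p]
    zeta = zeta_s + (mu @ beta if p else 0.0)
    return PolrFit(
        beta=beta,
        zeta=zeta,
        columns=columns,
        observed_levels=observed,
        n_obs=X.shape[0],
        loglik=-float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
        encoding_spec=encoding_spec,
    )


def polr_fit_reduced(
    design: DesignMatrix | np.ndarray,
    labels: Sequence[int],
    encoding_spec: EncodingSpec | None = None,
    **options,
) -> PolrFit:
    """Fit after dropping degenerate design columns, refilling zero slopes.

    Small subsamples routinely miss a dummy level entirely, leaving a
    constant (or collinear) column. Those columns are removed for the fit
    and re-enter the returned coefficient vector as exact zeros, so the
    fit still predicts on the full design. Used by the undersampling
    ensemble and the sample-size simulation.
    """
    X = _as_matrix(design)
    columns = (
        list(design.columns)
        if isinstance(design, DesignMatrix)
        else [f"x{j}" for j in range(X.shape[1])]
    )
    if encoding_spec is None and isinstance(design, DesignMatrix):
        encoding_spec = design.spec
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    while keep:
        Z = np.column_stack([np.ones(X.shape[0]), X[:, keep]])
        if np.linalg.matrix_rank(Z) == Z.shape[1]:
            break
        keep.pop()
    if len(keep) < X.shape[1]:
        dropped = [columns[j] for j in range(X.shape[1]) if j not in keep]
        logger.debug("polr_fit_reduced: dropped degenerate columns %s", dropped)
    fit = polr_fit(X[:, keep], labels, encoding_spec=encoding_spec, **options)
    beta_full = np.zeros(X.shape[1])
    beta_full[keep] = fit.beta
    fit.beta = beta_full
    fit.columns = columns
    return fit


def polr_predict(fit: PolrFit, design: DesignMatrix | np.ndarray) -> np.ndarray:
    """Per-patient probability vectors over the full 8 GOSE categories.

    Levels unobserved in training receive probability exactly 0; each row
    is non-negative and sums to 1 within 1e-12.
    """
    X = _as_matrix(design)
    if X.shape[1] != fit.beta.size:
        raise PolrError(
            f"design has {X.shape[1]} columns but fit expects {fit.beta.size}"
        )
    eta = X @ fit.beta if fit.beta.size else np.zeros(X.shape[0])
    F = expit(fit.zeta[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((len(eta), 1)), F, np.ones((len(eta), 1))])
    probs_obs = np.diff(cum, axis=1)
    probs_obs = np.clip(probs_obs, 0.0, None)
    out = np.zeros((X.shape[0], N_CATEGORIES))
    for k, lvl in enumerate(fit.observed_levels):
        out[:, lvl - 1] = probs_obs[:, k]
    out /= out.sum(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Brant test


def _logistic_irls(
    Z: np.ndarray, t: np.ndarray, maxiter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Newton-Raphson for binary logistic regression (no penalty)."""
    coef = np.zeros(Z.shape[1])
    for _ in range(maxiter):
        p = expit(Z @ coef)
        W = p * (1.0 - p)
        grad = Z.T @ (t - p)
        H = (Z * W[:, None]).T @ Z
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(Z.shape[1]), grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise PolrError("singular Hessian in cumulative logistic fit") from exc
        coef = coef + step
        if np.max(np.abs(step)) < tol:
            break
    return coef


def brant_test(
    design: DesignMatrix | np.ndarray,
    labels: Sequence[int],
    on_degenerate_split: str = "warn",
) -> BrantResult:
    """Brant (1990) test of the parallel-regression assumption.

    Fits the J-1 binary logistic regressions I(y > level_j), assembles the
    joint covariance of the stacked slope vectors from shared-observation
    blocks, and computes the omnibus Wald statistic for equality of slopes
    across splits (df = (J-2) * p) plus per-variable statistics (df = J-2).

    Splits where one class is absent are excluded with a warning (df
    adjusted) when ``on_degenerate_split="warn"``, or raise when "error".
    """
    X = _as_matrix(design)
    columns = (
        list(design.columns)
        if isinstance(design, DesignMatrix)
        else [f"x{j}" for j in range(X.shape[1])]
    )
    p = X.shape[1]
    if p == 0:
        raise PolrError("Brant test requires at least one covariate")
    y = np.asarray(labels, dtype=int)
    _check_rank(X, columns)
    levels = np.sort(np.unique(y))
    splits = []
    excluded = []
    for j, lvl in enumerate(levels[:-1]):
        t = (y > lvl).astype(float)
        if t.min() == t.max():
            if on_degenerate_split == "error":
                raise PolrError(f"cumulative split y>{lvl} has a single class")
            excluded.append(int(lvl))
            warnings.warn(
                f"Brant: split y>{lvl} has one class; excluded, df adjusted",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        splits.append(t)
    m = len(splits)
    if m < 2:
        raise PolrError("Brant test needs >= 2 usable cumulative splits")

    Z = np.column_stack([np.ones(X.shape[0]), X])
    coefs = []
    pis = []
    for t in splits:
        coef = _logistic_irls(Z, t)
        coefs.append(coef)
        pis.append(expit(Z @ coef))

    # joint covariance of the stacked slope estimates, Brant (1990)
    XtWX_inv = []
    for j in range(m):
        W = pis[j] * (1.0 - pis[j])
        XtWX_inv.append(np.linalg.inv((Z * W[:, None]).T @ Z))
    V = np.zeros((m * p, m * p))
    for j in range(m):
        for l in range(j, m):
            if j == l:
                block = XtWX_inv[j]
            else:
                # for j < l: pi_l <= pi_j, w = pi_l - pi_j * pi_l
                W_jl = pis[l] - pis[j] * pis[l]
                middle = (Z * W_jl[:, None]).T @ Z
                block = XtWX_inv[j] @ middle @ XtWX_inv[l]
            slope_block = block[1:, 1:]
            V[j * p : (j + 1) * p, l * p : (l + 1) * p] = slope_block
            V[l * p : (l + 1) * p, j * p : (j + 1) * p] = slope_block.T

    beta_stack = np.concatenate([c[1:] for c in coefs])

    # contrasts beta_1 - beta_j, j = 2..m
    D = np.zeros(((m - 1) * p, m * p))
    for j in range(1, m):
        D[(j - 1) * p : j * p, 0:p] = np.eye(p)
        D[(j - 1) * p : j * p, j * p : (j + 1) * p] = -np.eye(p)
    diff = D @ beta_stack
    cov = D @ V @ D.T
    stat = float(diff @ np.linalg.solve(cov, diff))
    df = (m - 1) * p
    pval = float(stats.chi2.sf(stat, df))

    per_variable = []
    for k in range(p):
        idx = np.arange(m) * p + k
        bk = beta_stack[idx]
        Vk = V[np.ix_(idx, idx)]
        Dk = np.zeros((m - 1, m))
        Dk[:, 0] = 1.0
        Dk[np.arange(m - 1), np.arange(1, m)] = -1.0
        dk = Dk @ bk
        ck = Dk @ Vk @ Dk.T
        sk = float(dk @ np.linalg.solve(ck, dk))
        per_variable.append((columns[k], sk, m - 1, float(stats.chi2.sf(sk, m - 1))))

    return BrantResult(
        omnibus_stat=stat,
        omnibus_df=df,
        omnibus_p=pval,
        per_variable=per_variable,
        n_splits=m,
        excluded_splits=excluded,
    )
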