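"""Single-response partial least squares regression by NIPALS.

PLS1 projects a collinear, possibly p > n predictor block X onto a few
latent components t_a = X w_a chosen to covary maximally with the response,
deflating X after each component. The quantities screening needs are:

* R²Y(cum) — fraction of (scaled) response variance explained in training;
* Q²(cum)  — 1 − PRESS/TSS from K-fold cross-validation, the predictive
  counterpart (Q² > 0.5 is the conventional "good predictivity" bar);
* VIP_j    — variable importance in the projection, whose squares average
  to one over predictors, so VIP > 1 flags above-average influence;
* standardized regression coefficients b = W (PᵀW)⁻¹ q mapping autoscaled
  X to the autoscaled response.

A response-permutation test guards against overfitting: the response is
shuffled many times, the model refit, and the real R²/Q² compared with the
permuted distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, FitError

SCALINGS = ("autoscale", "center", "none")
_EPS = 1e-12


def _preprocess(X, y, scaling, feature_names):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if scaling not in SCALINGS:
        raise ConfigError(f"scaling must be one of {SCALINGS}")
    if scaling == "none":
        x_mean = np.zeros(p)
        x_sd = np.ones(p)
        y_mean, y_sd = 0.0, 1.0
    else:
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        if scaling == "autoscale":
            x_sd = X.std(axis=0, ddof=1)
            zero = np.flatnonzero(x_sd <= 0)
            if zero.size:
                names = ([feature_names[j] for j in zero]
                         if feature_names is not None else list(zero))
                raise FitError(
                    f"zero-variance predictor column(s) under autoscaling: {names}")
            y_sd = y.std(ddof=1)
            if y_sd <= 0:
                raise FitError("response has zero variance")
        else:
            x_sd = np.ones(p)
            y_sd = 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    return Xs, ys, x_mean, x_sd, y_mean, y_sd


@dataclass
class PLSModel:
    """A fitted PLS1 model with its preprocessing frozen in."""

    n_components: int
    x_weights: np.ndarray        # p × A
    x_loadings: np.ndarray       # p × A
    y_loadings: np.ndarray       # A
    scores: np.ndarray           # n × A
    r2y_by_component: np.ndarray
    r2y_cum: float
    coefficients: np.ndarray     # standardized (scaled-metric) b
    vip: np.ndarray
    scaling: str
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    feature_names: list[str] | None = None
    q2_cum: float | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X_new, dtype=float) - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Xs @ self.coefficients)


def _nipals(Xs: np.ndarray, ys: np.ndarray, A: int,
            tol: float = 1e-12, max_iter: int = 500):
    """Core NIPALS deflation loop on preprocessed data."""
    n, p = Xs.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros(A)
    T = np.zeros((n, A))
    Xr, yr = Xs.copy(), ys.copy()
    a_used = 0
    for a in range(A):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < _EPS:
            break  # residual X carries no covariance with the response
        w /= norm
        # single-response NIPALS converges in one pass; iterate defensively
        for _ in range(max_iter):
            t = Xr @ w
            tt = t @ t
            if tt < _EPS:
                break
            w_new = Xr.T @ yr
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xr @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_a = Xr.T @ t / tt
        q_a = yr @ t / tt
        Xr = Xr - np.outer(t, p_a)
        yr = yr - q_a * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t
        a_used += 1
    return W[:, :a_used], P[:, :a_used], Q[:a_used], T[:, :a_used], a_used


def _coefficients(W, P, Q):
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    M = P.T @ W
    try:
        inner = np.linalg.solve(M, Q)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular P'W matrix; reduce n_components") from exc
    return W @ inner


def _vip(W, T, Q, n_features):
    ssy = Q ** 2 * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total <= 0:
        raise FitError("model explains no response variance; VIP undefined")
    wnorm2 = (W / np.maximum(np.linalg.norm(W, axis=0), _EPS)) ** 2
    return np.sqrt(n_features * (wnorm2 @ ssy) / total)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scaling: str = "autoscale",
    feature_names: list[str] | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ConfigError("X and y have different numbers of samples")
    if n < 3:
        raise ConfigError("need at least 3 samples to fit")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ConfigError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    Xs, ys, x_mean, x_sd, y_mean, y_sd = _preprocess(X, y, scaling, feature_names)
    tss = ys @ ys
    if tss <= 0:
        raise FitError("response has zero variance")
    W, P, Q, T, a_used = _nipals(Xs, ys, n_components)
    if a_used == 0:
        raise FitError("no usable component: X carries no response covariance")
    r2_by = Q ** 2 * np.einsum("ia,ia->a", T, T) / tss
    coef = _coefficients(W, P, Q)
    vip = _vip(W, T, Q, p)
    return PLSModel(
        n_components=a_used,
        x_weights=W, x_loadings=P, y_loadings=Q, scores=T,
        r2y_by_component=r2_by, r2y_cum=float(r2_by.sum()),
        coefficients=coef, vip=vip,
        scaling=scaling, x_mean=x_mean, x_sd=x_sd,
        y_mean=y_mean, y_sd=y_sd,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """Recompute VIP from the stored weights/scores (mean of VIP² is 1)."""
    return _vip(model.x_weights, model.scores, model.y_loadings,
                model.x_weights.shape[0])


def standardized_coefficients(model: PLSModel) -> np.ndarray:
    """Regression coefficients on the autoscaled X / autoscaled y metric."""
    return _coefficients(model.x_weights, model.x_loadings, model.y_loadings)


def _fold_assignment(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def cross_validate_q2(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    folds: int = 7,
    seed: int = 0,
    scaling: str = "autoscale",
) -> np.ndarray:
    """Q²(A) = 1 − PRESS(A)/TSS for A = 1..max_components.

    Preprocessing is re-estimated inside each training fold; PRESS uses the
    held-out predictions and TSS the deviation from the full-sample mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if not (2 <= folds <= n):
        raise ConfigError(f"folds must lie in [2, n]={n}")
    assignment = _fold_assignment(n, folds, seed)
    press = np.zeros(max_components)
    for test_idx in assignment:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if train_idx.size < 2:
            raise FitError("training fold has fewer than 2 samples")
        Xs, ys, x_mean, x_sd, y_mean, y_sd = _preprocess(
            X[train_idx], y[train_idx], scaling, None)
        A_fit = min(max_components, train_idx.size - 1, X.shape[1])
        W, P, Q, T, a_used = _nipals(Xs, ys, A_fit)
        Xt = (X[test_idx] - x_mean) / x_sd
        for A in range(1, max_components + 1):
            a = min(A, a_used)
            if a == 0:
                pred = np.full(test_idx.size, y_mean)
            else:
                b = _coefficients(W[:, :a], P[:, :a], Q[:a])
                pred = y_mean + y_sd * (Xt @ b)
            press[A - 1] += np.sum((y[test_idx] - pred) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    if tss <= 0:
        raise FitError("response has zero variance")
    return 1.0 - press / tss


def select_components(q2_by_A: np.ndarray, rule: str = "max_q2") -> int:
    """Pick the working number of latent components from the Q² profile."""
    q2 = np.asarray(q2_by_A, dtype=float)
    if q2.size == 0:
        raise ConfigError("empty Q² profile")
    if np.all(q2 < 0):
        warnings.warn("no predictive component (all Q² < 0); using A=1")
        return 1
    if rule == "max_q2":
        best = q2.max()
        return int(np.flatnonzero(q2 >= best - 0.01)[0]) + 1
    if rule == "gain_threshold":
        A = 1
        while A < q2.size and q2[A] - q2[A - 1] > 0.05:
            A += 1
        return A
    raise ConfigError(f"unknown selection rule {rule!r}")


@dataclass
class PermutationResult:
    """Y-permutation validation record for one fitted model."""

    n_permutations: int
    permuted_r2: np.ndarray
    permuted_q2: np.ndarray
    permuted_correlations: np.ndarray
    observed_r2: float
    observed_q2: float
    r2_intercept: float
    q2_intercept: float
    empirical_p_q2: float


def _intercept(cors, stats, obs_cor, obs_stat):
    # OLS of statistic on |correlation|, the observed model included at |r|=1
    x = np.concatenate([cors, [obs_cor]])
    s = np.concatenate([stats, [obs_stat]])
    slope, intercept = np.polyfit(x, s, 1)
    return float(intercept)


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_permutations: int = 199,
    seed: int = 0,
    folds: int = 7,
    scaling: str = "autoscale",
) -> PermutationResult:
    """Refit after shuffling the response ``n_permutations`` times.

    Records the permuted R²/Q² distributions, the chance-line intercepts
    from regressing each statistic on |cor(y_perm, y)|, and the empirical
    one-sided p-value of the observed Q².
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_permutations < 20:
        raise ConfigError("need at least 20 permutations")
    if np.ptp(y) == 0:
        raise FitError("constant response cannot be permuted meaningfully")
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2 ** 31 - 1))

    def _stats(y_vec):
        model = fit_pls(X, y_vec, n_components, scaling=scaling)
        q2 = cross_validate_q2(X, y_vec, n_components, folds=folds,
                               seed=cv_seed, scaling=scaling)[n_components - 1]
        return model.r2y_cum, float(q2)

    obs_r2, obs_q2 = _stats(y)
    perm_r2 = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    cors = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        cors[i] = abs(np.corrcoef(y_perm, y)[0, 1])
        perm_r2[i], perm_q2[i] = _stats(y_perm)
    p = (1 + np.sum(perm_q2 >= obs_q2)) / (n_permutations + 1)
    return PermutationResult(
        n_permutations=n_permutations,
        permuted_r2=perm_r2, permuted_q2=perm_q2,
        permuted_correlations=cors,
        observed_r2=float(obs_r2), observed_q2=float(obs_q2),
        r2_intercept=_intercept(cors, perm_r2, 1.0, obs_r2),
        q2_intercept=_intercept(cors, perm_q2, 1.0, obs_q2),
        empirical_p_q2=float(p),
    )
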