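"""Elastic-net penalized logistic regression.

The signature models minimize

    -(1/n) * binomial log-likelihood
        + lambda * sum_j [ alpha*|beta_j| + (1 - alpha)/2 * beta_j**2 ]

with an unpenalized intercept, predictors standardized internally to
zero mean and unit population SD, and coefficients reported back on the
input scale. ``alpha`` mixes lasso (exact zeros) and ridge; ``lambda``
is the overall penalty strength, selected as the median of the
deviance-minimizing values over repeated stratified internal
cross-validation.

The solver is iteratively reweighted least squares with cyclic
coordinate descent on the penalized weighted quadratic approximation,
warm-started along a decreasing lambda path.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, ClassifierMixin

from ._folds import stratified_assign
from .core import ElasticNetModel, ValidationError

#: coefficients with absolute value below this (standardized scale) are
#: reported as exact zeros
ZERO_TOL = 1e-8

#: floor on alpha in the lambda_max formula, keeping it finite near ridge
ALPHA_FLOOR = 1e-3

#: minimum IRLS working weight, guarding against degenerate curvature
MIN_WEIGHT = 1e-5


@njit(cache=True)
def _fit_at_lambda(Xs, y, alpha, lam, beta, beta0, tol, max_irls, max_cd):
    """IRLS + coordinate-descent solve at one lambda; beta updated in place.

    Each IRLS step forms the weighted Gram matrix once ("covariance
    updates"), making every coordinate update O(p) instead of O(n).
    """
    n, p = Xs.shape
    thr = lam * alpha
    ridge = lam * (1.0 - alpha)
    eta = beta0 + Xs @ beta
    for _ in range(max_irls):
        w = np.empty(n)
        wz = np.empty(n)
        for i in range(n):
            e = eta[i]
            if e > 30.0:
                e = 30.0
            elif e < -30.0:
                e = -30.0
            prob = 1.0 / (1.0 + np.exp(-e))
            wi = prob * (1.0 - prob)
            if wi < MIN_WEIGHT:
                wi = MIN_WEIGHT
            w[i] = wi
            # weighted working response: w*z with z = eta + (y - p)/w
            wz[i] = wi * eta[i] + (y[i] - prob)
        q = (Xs.T @ wz) / n  # (1/n) X'Wz
        gw = (Xs.T @ w) / n  # (1/n) X'w
        q0 = wz.sum() / n
        s0 = w.sum() / n
        G = (Xs.T @ (Xs * w.reshape(n, 1))) / n  # (1/n) X'WX
        Gb = G @ beta

        outer_change = 0.0
        it = 0
        while it < max_cd:
            dmax = 0.0
            for j in range(p):
                bj = beta[j]
                rho = q[j] - beta0 * gw[j] - Gb[j] + G[j, j] * bj
                if rho > thr:
                    bnew = (rho - thr) / (G[j, j] + ridge)
                elif rho < -thr:
                    bnew = (rho + thr) / (G[j, j] + ridge)
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    beta[j] = bnew
                    for k in range(p):
                        Gb[k] += G[k, j] * d
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            gb = 0.0
            for j in range(p):
                gb += gw[j] * beta[j]
            b0new = (q0 - gb) / s0
            d0 = b0new - beta0
            beta0 = b0new
            if abs(d0) > dmax:
                dmax = abs(d0)
            it += 1
            if dmax > outer_change:
                outer_change = dmax
            if dmax < tol:
                break
        eta = beta0 + Xs @ beta
        if outer_change < tol:
            break
    return beta0


def _standardize(X):
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD (divisor n)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-dimensional")
    if not np.isfinite(X).all():
        raise ValidationError("X contains non-finite values")
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("X and y length mismatch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(
            f"y must contain exactly two classes, found {classes.size}"
        )
    y01 = (y == classes[1]).astype(float)
    return X, y01, classes


def lambda_max(X, y, alpha: float) -> float:
    """Smallest lambda at which all penalized coefficients are zero.

    Computed on the standardized predictors:
    max_j |<x_j_std, y - ybar>| / (n * max(alpha, 1e-3)).
    """
    X, y01, _ = _validate_xy(X, y)
    Xs, _, _ = _standardize(X)
    n = Xs.shape[0]
    score = np.abs(Xs.T @ (y01 - y01.mean())) / n
    return float(score.max() / max(alpha, ALPHA_FLOOR))


def lambda_path(
    X, y, alpha: float, n_lambdas: int = 100, min_ratio: float | None = None
) -> np.ndarray:
    """Log-spaced decreasing lambda path from lambda_max."""
    lmax = lambda_max(X, y, alpha)
    if min_ratio is None:
        n, p = np.asarray(X).shape
        min_ratio = 1e-4 if n > p else 1e-2
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


class ElasticNetLogit(BaseEstimator, ClassifierMixin):
    """Logistic regression with the elastic-net penalty at fixed lambda.

    Parameters
    ----------
    alpha : mixing parameter in (0, 1]; 1 is pure lasso, near 0 near ridge.
    lam : penalty strength (>= 0); 0 gives the unpenalized MLE.
    tol : convergence tolerance on coefficient updates (standardized scale).
    max_iter : maximum IRLS iterations.

    Attributes
    ----------
    coef_ : (1, p) coefficients on the input scale.
    intercept_ : (1,) intercept on the input scale.
    classes_ : the two class labels; the larger is the positive class.
    n_iter_ : IRLS iterations used (upper bound max_iter).
    """

    def __init__(self, alpha: float = 0.05, lam: float = 0.0, tol: float = 1e-9,
                 max_iter: int = 200):
        self.alpha = alpha
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, warm_start: np.ndarray | None = None):
        if self.lam < 0:
            raise ValidationError(f"lam={self.lam} negative")
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1]")
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y01, classes = _validate_xy(X, y)
        if X.shape[0] < 2:
            raise ValidationError("need at least 2 samples")
        Xs, mean, sd = _standardize(X)
        beta = np.zeros(X.shape[1]) if warm_start is None else warm_start.copy()
        ybar = y01.mean()
        beta0 = float(np.log(ybar / (1 - ybar)))
        beta0 = _fit_at_lambda(
            Xs, y01, float(self.alpha), float(self.lam), beta, beta0,
            float(self.tol), int(self.max_iter), 1000,
        )
        beta[np.abs(beta) < ZERO_TOL] = 0.0
        self.classes_ = classes
        self.scale_mean_ = mean
        self.scale_sd_ = sd
        self.coef_std_ = beta
        coef = beta / sd
        self.coef_ = coef[None, :]
        self.intercept_ = np.array([beta0 - float(coef @ mean)])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_[0] + X @ self.coef_[0]

    def predict_proba(self, X) -> np.ndarray:
        from scipy.special import expit

        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def to_model(self, genes) -> ElasticNetModel:
        genes = tuple(genes)
        if len(genes) != self.n_features_in_:
            raise ValidationError("gene list length differs from fitted features")
        return ElasticNetModel(
            genes=genes,
            alpha=float(self.alpha),
            lam=float(self.lam),
            intercept=float(self.intercept_[0]),
            coef=tuple(self.coef_[0]),
            mean=tuple(self.scale_mean_),
            sd=tuple(self.scale_sd_),
        )


def enet_path(X, y, alpha: float, lambdas: np.ndarray, tol: float = 1e-6,
              max_iter: int = 12, dev_stop: float = 0.995):
    """Warm-started fits along a decreasing lambda path.

    Returns ``(intercepts, coefs)`` with coefs of shape
    (len(lambdas), p) on the *input* scale. The path stops early once
    the in-sample deviance explained exceeds ``dev_stop`` of the null
    deviance (the data are then effectively separated and smaller
    lambdas only inflate coefficients); remaining entries repeat the
    last computed solution.
    """
    X, y01, _ = _validate_xy(X, y)
    Xs, mean, sd = _standardize(X)
    n, p = Xs.shape
    beta = np.zeros(p)
    ybar = y01.mean()
    beta0 = float(np.log(ybar / (1 - ybar)))
    null_dev = binomial_deviance(y01, np.full(n, ybar))
    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), p))
    for k, lam in enumerate(lambdas):
        beta0 = _fit_at_lambda(
            Xs, y01, float(alpha), float(lam), beta, beta0, tol, max_iter, 200
        )
        b = beta.copy()
        b[np.abs(b) < ZERO_TOL] = 0.0
        coefs[k] = b / sd
        intercepts[k] = beta0 - coefs[k] @ mean
        eta = np.clip(beta0 + Xs @ beta, -30, 30)
        dev = binomial_deviance(y01, 1 / (1 + np.exp(-eta)))
        if null_dev > 0 and 1 - dev / null_dev > dev_stop:
            intercepts[k + 1:] = intercepts[k]
            coefs[k + 1:] = coefs[k]
            break
    return intercepts, coefs


def binomial_deviance(y, prob) -> float:
    """Mean binomial deviance, -2/n * log-likelihood."""
    prob = np.clip(np.asarray(prob, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


class ElasticNetLogitCV(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic regression with internal lambda selection.

    For each of ``n_repeats`` repeats, samples are split into
    ``n_folds`` stratified folds; the out-of-fold mean binomial deviance
    is computed along a shared lambda path and a lambda recorded:
    the deviance-minimizing one (``lambda_rule="min"``) or the largest
    lambda within one standard error of the minimum
    (``lambda_rule="1se"``, the conservative choice favoured for
    feature-selection runs). The final lambda is the median over
    repeats, and the model is refitted at it on the full data.

    Attributes (after fit): ``lambda_``, ``lambdas_`` (the path),
    ``lambda_per_repeat_``, plus the fitted-model attributes of
    :class:`ElasticNetLogit`.
    """

    def __init__(self, alpha: float = 0.05, n_folds: int = 6,
                 n_repeats: int = 100, n_lambdas: int = 100,
                 min_ratio: float | None = None, lambda_rule: str = "min",
                 random_state=None):
        self.alpha = alpha
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.n_lambdas = n_lambdas
        self.min_ratio = min_ratio
        self.lambda_rule = lambda_rule
        self.random_state = random_state

    def fit(self, X, y):
        if self.lambda_rule not in ("min", "1se"):
            raise ValidationError(f"unknown lambda_rule {self.lambda_rule!r}")
        Xarr, y01, classes = _validate_xy(X, y)
        counts = np.bincount(y01.astype(int))
        if counts.min() < 2:
            raise ValidationError(
                "minority class has fewer than 2 samples; every internal "
                "split would leave a single-class fold"
            )
        lambdas = lambda_path(Xarr, y01, self.alpha, self.n_lambdas, self.min_ratio)
        rng = np.random.default_rng(self.random_state)
        selected = np.empty(self.n_repeats)
        for rep in range(self.n_repeats):
            folds = stratified_assign(y01, self.n_folds, rng)
            fold_dev = []
            for f in np.unique(folds):
                test = folds == f
                train = ~test
                if len(np.unique(y01[train])) < 2 or not test.any():
                    continue
                ints, coefs = enet_path(Xarr[train], y01[train], self.alpha, lambdas)
                eta = ints[None, :] + Xarr[test] @ coefs.T
                prob = np.clip(1 / (1 + np.exp(-np.clip(eta, -30, 30))),
                               1e-12, 1 - 1e-12)
                yt = y01[test][:, None]
                fold_dev.append(
                    (-2.0 * (yt * np.log(prob)
                             + (1 - yt) * np.log(1 - prob))).mean(axis=0)
                )
            fold_dev = np.asarray(fold_dev)
            mean_dev = fold_dev.mean(axis=0)
            k_min = int(np.argmin(mean_dev))
            if self.lambda_rule == "1se" and fold_dev.shape[0] > 1:
                se = fold_dev[:, k_min].std(ddof=1) / np.sqrt(fold_dev.shape[0])
                k = int(np.argmax(mean_dev <= mean_dev[k_min] + se))
            else:
                k = k_min
            selected[rep] = lambdas[k]
        self.lambdas_ = lambdas
        self.lambda_per_repeat_ = selected
        self.lambda_ = float(np.median(selected))
        warm_path = np.append(lambdas[lambdas > self.lambda_], self.lambda_)
        _, warm_coefs = enet_path(Xarr, y01, self.alpha, warm_path)
        sd = Xarr.std(axis=0)
        warm = warm_coefs[-1] * np.where(sd > 0, sd, 1.0)
        final = ElasticNetLogit(alpha=self.alpha, lam=self.lambda_).fit(
            X, y, warm_start=warm)
        for attr in ("coef_", "intercept_", "coef_std_", "scale_mean_",
                     "scale_sd_", "classes_", "n_features_in_"):
            setattr(self, attr, getattr(final, attr))
        if hasattr(final, "feature_names_in_"):
            self.feature_names_in_ = final.feature_names_in_
        self._final = final
        return self

    def decision_function(self, X):
        return self._final.decision_function(X)

    def predict_proba(self, X):
        return self._final.predict_proba(X)

    def predict(self, X):
        return self._final.predict(X)

    def to_model(self, genes) -> ElasticNetModel:
        return self._final.to_model(genes)


# ---------------------------------------------------------------------------
# functional wrappers and utilities
# ---------------------------------------------------------------------------


def fit_enet(X, y, alpha: float, lam: float, genes=None) -> ElasticNetModel:
    """Fit at fixed (alpha, lambda); thin wrapper over ElasticNetLogit."""
    est = ElasticNetLogit(alpha=alpha, lam=lam).fit(X, y)
    if genes is None:
        genes = getattr(
            est, "feature_names_in_",
            [f"x{j}" for j in range(est.n_features_in_)],
        )
    return est.to_model(genes)


def select_lambda(X, y, alpha: float, inner_folds: int = 6,
                  inner_repeats: int = 100, random_state=None):
    """Repeated-CV lambda selection; returns the fitted CV estimator."""
    return ElasticNetLogitCV(
        alpha=alpha, n_folds=inner_folds, n_repeats=inner_repeats,
        random_state=random_state,
    ).fit(X, y)


def predict_probability(model: ElasticNetModel, X) -> np.ndarray:
    """Probability of the positive class under a fitted model.

    When X is a DataFrame its columns must match the model's genes.
    """
    if hasattr(X, "columns"):
        cols = list(X.columns)
        if cols != list(model.genes):
            missing = set(model.genes) - set(cols)
            if missing:
                raise ValidationError(f"missing gene columns: {sorted(missing)}")
            X = X.loc[:, list(model.genes)]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.genes):
        raise ValidationError(
            f"expected {len(model.genes)} gene columns, got {X.shape[1]}"
        )
    return model.predict_probability(X)


def median_model(ensemble: list[ElasticNetModel]) -> ElasticNetModel:
    """Coefficient-wise (and intercept) median of an ensemble.

    Even-sized ensembles use the mean of the two middle values, so a
    zero-heavy ensemble can still yield a non-zero median.
    """
    if not ensemble:
        raise ValidationError("empty model ensemble")
    genes = ensemble[0].genes
    alpha = ensemble[0].alpha
    for m in ensemble[1:]:
        if m.genes != genes:
            raise ValidationError("inconsistent gene order across ensemble")
        if m.alpha != alpha:
            raise ValidationError("inconsistent alpha across ensemble")
    coefs = np.array([m.coef for m in ensemble])
    return ElasticNetModel(
        genes=genes,
        alpha=alpha,
        lam=float(np.median([m.lam for m in ensemble])),
        intercept=float(np.median([m.intercept for m in ensemble])),
        coef=tuple(np.median(coefs, axis=0)),
    )


def kkt_violation(model: ElasticNetModel, X, y) -> float:
    """Maximum KKT residual of a fitted model (standardized scale).

    At the optimum, for zero coefficients |gradient_j| <= lambda*alpha;
    for non-zero coefficients the subgradient equation holds exactly.
    Returns the largest violation over coefficients and intercept.
    """
    X, y01, _ = _validate_xy(X, y)
    Xs, mean, sd = _standardize(X)
    n = Xs.shape[0]
    beta_std = np.asarray(model.coef) * sd
    beta0_std = model.intercept + np.asarray(model.coef) @ mean
    eta = beta0_std + Xs @ beta_std
    prob = 1 / (1 + np.exp(-np.clip(eta, -30, 30)))
    grad = -(Xs.T @ (y01 - prob)) / n
    lam, alpha = model.lam, model.alpha
    viol = np.abs(grad[beta_std == 0]) - lam * alpha
    v_zero = float(viol.max(initial=0.0))
    nz = beta_std != 0
    v_nz = float(
        np.abs(grad[nz] + lam * alpha * np.sign(beta_std[nz])
               + lam * (1 - alpha) * beta_std[nz]).max(initial=0.0)
    )
    v_int = float(abs(np.mean(y01 - prob)))
    return max(v_zero, v_nz, v_int)
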