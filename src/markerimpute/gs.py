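"""Genomic-selection models and cross-validated accuracy.

* :class:`RidgeBLUP` — the mixed model y = 1*mu + X u + e with i.i.d. normal
  marker effects, variance components by spectral REML (a one-dimensional
  search over the ratio lambda = sigma2_e / sigma2_u), effects from the ridge
  solution at the REML ratio. Equivalent to GBLUP with kinship X Xc^T.
* :class:`BayesianLasso` — Park & Casella's Gibbs sampler: double-exponential
  shrinkage priors on marker effects via the scale-mixture-of-normals
  augmentation, a Gamma hyperprior on lambda^2, reproducible under a seed.
* :func:`cross_validate` — k-fold accuracy: Pearson correlation between
  breeding-value phenotypes and the genomic estimated breeding values of each
  held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold


@dataclass
class CVResult:
    fold_assignment: np.ndarray  # 1..n_folds per individual
    gebv: np.ndarray  # predicted out-of-fold
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    model: str
    seed: int


class RidgeBLUP(RegressorMixin, BaseEstimator):
    """RR-BLUP: ridge regression of phenotypes on centred markers.

    Parameters
    ----------
    ratio : float, optional
        Fixed lambda = sigma2_e / sigma2_u. When None (default) the ratio is
        estimated by REML on the spectral decomposition of the marker kinship.
    """

    def __init__(self, ratio: Optional[float] = None):
        self.ratio = ratio

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        m, n = X.shape
        if m != y.size:
            raise ValueError("X and y have inconsistent numbers of individuals")
        if m < 3:
            raise ValueError("need at least 3 individuals")
        if np.isnan(X).any():
            raise ValueError("X must be complete (impute first)")
        self.col_means_ = X.mean(axis=0)
        Xc = X - self.col_means_
        K = Xc @ Xc.T
        d, U = np.linalg.eigh(K)
        d = np.maximum(d, 0.0)
        yt = U.T @ y
        xt = U.T @ np.ones(m)

        def profile(delta: float):
            w = 1.0 / (d + delta)
            xwx = float((xt * w * xt).sum())
            mu = float((xt * w * yt).sum()) / xwx
            r = yt - xt * mu
            s2u = float((r * r * w).sum()) / (m - 1)
            return mu, s2u, xwx, r, w

        if self.ratio is None:
            def nll(log_delta: float) -> float:
                delta = np.exp(log_delta)
                mu, s2u, xwx, r, w = profile(delta)
                if s2u <= 0:
                    return np.inf
                return 0.5 * (
                    (m - 1) * np.log(s2u)
                    + np.log(d + delta).sum()
                    + np.log(xwx)
                    + (m - 1)
                )

            res = minimize_scalar(nll, bounds=(-12.0, 12.0), method="bounded")
            delta = float(np.exp(res.x))
        else:
            delta = float(self.ratio)
        mu, s2u, _, _, _ = profile(delta)
        self.mu_ = mu
        self.sigma2_u_ = s2u
        self.sigma2_e_ = s2u * delta
        self.delta_ = delta
        # u = Xc' (K + delta I)^-1 (y - mu)  ==  (Xc'Xc + delta I)^-1 Xc'(y - mu)
        alpha = U @ ((U.T @ (y - mu)) / (d + delta))
        self.marker_effects_ = Xc.T @ alpha
        self.coef_ = self.marker_effects_
        self.n_features_in_ = n
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.mu_ + (X - self.col_means_) @ self.marker_effects_


class BayesianLasso(RegressorMixin, BaseEstimator):
    """Bayesian LASSO regression of phenotypes on centred markers.

    Gibbs sampler with the scale-mixture representation of the
    double-exponential prior: beta_j | tau_j^2 ~ N(0, sigma2 tau_j^2),
    1/tau_j^2 | beta ~ InvGaussian, lambda^2 ~ Gamma(shape=a, rate=b), and a
    scaled-inverse-chi-square draw for sigma2. Posterior-mean effects are the
    point estimates; chains are reproducible under ``random_state``.
    """

    def __init__(
        self,
        n_iter: int = 10000,
        burn_in: int = 2000,
        thin: int = 1,
        lambda2_shape: float = 0.1,
        lambda2_rate: float = 0.1,
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.lambda2_shape = lambda2_shape
        self.lambda2_rate = lambda2_rate
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        m, p = X.shape
        if m < 3:
            raise ValueError("need at least 3 individuals")
        if np.isnan(X).any():
            raise ValueError("X must be complete (impute first)")
        rng = np.random.default_rng(self.random_state)
        self.col_means_ = X.mean(axis=0)
        Xc = X - self.col_means_
        XtX = Xc.T @ Xc
        Xty_base = Xc.T @ y

        mu = float(y.mean())
        beta = np.zeros(p)
        sigma2 = float(y.var()) / 2.0 or 1.0
        inv_tau2 = np.ones(p)
        lambda2 = 1.0

        keep_beta = np.zeros(p)
        keep_mu = 0.0
        keep_lambda2 = 0.0
        kept = 0
        for it in range(self.n_iter):
            # beta | rest
            A = XtX + np.diag(inv_tau2)
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                L = np.linalg.cholesky(A + 1e-8 * np.eye(p))
            rhs = Xty_base - Xc.T @ np.full(m, mu)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            z = rng.standard_normal(p)
            beta = mean + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
            # mu | rest
            resid0 = y - Xc @ beta
            mu = float(rng.normal(resid0.mean(), np.sqrt(sigma2 / m)))
            # sigma2 | rest
            resid = resid0 - mu
            shape = (m - 1 + p) / 2.0
            scale = (resid @ resid + beta @ (inv_tau2 * beta)) / 2.0
            sigma2 = float(scale / rng.gamma(shape))
            if not np.isfinite(sigma2) or sigma2 <= 0:
                raise RuntimeError("divergent chain: non-finite sigma2")
            # 1/tau_j^2 | rest  ~ inverse Gaussian
            babs = np.maximum(np.abs(beta), 1e-12)
            ig_mean = np.sqrt(lambda2 * sigma2) / babs
            inv_tau2 = rng.wald(ig_mean, lambda2)
            inv_tau2 = np.maximum(inv_tau2, 1e-12)
            # lambda^2 | rest
            tau2_sum = float((1.0 / inv_tau2).sum())
            lambda2 = float(
                rng.gamma(p + self.lambda2_shape, 1.0 / (tau2_sum / 2.0 + self.lambda2_rate))
            )
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                keep_beta += beta
                keep_mu += mu
                keep_lambda2 += lambda2
                kept += 1
        if not np.all(np.isfinite(keep_beta)):
            raise RuntimeError("divergent chain: non-finite effect draws")
        self.marker_effects_ = keep_beta / kept
        self.coef_ = self.marker_effects_
        self.mu_ = keep_mu / kept
        self.lambda2_mean_ = keep_lambda2 / kept
        self.n_draws_kept_ = kept
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.mu_ + (X - self.col_means_) @ self.marker_effects_


def fit_rrblup(X, y, ratio: Optional[float] = None) -> RidgeBLUP:
    return RidgeBLUP(ratio=ratio).fit(X, y)


def fit_bayesian_lasso(
    X, y, n_iter: int = 10000, burn_in: int = 2000, seed: int = 0, **kw
) -> BayesianLasso:
    return BayesianLasso(
        n_iter=n_iter, burn_in=burn_in, random_state=seed, **kw
    ).fit(X, y)


def _make_model(model: Union[str, BaseEstimator], seed: int, **model_kw):
    if isinstance(model, BaseEstimator):
        return model
    key = model.lower()
    if key in {"rr", "rrblup", "ridge"}:
        return RidgeBLUP(**model_kw)
    if key in {"bl", "bayesian_lasso", "blasso"}:
        model_kw.setdefault("random_state", seed)
        return BayesianLasso(**model_kw)
    raise ValueError(f"unknown GS model {model!r}")


def cross_validate(
    X,
    y,
    model: Union[str, BaseEstimator] = "rr",
    n_folds: int = 10,
    seed: int = 0,
    **model_kw,
) -> CVResult:
    """k-fold cross-validated GS accuracy.

    Folds are a single random partition under ``seed``; each fold's GEBVs are
    predicted by a model trained on the remaining individuals, and accuracy
    is the per-fold Pearson correlation between GEBV and phenotype, averaged
    across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m = y.size
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if m // n_folds < 2:
        raise ValueError("folds would contain fewer than 2 individuals")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    gebv = np.empty(m)
    folds = np.empty(m, dtype=int)
    accs = []
    model_name = model if isinstance(model, str) else type(model).__name__
    for f, (train, test) in enumerate(kf.split(X), start=1):
        est = _make_model(model, seed=seed + f, **model_kw)
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        gebv[test] = pred
        folds[test] = f
        sy, sp = np.std(y[test]), np.std(pred)
        if sy == 0 or sp == 0:
            accs.append(0.0)
        else:
            accs.append(float(np.corrcoef(pred, y[test])[0, 1]))
    accs = np.asarray(accs)
    return CVResult(
        fold_assignment=folds,
        gebv=gebv,
        per_fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        model=model_name,
        seed=seed,
    )
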