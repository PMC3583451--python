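"""Map-independent imputation of unordered marker matrices.

Five methods, all treating genotype codes as continuous values on an
``m x n`` matrix (individuals x markers, NaN = missing):

* **MNI** — per-marker mean imputation.
* **kNNI** — weighted average of the k nearest marker columns by Euclidean
  distance, with every marker also present as a sign-flipped copy so that
  markers in perfect negative LD rank as distance-0 neighbours; weights 1/d^2.
* **SVDI** — iterative low-rank regression: regress each marker on the top-k
  left singular vectors of the current completed matrix, refill, repeat until
  the relative change in residual sum of squares falls below 0.02.
* **EMI** — EM under a multivariate-normal model of the individuals (markers
  are i.i.d. observations of an m-vector); missing cells are filled with
  their conditional expectations given the observed cells of the same marker.
* **RFI** — missForest-style random-forest regression: markers sorted by
  missing fraction, each marker's holes predicted from all other markers by a
  bagged ensemble of 100 regression trees, sweeping until the relative
  matrix change (delta-N) first increases.

Each method is an sklearn-style transformer plus a thin functional wrapper
returning an :class:`ImputationResult`. Observed cells are always returned
bit-exactly unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor

from .matrix import GenotypeMatrix


@dataclass
class ImputationResult:
    completed: GenotypeMatrix  # continuous values, zero missing cells
    method: str
    hyperparams: dict
    convergence_trace: list
    iterations_run: int
    seed: Optional[int] = None
    imputed_mask: Optional[np.ndarray] = None
    model_state: Optional[dict] = None


@dataclass
class KSelectionReport:
    method: str
    grid: list
    cv_error_per_k: np.ndarray
    chosen_k: int


def _check_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.any(np.isnan(X).all(axis=0)):
        bad = np.flatnonzero(np.isnan(X).all(axis=0))
        raise ValueError(f"marker column(s) {bad[:5].tolist()} have no observed values")
    return X


def _mean_prefill(X: np.ndarray) -> np.ndarray:
    M = X.copy()
    col_means = np.nanmean(X, axis=0)
    holes = np.isnan(M)
    M[holes] = np.broadcast_to(col_means, X.shape)[holes]
    return M


class _MarkerImputerBase(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing; subclasses implement ``_impute``."""

    def fit(self, X, y=None):
        _check_matrix(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = _check_matrix(X)
        out = self._impute(X)
        # observed cells must survive bit-exactly
        obs = ~np.isnan(X)
        out[obs] = X[obs]
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class MeanImputer(_MarkerImputerBase):
    """Replace each missing cell with its marker's non-missing mean (MNI)."""

    def _impute(self, X):
        self.convergence_trace_ = []
        self.iterations_run_ = 0
        return _mean_prefill(X)


class KNNMarkerImputer(_MarkerImputerBase):
    """k-nearest-marker imputation with sign-flipped duplicate columns (kNNI).

    Distances are Euclidean between marker columns of the mean-prefilled
    matrix, computed against the doubled matrix [columns; flipped columns]
    where flipping reflects codes about ``midpoint`` (0 for -1/1 data). Each
    missing cell is the 1/d^2-weighted average of the values at the k nearest
    candidate markers that were *originally* observed in that row; candidates
    at distance zero are averaged unweighted. A marker and its own flip are
    never candidates for themselves.
    """

    def __init__(self, k: int = 5, midpoint: float = 0.0):
        self.k = k
        self.midpoint = midpoint

    def _impute(self, X):
        m, n = X.shape
        if not 1 <= self.k <= max(1, 2 * (n - 1)):
            raise ValueError(f"k must be in [1, {2 * (n - 1)}], got {self.k}")
        M = _mean_prefill(X)
        obs = ~np.isnan(X)
        flipped = 2.0 * self.midpoint - M
        doubled = np.hstack([M, flipped])  # m x 2n
        sq = np.einsum("ij,ij->j", doubled, doubled)
        G = M.T @ doubled  # n x 2n
        d2 = sq[:n, None] + sq[None, :] - 2.0 * G
        np.maximum(d2, 0.0, out=d2)

        out = M
        self.n_fallback_cells_ = 0
        eps = 1e-12
        for j in range(n):
            miss_rows = np.flatnonzero(~obs[:, j])
            if miss_rows.size == 0:
                continue
            cand = np.argsort(d2[j], kind="stable")
            cand = cand[(cand != j) & (cand != j + n)]
            cand_col = cand % n
            cand_flip = cand >= n
            cand_d2 = d2[j, cand]
            for i in miss_rows:
                avail = np.flatnonzero(obs[i, cand_col])
                if avail.size == 0:
                    self.n_fallback_cells_ += 1  # keep the MNI value
                    continue
                if cand_d2[avail[0]] < eps:
                    # limit of 1/d^2 weighting: average all exact matches
                    zero = avail[cand_d2[avail] < eps]
                    vals = X[i, cand_col[zero]]
                    vals = np.where(cand_flip[zero], 2.0 * self.midpoint - vals, vals)
                    out[i, j] = vals.mean()
                else:
                    sel = avail[: self.k]
                    vals = X[i, cand_col[sel]]
                    vals = np.where(cand_flip[sel], 2.0 * self.midpoint - vals, vals)
                    w = 1.0 / cand_d2[sel]
                    out[i, j] = (w * vals).sum() / w.sum()
        self.convergence_trace_ = []
        self.iterations_run_ = 0
        return out


class SVDImputer(_MarkerImputerBase):
    """Iterative truncated-SVD regression imputation (SVDI).

    Each iteration takes the top-k left singular vectors of the current
    completed matrix and, marker by marker, regresses the *originally
    observed* entries of that column on them; the fitted model predicts the
    missing entries. Iteration stops when |RSS0 - RSS1| / RSS1 < tol, where
    RSS sums squared model residuals over all originally observed cells, or
    after ``max_iter`` iterations.
    """

    def __init__(self, k: Optional[int] = None, max_iter: int = 10, tol: float = 0.02):
        self.k = k
        self.max_iter = max_iter
        self.tol = tol

    def _resolve_k(self, m: int, n: int) -> int:
        k = self.k if self.k is not None else max(1, min(m, n) // 10)
        if not 1 <= k <= min(m, n) - 1:
            raise ValueError(f"k must be in [1, {min(m, n) - 1}], got {k}")
        return k

    def _impute(self, X):
        m, n = X.shape
        k = self._resolve_k(m, n)
        obs = ~np.isnan(X)
        M = _mean_prefill(X)
        trace: list[float] = []
        any_holes = bool((~obs).any())
        for it in range(1, self.max_iter + 1):
            U, s, Vt = np.linalg.svd(M, full_matrices=False)
            Uk = U[:, :k]
            rss = 0.0
            for j in range(n):
                o = obs[:, j]
                beta, *_ = np.linalg.lstsq(Uk[o], X[o, j], rcond=None)
                pred = Uk @ beta
                resid = X[o, j] - pred[o]
                rss += float(resid @ resid)
                M[~o, j] = pred[~o]
            trace.append(rss)
            if not any_holes:
                break
            if len(trace) >= 2 and abs(trace[-2] - trace[-1]) / max(trace[-1], 1e-300) < self.tol:
                break
        self.convergence_trace_ = trace
        self.iterations_run_ = len(trace)
        return M


class EMImputer(_MarkerImputerBase):
    """EM imputation under a multivariate-normal model of individuals (EMI).

    Marker columns are modelled as i.i.d. draws of an m-vector with mean
    ``mu`` (one entry per individual) and covariance ``Sigma`` across
    individuals. The E-step fills each marker's missing entries with the
    conditional expectation given that marker's observed entries; the M-step
    re-estimates mu and Sigma from the completed matrix. Convergence is
    declared when the largest absolute change over the concatenation of mu
    and the entries of Sigma @ Sigma^T drops to ``tol`` (default 0.02).
    """

    def __init__(self, tol: float = 0.02, max_iter: int = 50, ridge: float = 1e-9):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    def _impute(self, X):
        m, n = X.shape
        if m < 2:
            raise ValueError("EMI needs at least 2 individuals")
        obs = ~np.isnan(X)
        M = _mean_prefill(X)
        trace: list[float] = []
        theta_prev = None
        mu = M.mean(axis=1)
        S = np.cov(M, bias=True) + self.ridge * np.eye(m)
        it = 0
        for it in range(1, self.max_iter + 1):
            mu = M.mean(axis=1)
            Xc = M - mu[:, None]
            S = (Xc @ Xc.T) / n + self.ridge * np.eye(m)
            for j in range(n):
                o = obs[:, j]
                mis = ~o
                if not mis.any():
                    continue
                rhs = X[o, j] - mu[o]
                try:
                    a = np.linalg.solve(S[np.ix_(o, o)], rhs)
                except np.linalg.LinAlgError:
                    a = np.linalg.solve(
                        S[np.ix_(o, o)] + 1e-6 * np.eye(int(o.sum())), rhs
                    )
                M[mis, j] = mu[mis] + S[np.ix_(mis, o)] @ a
            gram = S @ S.T
            theta = np.concatenate([mu, gram.ravel()])
            if theta_prev is not None:
                delta = float(np.max(np.abs(theta - theta_prev)))
                trace.append(delta)
                if delta <= self.tol:
                    theta_prev = theta
                    break
            else:
                trace.append(np.inf)
            theta_prev = theta
            if not (~obs).any():
                break
        self.mu_ = mu
        self.sigma_ = S
        self.convergence_trace_ = trace
        self.iterations_run_ = it
        return M


class RandomForestImputer(_MarkerImputerBase):
    """missForest-style random-forest regression imputation (RFI).

    Markers are processed from lowest to highest missing fraction. For each
    marker with holes, ``n_trees`` regression trees are grown on bootstrap
    samples of the originally observed rows, with all other markers (their
    current completed values) as predictors; the ensemble mean fills the
    holes and the matrix is updated in place. Full sweeps repeat until the
    relative change delta-N = sum (M1 - M0)^2 / sum M1^2 (over columns that
    had holes) first increases — the previous matrix is then returned — or
    until ``max_iter`` sweeps.
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_iter: int = 10,
        mtry: str = "all",
        min_samples_leaf: int = 5,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_iter = max_iter
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _impute(self, X):
        m, n = X.shape
        obs = ~np.isnan(X)
        hole_cols = np.flatnonzero((~obs).any(axis=0))
        M = _mean_prefill(X)
        self.convergence_trace_ = []
        self.iterations_run_ = 0
        if hole_cols.size == 0:
            return M
        order = hole_cols[np.argsort((~obs[:, hole_cols]).mean(axis=0), kind="stable")]
        max_features = 1.0 if self.mtry == "all" else "sqrt"
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.max_iter * order.size
        )
        prev = M.copy()
        deltas: list[float] = []
        denom_cols = hole_cols
        s = 0
        for sweep in range(1, self.max_iter + 1):
            for j in order:
                o = obs[:, j]
                other = np.delete(M, j, axis=1)
                rf = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    max_features=max_features,
                    min_samples_leaf=self.min_samples_leaf,
                    bootstrap=True,
                    random_state=int(seeds[s] % (2**32 - 1)),
                    n_jobs=1,
                )
                s += 1
                rf.fit(other[o], X[o, j])
                M[~o, j] = rf.predict(other[~o])
            num = float(((M - prev)[:, denom_cols] ** 2).sum())
            den = float((M[:, denom_cols] ** 2).sum())
            deltas.append(num / max(den, 1e-300))
            self.iterations_run_ = sweep
            if len(deltas) >= 2 and deltas[-1] > deltas[-2]:
                self.convergence_trace_ = deltas
                return prev  # M0: the matrix before delta-N increased
            prev = M.copy()
        self.convergence_trace_ = deltas
        return M


# ---------------------------------------------------------------------------
# functional wrappers on GenotypeMatrix


def _wrap(gm: GenotypeMatrix, est, method: str, seed=None) -> ImputationResult:
    completed_values = est.fit_transform(gm.values)
    completed = replace(gm, values=completed_values, continuous=True)
    state = None
    if hasattr(est, "mu_"):
        state = {"mu": est.mu_, "sigma": est.sigma_}
    return ImputationResult(
        completed=completed,
        method=method,
        hyperparams=est.get_params(),
        convergence_trace=list(getattr(est, "convergence_trace_", [])),
        iterations_run=int(getattr(est, "iterations_run_", 0)),
        seed=seed,
        imputed_mask=gm.missing_mask,
        model_state=state,
    )


def impute_mni(gm: GenotypeMatrix) -> ImputationResult:
    return _wrap(gm, MeanImputer(), "MNI")


def impute_knni(gm: GenotypeMatrix, k: int = 5) -> ImputationResult:
    return _wrap(gm, KNNMarkerImputer(k=k, midpoint=gm.coding.midpoint), "kNNI")


def impute_svdi(
    gm: GenotypeMatrix, k: Optional[int] = None, max_iter: int = 10, tol: float = 0.02
) -> ImputationResult:
    return _wrap(gm, SVDImputer(k=k, max_iter=max_iter, tol=tol), "SVDI")


def impute_emi(
    gm: GenotypeMatrix, tol: float = 0.02, max_iter: int = 50, ridge: float = 1e-9
) -> ImputationResult:
    return _wrap(gm, EMImputer(tol=tol, max_iter=max_iter, ridge=ridge), "EMI")


def impute_rfi(
    gm: GenotypeMatrix,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    mtry: str = "all",
) -> ImputationResult:
    est = RandomForestImputer(
        n_trees=n_trees, max_iter=max_iter, mtry=mtry, random_state=seed
    )
    return _wrap(gm, est, "RFI", seed=seed)


_METHODS = {
    "MNI": impute_mni,
    "kNNI": impute_knni,
    "SVDI": impute_svdi,
    "EMI": impute_emi,
    "RFI": impute_rfi,
}


def impute(gm: GenotypeMatrix, method: str, **kwargs) -> ImputationResult:
    """Dispatch to one of MNI / kNNI / SVDI / EMI / RFI by name."""
    key = {m.lower(): m for m in _METHODS}[method.lower()]
    return _METHODS[key](gm, **kwargs)


def select_k_cv(
    gm: GenotypeMatrix,
    method: str,
    grid: Sequence[int],
    n_folds: int = 10,
    seed: int = 0,
    mask_fraction: float = 0.05,
) -> KSelectionReport:
    """Choose k for kNNI or SVDI by masking-and-scoring cross-validation.

    Each fold hides a random ``mask_fraction`` of the observed cells, imputes
    with every k in the grid, and scores mean squared error against the
    held-out truth; errors are averaged over folds and the smallest k among
    the minimisers is chosen.
    """
    method_key = method.lower()
    if method_key not in {"knni", "svdi"}:
        raise ValueError("select_k_cv supports methods 'kNNI' and 'SVDI'")
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("empty k grid")
    m, n = gm.values.shape
    for k in grid:  # validate before any fold runs
        if method_key == "knni" and not 1 <= k <= 2 * (n - 1):
            raise ValueError(f"invalid k={k} for kNNI (max {2 * (n - 1)})")
        if method_key == "svdi" and not 1 <= k <= min(m, n) - 1:
            raise ValueError(f"invalid k={k} for SVDI (max {min(m, n) - 1})")

    rng = np.random.default_rng(seed)
    obs_cells = np.argwhere(~gm.missing_mask)
    errors = np.zeros((n_folds, len(grid)))
    for f in range(n_folds):
        n_hide = max(1, int(round(mask_fraction * obs_cells.shape[0])))
        pick = rng.choice(obs_cells.shape[0], size=n_hide, replace=False)
        hidden = obs_cells[pick]
        masked = gm.values.copy()
        truth_vals = masked[hidden[:, 0], hidden[:, 1]].copy()
        masked[hidden[:, 0], hidden[:, 1]] = np.nan
        # a fold's masking may empty a column; skip such folds' columns safely
        bad_cols = np.isnan(masked).all(axis=0)
        if bad_cols.any():
            col_means = np.nanmean(gm.values, axis=0)
            masked[:, bad_cols] = np.where(
                np.isnan(masked[:, bad_cols]),
                col_means[bad_cols][None, :],
                masked[:, bad_cols],
            )
        for a, k in enumerate(grid):
            if method_key == "knni":
                est = KNNMarkerImputer(k=k, midpoint=gm.coding.midpoint)
            else:
                est = SVDImputer(k=k)
            filled = est.fit_transform(masked)
            pred = filled[hidden[:, 0], hidden[:, 1]]
            errors[f, a] = float(np.mean((pred - truth_vals) ** 2))
    cv = errors.mean(axis=0)
    chosen = grid[int(np.argmin(cv))]
    return KSelectionReport(
        method="kNNI" if method_key == "knni" else "SVDI",
        grid=list(grid),
        cv_error_per_k=cv,
        chosen_k=chosen,
    )
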