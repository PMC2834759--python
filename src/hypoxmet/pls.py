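"""PLS1 regression of hypoxia duration on the metabolome.

NIPALS PLS1 with mean-centering and unit-variance scaling, leave-one-out
component selection, k-fold cross-validated Q2/RMSE (scaling refit inside
every training fold -- no leakage), permutation-null significance, VIP
(variable importance in the projection) scoring with the normalization
mean(VIP^2) = 1, VIP-threshold model reduction, and VIP stability bands
across resampling.

The NIPALS recursion per component a:

    w_a = X'y / ||X'y||          (unit-norm weights)
    t_a = X w_a                  (scores)
    p_a = X't_a / t_a't_a        (loadings)
    q_a = y't_a / t_a't_a        (response loading)
    X  <- X - t_a p_a',  y <- y - q_a t_a

VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ) with SS_a = q_a^2 t_a't_a
(weights already unit norm).  The permutation p-value is the add-one-smoothed
proportion of label-permuted models whose cross-validated RMSE is at least as
small as the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ValidationError

log = logging.getLogger("hypoxmet")

_EPS = 1e-12


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_ids = [f"x{j}" for j in range(Xa.shape[1])]
    ya = (y.to_numpy(dtype=float) if isinstance(y, (pd.Series, pd.DataFrame)) else np.asarray(y, dtype=float)).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValidationError(f"X has {Xa.shape[0]} rows but y has {ya.shape[0]}")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValidationError("PLS input contains missing values; impute upstream")
    return Xa, ya, feature_ids


def _nipals(Xc: np.ndarray, yc: np.ndarray, A: int):
    """NIPALS PLS1 on already centered/scaled data; truncates A at the rank."""
    n, p = Xc.shape
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    X = Xc.copy()
    y = yc.copy()
    used = 0
    for a in range(A):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = X.T @ t / tt
        q[a] = float(y @ t) / tt
        X -= np.outer(t, P[:, a])
        y = y - q[a] * t
        used = a + 1
    return W[:, :used], P[:, :used], T[:, :used], q[:used]


@dataclass
class PLSModel:
    """Fitted PLS1 model (scaled space) plus the constants to undo the scaling."""

    W: np.ndarray  # features x components, unit-norm columns
    P: np.ndarray  # loadings
    T: np.ndarray  # training scores
    q: np.ndarray  # y-loadings (scaled y units)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    feature_ids: list
    dropped_features: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def coef_(self) -> np.ndarray:
        """Regression vector in scaled space: B = W (P'W)^-1 q."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.q)

    def predict(self, X) -> np.ndarray:
        Xa = X[self.feature_ids].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        Xs = (Xa - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Xs @ self.coef_)

    @property
    def fitted(self) -> np.ndarray:
        """Fitted values on the training data, original y scale."""
        return self.y_mean + self.y_sd * (self.T @ self.q)


def fit_pls1(X, y, A: int) -> PLSModel:
    """Fit a PLS1 model with ``A`` components on mean-centered, UV-scaled data.

    Zero-variance features are dropped with a warning; ``A`` beyond the rank
    of X is truncated with a warning.
    """
    Xa, ya, feature_ids = _as_xy(X, y)
    n, p = Xa.shape
    if A < 1:
        raise ValidationError("A must be >= 1")
    if n < A + 2:
        raise ValidationError(f"need at least A+2={A + 2} samples, got {n}")

    sd = Xa.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(feature_ids, keep) if not k]
    if dropped:
        log.warning("dropping %d zero-variance features: %s", len(dropped), dropped[:5])
        Xa = Xa[:, keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
        sd = sd[keep]
    if Xa.shape[1] == 0:
        raise ValidationError("no features with positive variance")

    x_mean = Xa.mean(axis=0)
    y_mean = float(ya.mean())
    y_sd = float(ya.std(ddof=1))
    if y_sd == 0:
        raise ValidationError("y is constant")

    A_cap = min(A, n - 1, Xa.shape[1])
    W, P, T, q = _nipals((Xa - x_mean) / sd, (ya - y_mean) / y_sd, A_cap)
    if W.shape[1] < A:
        log.warning("requested %d components, fit %d (rank limit)", A, W.shape[1])
    return PLSModel(W, P, T, q, x_mean, sd, y_mean, y_sd, feature_ids, dropped)


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list:
    perm = rng.permutation(n)
    return [perm[i::n_folds] for i in range(n_folds)]  # sizes differ by <= 1


def _cv_predictions(Xa: np.ndarray, ya: np.ndarray, A_max: int, folds: list) -> np.ndarray:
    """Held-out predictions for every component count 1..A_max.

    Returns an (n, A_max) array; column a-1 holds the prediction using a
    components.  Scaling is refit on each training fold.
    """
    n = Xa.shape[0]
    pred = np.full((n, A_max), np.nan)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test, assume_unique=False)
        Xtr, ytr = Xa[train], ya[train]
        sd = Xtr.std(axis=0, ddof=1)
        keep = sd > 0
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        ysd = ytr.std(ddof=1)
        if ysd == 0:
            ysd = 1.0
        W, P, T, q = _nipals((Xtr[:, keep] - xm[keep]) / sd[keep], (ytr - ym) / ysd, min(A_max, len(train) - 1, int(keep.sum())))
        Xs = (Xa[np.ix_(test, np.flatnonzero(keep))] - xm[keep]) / sd[keep]
        yhat = np.zeros(len(test))
        used = W.shape[1]
        for a in range(A_max):
            if a < used:
                t = Xs @ W[:, a]
                yhat = yhat + q[a] * t
                Xs = Xs - np.outer(t, P[:, a])
            pred[test, a] = ym + ysd * yhat
    return pred


def select_components_loo(X, y, A_max: int = 10) -> int:
    """Number of components minimizing leave-one-out RMSE; ties go to fewer components."""
    if A_max < 1:
        raise ValidationError("A_max must be >= 1")
    Xa, ya, _ = _as_xy(X, y)
    n = Xa.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 samples for LOO component selection")
    A_max = min(A_max, n - 2, Xa.shape[1])
    folds = [np.array([i]) for i in range(n)]
    pred = _cv_predictions(Xa, ya, A_max, folds)
    rmse = np.sqrt(np.mean((pred - ya[:, None]) ** 2, axis=0))
    return int(np.argmin(rmse)) + 1  # argmin takes the first minimum -> smaller A on ties


def cross_validate(X, y, A: int, n_folds: int = 10, seed: int = 0):
    """Seeded k-fold CV; returns (q2, rmse) with rmse in the units of y (minutes)."""
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    Xa, ya, _ = _as_xy(X, y)
    n = Xa.shape[0]
    if n < n_folds:
        raise ValidationError(f"need at least n_folds={n_folds} samples, got {n}")
    tss = float(np.sum((ya - ya.mean()) ** 2))
    if tss == 0:
        raise ValidationError("y is constant; Q2 undefined")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, n_folds, rng)
    pred = _cv_predictions(Xa, ya, A, folds)[:, A - 1]
    press = float(np.sum((pred - ya) ** 2))
    return 1.0 - press / tss, float(np.sqrt(press / n))


def compute_vip(model: PLSModel) -> pd.Series:
    """VIP score per feature; checks the normalization mean(VIP^2) = 1."""
    if model.n_components == 0:
        raise ValidationError("model has no components")
    p = len(model.feature_ids)
    ss = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)  # q_a^2 t_a't_a
    denom = ss.sum()
    if denom <= 0:
        raise ValidationError("model explains no variance; VIP undefined")
    vip = np.sqrt(p * (model.W**2 @ ss) / denom)
    if abs(float(np.mean(vip**2)) - 1.0) > 1e-8:
        raise AssertionError("VIP normalization violated: mean(VIP^2) != 1")
    return pd.Series(vip, index=model.feature_ids, name="vip")


def permutation_test(
    X, y, n_perm: int = 5000, seed: int = 0, A: int | None = None,
    n_folds: int = 10, A_max: int = 10, reselect_components: bool = False,
) -> float:
    """Empirical significance of the cross-validated RMSE under label permutation.

    The observed CV RMSE is compared with the RMSE of the identical procedure
    run on randomly permuted y; the returned p is the add-one-smoothed
    fraction of permutations performing at least as well (RMSE <= observed).
    By default the component count stays fixed across permutations;
    ``reselect_components`` reruns the LOO selection inside every permutation.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    Xa, ya, _ = _as_xy(X, y)
    if Xa.shape[0] < 6:
        raise ValidationError("need at least 6 samples for a permutation test")
    if A is None:
        A = select_components_loo(Xa, ya, A_max)
    rng = np.random.default_rng(seed)
    _, rmse_obs = cross_validate(Xa, ya, A, n_folds, seed=int(rng.integers(2**31)))
    n_better = 0
    for _ in range(n_perm):
        yp = rng.permutation(ya)
        Ap = select_components_loo(Xa, yp, A_max) if reselect_components else A
        _, rmse_p = cross_validate(Xa, yp, Ap, n_folds, seed=int(rng.integers(2**31)))
        if rmse_p <= rmse_obs:
            n_better += 1
    return (1.0 + n_better) / (n_perm + 1.0)


def vip_stability(
    X, y, A: int, n_folds: int = 10, seed: int = 0,
    quantiles: tuple = (0.1, 0.9), n_resamples: int | None = None,
) -> pd.DataFrame:
    """Median and quantile band of VIP scores across resampled training sets.

    By default VIP is recomputed on each training fold of the seeded k-fold
    partition; ``n_resamples`` switches to that many random 90% subsamples
    (with ``quantiles=(0.2, 0.8)`` this reproduces the alternative
    30-resample parameterization).
    """
    Xa, ya, feature_ids = _as_xy(X, y)
    n = Xa.shape[0]
    if n_folds < 2 or n < n_folds:
        raise ValidationError("need 2 <= n_folds <= n samples")
    rng = np.random.default_rng(seed)
    if n_resamples is None:
        train_sets = [np.setdiff1d(np.arange(n), f) for f in _fold_indices(n, n_folds, rng)]
    else:
        m = max(A + 2, int(round(0.9 * n)))
        train_sets = [rng.choice(n, size=m, replace=False) for _ in range(n_resamples)]
    Xdf = pd.DataFrame(Xa, columns=feature_ids)
    vips = []
    for train in train_sets:
        model = fit_pls1(Xdf.iloc[train], ya[train], A)
        vips.append(compute_vip(model).reindex(feature_ids))
    mat = pd.concat(vips, axis=1)
    lo, hi = quantiles
    return pd.DataFrame({
        "vip_median": mat.median(axis=1),
        "vip_lo": mat.quantile(lo, axis=1),
        "vip_hi": mat.quantile(hi, axis=1),
    })


@dataclass
class PLSFitReport:
    """Summary of the full and VIP-reduced duration models."""

    r2: float  # reduced model, in-sample
    r2_adj: float  # 1 - (1 - r2)(n - 1)/(n - 1 - A)
    q2: float  # reduced model, cross-validated
    rmse: float  # minutes
    empirical_p: float
    n_components: int
    vip: pd.Series  # full-model VIP per feature
    selected_features: list
    full_r2: float
    full_q2: float
    full_rmse: float
    full_n_components: int
    vip_stability: pd.DataFrame | None = None


def reduce_and_refit(
    X, y, vip_threshold: float = 1.0, A_max: int = 10, n_folds: int = 10,
    n_perm: int = 200, seed: int = 0, compute_stability: bool = True,
    stability_quantiles: tuple = (0.1, 0.9), stability_resamples: int | None = None,
) -> PLSFitReport:
    """Fit the full PLS model, keep features with VIP strictly above threshold, refit and re-assess.

    Both the full and the reduced model get their component count from LOO
    selection; Q2/RMSE come from seeded k-fold CV on the reduced set and the
    empirical p from the permutation test on the reduced set.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=[f"x{j}" for j in range(np.asarray(X).shape[1])])
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)

    A_full = select_components_loo(X, ya, A_max)
    model_full = fit_pls1(X, ya, A_full)
    vip = compute_vip(model_full)
    full_q2, full_rmse = cross_validate(X, ya, A_full, n_folds, seed)
    full_r2 = _r2(model_full.fitted, ya)

    selected = list(vip.index[vip > vip_threshold])
    if not selected:
        raise ValidationError(f"no features with VIP > {vip_threshold}; lower the threshold")

    X_red = X[selected]
    A_red = select_components_loo(X_red, ya, A_max)
    model_red = fit_pls1(X_red, ya, A_red)
    r2 = _r2(model_red.fitted, ya)
    q2, rmse = cross_validate(X_red, ya, A_red, n_folds, seed)
    emp_p = permutation_test(X_red, ya, n_perm=n_perm, seed=seed + 1, A=A_red, n_folds=n_folds)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - model_red.n_components)

    stab = None
    if compute_stability:
        stab = vip_stability(X_red, ya, A_red, n_folds, seed, quantiles=stability_quantiles, n_resamples=stability_resamples)

    return PLSFitReport(
        r2=r2, r2_adj=r2_adj, q2=q2, rmse=rmse, empirical_p=emp_p,
        n_components=model_red.n_components, vip=vip, selected_features=selected,
        full_r2=full_r2, full_q2=full_q2, full_rmse=full_rmse, full_n_components=model_full.n_components,
        vip_stability=stab,
    )


def _r2(fitted: np.ndarray, y: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
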