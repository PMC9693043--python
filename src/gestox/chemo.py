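"""Latent-variable chemometrics for two-class NMR feature matrices.

Implements the SIMCA-style modelling chain in-repo: mean-center / Pareto /
unit-variance scaling, PCA (SVD), PLS-DA (NIPALS, single binary response),
OPLS-DA (orthogonal signal filtering after Trygg & Wold, one predictive
component), VIP scores, per-feature correlation loadings, stratified
k-fold Q2, label-permutation validation and CV-ANOVA.

Class coding is y in {-1 (C, control), +1 (H, hypoxia)} throughout, and
the predictive score is oriented so that a positive correlation loading
means the feature is higher under hypoxia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .spectra import FeatureMatrix

import pandas as pd


class ChemoError(ValueError):
    """Raised for invalid modelling inputs."""


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingModel:
    mode: str
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean flag per feature

    def apply(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.mean
        if self.mode == "center":
            return Xc
        denom = np.where(self.constant, 1.0, self.sd)
        if self.mode == "pareto":
            return Xc / np.sqrt(denom)
        if self.mode == "uv":
            return Xc / denom
        raise ChemoError(f"unknown scaling mode {self.mode!r}")


def scale(matrix: FeatureMatrix, mode: Literal["center", "pareto", "uv"] = "pareto"
          ) -> tuple[FeatureMatrix, ScalingModel]:
    """Column scaling: center, Pareto (divide by sqrt(SD)) or unit variance.

    Constant columns are centered to zero and flagged rather than rejected.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ChemoError("scaling needs at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    model = ScalingModel(mode=mode, mean=mean, sd=sd, constant=constant)
    values = pd.DataFrame(model.apply(X), index=matrix.values.index,
                          columns=matrix.values.columns)
    out = FeatureMatrix(values, matrix.meta.copy(),
                        matrix.provenance + [f"scale({mode})"])
    return out, model


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_variance_ratio: np.ndarray  # R2X per component
    cumulative_r2x: float


def fit_pca(X: np.ndarray, n_components: int) -> PcaModel:
    """PCA of an already-scaled matrix via SVD.

    Sign convention: the largest-magnitude loading element of each
    component is made positive, so results are deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    if n_components > min(n - 1, f):
        raise ChemoError(
            f"n_components={n_components} exceeds min(samples-1, features)={min(n - 1, f)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_ss = float((X ** 2).sum())
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    ratio = (s[:n_components] ** 2) / total_ss if total_ss > 0 else np.zeros(n_components)
    return PcaModel(scores=scores, loadings=loadings,
                    explained_variance_ratio=ratio,
                    cumulative_r2x=float(ratio.sum()))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ChemoError(f"need exactly two classes in y, got {classes}")
    return y


def _fix_sign(w: np.ndarray) -> float:
    """Deterministic sign: largest-magnitude weight element positive."""
    j = int(np.argmax(np.abs(w)))
    return -1.0 if w[j] < 0 else 1.0


@dataclass
class PlsdaModel:
    W: np.ndarray  # features x A, component weights
    P: np.ndarray  # features x A, X loadings
    q: np.ndarray  # A, y loadings
    T: np.ndarray  # samples x A, scores
    y_mean: float
    r2x: float
    r2y: float
    ssy_per_component: np.ndarray
    q2: float | None = None

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        # regression form: B = W (P'W)^-1 q
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return np.asarray(X, dtype=float) @ (R @ self.q) + self.y_mean


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int = 1) -> PlsdaModel:
    """NIPALS PLS1 with deflation on a scaled X and class vector y (+-1).

    With a single response the NIPALS weight vector is closed-form
    (w proportional to X'y), so no inner iteration is needed.
    """
    X = np.asarray(X, dtype=float).copy()
    y = _check_two_class(y)
    if n_components < 1:
        raise ChemoError("n_components must be >= 1")
    n, f = X.shape
    y_mean = float(y.mean())
    yc = y - y_mean
    ss_x = float((X ** 2).sum())
    ss_y = float((yc ** 2).sum())
    W = np.zeros((f, n_components))
    P = np.zeros((f, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ssy_comp = np.zeros(n_components)
    Xd, yd = X, yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ChemoError(f"no covariance left for component {a + 1}")
        w = w / norm * _fix_sign(w / norm)
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise ChemoError(f"degenerate score for component {a + 1}")
        p = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, qa
        ssy_comp[a] = qa ** 2 * tt
    r2x = 1.0 - float((Xd ** 2).sum()) / ss_x if ss_x > 0 else 0.0
    r2y = 1.0 - float((yd ** 2).sum()) / ss_y if ss_y > 0 else 0.0
    return PlsdaModel(W=W, P=P, q=q, T=T, y_mean=y_mean, r2x=r2x, r2y=r2y,
                      ssy_per_component=ssy_comp)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    w_p: np.ndarray  # predictive weights (features,)
    p_p: np.ndarray  # predictive loadings
    q: float  # y loading of the predictive component
    t_p: np.ndarray  # predictive score (samples,)
    W_o: np.ndarray  # features x n_orth orthogonal weights
    P_o: np.ndarray  # features x n_orth orthogonal loadings
    T_o: np.ndarray  # samples x n_orth orthogonal scores
    n_orth: int
    y_mean: float
    r2x: float
    r2y: float
    vip: np.ndarray | None = None
    r: np.ndarray | None = None
    q2: float | None = None

    def filter_orthogonal(self, X: np.ndarray) -> np.ndarray:
        """Remove the fitted y-orthogonal components from (centered) X."""
        Xf = np.asarray(X, dtype=float).copy()
        for i in range(self.n_orth):
            t_o = Xf @ self.W_o[:, i]
            Xf -= np.outer(t_o, self.P_o[:, i])
        return Xf

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xf = self.filter_orthogonal(X)
        t = Xf @ self.w_p
        return self.q * t + self.y_mean


def fit_oplsda(X: np.ndarray, y: np.ndarray, n_orth: int = 1) -> OplsdaModel:
    """OPLS-DA: strip ``n_orth`` y-orthogonal components, then one
    predictive PLS component (Trygg & Wold orthogonal projections).

    With ``n_orth=0`` this reduces exactly to 1-component PLS-DA.  The
    predictive score is oriented so that corr(t_p, y) > 0 (i.e. q > 0).
    """
    X = np.asarray(X, dtype=float).copy()
    y = _check_two_class(y)
    if n_orth < 0:
        raise ChemoError("n_orth must be >= 0")
    n, f = X.shape
    rank = np.linalg.matrix_rank(X)
    if n_orth >= rank:
        raise ChemoError(f"n_orth={n_orth} must be below rank(X)={rank}")
    y_mean = float(y.mean())
    yc = y - y_mean
    ss_x = float((X ** 2).sum())
    ss_y = float((yc ** 2).sum())
    w = X.T @ yc
    w /= np.linalg.norm(w)
    W_o = np.zeros((f, n_orth))
    P_o = np.zeros((f, n_orth))
    T_o = np.zeros((n, n_orth))
    Xd = X
    for i in range(n_orth):
        t = Xd @ w
        p = Xd.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ChemoError(
                f"no y-orthogonal variation left for orthogonal component {i + 1}")
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, i], P_o[:, i], T_o[:, i] = w_o, p_o, t_o
    t_p = Xd @ w
    tt = float(t_p @ t_p)
    p_p = Xd.T @ t_p / tt
    q = float(yc @ t_p / tt)
    if q < 0:  # orient toward the H class
        w, t_p, p_p, q = -w, -t_p, -p_p, -q
    X_res = Xd - np.outer(t_p, p_p)
    y_res = yc - q * t_p
    r2x = 1.0 - float((X_res ** 2).sum()) / ss_x if ss_x > 0 else 0.0
    r2y = 1.0 - float((y_res ** 2).sum()) / ss_y if ss_y > 0 else 0.0
    model = OplsdaModel(w_p=w, p_p=p_p, q=q, t_p=t_p, W_o=W_o, P_o=P_o,
                        T_o=T_o, n_orth=n_orth, y_mean=y_mean, r2x=r2x, r2y=r2y)
    model.vip = compute_vip(model)
    return model


# ---------------------------------------------------------------------------
# VIP and correlation loadings
# ---------------------------------------------------------------------------

def compute_vip(model: PlsdaModel | OplsdaModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( F * sum_k SSY_k (w_jk/||w_k||)^2 / sum_k SSY_k ), with F
    the number of features; the squares of the VIPs average to exactly 1.
    For OPLS models only the predictive component enters (the orthogonal
    components explain no Y variance by construction).
    """
    if isinstance(model, OplsdaModel):
        w = model.w_p / np.linalg.norm(model.w_p)
        return np.sqrt(w.size * w ** 2)
    if isinstance(model, PlsdaModel):
        W = model.W
        f, a = W.shape
        ssy = model.ssy_per_component
        if ssy.sum() <= 0:
            raise ChemoError("model explains no Y variance; VIP undefined")
        wn = W / np.linalg.norm(W, axis=0, keepdims=True)
        return np.sqrt(f * (wn ** 2 @ ssy) / ssy.sum())
    raise ChemoError("compute_vip expects a fitted PLS-DA or OPLS-DA model")


def correlation_loadings(model: OplsdaModel, X: np.ndarray) -> np.ndarray:
    """Pearson correlation of each (scaled) feature with the predictive score.

    The score is oriented toward y=+1 (hypoxia) at fit time, so r > 0 means
    higher levels under hypoxia.  Zero-variance columns give NaN.
    """
    X = np.asarray(X, dtype=float)
    t = model.t_p
    tc = t - t.mean()
    denom_t = np.linalg.norm(tc)
    Xc = X - X.mean(axis=0)
    denom_x = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ tc) / (denom_x * denom_t)
    r[denom_x == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


# ---------------------------------------------------------------------------
# validation: CV, permutation test, CV-ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitSpec:
    """What to (re)fit during cross-validation and permutation."""

    method: Literal["plsda", "oplsda"] = "oplsda"
    n_components: int = 1  # PLS-DA components
    n_orth: int = 1  # OPLS-DA orthogonal components

    def fit(self, X: np.ndarray, y: np.ndarray):
        if self.method == "plsda":
            return fit_plsda(X, y, n_components=self.n_components)
        if self.method == "oplsda":
            return fit_oplsda(X, y, n_orth=self.n_orth)
        raise ChemoError(f"unknown method {self.method!r}")


def _cv_predictions(spec: FitSpec, X: np.ndarray, y: np.ndarray,
                    folds: int, seed: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    y = _check_two_class(y)
    n = y.size
    if folds < 2:
        raise ChemoError("folds must be >= 2")
    if folds >= n:  # leave-one-out
        splitter = KFold(n_splits=n)
    else:
        # stratification caps usable folds at the minority-class size
        n_min = int(min(np.sum(y == c) for c in np.unique(y)))
        if n_min < 2:
            raise ChemoError("a training fold contains a single class; "
                             "need >= 2 samples per class for stratified CV")
        splitter = StratifiedKFold(n_splits=min(folds, n_min), shuffle=True,
                                   random_state=seed)
    yhat = np.empty(n)
    for train, test in splitter.split(X, y):
        if np.unique(y[train]).size < 2:
            raise ChemoError("a training fold contains a single class; "
                             "reduce the number of folds")
        model = spec.fit(X[train], y[train])
        yhat[test] = model.predict(X[test])
    return yhat


def cross_validate(spec: FitSpec, X: np.ndarray, y: np.ndarray,
                   folds: int = 7, seed: int = 0) -> float:
    """Q2 = 1 - PRESS / SS with class-stratified folds (LOO when folds >= n)."""
    y = _check_two_class(y)
    yhat = _cv_predictions(spec, X, y, folds, seed)
    press = float(((y - yhat) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss


@dataclass
class PermutationResult:
    n_perm: int
    observed_r2y: float
    observed_q2: float
    null_r2y: np.ndarray
    null_q2: np.ndarray
    p_r2y: float
    p_q2: float


def permutation_test(spec: FitSpec, X: np.ndarray, y: np.ndarray,
                     n_perm: int = 200, seed: int = 0, folds: int = 7
                     ) -> PermutationResult:
    """Label-permutation validation of R2Y and Q2.

    Empirical p uses the add-one estimator (1 + #{null >= observed}) /
    (n_perm + 1), so the smallest attainable p at the default n_perm = 200
    is 1/201.
    """
    if n_perm < 1:
        raise ChemoError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = _check_two_class(y)
    obs_model = spec.fit(X, y)
    obs_r2y = obs_model.r2y
    obs_q2 = cross_validate(spec, X, y, folds=folds, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null_r2y = np.empty(n_perm)
    null_q2 = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        while np.unique(yp).size < 2:  # cannot happen for two-class y, kept defensive
            yp = rng.permutation(y)
        null_r2y[i] = spec.fit(X, yp).r2y
        null_q2[i] = cross_validate(spec, X, yp, folds=folds, seed=seed + i + 1)
    p_r2y = (1.0 + float((null_r2y >= obs_r2y).sum())) / (n_perm + 1.0)
    p_q2 = (1.0 + float((null_q2 >= obs_q2).sum())) / (n_perm + 1.0)
    return PermutationResult(n_perm=n_perm, observed_r2y=obs_r2y, observed_q2=obs_q2,
                             null_r2y=null_r2y, null_q2=null_q2,
                             p_r2y=p_r2y, p_q2=p_q2)


@dataclass
class CvAnovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    press: float
    ss_total: float
    degenerate: bool = False


def cv_anova(spec: FitSpec, X: np.ndarray, y: np.ndarray,
             folds: int = 7, seed: int = 0) -> CvAnovaResult:
    """CV-ANOVA: F-test of cross-validated residuals against total Y variance.

    F = ((SS_tot - PRESS)/A) / (PRESS/(N-1-A)) with A the number of fitted
    components (predictive + orthogonal for OPLS), p from F(A, N-1-A).
    """
    y = _check_two_class(y)
    yhat = _cv_predictions(spec, X, y, folds, seed)
    press = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    a = spec.n_components if spec.method == "plsda" else 1 + spec.n_orth
    df_den = y.size - 1 - a
    if df_den <= 0:
        raise ChemoError("too few samples for CV-ANOVA with this many components")
    if press <= np.finfo(float).eps * ss_tot:
        return CvAnovaResult(f_statistic=np.inf, df_num=a, df_den=df_den,
                             p_value=np.finfo(float).eps, press=press,
                             ss_total=ss_tot, degenerate=True)
    f = max(0.0, (ss_tot - press) / a) / (press / df_den)
    p = float(stats.f.sf(f, a, df_den))
    return CvAnovaResult(f_statistic=float(f), df_num=a, df_den=df_den,
                         p_value=p, press=press, ss_total=ss_tot)


def model_summary(model, extras: dict | None = None) -> dict:
    """JSON-ready scalar summary of a fitted latent-variable model."""
    out: dict = {}
    if isinstance(model, OplsdaModel):
        out.update({"method": "oplsda", "n_orth": model.n_orth,
                    "r2x": model.r2x, "r2y": model.r2y, "q2": model.q2})
    elif isinstance(model, PlsdaModel):
        out.update({"method": "plsda", "n_components": model.n_components,
                    "r2x": model.r2x, "r2y": model.r2y, "q2": model.q2})
    elif isinstance(model, PcaModel):
        out.update({"method": "pca",
                    "r2x_per_component": model.explained_variance_ratio.tolist(),
                    "cumulative_r2x": model.cumulative_r2x})
    if extras:
        out.update(extras)
    return out
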