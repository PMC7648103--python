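"""Statistical stage: variance stabilization, univariate and multivariate tests.

The downstream analysis of a filtered, imputed, IS-normalized feature table:

* generalized log (glog) transform, ``x -> log2((x + sqrt(x^2 + lambda^2))/2)``,
  with lambda defaulting to the table's minimum positive value;
* autoscaling (per-feature mean 0, unit n-1 sd);
* two-tailed Welch t-test per feature (on transformed, autoscaled data) and
  fold change (on untransformed IS-normalized abundances) combined by the
  volcano rule p < 0.05 and FC > 2 or FC < 0.5;
* PLS-DA via NIPALS (PLS1 against a +/-1 class code) with VIP scores, with
  the discriminant set defined as volcano-passing features with VIP > 1.8;
* orthogonal PLS-DA (one OSC component then a 1-component PLS) and
  leave-one-out cross-validation with in-fold re-scaling;
* PCA and Pearson correlation maps.

Fold changes live on raw normalized abundances while p-values, loadings and
correlations live on glog + autoscaled data — the two scales serve different
questions (effect magnitude versus evidence), and mixing them is a classic
volcano-plot mistake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TransformedMatrix",
    "VolcanoResult",
    "PlsModel",
    "OplsModel",
    "CvResult",
    "glog_transform",
    "autoscale",
    "welch_t_test",
    "fold_change",
    "volcano",
    "volcano_select",
    "plsda_fit",
    "vip_scores",
    "select_significant",
    "oplsda_fit",
    "loo_cv",
    "pca",
    "pearson_correlation_map",
    "correlation_to_anchor",
]


@dataclass
class TransformedMatrix:
    """A samples x features real matrix plus the transform parameters used."""

    values: pd.DataFrame
    glog_lambda: float | None = None
    scale_means: np.ndarray | None = None
    scale_sds: np.ndarray | None = None


def glog_transform(
    values: pd.DataFrame, lam: float | str = "auto"
) -> TransformedMatrix:
    """Generalized log2 transform; lambda = 'auto' uses the min positive value.

    Monotone in x, and reduces to plain log2 as lambda -> 0.  Requires all
    values positive (run after imputation).
    """
    X = values.to_numpy(dtype=float)
    if np.any(~np.isfinite(X)) or np.any(X <= 0):
        raise ValueError("glog requires a complete, strictly positive matrix")
    if lam == "auto":
        lam = float(X[X > 0].min())
    lam = float(lam)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out = np.log2((X + np.sqrt(X**2 + lam**2)) / 2.0)
    return TransformedMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns), glog_lambda=lam
    )


def autoscale(values: pd.DataFrame | TransformedMatrix) -> TransformedMatrix:
    """Center each feature to mean 0 and scale to unit (n-1) standard deviation."""
    lam = None
    if isinstance(values, TransformedMatrix):
        lam = values.glog_lambda
        values = values.values
    X = values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling requires at least two samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [values.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant feature column(s): {bad}")
    out = (X - means) / sds
    return TransformedMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        glog_lambda=lam,
        scale_means=means,
        scale_sds=sds,
    )


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-tailed p-value of Welch's unequal-variance t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's test needs at least two values per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def fold_change(
    values: pd.DataFrame, group1_ids: Sequence, group2_ids: Sequence
) -> pd.Series:
    """Per-feature ratio mean(group2)/mean(group1) of raw normalized abundances."""
    m1 = values.loc[list(group1_ids)].mean(axis=0)
    m2 = values.loc[list(group2_ids)].mean(axis=0)
    if (m1 == 0).any():
        raise ValueError("zero group-1 mean; fold change undefined")
    return m2 / m1


@dataclass
class VolcanoResult:
    """Per-feature fold change, Welch p-value, and pass/fail flags."""

    table: pd.DataFrame  # columns: fc, p_value, passes
    p_cut: float
    fc_hi: float
    fc_lo: float

    @property
    def passing(self) -> list:
        return [c for c in self.table.index[self.table["passes"]]]


def volcano(
    raw_values: pd.DataFrame,
    transformed: TransformedMatrix,
    group1_ids: Sequence,
    group2_ids: Sequence,
    p_cut: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> VolcanoResult:
    """Welch p-values on the transformed matrix, FCs on raw abundances.

    Strict inequalities: a feature passes iff p < p_cut and (fc > fc_hi or
    fc < fc_lo).
    """
    fc = fold_change(raw_values, group1_ids, group2_ids)
    T = transformed.values
    ps = pd.Series(
        {
            col: welch_t_test(T.loc[list(group1_ids), col], T.loc[list(group2_ids), col])
            for col in T.columns
        }
    )
    passes = (ps < p_cut) & ((fc > fc_hi) | (fc < fc_lo))
    tab = pd.DataFrame({"fc": fc, "p_value": ps, "passes": passes})
    return VolcanoResult(tab, p_cut, fc_hi, fc_lo)


def volcano_select(
    result: VolcanoResult,
    p_cut: float | None = None,
    fc_hi: float | None = None,
    fc_lo: float | None = None,
) -> list:
    """Feature set passing the volcano criteria (optionally re-thresholded)."""
    t = result.table
    p_cut = result.p_cut if p_cut is None else p_cut
    fc_hi = result.fc_hi if fc_hi is None else fc_hi
    fc_lo = result.fc_lo if fc_lo is None else fc_lo
    mask = (t["p_value"] < p_cut) & ((t["fc"] > fc_hi) | (t["fc"] < fc_lo))
    return [c for c in t.index[mask]]


# --------------------------------------------------------------------------
# PLS-DA (NIPALS, PLS1) and VIP
# --------------------------------------------------------------------------


@dataclass
class PlsModel:
    """Fitted PLS1 discriminant model (NIPALS, deterministic)."""

    n_components: int
    scores: np.ndarray  # T, n x A
    weights: np.ndarray  # W, p x A, unit columns
    x_loadings: np.ndarray  # P, p x A
    y_loadings: np.ndarray  # q, A
    y_mean: float
    classes: tuple
    feature_names: list = field(default_factory=list)

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        """Continuous predicted y for (already scaled/centered) rows of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
        yhat = np.full(X.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = X @ self.weights[:, a]
            yhat += t * self.y_loadings[a]
            X -= np.outer(t, self.x_loadings[:, a])
        return yhat

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """Class label by thresholding predicted y at the class-code midpoint."""
        yhat = self.predict_value(X)
        return np.where(yhat >= 0.0, self.classes[1], self.classes[0])


def _encode_y(y: Sequence, classes: tuple | None = None) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    if classes is None:
        found = list(dict.fromkeys(y.tolist()))  # order of first appearance
        if len(found) != 2:
            raise ValueError(f"expected exactly two classes, found {found}")
        classes = tuple(found)
    code = np.where(y == classes[1], 1.0, -1.0)
    return code, classes


def plsda_fit(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    n_components: int = 2,
    classes: tuple | None = None,
) -> PlsModel:
    """PLS1 discriminant analysis via NIPALS on X versus a +/-1 class code.

    X should already be transformed and autoscaled.  Components are extracted
    by successive weight/score/loading triplets with X-deflation; with a
    single y column NIPALS needs no iteration and no random initialization,
    so the fit is deterministic.  Score columns come out mutually orthogonal.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    Xm = np.asarray(X, dtype=float).copy()
    code, classes = _encode_y(y, classes)
    y_mean = float(code.mean())
    yc = code - y_mean
    n, p = Xm.shape
    A = int(n_components)
    if A < 1 or A > min(n - 1, p):
        raise ValueError(f"n_components={A} out of range for X of shape {Xm.shape}")
    T = np.zeros((n, A))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xm.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("rank deficiency: no y-covarying structure left")
        w /= nw
        t = Xm @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("degenerate component (zero score variance)")
        pl = Xm.T @ t / tt
        q[a] = float(yc @ t / tt)
        Xm -= np.outer(t, pl)
        T[:, a], W[:, a], P[:, a] = t, w, pl
    return PlsModel(A, T, W, P, q, y_mean, classes, feature_names)


def vip_scores(model: PlsModel) -> pd.Series:
    """Variable importance in projection for every feature.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) where
    SSY_a = q_a^2 t_a't_a is the y-variance captured by component a.  The
    mean of VIP^2 over features is exactly 1.
    """
    W = model.weights
    p = W.shape[0]
    ssy = model.y_loadings**2 * np.einsum("ia,ia->a", model.scores, model.scores)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
    index = model.feature_names if model.feature_names else pd.RangeIndex(p)
    return pd.Series(vip, index=index, name="vip")


def select_significant(
    volcano_features: Sequence, vip: pd.Series, vip_cut: float = 1.8
) -> list:
    """Intersection of volcano-passing features with VIP strictly above cutoff."""
    high = set(vip.index[vip > vip_cut])
    return [f for f in volcano_features if f in high]


# --------------------------------------------------------------------------
# O-PLS-DA and cross-validation
# --------------------------------------------------------------------------


@dataclass
class OplsModel:
    """Orthogonal-signal-corrected PLS1: n_ortho filter components + 1 predictive."""

    n_ortho: int
    w_ortho: np.ndarray  # p x n_ortho
    p_ortho: np.ndarray  # p x n_ortho
    pls: PlsModel

    def _filter(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
        for a in range(self.n_ortho):
            t = X @ self.w_ortho[:, a]
            X -= np.outer(t, self.p_ortho[:, a])
        return X

    @property
    def predictive_scores(self) -> np.ndarray:
        return self.pls.scores[:, 0]

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict_value(self._filter(X))

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict_class(self._filter(X))


def oplsda_fit(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    n_ortho: int = 1,
    classes: tuple | None = None,
) -> OplsModel:
    """Orthogonal PLS-DA: strip y-orthogonal variation, then 1-component PLS.

    Each orthogonal component is built Trygg-Wold style: project the loading
    of a provisional PLS component onto the subspace orthogonal to the
    y-predictive weight, deflate X by the resulting orthogonal score, repeat.
    With no y-orthogonal structure present the predictive component equals
    plain PLS component 1.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    Xm = np.asarray(X, dtype=float).copy()
    code, classes = _encode_y(y, classes)
    yc = code - code.mean()
    w = Xm.T @ yc
    w /= np.linalg.norm(w)
    p_feat = Xm.shape[1]
    Wo = np.zeros((p_feat, n_ortho))
    Po = np.zeros((p_feat, n_ortho))
    for a in range(n_ortho):
        t = Xm @ w
        pl = Xm.T @ t / float(t @ t)
        w_o = pl - float(w @ pl) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            # no orthogonal variation left; keep a zero filter component
            Wo[:, a] = 0.0
            Po[:, a] = 0.0
            continue
        w_o /= n_wo
        t_o = Xm @ w_o
        p_o = Xm.T @ t_o / float(t_o @ t_o)
        Xm -= np.outer(t_o, p_o)
        Wo[:, a] = w_o
        Po[:, a] = p_o
    Xf = pd.DataFrame(Xm, columns=feature_names) if feature_names else Xm
    pls = plsda_fit(Xf, y, n_components=1, classes=classes)
    return OplsModel(n_ortho, Wo, Po, pls)


@dataclass
class CvResult:
    """Leave-one-out classification outcome."""

    predictions: pd.Series
    truth: pd.Series
    positive_class: object
    sensitivity: float
    specificity: float
    accuracy: float
    confusion: dict


def loo_cv(
    X: pd.DataFrame,
    y: Sequence,
    fit: Callable[[pd.DataFrame, Sequence], PlsModel | OplsModel] | None = None,
    positive_class=None,
    classes: tuple | None = None,
) -> CvResult:
    """Leave-one-out cross-validation with in-fold re-autoscaling.

    ``X`` is the transformed (e.g. glog) but *unscaled* matrix: each training
    fold re-estimates feature means and sds, applies them to the held-out
    sample, fits, and predicts.  The positive class defaults to the second
    class (the stimulated / post-challenge group in a two-group design).
    """
    y = pd.Series(np.asarray(y), index=X.index)
    _, found = _encode_y(y, classes)
    if positive_class is None:
        positive_class = found[1]
    if fit is None:
        fit = lambda Xt, yt: oplsda_fit(Xt, yt, n_ortho=1, classes=found)
    if len(X) < 3:
        raise ValueError("LOO-CV needs at least three samples")
    preds = {}
    for i in X.index:
        train = X.drop(index=i)
        ytr = y.drop(index=i)
        if ytr.nunique() < 2:
            raise ValueError("a training fold contains a single class")
        sds = train.std(axis=0, ddof=1)
        keep = sds > 0
        means = train.mean(axis=0)
        Xtr = (train.loc[:, keep] - means[keep]) / sds[keep]
        model = fit(Xtr, ytr)
        xte = ((X.loc[[i], keep] - means[keep]) / sds[keep]).to_numpy()
        preds[i] = model.predict_class(xte)[0]
    preds = pd.Series(preds).loc[X.index]
    pos = y == positive_class
    tp = int(((preds == positive_class) & pos).sum())
    fn = int(((preds != positive_class) & pos).sum())
    tn = int(((preds != positive_class) & ~pos).sum())
    fp = int(((preds == positive_class) & ~pos).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y)
    return CvResult(
        preds, y, positive_class, sens, spec, acc,
        {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    )


# --------------------------------------------------------------------------
# PCA and correlations
# --------------------------------------------------------------------------


def pca(X: pd.DataFrame | np.ndarray, n_components: int | None = None):
    """PCA of a (transformed, autoscaled) matrix via SVD of the centered data.

    Returns (scores, loadings, explained_variance); components are ordered by
    decreasing variance, with the sign convention that each component's
    largest-magnitude loading is positive.  Explained variances sum to the
    total per-feature variance.
    """
    Xm = np.asarray(X, dtype=float)
    if Xm.shape[0] < 2:
        raise ValueError("PCA requires at least two samples")
    Xc = Xm - Xm.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = Xm.shape[0]
    var = S**2 / (n - 1)
    if n_components is not None:
        U, S, Vt, var = U[:, :n_components], S[:n_components], Vt[:n_components], var[:n_components]
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = U * S * flip
    return scores, Vt.T, var


def pearson_correlation_map(X: pd.DataFrame) -> pd.DataFrame:
    """Feature x feature Pearson correlation matrix (unit diagonal, symmetric)."""
    Xm = X.to_numpy(dtype=float)
    if Xm.shape[0] < 3:
        raise ValueError("correlation map needs at least three samples")
    if np.any(Xm.std(axis=0) == 0):
        raise ValueError("constant feature column")
    r = np.corrcoef(Xm, rowvar=False)
    return pd.DataFrame(r, index=X.columns, columns=X.columns)


def correlation_to_anchor(X: pd.DataFrame, anchor_feature) -> pd.Series:
    """Pearson r of every feature against one anchor feature."""
    r = pearson_correlation_map(X)
    return r[anchor_feature]
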