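"""Feature-space normalization, scaling fits, and disease-state classifiers.

Specimens live in a two-dimensional feature space with a shape axis
(normalized total-curvature fluctuation, ``delta_K_tilde``) and a size
axis (normalized inverse radius, ``ell_tilde_inv``), both scaled by the
normal-group means.  This module fits the scaling laws that justify the
single inner length scale, the power-law structure of the delta_K
marginal, and the power-law relation ``delta_K_tilde = alpha *
ell_tilde^-beta`` in the normalized space; and implements the five
classification models used to compare size-only and shape+size
decision rules: (A) pooled-mean thresholds, (B) midpoint-of-means
thresholds, (C) multinomial logistic regression over random 50/50
splits, (D) 2D group-mean thresholds, and (E) a lasso sweep that
shrinks the size coefficient of a binomial logistic boundary.

The classifiers follow the sklearn estimator protocol (fit/predict,
get_params/set_params, trailing-underscore fitted attributes) and
compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NormalizationConstants",
    "normalize",
    "size_scaling_fit",
    "fit_delta_K_power_law",
    "fit_size_gaussian",
    "fit_feature_space_curve",
    "ThresholdClassifier",
    "PenalizedSizeLogistic",
    "threshold_classifier",
    "multinomial_logistic",
    "lasso_boundary_sweep",
    "ClassifierResult",
    "CLASS_ORDER",
]

CLASS_ORDER = ("normal", "success", "failed")


# -- normalization ------------------------------------------------------


@dataclass
class NormalizationConstants:
    """Normal-group means used to normalize the feature axes."""

    delta_K_norm: float
    ell_norm: float

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out["delta_K_tilde"] = out["delta_K"] / self.delta_K_norm
        out["ell_tilde_inv"] = (1.0 / out["ell"]) / (1.0 / self.ell_norm)
        return out


def normalize(
    table: pd.DataFrame, group_col: str = "group", normal_label: str = "normal"
) -> tuple[pd.DataFrame, NormalizationConstants]:
    """Normalize delta_K and inverse size by the normal-group means.

    By construction the normal group has mean ``delta_K_tilde = 1`` and
    mean ``ell_tilde_inv`` near 1 (exactly 1 when sizes are constant).
    The constants are returned for reuse on held-out specimens.
    """
    normals = table[table[group_col] == normal_label]
    if len(normals) == 0:
        raise ValueError(f"no rows labeled {normal_label!r}")
    consts = NormalizationConstants(
        delta_K_norm=float(normals["delta_K"].mean()),
        ell_norm=float(normals["ell"].mean()),
    )
    return consts.apply(table), consts


# -- scaling and distribution fits --------------------------------------


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(x * y) / np.sum(x * x))


def size_scaling_fit(table: pd.DataFrame, x_col: str = "max_radius") -> dict:
    """Through-origin slopes of every size measure against 2*R_m.

    Linear measures collapse with slope ~1 relative to each other, while
    sqrt(A_T) and V^(1/3) carry the generalized-cylinder prefactors
    sqrt(2*pi*c) and (pi*c)^(1/3).  When a ``centerline_length`` column
    exists (synthetic tubes), ``c = mean(L / ell)`` is also reported.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for scaling fits")
    x = 2.0 * table[x_col].to_numpy(float)
    slopes = {}
    candidates = {
        "mean_radius": lambda t: t["mean_radius"].to_numpy(float),
        "ell": lambda t: t["ell"].to_numpy(float),
        "inv_mean_curvedness": lambda t: 1.0 / t["mean_curvedness"].to_numpy(float),
        "sqrt_area": lambda t: np.sqrt(t["total_area"].to_numpy(float)),
        "cbrt_volume": lambda t: np.cbrt(t["volume"].to_numpy(float)),
    }
    for name, fn in candidates.items():
        try:
            y = fn(table)
        except KeyError:
            continue
        if np.all(np.isfinite(y)):
            slopes[name] = _through_origin_slope(x, y)
    out = {"slopes": slopes}
    if "sqrt_area" in slopes:
        # A_T ~ 2*pi*c*ell^2 with x = 2*ell: slope = sqrt(2*pi*c)/2
        out["c_from_area"] = (2.0 * slopes["sqrt_area"]) ** 2 / (2 * np.pi)
    if "cbrt_volume" in slopes:
        out["c_from_volume"] = (2.0 * slopes["cbrt_volume"]) ** 3 / np.pi
    if "centerline_length" in table.columns and "ell" in table.columns:
        ratio = table["centerline_length"].to_numpy(float) / table["ell"].to_numpy(float)
        out["c_mean"] = float(np.mean(ratio))
        out["c_sd"] = float(np.std(ratio, ddof=0))
    return out


@dataclass
class DistributionFit:
    """Result of a histogram distribution fit."""

    params: dict
    loglog_slope: float
    loglog_r2: float
    ok: bool
    message: str = ""


def _histogram_density(values: np.ndarray, bins: int = 24, log_bins: bool = False):
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if log_bins:
        v = v[v > 0]
        edges = np.geomspace(v.min(), v.max(), bins + 1)
    else:
        edges = np.linspace(v.min(), v.max(), bins + 1)
    dens, _ = np.histogram(v, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = dens > 0
    return centers[keep], dens[keep]


def _loglog_linear(x: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    lx, lp = np.log10(x), np.log10(p)
    slope, intercept = np.polyfit(lx, lp, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((lp - pred) ** 2)
    ss_tot = np.sum((lp - lp.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2)


def fit_delta_K_power_law(values: Sequence[float], bins: int = 24) -> DistributionFit:
    """Fit the delta_K histogram to P = a*x^b + c and a log-log line.

    The log-log linear fit slope is the density exponent; a high R^2
    indicates power-law behavior of the shape-fluctuation marginal.
    Non-convergence or degenerate data is flagged, not raised.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < 30:
        return DistributionFit({}, np.nan, np.nan, False, "need >= 30 positive values")
    if np.ptp(v) <= 0:
        return DistributionFit({}, np.nan, np.nan, False, "constant data")
    x, p = _histogram_density(v, bins=bins, log_bins=True)
    if len(x) < 4:
        return DistributionFit({}, np.nan, np.nan, False, "too few occupied bins")
    slope, _, r2 = _loglog_linear(x, p)
    try:
        popt, _ = curve_fit(
            lambda xx, a, b, c: a * xx**b + c,
            x, p, p0=(p[0] * x[0] ** (-slope), slope, 0.0), maxfev=20000,
        )
        params = {"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])}
        ok = True
        msg = ""
    except RuntimeError as err:
        params, ok, msg = {}, False, str(err)
    return DistributionFit(params, slope, r2, ok, msg)


def fit_size_gaussian(values: Sequence[float], bins: int = 24) -> DistributionFit:
    """Fit the size histogram to a two-term Gaussian mixture shape.

    Also reports the log-log linear fit, whose low R^2 distinguishes
    Gaussian size marginals from power-law shape marginals.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 30:
        return DistributionFit({}, np.nan, np.nan, False, "need >= 30 values")
    if np.ptp(v) <= 0:
        return DistributionFit({}, np.nan, np.nan, False, "constant data")
    x, p = _histogram_density(v, bins=bins)
    slope, _, r2 = _loglog_linear(x[x > 0], p[x > 0]) if (x > 0).sum() >= 3 else (np.nan, np.nan, np.nan)

    def two_gauss(xx, a1, b1, c1, a2, b2, c2):
        return a1 * np.exp(-(((xx - b1) / c1) ** 2)) + a2 * np.exp(-(((xx - b2) / c2) ** 2))

    mu, sd = v.mean(), v.std()
    try:
        popt, _ = curve_fit(
            two_gauss, x, p,
            p0=(p.max(), mu - 0.5 * sd, sd, 0.5 * p.max(), mu + 0.5 * sd, sd),
            maxfev=20000,
        )
        params = dict(zip(("a1", "b1", "c1", "a2", "b2", "c2"), map(float, popt)))
        resid = p - two_gauss(x, *popt)
        ss_tot = np.sum((p - p.mean()) ** 2)
        params["fit_r2"] = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0
        ok = True
        msg = ""
    except RuntimeError as err:
        params, ok, msg = {}, False, str(err)
    return DistributionFit(params, slope, r2, ok, msg)


def fit_feature_space_curve(
    delta_K_tilde: Sequence[float], ell_tilde_inv: Sequence[float]
) -> dict:
    """Fit delta_K_tilde = alpha * (ell_tilde_inv)^beta in normalized space.

    Equivalently ``alpha * ell_tilde^-beta``.  Degenerate spread along
    either axis is flagged instead of fitted.
    """
    y = np.asarray(delta_K_tilde, float)
    x = np.asarray(ell_tilde_inv, float)
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        return {"ok": False, "message": "need >= 10 rows"}
    if np.ptp(np.log(x)) < 0.05 or np.ptp(np.log(y)) < 0.05:
        return {"ok": False, "message": "degenerate spread (single cluster)"}
    slope, intercept, _ = _loglog_linear(x, y)
    popt, _ = curve_fit(
        lambda xx, a, b: a * xx**b, x, y, p0=(10**intercept, slope), maxfev=20000
    )
    alpha, beta = float(popt[0]), float(popt[1])
    residuals = y - alpha * x**beta
    return {"ok": True, "alpha": alpha, "beta": beta, "residuals": residuals}


# -- classifiers --------------------------------------------------------


@dataclass
class ClassifierResult:
    """Accuracies and decision-boundary parameters of one model."""

    model_id: str
    accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    params: dict = field(default_factory=dict)


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(pred == truth))


class ThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Per-axis threshold classifier over ordered groups.

    One threshold separates each pair of adjacent groups along every
    feature axis.  ``mode='pooled_mean'`` places the threshold at the
    mean of the pooled values of the two adjacent groups;
    ``mode='midpoint_of_means'`` at the midpoint of the group means.
    With two feature axes the per-axis thresholds define a 3x3 grid of
    cells, resolved to classes by the nearest group centroid in
    standardized feature space (the published rule does not state a cell
    mapping, so nearest-centroid is the package's documented choice).
    """

    def __init__(self, mode: str = "pooled_mean", order: Sequence[str] = CLASS_ORDER):
        self.mode = mode
        self.order = order

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 1 and len(np.asarray(y)) != 1:
            X = X.T
        y = np.asarray(y)
        order = [g for g in self.order if g in set(y)]
        if len(order) < 2:
            raise ValueError("need at least two groups present")
        for g in order:
            if (y == g).sum() == 0:
                raise ValueError(f"empty group {g!r}")
        self.classes_ = np.asarray(order, dtype=object)
        n_axes = X.shape[1]
        thresholds = np.empty((n_axes, len(order) - 1))
        signs = np.ones(n_axes)
        for ax in range(n_axes):
            # orient each axis so group means increase with class order
            # (e.g. curvedness decreases with size, inverse-size increases)
            gmeans = [X[y == g, ax].mean() for g in order]
            if gmeans[-1] < gmeans[0]:
                signs[ax] = -1.0
            vals = signs[ax] * X[:, ax]
            for i, (g1, g2) in enumerate(zip(order[:-1], order[1:])):
                v1, v2 = vals[y == g1], vals[y == g2]
                if self.mode == "pooled_mean":
                    thresholds[ax, i] = np.concatenate([v1, v2]).mean()
                elif self.mode == "midpoint_of_means":
                    thresholds[ax, i] = 0.5 * (v1.mean() + v2.mean())
                else:
                    raise ValueError(f"unknown mode {self.mode!r}")
        self.thresholds_ = thresholds
        self.signs_ = signs
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        self.centroids_ = np.stack([X[y == g].mean(axis=0) for g in order])
        self.n_features_in_ = n_axes
        return self

    def _cells(self, X: np.ndarray) -> np.ndarray:
        """Per-axis ordinal cell index via the sorted thresholds."""
        cells = np.empty(X.shape, dtype=int)
        for ax in range(X.shape[1]):
            cells[:, ax] = np.searchsorted(
                np.sort(self.thresholds_[ax]), self.signs_[ax] * X[:, ax]
            )
        return cells

    def predict(self, X):
        check_is_fitted(self, "thresholds_")
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            X = X.T
        cells = self._cells(X)
        if self.n_features_in_ == 1:
            return self.classes_[cells[:, 0]]
        # map each grid cell to the class whose centroid cell-center is nearest
        pred = np.empty(len(X), dtype=object)
        agree = np.all(cells == cells[:, [0]], axis=1)
        pred[agree] = self.classes_[cells[agree, 0]]
        if (~agree).any():
            d = np.linalg.norm(
                (X[~agree, None, :] - self.centroids_[None, :, :]) / self.scale_, axis=2
            )
            pred[~agree] = self.classes_[np.argmin(d, axis=1)]
        return pred


def threshold_classifier(
    table: pd.DataFrame,
    features: Sequence[str],
    mode: str = "pooled_mean",
    group_col: str = "group",
    order: Sequence[str] = CLASS_ORDER,
) -> ClassifierResult:
    """In-sample accuracy of the threshold model (no train/test split)."""
    X = table[list(features)].to_numpy(float)
    y = table[group_col].to_numpy()
    clf = ThresholdClassifier(mode=mode, order=order).fit(X, y)
    acc = _accuracy(clf.predict(X), y)
    dims = len(features)
    return ClassifierResult(
        model_id="A" if (mode == "pooled_mean" and dims == 1) else
                 "B" if dims == 1 else "D",
        accuracies=np.array([acc]),
        mean_accuracy=acc,
        sd_accuracy=0.0,
        params={
            "thresholds": (clf.signs_[:, None] * clf.thresholds_).tolist(),
            "mode": mode,
        },
    )


def multinomial_logistic(
    table: pd.DataFrame,
    features: Sequence[str],
    n_permutations: int = 1000,
    split: float = 0.5,
    seed: int = 0,
    group_col: str = "group",
) -> ClassifierResult:
    """Multinomial logistic accuracy over random train/test permutations.

    Each permutation draws an unstratified random 50/50 split, fits an
    unregularized maximum-likelihood multinomial model on the training
    half, and scores the held-out half.  Splits that leave a class
    absent from training are redrawn.  Returns all per-split accuracies.
    """
    X = table[list(features)].to_numpy(float)
    y = table[group_col].to_numpy()
    classes = np.unique(y)
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 rows per group")
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round(split * n))
    accuracies = np.empty(n_permutations)
    redraws = 0
    for i in range(n_permutations):
        while True:
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(y[tr])) == len(classes) and len(te) > 0:
                break
            redraws += 1
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        clf.fit(X[tr], y[tr])
        accuracies[i] = _accuracy(clf.predict(X[te]), y[te])
    return ClassifierResult(
        model_id="C",
        accuracies=accuracies,
        mean_accuracy=float(accuracies.mean()),
        sd_accuracy=float(accuracies.std(ddof=0)),
        params={"n_redraws": redraws, "features": list(features)},
    )


class PenalizedSizeLogistic(BaseEstimator, ClassifierMixin):
    """Binomial logistic regression with an L1 penalty on the size axis.

    Minimizes the negative mean log-likelihood plus ``lambda_ *
    |beta_size|``, where the size coefficient is the one indexed by
    ``size_index`` (the shape coefficient and intercept are never
    penalized).  The non-smooth objective is solved exactly by splitting
    the penalized coefficient into positive and negative parts and
    running L-BFGS-B with box constraints.  At ``lambda_ = 0`` the fit
    coincides with unpenalized maximum likelihood; for large ``lambda_``
    the size coefficient shrinks to zero and the decision boundary
    becomes a pure-shape threshold.
    """

    def __init__(self, lambda_: float = 0.0, size_index: int = 1, tol: float = 1e-10):
        self.lambda_ = lambda_
        self.size_index = size_index
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary problem required")
        t = (y == self.classes_[1]).astype(float)
        n, p = X.shape
        si = self.size_index

        def unpack(z):
            beta = np.empty(p)
            free = [j for j in range(p) if j != si]
            beta[free] = z[1 : p]
            beta[si] = z[p] - z[p + 1]
            return z[0], beta

        def objective(z):
            b0, beta = unpack(z)
            eta = b0 + X @ beta
            # stable log(1 + e^eta)
            nll = np.mean(np.logaddexp(0.0, eta) - t * eta)
            return nll + self.lambda_ * (z[p] + z[p + 1])

        def grad(z):
            b0, beta = unpack(z)
            eta = b0 + X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            r = (mu - t) / n
            g_beta = X.T @ r
            g = np.empty(p + 2)
            g[0] = r.sum()
            free = [j for j in range(p) if j != si]
            g[1:p] = g_beta[free]
            g[p] = g_beta[si] + self.lambda_
            g[p + 1] = -g_beta[si] + self.lambda_
            return g

        z0 = np.zeros(p + 2)
        bounds = [(None, None)] * p + [(0, None), (0, None)]
        res = minimize(
            objective, z0, jac=grad, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 5000, "ftol": self.tol, "gtol": 1e-10},
        )
        self.converged_ = bool(res.success)
        self.intercept_, self.coef_ = unpack(res.x)
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, float) @ self.coef_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def lasso_boundary_sweep(
    table: pd.DataFrame,
    lambdas: Optional[np.ndarray] = None,
    features: Sequence[str] = ("delta_K_tilde", "ell_tilde_inv"),
    size_feature: str = "ell_tilde_inv",
    group_col: str = "group",
    order: Sequence[str] = CLASS_ORDER,
) -> ClassifierResult:
    """Sweep the size-coefficient penalty over a lambda grid (model E).

    Two binary boundaries (normal vs success, success vs failed) are
    refit at each lambda; the report carries the per-lambda 3-class
    accuracy, the boundary coefficients, and the interquartile band of
    the boundary position along the shape axis.  Non-convergent fits
    are skipped with a warning entry.
    """
    if lambdas is None:
        lambdas = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 19)])
    feats = list(features)
    si = feats.index(size_feature)
    X = table[feats].to_numpy(float)
    y = table[group_col].to_numpy()
    pairs = [(order[0], order[1]), (order[1], order[2])]

    accuracies, boundaries, skipped = [], [], []
    for lam in lambdas:
        models = []
        ok = True
        for g1, g2 in pairs:
            m = (y == g1) | (y == g2)
            clf = PenalizedSizeLogistic(lambda_=float(lam), size_index=si)
            clf.fit(X[m], y[m])
            if not clf.converged_:
                ok = False
                break
            models.append(clf)
        if not ok:
            skipped.append(float(lam))
            continue
        # 3-class rule from the two ordered boundaries: the distal
        # boundary decides membership in the last group, otherwise the
        # proximal boundary separates the first two
        p01 = models[0].predict(X)
        p12 = models[1].predict(X)
        pred = np.where(p12 == order[2], order[2], np.where(p01 == order[1], order[1], order[0]))
        accuracies.append(_accuracy(pred, y))
        boundaries.append(
            [
                {
                    "intercept": float(m.intercept_),
                    "coef": m.coef_.tolist(),
                }
                for m in models
            ]
        )
    acc = np.asarray(accuracies)
    # boundary position on the shape axis at the mean size, per lambda
    shape_idx = 1 - si
    mean_size = float(X[:, si].mean())
    crossings = []
    for bset in boundaries:
        b = bset[1]  # success/failed boundary
        coef = np.asarray(b["coef"])
        if abs(coef[shape_idx]) > 1e-12:
            crossings.append(-(b["intercept"] + coef[si] * mean_size) / coef[shape_idx])
    band = (
        tuple(np.percentile(crossings, [25, 75])) if crossings else (np.nan, np.nan)
    )
    return ClassifierResult(
        model_id="E",
        accuracies=acc,
        mean_accuracy=float(acc.mean()) if len(acc) else np.nan,
        sd_accuracy=float(acc.std(ddof=0)) if len(acc) else np.nan,
        params={
            "lambdas": np.asarray(lambdas).tolist(),
            "boundaries": boundaries,
            "skipped": skipped,
            "boundary_iqr_shape_axis": band,
        },
    )
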