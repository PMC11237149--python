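"""Decomposition and classifiers on PC scores.

PCA is a mean-centered singular value decomposition with a fixed sign
convention; component selection keeps the smallest number of PCs whose
cumulative explained variance reaches a threshold (99% by default), and
Hotelling's T-squared in score space flags outlying spectra.

The discriminant classifiers are implemented from their defining math:
LDA and QDA are Gaussian discriminants (shared pooled covariance vs
per-class covariances) with empirical priors, and the SVM solves the
soft-margin dual problem directly (linear or RBF kernel; one-vs-one with
majority vote for more than two classes).  scikit-learn is deliberately
not used here — it serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import f as f_dist

#: ridge added to near-singular covariances, as a fraction of trace/dim
RIDGE = 1e-8


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Mean-centered PCA: scores = (X - mean) @ loadings.

    ``explained_pct`` covers the full decomposition (sums to 100 for
    non-degenerate data) even when fewer component columns are retained.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray        # (n_features, k)
    scores: np.ndarray          # (n_samples, k)
    explained_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(x, dtype=float)) - self.mean_spectrum) @ self.loadings


def pca_fit(data, max_components: int | None = None) -> PCAModel:
    """Fit PCA by SVD of the column-centered matrix.

    Accepts a SpectraSet or a plain ``(n_samples, n_features)`` matrix.
    Deterministic up to sign, fixed by making the largest-magnitude entry
    of each loading column positive.
    """
    x = data.absorbance if hasattr(data, "absorbance") else np.asarray(data, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("zero variance: all spectra identical")
    explained = 100.0 * s**2 / total
    k = min(n - 1, x.shape[1]) if max_components is None else min(max_components, s.size)
    k = max(k, 1)
    loadings = vt[:k].T.copy()
    # sign convention: largest-|value| loading entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    scores = xc @ loadings
    return PCAModel(mean, loadings, scores, explained)


def select_components(model: PCAModel, threshold_pct: float = 99.0) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold."""
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must be in (0, 100]")
    cum = np.cumsum(model.explained_pct)
    k = int(np.searchsorted(cum, threshold_pct - 1e-9)) + 1
    return min(max(k, 1), model.n_components)


def hotelling_t2(model: PCAModel, k: int, alpha: float = 0.05):
    """Hotelling T-squared per spectrum in the first k score dimensions.

    T2_i = sum_j score_ij^2 / var_j (sample variance per component); the
    control limit is k(n-1)/(n-k) * F_{1-alpha}(k, n-k).  Returns
    ``(t2, limit, flags)`` with flags True where T2 exceeds the limit.
    """
    n = model.scores.shape[0]
    if k > model.n_components:
        raise ValueError("k exceeds the number of fitted components")
    if n <= k:
        raise ValueError("need more samples than components for the T2 limit")
    sc = model.scores[:, :k]
    var = sc.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise ValueError("zero-variance score component")
    t2 = np.sum(sc**2 / var, axis=1)
    limit = k * (n - 1) / (n - k) * f_dist.ppf(1 - alpha, k, n - k)
    return t2, float(limit), t2 > limit


# ---------------------------------------------------------------------------
# Gaussian discriminants


def _regularized(cov: np.ndarray, context: str) -> np.ndarray:
    """Ridge a covariance toward invertibility; raise if hopeless."""
    dim = cov.shape[0]
    cov = 0.5 * (cov + cov.T)
    try:
        np.linalg.cholesky(cov)
        if np.linalg.cond(cov) < 1e12:
            return cov
    except np.linalg.LinAlgError:
        pass
    ridge = RIDGE * max(np.trace(cov) / dim, 1e-300)
    cov = cov + ridge * np.eye(dim)
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        raise ValueError(
            f"singular covariance in {context} even after ridge "
            f"({dim} dimensions)"
        ) from None


@dataclass
class DiscriminantModel:
    """Gaussian discriminant: shared (LDA) or per-class (QDA) covariance."""

    kind: str                    # "LDA" | "QDA"
    class_names: list[str]
    class_means: np.ndarray      # (n_classes, dim)
    covariances: np.ndarray      # (dim, dim) pooled, or (n_classes, dim, dim)
    priors: np.ndarray

    def discriminants(self, x: np.ndarray) -> np.ndarray:
        """Log-discriminant score per class, up to a shared constant."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], len(self.class_names)))
        if self.kind == "LDA":
            cov_inv = np.linalg.inv(self.covariances)
            for j, mu in enumerate(self.class_means):
                w = cov_inv @ mu
                out[:, j] = x @ w - 0.5 * mu @ w + np.log(self.priors[j])
        else:
            for j, mu in enumerate(self.class_means):
                cov = self.covariances[j]
                sign, logdet = np.linalg.slogdet(cov)
                d = x - mu
                maha = np.sum(d @ np.linalg.inv(cov) * d, axis=1)
                out[:, j] = np.log(self.priors[j]) - 0.5 * logdet - 0.5 * maha
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        # argmax takes the first maximum: ties resolve to the first class in
        # sorted class-name order (class_names is sorted at fit time)
        scores = self.discriminants(x)
        return np.asarray(self.class_names, dtype=object)[np.argmax(scores, axis=1)]


def _check_classes(labels: np.ndarray) -> list[str]:
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return classes


def lda_fit(scores: np.ndarray, labels, priors: str = "empirical") -> DiscriminantModel:
    """Gaussian discriminant with pooled covariance Sum_c (n_c-1) S_c / (n-C)."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = _check_classes(labels)
    n, dim = x.shape
    means, pooled, counts = [], np.zeros((dim, dim)), []
    for c in classes:
        xc = x[labels == c]
        counts.append(len(xc))
        mu = xc.mean(axis=0)
        means.append(mu)
        d = xc - mu
        pooled += d.T @ d
    pooled /= (n - len(classes))
    pooled = _regularized(pooled, "LDA pooled covariance")
    pr = np.array(counts, dtype=float) / n if priors == "empirical" \
        else np.full(len(classes), 1.0 / len(classes))
    return DiscriminantModel("LDA", classes, np.vstack(means), pooled, pr)


def lda_predict(model: DiscriminantModel, scores: np.ndarray) -> np.ndarray:
    return model.predict(scores)


def qda_fit(scores: np.ndarray, labels, priors: str = "empirical") -> DiscriminantModel:
    """Gaussian discriminant with one covariance per class (ridged as needed)."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = _check_classes(labels)
    means, covs, counts = [], [], []
    for c in classes:
        xc = x[labels == c]
        counts.append(len(xc))
        mu = xc.mean(axis=0)
        means.append(mu)
        d = xc - mu
        cov = d.T @ d / (len(xc) - 1)
        covs.append(_regularized(cov, f"QDA covariance of class {c!r}"))
    pr = np.array(counts, dtype=float) / x.shape[0] if priors == "empirical" \
        else np.full(len(classes), 1.0 / len(classes))
    return DiscriminantModel("QDA", classes, np.vstack(means), np.stack(covs), pr)


def qda_predict(model: DiscriminantModel, scores: np.ndarray) -> np.ndarray:
    return model.predict(scores)


# ---------------------------------------------------------------------------
# Support vector machine

#: canonical numeric class codes used for the calibration R2/RMSEC report
_CODE_ORDER = ("healthy", "IBD", "UC", "CD")


def class_codes(classes: Sequence[str]) -> dict[str, int]:
    """Deterministic class -> numeric code map (healthy=0, then disease labels)."""
    ordered = [c for c in _CODE_ORDER if c in classes]
    ordered += [c for c in sorted(classes) if c not in ordered]
    return {c: i for i, c in enumerate(ordered)}


def _kernel(a: np.ndarray, b: np.ndarray, kernel: str, gamma: float) -> np.ndarray:
    if kernel == "linear":
        return a @ b.T
    if kernel == "rbf":
        d2 = np.sum(a**2, axis=1)[:, None] + np.sum(b**2, axis=1)[None, :] - 2 * a @ b.T
        return np.exp(-gamma * np.maximum(d2, 0.0))
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class _BinarySVM:
    """One maximum-margin separator from the soft-margin dual problem."""

    support_x: np.ndarray
    dual_coef: np.ndarray        # alpha_i * y_i over support vectors
    bias: float

    def decision(self, x: np.ndarray, kernel: str, gamma: float) -> np.ndarray:
        return _kernel(np.atleast_2d(x), self.support_x, kernel, gamma) @ self.dual_coef + self.bias


def _solve_binary(x: np.ndarray, y: np.ndarray, kernel: str, c: float, gamma: float) -> _BinarySVM:
    """Solve max sum(a) - 1/2 a^T Q a, 0 <= a <= C, a.y = 0 (Q = y y^T K)."""
    n = x.shape[0]
    k = _kernel(x, x, kernel, gamma)
    q = (y[:, None] * y[None, :]) * k
    q = q + 1e-10 * np.eye(n)  # keep the QP strictly convex

    def obj(a):
        return 0.5 * a @ q @ a - a.sum()

    def jac(a):
        return q @ a - 1.0

    res = optimize.minimize(
        obj, x0=np.zeros(n), jac=jac, method="SLSQP",
        bounds=[(0.0, c)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    alpha = np.clip(res.x, 0.0, c)
    sv = alpha > 1e-8
    if not sv.any():
        sv = np.ones(n, dtype=bool)
    dual = alpha[sv] * y[sv]
    k_sv = k[np.ix_(sv, sv)]
    # bias from margin support vectors (0 < alpha < C), else KKT midpoint
    inside = (alpha[sv] > 1e-6) & (alpha[sv] < c - 1e-6)
    f_no_b = k_sv @ dual
    if inside.any():
        bias = float(np.mean(y[sv][inside] - f_no_b[inside]))
    else:
        f_all = k[:, sv] @ dual
        lo = np.max((y * 1.0 - f_all)[(y > 0) & (alpha < c - 1e-6) | (y < 0) & (alpha > 1e-6)],
                    initial=-np.inf)
        hi = np.min((y * 1.0 - f_all)[(y < 0) & (alpha < c - 1e-6) | (y > 0) & (alpha > 1e-6)],
                    initial=np.inf)
        bias = float(np.clip(0.0, lo, hi)) if np.isfinite(lo) and np.isfinite(hi) \
            else float(np.mean(y - f_all))
    return _BinarySVM(x[sv].copy(), dual, bias)


@dataclass
class SVMModel:
    """Soft-margin SVM; one-vs-one majority vote for more than two classes.

    Scores are standardized with training-set statistics before the margin
    problem is solved (soft margins are scale-sensitive; PC scores can be
    orders of magnitude below the unit margin).
    """

    kernel: str
    c: float
    gamma: float
    class_names: list[str]
    codes: dict[str, int]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    machines: dict[tuple[str, str], _BinarySVM] = field(default_factory=dict)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if self.center is None:
            return x
        return (x - self.center) / self.scale

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = self._standardize(np.atleast_2d(np.asarray(x, dtype=float)))
        votes = np.zeros((x.shape[0], len(self.class_names)))
        sums = np.zeros_like(votes)
        idx = {c: i for i, c in enumerate(self.class_names)}
        for (a, b), m in self.machines.items():
            dec = m.decision(x, self.kernel, self.gamma)
            votes[:, idx[a]] += dec > 0
            votes[:, idx[b]] += dec <= 0
            sums[:, idx[a]] += dec
            sums[:, idx[b]] -= dec
        # majority vote; ties broken by summed decision values
        best = votes + 1e-9 * np.tanh(sums)
        return np.asarray(self.class_names, dtype=object)[np.argmax(best, axis=1)]


def svm_fit(scores: np.ndarray, labels, kernel: str = "linear",
            c: float = 1.0, gamma: float | str = "scale",
            standardize: bool = True) -> SVMModel:
    """Fit one-vs-one soft-margin SVMs on the score matrix."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if c <= 0:
        raise ValueError("C must be positive")
    center = scale = None
    if standardize:
        center = x.mean(axis=0)
        scale = x.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        x = (x - center) / scale
    if gamma == "scale":
        v = x.var()
        gamma_val = 1.0 / (x.shape[1] * v) if v > 0 else 1.0
    else:
        gamma_val = float(gamma)
    model = SVMModel(kernel, c, gamma_val, classes, class_codes(classes),
                     center=center, scale=scale)
    for a, b in combinations(classes, 2):
        mask = (labels == a) | (labels == b)
        y = np.where(labels[mask] == a, 1.0, -1.0)
        model.machines[(a, b)] = _solve_binary(x[mask], y, kernel, c, gamma_val)
    return model


def svm_predict(model: SVMModel, scores: np.ndarray) -> np.ndarray:
    return model.predict(scores)


def svm_regression_stats(model: SVMModel, scores: np.ndarray, labels) -> tuple[float, float]:
    """Calibration R2 (%) and RMSEC between true and fitted numeric class codes.

    Classes are coded healthy=0 then disease labels in canonical order; the
    model's predicted classes on the calibration set are mapped to the same
    codes and compared as a regression (R2 = 100 for a perfect fit).
    """
    labels = np.asarray(labels)
    y_true = np.array([model.codes[c] for c in labels], dtype=float)
    y_fit = np.array([model.codes[c] for c in model.predict(scores)], dtype=float)
    ss_res = float(np.sum((y_true - y_fit) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 100.0 * (1.0 - ss_res / ss_tot) if ss_tot > 0 else (100.0 if ss_res == 0 else 0.0)
    rmsec = float(np.sqrt(ss_res / len(y_true)))
    return r2, rmsec
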