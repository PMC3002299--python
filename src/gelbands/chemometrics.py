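"""Multivariate discrimination of aligned fingerprints.

The aligned lane profiles form a lanes x 731 matrix.  Group structure is
modelled with Partial Least Squares Discriminant Analysis (PLS-DA): a
NIPALS PLS2 regression of the profiles onto one-hot class indicators,
validated by *leave-sample-out* cross-validation in which all replicate
lanes of a biological sample are held out together (the sample, not the
lane, is the statistical unit).  Significance of the classification
success rate is assessed by y-scrambling: class labels are permuted at
the sample level and the cross-validated success recomputed to build the
null distribution.  Canonical Variate Analysis (CVA) of the PLS scores
gives the optimal two-dimensional view of a three-group structure, and
the first-component loadings rank the bands driving the separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, signal, stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS2 discriminant classifier (NIPALS), sklearn-compatible.

    The response is the one-hot class indicator matrix; X and Y are
    column-centered (no column autoscaling -- lanes are already 0-1
    scaled).  Prediction maps a profile to indicator scores and assigns
    the argmax class.  Score vectors of successive components are
    mutually orthogonal; weight vectors have unit norm.

    Parameters
    ----------
    n_components : int
        Number of latent components to extract.
    max_iter, tol : NIPALS inner-loop controls (relative change of the
        weight vector).
    """

    def __init__(self, n_components: int = 4, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if np.any(~np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        g = self.classes_.size
        Y = np.zeros((n, g))
        Y[np.arange(n), y_idx] = 1.0

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xd = X - self.x_mean_
        Yd = Y - self.y_mean_

        max_rank = min(n - 1, p)
        if self.n_components > max_rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank bound "
                f"min(n_samples - 1, n_features) = {max_rank}"
            )

        W = np.empty((p, self.n_components))
        P = np.empty((p, self.n_components))
        Q = np.empty((g, self.n_components))
        T = np.empty((n, self.n_components))
        x_tot = float(np.sum(Xd * Xd))
        eps = np.finfo(float).eps
        for a in range(self.n_components):
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
            if np.sum(u * u) < eps * max(x_tot, 1.0):
                raise ValueError(
                    f"Y residual exhausted after {a} components; "
                    f"n_components={self.n_components} exceeds the data rank"
                )
            w = np.zeros(p)
            for _ in range(self.max_iter):
                w_new = Xd.T @ u
                norm = np.linalg.norm(w_new)
                if norm < eps:
                    raise ValueError(
                        f"X residual exhausted after {a} components; "
                        f"n_components={self.n_components} exceeds the data rank"
                    )
                w_new /= norm
                t = Xd @ w_new
                tt = t @ t
                q = Yd.T @ t / tt
                u = Yd @ q / (q @ q)
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w = w_new
            t = Xd @ w
            tt = t @ t
            if tt < eps * max(x_tot, 1.0) * 1e-8:
                raise ValueError(
                    f"degenerate component {a + 1}: n_components exceeds the data rank"
                )
            pvec = Xd.T @ t / tt
            q = Yd.T @ t / tt
            Xd = Xd - np.outer(t, pvec)
            Yd = Yd - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = Q
        self.x_scores_ = T
        self.n_features_in_ = p
        return self

    def _rotations(self, n_components: int) -> np.ndarray:
        W = self.x_weights_[:, :n_components]
        P = self.x_loadings_[:, :n_components]
        return W @ np.linalg.inv(P.T @ W)

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        """Latent scores of new profiles (first ``n_components`` columns)."""
        check_is_fitted(self, "x_weights_")
        k = n_components or self.n_components
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self._rotations(k)

    def decision_function(self, X, n_components: int | None = None) -> np.ndarray:
        """Predicted class-indicator values (linear map to Y-space)."""
        check_is_fitted(self, "x_weights_")
        k = n_components or self.n_components
        R = self._rotations(k)
        B = R @ self.y_loadings_[:, :k].T
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ B + self.y_mean_

    def predict(self, X, n_components: int | None = None):
        scores = self.decision_function(X, n_components)
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# grouped cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Leave-sample-out cross-validation outcome."""

    components: np.ndarray  # 1..K
    success_rates: np.ndarray  # per component count, fraction of samples
    best_k: int  # first local maximum of the curve
    predictions: pd.DataFrame  # sample_id, group, predicted (at best_k)
    segments: list[list[int]]  # lane indices per held-out sample
    models: list  # fitted fold models (training-segment PLS fits)


def first_local_maximum(rates: np.ndarray) -> int:
    """1-based component count of the first local maximum (ties -> fewer)."""
    rates = np.asarray(rates, float)
    for k in range(rates.size - 1):
        if rates[k] >= rates[k + 1]:
            return k + 1
    return rates.size


def _check_segments(y: np.ndarray, sample_ids: np.ndarray) -> list[np.ndarray]:
    samples = pd.unique(sample_ids)
    segs = []
    for s in samples:
        test = np.flatnonzero(sample_ids == s)
        train_classes = set(y[np.setdiff1d(np.arange(y.size), test)])
        if set(np.unique(y)) - train_classes:
            raise ValueError(
                f"holding out sample {s!r} removes an entire class from training"
            )
        segs.append(test)
    return segs


def cross_validate(
    X,
    y,
    sample_ids,
    max_components: int = 10,
    keep_models: bool = True,
) -> CVResult:
    """Leave-sample-out PLS-DA cross-validation over 1..max_components.

    Replicate lanes of a sample are always held out together; the
    held-out lanes' predicted indicator vectors are averaged and the
    sample is assigned the argmax class.  The success rate at each
    component count is the fraction of correctly assigned samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sample_ids = np.asarray(sample_ids)
    segments = _check_segments(y, sample_ids)
    n_samples = len(segments)
    classes = np.unique(y)

    correct = np.zeros((max_components, n_samples), dtype=bool)
    predicted = np.empty((max_components, n_samples), dtype=object)
    truth = []
    models = []
    for si, test in enumerate(segments):
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        k_max = min(max_components, train.size - 1)
        model = PLSDAClassifier(n_components=k_max).fit(X[train], y[train])
        if keep_models:
            models.append(model)
        truth.append(y[test[0]])
        for k in range(1, max_components + 1):
            kk = min(k, k_max)
            scores = model.decision_function(X[test], n_components=kk).mean(axis=0)
            pred = model.classes_[int(np.argmax(scores))]
            predicted[k - 1, si] = pred
            correct[k - 1, si] = pred == truth[-1]

    rates = correct.mean(axis=1)
    best_k = first_local_maximum(rates)
    samples = pd.unique(sample_ids)
    preds = pd.DataFrame(
        {
            "sample_id": samples,
            "group": truth,
            "predicted": predicted[best_k - 1, :],
        }
    )
    return CVResult(
        components=np.arange(1, max_components + 1),
        success_rates=rates,
        best_k=best_k,
        predictions=preds,
        segments=[list(s) for s in segments],
        models=models,
    )


# ---------------------------------------------------------------------------
# permutation (y-scrambling) test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    n_resamples: int
    null_rates: np.ndarray
    observed_rate: float
    p_empirical: float
    p_tail: float  # Gaussian tail estimate for below-resolution p values

    def __post_init__(self) -> None:
        assert self.p_empirical >= 1.0 / (self.n_resamples + 1) - 1e-12


def _loso_success_at_k(X, y, segments, k: int) -> float:
    n_ok = 0
    for test in segments:
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        kk = min(k, train.size - 1)
        model = PLSDAClassifier(n_components=kk).fit(X[train], y[train])
        scores = model.decision_function(X[test]).mean(axis=0)
        if model.classes_[int(np.argmax(scores))] == y[test[0]]:
            n_ok += 1
    return n_ok / len(segments)


def permutation_test(
    X,
    y,
    sample_ids,
    n_components: int,
    n_resamples: int = 1000,
    seed=None,
) -> PermutationResult:
    """y-scrambling null distribution of the cross-validated success rate.

    Labels are permuted at the *sample* level (replicate lanes keep their
    sample's permuted label), the leave-sample-out success at
    ``n_components`` recomputed per resample.  The empirical p value is
    (1 + #{null >= observed}) / (n_resamples + 1); a Gaussian fit to the
    null provides a tail estimate for results beyond the empirical
    resolution of the resample count.
    """
    if n_resamples < 20:
        raise ValueError("n_resamples must be at least 20")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sample_ids = np.asarray(sample_ids)
    rng = np.random.default_rng(seed)

    segments = _check_segments(y, sample_ids)
    observed = _loso_success_at_k(X, y, segments, n_components)

    samples = pd.unique(sample_ids)
    sample_labels = np.array([y[sample_ids == s][0] for s in samples])
    lane_sample_idx = pd.Index(samples).get_indexer(sample_ids)
    null = np.empty(n_resamples)
    for r in range(n_resamples):
        perm = rng.permutation(sample_labels)
        y_perm = perm[lane_sample_idx]
        try:
            segs = _check_segments(y_perm, sample_ids)
            null[r] = _loso_success_at_k(X, y_perm, segs, n_components)
        except ValueError:
            null[r] = np.nan
    null = null[np.isfinite(null)]
    p_emp = (1.0 + np.sum(null >= observed)) / (null.size + 1.0)
    sd = null.std(ddof=1)
    p_tail = float(stats.norm.sf((observed - null.mean()) / sd)) if sd > 0 else p_emp
    return PermutationResult(
        n_resamples=null.size,
        null_rates=null,
        observed_rate=observed,
        p_empirical=float(p_emp),
        p_tail=p_tail,
    )


# ---------------------------------------------------------------------------
# canonical variate analysis
# ---------------------------------------------------------------------------

class CanonicalVariateAnalysis(BaseEstimator, TransformerMixin):
    """CVA / multi-group linear discriminant projection.

    Canonical directions are eigenvectors of (within-group scatter)^-1
    (between-group scatter), ordered by eigenvalue; at most
    ``min(n_groups - 1, n_features)`` variates exist.  A tiny ridge is
    added to a singular within-group scatter (with a warning).
    """

    def __init__(self, n_components: int = 2, ridge: float = 1e-8):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        g, p = self.classes_.size, X.shape[1]
        self.mean_ = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        for c in self.classes_:
            Xc = X[y == c]
            mc = Xc.mean(axis=0)
            d = Xc - mc
            Sw += d.T @ d
            diff = (mc - self.mean_)[:, None]
            Sb += Xc.shape[0] * (diff @ diff.T)
        try:
            linalg.cholesky(Sw)
        except linalg.LinAlgError:
            warnings.warn(
                "singular within-group scatter; adding ridge", stacklevel=2
            )
            Sw = Sw + self.ridge * np.trace(Sw) * np.eye(p)
        evals, evecs = linalg.eigh(Sb, Sw)
        order = np.argsort(evals)[::-1]
        k = min(self.n_components, g - 1, p)
        self.eigenvalues_ = evals[order][:k]
        self.directions_ = evecs[:, order][:, :k]
        self.centroids_ = np.vstack(
            [((X[y == c]).mean(axis=0) - self.mean_) @ self.directions_ for c in self.classes_]
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "directions_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.directions_


@dataclass
class CVAProjection:
    scores: np.ndarray  # (n_lanes, 2) canonical scores
    directions: np.ndarray  # canonical directions in PLS-score space
    centroids: pd.DataFrame  # group, cv1, cv2
    classes: np.ndarray


def fit_cva(pls_scores, labels, n_components: int = 2) -> CVAProjection:
    """CVA projection of PLS score columns (full-data fit)."""
    cva = CanonicalVariateAnalysis(n_components=n_components).fit(pls_scores, labels)
    scores = cva.transform(pls_scores)
    cent = pd.DataFrame(cva.centroids_, columns=[f"cv{i+1}" for i in range(scores.shape[1])])
    cent.insert(0, "group", cva.classes_)
    return CVAProjection(
        scores=scores,
        directions=cva.directions_,
        centroids=cent,
        classes=cva.classes_,
    )


def cross_validated_cva(
    X, y, sample_ids, n_pls_components: int = 4
) -> tuple[np.ndarray, CVAProjection]:
    """Leave-sample-out CVA scores: each held-out sample's lanes are
    projected through the training fold's PLS + CVA maps.

    Returns the per-lane cross-validated 2-D scores and the full-data
    projection (for centroids/directions).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sample_ids = np.asarray(sample_ids)
    segments = _check_segments(y, sample_ids)
    cv_scores = np.zeros((X.shape[0], 2))
    for test in segments:
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        pls = PLSDAClassifier(n_components=n_pls_components).fit(X[train], y[train])
        cva = CanonicalVariateAnalysis(n_components=2).fit(
            pls.transform(X[train]), y[train]
        )
        cv_scores[test] = cva.transform(pls.transform(X[test]))
    pls_full = PLSDAClassifier(n_components=n_pls_components).fit(X, y)
    full = fit_cva(pls_full.transform(X), y)
    return cv_scores, full


# ---------------------------------------------------------------------------
# discriminant-band ranking
# ---------------------------------------------------------------------------

@dataclass
class BandRanking:
    table: pd.DataFrame  # rank, rf, mean_loading, range_low, range_high
    consistent: bool  # same top-n positions rank top in every segment


def _loading_peaks(values: np.ndarray, distance: int) -> np.ndarray:
    idx, _ = signal.find_peaks(values, distance=distance)
    return idx


def rank_discriminant_bands(
    cv_models: list[PLSDAClassifier],
    rf_axis: np.ndarray,
    top_n: int = 4,
    min_separation: float = 0.004,
    tolerance: float = 0.008,
) -> BandRanking:
    """Rank bands by the first-component loading magnitude across folds.

    The first PLS loading from every cross-validation training segment is
    sign-aligned, averaged, and peak-picked; peaks are ranked by height.
    Stability is reported as the min-max range of |loading| across
    segments at each ranked position, and the consistency flag records
    whether the same ``top_n`` positions (within ``tolerance`` Rf) rank
    top in every segment.
    """
    rf_axis = np.asarray(rf_axis, float)
    if top_n == 0 or not cv_models:
        return BandRanking(
            table=pd.DataFrame(
                columns=["rank", "rf", "mean_loading", "range_low", "range_high"]
            ),
            consistent=bool(cv_models),
        )
    L = np.stack([m.x_loadings_[:, 0] for m in cv_models])
    ref = L[0]
    signs = np.sign(L @ ref)
    signs[signs == 0] = 1.0
    L = L * signs[:, None]
    mean_abs = np.abs(L.mean(axis=0))
    absL = np.abs(L)

    step = float(np.median(np.diff(rf_axis)))
    distance = max(1, int(round(min_separation / step)))
    peaks = _loading_peaks(mean_abs, distance)
    if peaks.size < top_n:
        warnings.warn(
            f"only {peaks.size} loading peaks found (top_n={top_n})", stacklevel=2
        )
    order = peaks[np.argsort(mean_abs[peaks])[::-1]][:top_n]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, order.size + 1),
            "rf": rf_axis[order],
            "mean_loading": mean_abs[order],
            "range_low": absL[:, order].min(axis=0),
            "range_high": absL[:, order].max(axis=0),
        }
    )

    top_rfs = np.sort(rf_axis[order])
    consistent = True
    for f in range(L.shape[0]):
        fold_peaks = _loading_peaks(absL[f], distance)
        if fold_peaks.size < order.size:
            consistent = False
            break
        fold_top = fold_peaks[np.argsort(absL[f][fold_peaks])[::-1]][: order.size]
        fold_rfs = np.sort(rf_axis[fold_top])
        if fold_rfs.size != top_rfs.size or np.any(np.abs(fold_rfs - top_rfs) > tolerance):
            consistent = False
            break
    return BandRanking(table=table, consistent=consistent)
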