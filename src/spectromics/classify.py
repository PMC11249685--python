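"""Classification of patient fingerprints: PCA-LDA and cross-validated SVM.

The estimation API follows the model/results convention: ``PCALDA(X, y)``
holds the data and design, ``.fit(n_pcs)`` returns a :class:`PCALDAResults`
carrying the estimates (centering vector, PC loadings, explained variance,
discriminant weights, class statistics), diagnostics (Mahalanobis
separation, resubstitution confusion counts and quality parameters) and a
``summary()`` table. ``SpectromicsSVM(X, y, config)`` wraps a Gaussian-kernel
support vector machine with nested grid search; ``.cross_validate()``
returns accumulated-hit confusion counts and quality parameters.

The positive class is OA, the negative class Control, throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .spectrum import CONTROL, OA

# ---------------------------------------------------------------------------
# confusion counts and quality parameters
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """Accumulated hits. Positive class = OA, negative class = Control."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.sum((y_true == OA) & (y_pred == OA))),
            tn=int(np.sum((y_true == CONTROL) & (y_pred == CONTROL))),
            fp=int(np.sum((y_true == CONTROL) & (y_pred == OA))),
            fn=int(np.sum((y_true == OA) & (y_pred == CONTROL))),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def rates(self) -> np.ndarray:
        """Row-normalized 2x2 rate matrix, rows = true (Control, OA),
        columns = predicted (Control, OA), in percent."""
        m = np.array(
            [[self.tn, self.fp], [self.fn, self.tp]], dtype=float
        )
        sums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * m / sums, np.nan)


@dataclass(frozen=True)
class QualityReport:
    """Accuracy, sensitivity (OA recall), specificity (Control recall) and
    their harmonic-mean F-score, all in percent."""

    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float

    def rounded(self, ndigits: int = 1) -> "QualityReport":
        return QualityReport(
            *(round(v, ndigits) for v in
              (self.accuracy, self.sensitivity, self.specificity,
               self.f_score))
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_score": self.f_score,
        }


def quality_parameters(counts: ConfusionCounts) -> QualityReport:
    """Quality parameters from accumulated hits.

    accuracy    = (TP+TN) / (TP+FP+TN+FN) * 100
    sensitivity = TP / (TP+FN) * 100
    specificity = TN / (TN+FP) * 100
    f_score     = 2 * SENS * SPEC / (SENS + SPEC)   (0 when SENS+SPEC = 0)
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive (OA) samples: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative (Control) samples: specificity undefined")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    sens = 100.0 * counts.tp / (counts.tp + counts.fn)
    spec = 100.0 * counts.tn / (counts.tn + counts.fp)
    f = 2.0 * sens * spec / (sens + spec) if sens + spec > 0 else 0.0
    return QualityReport(acc, sens, spec, f)


# ---------------------------------------------------------------------------
# PCA-LDA
# ---------------------------------------------------------------------------


def _as_labels(y) -> np.ndarray:
    y = np.asarray(y)
    bad = set(np.unique(y)) - {CONTROL, OA}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return y


def fit_pca(X: np.ndarray, n_components: int) -> PCA:
    """Mean-centered PCA with components by descending explained variance.

    Thin wrapper fixing the solver so that scores are exactly
    (X - center) @ loadings.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}] for data of shape"
            f" {X.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return pca


@dataclass
class LDAonScores:
    """Fisher discriminant over PC scores with pooled within-class
    covariance. Prediction assigns the nearer class mean along the
    discriminant; exact ties go to Control (the negative class)."""

    class_means: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    weights: np.ndarray
    ridge_applied: float = 0.0

    @classmethod
    def fit(cls, scores: np.ndarray, y) -> "LDAonScores":
        scores = np.asarray(scores, dtype=float)
        y = _as_labels(y)
        if scores.ndim == 1:
            scores = scores[:, None]
        groups = {c: scores[y == c] for c in (CONTROL, OA)}
        for c, g in groups.items():
            if len(g) < 2:
                raise ValueError(f"class {c!r} needs at least 2 samples")
        k = scores.shape[1]
        n = scores.shape[0]
        means = {c: g.mean(axis=0) for c, g in groups.items()}
        sw = np.zeros((k, k))
        for c, g in groups.items():
            d = g - means[c]
            sw += d.T @ d
        sw /= n - 2  # pooled within-class covariance
        ridge = 0.0
        try:
            weights = np.linalg.solve(sw, means[OA] - means[CONTROL])
            if not np.all(np.isfinite(weights)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(sw) / k
            if ridge == 0.0:
                ridge = 1e-8
            sw = sw + ridge * np.eye(k)
            weights = np.linalg.solve(sw, means[OA] - means[CONTROL])
        return cls(means, sw, weights, ridge)

    def discriminant(self, scores: np.ndarray) -> np.ndarray:
        """Signed discriminant coordinate in Mahalanobis units (the class
        mean difference along this coordinate equals the Mahalanobis
        distance between the class centroids)."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        scale = float(self.weights @ self.pooled_cov @ self.weights)
        if scale <= 0.0:
            # coincident class means (no discriminant axis) or cancellation
            # in a near-singular, ridge-stabilized covariance
            return np.zeros(scores.shape[0])
        return scores @ self.weights / np.sqrt(scale)

    def predict(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        z = scores @ self.weights
        z_ctrl = float(self.class_means[CONTROL] @ self.weights)
        z_oa = float(self.class_means[OA] @ self.weights)
        midpoint = 0.5 * (z_ctrl + z_oa)
        # z_oa > z_ctrl by construction of weights (unless degenerate)
        side = z - midpoint if z_oa >= z_ctrl else midpoint - z
        return np.where(side > 0, OA, CONTROL)


def fit_lda_on_scores(scores: np.ndarray, y) -> LDAonScores:
    """Functional alias for :meth:`LDAonScores.fit`."""
    return LDAonScores.fit(scores, y)


class PCALDA:
    """PCA-LDA classifier of patient fingerprints.

    Parameters
    ----------
    X : (n_samples, n_features) fingerprint matrix (one row per patient)
    y : class labels, "Control" or "OA"
    """

    def __init__(self, X: np.ndarray, y):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        self.y = _as_labels(y)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y must have equal length")

    def fit(self, n_pcs: int = 20) -> "PCALDAResults":
        """Truncate to ``n_pcs`` principal components, then fit the Fisher
        discriminant on the scores."""
        pca = fit_pca(self.X, n_pcs)
        scores = pca.transform(self.X)
        lda = LDAonScores.fit(scores, self.y)
        return PCALDAResults(self, pca, lda, n_pcs)


class PCALDAResults:
    """Fitted PCA-LDA model: estimates, diagnostics and summary."""

    def __init__(self, model: PCALDA, pca: PCA, lda: LDAonScores, n_pcs: int):
        self.model = model
        self._pca = pca
        self.lda = lda
        self.n_pcs = n_pcs

    # -- estimates ---------------------------------------------------------
    @property
    def center(self) -> np.ndarray:
        """Column-mean centering vector."""
        return self._pca.mean_

    @property
    def loadings(self) -> np.ndarray:
        """(n_features, n_pcs) orthonormal PC basis."""
        return self._pca.components_.T

    @property
    def explained_variance(self) -> np.ndarray:
        """Per-PC explained variance in percent, non-increasing."""
        return 100.0 * self._pca.explained_variance_ratio_

    @property
    def ld_weights(self) -> np.ndarray:
        """Discriminant weight per retained PC score."""
        return self.lda.weights

    # -- scores / prediction ----------------------------------------------
    def transform(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.model.X if X is None else np.asarray(X, dtype=float)
        return (X - self.center) @ self.loadings

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        return self.lda.predict(self.transform(X))

    # -- diagnostics -------------------------------------------------------
    def confusion(self) -> ConfusionCounts:
        """Resubstitution confusion counts on the training fingerprints."""
        return ConfusionCounts.from_predictions(self.model.y, self.predict())

    def quality(self) -> QualityReport:
        return quality_parameters(self.confusion())

    def mahalanobis_separation(self) -> "MahalanobisSeparation":
        return mahalanobis_separation(self.lda, self.transform(), self.model.y)

    def summary(self) -> str:
        q = self.quality().rounded()
        sep = self.mahalanobis_separation()
        ev = self.explained_variance
        lines = [
            "PCA-LDA results",
            "=" * 50,
            f"samples: {len(self.model.y)}   features: "
            f"{self.model.X.shape[1]}   PCs retained: {self.n_pcs}",
            f"cumulative explained variance: {ev.sum():.1f}%",
            f"discriminant ridge: {self.lda.ridge_applied:.3g}",
            "-" * 50,
            f"{'accuracy':>12} {'sensitivity':>12} {'specificity':>12} "
            f"{'f_score':>12}",
            f"{q.accuracy:>12.1f} {q.sensitivity:>12.1f} "
            f"{q.specificity:>12.1f} {q.f_score:>12.1f}",
            "-" * 50,
            f"Mahalanobis separation (mean)  : {sep.mean_difference:.4f}",
            f"Mahalanobis separation (median): {sep.median_difference:.4f}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class MahalanobisSeparation:
    """Per-sample Mahalanobis distances to each class centroid plus the
    separation summaries along the discriminant."""

    distances: dict[str, np.ndarray]
    mean_difference: float
    median_difference: float


def mahalanobis_separation(
    lda: LDAonScores, scores: np.ndarray, y
) -> MahalanobisSeparation:
    """Class segregation under the pooled within-class covariance.

    ``distances[c]`` holds every sample's Mahalanobis distance to the
    centroid of class ``c``. The summaries are the absolute difference of
    the class-wise means (and medians) of the discriminant coordinate,
    expressed in Mahalanobis units; for coincident centroids both are 0.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = _as_labels(y)
    k = scores.shape[1]
    cov = lda.pooled_cov  # already ridge-stabilized if the fit needed it
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.pinv(cov)
    distances = {}
    for c, mu in lda.class_means.items():
        d = scores - mu
        distances[c] = np.sqrt(np.einsum("ij,jk,ik->i", d, cov_inv, d))
    t = lda.discriminant(scores)
    t_ctrl, t_oa = t[y == CONTROL], t[y == OA]
    return MahalanobisSeparation(
        distances=distances,
        mean_difference=float(abs(t_oa.mean() - t_ctrl.mean())),
        median_difference=float(
            abs(np.median(t_oa) - np.median(t_ctrl))
        ),
    )


def resubstitution_quality(
    X: np.ndarray, y, n_pcs: int
) -> tuple[ConfusionCounts, QualityReport]:
    """Fit PCA-LDA on the full fingerprint set and classify the same set."""
    res = PCALDA(X, y).fit(n_pcs)
    counts = res.confusion()
    return counts, quality_parameters(counts)


# ---------------------------------------------------------------------------
# SVM with nested grid search
# ---------------------------------------------------------------------------

#: Coarse power-of-two grids spanning c in 2^-5..2^15, gamma in 2^-15..2^3.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SvmConfig:
    """Gaussian-kernel SVM settings: parameter grids and CV scheme.

    ``cv_scheme`` is "loo" or "kfold"; ``repeats`` averages accumulated
    counts over that many independently seeded k-fold partitions (ignored
    for LOO, whose splits carry no randomness).
    """

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_scheme: str = "loo"
    k: int = 3
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be non-empty")
        if any(v <= 0 for v in self.c_grid + self.gamma_grid):
            raise ValueError("c and gamma must be positive")
        if self.cv_scheme not in ("loo", "kfold"):
            raise ValueError("cv_scheme must be 'loo' or 'kfold'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _grid_search(
    X: np.ndarray, y: np.ndarray, config: SvmConfig, seed: int
) -> tuple[float, float]:
    """Pick (c, gamma) by inner stratified 3-fold accuracy on the training
    portion only; ties resolve to the smallest c, then smallest gamma."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(3, counts.min()))
    if n_splits < 2:
        # too few samples per class for an inner split: fall back to the
        # grid's first entries
        return config.c_grid[0], config.gamma_grid[0]
    inner = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(inner.split(X, y))
    best = (-1.0, config.c_grid[0], config.gamma_grid[0])
    for c in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            hits = 0
            total = 0
            for tr, te in splits:
                clf = SVC(C=c, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                hits += int(np.sum(clf.predict(X[te]) == y[te]))
                total += len(te)
            acc = hits / total
            if acc > best[0]:  # strict: earlier (smaller) c, gamma win ties
                best = (acc, c, gamma)
    return best[1], best[2]


@dataclass
class SVMCVResults:
    """Accumulated-hit confusion counts over all CV test folds."""

    counts: ConfusionCounts
    quality: QualityReport
    rates: np.ndarray
    chosen_params: list[tuple[float, float]]
    config: SvmConfig

    def summary(self) -> str:
        q = self.quality.rounded()
        scheme = (
            "leave-one-out"
            if self.config.cv_scheme == "loo"
            else f"{self.config.k}-fold x{self.config.repeats}"
        )
        r = self.rates
        return "\n".join(
            [
                f"SVM (Gaussian kernel), {scheme} cross-validation",
                "=" * 50,
                f"accumulated counts: TP={self.counts.tp} TN={self.counts.tn}"
                f" FP={self.counts.fp} FN={self.counts.fn}",
                "rates (%, rows true Control/OA, cols pred Control/OA):",
                f"  Control: {r[0, 0]:6.1f} {r[0, 1]:6.1f}",
                f"  OA     : {r[1, 0]:6.1f} {r[1, 1]:6.1f}",
                "-" * 50,
                f"{'accuracy':>12} {'sensitivity':>12} {'specificity':>12} "
                f"{'f_score':>12}",
                f"{q.accuracy:>12.1f} {q.sensitivity:>12.1f} "
                f"{q.specificity:>12.1f} {q.f_score:>12.1f}",
            ]
        )


class SpectromicsSVM:
    """Gaussian-kernel SVM over patient fingerprints with nested CV.

    For every outer split the regularization constant c and kernel width
    gamma are chosen by an inner stratified 3-fold grid search on the
    training portion only, so model training never sees the test subset.
    Test predictions are accumulated across splits into a single confusion
    matrix before quality parameters are computed.
    """

    def __init__(self, X: np.ndarray, y, config: SvmConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = _as_labels(y)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.config = config or SvmConfig()
        _, counts = np.unique(self.y, return_counts=True)
        if counts.min() < 2 or len(counts) < 2:
            raise ValueError("need at least 2 samples in each class")

    def cross_validate(self) -> SVMCVResults:
        cfg = self.config
        if cfg.cv_scheme == "loo":
            partitions = [list(LeaveOneOut().split(self.X))]
        else:
            _, counts = np.unique(self.y, return_counts=True)
            if counts.min() < cfg.k:
                raise ValueError(
                    f"a {cfg.k}-fold split would leave a fold without one "
                    "class; use stratification-compatible k or LOO"
                )
            partitions = [
                list(
                    StratifiedKFold(
                        n_splits=cfg.k, shuffle=True,
                        random_state=cfg.seed + rep,
                    ).split(self.X, self.y)
                )
                for rep in range(cfg.repeats)
            ]

        total = ConfusionCounts()
        chosen: list[tuple[float, float]] = []
        for rep, splits in enumerate(partitions):
            for i, (tr, te) in enumerate(splits):
                c, gamma = _grid_search(
                    self.X[tr], self.y[tr], cfg,
                    seed=cfg.seed + 1000 * rep + i,
                )
                chosen.append((c, gamma))
                clf = SVC(C=c, gamma=gamma, kernel="rbf")
                clf.fit(self.X[tr], self.y[tr])
                pred = clf.predict(self.X[te])
                total = total + ConfusionCounts.from_predictions(
                    self.y[te], pred
                )
        return SVMCVResults(
            counts=total,
            quality=quality_parameters(total),
            rates=total.rates(),
            chosen_params=chosen,
            config=cfg,
        )


def svm_cross_validate(
    X: np.ndarray, y, config: SvmConfig | None = None
) -> SVMCVResults:
    """Functional alias for ``SpectromicsSVM(X, y, config).cross_validate()``."""
    return SpectromicsSVM(X, y, config).cross_validate()
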