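"""Gender modelling: Fisher LDA, greedy feature selection, masculinity score.

The model stack mirrors a sex-classification approach widely used in
facial-morphometrics studies: a wrapper feature search ("GEFS-style"
greedy forward selection scored by cross-validated accuracy) picks the
most sex-discriminating of the 52 distances, a two-class Fisher linear
discriminant is fitted on the selected features, and each face receives a
*masculinity score*: its signed projection distance from the midpoint of
the two class means on the discriminant axis, min-max scaled over the
training sample to [0, 1] (0 = most feminine, 1 = most masculine face in
the sample).

All estimators follow scikit-learn conventions (``fit``, ``predict``,
``get_params``; fitted attributes end in ``_``) and compose with sklearn
model selection.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class FisherLDA(BaseEstimator, ClassifierMixin):
    """Two-class Fisher linear discriminant.

    The axis is the classical solution ``w = Sw^-1 (mu_pos - mu_neg)``
    with ``Sw`` the pooled within-class covariance; classification is by
    nearest projected class mean.  If ``Sw`` is singular the solve is
    retried with a small ridge and a warning is logged.

    Parameters
    ----------
    positive_class:
        Label projected on the positive side of the axis (defaults to the
        lexicographically last class, so "male" beats "female").
    ridge:
        Relative ridge used in the singular-covariance retry.
    """

    def __init__(self, positive_class=None, ridge: float = 1e-8):
        self.positive_class = positive_class
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(_as_frame(X), dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"FisherLDA requires exactly 2 classes, got {list(classes)}"
            )
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        if pos not in classes:
            raise ValueError(f"positive_class {pos!r} not among {list(classes)}")
        neg = classes[classes != pos][0]
        Xp, Xn = X[y == pos], X[y == neg]
        if len(Xp) < 2 or len(Xn) < 2:
            raise ValueError("each class needs at least 2 samples")
        mu_p = Xp.mean(axis=0)
        mu_n = Xn.mean(axis=0)
        scatter = ((Xp - mu_p).T @ (Xp - mu_p)
                   + (Xn - mu_n).T @ (Xn - mu_n))
        Sw = scatter / (len(X) - 2)
        diff = mu_p - mu_n
        try:
            w = np.linalg.solve(Sw, diff)
            if not np.all(np.isfinite(w)):
                raise np.linalg.LinAlgError("non-finite solution")
            # guard against a numerically singular (but invertible) solve
            if np.linalg.cond(Sw) > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned covariance")
        except np.linalg.LinAlgError:
            lam = self.ridge * (np.trace(Sw) / len(Sw) + 1.0)
            log.warning(
                "pooled covariance singular; retrying with ridge %.3g", lam
            )
            w = np.linalg.solve(Sw + lam * np.eye(len(Sw)), diff)

        self.classes_ = np.array([neg, pos])
        self.positive_class_ = pos
        self.coef_ = w
        self.mean_pos_ = float(mu_p @ w)
        self.mean_neg_ = float(mu_n @ w)
        self.midpoint_ = 0.5 * (self.mean_pos_ + self.mean_neg_)
        self.n_features_in_ = X.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(_as_frame(X), dtype=float)
        return X @ self.coef_ - self.midpoint_

    def predict(self, X):
        d = self.decision_function(X)
        neg, pos = self.classes_
        return np.where(d >= 0, pos, neg)


def cv_accuracy(estimator, X: pd.DataFrame, y, k: int = 10,
                seed: int = 0, folds=None) -> float:
    """Mean held-out accuracy under seeded stratified k-fold CV."""
    X = _as_frame(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k}"
        )
    if folds is None:
        folds = list(
            StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            .split(X, y)
        )
    accs = []
    Xv = X.to_numpy(dtype=float)
    for tr, te in folds:
        est = clone(estimator)
        est.fit(Xv[tr], y[tr])
        accs.append(float(np.mean(est.predict(Xv[te]) == y[te])))
    return float(np.mean(accs))


class GreedyForwardSelector(BaseEstimator):
    """Wrapper feature selection maximising cross-validated accuracy.

    Starting from the empty set, the candidate whose addition yields the
    highest CV accuracy is appended; selection stops when no candidate
    improves accuracy by more than ``tol`` or ``max_features`` is
    reached.  Ties are broken by the larger absolute standardised mean
    class difference, then lexicographic feature name, so fits are fully
    deterministic given the seed.

    With ``exhaustive=True`` (feasible up to ~12 features) every
    non-empty subset is scored instead and the best is returned; this
    serves as the reference optimum for the greedy search.
    """

    def __init__(self, estimator=None, max_features: int | None = None,
                 k: int = 10, seed: int = 0, tol: float = 0.01,
                 n_repeats: int = 3, exhaustive: bool = False):
        self.estimator = estimator
        self.max_features = max_features
        self.k = k
        self.seed = seed
        self.tol = tol
        self.n_repeats = n_repeats
        self.exhaustive = exhaustive

    def _standardized_gap(self, X: pd.DataFrame, y) -> pd.Series:
        classes = np.unique(y)
        a = X[y == classes[0]]
        b = X[y == classes[1]]
        na, nb = len(a), len(b)
        pooled = np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
            / (na + nb - 2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            gap = (b.mean() - a.mean()).abs() / pooled
        return gap.fillna(0.0)

    def fit(self, X, y):
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        X = _as_frame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 candidate features")
        y = np.asarray(y)
        base = self.estimator if self.estimator is not None else FisherLDA()
        # repeated CV: averaging over several fold splits damps the
        # fold-overfitting of the max over candidates
        folds = []
        for rep in range(max(1, self.n_repeats)):
            folds.extend(
                StratifiedKFold(n_splits=self.k, shuffle=True,
                                random_state=self.seed + 997 * rep)
                .split(X, y)
            )
        names = list(X.columns)
        gaps = self._standardized_gap(X, y)

        def score(subset: list[str]) -> float:
            return cv_accuracy(base, X[subset], y, folds=folds)

        if self.exhaustive:
            if X.shape[1] > 12:
                raise ValueError("exhaustive search limited to 12 features")
            best_subset, best_acc = None, -np.inf
            max_size = self.max_features or X.shape[1]
            for size in range(1, max_size + 1):
                for comb in itertools.combinations(sorted(names), size):
                    acc = score(list(comb))
                    if acc > best_acc + 1e-12:
                        best_subset, best_acc = list(comb), acc
            self.selected_features_ = best_subset
            self.cv_accuracy_ = best_acc
            self.accuracy_path_ = [best_acc]
            return self

        selected: list[str] = []
        acc_path: list[float] = []
        current = -np.inf
        limit = self.max_features or X.shape[1]
        while len(selected) < limit:
            remaining = [f for f in names if f not in selected]
            if not remaining:
                break
            scores = {f: score(selected + [f]) for f in remaining}
            best = max(
                remaining,
                key=lambda f: (scores[f], gaps[f], _neg_lex(f)),
            )
            if scores[best] <= (current + self.tol if selected else -np.inf):
                break
            selected.append(best)
            current = scores[best]
            acc_path.append(current)
        self.selected_features_ = selected
        self.cv_accuracy_ = current
        self.accuracy_path_ = acc_path
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return _as_frame(X)[self.selected_features_]


class _neg_lex(str):
    """Reverse lexicographic ordering helper for max()-based tie-breaks."""

    def __lt__(self, other):  # max() prefers the lexicographically smaller
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


class GenderMasculinityModel(BaseEstimator, TransformerMixin):
    """Full gender model: selection + Fisher LDA + masculinity scoring.

    ``fit`` runs feature selection (unless ``feature_subset`` pins the
    features), fits the discriminant on the whole training sample (the
    same sample is then scored; cross-validation is used only to report
    classifier accuracy), and freezes the score scaling: the training
    minimum and maximum of the signed projection distance from the
    class-mean midpoint map to 0 and 1.  Out-of-sample scores are clipped
    into [0, 1] with a logged flag.

    Fitted attributes
    -----------------
    selected_features_ : ordered list of feature names
    lda_ : the fitted :class:`FisherLDA`
    cv_accuracy_ : stratified k-fold CV accuracy on the selected features
    scale_bounds_ : (min, max) signed projection over the training sample
    """

    def __init__(self, feature_subset: list[str] | None = None,
                 max_features: int | None = 10, k: int = 10, seed: int = 0,
                 tol: float = 1e-6, positive_class: str = "male"):
        self.feature_subset = feature_subset
        self.max_features = max_features
        self.k = k
        self.seed = seed
        self.tol = tol
        self.positive_class = positive_class

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if self.feature_subset is not None:
            missing = [f for f in self.feature_subset if f not in X.columns]
            if missing:
                raise ValueError(f"features not in table: {missing}")
            self.selected_features_ = list(self.feature_subset)
        else:
            sel = GreedyForwardSelector(
                FisherLDA(positive_class=self.positive_class),
                max_features=self.max_features, k=self.k, seed=self.seed,
                tol=self.tol,
            ).fit(X, y)
            self.selected_features_ = sel.selected_features_
        Xs = X[self.selected_features_]
        self.lda_ = FisherLDA(positive_class=self.positive_class).fit(Xs, y)
        self.cv_accuracy_ = cv_accuracy(
            FisherLDA(positive_class=self.positive_class), Xs, y,
            k=self.k, seed=self.seed,
        )
        proj = self.lda_.decision_function(Xs)
        lo, hi = float(proj.min()), float(proj.max())
        if not lo < hi:
            raise ValueError("degenerate projection: all faces identical")
        self.scale_bounds_ = (lo, hi)
        self.classes_ = self.lda_.classes_
        return self

    # -- scoring -----------------------------------------------------------

    def masculinity_score(self, X) -> np.ndarray:
        """Scores in [0, 1]; training min/max map exactly to 0/1."""
        check_is_fitted(self, "lda_")
        X = _as_frame(X)
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise ValueError(f"missing selected feature(s): {missing}")
        proj = self.lda_.decision_function(X[self.selected_features_])
        lo, hi = self.scale_bounds_
        raw = (proj - lo) / (hi - lo)
        n_out = int(np.sum((raw < 0) | (raw > 1)))
        if n_out:
            log.info("clipped %d out-of-sample masculinity score(s)", n_out)
        return np.clip(raw, 0.0, 1.0)

    def transform(self, X) -> np.ndarray:
        return self.masculinity_score(X)[:, None]

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(_as_frame(X)[self.selected_features_])

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "lda_")
        payload = {
            "selected_features": self.selected_features_,
            "weights": [float(v) for v in self.lda_.coef_],
            "class_means": {
                str(self.lda_.classes_[1]): self.lda_.mean_pos_,
                str(self.lda_.classes_[0]): self.lda_.mean_neg_,
            },
            "midpoint": self.lda_.midpoint_,
            "scale_bounds": list(self.scale_bounds_),
            "cv_accuracy": self.cv_accuracy_,
            "k": self.k,
            "seed": self.seed,
            "positive_class": self.positive_class,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GenderMasculinityModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        model = cls(
            feature_subset=payload["selected_features"],
            k=payload["k"], seed=payload["seed"],
            positive_class=payload["positive_class"],
        )
        model.selected_features_ = payload["selected_features"]
        lda = FisherLDA(positive_class=payload["positive_class"])
        lda.coef_ = np.asarray(payload["weights"], dtype=float)
        means = payload["class_means"]
        pos = payload["positive_class"]
        neg = [c for c in means if c != pos][0]
        lda.mean_pos_ = float(means[pos])
        lda.mean_neg_ = float(means[neg])
        lda.midpoint_ = float(payload["midpoint"])
        lda.classes_ = np.array([neg, pos])
        lda.positive_class_ = pos
        lda.n_features_in_ = len(payload["weights"])
        model.lda_ = lda
        model.scale_bounds_ = tuple(payload["scale_bounds"])
        model.cv_accuracy_ = payload["cv_accuracy"]
        model.classes_ = lda.classes_
        return model


# -- thin functional wrappers ---------------------------------------------

def fit_lda(features, sex_labels, feature_subset=None) -> FisherLDA:
    """Fit a Fisher discriminant, optionally on a feature subset."""
    X = _as_frame(features)
    if feature_subset is not None:
        X = X[list(feature_subset)]
    return FisherLDA().fit(X, sex_labels)


def cross_validate(features, sex_labels, feature_subset=None, k: int = 10,
                   seed: int = 0) -> float:
    """Stratified k-fold CV accuracy of the Fisher discriminant."""
    X = _as_frame(features)
    if feature_subset is not None:
        X = X[list(feature_subset)]
    return cv_accuracy(FisherLDA(), X, sex_labels, k=k, seed=seed)


def gefs_select(features, sex_labels, max_features: int | None = None,
                seed: int = 0, k: int = 10) -> list[str]:
    """Greedy forward selection; returns the ordered selected features."""
    sel = GreedyForwardSelector(
        max_features=max_features, seed=seed, k=k
    ).fit(_as_frame(features), sex_labels)
    return sel.selected_features_


def masculinity_score(model: GenderMasculinityModel, feature_vector):
    """Score one subject (mapping/Series of features) with a fitted model."""
    if isinstance(feature_vector, pd.DataFrame):
        return model.masculinity_score(feature_vector)
    row = pd.DataFrame([pd.Series(feature_vector)])
    return float(model.masculinity_score(row)[0])
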